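"""Synthetic data with known ground truth for every pipeline stage.

Generative model for Ct matrices::

    Ct[i, g, j, r] = B_i + L_gj + delta_ig + eps_igjr

with gene baseline B_i, a loading effect L_gj ~ N(0, tau^2) shared by all
genes of a biological unit, a fixed per-group regulation effect delta_ig,
and gene noise eps ~ N(0, sigma_i^2) drawn per replicate.  The true
instability of a gene is sqrt(sigma_i^2 + Var_g(delta_ig)).

Also simulates serial-dilution Ct series with a known amplification
efficiency and two-library screening tables with a known per-family
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CtMatrix
from .screening import ScreeningRecord

__all__ = [
    "GeneSpec", "SimConfig", "SimTruth", "simulate_ct",
    "simulate_dilution_series", "simulate_screening_table",
    "paper_scale_configs", "default_gene_specs",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth behaviour of one simulated gene."""

    name: str
    baseline: float                  # cycles
    sigma: float = 0.2               # gene-noise SD in cycles
    group_effects: dict[str, float] = field(default_factory=dict)  # cycles

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SimulationError(f"sigma must be >= 0 for {self.name!r}")


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated sample set.

    ``groups`` maps group label -> number of biological units; every unit
    gets ``replicates`` technical/biological replicate wells.
    """

    genes: tuple[GeneSpec, ...]
    groups: dict[str, int]
    replicates: int = 1
    loading_sd: float = 0.0          # tau, cycles
    set_name: str = "set"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise SimulationError("no gene specs")
        if not self.groups or any(n < 1 for n in self.groups.values()):
            raise SimulationError("every group needs >=1 biological unit")
        if self.replicates < 1:
            raise SimulationError("replicates must be >=1")
        if self.loading_sd < 0:
            raise SimulationError("loading SD must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Known instability scores and the implied stability order."""

    instability: dict[str, float]
    order: tuple[str, ...]           # most stable first


def _true_instability(spec: GeneSpec, groups: list[str]) -> float:
    deltas = np.array([spec.group_effects.get(g, 0.0) for g in groups])
    return math.sqrt(spec.sigma ** 2 + float(np.var(deltas)))


def simulate_ct(config: SimConfig) -> tuple[CtMatrix, SimTruth]:
    """Draw a Ct matrix from the generative model; fully seeded."""
    rng = np.random.default_rng(config.seed)
    genes = [g.name for g in config.genes]
    group_names = list(config.groups)

    samples: list[str] = []
    meta_rows = []
    cols: list[np.ndarray] = []
    for gname, n_units in config.groups.items():
        for j in range(1, n_units + 1):
            loading = rng.normal(0.0, config.loading_sd) if config.loading_sd else 0.0
            for r in range(1, config.replicates + 1):
                ct_col = np.array([
                    spec.baseline + loading + spec.group_effects.get(gname, 0.0)
                    + (rng.normal(0.0, spec.sigma) if spec.sigma else 0.0)
                    for spec in config.genes
                ])
                sid = f"{gname}_{j}" + (f"_r{r}" if config.replicates > 1 else "")
                samples.append(sid)
                cols.append(ct_col)
                meta_rows.append({
                    "sample_id": sid, "set": config.set_name, "group": gname,
                    "unit": f"{gname}_{j}", "tissue": pd.NA, "time": pd.NA,
                    "replicate": r,
                })
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = CtMatrix(genes=genes, samples=samples,
                      ct=np.column_stack(cols), meta=meta)
    instab = {g.name: _true_instability(g, group_names) for g in config.genes}
    order = tuple(sorted(instab, key=lambda g: (instab[g], g)))
    return matrix, SimTruth(instability=instab, order=order)


def simulate_dilution_series(
    true_e: float,
    sigma_ct: float,
    n_dilutions: int = 5,
    replicates: int = 3,
    seed: int | None = None,
    fold: float = 5.0,
    intercept: float = 20.0,
    gene: str = "gene",
) -> pd.DataFrame:
    """Serial-dilution Ct table with a known amplification efficiency.

    Noise-free Ct at relative amount d is
    ``intercept - log10(d) / log10(1 + true_e)`` (one cycle per
    (1+E)-fold dilution); Gaussian noise of ``sigma_ct`` cycles is added
    per replicate well.  Columns match :func:`refstab.primer_qc.read_dilution_table`.
    """
    if not (0.5 <= true_e <= 1.5):
        raise SimulationError("true efficiency outside plausible range [0.5, 1.5]")
    if n_dilutions < 3:
        raise SimulationError("need >=3 dilutions for a fit")
    rng = np.random.default_rng(seed)
    slope = -1.0 / math.log10(1.0 + true_e)
    rows = []
    for step in range(n_dilutions):
        d = fold ** (-step)
        base_ct = intercept + slope * math.log10(d)
        for _ in range(replicates):
            noise = rng.normal(0.0, sigma_ct) if sigma_ct else 0.0
            rows.append({"gene": gene, "dilution": d, "ct": base_ct + noise})
    return pd.DataFrame(rows)


def simulate_screening_table(
    n_families: int,
    per_family: int,
    seed: int | None = None,
) -> tuple[list[ScreeningRecord], dict[str, str | None]]:
    """Two-library screening records with a known per-family answer.

    FPKM pairs are log-normal with log2 ratios spanning both sides of the
    significance threshold.  Returns the records plus the expected
    selection per family (``None`` when every member is filtered out).
    """
    if n_families < 1 or per_family < 1:
        raise SimulationError("need >=1 family with >=1 member")
    rng = np.random.default_rng(seed)
    records: list[ScreeningRecord] = []
    truth: dict[str, str | None] = {}
    for f in range(1, n_families + 1):
        fam = f"fam{f:02d}"
        best_id, best_abs = None, math.inf
        for u in range(1, per_family + 1):
            a = float(np.exp(rng.normal(3.0, 1.0)))
            # half the members drawn clearly past the threshold
            ratio = rng.normal(0.0, 0.6) if rng.random() < 0.5 \
                else rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 3.0)
            b = a * 2.0 ** ratio
            gid = f"{fam}_u{u:02d}"
            records.append(ScreeningRecord(
                family=fam, gene_id=gid,
                length=int(rng.integers(300, 3000)), a_fpkm=a, b_fpkm=b,
            ))
            if abs(ratio) < 1.0 and abs(ratio) < best_abs:
                best_id, best_abs = gid, abs(ratio)
        truth[fam] = best_id
    return records, truth


# ---------------------------------------------------------------------------
# Study-scale default designs
# ---------------------------------------------------------------------------

def default_gene_specs(
    sigmas: list[float] | None = None,
    group_effects: dict[str, dict[str, float]] | None = None,
) -> tuple[GeneSpec, ...]:
    """Ten genes with staggered baselines (20-30 cycles) and given noise SDs."""
    names = [f"G{i:02d}" for i in range(1, 11)]
    if sigmas is None:
        sigmas = [0.2] * 10
    if len(sigmas) != len(names):
        raise SimulationError("need one sigma per gene")
    effects = group_effects or {}
    return tuple(
        GeneSpec(name=n, baseline=20.0 + i, sigma=s,
                 group_effects=effects.get(n, {}))
        for i, (n, s) in enumerate(zip(names, sigmas))
    )


def paper_scale_configs(
    seed: int,
    sigma: float = 0.2,
    loading_sd: float = 0.5,
    genes: tuple[GeneSpec, ...] | None = None,
) -> dict[str, SimConfig]:
    """Five sample-set designs at the scale of the motivating study.

    cultivars: 6 groups x 3 replicates; organs: 7 single samples;
    three stress sets: stress x time-point units, two tissues, 3 replicates.
    """
    if genes is None:
        genes = default_gene_specs(sigmas=[sigma] * 10)
    stresses = ["salt", "alkali", "drought"]
    n_time = 5
    cfgs = {
        "cultivars": SimConfig(
            genes=genes, groups={f"cv{i}": 1 for i in range(1, 7)},
            replicates=3, loading_sd=loading_sd, set_name="cultivars",
            seed=seed),
        "organs": SimConfig(
            genes=genes,
            groups={o: 1 for o in ["root", "stem", "leaf", "flower",
                                   "fruit_w", "fruit_r", "seed"]},
            replicates=3, loading_sd=loading_sd, set_name="organs",
            seed=seed + 1),
    }
    for t, tissue in enumerate(["leaf", "root"]):
        cfgs[f"stress_{tissue}"] = SimConfig(
            genes=genes, groups={s: n_time for s in stresses},
            replicates=3, loading_sd=loading_sd,
            set_name=f"stress_{tissue}", seed=seed + 2 + t)
    cfgs["stress_total"] = SimConfig(
        genes=genes,
        groups={f"{s}_{tis}": n_time for s in stresses
                for tis in ["leaf", "root"]},
        replicates=3, loading_sd=loading_sd, set_name="stress_total",
        seed=seed + 4)
    return cfgs
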