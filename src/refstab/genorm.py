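"""geNorm-style stability analysis.

Relative quantities Q = base^(Ct_min - Ct), pairwise variation V_jk
(SD of log2 Q-ratios over samples), per-gene average pairwise variation M,
stepwise exclusion ranking, per-sample normalization factors and the
V_n/n+1 series that decides how many reference genes are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CtMatrix

__all__ = [
    "QMatrix", "GenormResult", "relative_quantities", "gene_pair_variation",
    "m_values", "single_pass_ranking", "stepwise_ranking", "pairwise_variation_nf",
    "genorm",
]

DEFAULT_V_THRESHOLD = 0.15
DEFAULT_M_CUTOFF = 1.5


class GenormError(ValueError):
    pass


@dataclass
class QMatrix:
    """Genes x samples relative quantities in (0, 1], row maximum 1."""

    genes: list[str]
    samples: list[str]
    q: np.ndarray

    def row(self, gene: str) -> np.ndarray:
        return self.q[self.genes.index(gene)]


@dataclass
class GenormResult:
    """Output of the full geNorm procedure on one sample set."""

    genes: list[str]
    m_single_pass: dict[str, float]
    m_at_removal: dict[str, float]
    exclusion_order: list[str]        # least stable first; final pair last
    stepwise_trajectory: list[tuple[tuple[str, ...], dict[str, float]]]
    best_pair: tuple[str, str]
    best_pair_m: float
    v_series: dict[int, float] = field(default_factory=dict)  # n -> V_n/n+1
    recommended_n: int | None = None
    m_cutoff: float = DEFAULT_M_CUTOFF

    def ranking(self, mode: str = "single_pass") -> dict[str, int]:
        """Gene -> rank (1 = most stable).

        ``single_pass``: distinct ranks by M computed once on the full panel.
        ``stepwise``: competition ranking from the exclusion order with the
        final pair tied at rank 1 (next gene gets rank 3).
        """
        if mode == "single_pass":
            order = sorted(self.genes, key=lambda g: (self.m_single_pass[g], g))
            return {g: i + 1 for i, g in enumerate(order)}
        if mode == "stepwise":
            ranks: dict[str, int] = {}
            stability_order = list(reversed(self.exclusion_order))
            for i, g in enumerate(stability_order):
                ranks[g] = 1 if i < 2 else i + 1
            return ranks
        raise GenormError(f"unknown ranking mode {mode!r}")

    def flagged_unstable(self) -> list[str]:
        return [g for g, m in self.m_single_pass.items() if m > self.m_cutoff]


def relative_quantities(m: CtMatrix, base: float | dict[str, float] = 2.0) -> QMatrix:
    """Transform Ct to relative quantities Q = base^(row min Ct - Ct).

    ``base`` is 2 for the ideal-doubling assumption, or 1+E per gene when
    efficiency correction is wanted (pass a gene -> base mapping).
    """
    q = np.empty_like(m.ct)
    for i, g in enumerate(m.genes):
        b = base[g] if isinstance(base, dict) else base
        if b <= 1.0:
            raise GenormError(f"transformation base must exceed 1, got {b} for {g!r}")
        q[i] = np.power(b, m.ct[i].min() - m.ct[i])
    return QMatrix(genes=list(m.genes), samples=list(m.samples), q=q)


def gene_pair_variation(qj: np.ndarray, qk: np.ndarray) -> float:
    """V_jk: sample SD (n-1) of log2(Q_j / Q_k) across samples."""
    qj = np.asarray(qj, float)
    qk = np.asarray(qk, float)
    if qj.shape != qk.shape or qj.ndim != 1:
        raise GenormError("gene rows must be 1-D and equally long")
    if qj.size < 2:
        raise GenormError("need >=2 samples for pairwise variation")
    return float(np.std(np.log2(qj / qk), ddof=1))


def _v_matrix(q: np.ndarray) -> np.ndarray:
    """Full symmetric matrix of pairwise variations for a Q block."""
    logq = np.log2(q)
    n = q.shape[0]
    v = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            v[j, k] = v[k, j] = float(np.std(logq[j] - logq[k], ddof=1))
    return v


def m_values(q: QMatrix, subset: list[str] | None = None) -> dict[str, float]:
    """M_j = mean pairwise variation of gene j with every other panel gene."""
    genes = list(q.genes) if subset is None else list(subset)
    if len(genes) < 2:
        raise GenormError("need >=2 genes for M values")
    idx = [q.genes.index(g) for g in genes]
    v = _v_matrix(q.q[idx])
    n = len(genes)
    return {g: float(v[j].sum() / (n - 1)) for j, g in enumerate(genes)}


def single_pass_ranking(q: QMatrix) -> dict[str, float]:
    """M computed once on the full panel, no removal."""
    return m_values(q)


def stepwise_ranking(q: QMatrix, m_cutoff: float = DEFAULT_M_CUTOFF) -> GenormResult:
    """Iteratively remove the least stable gene until two remain.

    At each step M is recomputed on the surviving subset and the gene with
    the highest M is removed (ties broken toward the gene appearing later
    in the panel order, deterministically).  The final two genes cannot be
    separated by the method and tie as most stable.
    """
    if len(q.genes) < 3:
        raise GenormError("stepwise ranking needs >=3 genes")
    current = list(q.genes)
    m_single = m_values(q, current)
    exclusion: list[str] = []
    m_at_removal: dict[str, float] = {}
    trajectory: list[tuple[tuple[str, ...], dict[str, float]]] = []
    while len(current) > 2:
        ms = m_values(q, current)
        trajectory.append((tuple(current), ms))
        worst_m = max(ms.values())
        # later panel position wins ties
        worst = max((g for g in current if ms[g] == worst_m), key=q.genes.index)
        exclusion.append(worst)
        m_at_removal[worst] = ms[worst]
        current.remove(worst)
    final_ms = m_values(q, current)
    trajectory.append((tuple(current), final_ms))
    pair_m = final_ms[current[0]]  # both equal V of the pair
    for g in current:
        m_at_removal[g] = final_ms[g]
    exclusion.extend(current)
    return GenormResult(
        genes=list(q.genes),
        m_single_pass=m_single,
        m_at_removal=m_at_removal,
        exclusion_order=exclusion,
        stepwise_trajectory=trajectory,
        best_pair=(current[0], current[1]),
        best_pair_m=pair_m,
        m_cutoff=m_cutoff,
    )


def normalization_factors(q: QMatrix, genes: list[str]) -> np.ndarray:
    """NF per sample: geometric mean of Q over the given genes."""
    idx = [q.genes.index(g) for g in genes]
    return np.exp(np.mean(np.log(q.q[idx]), axis=0))


def pairwise_variation_nf(
    q: QMatrix,
    result: GenormResult,
    threshold: float = DEFAULT_V_THRESHOLD,
) -> GenormResult:
    """Fill in the V_n/n+1 series and recommended reference-gene count.

    For n = 2..G-1, V_n/n+1 is the sample SD of log2(NF_n / NF_{n+1}),
    where NF_n uses the n most stable genes of the stepwise ranking.  The
    recommended n is the smallest with V_n/n+1 < threshold; when no V drops
    below the threshold the recommendation stays ``None`` and the 2-3 most
    stable genes should be chosen from the V trend.
    """
    if len(q.genes) < 3:
        raise GenormError("pairwise variation needs >=3 genes")
    stability_order = list(reversed(result.exclusion_order))  # most stable first
    v_series: dict[int, float] = {}
    for n in range(2, len(stability_order)):
        nf_n = normalization_factors(q, stability_order[:n])
        nf_n1 = normalization_factors(q, stability_order[:n + 1])
        v_series[n] = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
    recommended = None
    for n in sorted(v_series):
        if v_series[n] < threshold:
            recommended = n
            break
    result.v_series = v_series
    result.recommended_n = recommended
    return result


def genorm(
    m: CtMatrix,
    base: float | dict[str, float] = 2.0,
    threshold: float = DEFAULT_V_THRESHOLD,
    m_cutoff: float = DEFAULT_M_CUTOFF,
) -> GenormResult:
    """Full geNorm pipeline on a Ct matrix."""
    q = relative_quantities(m, base=base)
    result = stepwise_ranking(q, m_cutoff=m_cutoff)
    return pairwise_variation_nf(q, result, threshold=threshold)


def genorm_frame(result: GenormResult) -> pd.DataFrame:
    """Per-gene table: single-pass M, M at removal, exclusion rank."""
    ranks = result.ranking("single_pass")
    step = result.ranking("stepwise")
    rows = [{
        "gene": g,
        "m_single_pass": result.m_single_pass[g],
        "m_at_removal": result.m_at_removal[g],
        "rank_single_pass": ranks[g],
        "rank_stepwise": step[g],
    } for g in result.genes]
    return pd.DataFrame(rows).set_index("gene")
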