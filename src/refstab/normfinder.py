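"""Model-based stability analysis (NormFinder-style).

Works on sample-centered log2 expression.  In grouped mode the per-gene
variation is decomposed into intra-group variance and inter-group
differences; the inter-group differences are shrunk toward zero by their
estimated sampling variance before being combined with the intra-group
term into a single stability value S (lower = more stable).  Ungrouped
mode reduces to the bias-corrected within-set SD of the centered signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import CtMatrix, SampleSet

__all__ = ["NormfinderResult", "normfinder_stability"]

log = logging.getLogger(__name__)


class NormfinderError(ValueError):
    pass


@dataclass
class NormfinderResult:
    genes: list[str]
    stability: dict[str, float]                  # gene -> S
    grouped: bool
    group_names: list[str] = field(default_factory=list)
    intra_var: dict[str, dict[str, float]] = field(default_factory=dict)
    group_diff: dict[str, dict[str, float]] = field(default_factory=dict)
    group_diff_shrunk: dict[str, dict[str, float]] = field(default_factory=dict)
    inter_group_var: float = 0.0                 # gamma^2 estimate
    best_pair: tuple[str, str] | None = None
    best_pair_stability: float | None = None

    def ranking(self) -> dict[str, int]:
        """Gene -> rank, ascending by S (ties broken by gene label)."""
        order = sorted(self.genes, key=lambda g: (self.stability[g], g))
        return {g: i + 1 for i, g in enumerate(order)}


def _centered_log_expression(m: CtMatrix) -> np.ndarray:
    """log2 relative quantity, centered per sample over genes.

    y = -Ct is log2 quantity up to per-gene constants; those constants
    cancel in every downstream quantity (variances and group contrasts),
    so -Ct is used directly.
    """
    y = -m.ct
    return y - y.mean(axis=0, keepdims=True)


def _corrected_variances(gamma_hat: np.ndarray, k: int) -> np.ndarray:
    """Undo the bias that sample-centering over k genes puts on per-gene
    within-group variances.

    For the raw within-group variance g_i of the centered signal,
    E[g_i] = s2_i (1 - 2/k) + (sum s2) / k^2; solving the system gives
    s2_i = k/(k-2) * (g_i - sum(g) / (k (k-1))).  Negative solutions are
    clamped to zero.
    """
    total = gamma_hat.sum()
    s2 = (gamma_hat - total / (k * (k - 1))) * k / (k - 2)
    neg = s2 < 0
    if neg.any():
        log.warning("clamping %d negative variance estimates to 0", int(neg.sum()))
        s2 = np.where(neg, 0.0, s2)
    return s2


def normfinder_stability(
    m: CtMatrix,
    groups: SampleSet | dict[str, list[str]] | None = None,
    simplified: bool = False,
) -> NormfinderResult:
    """Compute per-gene stability values, grouped or ungrouped.

    ``groups`` maps group label -> member sample ids (or a
    :class:`~refstab.core.SampleSet` carrying a partition).  Every group
    needs >=2 samples and the panel >=3 genes.  With ``simplified=True``
    the shrinkage is skipped: S = mean over groups of
    |d| + within-group SD / sqrt(n).
    """
    k = m.n_genes
    if k < 3:
        raise NormfinderError("need >=3 genes (sample-centering is degenerate)")
    z = _centered_log_expression(m)

    if isinstance(groups, SampleSet):
        if groups.groups is None:
            groups = None
        else:
            groups = {g: list(s) for g, s in groups.groups.items()}

    if not groups:
        return _ungrouped(m, z)

    group_names = sorted(groups)
    col_idx = {}
    for gname in group_names:
        members = groups[gname]
        if len(members) < 2:
            raise NormfinderError(f"group {gname!r} has fewer than 2 samples")
        col_idx[gname] = [m.samples.index(s) for s in members]

    G = len(group_names)
    n_g = np.array([len(col_idx[g]) for g in group_names], float)

    # per gene/group means and raw within-group variances of z
    zbar = np.empty((k, G))
    raw_var = np.empty((k, G))
    for a, gname in enumerate(group_names):
        block = z[:, col_idx[gname]]
        zbar[:, a] = block.mean(axis=1)
        raw_var[:, a] = block.var(axis=1, ddof=1)

    sigma2 = np.empty((k, G))
    for a in range(G):
        sigma2[:, a] = _corrected_variances(raw_var[:, a], k)

    d = zbar - zbar.mean(axis=1, keepdims=True)      # inter-group differences
    u = sigma2 / n_g                                  # sampling var of d

    if simplified:
        stab_mat = np.abs(d) + np.sqrt(u)
        gamma2 = float("nan")
        d_shrunk = d
    else:
        # variance of the true group differences, net of sampling noise
        gamma2 = float((d ** 2).sum() / ((k - 1) * (G - 1)) - u.mean())
        gamma2 = max(gamma2, 0.0)
        shrink = np.divide(gamma2, gamma2 + u, out=np.zeros_like(u),
                           where=(gamma2 + u) > 0)
        d_shrunk = d * shrink
        stab_mat = np.abs(d_shrunk) + np.sqrt(u * shrink)

    stability = {g: float(stab_mat[i].mean()) for i, g in enumerate(m.genes)}

    res = NormfinderResult(
        genes=list(m.genes),
        stability=stability,
        grouped=True,
        group_names=group_names,
        intra_var={g: {gr: float(sigma2[i, a]) for a, gr in enumerate(group_names)}
                   for i, g in enumerate(m.genes)},
        group_diff={g: {gr: float(d[i, a]) for a, gr in enumerate(group_names)}
                    for i, g in enumerate(m.genes)},
        group_diff_shrunk={g: {gr: float(d_shrunk[i, a])
                               for a, gr in enumerate(group_names)}
                           for i, g in enumerate(m.genes)},
        inter_group_var=gamma2 if not simplified else 0.0,
    )

    # best two-gene combination: averaged gene pair under the same model
    best, best_s = None, np.inf
    for i, j in combinations(range(k), 2):
        d_pair = 0.5 * (d[i] + d[j])
        u_pair = 0.25 * (sigma2[i] + sigma2[j]) / n_g
        if simplified:
            s_pair = float(np.mean(np.abs(d_pair) + np.sqrt(u_pair)))
        else:
            shrink = np.divide(gamma2, gamma2 + u_pair, out=np.zeros_like(u_pair),
                               where=(gamma2 + u_pair) > 0)
            s_pair = float(np.mean(np.abs(d_pair * shrink)
                                   + np.sqrt(u_pair * shrink)))
        if s_pair < best_s:
            best, best_s = (m.genes[i], m.genes[j]), s_pair
    res.best_pair = best
    res.best_pair_stability = best_s
    return res


def _ungrouped(m: CtMatrix, z: np.ndarray) -> NormfinderResult:
    k = m.n_genes
    if m.n_samples < 2:
        raise NormfinderError("need >=2 samples")
    raw_var = z.var(axis=1, ddof=1)
    sigma2 = _corrected_variances(raw_var, k)
    stability = {g: float(np.sqrt(sigma2[i])) for i, g in enumerate(m.genes)}
    best, best_s = None, np.inf
    for i, j in combinations(range(k), 2):
        s_pair = float(np.sqrt(0.25 * (sigma2[i] + sigma2[j])))
        if s_pair < best_s:
            best, best_s = (m.genes[i], m.genes[j]), s_pair
    return NormfinderResult(
        genes=list(m.genes), stability=stability, grouped=False,
        intra_var={g: {"all": float(sigma2[i])} for i, g in enumerate(m.genes)},
        best_pair=best, best_pair_stability=best_s,
    )


def normfinder_frame(res: NormfinderResult) -> pd.DataFrame:
    ranks = res.ranking()
    rows = []
    for g in res.genes:
        row = {"gene": g, "stability_value": res.stability[g], "rank": ranks[g]}
        for gr, v in res.intra_var.get(g, {}).items():
            row[f"intra_var_{gr}"] = v
        for gr, v in res.group_diff.get(g, {}).items():
            row[f"d_{gr}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
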