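"""BestKeeper-style descriptive stability on raw Ct values.

Per-gene SD and CV of Ct, the BestKeeper index (per-sample geometric mean
of all candidate genes' Ct) and each gene's Pearson correlation with that
index.  Genes are ranked by SD; SD < 1 cycle marks a stably expressed gene.
Unlike geNorm/NormFinder, this operates on the raw Ct scale and is
deliberately sensitive to sample-wide loading shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CtMatrix

__all__ = ["BestkeeperResult", "bestkeeper"]

log = logging.getLogger(__name__)

SD_STABLE_CUTOFF = 1.0


class BestkeeperError(ValueError):
    pass


@dataclass
class BestkeeperResult:
    genes: list[str]
    table: pd.DataFrame      # per-gene stats, indexed by gene
    index: np.ndarray        # per-sample geometric mean Ct

    def ranking(self) -> dict[str, int]:
        """Gene -> rank, ascending by SD (ties broken by gene label)."""
        sd = self.table["sd"]
        order = sorted(self.genes, key=lambda g: (sd[g], g))
        return {g: i + 1 for i, g in enumerate(order)}


def bestkeeper(
    m: CtMatrix,
    use_mad: bool = False,
    geometric_cv: bool = False,
    exclude_self: bool = False,
) -> BestkeeperResult:
    """Descriptive stability statistics and index correlations.

    ``use_mad`` replaces the sample SD with the mean absolute deviation
    from the arithmetic mean (the dispersion the original spreadsheet
    reports), ``geometric_cv`` divides CV by the geometric rather than the
    arithmetic mean, and ``exclude_self`` drops the gene being correlated
    from its own index.
    """
    if m.n_genes < 2:
        raise BestkeeperError("need >=2 genes")
    if m.n_samples < 3:
        raise BestkeeperError("need >=3 samples")
    ct = m.ct
    log_ct = np.log(ct)
    index = np.exp(log_ct.mean(axis=0))

    rows = []
    for i, g in enumerate(m.genes):
        x = ct[i]
        geo = float(np.exp(np.log(x).mean()))
        mean = float(x.mean())
        if use_mad:
            sd = float(np.abs(x - mean).mean())
        else:
            sd = float(np.std(x, ddof=1))
        denom = geo if geometric_cv else mean
        cv = 100.0 * sd / denom
        if exclude_self:
            idx_i = np.exp((log_ct.sum(axis=0) - log_ct[i]) / (m.n_genes - 1))
        else:
            idx_i = index
        if np.std(x) == 0 or np.std(idx_i) == 0:
            log.warning("gene %s: zero variance, correlation undefined", g)
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, idx_i)
        rows.append({
            "gene": g, "geo_mean": geo, "ar_mean": mean,
            "min": float(x.min()), "max": float(x.max()),
            "sd": sd, "cv_pct": cv, "r": float(r), "p": float(p),
            "stable": sd < SD_STABLE_CUTOFF,
        })
    table = pd.DataFrame(rows).set_index("gene")
    res = BestkeeperResult(genes=list(m.genes), table=table, index=index)
    table["rank"] = table.index.map(res.ranking())
    return res
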