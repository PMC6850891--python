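"""Assemble per-sample-set stability reports across the three methods."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bestkeeper import BestkeeperResult, bestkeeper
from .consensus import ConsensusTable, consensus_rank
from .core import CtMatrix, SampleSet
from .genorm import GenormResult, genorm
from .normfinder import NormfinderResult, normfinder_stability

__all__ = ["SetReport", "analyze_sample_set", "combined_table"]


@dataclass
class SetReport:
    """All three stability analyses plus consensus for one sample set."""

    set_name: str
    genorm: GenormResult
    normfinder: NormfinderResult
    bestkeeper: BestkeeperResult
    consensus: ConsensusTable


def analyze_sample_set(
    m: CtMatrix,
    sample_set: SampleSet | None = None,
    grouped: bool | None = None,
    genorm_threshold: float = 0.15,
    m_cutoff: float = 1.5,
    genorm_rank_mode: str = "single_pass",
) -> SetReport:
    """Run geNorm, NormFinder and BestKeeper on one sample set and merge ranks.

    ``grouped=None`` lets the data decide: NormFinder runs grouped when the
    sample set carries a group partition with >=2 groups of >=2 samples.
    """
    name = sample_set.name if sample_set is not None else "all"
    sub = m.subset_samples(list(sample_set.members)) if sample_set is not None else m

    groups = None
    if sample_set is not None and sample_set.groups:
        usable = (len(sample_set.groups) >= 2
                  and all(len(g) >= 2 for g in sample_set.groups.values()))
        if grouped is None:
            grouped = usable
        if grouped and not usable:
            raise ValueError(
                f"set {name!r}: grouped NormFinder needs >=2 groups of >=2 samples")
        if grouped:
            groups = {g: list(s) for g, s in sample_set.groups.items()}

    gn = genorm(sub, threshold=genorm_threshold, m_cutoff=m_cutoff)
    nf = normfinder_stability(sub, groups=groups)
    bk = bestkeeper(sub)
    cons = consensus_rank({
        "genorm": gn.ranking(genorm_rank_mode),
        "normfinder": nf.ranking(),
        "bestkeeper": bk.ranking(),
    })
    return SetReport(set_name=name, genorm=gn, normfinder=nf,
                     bestkeeper=bk, consensus=cons)


def combined_table(report: SetReport) -> pd.DataFrame:
    """One row per gene: M, S, SD/CV with per-method ranks, geomean, com rank."""
    gn, nf, bk = report.genorm, report.normfinder, report.bestkeeper
    cons = report.consensus.table
    rows = []
    for g in gn.genes:
        rows.append({
            "gene": g,
            "m": gn.m_single_pass[g],
            "rank_genorm": cons.loc[g, "rank_genorm"],
            "s": nf.stability[g],
            "rank_normfinder": cons.loc[g, "rank_normfinder"],
            "sd": bk.table.loc[g, "sd"],
            "cv_pct": bk.table.loc[g, "cv_pct"],
            "rank_bestkeeper": cons.loc[g, "rank_bestkeeper"],
            "geomean": cons.loc[g, "geomean"],
            "com_rank": cons.loc[g, "com_rank"],
        })
    return pd.DataFrame(rows).set_index("gene").sort_values("com_rank")


def report_summary(report: SetReport) -> dict:
    """JSON-ready summary of one sample set's analysis."""
    return {
        "set": report.set_name,
        "best_genes": report.consensus.best_genes,
        "worst_gene": report.consensus.worst_gene,
        "genorm_best_pair": list(report.genorm.best_pair),
        "genorm_best_pair_m": report.genorm.best_pair_m,
        "genorm_recommended_n": report.genorm.recommended_n,
        "genorm_v_series": {str(k): v for k, v in report.genorm.v_series.items()},
        "normfinder_best_pair": (list(report.normfinder.best_pair)
                                 if report.normfinder.best_pair else None),
        "normfinder_best_pair_stability": report.normfinder.best_pair_stability,
        "normfinder_grouped": report.normfinder.grouped,
    }
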