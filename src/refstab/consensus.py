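"""Cross-method consensus ranking and relative-quantification validation.

The consensus rank of a gene is the geometric mean of its ranks under the
three stability methods; relative expression of a target against chosen
reference genes uses the 2^-ddCt method.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import CtMatrix

__all__ = ["ConsensusTable", "RelativeExpression", "consensus_rank", "ddct",
           "reference_choice_sensitivity"]


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusTable:
    table: pd.DataFrame          # per-gene method ranks, geomean, com_rank
    best_genes: list[str]
    worst_gene: str


@dataclass
class RelativeExpression:
    target: str
    references: list[str]
    calibrator: str
    samples: list[str]
    fold_change: np.ndarray      # per sample, calibrator == 1

    def as_series(self) -> pd.Series:
        return pd.Series(self.fold_change, index=self.samples, name=self.target)


def consensus_rank(rank_vectors: dict[str, dict[str, int]]) -> ConsensusTable:
    """Aggregate per-method gene ranks by geometric mean.

    ``rank_vectors`` maps method name -> (gene -> rank).  All methods must
    cover the same gene set.  Comprehensive ranks use competition ranking:
    equal geometric means share a rank and the next distinct mean skips
    the tied positions.
    """
    if not rank_vectors:
        raise ConsensusError("no rank vectors given")
    methods = list(rank_vectors)
    genes = set(rank_vectors[methods[0]])
    for meth in methods[1:]:
        if set(rank_vectors[meth]) != genes:
            raise ConsensusError(f"method {meth!r} covers a different gene set")
    rows = []
    for g in sorted(genes):
        ranks = [rank_vectors[meth][g] for meth in methods]
        geomean = float(np.exp(np.mean(np.log(ranks))))
        rows.append({"gene": g, **{f"rank_{m}": r for m, r in zip(methods, ranks)},
                     "geomean": geomean})
    df = pd.DataFrame(rows).set_index("gene").sort_values(["geomean", "gene"])
    # competition ranking over geomeans
    com = []
    for i, gm in enumerate(df["geomean"]):
        if i > 0 and np.isclose(gm, df["geomean"].iloc[i - 1]):
            com.append(com[-1])
        else:
            com.append(i + 1)
    df["com_rank"] = com
    best = list(df.index[df["com_rank"] == df["com_rank"].min()])
    worst = df.index[df["geomean"].argmax()]
    return ConsensusTable(table=df, best_genes=best, worst_gene=str(worst))


def _calibrator_columns(m: CtMatrix, calibrator: str,
                        group_mean: bool) -> list[int]:
    if calibrator in m.samples:
        return [m.samples.index(calibrator)]
    hits = [j for j, s in enumerate(m.samples)
            if str(m.meta.iloc[j].get("group")) == calibrator]
    if not hits:
        raise ConsensusError(f"calibrator {calibrator!r} matches no sample or group")
    if len(hits) > 1 and not group_mean:
        raise ConsensusError(
            f"calibrator {calibrator!r} matches {len(hits)} samples; "
            "set group_mean=True to average them"
        )
    return hits


def ddct(
    m: CtMatrix,
    target: str,
    references: list[str],
    calibrator: str,
    group_mean: bool = False,
) -> RelativeExpression:
    """Fold change of ``target`` by the 2^-ddCt method.

    The per-sample reference Ct is the arithmetic mean of the reference
    genes' Ct (the geometric mean of their quantities); dCt subtracts it
    from the target Ct, ddCt subtracts the calibrator's dCt (a sample id or
    a group label; a multi-sample calibrator needs ``group_mean=True``).
    """
    if not references:
        raise ConsensusError("need at least one reference gene")
    t = m.row(target)
    ref = np.mean([m.row(r) for r in references], axis=0)
    dct = t - ref
    cal_cols = _calibrator_columns(m, calibrator, group_mean)
    ddct_vals = dct - np.mean(dct[cal_cols])
    return RelativeExpression(
        target=target, references=list(references), calibrator=calibrator,
        samples=list(m.samples), fold_change=np.power(2.0, -ddct_vals),
    )


def reference_choice_sensitivity(
    m: CtMatrix,
    target: str,
    candidate_refs: list[str],
    calibrator: str,
    group_mean: bool = False,
) -> pd.DataFrame:
    """Compare the target's fold-change profile under each candidate reference.

    Returns one row per unordered reference pair with the maximum absolute
    log2 divergence between the two profiles and a flag for samples where
    the direction of change (up vs down relative to the calibrator) flips.
    """
    if len(candidate_refs) < 2:
        raise ConsensusError("need >=2 candidate references to compare")
    profiles = {
        r: ddct(m, target, [r], calibrator, group_mean=group_mean).fold_change
        for r in candidate_refs
    }
    rows = []
    for a, b in combinations(candidate_refs, 2):
        la, lb = np.log2(profiles[a]), np.log2(profiles[b])
        div = float(np.max(np.abs(la - lb)))
        flip = bool(np.any((la > 0) & (lb < 0)) or np.any((la < 0) & (lb > 0)))
        rows.append({"ref_a": a, "ref_b": b,
                     "max_abs_log2_divergence": div, "direction_flip": flip})
    return pd.DataFrame(rows)
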