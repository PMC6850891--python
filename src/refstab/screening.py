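"""Candidate screening from two-library expression tables.

Computes RPKM, the signed log2 expression ratio between two libraries and,
per gene family, selects the member whose expression differs least between
the libraries (|log2 ratio| < 1, minimal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["ScreeningRecord", "rpkm", "log2ratio", "select_candidates",
           "read_screening_table", "screening_frame"]

#: |log2 ratio| at or above which expression differs significantly.
SIGNIFICANCE_THRESHOLD = 1.0


class ScreeningError(ValueError):
    pass


@dataclass
class ScreeningRecord:
    """One candidate unigene with expression in two libraries (a and b)."""

    family: str
    gene_id: str
    length: int
    a_fpkm: float   # first library (e.g. white fruit)
    b_fpkm: float   # second library (e.g. red fruit)

    @property
    def log2ratio(self) -> float:
        return log2ratio(self.b_fpkm, self.a_fpkm)

    @property
    def abs_log2ratio(self) -> float:
        return abs(self.log2ratio)


def rpkm(c: float, n: float, l: float) -> float:
    """Reads per kilobase per million aligned reads: 1e9 * C / (N * L).

    ``c``: reads aligned to the gene; ``n``: total aligned reads in the
    library; ``l``: gene length in bases.
    """
    if n <= 0:
        raise ScreeningError(f"total read count must be positive, got {n}")
    if l <= 0:
        raise ScreeningError(f"gene length must be positive, got {l}")
    if c < 0:
        raise ScreeningError(f"read count must be non-negative, got {c}")
    return 1e9 * c / (n * l)


def log2ratio(b_rpkm: float, a_rpkm: float, pseudocount: float = 0.0) -> float:
    """Signed log2(b/a); positive means enriched in library b.

    Zero expression makes the ratio undefined; an optional pseudocount is
    added to both sides when explicitly requested.
    """
    b = b_rpkm + pseudocount
    a = a_rpkm + pseudocount
    if b <= 0 or a <= 0:
        raise ScreeningError(
            f"log2 ratio undefined for non-positive expression ({b_rpkm}, {a_rpkm}); "
            "pass a pseudocount to rescue zero-expression records"
        )
    return math.log2(b / a)


def select_candidates(
    records: list[ScreeningRecord],
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> pd.DataFrame:
    """Pick, per family, the record with the smallest |log2 ratio| below threshold.

    Returns a report frame with one row per record: its ratio, whether it
    was excluded by the significance filter, and whether it is the family's
    selection.  Families where every member exceeds the threshold are left
    without a selection (all rows flagged excluded).
    Ties on the minimal |log2 ratio| go to the lexicographically smallest
    gene id.
    """
    if not records:
        raise ScreeningError("no screening records given")
    rows = []
    for r in records:
        rows.append({
            "family": r.family, "gene_id": r.gene_id, "length": r.length,
            "a_fpkm": r.a_fpkm, "b_fpkm": r.b_fpkm,
            "log2ratio": r.log2ratio, "abs_log2ratio": r.abs_log2ratio,
        })
    df = pd.DataFrame(rows)
    df["excluded"] = df["abs_log2ratio"] >= threshold
    df["excluded_reason"] = df["excluded"].map(
        lambda e: f"|log2ratio| >= {threshold}" if e else "")
    df["selected"] = False
    for fam, sub in df.groupby("family", sort=False):
        ok = sub[~sub["excluded"]]
        if ok.empty:
            continue
        best = ok.sort_values(["abs_log2ratio", "gene_id"]).index[0]
        df.loc[best, "selected"] = True
    return df


def read_screening_table(path) -> list[ScreeningRecord]:
    """Read a screening TSV/CSV.

    Accepts either precomputed FPKM columns (``a_fpkm``/``b_fpkm``, aliases
    ``w_fpkm``/``r_fpkm``) or raw counts plus library totals
    (``a_reads, b_reads, a_total, b_total`` / ``w_*, r_*``), from which RPKM
    is computed.  Mixing both representations for one library is rejected.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = set(df.columns)
    ren = {"w_fpkm": "a_fpkm", "r_fpkm": "b_fpkm",
           "w_reads": "a_reads", "r_reads": "b_reads",
           "w_total": "a_total", "r_total": "b_total"}
    df = df.rename(columns={k: v for k, v in ren.items() if k in cols})
    cols = set(df.columns)
    has_fpkm = {"a_fpkm", "b_fpkm"} <= cols
    has_counts = {"a_reads", "b_reads", "a_total", "b_total"} <= cols
    if has_fpkm and has_counts:
        raise ScreeningError("give either FPKM columns or count columns, not both")
    if not has_fpkm and not has_counts:
        raise ScreeningError("missing expression columns (FPKM or counts)")
    records = []
    for _, r in df.iterrows():
        length = int(r["length"])
        if has_fpkm:
            a, b = float(r["a_fpkm"]), float(r["b_fpkm"])
        else:
            a = rpkm(float(r["a_reads"]), float(r["a_total"]), length)
            b = rpkm(float(r["b_reads"]), float(r["b_total"]), length)
        records.append(ScreeningRecord(
            family=str(r["family"]), gene_id=str(r["gene_id"]),
            length=length, a_fpkm=a, b_fpkm=b,
        ))
    return records


def screening_frame(records: list[ScreeningRecord]) -> pd.DataFrame:
    """Convenience: records -> plain frame without selection logic."""
    return pd.DataFrame([{
        "family": r.family, "gene_id": r.gene_id, "length": r.length,
        "a_fpkm": r.a_fpkm, "b_fpkm": r.b_fpkm,
        "log2ratio": r.log2ratio, "abs_log2ratio": r.abs_log2ratio,
    } for r in records])
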