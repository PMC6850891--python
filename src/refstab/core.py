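"""Core domain types, Ct table I/O and descriptive statistics.

The central object is :class:`CtMatrix`: a genes x samples matrix of
quantification-cycle (Ct) values plus a per-sample metadata frame holding
the experimental design (sample set, group, tissue, time point, replicate
index).  All stability algorithms operate on this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "CtSummary",
    "SampleSet",
    "read_ct_table",
    "write_ct_table",
    "collapse_replicates",
    "summarize_ct",
]

#: Metadata columns recognised in a sample sheet.
META_COLUMNS = ("set", "group", "tissue", "time", "replicate")


class CtDataError(ValueError):
    """Raised for malformed or inconsistent Ct input data."""


@dataclass
class CtMatrix:
    """Genes x samples Ct values with per-sample metadata.

    Parameters
    ----------
    genes
        Ordered gene labels (unique).
    samples
        Ordered sample identifiers (unique).
    ct
        ``(n_genes, n_samples)`` array of finite, positive Ct values.
    meta
        Per-sample metadata indexed by sample id. Missing columns from
        :data:`META_COLUMNS` are filled with NA.
    """

    genes: list[str]
    samples: list[str]
    ct: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.genes), len(self.samples)):
            raise CtDataError(
                f"ct shape {self.ct.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise CtDataError("duplicate gene labels")
        if len(set(self.samples)) != len(self.samples):
            raise CtDataError("duplicate sample ids")
        if not np.all(np.isfinite(self.ct)):
            bad = np.argwhere(~np.isfinite(self.ct))[0]
            raise CtDataError(
                f"non-finite Ct at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if np.any(self.ct <= 0):
            bad = np.argwhere(self.ct <= 0)[0]
            raise CtDataError(
                f"non-positive Ct at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.samples, name="sample_id"))
        else:
            self.meta = self.meta.copy()
            self.meta.index = self.meta.index.astype(str)
            missing = set(self.samples) - set(self.meta.index)
            if missing:
                raise CtDataError(f"samples missing from metadata: {sorted(missing)}")
            self.meta = self.meta.loc[self.samples]
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = pd.NA

    # -- convenience -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.ct[self.gene_index(gene)]

    def subset_samples(self, sample_ids: list[str]) -> "CtMatrix":
        """Return a new matrix restricted to ``sample_ids`` (kept in given order)."""
        idx = []
        for s in sample_ids:
            if s not in self.samples:
                raise KeyError(f"unknown sample {s!r}")
            idx.append(self.samples.index(s))
        return CtMatrix(
            genes=list(self.genes),
            samples=[self.samples[i] for i in idx],
            ct=self.ct[:, idx].copy(),
            meta=self.meta.iloc[idx],
        )

    def subset_genes(self, genes: list[str]) -> "CtMatrix":
        idx = [self.gene_index(g) for g in genes]
        return CtMatrix(
            genes=[self.genes[i] for i in idx],
            samples=list(self.samples),
            ct=self.ct[idx].copy(),
            meta=self.meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=pd.Index(self.genes, name="gene"),
                            columns=self.samples)

    def copy(self) -> "CtMatrix":
        return replace(self, ct=self.ct.copy(), meta=self.meta.copy())


@dataclass(frozen=True)
class CtSummary:
    """Per-gene descriptive statistics of Ct values (all in cycles, CV in %)."""

    gene: str
    mean: float
    sd: float
    cv_pct: float
    min: float
    max: float
    delta_ct: float
    q25: float
    median: float
    q75: float


@dataclass(frozen=True)
class SampleSet:
    """A named collection of samples with an optional group partition."""

    name: str
    members: tuple[str, ...]
    groups: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise CtDataError(f"sample set {self.name!r} needs >=2 members")
        if self.groups is not None:
            pooled = [s for g in self.groups.values() for s in g]
            if sorted(pooled) != sorted(self.members):
                raise CtDataError(
                    f"groups of sample set {self.name!r} do not partition its members"
                )

    @classmethod
    def from_meta(cls, meta: pd.DataFrame, name: str,
                  group_col: str = "group") -> "SampleSet":
        """Build the sample set ``name`` from a metadata frame ('set' column)."""
        sub = meta[meta["set"] == name]
        if sub.empty:
            raise CtDataError(f"no samples belong to set {name!r}")
        members = tuple(sub.index)
        groups = None
        if group_col in sub.columns and sub[group_col].notna().any():
            groups = {
                str(g): tuple(d.index)
                for g, d in sub.groupby(group_col, sort=True, dropna=False)
            }
        return cls(name=name, members=members, groups=groups)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path, **kw) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, **kw)


def _parse_ct_cell(value, gene: str, sample: str) -> float:
    try:
        ct = float(value)
    except (TypeError, ValueError):
        raise CtDataError(
            f"non-numeric Ct {value!r} at gene {gene!r}, sample {sample!r}"
        ) from None
    return ct


def read_ct_table(path, layout: str = "wide", sample_sheet=None) -> CtMatrix:
    """Read a Ct table (wide or long) and an optional sample sheet.

    Wide layout: first column is the gene label, remaining columns are
    sample ids.  Long layout: columns ``gene``, ``sample``, ``ct``.  The
    sample sheet has a ``sample_id`` column plus any of
    ``set, group, tissue, time, replicate``.
    """
    if layout not in ("wide", "long"):
        raise CtDataError(f"unknown layout {layout!r}")
    raw = _read_table(path)
    if layout == "wide":
        gene_col = raw.columns[0]
        genes = list(raw[gene_col])
        samples = [str(c) for c in raw.columns[1:]]
        ct = np.empty((len(genes), len(samples)))
        for i, g in enumerate(genes):
            for j, s in enumerate(samples):
                ct[i, j] = _parse_ct_cell(raw.iloc[i, j + 1], g, s)
    else:
        need = {"gene", "sample", "ct"}
        if not need.issubset(raw.columns):
            raise CtDataError(f"long table must have columns {sorted(need)}")
        genes = list(dict.fromkeys(raw["gene"]))
        samples = list(dict.fromkeys(raw["sample"]))
        ct = np.full((len(genes), len(samples)), np.nan)
        gi = {g: i for i, g in enumerate(genes)}
        si = {s: j for j, s in enumerate(samples)}
        for _, r in raw.iterrows():
            i, j = gi[r["gene"]], si[r["sample"]]
            if not np.isnan(ct[i, j]):
                raise CtDataError(
                    f"duplicate entry for gene {r['gene']!r}, sample {r['sample']!r}"
                )
            ct[i, j] = _parse_ct_cell(r["ct"], r["gene"], r["sample"])
        if np.isnan(ct).any():
            i, j = np.argwhere(np.isnan(ct))[0]
            raise CtDataError(
                f"missing Ct for gene {genes[i]!r}, sample {samples[j]!r}"
            )

    meta = None
    if sample_sheet is not None:
        sheet = _read_table(sample_sheet)
        if "sample_id" not in sheet.columns:
            raise CtDataError("sample sheet must have a 'sample_id' column")
        if sheet["sample_id"].duplicated().any():
            dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CtDataError(f"duplicate sample_id {dup!r} in sample sheet")
        unknown = set(sheet["sample_id"]) - set(samples)
        if unknown:
            raise CtDataError(f"sample sheet lists unknown samples: {sorted(unknown)}")
        uncovered = set(samples) - set(sheet["sample_id"])
        if uncovered:
            raise CtDataError(f"sample sheet does not cover: {sorted(uncovered)}")
        meta = sheet.set_index("sample_id")
        if "replicate" in meta.columns:
            meta["replicate"] = pd.to_numeric(meta["replicate"], errors="coerce")
    return CtMatrix(genes=genes, samples=samples, ct=ct, meta=meta)


def write_ct_table(m: CtMatrix, path, sample_sheet_path=None) -> None:
    """Write a wide TSV/CSV Ct table and, optionally, its sample sheet.

    Ct values are written with ``repr`` round-trip precision so that a
    read-back matrix is bitwise identical.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = m.to_frame()
    df.to_csv(path, sep=sep, float_format="%.17g")
    if sample_sheet_path is not None:
        sep2 = "\t" if str(sample_sheet_path).endswith((".tsv", ".txt")) else ","
        out = m.meta.copy()
        out.index.name = "sample_id"
        out.to_csv(sample_sheet_path, sep=sep2)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def collapse_replicates(m: CtMatrix, policy: str = "mean") -> CtMatrix:
    """Average biological replicates into one column per biological unit.

    A biological unit is the combination of every metadata column except
    ``replicate``.  With ``policy='none'`` the input is returned unchanged.
    Mixed replicate counts are averaged over whatever is available.
    """
    if policy == "none":
        return m
    if policy != "mean":
        raise CtDataError(f"unknown replicate policy {policy!r}")
    if m.meta["replicate"].isna().all():
        raise CtDataError("policy='mean' requires replicate indices in metadata")

    key_cols = [c for c in m.meta.columns if c != "replicate"]
    keys = m.meta[key_cols].astype(str).agg("|".join, axis=1)
    new_samples: list[str] = []
    new_meta_rows = []
    cols: list[np.ndarray] = []
    for key in dict.fromkeys(keys):
        members = [s for s, k in zip(m.samples, keys) if k == key]
        if not members:
            raise CtDataError("empty replicate group")
        idx = [m.samples.index(s) for s in members]
        cols.append(m.ct[:, idx].mean(axis=1))
        new_samples.append(members[0])
        row = m.meta.loc[members[0]].copy()
        row["replicate"] = pd.NA
        new_meta_rows.append(row)
    meta = pd.DataFrame(new_meta_rows, index=pd.Index(new_samples, name="sample_id"))
    return CtMatrix(genes=list(m.genes), samples=new_samples,
                    ct=np.column_stack(cols), meta=meta)


def summarize_ct(m: CtMatrix, ddof: int = 1) -> list[CtSummary]:
    """Per-gene mean/SD/CV%/range/quartile summary of Ct values.

    SD uses the sample standard deviation (``ddof=1``) by default;
    CV% = 100 * SD / mean; the Ct range is max - min.  Quartiles use
    linear interpolation between order statistics.
    """
    if m.n_samples < 2:
        raise CtDataError("need >=2 samples to compute SD")
    out = []
    for i, g in enumerate(m.genes):
        x = m.ct[i]
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=ddof))
        q25, med, q75 = (float(v) for v in np.percentile(x, [25, 50, 75]))
        out.append(CtSummary(
            gene=g, mean=mean, sd=sd, cv_pct=100.0 * sd / mean,
            min=float(np.min(x)), max=float(np.max(x)),
            delta_ct=float(np.max(x) - np.min(x)),
            q25=q25, median=med, q75=q75,
        ))
    return out


def summary_frame(summaries: list[CtSummary]) -> pd.DataFrame:
    """Tabulate :func:`summarize_ct` output."""
    return pd.DataFrame([s.__dict__ for s in summaries]).set_index("gene")
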