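"""Standard-curve fitting and amplification-efficiency QC.

A serial-dilution Ct series is regressed against log10(relative template
amount); the slope k gives the amplification efficiency E = 10^(-1/k) - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StandardCurve", "fit_standard_curve", "efficiency_from_slope",
           "efficiency_report", "read_dilution_table"]


class StandardCurveError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of Ct against log10 relative template amount."""

    gene: str
    slope: float        # cycles per log10 unit; negative for valid curves
    intercept: float    # cycles at the undiluted reference amount
    r_squared: float
    efficiency: float   # fraction: 1.0 == perfect doubling

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * self.efficiency


def efficiency_from_slope(slope: float) -> float:
    """E = 10^(-1/k) - 1 for standard-curve slope k."""
    if slope == 0:
        raise StandardCurveError("slope of zero has no defined efficiency")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(dilutions, ct, gene: str = "") -> StandardCurve:
    """Fit a standard curve from matched dilution factors and mean Ct values.

    ``dilutions`` are relative template amounts (e.g. 1, 1/5, 1/25, ...);
    replicate Ct values at the same dilution are averaged before fitting.
    The x axis is log10(dilution), so the undiluted sample sits at 0; slope
    and efficiency do not depend on which amount is called "1".
    """
    d = np.asarray(dilutions, dtype=float)
    y = np.asarray(ct, dtype=float)
    if d.shape != y.shape:
        raise StandardCurveError("dilutions and ct must have matching length")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(d)):
        raise StandardCurveError("non-finite values in dilution series")
    if np.any(d <= 0):
        raise StandardCurveError("dilution factors must be positive")
    # average replicate rows at identical dilution
    df = pd.DataFrame({"x": np.log10(d), "y": y}).groupby("x", as_index=False).mean()
    if len(df) < 3:
        raise StandardCurveError("need >=3 distinct dilutions")
    if np.ptp(df["x"].to_numpy()) == 0:
        raise StandardCurveError("zero variance in log10 dilution")
    res = stats.linregress(df["x"], df["y"])
    slope = float(res.slope)
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=efficiency_from_slope(slope),
    )


def efficiency_report(
    curves: list[StandardCurve],
    e_min: float = 0.90,
    e_max: float = 1.10,
    r2_min: float = 0.99,
) -> pd.DataFrame:
    """Flag genes whose efficiency or R-squared falls outside the QC band.

    Defaults: 90-110% efficiency and R^2 >= 0.99 (tool policy, configurable).
    """
    rows = []
    for c in curves:
        ok = (e_min <= c.efficiency <= e_max) and c.r_squared >= r2_min
        rows.append({
            "gene": c.gene, "slope": c.slope, "intercept": c.intercept,
            "r_squared": c.r_squared, "efficiency_pct": c.efficiency_pct,
            "pass": ok,
        })
    return pd.DataFrame(rows)


def read_dilution_table(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a dilution-series TSV/CSV with columns gene, dilution, ct.

    Replicate rows per (gene, dilution) are allowed and kept; averaging
    happens inside :func:`fit_standard_curve`.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    need = {"gene", "dilution", "ct"}
    if not need.issubset(df.columns):
        raise StandardCurveError(f"dilution table must have columns {sorted(need)}")
    out = {}
    for gene, sub in df.groupby("gene", sort=False):
        out[str(gene)] = (sub["dilution"].to_numpy(float), sub["ct"].to_numpy(float))
    return out
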