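"""Independent brute-force oracles used to check the package implementations.

Everything here is written straight from the defining formulas with plain
Python loops and must stay independent of the refstab code paths it checks.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations


def sample_sd(xs) -> float:
    return statistics.stdev(xs)


def brute_q(ct_row, base=2.0):
    mn = min(ct_row)
    return [base ** (mn - c) for c in ct_row]


def brute_pair_v(q1, q2) -> float:
    ratios = [math.log2(a / b) for a, b in zip(q1, q2)]
    return sample_sd(ratios)


def brute_m(q_rows: dict[str, list[float]]) -> dict[str, float]:
    genes = list(q_rows)
    out = {}
    for g in genes:
        vs = [brute_pair_v(q_rows[g], q_rows[h]) for h in genes if h != g]
        out[g] = sum(vs) / len(vs)
    return out


def brute_stepwise(q_rows: dict[str, list[float]], panel_order: list[str]):
    """Exclusion order by repeated M computation; ties remove the gene
    later in panel order.  Returns (exclusion_order, m_at_removal)."""
    current = list(panel_order)
    order, m_at = [], {}
    while len(current) > 2:
        ms = brute_m({g: q_rows[g] for g in current})
        worst_m = max(ms.values())
        worst = max((g for g in current if ms[g] == worst_m),
                    key=panel_order.index)
        order.append(worst)
        m_at[worst] = ms[worst]
        current.remove(worst)
    ms = brute_m({g: q_rows[g] for g in current})
    for g in current:
        m_at[g] = ms[g]
    order.extend(current)
    return order, m_at


def brute_nf(q_rows: dict[str, list[float]], genes: list[str]):
    n = len(next(iter(q_rows.values())))
    out = []
    for j in range(n):
        prod = 1.0
        for g in genes:
            prod *= q_rows[g][j]
        out.append(prod ** (1.0 / len(genes)))
    return out


def brute_v_series(q_rows: dict[str, list[float]], stability_order: list[str]):
    out = {}
    for n in range(2, len(stability_order)):
        nf_n = brute_nf(q_rows, stability_order[:n])
        nf_n1 = brute_nf(q_rows, stability_order[:n + 1])
        out[n] = sample_sd([math.log2(a / b) for a, b in zip(nf_n, nf_n1)])
    return out


def brute_bestkeeper(ct_rows: dict[str, list[float]]):
    """Per-gene SD/CV and Pearson r with the geometric-mean index."""
    genes = list(ct_rows)
    n = len(next(iter(ct_rows.values())))
    index = []
    for j in range(n):
        logs = [math.log(ct_rows[g][j]) for g in genes]
        index.append(math.exp(sum(logs) / len(genes)))
    out = {}
    for g in genes:
        x = ct_rows[g]
        mean = sum(x) / n
        sd = sample_sd(x)
        r = _pearson(x, index)
        out[g] = {"sd": sd, "cv_pct": 100.0 * sd / mean, "r": r,
                  "geo_mean": math.exp(sum(math.log(v) for v in x) / n)}
    return out, index


def _pearson(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den


def brute_normfinder_grouped(ct_rows: dict[str, list[float]],
                             groups: dict[str, list[int]]):
    """Straight transcription of the grouped variance-decomposition model.

    ``groups`` maps group name -> column indices.  Returns gene -> S.
    """
    genes = list(ct_rows)
    k = len(genes)
    n_cols = len(next(iter(ct_rows.values())))
    # sample-centered -Ct
    y = {g: [-c for c in ct_rows[g]] for g in genes}
    col_mean = [sum(y[g][j] for g in genes) / k for j in range(n_cols)]
    z = {g: [y[g][j] - col_mean[j] for j in range(n_cols)] for g in genes}

    gnames = sorted(groups)
    G = len(gnames)
    zbar = {g: {} for g in genes}
    raw_var = {g: {} for g in genes}
    for gr in gnames:
        cols = groups[gr]
        for g in genes:
            vals = [z[g][j] for j in cols]
            zbar[g][gr] = sum(vals) / len(vals)
            raw_var[g][gr] = statistics.variance(vals)
    sigma2 = {g: {} for g in genes}
    for gr in gnames:
        tot = sum(raw_var[g][gr] for g in genes)
        for g in genes:
            v = (raw_var[g][gr] - tot / (k * (k - 1))) * k / (k - 2)
            sigma2[g][gr] = max(v, 0.0)
    d = {g: {} for g in genes}
    for g in genes:
        mean_over_groups = sum(zbar[g][gr] for gr in gnames) / G
        for gr in gnames:
            d[g][gr] = zbar[g][gr] - mean_over_groups
    u = {g: {gr: sigma2[g][gr] / len(groups[gr]) for gr in gnames}
         for g in genes}
    ssd = sum(d[g][gr] ** 2 for g in genes for gr in gnames)
    mean_u = sum(u[g][gr] for g in genes for gr in gnames) / (k * G)
    gamma2 = max(ssd / ((k - 1) * (G - 1)) - mean_u, 0.0)
    stab = {}
    for g in genes:
        terms = []
        for gr in gnames:
            denom = gamma2 + u[g][gr]
            shrink = gamma2 / denom if denom > 0 else 0.0
            terms.append(abs(d[g][gr] * shrink)
                         + math.sqrt(u[g][gr] * shrink))
        stab[g] = sum(terms) / G
    return stab


def brute_normfinder_ungrouped(ct_rows: dict[str, list[float]]):
    genes = list(ct_rows)
    k = len(genes)
    n = len(next(iter(ct_rows.values())))
    y = {g: [-c for c in ct_rows[g]] for g in genes}
    col_mean = [sum(y[g][j] for g in genes) / k for j in range(n)]
    z = {g: [y[g][j] - col_mean[j] for j in range(n)] for g in genes}
    raw = {g: statistics.variance(z[g]) for g in genes}
    tot = sum(raw.values())
    return {g: math.sqrt(max((raw[g] - tot / (k * (k - 1))) * k / (k - 2), 0.0))
            for g in genes}


def brute_geomean_ranks(rank_lists: dict[str, list[int]]):
    out = {}
    for g, ranks in rank_lists.items():
        prod = 1.0
        for r in ranks:
            prod *= r
        out[g] = prod ** (1.0 / len(ranks))
    return out


def brute_ddct(target_row, ref_rows, cal_idx):
    n = len(target_row)
    ref_mean = [sum(r[j] for r in ref_rows) / len(ref_rows) for j in range(n)]
    dct = [target_row[j] - ref_mean[j] for j in range(n)]
    cal = sum(dct[j] for j in cal_idx) / len(cal_idx)
    return [2.0 ** -(v - cal) for v in dct]
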