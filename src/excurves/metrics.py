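"""Inequality and progression statistics.

Implements the cohort-level summaries: Gini coefficients of workload
distributions, coefficients of variation, Kruskal–Wallis tests with
eta-squared effect sizes, Wilson proportion intervals, per-PGY acuity
and admission progression, and the heavy-tail frequency buckets of
per-topic encounter counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import UndefinedGiniError, ValidationError
from .model import Resident, assign_pgy


def gini(values, *, sample_corrected: bool = False) -> float:
    """Gini coefficient of a nonnegative vector.

    Population (ordered-pair) form::

        G = sum_ij |x_i - x_j| / (2 n^2 xbar)

    which equals the area-based Lorenz-curve definition and is bounded
    by (n-1)/n.  ``sample_corrected`` rescales by n/(n-1), the
    small-sample variant some packages report.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValidationError("gini needs a 1-d vector with n >= 1")
    if (x < 0).any():
        raise ValidationError("gini undefined for negative values")
    if not (x > 0).any():
        raise UndefinedGiniError("gini undefined for all-zero input")
    n = x.size
    xs = np.sort(x)
    # sum_ij |x_i - x_j| = 2 * sum_k (2k - n + 1) x_(k),  k = 0..n-1
    mad_sum = 2.0 * np.sum((2 * np.arange(n) - n + 1) * xs)
    g = mad_sum / (2.0 * n * n * xs.mean())
    if sample_corrected and n > 1:
        g *= n / (n - 1)
    return float(g)


def coefficient_of_variation(values) -> float:
    """Sample CV as a percentage: 100 * sd(n-1) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("CV needs n >= 2")
    m = x.mean()
    if m == 0:
        raise ValidationError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


def kruskal_wallis_eta2(*groups) -> tuple[float, float, float]:
    """Kruskal–Wallis H (midrank ties correction), chi-square p value,
    and eta-squared effect size ``(H - k + 1)/(n - k)`` floored at 0."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValidationError("empty group")
    n, k = sum(sizes), len(groups)
    if n <= k:
        raise ValidationError("need total n > number of groups")
    h, p = stats.kruskal(*groups)
    eta2 = max(0.0, (h - k + 1) / (n - k))
    return float(h), float(p), float(eta2)


def proportion_with_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Proportion with a Wilson score interval, all as fractions."""
    if trials <= 0:
        raise ValidationError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValidationError("successes outside [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    return successes / trials, float(lo), float(hi)


def frequency_buckets(
    topic_counts: dict[str, int] | pd.Series,
    catalog_size: int | None = None,
    thresholds: tuple[int, int] = (100, 10),
) -> dict:
    """Heavy-tail bucket summary of per-topic encounter counts.

    Buckets partition all catalog topics: count > hi; lo <= count <= hi;
    count < lo (zero-count topics fall in the last bucket).  Fractions
    use the catalog size as denominator, reported to 1 decimal as
    percentages.
    """
    counts = pd.Series(topic_counts, dtype=float)
    n_topics = catalog_size if catalog_size is not None else len(counts)
    if len(counts) > n_topics:
        raise ValidationError("more counted topics than catalog size")
    hi, lo = thresholds
    n_gt = int((counts > hi).sum())
    n_mid = int(((counts >= lo) & (counts <= hi)).sum())
    # topics absent from `counts` are zero-count -> rare bucket
    n_lt = n_topics - n_gt - n_mid
    return {
        "n_gt_high": n_gt,
        "n_mid": n_mid,
        "n_lt_low": n_lt,
        "pct_gt_high": round(100.0 * n_gt / n_topics, 1),
        "pct_mid": round(100.0 * n_mid / n_topics, 1),
        "pct_lt_low": round(100.0 * n_lt / n_topics, 1),
        "catalog_size": n_topics,
    }


@dataclass
class ComplexityRow:
    pgy: int
    n_encounters: int
    mean_esi: float
    high_acuity_fraction: float
    admission_rate: float


def complexity_progression(
    attributions: pd.DataFrame,
    encounters: pd.DataFrame,
    residents: list[Resident],
) -> pd.DataFrame:
    """Per-PGY mean ESI, high-acuity (ESI 1-2) fraction, admission rate.

    Uses unique-encounter counting: each encounter contributes once, to
    the PGY of its *primary* resident at arrival.  Missing ESI is
    excluded from ESI numerators and denominators.
    """
    by_id = {r.resident_id: r for r in residents}
    prim = attributions[attributions["role"] == "primary"]
    merged = prim.merge(encounters, on="encounter_id", how="inner")
    rows = []
    pgys = []
    for rec in merged.itertuples():
        res = by_id.get(rec.resident_id)
        pgys.append(assign_pgy(res, rec.arrival_time) if res else None)
    merged = merged.assign(pgy=pd.array(pgys, dtype="Int64"))
    merged = merged.dropna(subset=["pgy"])
    for pgy, grp in merged.groupby("pgy"):
        esi = grp["esi"].dropna().astype(float)
        rows.append(
            ComplexityRow(
                pgy=int(pgy),
                n_encounters=len(grp),
                mean_esi=float(esi.mean()) if len(esi) else float("nan"),
                high_acuity_fraction=float((esi <= 2).mean()) if len(esi) else float("nan"),
                admission_rate=float((grp["disposition"] == "admitted").mean()),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("pgy").sort_index()


def topic_gini_summary(
    resident_topic_counts: pd.DataFrame, *, sample_corrected: bool = False
) -> dict:
    """Gini of topic-distribution inequality, both ways the quantity can
    be read: per-resident (Gini of each resident's per-topic count
    vector, averaged) and pooled (Gini of the summed per-topic counts).

    ``resident_topic_counts``: residents x topics count matrix.
    """
    per_res = [
        gini(row, sample_corrected=sample_corrected)
        for _, row in resident_topic_counts.iterrows()
        if row.sum() > 0
    ]
    pooled = gini(resident_topic_counts.sum(axis=0), sample_corrected=sample_corrected)
    return {
        "mean_per_resident": float(np.mean(per_res)) if per_res else float("nan"),
        "pooled": pooled,
    }
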