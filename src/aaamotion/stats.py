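"""Cohort-level change and correlation statistics.

Reproduces the study's statistical surface for a paired-timepoint cohort:

- per-variable change summary (median [IQR] at each timepoint, absolute and
  percent per-patient deltas, Wilcoxon signed-rank p, and the per-patient
  change normalized per 12 months);
- Pearson correlations of the absolute metric deltas with the absolute PWS and
  PWRI deltas;
- Pearson correlations of the three maximum-point motion distances with all
  metric deltas (the study's null finding);
- a high-vs-low motion group comparison by median split with rank-sum tests.

Per-patient quantities (delta %, normalization per 12 months) are computed per
patient first and then summarized — never as ratios of cohort medians.
Quartiles use linear interpolation (numpy's default, R type 7). No
multiple-testing correction is applied, matching the study's reporting; a
Benjamini-Hochberg column can be requested as a clearly labelled extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Variables summarized in the change table, in reporting order.
CHANGE_VARIABLES = (
    "max_diameter",
    "alpha_angle",
    "beta_angle",
    "neck_length",
    "neck_diameter",
    "aortic_tortuosity",
    "iliac_tortuosity",
    "max_lumen_diameter",
    "max_ilt_thickness",
    "lumen_volume",
    "vessel_volume",
    "ilt_volume",
    "pws",
    "pwri",
)

MOTION_COLUMNS = ("motion_max_ilt", "motion_max_pws", "motion_max_pwri")


class DegenerateTestError(ValueError):
    """A test was requested on data that cannot support it."""


def normalize_per_12_months(delta: float, interval_months: float) -> float:
    """Scale a per-patient change to a 12-month (per-year) rate."""
    if not interval_months > 0:
        raise ValueError(f"interval_months must be > 0, got {interval_months}")
    return delta * 12.0 / interval_months


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation quartiles; NaNs excluded."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("median_iqr: no non-missing values")
    if v.size < len(np.atleast_1d(values)):
        logger.info("median_iqr: excluded %d missing values", len(np.atleast_1d(values)) - v.size)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def wilcoxon_signed_rank(ct1, ct2) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test of CT2 vs CT1.

    Zero differences are dropped (Wilcoxon convention) and counted in the log.
    The null distribution is enumerated exactly for n <= 25 without ties;
    otherwise the normal approximation with continuity and tie correction is
    used. Returns (statistic, p). If every difference is zero the test is
    degenerate: (0, 1) is returned and a warning logged.
    """
    a, b = np.asarray(ct1, float), np.asarray(ct2, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    n_zero = int(np.sum(d == 0))
    if n_zero:
        logger.info("wilcoxon_signed_rank: dropped %d zero differences", n_zero)
    d = d[d != 0]
    if d.size == 0:
        logger.warning("wilcoxon_signed_rank: all differences zero; degenerate p = 1")
        return 0.0, 1.0
    if d.size < 5:
        logger.warning("wilcoxon_signed_rank: only %d non-zero differences", d.size)
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test between two independent groups.

    Exact null distribution for m + n <= 20 without ties; otherwise normal
    approximation with continuity and tie correction.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum: both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson correlation with two-sided t-based p; pairwise-complete.

    Missing (NaN) entries are removed pairwise and the effective n returned.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("pearson: unequal lengths")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"pearson: need n >= 3 complete pairs, got {n}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson: zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class CohortTables:
    """The four cohort-analysis tables plus processing notes."""

    change_table: pd.DataFrame
    correlation_changes: pd.DataFrame  # deltas vs delta-PWS / delta-PWRI
    correlation_motion: pd.DataFrame  # motions vs deltas
    group_comparison: pd.DataFrame  # median-split rank-sum per motion
    notes: list = field(default_factory=list)


def _available_variables(records: pd.DataFrame) -> list[str]:
    return [
        v
        for v in CHANGE_VARIABLES
        if f"{v}_ct1" in records.columns and f"{v}_ct2" in records.columns
        and records[f"{v}_ct1"].notna().any()
    ]


def build_cohort_tables(records: pd.DataFrame, alpha: float = 0.05,
                        bh_column: bool = False) -> CohortTables:
    """Build the full cohort analysis from a per-patient record table.

    ``records`` must hold one row per patient with ``interval_months``,
    ``<var>_ct1`` / ``<var>_ct2`` columns for the tracked variables, and the
    three ``motion_max_*`` distance columns (mm). Optional: ``age_years``.

    Raises on fewer than 3 records. Patients with a zero CT1 value for a
    variable are excluded from that variable's percent change (logged).
    """
    if len(records) < 3:
        raise ValueError(f"need >= 3 patient records, got {len(records)}")
    if (records["interval_months"] <= 0).any():
        raise ValueError("interval_months must be > 0 for every patient")
    notes: list[str] = []
    variables = _available_variables(records)

    rows = []
    deltas = pd.DataFrame(index=records.index)
    for v in variables:
        ct1, ct2 = records[f"{v}_ct1"].to_numpy(float), records[f"{v}_ct2"].to_numpy(float)
        d = ct2 - ct1
        deltas[v] = d
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(ct1 != 0, 100.0 * d / ct1, np.nan)
        n_zero_base = int(np.sum((ct1 == 0) & np.isfinite(d)))
        if n_zero_base:
            msg = f"{v}: {n_zero_base} patients with CT1 = 0 excluded from percent change"
            logger.info(msg)
            notes.append(msg)
        norm = d * 12.0 / records["interval_months"].to_numpy(float)
        complete = np.isfinite(ct1) & np.isfinite(ct2)
        if np.all(d[complete] == 0):
            p = 1.0
            notes.append(f"{v}: all differences zero; Wilcoxon degenerate (p = 1)")
        else:
            _, p = wilcoxon_signed_rank(ct1[complete], ct2[complete])
        m1, q11, q31 = median_iqr(ct1)
        m2, q12, q32 = median_iqr(ct2)
        md, qd1, qd3 = median_iqr(d)
        mp_, qp1, qp3 = (np.nan,) * 3 if not np.isfinite(pct).any() else median_iqr(pct)
        mn, qn1, qn3 = median_iqr(norm)
        rows.append(
            dict(
                variable=v,
                ct1_median=m1, ct1_q1=q11, ct1_q3=q31,
                ct2_median=m2, ct2_q1=q12, ct2_q3=q32,
                delta_abs_median=md, delta_abs_q1=qd1, delta_abs_q3=qd3,
                delta_pct_median=mp_, delta_pct_q1=qp1, delta_pct_q3=qp3,
                p_wilcoxon=p,
                significant=p < alpha,
                norm12_median=mn, norm12_q1=qn1, norm12_q3=qn3,
            )
        )
    change_table = pd.DataFrame(rows)
    if bh_column and len(change_table):
        change_table["p_bh_adjusted_extension"] = _bh_adjust(change_table["p_wilcoxon"].to_numpy())

    # correlations of deltas (plus age, interval) with delta PWS / delta PWRI
    predictors: dict[str, np.ndarray] = {}
    if "age_years" in records.columns and records["age_years"].notna().any():
        predictors["age_years"] = records["age_years"].to_numpy(float)
    predictors["interval_months"] = records["interval_months"].to_numpy(float)
    for v in variables:
        if v not in ("pws", "pwri"):
            predictors[f"delta_{v}"] = deltas[v].to_numpy()

    corr_rows = []
    for name, x in predictors.items():
        row: dict = {"variable": name}
        for target in ("pws", "pwri"):
            if target in deltas:
                try:
                    r, p, n = pearson(x, deltas[target].to_numpy())
                except ValueError:
                    r, p, n = np.nan, np.nan, 0
                row[f"r_delta_{target}"] = r
                row[f"p_delta_{target}"] = p
                row[f"n_delta_{target}"] = n
                row[f"sig_delta_{target}"] = bool(p < alpha) if np.isfinite(p) else False
        corr_rows.append(row)
    correlation_changes = pd.DataFrame(corr_rows)

    # motion distances vs every delta (study's null-result table)
    motion_rows = []
    motion_cols = [c for c in MOTION_COLUMNS if c in records.columns]
    all_deltas = dict(predictors)
    for target in ("pws", "pwri"):
        if target in deltas:
            all_deltas[f"delta_{target}"] = deltas[target].to_numpy()
    for name, x in all_deltas.items():
        row = {"variable": name}
        for mc in motion_cols:
            try:
                r, p, n = pearson(x, records[mc].to_numpy(float))
            except ValueError:
                r, p, n = np.nan, np.nan, 0
            row[f"r_{mc}"] = r
            row[f"p_{mc}"] = p
            row[f"sig_{mc}"] = bool(p < alpha) if np.isfinite(p) else False
        motion_rows.append(row)
    correlation_motion = pd.DataFrame(motion_rows)

    # high vs low motion groups: median split per motion distance
    group_rows = []
    for mc in motion_cols:
        dist = records[mc].to_numpy(float)
        med = float(np.nanmedian(dist))
        high = dist > med  # ties at the median fall into the low group
        n_tie = int(np.sum(dist == med))
        if n_tie:
            notes.append(f"{mc}: {n_tie} patients at the median assigned to the low-motion group")
        for v in variables:
            d = deltas[v].to_numpy()
            lo, hi = d[~high & np.isfinite(d)], d[high & np.isfinite(d)]
            if lo.size == 0 or hi.size == 0:
                stat, p = np.nan, np.nan
            else:
                stat, p = rank_sum(lo, hi)
            group_rows.append(
                dict(motion=mc, variable=v, n_low=int(lo.size), n_high=int(hi.size),
                     statistic=stat, p_ranksum=p,
                     significant=bool(p < alpha) if np.isfinite(p) else False)
            )
    group_comparison = pd.DataFrame(group_rows)

    return CohortTables(
        change_table=change_table,
        correlation_changes=correlation_changes,
        correlation_motion=correlation_motion,
        group_comparison=group_comparison,
        notes=notes,
    )
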