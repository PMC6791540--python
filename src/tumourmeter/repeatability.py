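"""Measurement-agreement statistics for calliper / scan records.

Record collections are pandas DataFrames in the canonical schema produced
by :mod:`tumourmeter.data_io`: columns ``study_id, mouse_id, day,
operator_id, instrument, length, width, height, area, weight, excluded``
(optional columns may be absent or NaN).  Rows flagged ``excluded`` are
dropped before any statistic.

Implemented statistics: inter-operator coefficient of variation per
(mouse, day) group, CV precision banding at an acceptability threshold,
ICC(2,1) (two-way random effects, absolute agreement, single measurement)
stratified by operator count with F-based 95% CIs, Bland-Altman
volume-vs-weight agreement, relative-error banding against excised weight,
scan-vs-calliper same-day consistency counting, and one-sided Welch t-tests
with Holm adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DataError
from .measure import cylindrical_volume, ellipsoid_volume, spheroid_volume

MM3_PER_CM3 = 1000.0

VOLUME_FORMULAE = ("eq1", "eq2", "ell")


def _excluded_mask(col: pd.Series) -> pd.Series:
    return col.map(lambda v: bool(v) if pd.notna(v) else False)


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman summary of volume-estimate vs weight-equivalent volume."""

    mean_discrepancy: float  # mm^3
    median_discrepancy: float  # mm^3
    slope_m: float
    slope_ci: tuple[float, float]
    r_squared: float
    n: int


def record_volume(row: pd.Series, formula: str = "eq1") -> float:
    """Volume (mm^3) of one measurement record under the chosen formula."""
    if formula == "eq1":
        l, w = float(row["length"]), float(row["width"])
        if w > l:
            l, w = w, l
        return spheroid_volume(l, w)
    if formula == "eq2":
        return cylindrical_volume(float(row["area"]), float(row["height"]))
    if formula == "ell":
        l, w = float(row["length"]), float(row["width"])
        if w > l:
            l, w = w, l
        return ellipsoid_volume(l, w, float(row["height"]))
    raise ValueError(f"unknown volume formula {formula!r}; expected one of {VOLUME_FORMULAE}")


def add_volumes(records: pd.DataFrame, formula: str = "eq1") -> pd.DataFrame:
    """Drop excluded rows and attach a ``volume`` column (mm^3)."""
    df = records.copy()
    if "excluded" in df.columns:
        df = df[~_excluded_mask(df["excluded"])]
    if formula == "eq1":
        l = df[["length", "width"]].max(axis=1)
        w = df[["length", "width"]].min(axis=1)
        df["volume"] = math.pi / 6.0 * l * w**2
    elif formula == "eq2":
        df["volume"] = df["area"] * df["height"]
    elif formula == "ell":
        l = df[["length", "width"]].max(axis=1)
        w = df[["length", "width"]].min(axis=1)
        df["volume"] = math.pi / 6.0 * l * w * df["height"]
    else:
        raise ValueError(f"unknown volume formula {formula!r}")
    return df


def coefficient_of_variation(values) -> float | None:
    """Sample sd (n-1 denominator) over mean; None with <2 values or mean <= 0."""
    x = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if x.size < 2:
        return None
    mu = x.mean()
    if mu <= 0:
        return None
    return float(x.std(ddof=1) / mu)


def precision_points(records: pd.DataFrame, volume_formula: str = "eq1") -> pd.DataFrame:
    """Inter-operator CV per (mouse, day) group.

    Duplicate same-operator measurements are averaged first; groups with a
    single operator yield no point; groups with >= 2 operators but fewer
    than 2 valid volumes yield a null CV.  Columns: mouse_id, day,
    n_operators, cv.
    """
    df = add_volumes(records, volume_formula)
    rows = []
    for (mouse, day), grp in df.groupby(["mouse_id", "day"], sort=True):
        per_op = grp.groupby("operator_id")["volume"].mean()
        if len(per_op) < 2:
            continue
        rows.append(
            {
                "mouse_id": mouse,
                "day": day,
                "n_operators": int(len(per_op)),
                "cv": coefficient_of_variation(per_op.to_numpy()),
            }
        )
    return pd.DataFrame(rows, columns=["mouse_id", "day", "n_operators", "cv"])


def precision_band_summary(
    points: pd.DataFrame, threshold: float = 0.2
) -> tuple[float, float, float]:
    """(fraction below threshold, fraction at/above, fraction null) over all points."""
    if len(points) == 0:
        raise DataError("no precision points to summarise")
    cv = points["cv"]
    n = len(points)
    n_null = int(cv.isna().sum())
    n_below = int((cv < threshold).sum())
    n_above = n - n_null - n_below
    return (n_below / n, n_above / n, n_null / n)


def icc2_1(table: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``table`` is an (n_subjects, k_raters) matrix.  Returns (icc, ci_low,
    ci_high); the CI follows the McGraw & Wong F-based construction with a
    Satterthwaite df for the denominator.
    """
    y = np.asarray(table, dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise DataError("ICC needs at least 2 subjects and 2 raters")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (mse == 0 and msc == msr):
        return 1.0, 1.0, 1.0
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0:
        return float(icc), float(icc), float(icc)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), float(icc), float(icc)
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), float(lower), float(upper)


def icc_by_operator_count(
    records: pd.DataFrame, volume_formula: str = "eq1", confidence: float = 0.95
) -> pd.DataFrame:
    """Stratify (mouse, day) groups by distinct-operator count k and compute the
    ICC of per-operator volumes within each stratum.

    Operators vary between groups, so within each group the per-operator
    mean volumes are assigned to rater columns in operator-id order — raters
    are treated as interchangeable draws from the operator pool.  Strata
    with fewer than 2 groups are skipped.  Columns: n_operators, icc,
    ci_low, ci_high, n_groups.
    """
    df = add_volumes(records, volume_formula)
    by_k: dict[int, list[np.ndarray]] = {}
    for (_, _), grp in df.groupby(["mouse_id", "day"], sort=True):
        per_op = grp.groupby("operator_id")["volume"].mean().sort_index()
        k = len(per_op)
        if k < 2 or per_op.isna().any():
            continue
        by_k.setdefault(k, []).append(per_op.to_numpy())
    rows = []
    for k in sorted(by_k):
        tables = by_k[k]
        if len(tables) < 2:
            continue
        icc, lo, hi = icc2_1(np.vstack(tables), confidence)
        rows.append(
            {
                "n_operators": k,
                "icc": icc,
                "ci_low": lo,
                "ci_high": hi,
                "n_groups": len(tables),
            }
        )
    return pd.DataFrame(rows, columns=["n_operators", "icc", "ci_low", "ci_high", "n_groups"])


def weight_equivalent_volume(weights_g, density: float = 1.0) -> np.ndarray:
    """Excised weight (g) converted to volume (mm^3) at the given density (g/cm^3)."""
    w = np.asarray(weights_g, dtype=float)
    return w / density * MM3_PER_CM3


def bland_altman(
    volumes, weights, density: float = 1.0
) -> tuple[AgreementSummary, pd.DataFrame]:
    """Bland-Altman agreement of volume estimates (mm^3) with excised weights (g).

    Weights are converted to equivalent volumes at ``density``; returns the
    summary (mean/median discrepancy, OLS slope of difference vs mean with
    95% CI, R^2) and the per-pair (mean, difference) points.
    """
    v = np.asarray(volumes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise DataError("volumes and weights must be paired (equal length)")
    if v.size < 3:
        raise DataError("need at least 3 pairs")
    veq = weight_equivalent_volume(w, density)
    diff = v - veq
    mean = (v + veq) / 2.0
    if np.allclose(mean, mean[0]):
        slope, ci, r2 = 0.0, (0.0, 0.0), 0.0
    else:
        fit = stats.linregress(mean, diff)
        tcrit = stats.t.ppf(0.975, v.size - 2)
        slope = float(fit.slope)
        ci = (slope - tcrit * fit.stderr, slope + tcrit * fit.stderr)
        r2 = float(fit.rvalue**2)
    summary = AgreementSummary(
        mean_discrepancy=float(diff.mean()),
        median_discrepancy=float(np.median(diff)),
        slope_m=slope,
        slope_ci=(float(ci[0]), float(ci[1])),
        r_squared=r2,
        n=int(v.size),
    )
    points = pd.DataFrame({"mean": mean, "difference": diff})
    return summary, points


def relative_error_banding(
    volumes,
    weights,
    density: float = 1.0,
    bands: tuple[float, ...] = (0.2, 0.5),
) -> dict:
    """Relative error of gram-equivalent volume vs excised weight, banded.

    relative error = (V * density / 1000 - W) / W per pair.  Returns
    proportions: ``volume_gt_weight`` (error > 0), ``abs_err_lt_<band>``
    for each band, ``weight_ge_half_volume`` (weight at least half the
    volume equivalent, i.e. error <= 1), plus ``n`` and ``n_dropped``
    (zero-weight pairs).
    """
    v = np.asarray(volumes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise DataError("volumes and weights must be paired (equal length)")
    ok = w > 0
    n_dropped = int((~ok).sum())
    v, w = v[ok], w[ok]
    if v.size == 0:
        raise DataError("no usable pairs (all weights zero)")
    veq_g = v * density / MM3_PER_CM3
    err = (veq_g - w) / w
    out = {
        "volume_gt_weight": float((err > 0).mean()),
        "weight_ge_half_volume": float((w >= 0.5 * veq_g).mean()),
        "n": int(v.size),
        "n_dropped": n_dropped,
    }
    for band in bands:
        out[f"abs_err_lt_{band:g}"] = float((np.abs(err) < band).mean())
    return out


def consistency_within(
    scan_records: pd.DataFrame,
    calliper_records: pd.DataFrame,
    tolerance: float = 3.0,
    outlier_threshold: float = 8.0,
    dimensions: tuple[str, ...] = ("length", "width"),
) -> dict[str, dict]:
    """Same-day scan-vs-calliper agreement of linear measurements.

    Each scan is paired with the mean calliper value for the same
    (mouse_id, day); unmatched scans are excluded and counted.  Per
    dimension, reports the fraction of differences within ``+/- tolerance``
    mm, the fraction beyond ``outlier_threshold`` mm, and 1-mm-binned
    difference counts (split by ``strain`` when that column is present).
    """
    scan = scan_records.copy()
    cal = calliper_records.copy()
    for df in (scan, cal):
        if "excluded" in df.columns:
            df.drop(df.index[_excluded_mask(df["excluded"])], inplace=True)
    out: dict[str, dict] = {}
    cal_means = cal.groupby(["mouse_id", "day"])[list(dimensions)].mean()
    merged = scan.merge(
        cal_means, on=["mouse_id", "day"], how="left", suffixes=("", "_cal")
    )
    for dim in dimensions:
        diff = merged[dim] - merged[f"{dim}_cal"]
        matched = diff.notna()
        d = diff[matched].to_numpy()
        if d.size == 0:
            raise DataError(f"no matched scan/calliper pairs for {dim}")
        lo = np.floor(d.min())
        hi = np.ceil(d.max())
        edges = np.arange(lo, hi + 1.0)
        if len(edges) < 2:
            edges = np.array([lo, lo + 1.0])
        binned = pd.cut(d, bins=edges, include_lowest=True)
        hist = pd.DataFrame({"bin": binned})
        if "strain" in merged.columns:
            hist["strain"] = merged.loc[matched, "strain"].to_numpy()
            counts = hist.groupby(["bin", "strain"], observed=True).size().reset_index(name="count")
        else:
            counts = hist.groupby("bin", observed=True).size().reset_index(name="count")
        out[dim] = {
            "fraction_within": float((np.abs(d) <= tolerance).mean()),
            "fraction_beyond": float((np.abs(d) > outlier_threshold).mean()),
            "histogram": counts,
            "n_pairs": int(d.size),
            "n_unmatched": int((~matched).sum()),
        }
    return out


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def welch_one_sided_tests(
    groups_a,
    groups_b,
    labels=None,
    alternative: str = "less",
) -> pd.DataFrame:
    """Welch (unequal-variance) one-sided t-tests with Holm adjustment.

    ``groups_a``/``groups_b`` are parallel lists of samples; ``alternative``
    states the direction for group a relative to group b.  Degenerate
    comparisons (both groups constant and equal) get p = 1 and are flagged.
    """
    if len(groups_a) != len(groups_b):
        raise DataError("groups_a and groups_b must have the same length")
    if labels is None:
        labels = [f"comparison_{i}" for i in range(len(groups_a))]
    rows = []
    for label, a, b in zip(labels, groups_a, groups_b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise DataError(f"{label}: each group needs >= 2 values")
        degenerate = a.std() == 0 and b.std() == 0
        if degenerate:
            if a.mean() != b.mean():
                warnings.warn(f"{label}: zero variance with unequal means", stacklevel=2)
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        rows.append({"label": label, "t": float(t), "p_raw": float(p), "degenerate": degenerate})
    df = pd.DataFrame(rows)
    df["p_adj"] = holm_adjust(df["p_raw"].to_numpy())
    return df[["label", "t", "p_raw", "p_adj", "degenerate"]]
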