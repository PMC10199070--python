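"""Grader adjudication, delta outcomes, dichotomization and univariate tests.

Sign conventions (they matter and are used everywhere downstream):

* ``d_bcva_letters`` = visit minus baseline (positive = vision gain);
* ``d_crt*_um``     = baseline minus visit (positive = thinning).

Unpaired group contrasts use Welch's t or the Wilcoxon rank-sum
(Mann-Whitney) test; the signed-rank test is reserved for paired
within-eye month contrasts, matching each test to its sampling design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLDS = {
    "vd": 0.1,
    "ldl_mmol_l": 2.6,
    "bcva_letters": 70.0,  # "excellent" visual outcome
}

_DELTA_COLS = {
    "bcva_letters": ("d_bcva_letters", +1),  # visit - baseline
    "crt1_um": ("d_crt1_um", -1),  # baseline - visit
    "crt3_um": ("d_crt3_um", -1),
    "crt6_um": ("d_crt6_um", -1),
}


def adjudicate(grader1, grader2, grader3, domain: Sequence | None = None):
    """Consensus grade: grader1 when the first two agree, else grader3.

    Accepts scalars or equal-length arrays.  When ``domain`` is given,
    every grade must belong to it (guards against mixing feature columns).
    """
    g1, g2, g3 = (np.asarray(g, dtype=object) for g in (grader1, grader2, grader3))
    if not (g1.shape == g2.shape == g3.shape):
        raise ValueError("grader inputs must have identical shape")
    if domain is not None:
        allowed = set(domain)
        for g in (g1, g2, g3):
            bad = {v for v in np.atleast_1d(g).tolist() if v not in allowed}
            if bad:
                raise ValueError(f"grades outside domain {sorted(map(str, allowed))}: {bad}")
    out = np.where(g1 == g2, g1, g3)
    return out.item() if out.ndim == 0 else out


def disagreement_rate(grader1, grader2) -> float:
    g1, g2 = np.asarray(grader1, dtype=object), np.asarray(grader2, dtype=object)
    if g1.size == 0:
        raise ValueError("no grades to compare")
    return float(np.mean(g1 != g2))


def compute_deltas(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-eye change-from-baseline table (month-0 rows are exactly zero).

    Missing months simply yield no row; nothing is imputed.  Duplicate
    (eye, month) rows and eyes without a month-0 visit are errors.
    """
    key = ["patient_id", "eye"]
    if visits.duplicated(subset=key + ["month"]).any():
        dupes = visits[visits.duplicated(subset=key + ["month"], keep=False)]
        raise ValueError(f"duplicate (eye, month) visit rows:\n{dupes[key + ['month']]}")
    baselines = visits[visits["month"] == 0].set_index(key)
    missing = set(map(tuple, visits[key].drop_duplicates().values)) - set(baselines.index)
    if missing:
        raise ValueError(f"eyes without a month-0 visit: {sorted(missing)}")

    merged = visits.merge(
        baselines[[c for c in _DELTA_COLS if c in visits.columns]],
        left_on=key, right_index=True, suffixes=("", "_baseline"),
    )
    out = merged[key + ["month"]].copy()
    for col, (name, sign) in _DELTA_COLS.items():
        if col in visits.columns:
            diff = merged[col] - merged[f"{col}_baseline"]
            out[name] = sign * diff
    return out.sort_values(key + ["month"]).reset_index(drop=True)


def dichotomize(
    records: pd.DataFrame, variable: str, threshold: float | None = None
) -> tuple[pd.DataFrame, int]:
    """Flag records at ``value >= threshold``; returns (records, n_missing).

    The flag column is named ``{variable}_ge_{threshold}``; rows with a
    missing value get a missing flag and are counted, never silently kept.
    """
    if variable not in records.columns:
        raise KeyError(f"variable {variable!r} not present")
    if threshold is None:
        if variable not in DEFAULT_THRESHOLDS:
            raise ValueError(f"no default threshold for {variable!r}")
        threshold = DEFAULT_THRESHOLDS[variable]
    values = pd.to_numeric(records[variable], errors="coerce")
    flag = values >= threshold
    flag = flag.astype(object)
    flag[values.isna()] = pd.NA
    out = records.copy()
    out[f"{variable}_ge_{threshold:g}"] = flag
    return out, int(values.isna().sum())


@dataclass(frozen=True)
class GroupComparison:
    grouping: str
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    statistic: float
    p_value: float
    test_name: str


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    group_a, group_b, method: str = "t", grouping: str = ""
) -> GroupComparison:
    """Two-sample contrast: Welch t (``method='t'``) or Wilcoxon rank-sum.

    The rank-sum p is computed by exact enumeration when both groups have
    n <= 20 and there are no ties, and by the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if method == "t":
        statistic, p = _welch(a, b)
        name = "welch_t"
    elif method == "ranksum":
        pooled = np.concatenate([a, b])
        exact = len(a) <= 20 and len(b) <= 20 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        statistic, p = float(res.statistic), float(res.pvalue)
        name = "wilcoxon_ranksum_" + ("exact" if exact else "normal")
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        grouping=grouping,
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        statistic=statistic,
        p_value=min(float(p), 1.0),
        test_name=name,
    )


def paired_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired within-eye contrasts."""
    res = stats.wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def welch_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch t-test from published summary statistics."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def percent_reduction(baseline_mean: float, change_mean: float) -> int:
    """Mean change as a rounded percentage of the baseline mean."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return int(math.floor(100.0 * change_mean / baseline_mean + 0.5))


#: standard Snellen chart lines (denominators of 20/x)
_SNELLEN_DENOMS = (10.0, 12.5, 16.0, 20.0, 25.0, 32.0, 40.0, 50.0, 63.0,
                   80.0, 100.0, 125.0, 160.0, 200.0, 250.0, 320.0, 400.0,
                   500.0, 630.0, 800.0)


def letters_to_snellen(letters: float) -> str:
    """Approximate Snellen line for an ETDRS letter score.

    Uses logMAR = (85 - letters) / 50 and snaps the implied denominator to
    the nearest standard chart line in log space (85 letters <-> 20/20).
    """
    if not 0.0 <= letters <= 100.0:
        raise ValueError("letters must lie in [0, 100]")
    logmar = (85.0 - letters) / 50.0
    denom = 20.0 * 10.0**logmar
    best = min(_SNELLEN_DENOMS, key=lambda d: abs(math.log10(d) - math.log10(denom)))
    return f"20/{best:g}"
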