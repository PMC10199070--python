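"""Longitudinal synthetic cohorts with eye-within-patient correlation.

The outcome model for eye *i* of patient *j* at month *t* is

    y_ijt = calibrated(subgroup baseline mean - signed change at t)
            + b_j + effect_i + eps_ijt

with a patient random intercept ``b_j`` shared by both eyes, independent
per-visit residuals, BCVA clipped to a letter range and CRT floored at a
physiological minimum.  Because clipping would otherwise shift subgroup
means away from their trajectory targets, the location parameter of each
(subgroup, month) marginal is recentered so the *post*-clipping expectation
equals the trajectory value exactly (``calibrate_clamped_means``).

Covariates are drawn independently with configurable marginal frequencies;
systemic covariates live at the patient level and are shared by both eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

_STRUCTURE_STREAM = 201
_COVARIATE_STREAM = 202
_OUTCOME_STREAM = 203

MONTHS = tuple(range(7))

BCVA_BOUNDS = (0.0, 100.0)
CRT_MIN_UM = 150.0


class CohortConfigError(ValueError):
    """Invalid cohort generator configuration."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one baseline covariate.

    kind: 'binary' (params: p), 'categorical' (params: levels, probs) or
    'normal' (params: mean, sd, optional lo/hi for truncation).
    level: 'patient' (shared by both eyes) or 'eye'.
    """

    name: str
    kind: str
    level: str = "patient"
    p: float | None = None
    levels: tuple[str, ...] | None = None
    probs: tuple[float, ...] | None = None
    mean: float | None = None
    sd: float | None = None
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "normal"):
            raise CohortConfigError(f"unknown covariate kind {self.kind!r}")
        if self.level not in ("patient", "eye"):
            raise CohortConfigError(f"unknown covariate level {self.level!r}")
        if self.kind == "binary":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise CohortConfigError(f"{self.name}: p must lie in [0, 1]")
        if self.kind == "categorical":
            if not self.levels or not self.probs or len(self.levels) != len(self.probs):
                raise CohortConfigError(f"{self.name}: levels/probs mismatch")
            if any(p < 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-6:
                raise CohortConfigError(f"{self.name}: probs must be a distribution")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "binary":
            return rng.random(n) < self.p
        if self.kind == "categorical":
            return rng.choice(np.asarray(self.levels, dtype=object), size=n, p=self.probs)
        if np.isfinite(self.lo) or np.isfinite(self.hi):
            a = (self.lo - self.mean) / self.sd
            b = (self.hi - self.mean) / self.sd
            return stats.truncnorm.rvs(
                a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
            )
        return rng.normal(self.mean, self.sd, size=n)


@dataclass(frozen=True)
class Trajectory:
    """Per-subgroup baseline moments and mean change per month.

    ``bcva_change`` is visit-minus-baseline (letters); ``crt_change`` is
    baseline-minus-visit (µm, positive = thinning).  Month 0 change must
    be zero.
    """

    bcva_baseline_mean: float
    bcva_baseline_sd: float
    crt_baseline_mean: float
    crt_baseline_sd: float
    bcva_change: tuple[float, ...]
    crt_change: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, tab in (("bcva_change", self.bcva_change), ("crt_change", self.crt_change)):
            if len(tab) != len(MONTHS):
                raise CohortConfigError(f"{name} must cover months {MONTHS}")
            if tab[0] != 0.0:
                raise CohortConfigError(f"{name} must be 0 at month 0")
        if self.bcva_baseline_sd < 0 or self.crt_baseline_sd < 0:
            raise CohortConfigError("baseline sds must be nonnegative")


@dataclass(frozen=True)
class CohortParams:
    n_patients: int = 48
    p_second_eye: float = 28.0 / 48.0
    group_var: str = "vd_ge_01"
    trajectories: Mapping[bool, Trajectory] = field(default_factory=dict)
    covariates: tuple[CovariateSpec, ...] = ()
    sd_patient_intercept_bcva: float = 8.0
    sd_patient_intercept_crt: float = 80.0
    #: residual sds; overridden per subgroup when the trajectory's baseline
    #: sd exceeds the patient-intercept sd (residual = sqrt(total² - b²))
    sd_residual_bcva: float = 5.0
    sd_residual_crt: float = 40.0
    derive_residual_from_baseline_sd: bool = True
    #: additive treatment-effect knobs: covariate name -> letters (µm of
    #: extra CRT reduction) per unit of the mean-centered covariate,
    #: applied at every post-baseline month
    bcva_effects: Mapping[str, float] = field(default_factory=dict)
    crt_effects: Mapping[str, float] = field(default_factory=dict)
    dropout_prob: float = 0.0
    vd_missing_prob: float = 0.0
    calibrate_clamped_means: bool = True
    bcva_bounds: tuple[float, float] = BCVA_BOUNDS
    crt_min_um: float = CRT_MIN_UM
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_second_eye", "dropout_prob", "vd_missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{name} must lie in [0, 1]")
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be at least 1")
        if not self.trajectories:
            raise CohortConfigError("trajectories must define at least one subgroup")


class Cohort(NamedTuple):
    eyes: pd.DataFrame
    visits: pd.DataFrame


# ---------------------------------------------------------------------------
# default parameterization: a 76-eye / 48-patient DME anti-VEGF cohort

def _default_covariates() -> tuple[CovariateSpec, ...]:
    b, c, n = "binary", "categorical", "normal"
    P, E = "patient", "eye"
    return (
        CovariateSpec("age", n, P, mean=59.9, sd=12.8, lo=18.0),
        CovariateSpec("male", b, P, p=0.604),
        CovariateSpec("dm_type1", b, P, p=0.167),
        CovariateSpec("dm_duration_years", n, P, mean=20.7, sd=9.4, lo=0.5),
        CovariateSpec("hba1c", n, P, mean=8.6, sd=2.0, lo=4.5),
        CovariateSpec("insulin_use", b, P, p=0.396),
        CovariateSpec("smoking", b, P, p=0.167),
        CovariateSpec("egfr", n, P, mean=70.8, sd=22.9, lo=5.0, hi=120.0),
        CovariateSpec("creatinine", n, P, mean=101.6, sd=78.5, lo=40.0),
        CovariateSpec("ldl_mmol_l", n, P, mean=2.5, sd=1.0, lo=0.3),
        CovariateSpec("hdl_mmol_l", n, P, mean=1.2, sd=0.4, lo=0.3),
        CovariateSpec("lipid_therapy", b, P, p=0.579),
        CovariateSpec("hypertension", b, P, p=0.724),
        CovariateSpec("mi", b, P, p=0.197),
        CovariateSpec("stroke", b, P, p=0.053),
        CovariateSpec("prior_prp", b, E, p=0.513),
        CovariateSpec("pseudophakic", b, E, p=0.289),
        CovariateSpec("prior_anti_vegf", b, E, p=0.395),
        CovariateSpec("prior_steroid", b, E, p=0.049),
        CovariateSpec("prior_vitrectomy", b, E, p=0.049),
        CovariateSpec("exudates", b, E, p=0.447),
        CovariateSpec("microaneurysm_class", c, E,
                      levels=("none", "lt10", "gt10"), probs=(0.026, 0.333, 0.641)),
        CovariateSpec("leakage_pattern", c, E,
                      levels=("focal", "intermediate", "diffuse"), probs=(0.293, 0.267, 0.440)),
        CovariateSpec("peripheral_nonperfusion", b, E, p=0.465),
        CovariateSpec("srf", b, E, p=0.227),
        CovariateSpec("inl_cysts", b, E, p=0.680),
        CovariateSpec("onl_cysts", b, E, p=0.959),
        CovariateSpec("dril", b, E, p=0.257),
        CovariateSpec("intact_elm_ez", b, E, p=0.838),
        CovariateSpec("hrf", b, E, p=0.797),
        CovariateSpec("intact_terminal_ring", b, E, p=0.267),
        CovariateSpec("perifoveal_capillary_loss", b, E, p=0.827),
        CovariateSpec("vd", n, E, mean=0.098, sd=0.018, lo=0.05, hi=0.14),
    )


#: reference subgroup trajectories (monthly mean change from baseline),
#: one preset per stratifying variable
_PRESET_TRAJECTORIES: dict[str, dict[bool, Trajectory]] = {
    "vd_ge_01": {
        True: Trajectory(71.0, 16.3, 373.0, 118.6,
                         (0.0, 2.5, 4.5, 5.5, 6.3, 6.5, 6.7),
                         (0.0, 45.0, 55.0, 60.0, 65.0, 67.0, 68.3)),
        False: Trajectory(71.7, 9.2, 405.8, 127.0,
                          (0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0),
                          (0.0, 70.0, 85.0, 95.0, 100.0, 103.0, 105.2)),
    },
    "peripheral_nonperfusion": {
        True: Trajectory(71.5, 13.0, 408.1, 140.7,
                         (0.0, 1.0, 2.0, 2.5, 3.0, 3.2, 3.4),
                         (0.0, 102.6, 108.9, 115.1, 129.7, 123.5, 117.3)),
        False: Trajectory(71.5, 13.0, 376.9, 110.3,
                          (0.0, 1.0, 2.0, 2.5, 3.0, 3.2, 3.2),
                          (0.0, 44.7, 54.1, 63.4, 61.7, 70.9, 80.0)),
    },
    "ldl_ge_26": {
        True: Trajectory(73.7, 12.3, 390.0, 120.0,
                         (0.0, 1.5, 2.3, 3.0, 3.5, 3.8, 4.0),
                         (0.0, 80.0, 90.0, 95.0, 100.0, 105.0, 110.0)),
        False: Trajectory(71.6, 10.4, 388.0, 120.0,
                          (0.0, 0.6, 1.0, 1.3, 1.5, 1.7, 1.8),
                          (0.0, 60.0, 68.0, 72.0, 76.0, 78.0, 80.0)),
    },
}

#: how derived group flags are computed from covariate columns
_DERIVED_FLAGS = {
    "vd_ge_01": ("vd", 0.1),
    "ldl_ge_26": ("ldl_mmol_l", 2.6),
}


def default_cohort_params(group_var: str = "vd_ge_01", seed: int = 0, **overrides) -> CohortParams:
    """Preset emulating a 76-eye, 48-patient monthly-anti-VEGF cohort."""
    if group_var not in _PRESET_TRAJECTORIES:
        raise CohortConfigError(
            f"no trajectory preset for group_var {group_var!r}; "
            f"available: {sorted(_PRESET_TRAJECTORIES)}"
        )
    kwargs = dict(
        group_var=group_var,
        trajectories=dict(_PRESET_TRAJECTORIES[group_var]),
        covariates=_default_covariates(),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortParams(**kwargs)


# ---------------------------------------------------------------------------
# clamp-aware mean calibration

def _expected_clipped(m: float, sigma: float, lo: float, hi: float) -> float:
    """E[clip(X, lo, hi)] for X ~ N(m, sigma)."""

    def e_excess(c: float) -> float:  # E[(X - c)+]
        if not np.isfinite(c):
            return 0.0
        z = (m - c) / sigma
        return (m - c) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)

    base = lo if np.isfinite(lo) else m - 40 * sigma
    return base + e_excess(base) - e_excess(hi)


def _calibrated_location(target: float, sigma: float, lo: float, hi: float) -> float:
    """Location m such that E[clip(N(m, sigma), lo, hi)] == target."""
    if sigma <= 0:
        if not (lo - 1e-9 <= target <= hi + 1e-9):
            raise CohortConfigError(f"target {target} outside clip bounds [{lo}, {hi}]")
        return target
    if np.isfinite(lo) and target <= lo:
        raise CohortConfigError(f"target {target} not above lower clip bound {lo}")
    if np.isfinite(hi) and target >= hi:
        raise CohortConfigError(f"target {target} not below upper clip bound {hi}")
    span = 12 * sigma + 1.0
    return brentq(lambda m: _expected_clipped(m, sigma, lo, hi) - target,
                  target - span, target + span, xtol=1e-10)


# ---------------------------------------------------------------------------

def _derive_flags(eyes: pd.DataFrame) -> pd.DataFrame:
    for flag, (col, thr) in _DERIVED_FLAGS.items():
        if col in eyes.columns:
            eyes[flag] = eyes[col] >= thr
    return eyes


def _residual_sd(total_sd: float, intercept_sd: float, fallback: float, derive: bool) -> float:
    if not derive:
        return fallback
    if intercept_sd > total_sd + 1e-9:
        raise CohortConfigError(
            f"patient-intercept sd {intercept_sd} exceeds subgroup baseline sd {total_sd}"
        )
    return float(np.sqrt(max(total_sd**2 - intercept_sd**2, 0.0)))


def simulate_cohort(params: CohortParams) -> Cohort:
    """Draw one cohort: an eye table and a monthly visit table.

    The returned eye table carries the drawn covariates, derived subgroup
    flags and (``truth_``-prefixed) generator internals useful for
    recovery tests; the visit table has one row per (eye, month) with
    BCVA letters and 1/3/6-mm CRT.
    """
    rng_struct = np.random.default_rng([params.seed, _STRUCTURE_STREAM])
    rng_cov = np.random.default_rng([params.seed, _COVARIATE_STREAM])
    rng_out = np.random.default_rng([params.seed, _OUTCOME_STREAM])

    n = params.n_patients
    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    second = rng_struct.random(n) < params.p_second_eye

    rows = []
    for pid, has_second in zip(patient_ids, second):
        rows.append({"patient_id": pid, "eye": "OD"})
        if has_second:
            rows.append({"patient_id": pid, "eye": "OS"})
    eyes = pd.DataFrame(rows)
    n_eyes = len(eyes)
    pidx = eyes["patient_id"].map({p: i for i, p in enumerate(patient_ids)}).to_numpy()

    for spec in params.covariates:
        if spec.level == "patient":
            vals = spec.draw(rng_cov, n)
            eyes[spec.name] = np.asarray(vals)[pidx]
        else:
            eyes[spec.name] = spec.draw(rng_cov, n_eyes)
    eyes = _derive_flags(eyes)

    if params.vd_missing_prob > 0 and "vd" in eyes.columns:
        missing = rng_cov.random(n_eyes) < params.vd_missing_prob
        eyes.loc[missing, "vd"] = np.nan
        if "vd_ge_01" in eyes.columns:
            eyes["vd_ge_01"] = eyes["vd_ge_01"].astype(object)
            eyes.loc[missing, "vd_ge_01"] = pd.NA

    if params.group_var not in eyes.columns:
        raise CohortConfigError(f"group_var {params.group_var!r} is not a generated column")
    group = eyes[params.group_var]
    for level in pd.unique(group.dropna()):
        if bool(level) not in params.trajectories:
            raise CohortConfigError(
                f"subgroup {level!r} of {params.group_var!r} has no trajectory"
            )

    b_bcva = rng_out.normal(0.0, params.sd_patient_intercept_bcva, size=n)
    b_crt = rng_out.normal(0.0, params.sd_patient_intercept_crt, size=n)
    eyes["truth_b_bcva"] = b_bcva[pidx]
    eyes["truth_b_crt"] = b_crt[pidx]
    eyes["truth_group"] = group.to_numpy()

    def centered_effect(effects: Mapping[str, float]) -> np.ndarray:
        out = np.zeros(n_eyes)
        for name, coef in effects.items():
            if name not in eyes.columns:
                raise CohortConfigError(f"effect covariate {name!r} not generated")
            x = pd.to_numeric(eyes[name], errors="raise").to_numpy(dtype=float)
            out += coef * (x - np.nanmean(x))
        return out

    eff_bcva = centered_effect(params.bcva_effects)
    eff_crt = centered_effect(params.crt_effects)

    lo_b, hi_b = params.bcva_bounds
    visit_rows = []
    # per-subgroup calibrated locations, resolved lazily
    loc_cache: dict[tuple[bool, int, str], float] = {}

    def location(level: bool, month: int, kind: str, crt_scale: float = 1.0,
                 crt_shift: float = 0.0) -> tuple[float, float, float]:
        """(calibrated location, residual sd, intercept sd) for one cell."""
        traj = params.trajectories[level]
        if kind == "bcva":
            sd_b = params.sd_patient_intercept_bcva
            sd_e = _residual_sd(traj.bcva_baseline_sd, sd_b,
                                params.sd_residual_bcva,
                                params.derive_residual_from_baseline_sd)
            target = traj.bcva_baseline_mean + traj.bcva_change[month]
            lo, hi = lo_b, hi_b
        else:
            sd_b = params.sd_patient_intercept_crt
            sd_e = _residual_sd(traj.crt_baseline_sd, sd_b,
                                params.sd_residual_crt,
                                params.derive_residual_from_baseline_sd)
            target = (traj.crt_baseline_mean + crt_shift
                      - crt_scale * traj.crt_change[month])
            lo, hi = params.crt_min_um, np.inf
        key = (level, month, f"{kind}:{crt_scale}:{crt_shift}")
        if key not in loc_cache:
            sigma_tot = float(np.hypot(sd_b, sd_e))
            loc_cache[key] = (
                _calibrated_location(target, sigma_tot, lo, hi)
                if params.calibrate_clamped_means else target
            )
        return loc_cache[key], sd_e, sd_b

    # 3- and 6-mm CRT: wider rings are thinner and change less than the
    # central 1-mm subfield; fixed affine relations keep them plausible
    crt_variants = (("crt1_um", 1.0, 0.0), ("crt3_um", 0.85, -15.0), ("crt6_um", 0.70, -30.0))

    for i in range(n_eyes):
        level = group.iloc[i]
        if pd.isna(level):
            level = bool(rng_out.random() < 0.5)  # ungraded: draw a latent group
        level = bool(level)
        pj = pidx[i]
        dropped = False
        for month in MONTHS:
            if month > 0 and params.dropout_prob > 0 and not dropped:
                dropped = rng_out.random() < params.dropout_prob
            if dropped:
                continue
            loc, sd_e, _ = location(level, month, "bcva")
            bcva = loc + b_bcva[pj] + (eff_bcva[i] if month > 0 else 0.0) \
                + rng_out.normal(0.0, sd_e)
            bcva = float(np.clip(bcva, lo_b, hi_b))
            row = {"patient_id": eyes["patient_id"].iloc[i],
                   "eye": eyes["eye"].iloc[i], "month": month,
                   "bcva_letters": bcva}
            for col, scale, shift in crt_variants:
                loc, sd_e, _ = location(level, month, "crt", scale, shift)
                crt = loc + b_crt[pj] - (scale * eff_crt[i] if month > 0 else 0.0) \
                    + rng_out.normal(0.0, sd_e)
                row[col] = float(max(crt, params.crt_min_um))
            visit_rows.append(row)

    visits = pd.DataFrame(visit_rows)
    return Cohort(eyes=eyes, visits=visits)
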