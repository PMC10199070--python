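"""Mixed-effects predictor screening with backward elimination.

Three response families share one modelling surface:

* ``bcva_improvement`` - longitudinal BCVA change (months 1..6);
* ``crt_reduction``    - longitudinal 1-mm CRT change (months 1..6);
* ``excellent_bcva``   - final-visit letter score >= 70, fitted on the
  linear-probability scale by default (so coefficients stay on the letter
  / probability scale of the other families); a logistic option exists.

Models carry a random intercept per patient (two eyes of one patient are
correlated) and, optionally, a nested random intercept per eye for the
longitudinal families.  Backward elimination repeatedly drops the
candidate with the largest Wald p >= alpha_stay; ties are broken by
removing the candidate latest in alphabetical order, making the procedure
deterministic and input-order invariant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

RESPONSE_FAMILIES = ("bcva_improvement", "excellent_bcva", "crt_reduction")

_RESPONSE_COL = {
    "bcva_improvement": "d_bcva_letters",
    "crt_reduction": "d_crt1_um",
}

#: ordinal encodings for the graded multi-level imaging features
ORDINAL_CODES = {
    "microaneurysm_class": {"none": 0, "lt10": 1, "gt10": 2},
    "leakage_pattern": {"focal": 0, "intermediate": 1, "diffuse": 2},
}

EXCELLENT_BCVA_LETTERS = 70.0


class RankDeficientDesignError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"rank-deficient design; offending columns: {columns}")


@dataclass
class FitResult:
    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    model_type: str  # 'mixedlm' | 'ols' | 'logit'
    n_obs: int
    random_intercept_var: float | None = None

    def coef(self, term: str) -> float:
        return float(self.params[term])


def _encode(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"fixed effect {col!r} not in data")
        if col in ORDINAL_CODES:
            out[col] = out[col].map(ORDINAL_CODES[col])
            if out[col].isna().any():
                raise ValueError(f"unknown level in {col!r}")
        elif out[col].dtype == bool or out[col].dtype == object:
            out[col] = pd.to_numeric(out[col], errors="raise")
        out[col] = out[col].astype(float)
    return out


def _check_rank(df: pd.DataFrame, columns: list[str]) -> None:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in columns])
    names = ["Intercept"] + list(columns)
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    # identify offenders by greedy QR: columns that do not raise the rank
    bad, kept = [], np.ones((len(df), 1))
    for name, j in zip(names, range(X.shape[1])):
        trial = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(trial) > kept.shape[1]:
            kept = trial
        elif name != "Intercept":
            bad.append(name)
    raise RankDeficientDesignError(bad)


def build_model_frame(
    deltas: pd.DataFrame | None,
    eyes: pd.DataFrame,
    response: str,
    fixed_effects: list[str],
    visits: pd.DataFrame | None = None,
    months: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    month_as: str = "categorical",
) -> tuple[pd.DataFrame, str, list[str]]:
    """Assemble the modelling frame; returns (frame, y column, extra terms)."""
    key = ["patient_id", "eye"]
    if response in _RESPONSE_COL:
        if deltas is None:
            raise ValueError(f"{response} requires a delta table")
        ycol = _RESPONSE_COL[response]
        frame = deltas[deltas["month"].isin(months)].merge(eyes, on=key, how="inner")
        extra = ["C(month)"] if (month_as == "categorical" and len(months) > 1) else (
            ["month"] if len(months) > 1 else [])
    elif response == "excellent_bcva":
        if visits is None:
            raise ValueError("excellent_bcva requires the visit table")
        final_month = int(visits["month"].max())
        final = visits[visits["month"] == final_month]
        frame = final.merge(eyes, on=key, how="inner").copy()
        frame["excellent"] = (frame["bcva_letters"] >= EXCELLENT_BCVA_LETTERS).astype(float)
        ycol, extra = "excellent", []
    else:
        raise ValueError(f"unknown response family {response!r}")
    frame = _encode(frame, fixed_effects)
    frame = frame.dropna(subset=fixed_effects + [ycol]).reset_index(drop=True)
    frame["eye_uid"] = frame["patient_id"].astype(str) + ":" + frame["eye"].astype(str)
    return frame, ycol, extra


def fit_lmm(
    deltas: pd.DataFrame | None,
    eyes: pd.DataFrame,
    response: str,
    fixed_effects: list[str],
    *,
    visits: pd.DataFrame | None = None,
    months: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    month_as: str = "categorical",
    eye_random_intercept: bool = True,
    binary_link: str = "linear",
) -> FitResult:
    """Fit one response family with a patient random intercept.

    Falls back to a fixed-effects (OLS / logit) fit with a logged warning
    when fewer than two patients contribute two eyes, in which case the
    random intercept is not identifiable.
    """
    frame, ycol, extra = build_model_frame(
        deltas, eyes, response, fixed_effects, visits=visits,
        months=months, month_as=month_as,
    )
    if len(frame) == 0:
        raise ValueError("empty modelling frame")
    _check_rank(frame, fixed_effects)
    rhs = " + ".join(fixed_effects + extra) if (fixed_effects or extra) else "1"
    formula = f"{ycol} ~ {rhs}"

    n_two_eyed = (frame.groupby("patient_id")["eye_uid"].nunique() >= 2).sum()
    longitudinal = response in _RESPONSE_COL and frame["month"].nunique() > 1

    if response == "excellent_bcva" and binary_link == "logistic":
        res = smf.logit(formula, frame).fit(disp=0)
        return FitResult(response, res.params, res.bse, res.pvalues,
                         bool(res.mle_retvals["converged"]), "logit", len(frame))

    if n_two_eyed < 2 and not (longitudinal and eye_random_intercept):
        log.warning(
            "only %d patients with two eyes: random intercept not identifiable, "
            "falling back to fixed-effects OLS", n_two_eyed,
        )
        res = smf.ols(formula, frame).fit()
        return FitResult(response, res.params, res.bse, res.pvalues, True,
                         "ols", len(frame))

    vc = {"eye": "0 + C(eye_uid)"} if (eye_random_intercept and longitudinal) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, frame, groups=frame["patient_id"],
                            re_formula="1", vc_formula=vc)
        res = model.fit(reml=True)
    params = res.params.drop(labels=[i for i in res.params.index
                                     if i == "Group Var" or i.endswith(" Var")])
    pv = res.pvalues.reindex(params.index)
    bse = res.bse.reindex(params.index)
    return FitResult(
        response, params, bse, pv, bool(res.converged), "mixedlm", len(frame),
        random_intercept_var=float(res.cov_re.iloc[0, 0]),
    )


@dataclass
class ScreeningReport:
    """Backward-elimination outcome for one response family."""

    response: str
    alpha_stay: float
    rows: pd.DataFrame  # predictor, retained, coefficient, std_err, p_value, exit_order, flag
    trace: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return sorted(self.rows.loc[self.rows["retained"], "predictor"])


def backward_eliminate(
    deltas: pd.DataFrame | None,
    eyes: pd.DataFrame,
    response: str,
    candidates: list[str],
    *,
    alpha_stay: float = 0.05,
    forced: list[str] | None = None,
    **fit_kwargs,
) -> ScreeningReport:
    """Iteratively drop the worst candidate with p >= alpha_stay.

    ``forced`` terms stay in every model without being eligible for
    removal.  Every eliminated predictor carries its exit p-value and the
    step at which it left; the trace records the full audit trail.
    """
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidates")
    current = sorted(candidates)
    forced = list(forced or [])
    records: dict[str, dict] = {}
    trace: list[str] = []
    step = 0
    fit: FitResult | None = None

    while True:
        try:
            fit = fit_lmm(deltas, eyes, response, forced + current, **fit_kwargs)
        except (np.linalg.LinAlgError, ValueError) as exc:
            if isinstance(exc, RankDeficientDesignError):
                raise
            trace.append(f"fit failed ({exc}); retaining remaining predictors")
            for name in current:
                records[name] = dict(retained=True, coefficient=np.nan,
                                     std_err=np.nan, p_value=np.nan,
                                     exit_order=None, flag="nonconvergent")
            current = []
            break
        if not fit.converged:
            trace.append("refit did not converge; p-values used as-is")
        pvals = {c: float(fit.pvalues.get(c, np.nan)) for c in current}
        droppable = {c: p for c, p in pvals.items() if np.isnan(p) or p >= alpha_stay}
        if not droppable or not current:
            break
        worst_p = np.nanmax([p for p in droppable.values() if not np.isnan(p)]) \
            if any(not np.isnan(p) for p in droppable.values()) else np.nan
        if np.isnan(worst_p):
            ties = sorted(droppable)
        else:
            ties = sorted(c for c, p in droppable.items()
                          if np.isnan(p) or abs(p - worst_p) < 1e-12)
        victim = ties[-1]  # alphabetically latest among tied worst
        step += 1
        exit_p = pvals[victim]
        records[victim] = dict(retained=False,
                               coefficient=float(fit.params.get(victim, np.nan)),
                               std_err=float(fit.bse.get(victim, np.nan)),
                               p_value=exit_p, exit_order=step, flag="")
        trace.append(f"step {step}: removed {victim} (p={exit_p:.4g})")
        current.remove(victim)

    if fit is not None:
        for name in current:
            records[name] = dict(retained=True,
                                 coefficient=float(fit.params.get(name, np.nan)),
                                 std_err=float(fit.bse.get(name, np.nan)),
                                 p_value=float(fit.pvalues.get(name, np.nan)),
                                 exit_order=None,
                                 flag="" if fit.converged else "nonconvergent")
    rows = pd.DataFrame(
        [{"predictor": k, **v} for k, v in records.items()]
    ).sort_values("predictor").reset_index(drop=True) if records else pd.DataFrame(
        columns=["predictor", "retained", "coefficient", "std_err",
                 "p_value", "exit_order", "flag"])
    return ScreeningReport(response=response, alpha_stay=alpha_stay,
                           rows=rows, trace=trace)


def build_table3(
    reports: dict[str, ScreeningReport], alpha: float = 0.05
) -> pd.DataFrame:
    """One row per baseline variable, p / significance / coefficient per family.

    Eliminated predictors show their exit p; coefficients are attached only
    where the entry is significant at ``alpha``.
    """
    variables = sorted({v for r in reports.values() for v in r.rows["predictor"]})
    out = pd.DataFrame({"variable": variables})
    for family in RESPONSE_FAMILIES:
        if family not in reports:
            continue
        rows = reports[family].rows.set_index("predictor")
        p = rows["p_value"].reindex(variables)
        c = rows["coefficient"].reindex(variables)
        sig = (p < alpha).fillna(False)
        out[f"p_{family}"] = p.to_numpy()
        out[f"sig_{family}"] = sig.to_numpy()
        out[f"c_{family}"] = np.where(sig.to_numpy(), c.to_numpy(), np.nan)
    return out
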