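"""Trial-level inference: mixed-effects models, rank correlations, effect sizes.

The mixed-model operation is a disciplined wrapper around statsmodels'
``MixedLM`` (REML), with the factor structures used throughout the analysis:
two-level fixed factors plus interactions, per-subject random intercepts, and
an optional per-subject random slope for a continuous burst covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class ModelSpec:
    """Declarative description of one mixed-effects model."""

    dependent: str
    fixed: list  # term names, e.g. ["drawing", "stim", "drawing:stim"]
    group: str = "subject"
    random_slope: str | None = None  # continuous covariate with subject slopes

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.dependent} ~ {rhs}"


@dataclass
class ModelResult:
    coefficients: pd.DataFrame  # index: term; columns: estimate, se, stat, p
    posthoc: pd.DataFrame | None
    converged: bool
    n_used: int
    n_dropped: int
    formula: str
    random_slope_dropped: bool = False
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni adjustment: min(1, p * m)."""
    return np.minimum(1.0, np.asarray(p, float) * m) if np.ndim(p) else min(1.0, float(p) * m)


def _fit(data: pd.DataFrame, spec: ModelSpec, use_slope: bool):
    re_formula = f"~{spec.random_slope}" if (use_slope and spec.random_slope) else "~1"
    model = smf.mixedlm(spec.formula, data, groups=data[spec.group], re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            return model.fit(reml=True)
        except np.linalg.LinAlgError:
            # boundary fits (zero group variance) can break the gradient
            # path; a derivative-free optimizer still converges there
            return model.fit(reml=True, method="powell")


def fit_mixed_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    posthoc_within: tuple[str, str] | None = None,
) -> ModelResult:
    """REML mixed model with subject random intercepts (optional random slope).

    Rows with missing values in any model variable are dropped listwise and
    counted. P-values are Wald (large-sample normal) — see the docs for the
    degrees-of-freedom caveat. ``posthoc_within=(factor, within)`` requests
    Bonferroni-adjusted contrasts of ``factor`` at each level of ``within``.
    A singular random-slope fit is retried with intercepts only and flagged.
    """
    variables = {spec.dependent, spec.group}
    factors = set()
    for term in spec.fixed:
        for tok in term.replace("*", ":").split(":"):
            tok = tok.strip()
            if tok:
                variables.add(tok)
                factors.add(tok)
    if spec.random_slope:
        variables.add(spec.random_slope)
    cols = [c for c in variables if c in data.columns]
    sub = data.dropna(subset=cols)
    n_dropped = len(data) - len(sub)
    if sub[spec.group].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    for f in factors & set(sub.columns):
        if sub[f].dtype == object and sub[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level after filtering")

    def _bse(res):
        # a singular random-effects covariance (boundary fit) can make the
        # SE computation blow up; report NaN SEs instead of failing
        try:
            bse = res.bse_fe
            return bse if np.all(np.isfinite(bse)) else None
        except np.linalg.LinAlgError:
            return None

    random_slope_dropped = False
    result = _fit(sub, spec, use_slope=True)
    bse = _bse(result)
    if spec.random_slope and bse is None:
        result = _fit(sub, spec, use_slope=False)
        bse = _bse(result)
        random_slope_dropped = True

    fe = result.fe_params
    if bse is not None:
        stat = fe / bse
        pvals = 2 * sps.norm.sf(np.abs(stat))
    else:
        bse = pd.Series(np.nan, index=fe.index)
        stat = pd.Series(np.nan, index=fe.index)
        pvals = np.full(len(fe), np.nan)
    coeffs = pd.DataFrame({"estimate": fe, "se": bse, "stat": stat, "p": pvals})

    posthoc = None
    if posthoc_within is not None:
        posthoc = _pairwise_within(result, sub, spec, *posthoc_within)

    return ModelResult(
        coefficients=coeffs,
        posthoc=posthoc,
        converged=bool(result.converged),
        n_used=len(sub),
        n_dropped=n_dropped,
        formula=spec.formula,
        random_slope_dropped=random_slope_dropped,
        extra={"mixedlm": result},
    )


def _pairwise_within(result, data: pd.DataFrame, spec: ModelSpec, factor: str, within: str) -> pd.DataFrame:
    """Contrast of ``factor`` levels at each level of ``within`` (Bonferroni)."""
    import patsy

    design_info = result.model.data.design_info
    f_levels = sorted(data[factor].unique())
    w_levels = sorted(data[within].unique())
    if len(f_levels) != 2:
        raise ValueError(f"posthoc factor {factor!r} must have exactly 2 levels")
    covariates = {
        c: data[c].mean()
        for c in data.columns
        if c not in (factor, within) and np.issubdtype(data[c].dtype, np.number)
    }
    other_factors = {
        c: data[c].iloc[0]
        for c in data.columns
        if c not in (factor, within) and data[c].dtype == object
    }
    rows = []
    for w in w_levels:
        frames = []
        for f in f_levels:
            cell = {factor: [f], within: [w], **{k: [v] for k, v in covariates.items()},
                    **{k: [v] for k, v in other_factors.items()}}
            (m,) = patsy.build_design_matrices([design_info], pd.DataFrame(cell))
            frames.append(np.asarray(m)[0])
        contrast = frames[1] - frames[0]
        k_fe = len(result.fe_params)
        tt = result.t_test(np.atleast_2d(contrast[:k_fe]))
        rows.append(
            {
                "contrast": f"{factor}[{f_levels[1]}-{f_levels[0]}] | {within}={w}",
                "estimate": float(np.squeeze(tt.effect)),
                "se": float(np.squeeze(tt.sd)),
                "stat": float(np.squeeze(tt.tvalue)),
                "p_raw": float(np.squeeze(tt.pvalue)),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p_raw"].to_numpy(), len(out))
    return out


def spearman_correlations(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Spearman rho per family with family-count Bonferroni adjustment."""
    m = len(pairs)
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 5:
            raise ValueError(f"family {name!r}: fewer than 5 complete pairs")
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"family": name, "rho": np.nan, "p_raw": np.nan,
                         "p_adj": np.nan, "n": int(x.size), "flagged": True})
            continue
        rho, p = sps.spearmanr(x, y)
        p_adj = bonferroni(p, m) if correction == "bonferroni" else p
        rows.append({"family": name, "rho": float(rho), "p_raw": float(p),
                     "p_adj": float(p_adj), "n": int(x.size), "flagged": False})
    return pd.DataFrame(rows).set_index("family")


def pooled_effect_size(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d with the pooled-SD denominator sqrt((s1^2 + s2^2) / 2)."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    return (m1 - m2) / np.sqrt((s1**2 + s2**2) / 2.0)


def paired_ci(
    mean_diff: float, t_stat: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """CI of a paired mean difference back-derived from its t statistic."""
    if t_stat == 0:
        raise ValueError("t statistic of 0: CI undefined")
    if n < 2:
        raise ValueError("need n >= 2")
    se = mean_diff / t_stat
    tcrit = sps.t.ppf(1 - (1 - level) / 2, n - 1)
    return (mean_diff - tcrit * se, mean_diff + tcrit * se)


def exclusion_filters(
    trials: pd.DataFrame,
    drop_inaccurate: bool = False,
    drop_tremor_subjects: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Apply the trial/subject exclusion rules; report counts per condition.

    Raises if a cell of the drawing x stimulation design would be emptied.
    """
    keep = pd.Series(True, index=trials.index)
    if drop_inaccurate and "inaccurate" in trials.columns:
        keep &= ~trials["inaccurate"].astype(bool)
    if drop_tremor_subjects and "tremor_subject" in trials.columns:
        keep &= ~trials["tremor_subject"].astype(bool)
    removed = trials[~keep]
    out = trials[keep].copy()
    report = {
        "n_removed": int(len(removed)),
        "by_condition": removed.groupby(["drawing", "stim"]).size().to_dict()
        if len(removed)
        else {},
    }
    for d in trials["drawing"].unique():
        for s in trials["stim"].unique():
            if ((out["drawing"] == d) & (out["stim"] == s)).sum() == 0:
                raise ValueError(f"exclusion emptied design cell ({d}, {s})")
    return out, report
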