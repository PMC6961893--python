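"""Inferential layer: random-intercept mixed models and the PSE-noise slope.

The window-mean bias per subject and condition is modelled as
``bias ~ fixed terms + (1 | subject)`` with velocity (deg/s) and noise
(fraction) as numeric covariates, fitted by maximum likelihood (not REML) so
that likelihood-ratio comparisons between nested fixed-effect structures are
coherent.  The PSE-versus-noise analysis fits a fixed slope with a random
per-subject slope; significance uses a t reference with ``n_subjects - 1``
degrees of freedom (a simple documented surrogate for Satterthwaite's
approximation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "MixedModelFit",
    "LrtResult",
    "PseSlopeFit",
    "fit_lmm",
    "lrt",
    "lrt_table",
    "fit_pse_slope",
]

_TERM_RHS = {"velocity": "velocity", "noise": "noise", "interaction": "velocity:noise"}


@dataclass
class MixedModelFit:
    """A maximum-likelihood random-intercept fit and its bookkeeping."""

    terms: tuple[str, ...]
    formula: str
    fe_params: pd.Series
    re_var: float
    resid_var: float
    llf: float
    n_fixed: int
    n_params: int
    n_obs: int
    converged: bool


@dataclass
class LrtResult:
    statistic: float
    df: int
    p: float


@dataclass
class PseSlopeFit:
    slope: float
    se: float
    t: float
    df: int
    p: float
    n_subjects: int
    ci: tuple[float, float]
    method: str


def _formula(terms: tuple[str, ...], response: str) -> str:
    unknown = set(terms) - set(_TERM_RHS)
    if unknown:
        raise ValueError(f"unknown terms {sorted(unknown)}")
    rhs = ["1"] + [_TERM_RHS[t] for t in ("velocity", "noise", "interaction") if t in terms]
    return f"{response} ~ " + " + ".join(rhs)


def fit_lmm(
    table: pd.DataFrame,
    terms: tuple[str, ...] = ("velocity", "noise", "interaction"),
    response: str = "window_mean_deg",
) -> MixedModelFit:
    """ML fit of ``response ~ terms + (random intercept | subject)``.

    ``terms`` is any subset of {"velocity", "noise", "interaction"}; the
    parameter count includes the fixed effects plus the two variance
    components, so nested-model likelihood-ratio degrees of freedom reduce to
    the difference in fixed-effect counts.
    """
    terms = tuple(terms)
    for col in ("subject", "velocity", "noise", response):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if table[["velocity", "noise"]].drop_duplicates().shape[0] < 2:
        raise ValueError("need at least 2 conditions")
    formula = _formula(terms, response)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = MixedLM.from_formula(formula, table, groups=table["subject"])
        res = None
        last_exc: Exception | None = None
        # the default optimizer occasionally fails at the post-fit Hessian
        # inversion on near-degenerate variance components; try alternatives
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = md.fit(reml=False, method=method, maxiter=1000)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if np.isfinite(cand.llf):
                if res is None or cand.llf > res.llf + 1e-8:
                    res = cand
                if cand.converged:
                    break
        if res is None:
            raise ValueError(
                f"mixed-model fit failed for formula {formula!r} "
                f"(singular or degenerate design): {last_exc}"
            ) from last_exc
    fe = res.fe_params
    return MixedModelFit(
        terms=terms,
        formula=formula,
        fe_params=fe,
        re_var=float(np.atleast_2d(res.cov_re)[0, 0] * res.scale)
        if res.cov_re.size
        else 0.0,
        resid_var=float(res.scale),
        llf=float(res.llf),
        n_fixed=len(fe),
        n_params=len(fe) + 2,
        n_obs=int(res.nobs),
        converged=bool(res.converged),
    )


def lrt(nested: MixedModelFit, full: MixedModelFit) -> LrtResult:
    """Likelihood-ratio test between two nested ML fits on the same data.

    The statistic ``2*(llf_full - llf_nested)`` is clipped at zero (optimizer
    jitter can leave it infinitesimally negative for equivalent models); the
    p-value comes from the chi-square upper tail with df equal to the
    difference in fixed-effect counts.
    """
    if nested.n_obs != full.n_obs:
        raise ValueError("models were fit to different data")
    if not set(nested.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    df = full.n_fixed - nested.n_fixed
    if df < 0:
        raise ValueError("nested model has more parameters than the full model")
    statistic = max(0.0, 2.0 * (full.llf - nested.llf))
    p = float(sps.chi2.sf(statistic, df)) if df > 0 else 1.0
    return LrtResult(statistic=statistic, df=df, p=p)


def lrt_table(table: pd.DataFrame, response: str = "window_mean_deg") -> pd.DataFrame:
    """The standard suite of nested model comparisons for the main experiment."""
    cache: dict[tuple[str, ...], MixedModelFit] = {}

    def fit(terms: tuple[str, ...]) -> MixedModelFit:
        if terms not in cache:
            cache[terms] = fit_lmm(table, terms, response=response)
        return cache[terms]

    comparisons = [
        ("Noise", (), ("noise",)),
        ("Velocity", (), ("velocity",)),
        ("Velocity + Noise", (), ("velocity", "noise")),
        ("Velocity : Noise", (), ("interaction",)),
        ("Velocity * Noise", (), ("velocity", "noise", "interaction")),
        ("Interaction added", ("velocity", "noise"), ("velocity", "noise", "interaction")),
        ("Fixed added", ("interaction",), ("velocity", "noise", "interaction")),
    ]
    rows = []
    for name, nested_terms, full_terms in comparisons:
        r = lrt(fit(nested_terms), fit(full_terms))
        rows.append(
            {"comparison": name, "nested": "+".join(nested_terms) or "intercept-only",
             "full": "+".join(full_terms), "chisq": r.statistic, "df": r.df, "p": r.p}
        )
    return pd.DataFrame(rows)


def _per_subject_ols(table: pd.DataFrame) -> tuple[float, float, int]:
    slopes = []
    for _, sub in table.groupby("subject"):
        if sub["noise"].nunique() < 2:
            raise ValueError("need at least 2 noise levels per subject")
        slopes.append(np.polyfit(sub["noise"], sub["pse_deg_s"], 1)[0])
    slopes = np.asarray(slopes, dtype=float)
    n = len(slopes)
    se = float(slopes.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return float(slopes.mean()), se, n


def fit_pse_slope(table: pd.DataFrame) -> PseSlopeFit:
    """Fixed slope of PSE on noise fraction with per-subject random slopes.

    Expects columns ``subject``, ``noise``, ``pse_deg_s`` (rows with missing
    PSEs are dropped).  For a single subject the slope reduces to that
    subject's ordinary least-squares slope.  If the random-slope fit fails
    numerically, falls back to the mean of per-subject OLS slopes with its
    between-subject standard error.
    """
    table = table.dropna(subset=["pse_deg_s"])
    if table.empty:
        raise ValueError("no PSE estimates to fit")
    n_subjects = int(table["subject"].nunique())
    if n_subjects == 1:
        if table["noise"].nunique() < 2:
            raise ValueError("need at least 2 noise levels per subject")
        slope, intercept = np.polyfit(table["noise"], table["pse_deg_s"], 1)
        resid = table["pse_deg_s"] - (slope * table["noise"] + intercept)
        dof = len(table) - 2
        sxx = float(((table["noise"] - table["noise"].mean()) ** 2).sum())
        se = float(np.sqrt((resid**2).sum() / dof / sxx)) if dof > 0 else 0.0
        method = "ols-single-subject"
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = MixedLM.from_formula(
                    "pse_deg_s ~ noise", table, groups=table["subject"],
                    re_formula="0 + noise",
                )
                res = md.fit(reml=False, method="lbfgs", maxiter=500)
            slope = float(res.fe_params["noise"])
            se = float(res.bse_fe["noise"])
            method = "mixedlm-random-slope"
            if not np.isfinite(se) or se == 0.0:
                raise ValueError("degenerate standard error")
        except Exception:
            slope, se, _ = _per_subject_ols(table)
            method = "per-subject-ols"
    df = max(n_subjects - 1, 1)
    t = slope / se if se and np.isfinite(se) and se > 0 else np.inf * np.sign(slope)
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    half = sps.t.ppf(0.975, df) * se if se and np.isfinite(se) else 0.0
    return PseSlopeFit(
        slope=float(slope), se=float(se), t=float(t), df=df, p=p,
        n_subjects=n_subjects, ci=(float(slope - half), float(slope + half)),
        method=method,
    )
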