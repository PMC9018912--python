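"""Inference: paired permutation tests, mixed-effects models, model comparison.

The permutation test is the canonical paired scheme — independent sign
flips of the pair differences — run either exhaustively (all 2^n patterns
when that is no more than the permutation budget) or by Monte Carlo with
the add-one p-value correction.

Dose-response and biomarker-velocity relations are linear mixed models with
a random intercept per subject, fitted by maximum likelihood (not REML) so
BIC values are comparable across fixed-effect specifications.  The reported
R² is the *marginal* pseudo-R² (fixed-effects variance over fixed + random
+ residual variance); the exponential amplitude/power relation is handled
by regressing natural-log power on stimulation amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import DegenerateInputError, InvalidArgumentError


@dataclass(frozen=True)
class StatsConfig:
    n_permutations: int = 10_000
    alpha: float = 0.05
    delta_bic_strong: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise InvalidArgumentError("n_permutations must be >= 100")


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    p_value: float
    n_used: int
    exhaustive: bool


@dataclass(frozen=True)
class MixedModelResult:
    coefficient: float
    se: float
    p_value: float
    r2: float
    bic: float
    n_obs: int
    n_groups: int
    formula_label: str
    converged: bool = True


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # pearson | spearman
    r: float
    p: float
    normality_p: tuple[float, float]


@dataclass(frozen=True)
class ModelComparison:
    delta_bic: float
    label: str  # strong | not strong | none
    preferred: str


def paired_permutation_test(x, y, cfg: StatsConfig = StatsConfig()) -> PermutationResult:
    """Two-sided paired permutation test of mean(x - y) by sign flipping.

    When ``2**n`` does not exceed the permutation budget the null is
    enumerated exhaustively and the p-value is the exact proportion of
    sign patterns at least as extreme as observed; otherwise ``n_permutations``
    Monte-Carlo sign flips are drawn and p = (#extreme + 1) / (n + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-d with equal length")
    n = len(x)
    if n < 3:
        raise InvalidArgumentError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InvalidArgumentError("missing pairs are not allowed")
    d = x - y
    observed = float(d.mean())
    if 2 ** n <= cfg.n_permutations:
        signs = np.array([[1 if (i >> b) & 1 else -1 for b in range(n)]
                          for i in range(2 ** n)], dtype=float)
        null = signs @ d / n
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
        return PermutationResult(observed, p, 2 ** n, exhaustive=True)
    rng = np.random.default_rng(cfg.rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(cfg.n_permutations, n))
    null = signs @ d / n
    extreme = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (extreme + 1) / (cfg.n_permutations + 1)
    return PermutationResult(observed, float(p), cfg.n_permutations, exhaustive=False)


def _fit_mixed(y: np.ndarray, x: np.ndarray, groups: np.ndarray,
               label: str) -> MixedModelResult:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if len(y) != len(x) or len(y) != len(groups):
        raise InvalidArgumentError("y, x and groups must have equal length")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise InvalidArgumentError("need at least 2 groups for a random intercept")
    if counts.min() < 3:
        raise InvalidArgumentError("need at least 3 observations per group")
    exog = sm.add_constant(x)
    model = MixedLM(y, exog, groups=groups)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False)
            converged = bool(res.converged)
        except Exception:
            res = model.fit(reml=False, method=["powell"])
            converged = bool(res.converged)
    llf = float(res.llf)
    if not np.isfinite(llf):
        # random-intercept variance on the boundary (zero): the mixed model
        # degenerates to OLS, whose likelihood is the correct profile value
        llf = float(sm.OLS(y, exog).fit().llf)
        converged = False
    slope = float(res.params[1])
    se = float(res.bse[1])
    # Wald test against a t reference with between-within denominator df
    # (n_obs - n_groups - 1) instead of the asymptotic normal, which is
    # anticonservative at cohort-sized group counts
    df = max(len(y) - len(uniq) - 1, 1)
    p = float(2.0 * sp_stats.t.sf(abs(slope) / se, df)) if se > 0 else float("nan")
    # marginal pseudo-R^2: fixed-effects variance over total variance
    var_fixed = float(np.var(exog @ res.fe_params))
    var_rand = float(res.cov_re.iloc[0, 0]) if hasattr(res.cov_re, "iloc") else float(res.cov_re[0, 0])
    var_resid = float(res.scale)
    r2 = var_fixed / (var_fixed + var_rand + var_resid)
    k = len(res.fe_params) + 2  # fixed effects + random-intercept var + residual var
    bic = float(-2.0 * llf + k * np.log(len(y)))
    return MixedModelResult(coefficient=slope, se=se, p_value=p, r2=r2, bic=bic,
                            n_obs=len(y), n_groups=len(uniq), formula_label=label,
                            converged=converged)


def fit_velocity_model(power, velocity, subject) -> MixedModelResult:
    """Velocity ~ band power with a random intercept per subject (ML fit)."""
    return _fit_mixed(np.asarray(velocity, dtype=float), np.asarray(power, dtype=float),
                      np.asarray(subject), label="velocity ~ power + (1|subject)")


def fit_dose_model(power, amplitude_mA, subject) -> MixedModelResult:
    """log(power) ~ stimulation amplitude with a random intercept per subject.

    Band power follows an exponential dose-response, so its natural log is
    modelled linearly in the amplitude; the slope is per mA.
    """
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise InvalidArgumentError("power values must be positive for the log transform")
    return _fit_mixed(np.log(power), np.asarray(amplitude_mA, dtype=float),
                      np.asarray(subject), label="log(power) ~ amplitude + (1|subject)")


def compare_models(a: MixedModelResult, b: MixedModelResult,
                   cfg: StatsConfig = StatsConfig()) -> ModelComparison:
    """BIC comparison; |ΔBIC| strictly above the threshold is 'strong' evidence."""
    if a.n_obs != b.n_obs:
        raise InvalidArgumentError("models must be fitted on identical observations")
    delta = b.bic - a.bic
    if not np.isfinite(delta):
        raise InvalidArgumentError("BIC comparison requires finite BIC values")
    if delta == 0:
        return ModelComparison(0.0, "none", "neither")
    label = "strong" if abs(delta) > cfg.delta_bic_strong else "not strong"
    return ModelComparison(float(delta), label, "a" if delta > 0 else "b")


def per_subject_correlation(x, y) -> CorrelationResult:
    """Pearson when both inputs pass Shapiro-Wilk normality (p >= 0.05), else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise InvalidArgumentError("need at least 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    nx = float(sp_stats.shapiro(x).pvalue)
    ny = float(sp_stats.shapiro(y).pvalue)
    if nx >= 0.05 and ny >= 0.05:
        r, p = sp_stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sp_stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method=method, r=float(r), p=float(p),
                             normality_p=(nx, ny))
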