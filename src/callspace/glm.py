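"""Group statistics: two-sample t-tests and Bayesian GLMs.

The group layer mirrors the study design: pooled-variance independent
t-tests compare FoxP2 expression between adult age classes, and Bayesian
generalized linear models relate each vocal learning measure to age class
(0 = young, 1 = older), the mean-centered FoxP2 MMSt/VSP expression ratio,
and their interaction.  Proportion-valued measures (plasticity,
convergence) use a Beta response with logit link; vocal diversity (a signed
area change) uses an identity-link normal response.

The GLM follows a model/results pattern: :class:`VocalLearningGLM` holds
the data and likelihood, and ``fit()`` runs an affine-invariant ensemble
MCMC sampler (emcee), returning :class:`GLMResults` with posterior medians,
95% highest-posterior-density intervals, R-hat and effective sample sizes
(walkers treated as chains), and a ``summary()`` table.  An effect is
flagged as supported when its 95% HPD interval excludes zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "TTestResult",
    "pooled_ttest",
    "ttest_from_summary",
    "SamplerConfig",
    "VocalLearningGLM",
    "GLMResults",
    "fit_glm",
    "summarize_results",
]


# ---------------------------------------------------------------------------
# t-tests


@dataclass
class TTestResult:
    """Pooled-variance two-sample t-test summary."""

    t: float
    df: int
    p: float
    mean1: float
    mean2: float
    se1: float
    se2: float
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return vars(self).copy()


def pooled_ttest(x, y) -> TTestResult:
    """Independent-samples t-test with pooled variance (df = n1 + n2 - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    n1, n2 = len(x), len(y)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() == y.mean():
        # identical constant samples: no evidence of a difference
        return TTestResult(0.0, n1 + n2 - 2, 1.0, x.mean(), y.mean(), 0.0, 0.0, n1, n2)
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise DegenerateDataError("zero pooled variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(
        t=float(res.statistic),
        df=n1 + n2 - 2,
        p=float(res.pvalue),
        mean1=float(x.mean()),
        mean2=float(y.mean()),
        se1=float(x.std(ddof=1) / np.sqrt(n1)),
        se2=float(y.std(ddof=1) / np.sqrt(n2)),
        n1=n1,
        n2=n2,
    )


def ttest_from_summary(m1, se1, n1, m2, se2, n2) -> TTestResult:
    """Two-sample t from published group summaries (mean, SE, n per group).

    t = (m1 - m2) / sqrt(se1^2 + se2^2) with df = n1 + n2 - 2; for equal
    group sizes this denominator coincides with the pooled-variance test.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValidationError("standard errors must be positive")
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs n >= 2")
    t = (m1 - m2) / np.sqrt(se1**2 + se2**2)
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), m1, m2, se1, se2, n1, n2)


# ---------------------------------------------------------------------------
# Bayesian GLM


@dataclass
class SamplerConfig:
    """Ensemble-MCMC settings.

    ``walkers`` plays the role of parallel chains (each walker's trajectory
    is one chain for R-hat/ESS); ``warmup`` ensemble iterations are
    discarded, ``iterations`` are kept.  Defaults match the headline
    analysis settings (10,000 + 10,000); tests use far smaller values.
    """

    walkers: int = 32
    warmup: int = 10_000
    iterations: int = 10_000
    seed: int = 0
    prior_sd: float = 5.0  # zero-centered normal prior SD on coefficients
    hpd_level: float = 0.95
    rhat_max: float = 1.01
    ess_min: float = 3000.0

    def validate(self, ndim: int) -> None:
        if self.walkers < 2 * ndim:
            raise ConfigurationError(f"need >= {2 * ndim} walkers for {ndim} parameters")
        if self.warmup < 1 or self.iterations < 1:
            raise ConfigurationError("warmup and iterations must be >= 1")


EFFECT_NAMES = ("intercept", "foxp2", "age", "foxp2_x_age")


class VocalLearningGLM:
    """Bayesian GLM of one vocal learning measure.

    Parameters
    ----------
    endog : response vector (proportions for the beta family).
    exog : design matrix; by convention [1, foxp2_centered, age, foxp2 x age].
    family : "normal" (identity link) or "beta" (logit link).
    names : coefficient names matching exog's columns.
    """

    def __init__(self, endog, exog, family: str = "normal", names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValidationError("endog and exog have different lengths")
        if self.endog.shape[0] < 6:
            raise InsufficientDataError("need at least 6 observations")
        if family not in ("normal", "beta"):
            raise ConfigurationError(f"unknown family {family!r}")
        self.family = family
        self.names = list(names) if names is not None else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]
        if family == "beta":
            y = self.endog
            if (y < 0).any() or (y > 1).any():
                raise ValidationError("beta-family responses must lie in [0, 1]")
            # boundary compression onto the open interval (monotone)
            n = len(y)
            self._y = (y * (n - 1) + 0.5) / n
            self._y_scale = 1.0  # priors live on the logit scale
        else:
            self._y = self.endog
            # scale weakly-informative priors by the response spread so the
            # same prior_sd setting stays vague whatever the response units
            self._y_scale = float(max(self._y.std(), 1e-12))
        # aux parameter: log sigma (normal) or log phi (beta precision)
        self.param_names = self.names + (["log_sigma"] if family == "normal" else ["log_phi"])
        self.ndim = len(self.param_names)

    @classmethod
    def from_measures(
        cls,
        measures: pd.DataFrame,
        response: str,
        foxp2: pd.DataFrame | pd.Series | None = None,
        family: str | None = None,
    ) -> "VocalLearningGLM":
        """Build the model from a per-bird measures table.

        ``measures`` needs bird_id, age_class and the response column;
        ``foxp2`` supplies per-bird MMSt/VSP ratios (a Series indexed by
        bird_id, or a frame with bird_id and foxp2_ratio columns) unless the
        measures table already has a ``foxp2_ratio`` column.  The ratio is
        centered on the mean of the birds entering the model.  The family
        defaults to beta for the proportion measures and normal otherwise.
        """
        df = measures.copy()
        if foxp2 is not None:
            if isinstance(foxp2, pd.DataFrame):
                foxp2 = foxp2.set_index("bird_id")["foxp2_ratio"]
            df = df.join(foxp2.rename("foxp2_ratio"), on="bird_id", rsuffix="_x")
        if "foxp2_ratio" not in df.columns:
            raise ValidationError("no FoxP2 ratio column available")
        if "included" in df.columns:
            df = df[df["included"]]
        df = df.dropna(subset=[response, "foxp2_ratio"])
        if family is None:
            family = "beta" if response in ("vocal_plasticity", "vocal_convergence") else "normal"
        age = (df["age_class"].astype(str) == "older").astype(float).to_numpy()
        ratio_c = (df["foxp2_ratio"] - df["foxp2_ratio"].mean()).to_numpy()
        exog = np.column_stack([np.ones(len(df)), ratio_c, age, ratio_c * age])
        model = cls(df[response].to_numpy(), exog, family=family, names=list(EFFECT_NAMES))
        model.response = response
        return model

    # log posterior, vectorized over parameter vectors (walkers)
    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        k = self.exog.shape[1]
        beta, aux = theta[:, :k], theta[:, k]
        eta = beta @ self.exog.T  # (walkers, n)
        prior_sd = self._prior_sd * self._y_scale
        lp = -0.5 * np.sum((beta / prior_sd) ** 2, axis=1)
        aux = np.clip(aux, -30.0, 30.0)  # keep exp() finite; tails are -inf anyway
        if self.family == "normal":
            sigma = np.exp(aux)
            # half-normal(5 * sd(y)) prior on sigma, plus the log-scale Jacobian
            lp += -0.5 * (sigma / (5.0 * self._y_scale)) ** 2 + aux
            resid = self._y[None, :] - eta
            lp += np.sum(
                -0.5 * (resid / sigma[:, None]) ** 2 - np.log(sigma[:, None]),
                axis=1,
            ) - 0.5 * len(self._y) * np.log(2 * np.pi)
        else:
            phi = np.exp(aux)
            # gamma(2, rate 0.1) prior on precision, plus Jacobian
            lp += 2.0 * np.log(phi) - 0.1 * phi  # shape-2 gamma up to constants
            mu = special.expit(eta)
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            a = mu * phi[:, None]
            b = (1.0 - mu) * phi[:, None]
            y = self._y[None, :]
            lp += np.sum(
                special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b)
                + (a - 1) * np.log(y) + (b - 1) * np.log(1 - y),
                axis=1,
            )
        lp[~np.isfinite(lp)] = -np.inf
        return lp

    def _initial_state(self, config: SamplerConfig) -> np.ndarray:
        rng = np.random.default_rng(config.seed)
        if self.family == "normal":
            target = self._y
        else:
            target = special.logit(self._y)
        beta0, *_ = np.linalg.lstsq(self.exog, target, rcond=None)
        resid = target - self.exog @ beta0
        aux0 = np.log(max(resid.std(), 1e-3)) if self.family == "normal" else np.log(10.0)
        center = np.concatenate([beta0, [aux0]])
        return center[None, :] + 0.05 * rng.standard_normal((config.walkers, self.ndim))

    def fit(self, config: SamplerConfig | None = None, **overrides) -> "GLMResults":
        """Sample the posterior; returns :class:`GLMResults`."""
        config = config or SamplerConfig()
        if overrides:
            config = SamplerConfig(**(vars(config) | overrides))
        config.validate(self.ndim)
        self._prior_sd = config.prior_sd
        sampler = emcee.EnsembleSampler(
            config.walkers,
            self.ndim,
            self._log_prob,
            vectorize=True,
            # differential-evolution moves mix far better than the default
            # stretch move on these correlated GLM posteriors
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(config.seed % (2**32)).get_state()
        state = sampler.run_mcmc(self._initial_state(config), config.warmup)
        sampler.reset()
        sampler.run_mcmc(state, config.iterations)
        chain = sampler.get_chain()  # (iterations, walkers, ndim)
        return GLMResults(self, config, np.moveaxis(chain, 1, 0))


@dataclass
class GLMResults:
    """Posterior summaries and diagnostics for one fitted GLM."""

    model: VocalLearningGLM
    config: SamplerConfig
    chain: np.ndarray = field(repr=False)  # (walkers-as-chains, draws, ndim)

    def __post_init__(self):
        names = self.model.param_names
        data = {name: self.chain[:, :, i] for i, name in enumerate(names)}
        self._idata = az.from_dict(posterior=data)
        self.medians = {n: float(np.median(data[n])) for n in names}
        hdi = az.hdi(self._idata, hdi_prob=self.config.hpd_level)
        self.hpd = {
            n: (float(hdi[n].sel(hdi="lower")), float(hdi[n].sel(hdi="higher")))
            for n in names
        }
        rhat = az.rhat(self._idata)
        ess = az.ess(self._idata)
        self.rhat = {n: float(rhat[n]) for n in names}
        self.ess = {n: float(ess[n]) for n in names}
        self.warnings: list[str] = []
        for n in names:
            if not self.rhat[n] < self.config.rhat_max:
                self.warnings.append(f"R-hat {self.rhat[n]:.4f} >= {self.config.rhat_max} for {n}")
            if self.ess[n] < self.config.ess_min:
                self.warnings.append(f"ESS {self.ess[n]:.0f} < {self.config.ess_min:.0f} for {n}")

    @property
    def converged(self) -> bool:
        return not any(w.startswith("R-hat") for w in self.warnings)

    def significant(self, name: str) -> bool:
        """True when the effect's HPD interval excludes zero."""
        lo, hi = self.hpd[name]
        return lo > 0 or hi < 0

    def summary(self) -> pd.DataFrame:
        """Coefficient table: posterior median, HPD bounds, diagnostics."""
        rows = []
        for n in self.model.param_names:
            lo, hi = self.hpd[n]
            rows.append(
                {
                    "parameter": n,
                    "estimate": self.medians[n],
                    "hpd_lower": lo,
                    "hpd_upper": hi,
                    "significant": self.significant(n),
                    "rhat": self.rhat[n],
                    "ess": self.ess[n],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "response": getattr(self.model, "response", None),
            "family": self.model.family,
            "n": int(len(self.model.endog)),
            "coefficients": {
                n: {
                    "estimate": self.medians[n],
                    "hpd_lower": self.hpd[n][0],
                    "hpd_upper": self.hpd[n][1],
                    "significant": self.significant(n),
                    "rhat": self.rhat[n],
                    "ess": self.ess[n],
                }
                for n in self.model.param_names
            },
            "sampler": {
                "walkers": self.config.walkers,
                "warmup": self.config.warmup,
                "iterations": self.config.iterations,
                "seed": self.config.seed,
            },
            "warnings": self.warnings,
        }


def fit_glm(
    measures: pd.DataFrame,
    response: str,
    foxp2: pd.DataFrame | pd.Series | None = None,
    config: SamplerConfig | None = None,
    family: str | None = None,
) -> GLMResults:
    """Convenience wrapper: build and fit the GLM for one learning measure."""
    return VocalLearningGLM.from_measures(measures, response, foxp2, family).fit(config)


def summarize_results(
    ttests: dict[str, TTestResult] | None = None,
    fits: dict[str, GLMResults] | None = None,
    path=None,
) -> dict:
    """Machine-readable report over all analyses.

    GLM effects whose 95% HPD interval excludes zero are flagged, mirroring
    the bold-face convention of a coefficient table.  Writes JSON when
    ``path`` is given; returns the report dict either way.
    """
    report: dict = {"t_tests": {}, "glm": {}}
    for name, res in (ttests or {}).items():
        d = res.to_dict()
        d["significant"] = d["p"] < 0.05
        report["t_tests"][name] = d
    for name, res in (fits or {}).items():
        report["glm"][name] = res.to_dict()
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    return report
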