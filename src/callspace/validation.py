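"""Ground-truth recovery experiments on synthetic flocks.

These experiments close the loop on the whole pipeline: known convergence
and diversity-trend rates go into the generator, calls flow through the
feature map, the joint embedding, the kernel-density regions and the
measure definitions, and the recovered per-bird measures are compared
against what the generator was told to do.  A companion experiment checks
the calibration of the Bayesian GLM layer on data with known effects.

Problem sizes default to reduced settings (25 calls per bird and block,
a 120-cell grid, short MCMC runs) so a full recovery study runs in minutes
on one core; every size is a parameter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._util import substream
from .glm import SamplerConfig, VocalLearningGLM
from .metrics import MetricsConfig, compute_measures
from .space import embed
from .synthetic import AgeClassParams, ExpressionParams, SimConfig, simulate_flocks

__all__ = [
    "simulate_flock_measures",
    "convergence_contrast",
    "diversity_sign_recovery",
    "glm_calibration",
]


def simulate_flock_measures(
    kappa: float,
    delta: float,
    seed: int,
    calls_per_bird_block: int = 25,
    rarefy_size: int = 20,
    rarefy_reps: int = 5,
    tsne_iterations: int = 400,
) -> pd.DataFrame:
    """Measures table for one simulated flock of four birds.

    The full pipeline runs at reduced size: one flock, ``calls_per_bird_block``
    calls per bird and block, t-SNE at perplexity 15, rarefaction scaled to
    the available calls.
    """
    cfg = SimConfig(
        n_flocks_per_age=1,
        calls_per_bird_block=calls_per_bird_block,
        age_params={"young": AgeClassParams(convergence_rate=kappa, diversity_trend=delta)},
        expression_params={"young": ExpressionParams()},
        seed=int(substream(seed, "sim").integers(2**31)),
    )
    calls, _ = simulate_flocks(cfg)
    emb = embed(
        calls,
        perplexity=15,
        seed=int(substream(seed, "embed").integers(2**31)),
        n_iter=tsne_iterations,
    )
    metrics_cfg = MetricsConfig(
        rarefy_size=rarefy_size,
        rarefy_reps=rarefy_reps,
        grid_cells=120,
        seed=int(substream(seed, "metrics").integers(2**31)),
    )
    return compute_measures(calls, emb, metrics_cfg)


def convergence_contrast(
    n_replicates: int = 20,
    kappa_high: float = 0.8,
    kappa_low: float = 0.0,
    seed: int = 0,
    **sim_kwargs,
) -> dict:
    """Mean vocal convergence under strong vs zero convergence dynamics.

    Runs ``n_replicates`` independent flocks per condition, takes each
    flock's mean convergence, and tests (one-sided Welch t) whether the
    high-kappa condition exceeds the low-kappa one.
    """
    means = {}
    for label, kappa in (("high", kappa_high), ("low", kappa_low)):
        vals = []
        for rep in range(n_replicates):
            m = simulate_flock_measures(
                kappa, 1.0, seed=int(substream(seed, "kappa", label, rep).integers(2**31)),
                **sim_kwargs,
            )
            vals.append(m["vocal_convergence"].mean())
        means[label] = np.asarray(vals)
    test = stats.ttest_ind(means["high"], means["low"], equal_var=False, alternative="greater")
    return {
        "mean_high": float(means["high"].mean()),
        "mean_low": float(means["low"].mean()),
        "p_one_sided": float(test.pvalue),
        "n_replicates": n_replicates,
    }


def diversity_sign_recovery(
    n_replicates: int = 10,
    delta_high: float = 1.3,
    delta_low: float = 0.7,
    seed: int = 0,
    **sim_kwargs,
) -> dict:
    """Sign of the mean vocal-diversity change under growing vs shrinking spread."""
    out = {}
    for label, delta in (("high", delta_high), ("low", delta_low)):
        vals = []
        for rep in range(n_replicates):
            m = simulate_flock_measures(
                0.2, delta, seed=int(substream(seed, "delta", label, rep).integers(2**31)),
                **sim_kwargs,
            )
            vals.append(m["vocal_diversity"].mean())
        out[f"mean_diversity_{label}"] = float(np.mean(vals))
    out["n_replicates"] = n_replicates
    out["sign_recovered"] = out["mean_diversity_high"] > 0 > out["mean_diversity_low"]
    return out


def _simulate_beta_dataset(n: int, age_effect: float, rng: np.random.Generator):
    age = rng.integers(0, 2, n).astype(float)
    fox = rng.normal(0.0, 0.2, n)
    mu = expit(0.3 + age_effect * age)
    y = rng.beta(mu * 30.0, (1.0 - mu) * 30.0)
    exog = np.column_stack([np.ones(n), fox, age, fox * age])
    return y, exog


def glm_calibration(
    n_seeds: int = 20,
    n_obs: int = 200,
    age_effect: float = 0.0,
    seed: int = 0,
    sampler: SamplerConfig | None = None,
) -> dict:
    """HPD calibration/power of the Beta GLM across simulated datasets.

    With ``age_effect = 0`` this measures how often each effect's 95% HPD
    interval covers zero (should be near nominal); with a nonzero effect it
    measures the rate at which the age HPD excludes zero (power).
    """
    sampler = sampler or SamplerConfig(
        walkers=24, warmup=1000, iterations=1000, ess_min=200
    )
    covered = {"foxp2": 0, "age": 0, "foxp2_x_age": 0}
    age_excludes_zero = 0
    for i in range(n_seeds):
        rng = substream(seed, "glm-calib", i)
        y, exog = _simulate_beta_dataset(n_obs, age_effect, rng)
        model = VocalLearningGLM(
            y, exog, family="beta", names=["intercept", "foxp2", "age", "foxp2_x_age"]
        )
        fit_cfg = SamplerConfig(**(vars(sampler) | {"seed": int(rng.integers(2**31))}))
        res = model.fit(fit_cfg)
        for name in covered:
            lo, hi = res.hpd[name]
            covered[name] += lo <= 0.0 <= hi
        age_excludes_zero += res.significant("age")
    return {
        "n_seeds": n_seeds,
        "age_effect": age_effect,
        "coverage": {k: v / n_seeds for k, v in covered.items()},
        "zero_effect_coverage": sum(
            covered[k] for k in ("foxp2", "foxp2_x_age") + (("age",) if age_effect == 0 else ())
        )
        / (n_seeds * (3 if age_effect == 0 else 2)),
        "age_power": age_excludes_zero / n_seeds,
    }
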