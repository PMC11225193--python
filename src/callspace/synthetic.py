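"""Synthetic flocks, calls, features and cell counts with known ground truth.

The generator emulates the structure of an adult vocal-learning assay in
budgerigars: replicate flocks of four unfamiliar adults per age class,
recorded over five blocks (block 1 = pre-flock baseline).  Each bird's
contact-call repertoire lives in a latent 2-D acoustic space as a Gaussian
mixture (mixture components = call types).  Two per-age-class rates drive
the dynamics:

* convergence rate ``kappa`` — from block 2 on, every call-type center
  moves toward the flock centroid by fraction kappa per block;
* diversity trend ``delta`` — the within-type call scatter at block *b* is
  scaled by ``delta**(b-1)``, so delta > 1 grows the repertoire's footprint
  and delta < 1 shrinks it.

Latent calls are pushed through a fixed 2-D -> 17-feature observation map
(a seeded linear map into free channels followed by monotone transforms
that guarantee a valid feature vector), so the embedding and density stages
downstream are exercised as a pipeline, not fed the latent space directly.

FoxP2 expression is emulated per bird and striatal region (MMSt, the vocal
learning nucleus; VSP, the adjacent non-learning striatum): a true
expression proportion per bird x region, realised as binomial FoxP2+ counts
out of a fixed number of DAPI+ cells per image, counted twice (two
observers) in each of two sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import substream
from .errors import ConfigurationError
from .features import FEATURE_NAMES, ID_COLUMNS

__all__ = [
    "AgeClassParams",
    "ExpressionParams",
    "SimConfig",
    "GroundTruth",
    "simulate_flocks",
    "simulate_cell_counts",
    "true_expression",
]

AGE_CLASSES = ("young", "older")


@dataclass
class AgeClassParams:
    """Latent-dynamics settings for one adult age class."""

    convergence_rate: float = 0.3  # kappa in [0, 1], per-block pull to flock centroid
    diversity_trend: float = 1.0  # delta, per-block multiplicative spread scale
    n_call_types: int = 3
    type_spread: float = 1.2  # SD of call-type centers around the bird mean
    within_type_noise: float = 0.5  # SD of calls around their type center
    bird_spread: float = 3.0  # SD of bird means around the flock origin

    def validate(self) -> None:
        if not 0.0 <= self.convergence_rate <= 1.0:
            raise ConfigurationError(f"convergence_rate must be in [0,1], got {self.convergence_rate}")
        if self.diversity_trend <= 0:
            raise ConfigurationError(f"diversity_trend must be > 0, got {self.diversity_trend}")
        if self.n_call_types < 1:
            raise ConfigurationError(f"n_call_types must be >= 1, got {self.n_call_types}")
        for name in ("type_spread", "within_type_noise", "bird_spread"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class ExpressionParams:
    """FoxP2 expression settings for one age class.

    Default true means follow the observed group means: young adults express
    FoxP2 in ~31% of MMSt cells and ~44% of VSP cells; older adults ~37%
    and ~48% (ratio below 1 = relative downregulation in the vocal nucleus).
    """

    mmst_mean: float = 0.31
    vsp_mean: float = 0.44
    between_bird_sd: float = 0.05
    cells_per_image: int = 150
    observer_noise: float = 0.02  # SD on the proportion scale; 0 = identical recounts

    def validate(self) -> None:
        for name in ("mmst_mean", "vsp_mean"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"{name} must be in (0,1), got {p}")
        if self.between_bird_sd < 0 or self.observer_noise < 0:
            raise ConfigurationError("SDs must be >= 0")
        if self.cells_per_image < 1:
            raise ConfigurationError("cells_per_image must be >= 1")


def _default_age_params() -> dict[str, AgeClassParams]:
    # young adults: stronger convergence and a growing repertoire;
    # older adults: weaker convergence, shrinking repertoire
    return {
        "young": AgeClassParams(convergence_rate=0.4, diversity_trend=1.15),
        "older": AgeClassParams(convergence_rate=0.25, diversity_trend=0.85),
    }


def _default_expression_params() -> dict[str, ExpressionParams]:
    return {
        "young": ExpressionParams(mmst_mean=0.31, vsp_mean=0.44),
        "older": ExpressionParams(mmst_mean=0.37, vsp_mean=0.48),
    }


@dataclass
class SimConfig:
    """Full configuration of the synthetic study.

    Defaults mirror the assay design: six replicate flocks per age class,
    four birds per flock, five recording blocks.  Per-bird call counts per
    block are not reported for the real study; the default of 220 lies in
    the range that exercises rarefaction at subset size 180.
    """

    n_flocks_per_age: int = 6
    birds_per_flock: int = 4
    n_blocks: int = 5
    calls_per_bird_block: int = 220
    age_params: dict[str, AgeClassParams] = field(default_factory=_default_age_params)
    expression_params: dict[str, ExpressionParams] = field(default_factory=_default_expression_params)
    feature_noise: float = 0.05  # observation noise SD on the raw feature channels
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_flocks_per_age", "birds_per_flock", "n_blocks", "calls_per_bird_block"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.feature_noise < 0:
            raise ConfigurationError("feature_noise must be >= 0")
        for params in self.age_params.values():
            params.validate()
        for params in self.expression_params.values():
            params.validate()

    @property
    def age_classes(self) -> tuple[str, ...]:
        return tuple(self.age_params)

    def bird_ids(self) -> list[tuple[str, str, str]]:
        """(bird_id, flock_id, age_class) for every simulated bird, in a stable order."""
        out = []
        for age in self.age_classes:
            for fi in range(1, self.n_flocks_per_age + 1):
                flock = f"{age}_f{fi}"
                for bi in range(1, self.birds_per_flock + 1):
                    out.append((f"{flock}_b{bi}", flock, age))
        return out


@dataclass
class GroundTruth:
    """Latent truth behind one simulated dataset; reproducible from (config, seed)."""

    # bird_id -> array (n_blocks, n_call_types, 2) of latent call-type centers
    centers: dict[str, np.ndarray]
    # flock_id -> latent flock centroid (mean over birds and types at block 1)
    flock_centroids: dict[str, np.ndarray]
    # bird_id -> {"mmst": p, "vsp": p, "ratio": p_mmst / p_vsp}
    expression: dict[str, dict[str, float]]

    def to_json(self, path) -> None:
        payload = {
            "centers": {b: c.tolist() for b, c in self.centers.items()},
            "flock_centroids": {f: c.tolist() for f, c in self.flock_centroids.items()},
            "expression": self.expression,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# latent space -> 17 observed features

_N_FREE = 15  # free channels; IQR and dominant range are derived


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _observation_map(seed: int) -> np.ndarray:
    """Fixed 2 -> 15 linear map, seeded independently of the call draws."""
    rng = substream(seed, "feature-map")
    return rng.normal(0.0, 0.6, size=(_N_FREE, 2))


def _latent_to_features(latent: np.ndarray, weights: np.ndarray, rng: np.random.Generator,
                        noise_sd: float) -> pd.DataFrame:
    """Map latent (n, 2) points to a valid 17-feature table.

    Raw channels are W @ latent + noise; monotone transforms then produce
    features that satisfy the feature-vector invariants by construction
    (quantile ordering, IQR/range identities, entropies in [0, 1]).
    """
    z = latent @ weights.T
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    median = 3.0 + 0.5 * z[:, 3]
    q_lo = 0.3 * _softplus(z[:, 4])
    q_hi = 0.3 * _softplus(z[:, 5])
    dom = 3.0 + 0.5 * z[:, 11]
    d_lo = 0.3 * _softplus(z[:, 12])
    d_hi = 0.3 * _softplus(z[:, 13])
    return pd.DataFrame(
        {
            "duration": 0.08 + 0.05 * _softplus(z[:, 0]),
            "spectral_mean": 3.0 + 0.5 * z[:, 1],
            "spectral_sd": 0.2 * _softplus(z[:, 2]),
            "spectral_median": median,
            "spectral_q25": median - q_lo,
            "spectral_q75": median + q_hi,
            "spectral_iqr": q_lo + q_hi,
            "spectral_skewness": 0.5 * z[:, 6],
            "spectral_kurtosis": 2.0 + _softplus(z[:, 7]),
            "spectral_entropy": _sigmoid(z[:, 8]),
            "spectral_flatness": _sigmoid(z[:, 9]),
            "time_entropy": _sigmoid(z[:, 10]),
            "dominant_mean": dom,
            "dominant_min": dom - d_lo,
            "dominant_max": dom + d_hi,
            "dominant_range": d_lo + d_hi,
            "modulation_index": _softplus(z[:, 14]),
        }
    )


# ---------------------------------------------------------------------------
# call simulation


def simulate_flocks(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate every flock's calls across all recording blocks.

    Returns ``(calls, truth)`` where ``calls`` has the ID columns plus the
    17 feature columns (one row per call) and ``truth`` records the latent
    call-type centers, flock centroids and expression truth.  Bit-identical
    for identical ``(config, seed)``.
    """
    config.validate()
    weights = _observation_map(config.seed)
    rows: list[pd.DataFrame] = []
    centers_truth: dict[str, np.ndarray] = {}
    centroids: dict[str, np.ndarray] = {}
    call_counter = 0
    for age in config.age_classes:
        pars = config.age_params[age]
        for fi in range(1, config.n_flocks_per_age + 1):
            flock = f"{age}_f{fi}"
            rng = substream(config.seed, "flock", flock)
            n_birds, n_types = config.birds_per_flock, pars.n_call_types
            bird_means = rng.normal(0.0, pars.bird_spread, size=(n_birds, 2))
            # block-1 call-type centers per bird
            centers = np.empty((config.n_blocks, n_birds, n_types, 2))
            centers[0] = bird_means[:, None, :] + rng.normal(
                0.0, pars.type_spread, size=(n_birds, n_types, 2)
            )
            centroid = centers[0].reshape(-1, 2).mean(axis=0)
            for b in range(1, config.n_blocks):
                centers[b] = centers[b - 1] + pars.convergence_rate * (centroid - centers[b - 1])
            centroids[flock] = centroid
            for bi in range(n_birds):
                bird = f"{flock}_b{bi + 1}"
                centers_truth[bird] = centers[:, bi]
                for b in range(config.n_blocks):
                    n_calls = config.calls_per_bird_block
                    types = rng.integers(0, n_types, size=n_calls)
                    scale = pars.diversity_trend ** b
                    latent = centers[b, bi, types] + scale * rng.normal(
                        0.0, pars.within_type_noise, size=(n_calls, 2)
                    )
                    feats = _latent_to_features(latent, weights, rng, config.feature_noise)
                    feats.insert(0, "call_id", [f"c{call_counter + i:07d}" for i in range(n_calls)])
                    feats.insert(1, "bird_id", bird)
                    feats.insert(2, "flock_id", flock)
                    feats.insert(3, "age_class", age)
                    feats.insert(4, "block", b + 1)
                    call_counter += n_calls
                    rows.append(feats)
    calls = pd.concat(rows, ignore_index=True)[list(ID_COLUMNS) + list(FEATURE_NAMES)]
    truth = GroundTruth(
        centers=centers_truth,
        flock_centroids=centroids,
        expression=_expression_truth(config),
    )
    return calls, truth


# ---------------------------------------------------------------------------
# cell-count simulation


def _expression_truth(config: SimConfig) -> dict[str, dict[str, float]]:
    rng = substream(config.seed, "expression-truth")
    truth: dict[str, dict[str, float]] = {}
    for bird, _flock, age in config.bird_ids():
        pars = config.expression_params[age]
        p_mmst = float(np.clip(rng.normal(pars.mmst_mean, pars.between_bird_sd), 0.005, 0.995))
        p_vsp = float(np.clip(rng.normal(pars.vsp_mean, pars.between_bird_sd), 0.005, 0.995))
        truth[bird] = {"mmst": p_mmst, "vsp": p_vsp, "ratio": p_mmst / p_vsp}
    return truth


def true_expression(config: SimConfig) -> pd.DataFrame:
    """Per-bird true expression proportions and ratio, as a table."""
    config.validate()
    truth = _expression_truth(config)
    recs = [
        {"bird_id": b, "age_class": age, "p_mmst": truth[b]["mmst"],
         "p_vsp": truth[b]["vsp"], "true_ratio": truth[b]["ratio"]}
        for b, _f, age in config.bird_ids()
    ]
    return pd.DataFrame(recs)


def simulate_cell_counts(config: SimConfig) -> pd.DataFrame:
    """Simulate FoxP2/DAPI cell counts per bird x region x section x observer.

    The first observer's FoxP2+ count is Binomial(cells_per_image, true
    proportion); the second observer re-counts the same image, drawn
    Binomial around the first observer's realised proportion jittered by
    ``observer_noise`` (zero noise reproduces observer 1's counts exactly).
    """
    config.validate()
    truth = _expression_truth(config)
    rng = substream(config.seed, "cell-counts")
    rows = []
    for bird, _flock, age in config.bird_ids():
        pars = config.expression_params[age]
        n_cells = pars.cells_per_image
        for region in ("MMSt", "VSP"):
            p_true = truth[bird]["mmst" if region == "MMSt" else "vsp"]
            for section in (1, 2):
                count1 = int(rng.binomial(n_cells, p_true))
                if pars.observer_noise == 0:
                    count2 = count1
                else:
                    p2 = np.clip(
                        count1 / n_cells + rng.normal(0.0, pars.observer_noise), 0.0, 1.0
                    )
                    count2 = int(rng.binomial(n_cells, p2))
                for observer, count in (("obs1", count1), ("obs2", count2)):
                    rows.append(
                        {
                            "bird_id": bird,
                            "age_class": age,
                            "region": region,
                            "section": section,
                            "observer_id": observer,
                            "dapi_count": n_cells,
                            "foxp2_count": count,
                        }
                    )
    return pd.DataFrame(rows)
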