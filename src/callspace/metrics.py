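"""Per-bird vocal learning measures and the call-count inclusion filter.

Three measures summarise what a bird did with its contact-call repertoire
between the pre-flock baseline (block 1) and the final recording block
(block 5), all computed on kernel-density regions in the shared 2-D
acoustic space:

* vocal diversity  — change in rarefied acoustic-space area, block 5 minus
  block 1 (positive = the repertoire's footprint grew);
* vocal plasticity — 1 minus the IoU of the bird's block-1 and block-5
  regions (higher = less similarity between initial and final calls);
* vocal convergence — IoU of the bird's block-5 region with the combined
  block-5 region of its flockmates (higher = greater matching of the
  bird's repertoire to its social group's).

Birds producing fewer than ``min_calls`` (default 6) contact calls in the
final block are excluded from the measures as too sparsely sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import substream
from .errors import ConfigurationError, InsufficientDataError
from .space import (
    DensityRegion,
    EmbeddingSpace,
    GridSpec,
    RarefiedArea,
    combine_regions,
    density_region,
    make_grid,
    rarefied_area,
    region_iou,
)

__all__ = [
    "MetricsConfig",
    "vocal_diversity",
    "vocal_plasticity",
    "vocal_convergence",
    "apply_inclusion_filter",
    "compute_measures",
]


def vocal_diversity(area_block1: RarefiedArea, area_block5: RarefiedArea) -> float:
    """Signed change in rarefied acoustic-space area from block 1 to block 5."""
    return area_block5.mean_area - area_block1.mean_area


def vocal_plasticity(region_block1: DensityRegion, region_block5: DensityRegion) -> float:
    """1 - IoU of a bird's initial and final acoustic-space regions, in [0, 1]."""
    if not region_block1.mask.any() or not region_block5.mask.any():
        raise InsufficientDataError("empty density region")
    return 1.0 - region_iou(region_block1, region_block5)


def vocal_convergence(
    self_block5: DensityRegion, flockmate_regions_block5: list[DensityRegion]
) -> float:
    """IoU of a bird's final region with its flockmates' combined region, in [0, 1]."""
    if not flockmate_regions_block5:
        raise InsufficientDataError("need at least one flockmate region")
    if not self_block5.mask.any():
        raise InsufficientDataError("empty density region")
    return region_iou(self_block5, combine_regions(flockmate_regions_block5))


def apply_inclusion_filter(
    call_counts: pd.DataFrame, min_calls: int = 6, block: int = 5
) -> pd.DataFrame:
    """Partition birds by the final-block call-count threshold.

    ``call_counts`` has one row per bird x block with a ``n_calls`` column
    (or one row per bird with ``n_calls`` already at the filter block).
    Birds with fewer than ``min_calls`` calls in ``block`` are excluded;
    exactly ``min_calls`` calls is enough.  Returns one row per bird with
    ``included`` and ``reason`` columns.
    """
    if min_calls < 0:
        raise ConfigurationError("min_calls must be >= 0")
    df = call_counts
    if "block" in df.columns:
        df = df[df["block"] == block]
        counts = df.set_index("bird_id")["n_calls"]
        all_birds = call_counts["bird_id"].unique()
        counts = counts.reindex(all_birds, fill_value=0)
    else:
        counts = df.set_index("bird_id")["n_calls"]
    out = counts.rename("n_calls_filter_block").reset_index()
    out["included"] = out["n_calls_filter_block"] >= min_calls
    out["reason"] = np.where(
        out["included"],
        "",
        out["n_calls_filter_block"].map(
            lambda c: f"fewer than {min_calls} calls in block {block} (produced {int(c)})"
        ),
    )
    return out


@dataclass
class MetricsConfig:
    """Settings for the per-bird measures computation.

    Defaults follow the study's stated parameters: rarefaction to 180 calls
    averaged over 30 subsets, 95% highest-density regions, and a minimum of
    6 final-block calls for inclusion.  ``flockmate_mode`` selects how the
    flockmates' combined space is built: "union" takes the union of their
    per-bird regions (the literal reading of combined area); "pooled" pools
    their calls before the KDE.
    """

    rarefy_size: int = 180
    rarefy_reps: int = 30
    hdr_level: float = 0.95
    min_calls: int = 6
    first_block: int = 1
    last_block: int = 5
    shortfall_policy: str = "use-all"
    flockmate_mode: str = "union"  # or "pooled"
    rarefy_regions: bool = True  # build IoU regions from one rarefied subset
    grid_cells: int = 200
    pad_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.flockmate_mode not in ("union", "pooled"):
            raise ConfigurationError(f"unknown flockmate_mode {self.flockmate_mode!r}")
        if self.shortfall_policy not in ("error", "use-all"):
            raise ConfigurationError(f"unknown shortfall_policy {self.shortfall_policy!r}")
        if not 0 < self.hdr_level <= 1:
            raise ConfigurationError("hdr_level must be in (0, 1]")


def _subset_points(
    points: np.ndarray, size: int, policy: str, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """One rarefied subset (without replacement); flags shortfall subsets."""
    if len(points) >= size:
        idx = rng.choice(len(points), size=size, replace=False)
        return points[idx], False
    if policy == "error":
        raise InsufficientDataError(f"{len(points)} points < rarefy size {size}")
    return points, True


def compute_measures(
    calls: pd.DataFrame,
    embedding: EmbeddingSpace,
    config: MetricsConfig | None = None,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Compute the three learning measures for every bird.

    ``calls`` is the validated call table (ID columns at least); ``embedding``
    the joint acoustic space aligned row-for-row with ``calls``.  Returns a
    per-bird table with call counts, inclusion flag and the measures (NaN
    where a bird is excluded or a required block has < 2 calls).
    """
    config = config or MetricsConfig()
    config.validate()
    pts = embedding.points
    if len(pts) != len(calls):
        raise ConfigurationError("embedding and call table have different lengths")
    if grid is None:
        grid = make_grid(pts, config.pad_fraction, config.grid_cells)

    calls = calls.reset_index(drop=True)
    birds = (
        calls[["bird_id", "flock_id", "age_class"]]
        .drop_duplicates("bird_id")
        .reset_index(drop=True)
    )
    counts = (
        calls.groupby(["bird_id", "block"], observed=True).size().rename("n_calls").reset_index()
    )
    inclusion = apply_inclusion_filter(counts, config.min_calls, config.last_block).set_index(
        "bird_id"
    )

    def block_points(bird: str, block: int) -> np.ndarray:
        sel = (calls["bird_id"] == bird) & (calls["block"] == block)
        return pts[sel.to_numpy()]

    def region_for(bird: str, block: int) -> DensityRegion | None:
        p = block_points(bird, block)
        if len(p) < 2:
            return None
        if config.rarefy_regions:
            rng = substream(config.seed, "region-subset", bird, block)
            p, short = _subset_points(p, config.rarefy_size, config.shortfall_policy, rng)
            if len(p) < 2:
                return None
        try:
            return density_region(p, grid, level=config.hdr_level)
        except InsufficientDataError:
            return None

    rows = []
    count_lookup = counts.set_index(["bird_id", "block"])["n_calls"]
    for _, bird_row in birds.iterrows():
        bird = bird_row.bird_id
        n1 = int(count_lookup.get((bird, config.first_block), 0))
        n5 = int(count_lookup.get((bird, config.last_block), 0))
        row = {
            "bird_id": bird,
            "flock_id": bird_row.flock_id,
            "age_class": bird_row.age_class,
            "n_calls_block1": n1,
            "n_calls_block5": n5,
            "included": bool(inclusion.loc[bird, "included"]),
            "exclusion_reason": inclusion.loc[bird, "reason"],
            "vocal_diversity": np.nan,
            "vocal_plasticity": np.nan,
            "vocal_convergence": np.nan,
        }
        if row["included"]:
            p1, p5 = block_points(bird, config.first_block), block_points(bird, config.last_block)
            try:
                a1 = rarefied_area(
                    p1, config.rarefy_size, config.rarefy_reps, grid,
                    level=config.hdr_level,
                    seed=substream(config.seed, "rarefy", bird, 1).integers(2**31),
                    shortfall_policy=config.shortfall_policy,
                )
                a5 = rarefied_area(
                    p5, config.rarefy_size, config.rarefy_reps, grid,
                    level=config.hdr_level,
                    seed=substream(config.seed, "rarefy", bird, 5).integers(2**31),
                    shortfall_policy=config.shortfall_policy,
                )
                row["vocal_diversity"] = vocal_diversity(a1, a5)
            except InsufficientDataError:
                pass
            r1, r5 = region_for(bird, config.first_block), region_for(bird, config.last_block)
            if r1 is not None and r5 is not None:
                row["vocal_plasticity"] = vocal_plasticity(r1, r5)
            if r5 is not None:
                mates = [
                    b for b in calls.loc[calls["flock_id"] == bird_row.flock_id, "bird_id"].unique()
                    if b != bird
                ]
                if config.flockmate_mode == "union":
                    mate_regions = [
                        r for r in (region_for(m, config.last_block) for m in mates)
                        if r is not None
                    ]
                    if mate_regions:
                        row["vocal_convergence"] = vocal_convergence(r5, mate_regions)
                else:  # pooled: one KDE over all flockmates' final-block calls
                    pooled = np.vstack(
                        [block_points(m, config.last_block) for m in mates]
                    ) if mates else np.empty((0, 2))
                    if len(pooled) >= 2:
                        if config.rarefy_regions:
                            rng = substream(config.seed, "region-subset", bird, "mates")
                            pooled, _ = _subset_points(
                                pooled, config.rarefy_size, config.shortfall_policy, rng
                            )
                        mate_region = density_region(pooled, grid, level=config.hdr_level)
                        row["vocal_convergence"] = vocal_convergence(r5, [mate_region])
        rows.append(row)
    return pd.DataFrame(rows)
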