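"""Joint 2-D acoustic space: embedding, kernel-density regions, overlap.

All calls (every bird, every block) are embedded jointly with t-SNE so the
resulting plane is commensurable across subsets.  A subset's "acoustic
space" is the highest-density region (HDR) of a product-Gaussian KDE of its
points, evaluated on one shared grid spanning the whole embedding; areas
are counted in grid cells x cell area, and overlap between two subsets is
the intersection-over-union of their occupancy masks.  Because HDR area
grows with sample size, areas are rarefied: the statistic is averaged over
repeated fixed-size random subsets so every bird/block is compared at the
same number of calls.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from ._util import substream
from .errors import (
    ConfigurationError,
    GridMismatchError,
    InsufficientDataError,
    ValidationError,
)
from .features import FEATURE_NAMES

__all__ = [
    "EmbeddingSpace",
    "GridSpec",
    "DensityRegion",
    "RarefiedArea",
    "embed",
    "make_grid",
    "density_region",
    "rarefied_area",
    "region_iou",
    "combine_regions",
    "silverman_bandwidth",
]


# ---------------------------------------------------------------------------
# embedding


@dataclass
class EmbeddingSpace:
    """Joint 2-D embedding of all calls.

    ``coords`` carries one (TSNE1, TSNE2) pair per input call, aligned with
    the input row order (plus call_id when the input supplied one).
    """

    coords: pd.DataFrame  # columns: [call_id?], TSNE1, TSNE2
    perplexity: float
    seed: int
    n_iter: int
    method: str
    feature_hash: str

    @property
    def points(self) -> np.ndarray:
        return self.coords[["TSNE1", "TSNE2"]].to_numpy()

    def to_csv(self, path) -> None:
        self.coords.to_csv(path, index=False)


def embed(
    features: pd.DataFrame | np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
    method: str = "tsne",
) -> EmbeddingSpace:
    """Embed the 17-feature call table into a joint 2-D acoustic space.

    Features are z-scored before embedding so no single scale dominates.
    ``method`` is "tsne" (default) or "pca" (a fast linear alternative kept
    behind the same interface).  Deterministic given (inputs, seed).
    """
    call_id = None
    if isinstance(features, pd.DataFrame):
        if set(FEATURE_NAMES).issubset(features.columns):
            x = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
        else:
            x = features.to_numpy(dtype=float)
        if "call_id" in features.columns:
            call_id = features["call_id"].to_numpy()
    else:
        x = np.asarray(features, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("features contain non-finite values")
    n = x.shape[0]
    if method == "tsne" and n < 3 * perplexity:
        raise ConfigurationError(
            f"need at least 3 x perplexity = {3 * perplexity:.0f} calls, got {n}"
        )
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    if method == "tsne":
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=int(seed),
            max_iter=int(n_iter),
            init="pca",
        )
        pts = tsne.fit_transform(z)
    elif method == "pca":
        pts = PCA(n_components=2, random_state=int(seed)).fit_transform(z)
    else:
        raise ConfigurationError(f"unknown embedding method {method!r}")
    coords = pd.DataFrame(pts, columns=["TSNE1", "TSNE2"])
    if call_id is not None:
        coords.insert(0, "call_id", call_id)
    digest = hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()[:16]
    return EmbeddingSpace(
        coords=coords,
        perplexity=perplexity,
        seed=seed,
        n_iter=n_iter,
        method=method,
        feature_hash=digest,
    )


# ---------------------------------------------------------------------------
# grid + KDE highest-density regions


@dataclass(frozen=True)
class GridSpec:
    """Shared evaluation grid: bounding box plus cells per axis."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    nx: int = 200
    ny: int = 200

    def __post_init__(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ConfigurationError("grid bounds must have positive extent")
        if self.nx < 2 or self.ny < 2:
            raise ConfigurationError("grid needs at least 2 cells per axis")

    @property
    def cell_area(self) -> float:
        return ((self.xmax - self.xmin) / self.nx) * ((self.ymax - self.ymin) / self.ny)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        dx = (self.xmax - self.xmin) / self.nx
        dy = (self.ymax - self.ymin) / self.ny
        xc = self.xmin + dx * (np.arange(self.nx) + 0.5)
        yc = self.ymin + dy * (np.arange(self.ny) + 0.5)
        return xc, yc


def make_grid(points: np.ndarray, pad_fraction: float = 0.05, n_cells: int = 200) -> GridSpec:
    """Grid spanning the point cloud's bounding box, padded per side."""
    pts = np.asarray(points, dtype=float)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    padx = (xmax - xmin) * pad_fraction or 1.0
    pady = (ymax - ymin) * pad_fraction or 1.0
    return GridSpec(xmin - padx, xmax + padx, ymin - pady, ymax + pady, n_cells, n_cells)


@dataclass
class DensityRegion:
    """Highest-density region of a KDE on a shared grid.

    ``mask`` is the boolean occupancy grid (ny, nx); ``area`` is the count
    of occupied cells times the cell area, in grid units squared.
    """

    grid: GridSpec
    bandwidth: tuple[float, float]
    level: float
    mask: np.ndarray
    n_points: int = 0
    rarefied: bool = False  # True when built from fewer points than requested

    @property
    def area(self) -> float:
        return float(self.mask.sum()) * self.grid.cell_area

    def to_json(self, path=None) -> str:
        payload = {
            "grid": vars(self.grid) | {},
            "bandwidth": list(self.bandwidth),
            "level": self.level,
            "n_points": self.n_points,
            "area": self.area,
            "mask_rle": _rle_encode(self.mask),
        }
        text = json.dumps({k: (dict(v) if isinstance(v, dict) else v) for k, v in payload.items()})
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "DensityRegion":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        grid = GridSpec(**payload["grid"])
        mask = _rle_decode(payload["mask_rle"], (grid.ny, grid.nx))
        return cls(
            grid=grid,
            bandwidth=tuple(payload["bandwidth"]),
            level=payload["level"],
            mask=mask,
            n_points=payload.get("n_points", 0),
        )


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of alternating False/True runs, starting with False."""
    flat = mask.ravel()
    out, run, current = [], 0, False
    for v in flat:
        if bool(v) == current:
            run += 1
        else:
            out.append(run)
            current = bool(v)
            run = 1
    out.append(run)
    return out


def _rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, current = 0, False
    for run in runs:
        if current:
            flat[pos : pos + run] = True
        pos += run
        current = not current
    return flat.reshape(shape)


def silverman_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Per-axis Silverman bandwidth for a 2-D product-Gaussian KDE.

    In two dimensions Silverman's factor (4 / (d + 2))**(1/(d+4)) equals 1,
    leaving h_i = sigma_i * n**(-1/6).
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    sigma = pts.std(axis=0, ddof=1)
    h = sigma * n ** (-1.0 / 6.0)
    return float(h[0]), float(h[1])


def density_region(
    points: np.ndarray,
    grid: GridSpec,
    bandwidth: tuple[float, float] | None = None,
    level: float = 0.95,
) -> DensityRegion:
    """KDE highest-density region of a point cloud on the shared grid.

    The KDE is a product of per-axis Gaussians (Silverman bandwidths by
    default) evaluated at cell centers.  The mask is the smallest set of
    cells containing fraction ``level`` of the grid-captured density mass:
    cells are sorted by density descending (ties by flat cell index) and
    accumulated until the first cell reaching the level, inclusive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"points must be (n, 2), got {pts.shape}")
    if pts.shape[0] < 2 or np.unique(pts, axis=0).shape[0] < 2:
        raise InsufficientDataError("need at least 2 distinct points for a density region")
    if not 0.0 < level <= 1.0:
        raise ConfigurationError(f"density level must be in (0, 1], got {level}")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pts)
    hx, hy = bandwidth
    if hx <= 0 or hy <= 0:
        raise ConfigurationError(f"bandwidths must be positive, got {bandwidth}")

    xc, yc = grid.centers()
    # (ny, nx) density: product kernel separates into two 1-D kernel matrices
    kx = np.exp(-0.5 * ((xc[:, None] - pts[None, :, 0]) / hx) ** 2)  # (nx, n)
    ky = np.exp(-0.5 * ((yc[:, None] - pts[None, :, 1]) / hy) ** 2)  # (ny, n)
    density = (ky @ kx.T) / (2 * np.pi * hx * hy * pts.shape[0])

    flat = density.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))  # density desc, ties by index
    mass = flat[order] * grid.cell_area
    total = mass.sum()
    if total <= 0:
        raise InsufficientDataError("no density mass captured by the grid")
    cum = np.cumsum(mass) / total
    cut = int(np.searchsorted(cum, level, side="left"))
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[: cut + 1]] = True
    if level >= 1.0:  # total-mass case: all cells with nonzero density
        mask = flat > 0
    return DensityRegion(
        grid=grid,
        bandwidth=(float(hx), float(hy)),
        level=level,
        mask=mask.reshape(density.shape),
        n_points=pts.shape[0],
    )


# ---------------------------------------------------------------------------
# rarefaction


@dataclass
class RarefiedArea:
    """Mean HDR area over repeated fixed-size random subsets."""

    subset_size: int
    n_subsets: int
    areas: np.ndarray
    shortfall: bool = False  # True when fewer points than subset_size were available

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))


def rarefied_area(
    points: np.ndarray,
    subset_size: int = 180,
    n_subsets: int = 30,
    grid: GridSpec | None = None,
    bandwidth: tuple[float, float] | None = None,
    level: float = 0.95,
    seed: int = 0,
    shortfall_policy: str = "error",
) -> RarefiedArea:
    """Rarefied acoustic-space area: mean over ``n_subsets`` subsets of size
    ``subset_size`` drawn uniformly without replacement.

    ``shortfall_policy`` governs subsets larger than the point count:
    "error" (default) raises; "use-all" computes a single pseudo-subset
    from all points and flags the result.
    """
    pts = np.asarray(points, dtype=float)
    if subset_size < 2:
        raise ConfigurationError(f"subset_size must be >= 2, got {subset_size}")
    if n_subsets < 1:
        raise ConfigurationError(f"n_subsets must be >= 1, got {n_subsets}")
    if grid is None:
        grid = make_grid(pts)
    n = pts.shape[0]
    if n < subset_size:
        if shortfall_policy == "error":
            raise InsufficientDataError(
                f"{n} points available but subset_size={subset_size}; "
                "set shortfall_policy='use-all' to rarefy with all points"
            )
        if shortfall_policy != "use-all":
            raise ConfigurationError(f"unknown shortfall_policy {shortfall_policy!r}")
        region = density_region(pts, grid, bandwidth, level)
        return RarefiedArea(subset_size=subset_size, n_subsets=1,
                            areas=np.array([region.area]), shortfall=True)
    rng = substream(seed, "rarefaction")
    areas = np.empty(n_subsets)
    for r in range(n_subsets):
        idx = rng.choice(n, size=subset_size, replace=False)
        areas[r] = density_region(pts[idx], grid, bandwidth, level).area
    return RarefiedArea(subset_size=subset_size, n_subsets=n_subsets, areas=areas)


# ---------------------------------------------------------------------------
# overlap


def _check_grids(a: DensityRegion, b: DensityRegion) -> None:
    if a.grid != b.grid:
        raise GridMismatchError("density regions were built on different grids")


def region_iou(a: DensityRegion, b: DensityRegion) -> float:
    """Intersection-over-union of two occupancy masks on a shared grid."""
    _check_grids(a, b)
    inter = np.logical_and(a.mask, b.mask).sum()
    union = np.logical_or(a.mask, b.mask).sum()
    if union == 0:
        raise InsufficientDataError("both masks are empty")
    return float(inter) / float(union)


def combine_regions(regions: list[DensityRegion]) -> DensityRegion:
    """Cellwise union of regions on a shared grid (combined acoustic space)."""
    if not regions:
        raise InsufficientDataError("need at least one region to combine")
    first = regions[0]
    mask = first.mask.copy()
    for other in regions[1:]:
        _check_grids(first, other)
        mask |= other.mask
    return DensityRegion(
        grid=first.grid,
        bandwidth=first.bandwidth,
        level=first.level,
        mask=mask,
        n_points=sum(r.n_points for r in regions),
    )
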