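"""FoxP2 expression quantification from cell-count tables.

Each record is a manual count from one confocal image: DAPI+ cells (all
neural cells) and FoxP2+ cells (only counted when overlaying a DAPI+ cell)
in one striatal region — MMSt, the parrot vocal-learning nucleus, or VSP,
the adjacent non-learning striatum — for one of two sections per bird,
counted by one of two observers.  The expression proportion of an image is
FoxP2+/DAPI+; the per-section MMSt/VSP ratio divides the two regions'
proportions, and a bird's expression ratio averages its two sections.
Ratios below 1 indicate relative FoxP2 downregulation in the vocal nucleus.

Inter-observer reliability uses ICC(A,1): the single-measurement,
absolute-agreement intraclass correlation from a two-way model, with the
F-based confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "ICCResult",
    "expression_proportion",
    "bird_ratio",
    "summarize_expression",
    "icc_agreement",
    "load_cell_counts",
]

REGIONS = ("MMSt", "VSP")
COUNT_COLUMNS = ("bird_id", "region", "section", "observer_id", "dapi_count", "foxp2_count")


def expression_proportion(foxp2_count: float, dapi_count: float) -> float:
    """Fraction of DAPI+ cells that are FoxP2+ in one image."""
    if dapi_count <= 0:
        raise ZeroDivisionError("dapi_count must be positive")
    if foxp2_count < 0 or foxp2_count > dapi_count:
        raise ValidationError(
            f"foxp2_count must be in [0, dapi_count], got {foxp2_count}/{dapi_count}"
        )
    return float(foxp2_count) / float(dapi_count)


def load_cell_counts(path) -> pd.DataFrame:
    """Read and validate a cell-count CSV."""
    df = pd.read_csv(path)
    return _validate_counts(df)


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cell-count table missing columns: {sorted(missing)}")
    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        raise ValidationError(f"unknown regions: {sorted(df.loc[bad_region, 'region'].unique())}")
    if (df["dapi_count"] <= 0).any():
        raise ValidationError("dapi_count must be positive for every record")
    if ((df["foxp2_count"] < 0) | (df["foxp2_count"] > df["dapi_count"])).any():
        rows = df.index[(df["foxp2_count"] < 0) | (df["foxp2_count"] > df["dapi_count"])]
        raise ValidationError(f"foxp2_count outside [0, dapi_count] at rows {list(rows)}")
    return df


def summarize_expression(
    counts: pd.DataFrame, observer_policy: str = "average"
) -> pd.DataFrame:
    """Per-bird expression summary from a cell-count table.

    ``observer_policy``: "average" (default) averages the observers' counts
    per image before computing proportions; "first" keeps only the first
    observer (sorted by observer_id).  Sections lacking either region are
    dropped with a warning.  Returns one row per bird: per-region mean
    proportions, per-section ratios and the bird's MMSt/VSP ratio.
    """
    df = _validate_counts(counts)
    if observer_policy == "first":
        first = sorted(df["observer_id"].unique())[0]
        df = df[df["observer_id"] == first]
    elif observer_policy != "average":
        raise ValidationError(f"unknown observer_policy {observer_policy!r}")
    per_image = (
        df.groupby(["bird_id", "region", "section"], observed=True)[["dapi_count", "foxp2_count"]]
        .mean()
        .reset_index()
    )
    per_image["proportion"] = per_image["foxp2_count"] / per_image["dapi_count"]

    rows = []
    for bird, sub in per_image.groupby("bird_id", observed=True):
        wide = sub.pivot(index="section", columns="region", values="proportion")
        complete = wide.dropna()
        dropped = set(wide.index) - set(complete.index)
        if dropped:
            warnings.warn(
                f"bird {bird}: dropping sections {sorted(dropped)} missing a region",
                stacklevel=2,
            )
        if complete.empty or not set(REGIONS).issubset(complete.columns):
            raise InsufficientDataError(f"bird {bird}: no section with both regions")
        if (complete["VSP"] == 0).any():
            raise ZeroDivisionError(f"bird {bird}: VSP proportion is 0 in a section")
        ratios = complete["MMSt"] / complete["VSP"]
        row = {
            "bird_id": bird,
            "prop_mmst": float(complete["MMSt"].mean()),
            "prop_vsp": float(complete["VSP"].mean()),
            "n_sections": int(len(complete)),
            "foxp2_ratio": float(ratios.mean()),
        }
        for section in complete.index:
            row[f"ratio_section{section}"] = float(ratios.loc[section])
        if "age_class" in counts.columns:
            row["age_class"] = counts.loc[counts["bird_id"] == bird, "age_class"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def bird_ratio(records: pd.DataFrame, observer_policy: str = "average") -> dict:
    """Expression summary for a single bird's records, as a dict."""
    out = summarize_expression(records, observer_policy)
    if len(out) != 1:
        raise ValidationError(f"expected records for one bird, got {len(out)}")
    return out.iloc[0].to_dict()


# ---------------------------------------------------------------------------
# inter-observer reliability


@dataclass
class ICCResult:
    """ICC(A,1) with its F-based 95% confidence interval and ANOVA mean squares."""

    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int

    def __post_init__(self):
        if not self.ci_lower <= self.icc <= self.ci_upper:  # pragma: no cover
            raise ValueError("CI must bracket the estimate")


def icc_agreement(ratings: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measurement absolute-agreement ICC from a subjects x raters table.

    Computes ICC(A,1) from the two-way ANOVA mean squares,

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E)),

    with the standard F-distribution confidence interval for the
    absolute-agreement single-measure case.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2-D subjects x raters table")
    if np.isnan(x).any():
        raise InsufficientDataError("ratings table is incomplete (NaNs present)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need at least 2 subjects and 2 raters")
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateDataError("zero total variance in ratings")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_error / ((n - 1) * (k - 1)), 0.0)

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # F-based interval (absolute agreement, single measures)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc) ** 2 + (b * mse) ** 2 > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:  # perfect agreement
        lower = upper = 1.0
    lower = min(lower, icc)
    upper = max(upper, icc)
    return ICCResult(
        icc=float(icc),
        ci_lower=float(lower),
        ci_upper=float(upper),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n_subjects=n,
        n_raters=k,
    )
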