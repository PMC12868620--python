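"""Per-cell shape statistics and the immunohistochemistry H-score.

Works from measurement tables (one row per segmented cell), not images.
Monolayer records are grouped by imaging ROI; tissue-microarray (TMA)
records by array and tissue class, with cores-per-array weights for the
weighted group means used in the tissue comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StainFractions",
    "form_factor",
    "summarize_rois",
    "tissue_group_means",
    "h_score",
    "equivalent_radius",
]

TISSUE_CLASSES = ("normal", "primary_tumor", "lymph_node_met")

#: Columns expected in a monolayer morphometry table.
MONOLAYER_COLUMNS = ["roi_id", "cell_id", "area_um2", "perimeter_um", "major_um", "minor_um"]
#: Extra columns for TMA tables.
TMA_COLUMNS = ["tma_id", "core_id", "tissue_class"]

FEATURES = ["area_um2", "perimeter_um", "major_um", "minor_um", "form_factor"]


def form_factor(area, perimeter):
    """Circularity index 4*pi*area / perimeter^2.

    Equals 1 for a circle and is < 1 for every other simple closed shape
    (isoperimetric inequality); scale-invariant.  Accepts scalars or arrays.
    """
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(area <= 0) or np.any(perimeter <= 0):
        raise ValueError("area and perimeter must be > 0")
    ff = 4.0 * np.pi * area / perimeter**2
    return float(ff) if ff.ndim == 0 else ff


def equivalent_radius(area):
    """Radius of the circle with the same area, sqrt(area/pi).

    Used as the "mean radius" of a spheroid's 2D projection.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be > 0")
    r = np.sqrt(area / np.pi)
    return float(r) if r.ndim == 0 else r


def _with_form_factor(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "form_factor" not in df.columns:
        df["form_factor"] = form_factor(df["area_um2"], df["perimeter_um"])
    return df


def summarize_rois(records: pd.DataFrame, group_col: str = "roi_id") -> pd.DataFrame:
    """Per-ROI mean of each shape feature, one row per ROI.

    The ROI mean -- not the single cell -- is the unit of statistical
    analysis downstream, so grand statistics are computed over these rows.
    Adds ``n_cells`` per ROI.  Extra grouping labels constant within an ROI
    (e.g. ``cell_line``) are carried through.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    df = _with_form_factor(records)
    features = [c for c in FEATURES if c in df.columns]
    carry = [
        c
        for c in df.columns
        if c not in features + [group_col, "cell_id"]
        and df.groupby(group_col)[c].nunique().max() == 1
    ]
    out = df.groupby(group_col, as_index=False).agg(
        **{f: (f, "mean") for f in features},
        n_cells=("cell_id", "size") if "cell_id" in df.columns else (features[0], "size"),
    )
    for c in carry:
        out[c] = df.groupby(group_col)[c].first().reindex(out[group_col]).to_numpy()
    return out


def tissue_group_means(records: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Weighted per-tissue-class mean area and form factor across TMAs.

    Records are first averaged per (tissue_class, tma_id); the class mean is
    then the weighted mean of those array-level means, with weights given by
    cores per array (``weights``: columns ``tma_id``, ``n_cores``).  With
    equal weights this reduces to the ordinary mean of array means.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    df = _with_form_factor(records)
    wmap = weights.set_index("tma_id")["n_cores"]
    missing = set(df["tma_id"]) - set(wmap.index)
    if missing:
        raise ValueError(f"missing weight for TMA id(s): {sorted(missing)}")
    if (wmap <= 0).any():
        raise ValueError("weights must be > 0")
    per_array = (
        df.groupby(["tissue_class", "tma_id"], as_index=False)[["area_um2", "form_factor"]]
        .mean()
    )
    per_array["weight"] = per_array["tma_id"].map(wmap)
    rows = []
    for cls, grp in per_array.groupby("tissue_class"):
        w = grp["weight"].to_numpy(dtype=float)
        rows.append(
            {
                "tissue_class": cls,
                "mean_area_um2": float(np.average(grp["area_um2"], weights=w)),
                "mean_form_factor": float(np.average(grp["form_factor"], weights=w)),
                "n_arrays": len(grp),
                "total_weight": float(w.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StainFractions:
    """Staining-intensity percentages of an immunohistochemistry sample."""

    pct_negative: float
    pct_weak: float
    pct_moderate: float
    pct_strong: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100]")
        total = self.pct_negative + self.pct_weak + self.pct_moderate + self.pct_strong
        if not math.isclose(total, 100.0, abs_tol=1e-9):
            raise ValueError(f"fractions must sum to 100 (got {total})")


def h_score(fractions: StainFractions) -> float:
    """H-score = 0*%negative + 1*%weak + 2*%moderate + 3*%strong, in [0, 300]."""
    return (
        0.0 * fractions.pct_negative
        + 1.0 * fractions.pct_weak
        + 2.0 * fractions.pct_moderate
        + 3.0 * fractions.pct_strong
    )
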