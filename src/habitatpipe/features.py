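"""First-order radiomics features per habitat and for the whole tumor.

For every region (each habitat, and optionally the whole tumor) and every
IVIM channel, the 18 standard first-order intensity statistics are computed
from the region's voxel values, plus the region volume (voxel count times
voxel volume, mm^3) and the volume ratio (region voxels / tumor voxels).
Entropy and uniformity are computed on a fixed-bin-count histogram of the
region's own value range.

Conventions (all configurable or documented):
- variance is the population moment (ddof = 0);
- skewness is the Fisher-Pearson g1; kurtosis is the Pearson convention
  (excess + 3); both are defined as 0 for constant regions so degenerate
  habitats do not drop the case;
- percentiles use linear interpolation between order statistics;
- robust mean absolute deviation is the MAD of values within [P10, P90];
- a region that is empty for a case yields missing (NaN) features and a
  flag, never fabricated zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ivim import IVIMMaps

__all__ = [
    "FIRST_ORDER_NAMES",
    "first_order",
    "region_feature_vector",
    "build_feature_table",
    "WHOLE",
]

WHOLE = "whole"

FIRST_ORDER_NAMES = (
    "mean", "median", "minimum", "maximum", "range",
    "p10", "p90", "iqr", "variance",
    "skewness", "kurtosis", "energy", "total_energy", "rms",
    "mad", "rmad", "entropy", "uniformity",
)
# 18 statistics; the standard deviation is omitted as redundant with the
# variance, following the standard first-order family.


def first_order(values, n_bins: int = 64, voxel_volume: float = 1.0) -> dict:
    """The first-order statistic set of one region's intensity values."""
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("first_order requires at least one finite value")
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    rng_ = float(x.max() - x.min())
    # a constant region is exactly degenerate; np.var returns rounding dust
    var = float(x.var()) if rng_ > 0 else 0.0
    if rng_ > 0:
        counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
        p = counts[counts > 0] / x.size
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p ** 2).sum())
    else:
        entropy, uniformity = 0.0, 1.0
    if var > 0:
        z = (x - mean) / np.sqrt(var)
        skew = float((z ** 3).mean())
        kurt = float((z ** 4).mean())  # Pearson: excess + 3
    else:
        skew, kurt = 0.0, 0.0
    sub = x[(x >= p10) & (x <= p90)]
    energy = float((x ** 2).sum())
    return {
        "mean": mean, "median": float(p50),
        "minimum": float(x.min()), "maximum": float(x.max()), "range": rng_,
        "p10": float(p10), "p90": float(p90), "iqr": float(p75 - p25),
        "variance": var,
        "skewness": skew, "kurtosis": kurt,
        "energy": energy, "total_energy": energy * voxel_volume,
        "rms": float(np.sqrt((x ** 2).mean())),
        "mad": float(np.abs(x - mean).mean()),
        "rmad": float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0,
        "entropy": entropy, "uniformity": uniformity,
    }


def region_feature_vector(maps: IVIMMaps, labels: np.ndarray,
                          region, voxel_volume: float,
                          channels=("f", "D"), n_bins: int = 64) -> dict:
    """Named feature vector of one region of one case.

    ``region`` is a habitat label (int) or :data:`WHOLE`.  An absent habitat
    yields NaN statistics and a ``<region>_missing`` flag of 1.
    """
    labels = np.asarray(labels)
    tumor = labels > 0
    n_tumor = int(tumor.sum())
    if region == WHOLE:
        sel = tumor
        rname = WHOLE
    else:
        sel = labels == int(region)
        rname = f"habitat{int(region)}"
    out = {}
    n_region = int(sel.sum())
    out[f"{rname}_volume"] = n_region * voxel_volume
    out[f"{rname}_volume_ratio"] = n_region / n_tumor if n_tumor else np.nan
    out[f"{rname}_missing"] = 0 if n_region else 1
    for c in channels:
        vals = maps.channel(c)[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            stats = first_order(vals, n_bins=n_bins, voxel_volume=voxel_volume)
        else:
            stats = {k: np.nan for k in FIRST_ORDER_NAMES}
        out.update({f"{c}_{rname}_{k}": v for k, v in stats.items()})
    return out


def build_feature_table(cases, K: int = 3, channels=("f", "D"),
                        voxel_volume: float = 1.0, include_whole: bool = False,
                        n_bins: int = 64) -> pd.DataFrame:
    """One row of habitat (and optionally whole-tumor) features per case.

    ``cases`` is an iterable of dicts with keys ``patient_id``, ``maps``
    (IVIMMaps), ``labels`` (3-D habitat label array) and optionally
    ``outcome`` and ``split``.  Column order is deterministic; duplicate
    patient ids raise.
    """
    rows, ids = [], set()
    for case in cases:
        pid = case["patient_id"]
        if pid in ids:
            raise ValueError(f"duplicate patient id {pid!r}")
        ids.add(pid)
        row = {"patient_id": pid}
        regions = ([WHOLE] if include_whole else []) + list(range(1, K + 1))
        for region in regions:
            row.update(region_feature_vector(case["maps"], case["labels"],
                                             region, voxel_volume,
                                             channels=channels, n_bins=n_bins))
        if "outcome" in case:
            row["outcome"] = case["outcome"]
        if "split" in case:
            row["split"] = case["split"]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    return df


def feature_columns(df: pd.DataFrame) -> list:
    """The feature columns of a table (everything but outcome/split/flags)."""
    drop = {"outcome", "split"}
    return [c for c in df.columns
            if c not in drop and not c.endswith("_missing")]
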