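"""Distance-to-airway binning of strain: radial profiles and kymographs.

Every strain evaluation point is assigned its Euclidean distance to the
nearest lumen pixel; distance/strain couples are sorted into half-open
bins of ``bin_width`` μm (default 15 μm) and averaged.  Stacking the
binned profile of every frame column-by-column gives a kymograph: strain
versus time (x) and distance to the airway (y), the standard picture of
how contraction-induced deformation spreads into the parenchyma and
relaxes again.

By default distances are measured from the *reference-frame* lumen
boundary: the strains are Lagrangian, indexed by reference position, so
binning them by reference-frame distance keeps both quantities in one
frame of reference.  A per-frame lumen may be passed instead to bin
against the current (deformed) boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .strain_core import StrainField

__all__ = [
    "RadialProfile",
    "Kymograph",
    "distance_map",
    "bin_average",
    "kymograph",
    "strain_time_series",
]


def distance_map(lumen_mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """Per-pixel Euclidean distance (μm) to the nearest lumen pixel; zero
    on and inside the lumen."""
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    if not lumen_mask.any():
        raise ValueError("empty lumen mask: distance map undefined")
    return ndimage.distance_transform_edt(~lumen_mask) * pixel_size


@dataclass
class RadialProfile:
    """Circumferentially averaged strain vs. distance to the airway.

    Bins are half-open ``[k*w, (k+1)*w)``; empty bins hold NaN (missing,
    not zero) with count 0.
    """

    bin_centers: np.ndarray      # um
    mean_major: np.ndarray
    mean_minor: np.ndarray
    counts: np.ndarray
    bin_width: float             # um

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_um": self.bin_centers,
            "mean_major": self.mean_major,
            "mean_minor": self.mean_minor,
            "n": self.counts,
        })


def bin_average(
    strain_field: StrainField,
    dmap: np.ndarray,
    bin_width: float = 15.0,
) -> RadialProfile:
    """Mean principal strains per distance bin over tissue grid points.

    Masked-out (non-tissue, zeroed) grid points are excluded: including
    them would drag every bin mean toward zero.
    """
    X, Y = strain_field.positions()
    d = dmap[Y, X]
    inc = strain_field.valid
    dist = d[inc]
    n_bins = int(np.floor(dmap.max() / bin_width)) + 1
    idx = np.minimum((dist // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_major = np.where(
            counts > 0,
            np.bincount(idx, strain_field.lambda_major[inc], minlength=n_bins)
            / np.maximum(counts, 1),
            np.nan,
        )
        mean_minor = np.where(
            counts > 0,
            np.bincount(idx, strain_field.lambda_minor[inc], minlength=n_bins)
            / np.maximum(counts, 1),
            np.nan,
        )
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return RadialProfile(centers, mean_major, mean_minor, counts, bin_width)


@dataclass
class Kymograph:
    """Binned mean strain stacked over time: rows = distance bins,
    columns = time points."""

    major: np.ndarray            # (n_bins, n_times)
    minor: np.ndarray
    counts: np.ndarray
    bin_centers: np.ndarray      # um
    times: np.ndarray            # s
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (time, bin)."""
        T, C = np.meshgrid(self.times, self.bin_centers)
        return pd.DataFrame({
            "time_s": T.ravel(),
            "bin_center_um": C.ravel(),
            "mean_major": self.major.ravel(),
            "mean_minor": self.minor.ravel(),
            "n": self.counts.ravel(),
        })


def kymograph(profiles: list[RadialProfile], times: np.ndarray) -> Kymograph:
    """Assemble per-frame radial profiles into a kymograph, column per
    frame.  All profiles must share bin width; shorter profiles are padded
    with missing bins."""
    if len(profiles) != len(times):
        raise ValueError("one profile per time point required")
    w = profiles[0].bin_width
    for p in profiles:
        if p.bin_width != w:
            raise ValueError("inconsistent bin widths across profiles")
    n_bins = max(len(p.bin_centers) for p in profiles)

    def pad(arr, fill):
        out = np.full(n_bins, fill, dtype=float)
        out[: len(arr)] = arr
        return out

    major = np.column_stack([pad(p.mean_major, np.nan) for p in profiles])
    minor = np.column_stack([pad(p.mean_minor, np.nan) for p in profiles])
    counts = np.column_stack([pad(p.counts, 0) for p in profiles])
    centers = (np.arange(n_bins) + 0.5) * w
    return Kymograph(major, minor, counts, centers, np.asarray(times, float), w)


def strain_time_series(
    kymo: Kymograph, distances: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0)
) -> pd.DataFrame:
    """Rows of the kymograph at the bins containing the requested
    distances (μm), long format: time_s, distance_um, mean_major,
    mean_minor.  A distance beyond the kymograph extent is an error."""
    w = kymo.bin_width
    max_d = (len(kymo.bin_centers)) * w
    rows = []
    for d in distances:
        if not (0 <= d < max_d):
            raise ValueError(
                f"distance {d} um outside the kymograph range [0, {max_d}) um"
            )
        k = int(d // w)
        rows.append(pd.DataFrame({
            "time_s": kymo.times,
            "distance_um": d,
            "bin_center_um": kymo.bin_centers[k],
            "mean_major": kymo.major[k],
            "mean_minor": kymo.minor[k],
        }))
    return pd.concat(rows, ignore_index=True)
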