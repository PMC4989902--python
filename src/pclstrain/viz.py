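"""Figure rendering: quiver overlays, strain maps, kymographs, profiles.

Conventions: strains use a diverging colormap centered at zero so
expansion (positive) and compression (negative) are visually signed;
displacement magnitude uses a sequential map.  Every figure's numbers are
also written as CSV by the CLI — figures are never the only record.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .flow import DisplacementField
from .lumen import LumenEllipse
from .radial import Kymograph
from .strain_core import StrainField

__all__ = [
    "quiver_overlay",
    "magnitude_map",
    "strain_maps",
    "kymograph_figure",
    "profile_lines",
    "area_curve",
]


def _scale_bar(ax, pixel_size: float, length_um: float = 100.0) -> None:
    npx = length_um / pixel_size
    x1 = ax.get_xlim()[1]
    y1 = max(ax.get_ylim())
    ax.plot([x1 - npx - 10, x1 - 10], [y1 - 15, y1 - 15], "w-", lw=3)
    ax.text(x1 - npx / 2 - 10, y1 - 25, f"{length_um:.0f} µm",
            color="w", ha="center", fontsize=8)


def _lumen_outline(ax, ellipse: LumenEllipse) -> None:
    phi = np.linspace(0, 2 * np.pi, 200)
    bx, by = ellipse.boundary_point(phi)
    ax.plot(bx, by, "w--", lw=1.2)


def quiver_overlay(
    frame: np.ndarray,
    field: DisplacementField,
    ellipse: LumenEllipse | None,
    path: str | Path,
    stride: int = 14,
) -> None:
    """Displacement vectors on the (initial or final) bright-field frame,
    with the pre-contraction lumen boundary dashed."""
    fig, ax = plt.subplots(figsize=(6, 6 * frame.shape[0] / frame.shape[1]))
    ax.imshow(frame, cmap="gray", vmin=0, vmax=1)
    ys = np.arange(stride // 2, frame.shape[0], stride)
    xs = np.arange(stride // 2, frame.shape[1], stride)
    X, Y = np.meshgrid(xs, ys)
    ax.quiver(X, Y, field.u[Y, X], field.v[Y, X], color="yellow",
              angles="xy", scale_units="xy", scale=1.0, width=0.002)
    if ellipse is not None:
        _lumen_outline(ax, ellipse)
    _scale_bar(ax, field.pixel_size)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def magnitude_map(field: DisplacementField, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6.4, 5.4))
    im = ax.imshow(field.magnitude_um, cmap="viridis")
    fig.colorbar(im, ax=ax, label="displacement (µm)")
    _scale_bar(ax, field.pixel_size)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def strain_maps(sfield: StrainField, path_major: str | Path, path_minor: str | Path) -> None:
    """Major (radial) and minor (circumferential) principal strain maps,
    diverging colormap centered at zero."""
    for arr, label, path in (
        (sfield.lambda_major, "major (radial) strain", path_major),
        (sfield.lambda_minor, "minor (circumferential) strain", path_minor),
    ):
        lim = np.nanmax(np.abs(arr)) or 1e-6
        fig, ax = plt.subplots(figsize=(6.4, 5.4))
        im = ax.imshow(
            arr, cmap="RdBu_r", vmin=-lim, vmax=lim,
            extent=(sfield.xs[0], sfield.xs[-1], sfield.ys[-1], sfield.ys[0]),
        )
        fig.colorbar(im, ax=ax, label=label)
        _scale_bar(ax, sfield.pixel_size)
        ax.set_axis_off()
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def kymograph_figure(kymo: Kymograph, path: str | Path) -> None:
    """Strain vs time (x) and distance to the airway (y), color-coded."""
    fig, axes = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    for ax, mat, label in (
        (axes[0], kymo.major, "radial (major) strain"),
        (axes[1], kymo.minor, "circumferential (minor) strain"),
    ):
        lim = np.nanmax(np.abs(mat)) or 1e-6
        im = ax.pcolormesh(
            kymo.times, kymo.bin_centers, mat,
            cmap="RdBu_r", vmin=-lim, vmax=lim, shading="nearest",
        )
        fig.colorbar(im, ax=ax, label=label)
        ax.set_ylabel("distance to airway (µm)")
    axes[1].set_xlabel("time (s)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def profile_lines(kymo: Kymograph, path: str | Path) -> None:
    """Mean strain vs distance, one line per time point, time color-coded."""
    cmap = plt.get_cmap("viridis")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    tmin, tmax = kymo.times[0], kymo.times[-1]
    span = (tmax - tmin) or 1.0
    for j, t in enumerate(kymo.times):
        c = cmap((t - tmin) / span)
        axes[0].plot(kymo.bin_centers, kymo.major[:, j], color=c, lw=1)
        axes[1].plot(kymo.bin_centers, kymo.minor[:, j], color=c, lw=1)
    for ax, label in zip(axes, ("radial (major)", "circumferential (minor)")):
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("distance to airway (µm)")
        ax.set_ylabel(f"{label} strain")
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(tmin, tmax))
    fig.colorbar(sm, ax=axes, label="time (s)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def area_curve(lumen_df, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(lumen_df["time_s"], lumen_df["area_um2"], "k.-", ms=3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("lumen area (µm²)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def spokes_figure(spoke_disp_df, path: str | Path) -> None:
    """Per-section inward displacement vs distance with variability bands,
    at the last analyzed time point."""
    t_last = spoke_disp_df["time_s"].max()
    df = spoke_disp_df[spoke_disp_df["time_s"] == t_last]
    sections = sorted(df["section"].unique())
    n = len(sections)
    ncol = min(4, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow),
                             sharex=True, sharey=True, squeeze=False)
    for s, ax in zip(sections, axes.ravel()):
        sub = df[df["section"] == s]
        ax.errorbar(sub["distance_um"], sub["mean_displacement_um"],
                    yerr=sub["sd_displacement_um"], fmt="-", lw=1, elinewidth=0.5)
        ax.set_title(f"section {chr(97 + int(s))}", fontsize=9)
        ax.axhline(0, color="k", lw=0.5)
    for ax in axes[-1]:
        ax.set_xlabel("distance (µm)")
    for row in axes:
        row[0].set_ylabel("inward displ. (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
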