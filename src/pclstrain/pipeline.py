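"""End-to-end analysis pipeline: movie in, displacement/strain/profile tables out.

This module wires the stages together in the order a strain-mapping run
uses them — preprocess, segment the lumen, build the tissue mask, estimate
reference-to-frame displacement fields, evaluate strain grids, bin by
distance to the airway — and carries one :class:`AnalysisConfig` with
every tunable parameter, serializable to JSON so a run's effective
configuration can be stored alongside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import morphology

from .flow import DisplacementField, FlowParams, estimate_displacement
from .imaging_io import FrameSequence, stretch_contrast, tissue_mask
from .lumen import LumenEllipse, fit_ellipse, lumen_area_series, segment_lumen
from .radial import Kymograph, bin_average, distance_map, kymograph
from .spokes import SpokeSet, build_spokes, spoke_displacement_profile, spoke_strain_profile
from .strain_core import StrainField, strain_field

logger = logging.getLogger("pclstrain")

__all__ = ["AnalysisConfig", "AnalysisResult", "preprocess", "analyze"]


@dataclass
class AnalysisConfig:
    """Every pipeline parameter, with documented defaults.

    Calibration defaults follow a typical inverted-microscope PCLS
    recording: 1.15 μm/px, one frame per 2 s, reference frame 0.
    """

    pixel_size_um: float = 1.15
    frame_interval_s: float = 2.0
    reference_index: int = 0
    # contrast stretch percentiles; the low/high mapping is taken from the
    # reference frame and applied to every frame so flow sees one scale
    contrast_p_low: float = 1.0
    contrast_p_high: float = 99.0
    # flow backend
    flow: FlowParams = field(default_factory=FlowParams)
    # strain evaluation
    grid_spacing_px: int = 7
    stencil_h_px: int = 7
    # tissue mask
    mask_window_px: int = 7
    mask_min_object_px: int = 100
    mask_max_hole_px: int = 50
    # keep strain stencils off the lumen rim: the lumen is excluded from
    # the tissue mask after dilation by this many px (about half the
    # stencil width, so stencils stay predominantly on tissue where the
    # flow is constrained by texture)
    lumen_exclusion_dilation_px: int = 4
    # radial binning
    bin_width_um: float = 15.0
    # "reference" bins Lagrangian strains against the reference-frame lumen
    # boundary; "per-frame" reproduces binning against the current frame's
    distance_frame: str = "reference"
    # spokes
    n_sections: int = 8
    n_spokes: int = 7
    spoke_radial_step_um: float = 8.05
    spoke_max_length_um: float = 400.0

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(source)
        d = json.loads(p.read_text() if p.exists() else str(source))
        flow = FlowParams(**d.pop("flow", {}))
        return cls(flow=flow, **d)


@dataclass
class AnalysisResult:
    """Everything one analysis run produced, in memory."""

    sequence: FrameSequence
    config: AnalysisConfig
    lumen_mask: np.ndarray               # reference frame
    ellipse: LumenEllipse
    tissue: np.ndarray                   # strain-support mask (lumen excluded)
    target_indices: list[int]
    fields: list[DisplacementField]
    strains: list[StrainField]
    profiles: list
    kymo: Kymograph
    lumen_df: pd.DataFrame | None = None

    def displacement_table(self) -> pd.DataFrame:
        rows = []
        for t, f, s in zip(self.target_indices, self.fields, self.strains):
            df = s.to_frame()
            X, Y = s.positions()
            df.insert(0, "time_s", self.sequence.times[t])
            df["u_px"] = f.u[Y, X].ravel()
            df["v_px"] = f.v[Y, X].ravel()
            df["disp_um"] = np.hypot(df.u_px, df.v_px) * f.pixel_size
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def preprocess(sequence: FrameSequence, config: AnalysisConfig) -> FrameSequence:
    """Contrast-stretch every frame with the linear map defined by the
    reference frame's percentiles (a shared monotone rescaling, so the
    flow backend sees consistent intensities)."""
    ref = sequence.frames[sequence.reference_index]
    lo, hi = np.percentile(ref, [config.contrast_p_low, config.contrast_p_high])
    if hi - lo <= 0:
        return sequence
    frames = [np.clip((f - lo) / (hi - lo), 0.0, 1.0) for f in sequence.frames]
    return FrameSequence(frames=frames, times=sequence.times,
                         pixel_size=sequence.pixel_size,
                         reference_index=sequence.reference_index)


def strain_support_mask(
    frame: np.ndarray, lumen: np.ndarray, config: AnalysisConfig
) -> np.ndarray:
    """Tissue mask for strain evaluation: textured tissue minus the lumen
    dilated by a small margin, so no evaluation point sits on the rim
    where flow is unconstrained."""
    tm = tissue_mask(
        frame,
        window=config.mask_window_px,
        min_object_px=config.mask_min_object_px,
        max_hole_px=config.mask_max_hole_px,
    )
    d = config.lumen_exclusion_dilation_px
    excl = morphology.dilation(lumen, morphology.disk(d)) if d > 0 else lumen
    return tm & ~excl


def analyze(
    sequence: FrameSequence,
    config: AnalysisConfig | None = None,
    target_indices: list[int] | None = None,
    segment_all_frames: bool = False,
) -> AnalysisResult:
    """Run the full pipeline on a calibrated sequence.

    ``target_indices`` selects the frames to compare against the
    reference (default: every non-reference frame).  With
    ``segment_all_frames`` the lumen caliber series over all frames is
    computed as well (it only needs segmentation, not flow).
    """
    config = config or AnalysisConfig()
    seq = preprocess(sequence, config)
    if target_indices is None:
        target_indices = [i for i in range(len(seq)) if i != seq.reference_index]

    ref = seq.reference
    lumen = segment_lumen(ref)
    ellipse = fit_ellipse(lumen)
    tissue = strain_support_mask(ref, lumen, config)
    logger.info("lumen: %d px, ellipse center (%.1f, %.1f)",
                lumen.sum(), ellipse.cx, ellipse.cy)

    dmap_ref = distance_map(lumen, seq.pixel_size)
    fields, strains, profiles = [], [], []
    for t in target_indices:
        f = estimate_displacement(seq, t, config.flow)
        s = strain_field(f, config.grid_spacing_px, config.stencil_h_px,
                         mask=tissue, lumen_center=ellipse.center)
        if config.distance_frame == "per-frame":
            dmap = distance_map(segment_lumen(seq.frames[t]), seq.pixel_size)
        else:
            dmap = dmap_ref
        profiles.append(bin_average(s, dmap, config.bin_width_um))
        fields.append(f)
        strains.append(s)
        logger.info("frame %d: flow + strain done", t)

    kymo = kymograph(profiles, seq.times[target_indices])
    lumen_df = lumen_area_series(seq) if segment_all_frames else None
    return AnalysisResult(
        sequence=seq, config=config, lumen_mask=lumen, ellipse=ellipse,
        tissue=tissue, target_indices=list(target_indices), fields=fields,
        strains=strains, profiles=profiles, kymo=kymo, lumen_df=lumen_df,
    )


def run_spokes(
    result: AnalysisResult,
) -> tuple[SpokeSet, pd.DataFrame, pd.DataFrame]:
    """Spokes analysis on an existing run: per-section displacement and
    strain profiles for every analyzed frame (long format with time)."""
    cfg = result.config
    spokes = build_spokes(
        result.ellipse,
        result.sequence.shape,
        result.sequence.pixel_size,
        n_sections=cfg.n_sections,
        n_spokes=cfg.n_spokes,
        radial_step=cfg.spoke_radial_step_um,
        max_length=cfg.spoke_max_length_um,
    )
    disp_rows, strain_rows = [], []
    for t, f in zip(result.target_indices, result.fields):
        d = spoke_displacement_profile(f, spokes)
        d.insert(0, "time_s", result.sequence.times[t])
        disp_rows.append(d)
        s = spoke_strain_profile(f, spokes, h=cfg.stencil_h_px)
        s.insert(0, "time_s", result.sequence.times[t])
        strain_rows.append(s)
    return spokes, pd.concat(disp_rows, ignore_index=True), pd.concat(strain_rows, ignore_index=True)
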