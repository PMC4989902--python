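"""Shared fixtures: synthetic movies with analytic ground truth.

The expensive artifacts (rendered movies and their optical-flow fields)
are session-scoped so every test file reuses one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from pclstrain import (
    FrameSequence,
    DisplacementField,
    estimate_displacement,
    fit_ellipse,
    segment_lumen,
    tissue_mask,
)
from pclstrain.pipeline import AnalysisConfig, strain_support_mask
from pclstrain.synthetic import (
    SyntheticTruth,
    annulus_contraction,
    make_speckle_texture,
    render_sequence,
    rigid_motion_sequence,
    uniform_stretch_sequence,
)

SIZE = 384
PIXEL_SIZE = 1.15          # um / px
R0_UM = 100.0
R1_UM = 80.0
CENTER = ((SIZE - 1) / 2.0, (SIZE - 1) / 2.0)


@pytest.fixture(scope="session")
def texture() -> np.ndarray:
    return make_speckle_texture((SIZE, SIZE), feature_scale=3.0, seed=1)


@dataclass
class AnnulusBundle:
    """Rendered contraction movie plus everything derived from it once."""

    truth: SyntheticTruth
    sequence: FrameSequence
    field: DisplacementField          # flow, reference -> final frame
    lumen0: np.ndarray
    tissue: np.ndarray                # strain-support mask
    ellipse: object
    analytic_field: DisplacementField  # exact displacement, same geometry

    def radius_um(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        cx, cy = self.truth.center
        return np.hypot(X - cx, Y - cy) * PIXEL_SIZE


@pytest.fixture(scope="session")
def annulus(texture) -> AnnulusBundle:
    truth = annulus_contraction(R0_UM, [R0_UM, R1_UM], CENTER, PIXEL_SIZE)
    seq = render_sequence(texture, truth, [0.0, 600.0], noise_sd=0.01, seed=2)
    field = estimate_displacement(seq, 1)
    lumen0 = segment_lumen(seq.frames[0])
    ellipse = fit_ellipse(lumen0)
    tissue = strain_support_mask(seq.frames[0], lumen0, AnalysisConfig())
    Y, X = np.mgrid[0:SIZE, 0:SIZE].astype(float)
    u, v = truth.displacement(X, Y, 1)
    analytic = DisplacementField(u, v, 0, 1, PIXEL_SIZE)
    return AnnulusBundle(truth, seq, field, lumen0, tissue, ellipse, analytic)


@pytest.fixture(scope="session")
def translation_bundle(texture):
    seq, truth = rigid_motion_sequence(texture, 3.0, -2.0, 0.0, pixel_size=PIXEL_SIZE)
    field = estimate_displacement(seq, 1)
    return seq, truth, field


@pytest.fixture(scope="session")
def rotation_bundle(texture):
    seq, truth = rigid_motion_sequence(texture, 0.0, 0.0, 10.0, pixel_size=PIXEL_SIZE)
    field = estimate_displacement(seq, 1)
    return seq, truth, field


@pytest.fixture(scope="session")
def stretch_bundle(texture):
    seq, truth = uniform_stretch_sequence(texture, alpha=1.1, pixel_size=PIXEL_SIZE)
    field = estimate_displacement(seq, 1)
    return seq, truth, field
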