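"""Antibody-uptake endocytosis quantification via four-mask voxel arithmetic.

The assay labels surface transporter with an epitope-tag antibody, stains
the remaining surface pool before permeabilization (Cy5) and the
internalized pool after permeabilization (Cy3).  Quantification builds
four boolean voxel masks from the background-subtracted stack:

* mask 1 — Cy5-positive voxels (total surface label);
* mask 2 — Cy3-positive voxels (raw intracellular label);
* mask 3 — Cy3-positive voxels that overlap Cy5-positive voxels,
  attributing that Cy3 signal to incomplete surface occupancy by the
  pre-permeabilization stain;
* mask 4 — mask 2 minus mask 3, the corrected internalized signal.

The endocytosis readout is the ratio of integrated Cy3 intensity over
mask 4 to integrated Cy5 intensity over mask 1 (the Cy3/Cy5 ratio, in
arbitrary linear units of fluorescence intensity).  Ratio time-courses
over an internalization interval are summarised by an ordinary
least-squares line with its R^2 linearity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .io import DegenerateInputError, ImageStack


def segment_channel(stack: ImageStack, channel: str, threshold) -> np.ndarray:
    """Threshold a channel into a boolean voxel mask (inclusive: >= threshold).

    ``threshold`` is either a non-negative scalar (the assay's manually
    chosen "minimal intensity" low threshold) or the string ``"otsu"``, in
    which case Otsu's criterion is computed over a 256-bin histogram of
    the channel's nonzero voxels.
    """
    grid = stack.channel(channel)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        nonzero = grid[grid > 0]
        if nonzero.size == 0:
            raise DegenerateInputError(
                f"channel {channel!r} is all zeros; Otsu threshold undefined"
            )
        t = float(threshold_otsu(nonzero, nbins=256))
    else:
        t = float(threshold)
        if t < 0:
            raise ValueError("threshold must be >= 0")
    return grid >= t


@dataclass
class MaskQuartet:
    """The four boolean masks of the endocytosis assay.

    Invariants (guaranteed by construction in :func:`build_mask_quartet`):
    mask3 = mask2 AND mask1, mask4 = mask2 AND NOT mask3, so mask3 and
    mask4 partition mask2.
    """

    mask1: np.ndarray  # surface (Cy5)
    mask2: np.ndarray  # raw internalized (Cy3)
    mask3: np.ndarray  # Cy3 overlapping Cy5
    mask4: np.ndarray  # corrected internalized
    thresholds: tuple


@dataclass
class EndocytosisResult:
    cy5_integrated: float  # a.l.u.f.i. summed over mask1
    cy3_integrated: float  # a.l.u.f.i. summed over mask4
    ratio: float           # cy3_integrated / cy5_integrated


@dataclass
class KineticsFit:
    slope: float       # ratio units per minute
    intercept: float
    r_squared: float


def build_mask_quartet(
    stack: ImageStack,
    cy5_threshold,
    cy3_threshold,
    dilation_radius: int = 0,
    cy5_channel: str = "Cy5",
    cy3_channel: str = "Cy3",
) -> MaskQuartet:
    """Build masks 1-4 from the surface and internalized channels.

    ``dilation_radius`` (voxels, default 0) optionally dilates mask 1
    before the overlap step to tolerate chromatic offset between the two
    channels; the overlap is voxelwise otherwise.
    """
    mask1 = segment_channel(stack, cy5_channel, cy5_threshold)
    mask2 = segment_channel(stack, cy3_channel, cy3_threshold)
    overlap_ref = mask1
    if dilation_radius > 0:
        overlap_ref = ndimage.binary_dilation(mask1, iterations=dilation_radius)
    mask3 = mask2 & overlap_ref
    mask4 = mask2 & ~mask3
    return MaskQuartet(
        mask1=mask1, mask2=mask2, mask3=mask3, mask4=mask4,
        thresholds=(cy5_threshold, cy3_threshold),
    )


def endocytosis_ratio(
    stack: ImageStack,
    quartet: MaskQuartet,
    cy5_channel: str = "Cy5",
    cy3_channel: str = "Cy3",
) -> EndocytosisResult:
    """Integrate channel intensities over masks 1 and 4 and form the ratio."""
    cy5 = stack.channel(cy5_channel)
    cy3 = stack.channel(cy3_channel)
    if quartet.mask1.shape != cy5.shape:
        raise ValueError("mask shape does not match stack shape")
    cy5_sum = float(cy5[quartet.mask1].sum())
    cy3_sum = float(cy3[quartet.mask4].sum())
    if cy5_sum == 0:
        raise DegenerateInputError("no surface signal: integrated Cy5 over mask1 is 0")
    return EndocytosisResult(
        cy5_integrated=cy5_sum, cy3_integrated=cy3_sum, ratio=cy3_sum / cy5_sum
    )


def fit_linear_kinetics(times_min, ratios) -> KineticsFit:
    """Ordinary least-squares line through a ratio time-course.

    R^2 is the squared Pearson correlation between fitted and observed
    ratios (1.0 for an exact line, 1.0 by convention for a perfectly
    constant series since the fit reproduces it exactly).
    """
    t = np.asarray(times_min, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.size != r.size:
        raise ValueError("times and ratios must have equal length")
    if np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct time points")
    res = stats.linregress(t, r)
    return KineticsFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
    )
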