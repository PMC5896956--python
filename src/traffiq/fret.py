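"""Sensitized-emission FRET with three-cube bleed-through correction.

Three filter channels are acquired: donor (CFP), acceptor (YFP) and FRET
(donor excitation, acceptor emission).  The raw FRET channel mixes true
sensitized emission with spectral bleed-through from both fluorophores.
With coefficients estimated from single-fluorophore control cells, the
corrected FRET image is computed pixelwise as

    FRET_c = I_FRET - a * I_CFP - b * I_YFP

where ``a`` is the donor and ``b`` the acceptor bleed-through fraction.
Region-level normalized FRET divides the mean corrected FRET by the
product of donor and acceptor means:

    FRETN = mean(FRET_c) / (mean(YFP) * mean(CFP))

FRETN is nonlinear when one fluorophore is in large molar excess, so a
region only enters comparisons when max(CFP, YFP)/min(CFP, YFP) <= 3.
FRETN carries reciprocal-intensity units and is acquisition-dependent;
only within-experiment comparisons (identical settings) are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import DegenerateInputError, ImageStack

#: Donor:acceptor stoichiometry beyond which a region is excluded.
STOICHIOMETRY_LIMIT = 3.0


@dataclass
class FretCalibration:
    """Bleed-through coefficients from single-fluorophore controls."""

    a_donor: float       # donor-channel signal appearing in the FRET channel
    b_acceptor: float    # acceptor-channel signal appearing in the FRET channel
    n_pixels_donor: int = 0
    n_pixels_acceptor: int = 0

    def __post_init__(self) -> None:
        if self.a_donor < 0 or self.b_acceptor < 0:
            raise ValueError("bleed-through coefficients must be >= 0")


@dataclass
class FretRoiResult:
    fretc_mean: float            # a.l.u.f.i.
    cfp_mean: float              # a.l.u.f.i.
    yfp_mean: float              # a.l.u.f.i.
    fretn: float                 # 1 / a.l.u.f.i.
    stoichiometry_ratio: float   # max(cfp,yfp)/min(cfp,yfp), >= 1
    included: bool               # stoichiometry_ratio <= 3


def estimate_bleedthrough(
    control: ImageStack,
    fluorophore_channel: str,
    fret_channel: str = "FRET",
    min_intensity: float = 0.0,
    min_pixels: int = 50,
) -> tuple[float, int]:
    """Estimate one bleed-through coefficient from a single-label control.

    The coefficient is the slope of a zero-intercept least-squares
    regression of FRET-channel intensity on fluorophore-channel intensity
    over pixels whose fluorophore intensity is >= ``min_intensity``,
    weighted by the inverse of the fluorophore intensity (the correct
    weighting under shot noise, whose variance scales with intensity).
    With those weights the slope reduces to the ratio of summed FRET to
    summed fluorophore intensity, which is also robust to the attenuation
    bias an unweighted slope suffers when the fluorophore channel itself
    is noisy.  The regression runs through the origin because backgrounds
    are subtracted upstream; an intercept would absorb residual offsets
    ambiguously.  Negative slopes are clamped to zero with a warning.

    Returns ``(coefficient, n_pixels_used)``.
    """
    x = control.channel(fluorophore_channel).ravel()
    y = control.channel(fret_channel).ravel()
    sel = x >= min_intensity
    n = int(sel.sum())
    if n < min_pixels:
        raise DegenerateInputError(
            f"only {n} pixels above min_intensity={min_intensity}; need >= {min_pixels}"
        )
    xs, ys = x[sel], y[sel]
    denom = float(xs.sum())
    if denom == 0:
        raise DegenerateInputError("selected pixels carry zero fluorophore intensity")
    slope = float(ys.sum()) / denom
    if slope < 0:
        warnings.warn(
            f"negative bleed-through slope {slope:.4g} clamped to 0", stacklevel=2
        )
        slope = 0.0
    return slope, n


def calibrate(
    donor_control: ImageStack,
    acceptor_control: ImageStack,
    donor_channel: str = "CFP",
    acceptor_channel: str = "YFP",
    fret_channel: str = "FRET",
    min_intensity: float = 0.0,
    min_pixels: int = 50,
) -> FretCalibration:
    """Estimate both coefficients from donor-only and acceptor-only stacks."""
    a, na = estimate_bleedthrough(
        donor_control, donor_channel, fret_channel, min_intensity, min_pixels
    )
    b, nb = estimate_bleedthrough(
        acceptor_control, acceptor_channel, fret_channel, min_intensity, min_pixels
    )
    return FretCalibration(a_donor=a, b_acceptor=b, n_pixels_donor=na, n_pixels_acceptor=nb)


def corrected_fret(
    stack: ImageStack,
    calib: FretCalibration,
    donor_channel: str = "CFP",
    acceptor_channel: str = "YFP",
    fret_channel: str = "FRET",
) -> np.ndarray:
    """Pixelwise corrected FRET: I_FRET - a*I_CFP - b*I_YFP.

    Negative pixels are retained so that region means stay unbiased.
    """
    cfp = stack.channel(donor_channel)
    yfp = stack.channel(acceptor_channel)
    fret = stack.channel(fret_channel)
    return fret - calib.a_donor * cfp - calib.b_acceptor * yfp


def _roi_selector(shape, roi):
    """Accept a boolean mask or ((z0,z1),(y0,y1),(x0,x1)) half-open box."""
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError("ROI mask shape mismatch")
        if not roi.any():
            raise ValueError("ROI is empty")
        return roi
    (z0, z1), (y0, y1), (x0, x1) = roi
    mask = np.zeros(shape, dtype=bool)
    mask[z0:z1, y0:y1, x0:x1] = True
    if not mask.any():
        raise ValueError("ROI is empty")
    return mask


def fretn_roi(
    stack: ImageStack,
    fretc_grid: np.ndarray,
    roi,
    donor_channel: str = "CFP",
    acceptor_channel: str = "YFP",
) -> FretRoiResult:
    """Region-level normalized FRET with stoichiometry gating.

    ``roi`` is either a boolean mask of the stack's shape or a rectangular
    region ``((z0,z1),(y0,y1),(x0,x1))`` with half-open bounds.
    """
    mask = _roi_selector(stack.shape, roi)
    cfp_mean = float(stack.channel(donor_channel)[mask].mean())
    yfp_mean = float(stack.channel(acceptor_channel)[mask].mean())
    fretc_mean = float(np.asarray(fretc_grid)[mask].mean())
    if cfp_mean <= 0 or yfp_mean <= 0:
        raise DegenerateInputError("donor/acceptor ROI mean must be > 0 for FRETN")
    ratio = max(cfp_mean, yfp_mean) / min(cfp_mean, yfp_mean)
    return FretRoiResult(
        fretc_mean=fretc_mean,
        cfp_mean=cfp_mean,
        yfp_mean=yfp_mean,
        fretn=fretc_mean / (yfp_mean * cfp_mean),
        stoichiometry_ratio=ratio,
        included=ratio <= STOICHIOMETRY_LIMIT,
    )


def compare_fretn(groups: dict[str, list[FretRoiResult]]) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise Welch two-tailed t tests on included FRETN values.

    Excluded regions (stoichiometry ratio beyond the gate) never enter the
    comparison.  Returns ``{(cond_a, cond_b): (t, p)}`` for every ordered
    pair with a < b in iteration order.
    """
    values: dict[str, np.ndarray] = {}
    for cond, rois in groups.items():
        vals = np.array([r.fretn for r in rois if r.included])
        if vals.size < 2:
            raise ValueError(f"condition {cond!r} has < 2 included ROIs")
        values[cond] = vals

    names = list(values)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.array_equal(values[a], values[b]):
                out[(a, b)] = (0.0, 1.0)
                continue
            t, p = stats.ttest_ind(values[a], values[b], equal_var=False)
            out[(a, b)] = (float(t), float(p))
    return out
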