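"""Ground-truth-annotated synthetic data for every assay in the package.

The generators here emulate, at the level needed to verify quantification
code, the four kinds of raw data the pipelines consume:

* confocal stacks of cells with a plasma-membrane (surface) fluorophore
  pool and punctate endosomal (internalized) pool — the antibody-uptake
  endocytosis assay (:func:`make_cell_stack`);
* two-channel stacks with a controlled fraction of one channel's puncta
  coinciding with the other's — endosomal colocalization
  (:func:`make_coloc_stack`);
* three-cube FRET acquisitions (donor, acceptor, FRET filter channels)
  with linear spectral bleed-through plus single-fluorophore control
  stacks (:func:`make_fret_triplet`);
* TIRF time-lapse movies of diffraction-limited spots with persistent and
  transient lifetimes (:func:`make_tirf_movie`);
* saturation-binding count tables with a linear nonspecific component
  (:func:`make_binding_dataset`).

Optics are deliberately simple — an isotropic Gaussian PSF, Poisson shot
noise scaled by a photon gain, and additive Gaussian read noise — because
the purpose is testing threshold/overlap/tracking/fit logic, not imaging
realism.  With ``noise=None`` every generator is an exact deterministic
function of its parameters.  Each call consumes a single NumPy Generator
seeded explicitly; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .binding import DEFAULT_CONCENTRATIONS_NM, BindingDataset
from .io import ImageStack, TirfMovie


@dataclass
class NoiseModel:
    """Photon-scaling Poisson noise plus Gaussian read noise.

    ``photon_scale`` converts the generator's intensity budget into
    expected photon counts before Poisson sampling; ``read_sd`` is the
    standard deviation of additive detector noise (counts).
    """

    photon_scale: float = 1.0
    read_sd: float = 2.0


@dataclass
class CellStackTruth:
    """Ground truth attached to simulated confocal stacks."""

    internalized_fraction: float
    overlap_fraction: float | None = None
    endosome_centers: list[tuple[int, int, int]] = field(default_factory=list)
    membrane_voxels: np.ndarray | None = None  # (n, 3) int coordinates
    surface_coplacement: float = 0.0
    label_budget: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"key": "internalized_fraction", "value": self.internalized_fraction},
            {"key": "overlap_fraction", "value": self.overlap_fraction},
            {"key": "surface_coplacement", "value": self.surface_coplacement},
            {"key": "label_budget", "value": self.label_budget},
        ]
        for z, y, x in self.endosome_centers:
            rows.append({"key": "endosome_center", "value": f"{z};{y};{x}"})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellStackTruth":
        def scalar(key, default=None):
            sel = df.loc[df["key"] == key, "value"]
            if sel.empty or pd.isna(sel.iloc[0]):
                return default
            return float(sel.iloc[0])

        centers = [
            tuple(int(float(p)) for p in str(v).split(";"))
            for v in df.loc[df["key"] == "endosome_center", "value"]
        ]
        return cls(
            internalized_fraction=scalar("internalized_fraction", 0.0),
            overlap_fraction=scalar("overlap_fraction"),
            surface_coplacement=scalar("surface_coplacement", 0.0),
            label_budget=scalar("label_budget", 0.0),
            endosome_centers=centers,
        )


@dataclass
class SpotTruth:
    """One simulated TIRF spot: lifetime interval and per-frame positions."""

    appearance_frame: int
    disappearance_frame: int
    positions: np.ndarray  # (n_alive_frames, 2) row/col
    persistent: bool

    @property
    def duration_frames(self) -> int:
        return self.disappearance_frame - self.appearance_frame


@dataclass
class TirfTruth:
    tracks: list[SpotTruth]
    persistent_fraction: float


@dataclass
class BindingTruth:
    """True parameters behind a simulated saturation-binding dataset."""

    kd_true: float          # nM
    bmax_true: float        # counts at saturation
    ns_slope_true: float    # counts per nM, linear nonspecific component

    def __post_init__(self) -> None:
        if self.kd_true <= 0 or self.bmax_true <= 0 or self.ns_slope_true < 0:
            raise ValueError("kd_true, bmax_true must be > 0 and ns_slope_true >= 0")


@dataclass
class FretTruth:
    a_donor: float
    b_acceptor: float
    sensitized: np.ndarray          # pre-noise sensitized-emission grid
    cfp_clean: np.ndarray           # pre-noise donor channel
    yfp_clean: np.ndarray           # pre-noise acceptor channel


# ---------------------------------------------------------------------------
# helpers


def _apply_noise(grid: np.ndarray, noise: NoiseModel | None, rng: np.random.Generator) -> np.ndarray:
    if noise is None:
        return grid
    counts = rng.poisson(np.maximum(grid * noise.photon_scale, 0.0)).astype(float)
    if noise.read_sd > 0:
        counts = counts + rng.normal(0.0, noise.read_sd, size=counts.shape)
    return np.maximum(counts, 0.0)


def _blur(grid: np.ndarray, sigma_lateral: float, sigma_axial: float | None) -> np.ndarray:
    if sigma_axial is None:
        sigma_axial = sigma_lateral
    return ndimage.gaussian_filter(grid, sigma=(sigma_axial, sigma_lateral, sigma_lateral))


def _gaussian_blob(shape, center, sigma, total):
    """Place a 3D Gaussian blob whose voxel sum is exactly ``total``."""
    grid = np.zeros(shape)
    half = int(np.ceil(5 * sigma))
    zc, yc, xc = center
    zs = slice(max(zc - half, 0), min(zc + half + 1, shape[0]))
    ys = slice(max(yc - half, 0), min(yc + half + 1, shape[1]))
    xs = slice(max(xc - half, 0), min(xc + half + 1, shape[2]))
    z, y, x = np.mgrid[zs, ys, xs]
    blob = np.exp(-((z - zc) ** 2 + (y - yc) ** 2 + (x - xc) ** 2) / (2 * sigma**2))
    blob *= total / blob.sum()
    grid[zs, ys, xs] = blob
    return grid


def _ellipsoid_radius(shape, margin):
    center = (np.array(shape) - 1) / 2.0
    semi = center - margin
    z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]]
    rho = np.sqrt(
        ((z - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((x - center[2]) / semi[2]) ** 2
    )
    return rho, center, semi


# ---------------------------------------------------------------------------
# confocal endocytosis stack


def make_cell_stack(
    shape: tuple[int, int, int] = (20, 96, 96),
    internalized_fraction: float = 0.3,
    n_endosomes: int = 12,
    psf_sigma: float = 1.0,
    noise: NoiseModel | None = NoiseModel(photon_scale=1.0, read_sd=2.0),
    seed: int = 0,
    surface_coplacement: float = 0.0,
    label_budget: float = 1.5e6,
    endosome_sigma: float = 1.5,
    psf_sigma_axial: float | None = None,
    shell_width: float = 0.12,
    membrane_clearance: float | None = None,
) -> tuple[ImageStack, CellStackTruth]:
    """Simulate an antibody-uptake endocytosis stack.

    A thin ellipsoidal shell plays the plasma membrane and carries
    ``1 - internalized_fraction`` of the label budget into the surface
    (Cy5) channel; ``n_endosomes`` Gaussian puncta well inside the shell
    carry ``internalized_fraction`` into the internalized (Cy3) channel.
    ``surface_coplacement`` additionally co-places that fraction of the
    Cy3 budget on membrane voxels, emulating incomplete occupancy of
    surface epitopes by the pre-permeabilization label.  A YFP channel
    holds the total (membrane + endosome) distribution.  All channels are
    blurred by the Gaussian PSF and noise is applied per
    :class:`NoiseModel`.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 8 for s in shape):
        raise ValueError("each stack dimension must be >= 8")
    if not 0.0 <= internalized_fraction <= 1.0:
        raise ValueError("internalized_fraction must lie in [0, 1]")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    if n_endosomes > 0 and internalized_fraction == 0:
        raise ValueError("n_endosomes > 0 contradicts internalized_fraction == 0")
    if n_endosomes == 0 and internalized_fraction > 0:
        raise ValueError("internalized_fraction > 0 needs n_endosomes >= 1")

    rng = np.random.default_rng(seed)
    margin = max(3.0, 3 * psf_sigma)
    rho, center, semi = _ellipsoid_radius(shape, margin)

    membrane = (rho >= 1.0 - shell_width) & (rho <= 1.0)
    if not membrane.any():
        raise ValueError("shape too small for a membrane shell at this margin")
    mem_coords = np.argwhere(membrane)

    surface_budget = (1.0 - internalized_fraction) * label_budget
    internal_budget = internalized_fraction * label_budget

    cy5 = np.zeros(shape)
    cy5[membrane] = surface_budget / membrane.sum()

    # endosome centers: cytoplasmic, with Euclidean clearance from the
    # membrane shell (endosomes do not sit against the plasma membrane, and
    # clearance keeps blurred blob skirts out of the surface mask)
    cy3 = np.zeros(shape)
    centers: list[tuple[int, int, int]] = []
    if membrane_clearance is None:
        membrane_clearance = 2.5 * (psf_sigma + endosome_sigma)
    dist_to_membrane = ndimage.distance_transform_edt(~membrane)
    interior = np.argwhere((rho < 1.0 - shell_width) & (dist_to_membrane >= membrane_clearance))
    if n_endosomes > 0 and interior.size == 0:
        raise ValueError("no interior voxels satisfy the membrane clearance")
    if n_endosomes > 0:
        min_sep = max(4.0, 4 * endosome_sigma)
        # greedy placement can dead-end on unlucky early draws; restart the
        # whole configuration rather than loosening the separation
        for _restart in range(100):
            centers = []
            attempts = 0
            while len(centers) < n_endosomes and attempts < 2000:
                attempts += 1
                cand = tuple(interior[rng.integers(len(interior))])
                if all(np.linalg.norm(np.subtract(cand, c)) >= min_sep for c in centers):
                    centers.append(cand)
            if len(centers) == n_endosomes:
                break
        if len(centers) < n_endosomes:
            raise ValueError("could not place endosomes with required separation")
        per_blob = internal_budget / n_endosomes
        for c in centers:
            cy3 += _gaussian_blob(shape, c, endosome_sigma, per_blob)

    if surface_coplacement > 0:
        coplaced = surface_coplacement * internal_budget
        cy3_mem = np.zeros(shape)
        cy3_mem[membrane] = coplaced / membrane.sum()
        cy3 = cy3 + cy3_mem

    yfp = cy5 + cy3

    channels = {}
    for name, grid in (("Cy5", cy5), ("Cy3", cy3), ("YFP", yfp)):
        blurred = _blur(grid, psf_sigma, psf_sigma_axial)
        channels[name] = _apply_noise(blurred, noise, rng)

    stack = ImageStack(channels=channels, metadata={"simulation": "cell_stack", "seed": str(seed)})
    truth = CellStackTruth(
        internalized_fraction=internalized_fraction,
        endosome_centers=centers,
        membrane_voxels=mem_coords,
        surface_coplacement=surface_coplacement,
        label_budget=label_budget,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# colocalization stack


def make_coloc_stack(
    shape: tuple[int, int, int] = (16, 96, 96),
    overlap_fraction: float = 0.5,
    n_puncta: int = 20,
    seed: int = 0,
    noise: NoiseModel | None = NoiseModel(photon_scale=1.0, read_sd=2.0),
    psf_sigma: float = 1.0,
    punctum_sigma: float = 1.5,
    budget_per_channel: float = 4.0e5,
) -> tuple[ImageStack, CellStackTruth]:
    """Simulate a two-channel stack with a controlled colocalized fraction.

    ``n_puncta`` equal-intensity puncta are placed in each of the YFP and
    TxR (cargo) channels.  ``round(overlap_fraction * n_puncta)`` YFP
    puncta share their centre with a TxR punctum; the rest are kept at
    least 6 blur widths from every TxR punctum.  Because puncta carry
    equal intensity, the true intensity-weighted colocalized fraction
    equals the realized punctum fraction, recorded in the returned truth.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)

    margin = int(np.ceil(max(4.0, 3.0 * np.hypot(punctum_sigma, psf_sigma))))
    lo = np.array([margin] * 3)
    hi = np.array(shape) - margin
    if np.any(hi <= lo):
        raise ValueError("shape too small for puncta placement margin")

    def sample_point():
        return tuple(int(rng.integers(lo[i], hi[i])) for i in range(3))

    min_sep = 6.0 * max(punctum_sigma, psf_sigma)

    txr_centers: list[tuple[int, int, int]] = []
    attempts = 0
    while len(txr_centers) < n_puncta and attempts < 20000:
        attempts += 1
        cand = sample_point()
        if all(np.linalg.norm(np.subtract(cand, c)) >= min_sep for c in txr_centers):
            txr_centers.append(cand)
    if len(txr_centers) < n_puncta:
        raise ValueError("could not place TxR puncta with required separation")

    n_overlap = int(round(overlap_fraction * n_puncta))
    yfp_centers = list(txr_centers[:n_overlap])
    attempts = 0
    while len(yfp_centers) < n_puncta and attempts < 20000:
        attempts += 1
        cand = sample_point()
        others = txr_centers + yfp_centers[n_overlap:]
        if all(np.linalg.norm(np.subtract(cand, c)) >= min_sep for c in others):
            yfp_centers.append(cand)
    if len(yfp_centers) < n_puncta:
        raise ValueError("could not place YFP puncta with required separation")

    per_blob = budget_per_channel / n_puncta
    yfp = np.zeros(shape)
    txr = np.zeros(shape)
    for c in yfp_centers:
        yfp += _gaussian_blob(shape, c, punctum_sigma, per_blob)
    for c in txr_centers:
        txr += _gaussian_blob(shape, c, punctum_sigma, per_blob)

    channels = {
        "YFP": _apply_noise(_blur(yfp, psf_sigma, None), noise, rng),
        "TxR": _apply_noise(_blur(txr, psf_sigma, None), noise, rng),
    }
    stack = ImageStack(channels=channels, metadata={"simulation": "coloc_stack", "seed": str(seed)})
    truth = CellStackTruth(
        internalized_fraction=0.0,
        overlap_fraction=n_overlap / n_puncta if n_puncta else 0.0,
        endosome_centers=list(txr_centers),
        label_budget=budget_per_channel,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# FRET triplet


def make_fret_triplet(
    shape: tuple[int, int, int] = (1, 96, 96),
    sensitized: float | np.ndarray = 20.0,
    a_donor: float = 0.5,
    b_acceptor: float = 0.2,
    seed: int = 0,
    noise: NoiseModel | None = NoiseModel(photon_scale=1.0, read_sd=2.0),
    donor_level: float = 400.0,
    acceptor_level: float = 400.0,
    texture_sd: float = 0.15,
) -> tuple[ImageStack, ImageStack, ImageStack, FretTruth]:
    """Simulate a three-cube FRET experiment plus single-fluorophore controls.

    The experiment stack has channels CFP (donor), YFP (acceptor) and FRET
    (donor excitation / acceptor emission).  Before noise the FRET channel
    obeys the linear bleed-through law

        FRET = sensitized + a_donor * CFP + b_acceptor * YFP.

    ``sensitized`` may be a scalar (uniform over the simulated cell
    region) or a full grid.  The two control stacks contain one
    fluorophore each under the same law (their sensitized term is zero),
    which is what lets the bleed-through coefficients be estimated
    independently.  Donor/acceptor channels carry smooth multiplicative
    texture (lognormal-like, sd ``texture_sd``) so the regressions see a
    spread of intensities.
    """
    if a_donor < 0 or b_acceptor < 0:
        raise ValueError("bleed-through coefficients must be >= 0")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)

    rho, _, _ = _ellipsoid_radius(shape, margin=3.0) if min(shape) >= 8 else (None, None, None)
    if rho is None or shape[0] < 8:
        # thin stacks: use a 2D ellipse mask replicated over planes
        center = (np.array(shape[1:]) - 1) / 2.0
        semi = center - 3.0
        y, x = np.mgrid[: shape[1], : shape[2]]
        r2d = np.sqrt(((y - center[0]) / semi[0]) ** 2 + ((x - center[1]) / semi[1]) ** 2)
        cell = np.broadcast_to(r2d <= 1.0, shape).copy()
    else:
        cell = rho <= 1.0

    def textured(level):
        tex = np.exp(rng.normal(0.0, texture_sd, size=shape))
        tex = ndimage.gaussian_filter(tex, sigma=2.0)
        grid = np.zeros(shape)
        grid[cell] = level * tex[cell]
        return grid

    cfp = textured(donor_level)
    yfp = textured(acceptor_level)
    if np.isscalar(sensitized):
        sens = np.zeros(shape)
        sens[cell] = float(sensitized)
    else:
        sens = np.asarray(sensitized, dtype=float)
        if sens.shape != shape:
            raise ValueError("sensitized grid shape mismatch")
    fret = sens + a_donor * cfp + b_acceptor * yfp

    def finish(grids: dict[str, np.ndarray]) -> ImageStack:
        return ImageStack(
            channels={k: _apply_noise(v, noise, rng) for k, v in grids.items()},
            metadata={"simulation": "fret_triplet", "seed": str(seed)},
        )

    experiment = finish({"CFP": cfp, "YFP": yfp, "FRET": fret})

    cfp_ctrl = textured(donor_level)
    donor_only = finish(
        {"CFP": cfp_ctrl, "YFP": np.zeros(shape), "FRET": a_donor * cfp_ctrl}
    )
    yfp_ctrl = textured(acceptor_level)
    acceptor_only = finish(
        {"CFP": np.zeros(shape), "YFP": yfp_ctrl, "FRET": b_acceptor * yfp_ctrl}
    )

    truth = FretTruth(
        a_donor=a_donor, b_acceptor=b_acceptor,
        sensitized=sens, cfp_clean=cfp, yfp_clean=yfp,
    )
    return experiment, donor_only, acceptor_only, truth


# ---------------------------------------------------------------------------
# TIRF movie


def make_tirf_movie(
    shape: tuple[int, int] = (96, 96),
    n_frames: int = 40,
    n_spots: int = 30,
    persistent_fraction: float = 0.35,
    transient_lifetime_frames: float = 3.0,
    spot_sigma: float = 1.3,
    diffusion_step: float = 0.2,
    noise: NoiseModel | None = NoiseModel(photon_scale=1.0, read_sd=3.0),
    seed: int = 0,
    amplitude: float = 400.0,
    background: float = 40.0,
    frame_interval: float = 1.0,
    min_spacing: float = 0.0,
    appearance_window: int | None = None,
) -> tuple[TirfMovie, TirfTruth]:
    """Simulate a TIRF movie of diffraction-limited membrane clusters.

    ``round(persistent_fraction * n_spots)`` spots are persistent: once
    they appear (within ``appearance_window`` frames of the start, default
    the first fifth of the movie) they remain until the final frame.  The
    remaining spots are transient with geometric lifetimes of mean
    ``transient_lifetime_frames``.  Positions follow a bounded Gaussian
    random walk of per-frame step ``diffusion_step`` pixels.  Frames are a
    constant ``background`` plus Gaussian spots of peak ``amplitude``,
    with Poisson and read noise from :class:`NoiseModel`.

    ``min_spacing`` > 0 enforces a minimum separation between initial
    spot positions (used when detection fidelity is being measured).
    """
    if not 0.0 <= persistent_fraction <= 1.0:
        raise ValueError("persistent_fraction must lie in [0, 1]")
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    if spot_sigma <= 0:
        raise ValueError("spot_sigma must be > 0")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if appearance_window is None:
        appearance_window = max(1, n_frames // 5)

    margin = 3.0 * spot_sigma + 2.0
    lo = np.array([margin, margin])
    hi = np.array(shape, dtype=float) - margin

    n_persistent = int(round(persistent_fraction * n_spots))
    tracks: list[SpotTruth] = []

    starts: list[np.ndarray] = []
    attempts = 0
    while len(starts) < n_spots and attempts < 50000:
        attempts += 1
        cand = rng.uniform(lo, hi)
        if min_spacing > 0 and any(np.linalg.norm(cand - s) < min_spacing for s in starts):
            continue
        starts.append(cand)
    if len(starts) < n_spots:
        raise ValueError("could not place spots with required min_spacing")

    for i in range(n_spots):
        persistent = i < n_persistent
        if persistent:
            appear = int(rng.integers(0, appearance_window))
            vanish = n_frames - 1
        else:
            appear = int(rng.integers(0, n_frames))
            life = int(rng.geometric(1.0 / max(transient_lifetime_frames, 1.0)))
            vanish = min(appear + life - 1, n_frames - 1)
        n_alive = vanish - appear + 1
        pos = np.empty((n_alive, 2))
        pos[0] = starts[i]
        for t in range(1, n_alive):
            step = rng.normal(0.0, diffusion_step, size=2)
            pos[t] = np.clip(pos[t - 1] + step, lo, hi)
        tracks.append(
            SpotTruth(
                appearance_frame=appear,
                disappearance_frame=vanish,
                positions=pos,
                persistent=persistent,
            )
        )

    frames = np.full((n_frames,) + shape, float(background))
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for tr in tracks:
        for t_idx, (r, c) in enumerate(tr.positions):
            frame = tr.appearance_frame + t_idx
            win = int(np.ceil(4 * spot_sigma))
            r0, c0 = int(round(r)), int(round(c))
            ys = slice(max(r0 - win, 0), min(r0 + win + 1, shape[0]))
            xs = slice(max(c0 - win, 0), min(c0 + win + 1, shape[1]))
            frames[frame, ys, xs] += amplitude * np.exp(
                -((yy[ys, xs] - r) ** 2 + (xx[ys, xs] - c) ** 2) / (2 * spot_sigma**2)
            )

    noisy = np.stack([_apply_noise(f, noise, rng) for f in frames])
    movie = TirfMovie(frames=noisy, frame_interval=frame_interval)
    truth = TirfTruth(tracks=tracks, persistent_fraction=persistent_fraction)
    return movie, truth


# ---------------------------------------------------------------------------
# saturation binding


def make_binding_dataset(
    truth: BindingTruth,
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_NM,
    replicates: int = 3,
    noise_model: str | None = "poisson",
    seed: int = 0,
    gaussian_cv: float = 0.05,
    condition: str = "sim",
) -> BindingDataset:
    """Simulate total and paired nonspecific wells of a saturation assay.

    Expected total counts at concentration ``c`` are
    ``Bmax*c/(K_D+c) + ns_slope*c``; paired nonspecific wells (saturating
    competitor present) expect ``ns_slope*c``.  ``noise_model`` is
    ``"poisson"`` (counting statistics), ``"gaussian-cv"`` (relative noise
    of coefficient of variation ``gaussian_cv``) or ``None`` (exact).
    """
    concentrations = tuple(float(c) for c in concentrations)
    if not concentrations:
        raise ValueError("concentration list must be non-empty")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_model not in ("poisson", "gaussian-cv", None):
        raise ValueError(f"unknown noise_model {noise_model!r}")

    rng = np.random.default_rng(seed)

    def sample(mean: float) -> float:
        if noise_model is None:
            return mean
        if noise_model == "poisson":
            return float(rng.poisson(max(mean, 0.0)))
        return float(mean * (1.0 + rng.normal(0.0, gaussian_cv)))

    rows = []
    for rep in range(1, replicates + 1):
        for c in concentrations:
            specific = truth.bmax_true * c / (truth.kd_true + c)
            ns = truth.ns_slope_true * c
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "concentration_nM": c,
                    "total_counts": sample(specific + ns),
                    "nonspecific_counts": sample(ns),
                }
            )
    return BindingDataset(points=pd.DataFrame(rows), condition=condition)
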