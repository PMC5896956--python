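# Methods

This note documents the quantitative procedures implemented in traffiq,
the modelling assumptions behind the synthetic-data generators, the
parameters that matter, and the limits of what the synthetic validation
demonstrates about real data.

## Image containers and background subtraction

All confocal quantification operates on `ImageStack`: named channels of
3D `(plane, row, col)` intensity grids, 0-based voxel indexing, voxel
size `(dz, dy, dx)` in nm (default 300/100/100, matching serial confocal
sections acquired at 200–400 nm axial intervals). Intensities are in
arbitrary linear units (a.l.u.f.i.); only within-experiment comparisons
are meaningful.

Background subtraction is per-channel with clamping at zero (mask
intensity integrals must stay non-negative): either a constant offset, a
channel percentile (restricted to ≤ 50 so the offset tracks background,
not signal), or — the default estimate when nothing is configured — the
modal intensity of the channel's first plane, which in sparsely labelled
images is background-dominated. The estimation rule is a package choice,
exposed in configuration; published protocols typically state only that
backgrounds were subtracted.

## Endocytosis mask arithmetic

Segmentation is a simple inclusive threshold (voxel ≥ t). Thresholds are
the assay's free parameter: in practice they are chosen per experiment
as the minimal intensity of genuine staining, so the API accepts explicit
scalars and offers Otsu's criterion (256-bin histogram of nonzero
voxels) as an automated default for synthetic work. The four masks are
defined voxelwise:

    mask1 = Cy5 ≥ t5          (surface)
    mask2 = Cy3 ≥ t3          (raw internalized)
    mask3 = mask2 ∧ mask1     (Cy3 on incompletely occupied surface)
    mask4 = mask2 ∧ ¬mask3    (corrected internalized)

mask3/mask4 partition mask2 exactly by construction. The readout is
Σ_Cy3(mask4)/Σ_Cy5(mask1), computed per image (fields typically contain
5–15 cells); no per-cell instance segmentation is attempted. An optional
dilation of mask 1 before the overlap (default 0) is provided for
chromatic offset between channels. Ratio time-courses are fitted by
ordinary least squares; R² is the squared Pearson correlation.

Quantification is unbiased when the two channels' structures are
captured comparably by their thresholds. On noisy data a single global
threshold treats an extended dim membrane differently from compact
bright endosomes — the reason thresholds are chosen manually per
experiment in practice. The noise-free recovery test isolates the mask
arithmetic from this thresholding ambiguity.

## Colocalization

The colocalized fraction is intensity-weighted and deliberately
asymmetric (fraction of channel A's mask intensity inside channel B's
mask). The cargo mask drops connected components smaller than a
configurable voxel count (default 2) because cargo resides in punctate
endosomes and single-voxel detections are noise. Deconvolution, used
upstream in some published workflows, is out of scope; an optional
Gaussian high-pass prefilter (default off) provides comparable punctum
sharpening when needed. Pearson/Costes statistics and object-based
colocalization are intentionally not implemented.

## Sensitized-emission FRET

The standard two-coefficient three-cube correction is used:
FRETᶜ = I_FRET − a·I_CFP − b·I_YFP, with a and b estimated from
donor-only and acceptor-only control cells imaged with identical
settings. No additional direct-excitation cross-terms are modelled.

The coefficient estimator is a zero-intercept least-squares slope over
signal pixels, weighted by the inverse fluorophore intensity — the
correct weighting when variance scales with intensity (shot noise) —
which reduces to Σ(I_FRET)/Σ(I_fluor). This form is also robust to the
attenuation bias that the unweighted slope suffers when the regressor
channel itself carries noise (errors-in-variables); in simulation the
unweighted slope under-estimates the coefficient by a few 10⁻³, enough
to leave a systematic positive residual in corrected FRET of zero-FRET
controls. The regression runs through the origin because backgrounds are
subtracted upstream. Negative estimates are clamped to zero with a
warning; a configurable floor (default 50) on the number of usable
pixels guards against degenerate controls.

FRETᶜ pixels may be negative and are retained, so ROI means stay
unbiased. FRETN = mean(FRETᶜ)/(mean(YFP)·mean(CFP)) carries reciprocal
intensity units and is acquisition-dependent; it is only compared within
an experiment. Because FRETN becomes nonlinear when donor or acceptor is
in large molar excess, ROIs with max(CFP,YFP)/min(CFP,YFP) > 3 are
flagged and excluded from group comparisons (Welch two-tailed t tests on
included ROIs). ROI selection is explicit (mask or box); no automated
structure detection is attempted.

## TIRF cluster analysis

Detection band-passes each frame with a difference of Gaussians (fine
sigma = expected spot sigma, coarse = 2×), takes local maxima above a
threshold (the `auto` threshold is median + 5 robust MAD-sigmas of the
filtered frame), prunes them greedily so no two accepted spots are
closer than `min_separation` pixels (brighter wins; row-major order
breaks exact ties, making detection deterministic), and refines
positions by intensity-weighted centroid in a (2·min_separation+1)²
window of the non-negative band-pass image.

Linking is per-frame-pair optimal bipartite assignment (Hungarian
algorithm) minimising total squared displacement, with a hard gate
`max_displacement` and bridging of up to `max_gap` missing frames
(default 1, for blinking robustness at 1–2 min frame intervals). This is
a reimplementation in spirit of commercial "Brownian motion" trackers,
not a clone; absolute parity with any particular software is not
claimed. Persistence is operationalised purely by track duration
(e.g. ≥ 1 h); a displacement-based immobility gate exists but is off by
default. Kymographs sample bilinear intensity profiles along a line,
max-projected across a perpendicular width, one column per frame.

## Saturation binding

Specific binding = total − nonspecific (replicate-matched wells;
negative values retained to keep the estimator unbiased). The one-site
hyperbola B(c) = Bmax·c/(K_D + c) is fitted by unweighted nonlinear
least squares (trust-region, parameter/function tolerances 1e-10,
non-negativity bounds), initialised at Bmax₀ = max specific count and
K_D₀ = concentration nearest Bmax₀/2. Standard errors come from the
Jacobian-based covariance. A Poisson-variance weighting option exists;
unweighted is the default because standard desktop packages fit this
model unweighted. Each replicate experiment is fitted separately;
condition comparisons report percent change in mean Bmax (and K_D) with
paired two-tailed t tests across positionally paired replicates. The
default concentration ladder is 4.12, 7.25, 13.5, 26, 51, 101 nM.

## Synthetic-data generators

Each generator draws from a single explicitly seeded NumPy Generator (no
global state; identical seeds give bit-identical outputs) and returns a
truth object alongside the data. With noise disabled the outputs are
exact deterministic functions of the parameters.

Optics are simple by design: structures are laid down as exact intensity
budgets (blob voxel sums are normalised, so placed intensity is
conserved to machine precision before noise), blurred with an isotropic
Gaussian PSF (separate axial sigma configurable), scaled, Poisson
sampled, and given additive Gaussian read noise (default sd 2 counts).
This suffices to validate threshold/overlap/tracking/fitting logic;
vectorial PSFs, evanescent-field depth profiles, photobleaching and
cell-shape realism are not modelled, so passing tests demonstrate
correctness of the quantification arithmetic and estimators, not
robustness to every optical artefact of real acquisitions.

Generator specifics and default choices:

* **Cell stacks** (endocytosis): a 20×96×96 ellipsoidal-shell membrane
  carries (1−f) of a 1.5×10⁶-count label budget in Cy5; f goes into
  Gaussian endosome puncta (sigma 1.5 voxels, within the 1–2 voxel range
  typical of diffraction-limited endosomes) placed with a Euclidean
  clearance from the membrane (default 2.5·(psf_sigma+endosome_sigma))
  — endosomes are cytoplasmic, and the clearance keeps blurred skirts
  out of the surface mask so ground truth stays well defined. A
  configurable `surface_coplacement` fraction of the internal budget is
  co-placed on membrane voxels to emulate incomplete surface-epitope
  occupancy (the confound mask 3 corrects). The budget gives per-voxel
  membrane intensities of order 10² counts, i.e. realistic confocal
  SNR.
* **Colocalization stacks**: 20 equal-intensity puncta per channel;
  `round(overlap·n)` YFP puncta share TxR centres, the rest are kept ≥ 6
  blur widths from every other punctum. Equal punctum intensities make
  the intensity-weighted true fraction equal the punctum fraction, which
  is recorded in the truth (the realized, rounded value).
* **FRET triplets**: donor/acceptor channels are smooth multiplicative
  textures (lognormal, sd 0.15, smoothed) at level 400 counts over an
  elliptical cell; the FRET channel obeys the linear bleed-through law
  exactly before noise. Controls are generated under the same law with
  one fluorophore absent.
* **TIRF movies**: `round(p·n)` persistent spots appear within the first
  fifth of the movie and last to the end; the rest appear uniformly and
  live geometric lifetimes (memoryless stand-in; mean 3 frames) — the
  published observations state no lifetime distribution. Positions
  follow a bounded Gaussian random walk (0.2 px/frame). Default peak
  amplitude 400 over background 40 gives SNR ≈ 15–20; `min_spacing`
  optionally enforces initial separation for detection-fidelity
  studies.
* **Binding datasets**: expected totals Bmax·c/(K_D+c) + ns·c and paired
  nonspecific wells ns·c, with Poisson counting noise (default) or
  relative Gaussian noise of configurable CV.

## Validation scales

The test suite and `scripts/acceptance.py` use problem sizes chosen to
exercise each estimator meaningfully while keeping a full run fast on a
single CPU: 500 random ≤ 16×16×4 stacks against brute-force voxel
loops; 7 internalized fractions (0.1–0.7) noise-free; 4 overlap levels ×
20 seeds; 20 FRET seeds (96×96 fields, ~9×10³ control pixels per
coefficient); 50-spot detection frames and 3 × 10 sixty-frame movies of
100 spots for persistence; 200 three-replicate binding datasets plus
5-replicate paired comparisons at Bmax ratios 0.6/0.74/0.9. The full
pytest run takes well under a minute of compute per heavy module and the
acceptance script about 15 s.

## Known limitations

* Threshold choice on noisy images remains the analyst's responsibility;
  Otsu is a convenience, not a recommendation for dim extended
  structures.
* The FRET module estimates corrected/normalized FRET, not FRET
  efficiency; no spectral unmixing or acceptor photobleaching support.
* The tracker has no motion model beyond the displacement gate; dense
  fields with crossing trajectories will swap identities.
* Binding fits assume a single site and linear nonspecific binding; no
  competition or kinetic models.
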