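# traffiq

Quantification pipelines for fluorescence-microscopy studies of membrane
transporter trafficking, with a synthetic-data module that makes every
pipeline verifiable against known ground truth.

The package targets the standard imaging readouts used to characterise
drug-induced endocytosis and oligomerization of plasma-membrane
transporters (e.g. the dopamine transporter, DAT):

* **Antibody-uptake endocytosis ratio** (`traffiq.endocytosis`).
  Surface transporter is labelled with an epitope-tag antibody; the
  remaining surface pool is stained before permeabilization (Cy5) and the
  internalized pool after (Cy3). Four voxel masks are built from the
  background-subtracted 3D stack: mask 1 = Cy5-positive (surface),
  mask 2 = Cy3-positive (raw internal), mask 3 = mask 2 ∧ mask 1 (Cy3
  attributable to incompletely occupied surface epitopes), and
  mask 4 = mask 2 \ mask 3 (corrected internal). The endocytosis readout
  is the Cy3/Cy5 ratio Σ₄(I_Cy3)/Σ₁(I_Cy5); ratio time-courses are
  summarised by an OLS line with its R² linearity coefficient.
* **Endosomal colocalization** (`traffiq.colocalization`).
  Intensity-weighted, asymmetric (Manders-style) fraction of a protein's
  fluorescence residing in cargo-positive voxels:
  Σ_A(mask_A ∧ mask_B)/Σ_A(mask_A), plus total cargo uptake Σ_B(mask_B).
* **Sensitized-emission FRET** (`traffiq.fret`). Three-cube acquisition
  (CFP, YFP, FRET channels); bleed-through coefficients *a*, *b* are
  estimated from single-fluorophore controls and corrected FRET is
  FRETᶜ = I_FRET − a·I_CFP − b·I_YFP per pixel. Region-level normalized
  FRET, FRETN = mean(FRETᶜ)/(mean(YFP)·mean(CFP)), is reported with a
  donor:acceptor stoichiometry gate (regions with >3-fold excess of
  either fluorophore are excluded from comparisons).
* **TIRF nanocluster analysis** (`traffiq.tirf`). Diffraction-limited
  spots are detected per frame as band-pass (difference-of-Gaussians)
  local maxima with sub-pixel centroids, counted (percent of the movie's
  maximum), linked into tracks by optimal bipartite assignment with a
  displacement gate and gap bridging, and classified as persistent by
  track duration. Kymographs (distance × time) support visual review.
* **Saturation radioligand binding** (`traffiq.binding`). Specific
  binding (total − nonspecific wells) is fitted per replicate with the
  one-site hyperbola B(c) = Bmax·c/(K_D + c); conditions are compared by
  percent change in Bmax and K_D with paired two-tailed t tests.

`traffiq.simulate` generates ground-truth-annotated inputs for all five
assays (membrane/endosome confocal stacks, controlled-overlap puncta,
FRET triplets with linear bleed-through, TIRF movies with persistent and
transient spots, binding count tables), which is how the test suite and
the acceptance script validate the quantification code without any
experimental data.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
$ python examples/endocytosis_ratio.py
surface (mask1) integrated Cy5 : 1046072 a.l.u.f.i.
internal (mask4) integrated Cy3: 443451 a.l.u.f.i.
Cy3/Cy5 ratio (mask4/mask1)    : 0.424
uncorrected ratio (mask2/mask1): 0.504
expected f/(1-f) for f=0.30    : 0.429
```

The simulated cell has 30% of its label internalized and, additionally,
30% of the internalized-channel label sitting on the plasma membrane
(unoccupied surface epitopes stained post-permeabilization). The naive
mask 2/mask 1 ratio over-reports endocytosis (0.504); subtracting mask 3
recovers the true internalized/surface partition f/(1−f) = 0.429 to
within ~1%. Intensities are in arbitrary linear units of fluorescence
intensity (a.l.u.f.i.).

```bash
$ python examples/binding_saturation_fit.py
vehicle rep 1: K_D = 14.29 +- 0.58 nM, Bmax = 982 +- 13
Bmax change : -24.9%  (p = 1.51e-04)
K_D change  : +2.3%  (p = 0.68)
```

Five paired replicate experiments were simulated with a true 26% Bmax
reduction and unchanged K_D in the second condition; the comparison
recovers a significant Bmax decrease with no significant K_D shift — the
signature of fewer binding sites rather than altered affinity.

A thin CLI mirrors the library (`traffiq simulate ...`,
`traffiq endocytosis`, `traffiq coloc`, `traffiq fret`, `traffiq tirf`,
`traffiq binding`); run `traffiq --help` for details.

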