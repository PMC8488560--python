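# Methods

`cryodiff` implements a density-attribution workflow for intermediate-
resolution cryo-EM: deciding, with per-voxel statistics, where a bound
ligand adds density to a macromolecular assembly, scoring rigid-body
placements of an atomic model into that density, and dissecting the
resulting protein–protein interface by computational alanine scanning.
This note records the models, the parameter choices, and what the
synthetic benchmarks do and do not demonstrate.

## Voxel-wise difference significance

### Model

Two conditions (e.g. a clathrin assembly with and without an adaptor
fragment) are each represented by an ensemble of *n* independent
reconstructions of the same structure — in practice, maps computed from
disjoint particle subsets.  Treating the n_A and n_B member values at
each voxel as independent samples, the difference between condition
means is tested with the classical pooled two-sample Student's t:

    t = (mean_A − mean_B) / sqrt( s_p^2 (1/n_A + 1/n_B) ),
    s_p^2 = ((n_A−1) s_A^2 + (n_B−1) s_B^2) / (n_A + n_B − 2),

with df = n_A + n_B − 2 and two-tailed probabilities by default (the
direction of a density change is not assumed).  A Welch unequal-variance
option exists but is off by default: with n of 3–4 per condition the
pooled form is the conventional choice for map comparison, and the
pooled df is the natural reading of "appropriate degrees of freedom"
for this design.  Voxels whose pooled variance falls below
`variance_floor` (default 1e-9) times the box-average pooled variance —
flat solvent or padding — are labelled *undetermined* and excluded
rather than being assigned t = ∞.

Probabilities are reported raw, per voxel, with no multiple-testing
correction; instead the run report states the expected number of
false-positive voxels in the weakest band under the null
(threshold × defined voxels).  Voxels are classified into ordered bands
by strictly decreasing p cutoffs, default (0.05, 0.0005, 0.0001); band k
means p < cutoff_k, so band 3 ⊆ band 2 ⊆ band 1.  The most stringent
band is the one read as direct ligand density; intermediate bands
typically mix ligand density with induced conformational differences.

### Amplitude matching and filtering

Independent reconstructions differ in overall amplitude falloff (defocus
sampling, weighting, effective B factor).  Left uncorrected, such global
differences masquerade as local density differences.  The pipeline
therefore:

1. computes the radial amplitude profile (mean Fourier modulus per
   integer-radius shell) of the **unfiltered** mean of the reference
   condition,
2. rescales every member of the other condition so its per-shell
   amplitudes match that profile (phases untouched; one profile per
   condition, applied identically to all members, so member-to-member
   variance within the condition is preserved up to a common radial
   factor),
3. low-pass filters all members, default cutoff 11 Å for whole
   assemblies and 12 Å for extracted sub-volumes, with a raised-cosine
   edge 3 shells wide.

Shells where the target amplitude is below 1e-12 × DC are passed through
unscaled (empty shells would otherwise blow up the ratio); their indices
are recorded.  Fourier-space corners beyond Nyquist reuse the
Nyquist-shell factor.

Numerical convention: the low-pass multiplier is constant within each
integer-rounded Fourier shell — the same shell indexing the profile
uses.  This makes "apply fixed shell factors" and "low-pass filter"
exactly commuting operations, so the scale-then-filter order is a
reproducibility convention rather than a numerical one.  Note the full
`scale_to_reference` operation re-estimates its target profile from its
input, so re-estimating *after* filtering would instead re-amplify the
filter's transition shells; the pipeline always estimates profiles on
unfiltered means for this reason.

### Masks and FSC

Soft masks follow the common refinement-mask recipe: binarize at
mean + kσ (default k = 3, with σ computed over the whole box), dilate by
`extend_px` voxels, and roll off cosine-smoothly from 1 to 0 over
`soften_px` voxels of Euclidean distance from the binary edge.  Fourier
shell correlation between two maps uses the same integer shells; the
resolution is reported at the first crossing below 0.143 (linearly
interpolated between shells), the standard criterion for independent
half-set comparisons.

## Rigid-body fit scoring

An atomic model placed in density is scored two ways:

* **fraction inside** — the fraction of atoms whose trilinearly
  interpolated map value is at or above the display contour
  (mean + 3σ).  Atoms outside the box count as outside, keeping poses
  near the edge comparable.
* **correlation of fit** — the about-mean Pearson correlation between a
  simulated model density and the experimental map over the map's 3σ
  region (or a supplied mask).  Simulated density is a sum of per-atom
  isotropic Gaussians with FWHM equal to the nominal resolution and peak
  amplitude proportional to atomic number; the region and normalization
  of this score are documented choices, since fitting programs differ
  here.

The local search is a deterministic exhaustive grid about the ligand
centroid: rotations as intrinsic x-y-z Euler angles over ±10° in 2°
steps and translations over ±10 Å in 1 Å steps by default, each axis
range independently adjustable so reduced subsets can be run.  Every
pose gets both scores.  Poses are merged into clusters when they lie
within one grid step per degree of freedom of a cluster exemplar
(exemplars taken in descending occupancy order), and each cluster's
hit rate is its member count divided by all evaluated poses.  The best
fit maximizes fraction inside, with ties broken by correlation and then
by lexicographic pose ordering, so selection is independent of
evaluation order.  A stochastic global optimizer could cover the same
space faster but would not be reproducible pose-for-pose; at these
search radii the exhaustive grid is affordable and testable.

The full 6-D default grid is ~12 million poses; tests and the
acceptance script search reduced axis subsets (a few thousand poses,
seconds to half a minute) which suffice to localize single-basin
planted offsets.

## Interface energetics

The alanine scan follows single-point, server-style practice: for each
residue on the chosen side of a fixed receptor/ligand partition, delete
side-chain atoms beyond Cβ (backbone and Cβ keep their coordinates, no
re-minimization) and record

    ΔΔG = E_interface(truncated) − E_interface(wild type)   [kJ/mol],

positive when the residue stabilizes the interface.  Gly and Ala give 0
by construction; Pro is scanned by the same rule with a warning; a
non-Gly residue without a Cβ is skipped with a warning.  A constellation
scan truncates a residue group simultaneously; its cooperativity is the
group ΔΔG minus the sum of the members' individual ΔΔGs, exactly, by
construction.  Hot spots are residues with ΔΔG at or above 5 kJ/mol;
constellation candidates are residues with ΔΔG strictly above 3 kJ/mol.
Salt bridges are cross-interface pairs of basic side-chain nitrogens
(Lys NZ; Arg NE/NH1/NH2) and acidic side-chain oxygens (Asp OD1/OD2;
Glu OE1/OE2) with minimum atom distance ≤ 4.0 Å.

The energy function is an explicitly generic stand-in: screened Coulomb
with distance-dependent dielectric ε(r) = 4r (i.e. a 1/r² energy),
Coulomb constant 1389.35 kJ mol⁻¹ Å e⁻², a 12-6 steric term with
well depth 0.4 kJ/mol and r₀ the sum of van der Waals radii, and an 8 Å
receptor–ligand pair cutoff.  Charges are coarse formal side-chain
charges; radii per element.  Because this model is strictly pairwise
additive across the interface, a constellation confined to one side has
cooperativity ≈ 0 (to rounding): nonzero cooperativity requires
many-body energy terms, as in the empirical forcefields behind published
scans.  The machinery — truncation rule, thresholds, cooperativity
arithmetic — is the deliverable; the ΔΔG magnitudes are not comparable
to forcefield values.

## Synthetic data

`make_ensemble` emulates a reconstruction ensemble as ground truth plus
i.i.d. real-space white Gaussian noise per member, by default a 48³ box
at 2.0 Å/voxel, n = 4 members, noise σ = 1.  The ground truth is a
"cage fragment" of pseudo-atom Gaussians: three legs radiating from a
central vertex with compact tip domains, peak amplitude 10 (i.e. 10× the
noise σ), occupying a realistic fraction of the box so that global
amplitude distortions have structure to act on.  Options plant a
compact Gaussian "ligand" blob (σ = 4 Å; the mask marks voxels above
half its maximum), apply a B-factor-like attenuation exp(−B s²/4) to
each member, or color the noise by low-pass filtering (robustness
experiments only).  `make_toy_complex` builds two facing strands with
charged termini reaching into an ~3 Å interface gap, clash-checked,
emitting a known contact list.

White noise is a deliberate idealization: it makes the per-voxel null
exactly Student-t and the calibration experiments clean.  Real
reconstruction noise is colored and spatially correlated, and real
condition pairs differ by conformational heterogeneity as well as
ligand density, so passing the synthetic benchmarks demonstrates the
statistical machinery is correct and calibrated — not that any given
experimental band-k region is ligand.  Independence of members and the
absence of registration error are assumed, not checked.

## Benchmark conditions (as run by `scripts/acceptance.py`)

* Null calibration: two 48³, n = 4 ensembles sharing the ground truth;
  the band-1 (p < 0.05) fraction sits near 0.05 and the raw per-voxel t
  values match Student t (df 6) closely in Kolmogorov–Smirnov distance
  over ~1.1 × 10⁵ voxels.
* Amplitude-distortion robustness: B = 100 Å² applied to one condition
  inflates the band-1 fraction to ~0.08 with scaling disabled and
  returns it to within 0.01 of nominal with scaling enabled — the
  purpose of reciprocal-space profile matching.
* Planted-ligand recovery: blob peak set to 5× the noise SD of the
  4-member condition mean (amplitude 2.5σ); ≥ 80% of mask voxels reach
  band 2 and the band-3 false-positive fraction outside stays ≤ 10⁻³.
* Fit recovery: a (4°, 2 Å) planted offset of the toy ligand in its own
  simulated density is recovered to within one grid step on a reduced
  axis subset of the default search ranges.
* Constellation arithmetic: the published clathrin/β2-appendage
  constellation table is reproduced exactly on every self-consistent
  row (9 of 11; two rows print cooperativities 0.1 kJ/mol off their own
  columns, evidently rounded from unrounded inputs upstream).

## Not reproducible at desk scale

The quantities below depend on the original micrograph-scale data
(tens of thousands of particles from public archives), on full
reconstruction pipelines, or on a proprietary empirical forcefield, and
are explicitly **not** targets of this package's benchmarks:

* the published map resolutions (9.1, 9.6, 10.5, 10.1 and 19.8 Å) and
  the particle counts behind them (57,528; 16,641; 13,983; 26,624);
* the 34% top-cluster hit-rate of the appendage fit into the real hub
  map (the synthetic analogue reports its own hit rate on a toy
  single-basin problem);
* published per-residue ΔΔG magnitudes, which come from an empirical
  forcefield; only the scan machinery, thresholds, and the constellation
  cooperativity arithmetic are reproduced here.

## Known limitations

* Radial operations (profiles, scaling, FSC, low-pass) require cubic
  grids; anisotropic voxels are rejected, never resampled.
* Inputs are assumed on a common grid; no alignment or registration.
* No CTF handling, sharpening, or symmetry operations.
* The correlation score re-simulates density per pose; the exhaustive
  search is meant for local refinement, not global 6-D docking.
* Charged-residue parameters are formal and coarse; no protonation
  states, no solvation.
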