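# Methods

This note documents the models, estimators, defaults and numerical
choices behind each module, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Coordinate and unit conventions

Arrays are `(z, y, x)`; voxel dimensions are `(dz, dy, dx)` in
nanometres, default 125 × 39.5 × 39.5 nm (the native anisotropy of the
reconstructed super-resolution stacks this pipeline targets). Physical
positions are `index × voxel_dim` at voxel centres, 0-based. All
distance computations (shells, contact, cluster profiling) use
anisotropic physical sampling; connectivity is 26-neighbourhood
throughout. Gene models follow the GTF convention (1-based inclusive);
internal interval arithmetic is 0-based half-open.

## Equal-variance intensity classes

**Model.** The DNA counterstain intensity sample of a region is
partitioned into `k = 7` contiguous classes whose within-class variance
is equal. The partition adapts to each region's intensity distribution,
making it threshold-free and invariant under affine intensity rescaling
(`a·I + b`, `a > 0`, maps boundaries to `a·b_i + b` with identical
labels).

**Estimator.** Within-class variance is defined on the *linearly
interpolated* empirical distribution: the empirical CDF is interpolated
between adjacent distinct values, giving a piecewise-uniform density
(an atom of mass `n_min/n` sits at the minimum). On point masses alone,
exact equalisation is impossible for heavy-tailed samples — the
equalising partition can leave only tens of voxels in the top class,
where moving a single point jumps its variance by ~10–20% — while on
the interpolated law interval variance is continuous in the borders and
equalisation is exact. Fitted borders always lie strictly between
adjacent distinct values, so the voxel assignment is the same as for
any other border in the same gap and tied intensities are never split.
The per-class variances reported in `ClassBoundaries.variances` are the
interpolated-law values the fit equalises; the atom-level variances of
the assigned voxels are kept in `diagnostics["sample_variances"]`.

**Algorithm.** Nested bisection: an outer bisection on the shared
target variance `v` (bracketed by `[0, Var(all)]`), and per candidate
`v` a left-to-right sweep closing each class at the border where its
variance reaches `v` (each border solved by an inner bisection; interval
moments are O(log m) from prefix sums over distinct values). The
leftover top-class variance decreases in `v`, so the equalising `v` is
found by sign bisection. Where a border responds discontinuously to `v`
(sparse upper tails make interval variance non-monotone in the lower
border), a Gauss–Seidel polish re-solves each border so adjacent class
variances agree, iterated to convergence. The procedure is
deterministic with no dependence on initialisation. Defaults:
`tol = 1e-3` on the coefficient of variation of the per-class
variances (typical converged CV is ~1e-9), `max_iter = 10 000`.
Degenerate inputs: fewer than `k` distinct values is an error; exactly
`k` distinct values forces the partition with borders at midpoints
between adjacent values (e.g. a two-point sample `{0, 1}` at `k = 2`
yields the border 0.5).

**Labelling.** Class `i` is `[b_{i-1}, b_i)`, the top class closed
above. Out-of-range intensities are clamped into the end classes by
default; a strict mode raises instead.

## Marker enrichment

Counts per class: `D_c` region voxels and `M_c` marker voxels, giving
expected/observed fractions `e_c = D_c/ΣD`, `o_c = M_c/ΣM` and relative
enrichment `r_c = o_c/e_c − 1`. Classes with `D_c = 0` are dropped with
a warning and reduce the degrees of freedom.

* **Goodness of fit.** Pearson `Σ (M_c − N e_c)²/(N e_c)` with
  `df = #classes − 1`, upper-tail chi-square p. Expected counts below 5
  set a `small_expected` flag pointing to an exact multinomial reading.
* **Pairwise class contrasts.** Densities `M_a/D_a` vs pooled
  `ΣM_b/ΣD_b` as a 2×2 table — Fisher's exact test when any cell is
  below 25, chi-square with continuity correction otherwise; two-sided.
* p-values that underflow double precision are reported as `<1e-300`
  with the statistic retained.

Marker positivity (`marker_mask`) defaults to Otsu within the region,
with a fixed-threshold option for reproducibility. On simulated
mitoses, enrichment statistics are computed from marker *event* counts
at the image-fitted class labels (the generator's placed events,
classified through the fitted class map): this mirrors "positive pixels
per class" under perfect detection and keeps the statistical question —
is placement proportional to class size? — separate from spot-detection
efficiency, which blurred overlapping puncta would otherwise fold in.

Calibration and recovery, both checked in the test suite and the
acceptance script: under proportional placement the goodness-of-fit
p-values are uniform (type-I error 0.05 ± 0.01 over 2000 simulated
stacks), and generator class weights are recovered as density ratios
within 5% at 10⁶ events.

## Segmentation and volumes

Segmentation: Gaussian smoothing (σ = 1 lateral voxel, scaled down
axially by the anisotropy so the physical kernel is isotropic), Otsu
threshold, morphological closing (ellipsoidal element, 2 lateral
voxels), 3-D hole fill, largest 26-connected component. Hole filling is
load-bearing: the DNA-free lacuna of pre-MGA nuclei must lie inside the
mask. Volume is `foreground voxels × dz·dy·dx`, reported in µm³.
Accuracy on rendered analytic ellipsoids at the native voxel size is
~0.3% (well under the 3%/5% noise-free/noisy bounds the tests assert);
the dominant error term is the half-voxel edge bias of thresholding,
which Otsu keeps near zero for bimodal channels.

Two caveats. DAPI-based segmentation of the *pre-MGA phenotype*
measures the chromatin hull, which stops ~0.6 µm short of the envelope
outside contact regions; envelope-referenced analyses therefore segment
the lamin B channel instead (below). And Otsu assumes a usable bimodal
histogram — strongly zero-inflated scenes with wide foreground spread
can mis-threshold.

Stage comparisons: two-sided Welch unequal-variance t tests per
requested pair, Bonferroni-multiplied over the requested family and
capped at 1. Identical constant groups return p = 1 by convention.

## Envelope topology

The envelope is segmented from the lamin B channel (the contiguous
border marker); the **shell** is every voxel within `t = 200 nm`
(physical) of the mask's interior boundary skin, computed by EDT from
that skin — the least-biased discrete band (+3% vs the analytic band
volume of a sphere, against −14%/+16% for mask-EDT variants). Per shell
voxel: `chromatin_contact` if a DNA-positive voxel lies within
`d_c = 200 nm`, `npc_present` if a pore-positive voxel lies within
`r_n = 150 nm` (of the order of the NPC outer diameter).

Positivity thresholds in this module default to a robust background
rule — median + 6σ with σ from the upper quartile distance
`(Q75 − median)/0.6745` — because Otsu fails on sparse punctate
channels (pore puncta occupy <1% of voxels) and the quartile scale
survives zero-inflated backgrounds where the MAD collapses. It assumes
signal occupies under a quarter of the voxels, and degrades to
"anything above zero" on noise-free renders. Otsu and fixed thresholds
remain available per config.

**Concordance** is the 2×2 contact × pore table over shell voxels, with
a two-sided Fisher p and an odds ratio (Haldane +0.5 when a single cell
is zero). If either contact category holds under 1% of shell voxels the
result is flagged degenerate (odds ratio undefined, p = 1, fractions
still reported): a fully contacted envelope leaves only a sub-percent
discretisation rim at the poles, and testing association on that rim
would manufacture spurious significance. Surface elements are shell
voxels, not mesh faces — simpler and resolution-dependent, recorded in
the output metadata.

**Structures**: 26-connected components of (lamin-positive ∪
pore-positive) voxels outside the shell band, minimum 5 voxels,
classified by topology — inside the nucleus and touching the shell →
invagination; inside and detached → interior vesicle; outside and
touching → extrusion; outside and detached → extranuclear segment.
Immunophenotype per channel: positive when ≥ 25% of the component's
voxels exceed the channel threshold. The census tallies counts per
(group × location × phenotype), per-nucleus means ± SEM, and
invagination percentages over the three immunophenotypes (summing to
100). **Clusters**: pore-positive components outside the nucleus and
beyond a 0.15 µm exclusion band (which removes blur spill-over from
envelope pores); a scene is `envelope_proximal` when the median
centroid-to-envelope distance is ≤ 0.5 µm, else `dispersed`.

## RINP

Introns are the maximal gene-span intervals not covered by any exon. A
read counts as intronic when ≥ 1 aligned base (match blocks only — skip
segments never cover positions) falls in an intron; a majority-overlap
rule is available behind a flag. Secondary, supplementary, duplicate
and unmapped records are excluded; strand is ignored. Covered intronic
positions are intron bases under ≥ 1 aligned base;
`RINP = reads/(uncovered + ε)` with `ε = 1` guarding full coverage, and
exactly 0 when there are no intronic reads. Gene sets pool by summing
numerators and uncovered denominators within a replicate (one shared
pseudocount), then stage values average the replicate RINPs.

## Synthetic data

One master seed per scene spawns per-component substreams in a fixed
documented order (nucleus: chromatin, npc, invaginations, vesicles,
clusters, noise; mitosis: chromatin, marker, noise; reads: assignment,
starts), so identical parameters and seed give bit-identical output and
adding one component never perturbs another.

**Nucleus scenes.** An ellipsoidal nucleus (default spherical, 2 µm
semi-axes — compact but resolvable at reasonable grid sizes; real
embryonic nuclei are larger, and size-sensitive checks use larger
phantoms) inside a ≥ 2 µm cytoplasm margin. Chromatin texture is a
thresholded/modulating smoothed Gaussian random field (300 nm
correlation length) at moderate contrast, keeping the DNA channel
bimodal against background; the envelope-flush rim is rendered denser
and more uniform (the lamina-associated chromatin layer), because a
patchy rim would defeat hole filling. Pre-MGA: chromatin occupies the
space between the lacuna (default 35% of the radius) and the envelope
but touches it only over a polar cap holding `contact_fraction` of the
surface area, with a 0.6 µm chromatin-free gap elsewhere. Post-MGA: a
~0.3 µm rim lines the whole envelope over a clumpy interior network.
The lamina is a uniform ~200 nm band on the envelope's interior side
(thick enough to stay contiguous under anisotropic blur). NPC puncta
are single-voxel deposits on the surface at 10/µm² of (contacted)
area, sampled uniformly on the cap (conditional mode) or the whole
surface. Invaginations are 150 nm-radius capsules along inward normals,
rendered into the channels their immunophenotype dictates; vesicles are
lamin-positive balls at 25–45% radius; extranuclear clusters are
pore-marker balls at 0.9–1.8 µm (dispersed) or 0.25–0.45 µm
(envelope-proximal) from the surface. Placed structures keep a minimum
angular separation (0.45 rad) so detected components do not merge.
Optics: anisotropic Gaussian PSF (FWHM 130 nm lateral / 300 nm axial,
rounded from the instrument class's ~120/~300 nm for stable kernels),
then Poisson noise on the signal and additive Gaussian read noise
(sd 2), the standard fluorescence model.

**Mitotic scenes.** A rosette of Gaussian chromatid cores on a ring,
multiplied by a radial falloff and a texture field, over a faint
cytoplasmic background — a continuous intensity law whose seven-class
partition has a large class 1 (background/cytoplasm) and progressively
smaller dense classes, as in real plates. The truth class map is the
equal-variance partition of the noise-free channel (deterministic);
marker events are then multinomial over classes with probability
∝ `weights[c] × D_c` — unit weights are exactly the proportional null.
Default grid 40 × 160 × 160 (≈10⁶ voxels) at native voxel size; the
calibration runs use 16 × 48 × 48 stacks so 2000 replicates stay cheap.

**Reads.** Per read: a uniform gene, then unspliced (uniform start on
the genomic span, one match block) with probability `u`, else spliced
(uniform start on the concatenated exons, mapped back with skip
segments). Spliced reads can never touch an intron, so `u = 0` forces
RINP = 0 exactly. Default read length 80 bases, matching the targeted
library design. Written as coordinate-sorted SAM with one `@SQ` line
per reference; no sequencing-error model.

**What the generators do not emulate** — and hence what green tests do
not establish about real data: structured-illumination reconstruction
artefacts, depth-dependent aberrations and channel misregistration;
chromatin texture fitted to real nuclei (the texture and punctum
intensities are free parameters, stated above, not estimates);
crowding, multiple nuclei per field, or mitotic stages other than an
idealised plate; library biases, mapping errors or intron-mappability
structure in the reads. Results on synthetic scenes demonstrate the
estimators' correctness and calibration under the stated model, not
instrument-level robustness.

## Problem sizes used in tests and the acceptance script

Equal-variance checks use 10⁶-sample draws; null calibration uses 2000
small (16 × 48 × 48) optics-free stacks at 3000 events; weight recovery
uses 10⁶ events on the default 10⁶-voxel grid; significance bounds use
10⁵ events with full optics; volume accuracy uses two analytic
ellipsoids at native voxel size; concordance uses 20 pre- and 20
post-activation scenes at default geometry; RINP uses 3 toy genes with
2 kb introns, 800 reads, 10 seeds per point of the u grid. These sizes
are the package's chosen study conditions and are printed alongside
each value in `results/acceptance.json`.

## Known limitations

* Voxel counts are treated as independent in all tests; spatial
  autocorrelation from the PSF inflates effective sample sizes, so
  p-values on real (or blurred synthetic) images are anti-conservative.
  The calibration result holds at the event level.
* The equal-variance partition is fitted per region; no cross-nucleus
  boundary sharing is provided.
* Structure immunophenotyping uses fixed fractions/thresholds where the
  original assessments were visual; the 69/18/13 percentage partition
  is reproduced from a fixture with those counts, not re-derived from
  images.
* Concordance odds ratios are resolution-dependent (shell voxels as
  surface elements); compare only across scenes with identical voxel
  geometry and shell thickness.
* `RINP`'s denominator pseudocount (ε = 1) matters only near full
  intron coverage; values there saturate toward the raw read count.
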