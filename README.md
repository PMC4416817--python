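# nuquant

Quantitative 3-D nuclear architecture analysis for preimplantation
embryos, built around super-resolution (3D-SIM-like) image stacks of
DAPI-stained DNA, lamin B and the nucleoporin NUP153, plus RNA-seq
alignments for nascent-transcription detection.

Bovine embryos rewire their nuclei around major embryonic genome
activation (MGA, 8-cell stage): before MGA, chromatin touches the
nuclear envelope only in patches, nuclear pore complexes (NPCs) are
confined to exactly those contact patches, the nuclear interior holds a
large DNA-free lacuna, and NUP153-positive clusters drift through the
cytoplasm; after MGA, a thin chromatin rim lines the whole envelope and
pores cover it uniformly while nuclear volumes fall stage by stage. This
package implements the measurements behind that picture, exercisable end
to end on ground-truthed synthetic data:

* **Seven equal-variance DNA intensity classes** — a
  threshold-independent voxel partition of the DAPI channel into ``k``
  contiguous classes with identical within-class intensity variance
  (class 1 ≈ background/cytoplasm, class 7 = densest chromatin).
  Boundaries ``b_0 < … < b_7`` are fitted by bisection on the shared
  target variance ``v`` with ``Var(I | b_{c-1} ≤ I < b_c) = v`` for all
  ``c``.
* **Marker enrichment statistics** — per class ``c``, expected fraction
  ``e_c = D_c/ΣD`` (DNA voxels), observed fraction ``o_c = M_c/ΣM``
  (marker voxels), relative enrichment ``r_c = o_c/e_c − 1``; the
  proportional-placement null ``o_c = e_c`` is tested with a Pearson
  goodness-of-fit statistic (df = 6), class contrasts with Fisher /
  chi-square 2×2 tests on densities ``M_c/D_c``.
* **Nuclear volumes** — smoothed-Otsu segmentation with 3-D hole fill
  (the pre-MGA lacuna counts as nuclear volume), voxel-count volumes at
  the native anisotropic voxel size (39.5 × 39.5 × 125 nm), Welch tests
  with Bonferroni adjustment between stages.
* **Envelope topology** — lamina shell extraction, a 2×2
  chromatin-contact × pore-presence concordance (odds ratio + Fisher p)
  over shell voxels, detection and immunophenotyping
  (NUP+/LamB+, NUP−/LamB+, NUP+/LamB−) of invaginations, interior
  vesicles, extrusions and extranuclear segments, and distance-based
  profiling of cytoplasmic NUP153 clusters.
* **RINP** — reads in intronic regions vs not-covered intronic
  positions, ``RINP = n_intronic_reads / (uncovered_intronic_positions
  + ε)``, a proxy for unspliced nascent transcripts, computed per gene
  from SAM/GTF, pooled over gene sets and averaged over replicates per
  stage.

The synthetic-data module (`nuquant.simulate`) renders both nuclear
phenotypes, mitotic plates with controlled per-class marker placement,
and spliced/unspliced read alignments, each with an exact ground-truth
record — so calibration, parameter recovery and structure detection are
all verifiable without the original microscopy data.

## Layout

```
src/nuquant/        library: simulate, segmentation, intensity,
                    enrichment, topology, rinp, pipeline, cli
analysis/           numbered drivers reproducing the study's analyses
                    over synthetic data; write tables into results/
scripts/acceptance.py   recomputes the headline quantities (below)
```

A `nuquant` CLI wraps the library (`nuquant simulate nucleus`,
`nuquant measure`, `nuquant classify`, `nuquant enrich`,
`nuquant topology`, `nuquant rinp`, `nuquant run --config cfg.yaml`).

## Worked example

```bash
python analysis/02_mitotic_enrichment.py
```

simulates a metaphase plate (10⁶ voxels, 10⁵ marker events placed with
weights 1, 6, 6, 4, 3, 2.5, 2 across the seven classes), refits the
classes from the rendered image and prints:

```
relative enrichment by class (0 = proportional to class size):
  class 1: r = -0.28 -
  class 2: r = +2.90 +++++++++++
  class 3: r = +3.09 ++++++++++++
  class 4: r = +1.83 +++++++
  class 5: r = +1.16 ++++
  class 6: r = +0.84 +++
  class 7: r = +0.39 +

tests:
  marker fraction vs class-size fraction over all classes: p = <1e-300
  density class 7 vs classes [2, 3]: p = 6.58e-43
  density class 7 vs classes [1]: p = 2.26e-11
  density class 2 vs classes [1]: p = <1e-300
```

Read: the marker accumulates over chromatin (classes 2–7 enriched
relative to the class-1 cytoplasm), most strongly at the chromatid
periphery (classes 2–3), and is depleted in the densest chromatin core
(class 7) relative to that periphery while still exceeding the
cytoplasm — with the proportional null rejected outright.
`analysis/01_volumes_and_census.py`, `03_envelope_concordance.py` and
`04_rinp_stages.py` run the volume, topology and transcription analyses
the same way.

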