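"""Intron derivation, coverage counting and RINP aggregation."""

import numpy as np
import pysam
import pytest

from nuquant.errors import InputError, ParameterError
from nuquant.rinp import (
    CoverageCounts,
    GeneModel,
    aggregate_rinp,
    compute_rinp,
    derive_introns,
    intronic_coverage,
    read_gene_models_gtf,
    write_gene_models_gtf,
)
from nuquant.simulate import ReadSimParams, default_gene_models, gen_reads, write_sam


@pytest.mark.parametrize(
    "exons,expected",
    [
        ([(1, 200), (801, 1000)], [(201, 800)]),
        ([(1, 1000)], []),
        ([(1, 100), (301, 400), (801, 1000)], [(101, 300), (401, 800)]),
    ],
)
def test_derive_introns(exons, expected):
    m = GeneModel("G", "chr1", "+", 1, 1000, exons)
    assert derive_introns(m) == expected


def test_gene_model_validation():
    with pytest.raises(ParameterError):
        GeneModel("G", "chr1", "+", 1, 100, [(50, 150)])  # exon beyond span
    with pytest.raises(ParameterError):
        GeneModel("G", "chr1", "+", 1, 100, [(1, 50), (40, 80)])  # overlap


def _write_reads(path, reads, refs={"chrT": 2000}):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": r, "LN": l} for r, l in refs.items()]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, (start1, cigar) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.reference_name = list(refs)[0]
            a.reference_start = start1 - 1
            a.cigartuples = cigar
            a.flag = 0
            a.mapping_quality = 60
            a.query_sequence = "A" * sum(l for op, l in cigar if op in (0, 1, 4))
            out.write(a)


TOY = GeneModel("TOY", "chrT", "+", 1, 1000, [(1, 200), (801, 1000)])


def test_tiled_reads_interval_oracle(tmp_path):
    """5 x 50 b reads at starts 201..401: 5 reads, 250 covered, 350 not."""
    sam = tmp_path / "tiled.sam"
    _write_reads(sam, [(s, [(0, 50)]) for s in range(201, 402, 50)])
    c = intronic_coverage(sam, TOY)
    assert (c.intronic_reads, c.covered_intronic_positions, c.uncovered_intronic_positions) == (5, 250, 350)
    assert compute_rinp(c) == pytest.approx(5 / 351)


def test_skip_segment_covers_nothing(tmp_path):
    """A junction read skipping the whole intron is not intronic."""
    sam = tmp_path / "skip.sam"
    _write_reads(sam, [(161, [(0, 40), (3, 600), (0, 40)])])  # 161-200 ^ 801-840
    c = intronic_coverage(sam, TOY)
    assert c.intronic_reads == 0
    assert c.covered_intronic_positions == 0


def test_no_reads_toy_gene(tmp_path):
    sam = tmp_path / "none.sam"
    _write_reads(sam, [])
    c = intronic_coverage(sam, TOY)
    assert (c.intronic_reads, c.intronic_positions, c.covered_intronic_positions, c.uncovered_intronic_positions) == (0, 600, 0, 600)


def test_secondary_and_duplicate_reads_ignored(tmp_path):
    sam = tmp_path / "flags.sam"
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": 2000}]}
    with pysam.AlignmentFile(str(sam), "wh", header=header) as out:
        for flag in (0, 256, 1024):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"f{flag}"
            a.reference_name = "chrT"
            a.reference_start = 300
            a.cigartuples = [(0, 50)]
            a.flag = flag
            a.mapping_quality = 60
            a.query_sequence = "A" * 50
            out.write(a)
    c = intronic_coverage(sam, TOY)
    assert c.intronic_reads == 1


def test_reference_mismatch_raises(tmp_path):
    sam = tmp_path / "ref.sam"
    _write_reads(sam, [(10, [(0, 50)])])
    other = GeneModel("G", "chrZ", "+", 1, 500, [(1, 100)])
    with pytest.raises(InputError):
        intronic_coverage(sam, other)


@pytest.mark.parametrize(
    "reads,uncovered,eps,expected",
    [(5, 350, 1.0, 5 / 351), (0, 600, 1.0, 0.0), (100, 0, 1.0, 100.0)],
)
def test_compute_rinp_values(reads, uncovered, eps, expected):
    c = CoverageCounts("G", reads, uncovered + 100, 100)
    assert c.uncovered_intronic_positions == uncovered
    assert compute_rinp(c, eps) == pytest.approx(expected)


def test_aggregate_single_gene_equals_per_gene():
    c = CoverageCounts("G", 5, 600, 250)
    table = aggregate_rinp([("st", "rep1", c)])
    assert table.pooled["rinp"].iloc[0] == pytest.approx(compute_rinp(c))


def test_aggregate_pools_counts_not_ratios():
    """Two identical genes pool to 2r/(2u + eps), ~ the per-gene value."""
    c1 = CoverageCounts("G1", 50, 10_600, 600)
    c2 = CoverageCounts("G2", 50, 10_600, 600)
    table = aggregate_rinp([("st", "rep1", c1), ("st", "rep1", c2)])
    pooled = table.pooled["rinp"].iloc[0]
    assert pooled == pytest.approx(100 / (20_000 + 1))
    assert pooled == pytest.approx(compute_rinp(c1), rel=1e-3)


def test_stage_mean_over_replicates():
    recs = []
    for rep, (r, u) in enumerate([(10, 99), (20, 99), (30, 99)], 1):
        recs.append(("st", f"rep{rep}", CoverageCounts("G", r, 200, 200 - u)))
    table = aggregate_rinp(recs)
    assert table.stage_mean["mean_rinp"].iloc[0] == pytest.approx(np.mean([10 / 100, 20 / 100, 30 / 100]))


def test_gtf_roundtrip(tmp_path):
    models = default_gene_models(n_genes=3)
    gtf = tmp_path / "genes.gtf"
    write_gene_models_gtf(models, gtf)
    back = read_gene_models_gtf(gtf)
    assert [m.gene_id for m in back] == [m.gene_id for m in models]
    assert all(a.exons == b.exons for a, b in zip(back, models))


def test_rinp_zero_at_no_unspliced_reads(tmp_path):
    models = default_gene_models(n_genes=2)
    recs = gen_reads(ReadSimParams(gene_models=models, unspliced_fraction=0.0, n_reads=1000, seed=5))
    sam = tmp_path / "u0.sam"
    write_sam(recs, models, sam)
    for m in models:
        assert compute_rinp(intronic_coverage(sam, m)) == 0.0
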