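"""RINP: reads in intronic regions vs not-covered intronic positions.

Spliced (mature) mRNA contains no intronic sequence, so reads covering
introns indicate unspliced pre-mRNA and hence ongoing transcription. For
a gene with intron set I, a library is summarised by

    RINP = (# reads with >= 1 aligned base in I) / (# positions of I not
            covered by any aligned base + epsilon)

which grows both with the number of intronic reads and with how much of
the intron space they cover. The statistic is computed per gene and
replicate, pooled over gene sets by summing numerators and denominators,
and averaged over replicates per developmental stage. Aligned bases are
taken from the alignment's match segments only — skip (splice-junction)
segments never cover positions.

Coordinates: gene models follow the annotation convention (1-based,
inclusive); all internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .errors import InputError, ParameterError

__all__ = [
    "GeneModel",
    "CoverageCounts",
    "RinpTable",
    "derive_introns",
    "intronic_coverage",
    "compute_rinp",
    "aggregate_rinp",
    "read_gene_models_gtf",
    "write_gene_models_gtf",
]


@dataclass
class GeneModel:
    """A gene span with its exon structure (1-based inclusive intervals)."""

    gene_id: str
    ref: str
    strand: str
    start: int
    end: int
    exons: List[Tuple[int, int]]

    def __post_init__(self):
        if self.end < self.start:
            raise ParameterError(f"{self.gene_id}: empty gene span")
        ex = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in ex:
            if b < a:
                raise ParameterError(f"{self.gene_id}: empty exon ({a}, {b})")
            if a < self.start or b > self.end:
                raise ParameterError(f"{self.gene_id}: exon ({a}, {b}) outside span")
            if prev_end is not None and a <= prev_end:
                raise ParameterError(f"{self.gene_id}: overlapping exons")
            prev_end = b
        self.exons = ex

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    @property
    def spliced_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)


@dataclass
class CoverageCounts:
    """Intronic read and position tallies for one gene in one library."""

    gene_id: str
    intronic_reads: int
    intronic_positions: int
    covered_intronic_positions: int

    def __post_init__(self):
        if self.covered_intronic_positions > self.intronic_positions:
            raise InputError("covered positions exceed intron size")

    @property
    def uncovered_intronic_positions(self) -> int:
        return self.intronic_positions - self.covered_intronic_positions


def derive_introns(model: GeneModel) -> List[Tuple[int, int]]:
    """Maximal gene-span intervals not covered by any exon (1-based incl.)."""
    introns = []
    cursor = model.start
    for a, b in model.exons:
        if a > cursor:
            introns.append((cursor, a - 1))
        cursor = max(cursor, b + 1)
    if cursor <= model.end:
        introns.append((cursor, model.end))
    return introns


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate
    )


def intronic_coverage(
    alignments: str | Path | pysam.AlignmentFile,
    model: GeneModel,
    majority_rule: bool = False,
) -> CoverageCounts:
    """Count intronic reads and covered intronic positions for one gene.

    A read is intronic when at least one aligned base falls inside an
    intron (``majority_rule=True`` instead requires more than half of its
    aligned bases to be intronic). Secondary, supplementary, duplicate and
    unmapped records are ignored.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r")
        own = True
    try:
        if model.ref not in alignments.references:
            raise InputError(
                f"reference {model.ref!r} absent from alignment header "
                f"(has {list(alignments.references)})"
            )
        span0 = (model.start - 1, model.end)  # 0-based half-open
        length = span0[1] - span0[0]
        intron_mask = np.zeros(length, dtype=bool)
        for a, b in derive_introns(model):
            intron_mask[a - 1 - span0[0] : b - span0[0]] = True
        covered = np.zeros(length, dtype=bool)
        n_intronic = 0
        for read in alignments.fetch(until_eof=True):
            if not _usable(read) or read.reference_name != model.ref:
                continue
            intronic_bases = 0
            aligned_bases = 0
            for b0, b1 in read.get_blocks():  # aligned match blocks, skips excluded
                aligned_bases += b1 - b0
                lo, hi = max(b0, span0[0]), min(b1, span0[1])
                if lo >= hi:
                    continue
                seg = slice(lo - span0[0], hi - span0[0])
                intronic_bases += int(intron_mask[seg].sum())
                covered[seg] = True
            if majority_rule:
                if aligned_bases and intronic_bases * 2 > aligned_bases:
                    n_intronic += 1
            elif intronic_bases >= 1:
                n_intronic += 1
        n_intron_pos = int(intron_mask.sum())
        n_covered = int((covered & intron_mask).sum())
        return CoverageCounts(
            gene_id=model.gene_id,
            intronic_reads=n_intronic,
            intronic_positions=n_intron_pos,
            covered_intronic_positions=n_covered,
        )
    finally:
        if own:
            alignments.close()


def compute_rinp(counts: CoverageCounts, epsilon: float = 1.0) -> float:
    """RINP = intronic reads / (uncovered intronic positions + epsilon).

    ``epsilon`` (default 1) keeps the ratio finite when every intronic
    position is covered; a gene with no intronic reads scores exactly 0.
    """
    if counts.intronic_reads == 0:
        return 0.0
    return counts.intronic_reads / (counts.uncovered_intronic_positions + epsilon)


@dataclass
class RinpTable:
    """Per-gene, pooled-per-replicate and per-stage RINP summaries."""

    per_gene: pd.DataFrame  # stage, replicate, gene, reads, uncovered, rinp
    pooled: pd.DataFrame  # stage, replicate, reads, uncovered, rinp
    stage_mean: pd.DataFrame  # stage, mean_rinp, n_replicates
    epsilon: float = 1.0


def aggregate_rinp(
    records: Iterable[Tuple[str, str, CoverageCounts]],
    epsilon: float = 1.0,
    stage_order: Sequence[str] | None = None,
) -> RinpTable:
    """Aggregate ``(stage, replicate, CoverageCounts)`` records.

    Within each replicate the gene set is pooled by summing intronic reads
    and uncovered positions (a single shared pseudocount), then replicate
    RINP values are averaged per stage.
    """
    rows = []
    for stage, rep, c in records:
        rows.append(
            {
                "stage": stage,
                "replicate": rep,
                "gene": c.gene_id,
                "intronic_reads": c.intronic_reads,
                "uncovered": c.uncovered_intronic_positions,
                "rinp": compute_rinp(c, epsilon),
            }
        )
    if not rows:
        raise InputError("no coverage records to aggregate")
    per_gene = pd.DataFrame(rows)
    pooled = (
        per_gene.groupby(["stage", "replicate"], as_index=False)[["intronic_reads", "uncovered"]]
        .sum()
    )
    pooled["rinp"] = np.where(
        pooled["intronic_reads"] == 0,
        0.0,
        pooled["intronic_reads"] / (pooled["uncovered"] + epsilon),
    )
    stage_mean = pooled.groupby("stage", as_index=False).agg(
        mean_rinp=("rinp", "mean"), n_replicates=("rinp", "size")
    )
    if stage_order is not None:
        stage_mean["stage"] = pd.Categorical(stage_mean["stage"], categories=stage_order, ordered=True)
        stage_mean = stage_mean.sort_values("stage").reset_index(drop=True)
    return RinpTable(per_gene=per_gene, pooled=pooled, stage_mean=stage_mean, epsilon=epsilon)


# --------------------------------------------------------------------- GTF


def write_gene_models_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene and exon features in GTF (1-based inclusive) format."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            fh.write(
                f"{m.ref}\tnuquant\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.ref}\tnuquant\texon\t{a}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gene_models_gtf(path: str | Path) -> List[GeneModel]:
    """Read gene models (gene + exon features) from a GTF file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [
            (e.start, e.end)
            for e in db.features_of_type("exon")
            if e.attributes.get("gene_id", [None])[0] == gene.attributes["gene_id"][0]
        ]
        models.append(
            GeneModel(
                gene_id=gene.attributes["gene_id"][0],
                ref=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
            )
        )
    return models
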