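"""Simulated RNA-seq alignments with a controlled unspliced fraction.

Each read is assigned to a gene (uniformly) and to one of two templates:
with probability ``u`` the *unspliced* pre-mRNA — a uniform start over
the full genomic gene span, one contiguous match — and otherwise the
*spliced* mRNA — a uniform start over the concatenated exons, mapped back
to genomic coordinates with skip segments bridging the introns. Spliced
reads therefore never place an aligned base inside an intron, so the
intron-coverage statistic is exactly zero at ``u = 0``.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import numpy as np
import pysam

from ..rinp import GeneModel
from .params import READ_STREAMS, ReadSimParams, spawn_streams

__all__ = ["gen_reads", "write_sam", "default_gene_models"]


def _spliced_cigar(model: GeneModel, tx_start: int, length: int):
    """Genomic position and CIGAR of a read starting at spliced offset."""
    # walk exons in transcript coordinates
    cig = []
    pos0 = None
    remaining = length
    offset = tx_start
    for a, b in model.exons:
        exon_len = b - a + 1
        if offset >= exon_len:
            offset -= exon_len
            continue
        take = min(exon_len - offset, remaining)
        start_here = (a - 1) + offset  # 0-based genomic
        if pos0 is None:
            pos0 = start_here
        else:
            gap = start_here - prev_end  # intron to skip
            if gap > 0:
                cig.append((3, gap))  # N
        cig.append((0, take))  # M
        prev_end = start_here + take
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    assert remaining == 0, "read ran past transcript end"
    # merge adjacent M (possible with zero-length introns)
    merged = []
    for op, ln in cig:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return pos0, merged


def gen_reads(params: ReadSimParams) -> List[dict]:
    """Simulate alignment records; deterministic per seed.

    Returns a list of dicts (qname, ref, pos0, cigar, is_unspliced, gene)
    sorted by reference and position; :func:`write_sam` serialises them.
    """
    rng = spawn_streams(params.seed, READ_STREAMS)
    models = list(params.gene_models)
    L = params.read_length
    n = params.n_reads
    gene_idx = rng["assignment"].integers(0, len(models), size=n)
    unspliced = rng["assignment"].random(n) < params.unspliced_fraction
    records = []
    for i in range(n):
        m = models[gene_idx[i]]
        if unspliced[i]:
            max_start = m.span_length - L
            s = int(rng["starts"].integers(0, max_start + 1))
            pos0 = (m.start - 1) + s
            cigar = [(0, L)]
        else:
            max_start = m.spliced_length - L
            s = int(rng["starts"].integers(0, max_start + 1))
            pos0, cigar = _spliced_cigar(m, s, L)
        records.append(
            {
                "qname": f"r{i:06d}",
                "ref": m.ref,
                "pos0": pos0,
                "cigar": tuple(cigar),
                "is_unspliced": bool(unspliced[i]),
                "gene": m.gene_id,
                "length": L,
            }
        )
    records.sort(key=lambda r: (r["ref"], r["pos0"], r["qname"]))
    return records


def write_sam(
    records: Sequence[dict], models: Sequence[GeneModel], path: str | Path
) -> None:
    """Write simulated records as SAM with one @SQ line per reference."""
    ref_len: dict = {}
    for m in models:
        ref_len[m.ref] = max(ref_len.get(m.ref, 0), m.end + 1000)
    refs = sorted(ref_len)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": r, "LN": ref_len[r]} for r in refs],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["qname"]
            a.reference_name = r["ref"]
            a.reference_start = r["pos0"]
            a.cigartuples = list(r["cigar"])
            a.mapping_quality = 60
            a.flag = 0
            a.query_sequence = "A" * r["length"]
            out.write(a)


def default_gene_models(
    n_genes: int = 4,
    exon_length: int = 300,
    intron_length: int = 400,
    n_exons: int = 3,
    ref: str = "chrS",
) -> List[GeneModel]:
    """Toy multi-exon gene models laid head to tail on one reference."""
    models = []
    cursor = 1001
    for g in range(n_genes):
        exons = []
        p = cursor
        for e in range(n_exons):
            exons.append((p, p + exon_length - 1))
            p += exon_length + intron_length
        end = exons[-1][1]
        models.append(
            GeneModel(
                gene_id=f"GENE{g + 1}",
                ref=ref,
                strand="+",
                start=cursor,
                end=end,
                exons=exons,
            )
        )
        cursor = end + 2000
    return models
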