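"""Shared fixtures: small deterministic references and SAM construction."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from editome import GenomeSpec, ReferenceBundle, Transcript, build_reference


@pytest.fixture(scope="session")
def small_ref() -> ReferenceBundle:
    """60 kb single-chromosome genome with 6 genes, fixed seed."""
    return build_reference(GenomeSpec(chrom_length=60_000, n_genes=6, seed=7))


def make_ref(seq: str, transcripts: list[Transcript] | None = None) -> ReferenceBundle:
    """Reference bundle around an explicit chr1 sequence."""
    return ReferenceBundle(chroms={"chr1": seq}, transcripts=transcripts or [], repeats=[])


def make_plus_gene(seq_len: int, utr5=(0, 30), cds=((30, 120),), utr3=(120, 150),
                   strand="+", chrom="chr1", tx_id="t1") -> Transcript:
    cds = [tuple(iv) for iv in cds]
    introns = [(cds[i][1], cds[i + 1][0]) for i in range(len(cds) - 1)]
    return Transcript(
        tx_id=tx_id, gene_id=tx_id.split(".")[0], chrom=chrom, strand=strand,
        utr5=tuple(utr5), cds_exons=cds, introns=introns, utr3=tuple(utr3),
    )


def write_sam(path, ref: ReferenceBundle, reads: list[dict]) -> str:
    """Write SAM records from dicts with keys
    name, chrom, pos0, seq, flag (default 0), mapq (default 60), qual
    (default constant 37, or list of per-base Phred scores)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.chroms.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = r.get("name", f"read{i}")
            a.query_sequence = r["seq"]
            a.flag = r.get("flag", 0)
            if not a.is_unmapped:
                a.reference_id = header.get_tid(r["chrom"])
                a.reference_start = r["pos0"]
                a.cigartuples = [(0, len(r["seq"]))]
            a.mapping_quality = r.get("mapq", 60)
            qual = r.get("qual", 37)
            if isinstance(qual, int):
                qual = [qual] * len(r["seq"])
            a.query_qualities = qual
            fh.write(a)
    return str(path)


@pytest.fixture
def sam_writer():
    return write_sam
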