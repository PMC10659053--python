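"""Filtered per-position, per-strand base counts from aligned reads.

Read-level filters applied here are the pipeline's front door: the first and
last ``trim_bases`` bases of every aligned read are discarded, bases below the
Phred floor are discarded, and (optionally) only uniquely aligned reads are
counted.  A read is considered unique iff its mapping quality is > 0 and it
is not flagged secondary or supplementary.

RNA base counts are kept per transcript strand, decoded from the strandedness
protocol ("forward": alignment strand == transcript strand).  DNA counts are
strand-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .reference import BASES, ReferenceBundle

log = logging.getLogger(__name__)

STRANDS_RNA = ("+", "-")
STRANDS_DNA = (".",)

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b in "ACGT":
    _CODE_TABLE[ord(_b)] = BASES.index(_b)


class ConfigurationError(ValueError):
    pass


@dataclass
class PileupTable:
    """Per-chromosome arrays of shape (n_strands, 4 bases, chrom length)."""

    counts: dict[str, np.ndarray]
    source: str  # 'RNA' | 'DNA'
    strands: tuple[str, ...]
    n_reads_used: int = 0
    n_reads_rejected: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def depth(self, chrom: str) -> np.ndarray:
        """(n_strands, L) total filtered depth."""
        return self.counts[chrom].sum(axis=1)

    def counts_at(self, chrom: str, pos0: int, strand: str = ".") -> dict[str, int]:
        sidx = self.strands.index(strand)
        col = self.counts[chrom][sidx, :, pos0]
        return {b: int(col[i]) for i, b in enumerate(BASES)}

    def to_dataframe(self, min_depth: int = 1) -> pd.DataFrame:
        rows = []
        for chrom, arr in self.counts.items():
            for sidx, strand in enumerate(self.strands):
                depth = arr[sidx].sum(axis=0)
                keep = np.flatnonzero(depth >= min_depth)
                for p in keep:
                    rows.append(
                        {
                            "chrom": chrom,
                            "pos": int(p) + 1,
                            "strand": strand,
                            **{b: int(arr[sidx, i, p]) for i, b in enumerate(BASES)},
                            "depth": int(depth[p]),
                        }
                    )
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", *BASES, "depth"])

    def write_tsv(self, path: str | Path, min_depth: int = 1) -> None:
        self.to_dataframe(min_depth).to_csv(path, sep="\t", index=False)


def build_pileup(
    alignments: str | Path,
    ref: ReferenceBundle,
    source: str = "RNA",
    min_base_quality: int = 30,
    trim_bases: int = 6,
    unique_only: bool = True,
    strandedness: str = "forward",
) -> PileupTable:
    """Accumulate filtered base counts from a SAM/BAM file.

    A base contributes iff its 1-based offset within the read lies in
    ``[trim_bases + 1, L - trim_bases]`` and its Phred quality is at least
    ``min_base_quality``; with ``unique_only`` the read itself must pass the
    uniqueness rule.  Reads without quality strings are rejected and counted.
    """
    if source not in ("RNA", "DNA"):
        raise ValueError("source must be 'RNA' or 'DNA'")
    if strandedness != "forward":
        raise ConfigurationError(f"unknown strandedness protocol {strandedness!r}")
    strands = STRANDS_RNA if source == "RNA" else STRANDS_DNA
    counts = {
        chrom: np.zeros((len(strands), 4, L), dtype=np.uint32)
        for chrom, L in ref.chrom_lengths().items()
    }
    rejected = {"unmapped": 0, "not_unique": 0, "no_qualities": 0, "unknown_chrom": 0}
    used = 0

    with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped:
                rejected["unmapped"] += 1
                continue
            if unique_only and (
                read.mapping_quality <= 0 or read.is_secondary or read.is_supplementary
            ):
                rejected["not_unique"] += 1
                continue
            if read.query_qualities is None:
                rejected["no_qualities"] += 1
                continue
            chrom = read.reference_name
            if chrom not in counts:
                rejected["unknown_chrom"] += 1
                continue
            seq = read.query_sequence
            L = len(seq)
            codes = _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            quals = np.asarray(read.query_qualities, dtype=np.int32)
            keep = (quals >= min_base_quality) & (codes < 4)
            if trim_bases > 0:
                keep[:trim_bases] = False
                keep[max(L - trim_bases, 0) :] = False
            if not keep.any():
                continue
            cig = read.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                refpos = read.reference_start + np.arange(L)
            else:  # general case: M/=/X only (pipeline simulates ungapped reads)
                pairs = read.get_aligned_pairs(matches_only=True)
                qidx = np.array([q for q, _ in pairs], dtype=np.intp)
                rpos = np.array([r for _, r in pairs], dtype=np.intp)
                full = np.full(L, -1, dtype=np.intp)
                full[qidx] = rpos
                refpos = full
                keep &= refpos >= 0
            sidx = 0
            if source == "RNA":
                sidx = 1 if read.is_reverse else 0
            np.add.at(counts[chrom][sidx], (codes[keep], refpos[keep]), 1)
            used += 1

    if rejected["no_qualities"]:
        log.warning("rejected %d reads lacking quality strings", rejected["no_qualities"])
    return PileupTable(
        counts=counts,
        source=source,
        strands=strands,
        n_reads_used=used,
        n_reads_rejected=rejected,
        params={
            "min_base_quality": min_base_quality,
            "trim_bases": trim_bases,
            "unique_only": unique_only,
            "strandedness": strandedness,
        },
    )


def merge_pileups(tables: list[PileupTable]) -> PileupTable:
    """Sum base counts across libraries built with identical filters."""
    if not tables:
        raise ValueError("no pileups to merge")
    first = tables[0]
    for t in tables[1:]:
        if t.strands != first.strands or t.source != first.source:
            raise ValueError("pileups differ in source/strand layout")
        if t.params != first.params:
            raise ValueError("pileups built with different filters cannot be merged")
    counts = {c: arr.copy() for c, arr in first.counts.items()}
    for t in tables[1:]:
        for c, arr in t.counts.items():
            counts[c] += arr
    merged_rej: dict[str, int] = {}
    for t in tables:
        for k, v in t.n_reads_rejected.items():
            merged_rej[k] = merged_rej.get(k, 0) + v
    return PileupTable(
        counts=counts,
        source=first.source,
        strands=first.strands,
        n_reads_used=sum(t.n_reads_used for t in tables),
        n_reads_rejected=merged_rej,
        params=dict(first.params),
    )


@dataclass
class SnpMask:
    """DNA-derived position classification.

    ``masked``: genomic variation supported by enough DNA reads — excluded
    from edit calling as a SNP.  ``uncallable``: DNA depth below the floor —
    also excluded, since the DNA genotype cannot be confirmed.
    """

    masked: dict[str, np.ndarray]
    uncallable: dict[str, np.ndarray]
    params: dict = field(default_factory=dict)

    def excluded(self, chrom: str) -> np.ndarray:
        return self.masked[chrom] | self.uncallable[chrom]

    def is_masked(self, chrom: str, pos0: int) -> bool:
        return bool(self.masked[chrom][pos0])

    def n_masked(self) -> int:
        return int(sum(m.sum() for m in self.masked.values()))


def mask_dna_variants(
    dna_pileup: PileupTable,
    ref: ReferenceBundle,
    min_dna_depth: int = 10,
    min_alt_reads: int = 2,
) -> SnpMask:
    """Build the SNP mask from the DNA pileup.

    A position is masked iff its filtered DNA depth is at least
    ``min_dna_depth`` and some non-reference base is supported by at least
    ``min_alt_reads`` reads; positions below the depth floor are uncallable.
    """
    if dna_pileup.source != "DNA":
        raise ValueError("mask_dna_variants expects a DNA pileup")
    masked: dict[str, np.ndarray] = {}
    uncallable: dict[str, np.ndarray] = {}
    for chrom, arr in dna_pileup.counts.items():
        cnt = arr.sum(axis=0)  # (4, L) summed over strands
        depth = cnt.sum(axis=0)
        refcode = ref.codes[chrom]
        alt = cnt.copy()
        valid = refcode < 4
        alt[refcode[valid], np.flatnonzero(valid)] = 0
        max_alt = alt.max(axis=0)
        masked[chrom] = (depth >= min_dna_depth) & (max_alt >= min_alt_reads)
        uncallable[chrom] = depth < min_dna_depth
    return SnpMask(
        masked=masked,
        uncallable=uncallable,
        params={"min_dna_depth": min_dna_depth, "min_alt_reads": min_alt_reads},
    )
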