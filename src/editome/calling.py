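"""Normal editing-site calling: RNA vs DNA pileup comparison.

A candidate site must be unmasked and DNA-callable, reach the RNA depth
floor, show exactly one alternate base, carry at least ``min_edited_reads``
alternate reads, and survive a one-sided binomial test of the alternate
count against the sequencing error rate with Benjamini-Hochberg FDR control
across all candidates.  Each call is typed as one of the 12 possible
mismatch classes in transcript orientation, so A-to-I editing appears as
A-to-G regardless of the gene's genomic strand.

The support-realignment filter re-checks every read supporting a call with
an internal k-mer seed-and-extend aligner: reads whose best placement on the
genome is not unique (a second locus scores within a configurable margin of
the best) are removed from the support, and the site is dropped when the
remaining unique support falls below ``min_edited_reads``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .pileup import PileupTable, SnpMask
from .reference import BASES, COMPLEMENT, ReferenceBundle, revcomp

log = logging.getLogger(__name__)

EDIT_TYPES = [
    f"{r}-to-{a}" for r in BASES for a in BASES if r != a
]  # 12 ordered mismatch classes

SITE_COLUMNS = [
    "chrom", "pos", "strand", "ref", "alt", "edit_type",
    "n_edited", "n_ref", "depth", "level", "p", "q", "mode",
]


def classify_type(ref_base: str, alt_base: str, gene_strand: str) -> str:
    """Mismatch class in transcript orientation.

    ``ref_base``/``alt_base`` are genome(+)-strand bases; for a gene on the
    '-' strand both are complemented, so genomic T-to-C on a '-' strand
    transcript is classified A-to-G.
    """
    if gene_strand == "-":
        ref_base, alt_base = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    return f"{ref_base}-to-{alt_base}"


def call_sites(
    rna_pileup: PileupTable,
    snp_mask: SnpMask,
    ref: ReferenceBundle,
    min_rna_depth: int = 10,
    min_edited_reads: int = 3,
    error_rate: float = 0.001,
    fdr: float = 0.05,
    noise_alt_threshold: int = 2,
) -> pd.DataFrame:
    """Call candidate editing sites from the RNA pileup.

    A second alternate base only counts as "observed" (triggering the
    multi-variant exclusion) when supported by at least
    ``noise_alt_threshold`` reads; below that it is treated as sequencing
    noise.  Returns an EditSite table sorted by (chrom, pos), mode='normal'.
    """
    if error_rate <= 0:
        raise ValueError("error_rate must be > 0")
    if rna_pileup.source != "RNA":
        raise ValueError("call_sites expects an RNA pileup")

    rows = []
    for chrom, arr in rna_pileup.counts.items():
        refcode = ref.codes[chrom]
        excluded = snp_mask.excluded(chrom)
        for sidx, strand in enumerate(rna_pileup.strands):
            cnt = arr[sidx]  # (4, L)
            depth = cnt.sum(axis=0)
            cand = np.flatnonzero((depth >= min_rna_depth) & ~excluded & (refcode < 4))
            if cand.size == 0:
                continue
            sub = cnt[:, cand].astype(np.int64)
            refc = refcode[cand]
            alt = sub.copy()
            alt[refc, np.arange(cand.size)] = 0
            observed = (alt >= noise_alt_threshold).sum(axis=0)
            alt_best = alt.argmax(axis=0)
            alt_n = alt[alt_best, np.arange(cand.size)]
            ok = (observed == 1) & (alt_n >= min_edited_reads)
            for j in np.flatnonzero(ok):
                pos0 = int(cand[j])
                gref = BASES[int(refc[j])]
                galt = BASES[int(alt_best[j])]
                n_ref = int(sub[refc[j], j])
                n_alt = int(alt_n[j])
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "strand": strand,
                        "ref": COMPLEMENT[gref] if strand == "-" else gref,
                        "alt": COMPLEMENT[galt] if strand == "-" else galt,
                        "edit_type": classify_type(gref, galt, strand),
                        "n_edited": n_alt,
                        "n_ref": n_ref,
                        "depth": int(depth[pos0]),
                        "level": n_alt / (n_alt + n_ref),
                    }
                )

    if not rows:
        return pd.DataFrame(columns=SITE_COLUMNS)
    df = pd.DataFrame(rows)
    df["p"] = binom.sf(df["n_edited"] - 1, df["depth"], error_rate)
    reject, q, _, _ = multipletests(df["p"], alpha=fdr, method="fdr_bh")
    df["q"] = q
    df = df[reject].copy()
    df["mode"] = "normal"
    df = df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    return df[SITE_COLUMNS]


# ---------------------------------------------------------------------------
# k-mer seed-and-extend uniqueness check (support realignment)
# ---------------------------------------------------------------------------

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b in BASES:
    _CODE_TABLE[ord(_b)] = BASES.index(_b)


def _seq_codes(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class _Hit:
    chrom: str
    strand: str
    start: int
    score: int


class KmerIndex:
    """Exact k-mer index of the (+) genome for ungapped seed-and-extend."""

    def __init__(self, ref: ReferenceBundle, k: int = 16):
        self.k = k
        self.ref = ref
        self.codes = {c: ref.codes[c] for c in ref.chroms}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in ref.chroms.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((chrom, i))

    def _candidates(self, seq: str) -> set[tuple[str, int]]:
        k = self.k
        cands: set[tuple[str, int]] = set()
        offsets = list(range(0, len(seq) - k + 1, k))
        if offsets and offsets[-1] != len(seq) - k:
            offsets.append(len(seq) - k)
        for off in offsets:
            for chrom, i in self.index.get(seq[off : off + k], ()):
                cands.add((chrom, i - off))
        return cands

    def align(self, seq: str) -> list[_Hit]:
        """Score every seeded placement of the read (both orientations) by
        ungapped match count."""
        hits: list[_Hit] = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            codes = _seq_codes(s)
            L = len(codes)
            for chrom, start in self._candidates(s):
                g = self.codes[chrom]
                if start < 0 or start + L > len(g):
                    continue
                score = int((g[start : start + L] == codes).sum())
                hits.append(_Hit(chrom, strand, start, score))
        hits.sort(key=lambda h: -h.score)
        return hits

    def is_unique(self, seq: str, margin_frac: float | None = 0.95) -> bool:
        """True iff the best placement beats every other placement by the
        margin.  ``margin_frac=None`` disables the check (never ambiguous)."""
        if margin_frac is None:
            return True
        hits = self.align(seq)
        if not hits:
            return False
        if len(hits) == 1:
            return True
        best, second = hits[0].score, hits[1].score
        return second < margin_frac * best


def collect_supporting_reads(
    sites: pd.DataFrame,
    alignments: str,
    ref: ReferenceBundle,
    max_reads_per_site: int = 20,
) -> dict[tuple[str, int, str], list[str]]:
    """Sequences of reads showing the alternate base at each called site."""
    want: dict[tuple[str, int, str], dict] = {}
    for _, row in sites.iterrows():
        galt = COMPLEMENT[row["alt"]] if row["strand"] == "-" else row["alt"]
        want[(row["chrom"], int(row["pos"]) - 1, row["strand"])] = {"alt": galt}
    support: dict[tuple[str, int, str], list[str]] = {k: [] for k in want}
    if not want:
        return support
    by_chrom: dict[str, dict[int, list[tuple[str, str]]]] = {}
    for (chrom, pos0, strand), meta in want.items():
        by_chrom.setdefault(chrom, {}).setdefault(pos0, []).append((strand, meta["alt"]))

    with pysam.AlignmentFile(alignments, "r", check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name not in by_chrom:
                continue
            rstrand = "-" if read.is_reverse else "+"
            start = read.reference_start
            seq = read.query_sequence
            end = start + len(seq)
            posmap = by_chrom[read.reference_name]
            for pos0 in range(start, end):
                if pos0 not in posmap:
                    continue
                for strand, galt in posmap[pos0]:
                    if strand != rstrand:
                        continue
                    if seq[pos0 - start] == galt:
                        key = (read.reference_name, pos0, strand)
                        if len(support[key]) < max_reads_per_site:
                            support[key].append(seq)
    return support


def realignment_check(
    sites: pd.DataFrame,
    alignments: str,
    ref: ReferenceBundle,
    k: int = 16,
    margin_frac: float | None = 0.95,
    min_unique_support: int = 3,
    index: KmerIndex | None = None,
) -> pd.DataFrame:
    """Drop sites whose support does not survive uniqueness realignment.

    Every supporting read is realigned by exact k-mer seeding and ungapped
    extension; ambiguous reads (second-best locus scoring >= margin_frac x
    best) no longer count as support.  With ``margin_frac=None`` the filter
    is disabled and all sites are kept.
    """
    if len(sites) == 0 or margin_frac is None:
        return sites.copy()
    if index is None:
        index = KmerIndex(ref, k=k)
    support = collect_supporting_reads(sites, alignments, ref)
    seen_unique: dict[str, bool] = {}
    keep_rows = []
    for i, row in sites.iterrows():
        key = (row["chrom"], int(row["pos"]) - 1, row["strand"])
        n_unique = 0
        for seq in support.get(key, ()):
            if seq not in seen_unique:
                seen_unique[seq] = index.is_unique(seq, margin_frac)
            if seen_unique[seq]:
                n_unique += 1
        if n_unique >= min_unique_support:
            keep_rows.append(i)
    dropped = len(sites) - len(keep_rows)
    if dropped:
        log.info("realignment check dropped %d/%d sites", dropped, len(sites))
    return sites.loc[keep_rows].reset_index(drop=True)
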