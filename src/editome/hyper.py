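"""Hyper-editing recovery from reads that fail normal alignment.

Densely A-to-I-edited reads carry too many A->G mismatches to align under a
normal mismatch cap.  The standard rescue is alignment in a transformed
space: all adenosines in the read and in the genome are rewritten to G, which
erases every A->G mismatch while leaving other differences visible.  Both
transcript strands are handled: a read from a '+' strand transcript is
searched A->G-transformed against the A->G genome, while the reverse
complement of a read from a '-' strand transcript is searched
T->C-transformed against the T->C genome (the genomic image of transcript
A->G on the minus strand).

After a unique transformed placement is found, the original read is compared
to the original genome: genome-A/read-G differences (transcript orientation)
are the recovered edits, everything else counts against ``max_other_mm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .calling import SITE_COLUMNS
from .pileup import PileupTable  # noqa: F401  (shared container, re-exported surface)
from .reference import ReferenceBundle

log = logging.getLogger(__name__)

HIT_COLUMNS = [
    "read_id", "chrom", "pos", "strand", "n_AtoG", "n_other", "n_A_span", "edit_pos",
]


@dataclass
class _Space:
    """One transformed search space: + (A->G) or - (T->C)."""

    strand: str
    codes: dict[str, np.ndarray]  # transformed genome codes
    index: dict[bytes, list[tuple[str, int]]]


def _transform_codes(codes: np.ndarray, src: int, dst: int) -> np.ndarray:
    out = codes.copy()
    out[out == src] = dst
    return out


def _build_space(ref: ReferenceBundle, strand: str, k: int) -> _Space:
    src, dst = (0, 2) if strand == "+" else (3, 1)  # A->G or T->C
    codes = {c: _transform_codes(ref.codes[c], src, dst) for c in ref.chroms}
    index: dict[bytes, list[tuple[str, int]]] = {}
    for chrom, arr in codes.items():
        buf = arr.tobytes()
        for i in range(len(buf) - k + 1):
            index.setdefault(buf[i : i + k], []).append((chrom, i))
    return _Space(strand=strand, codes=codes, index=index)


class TransformedIndex:
    """k-mer indexes of the A->G and T->C transformed genomes."""

    def __init__(self, ref: ReferenceBundle, k: int = 16):
        self.ref = ref
        self.k = k
        self.spaces = {s: _build_space(ref, s, k) for s in "+-"}


_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)


def _read_codes(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def transform_and_realign(
    reads: str | list[tuple[str, str]],
    ref: ReferenceBundle,
    k: int = 16,
    max_other_mm: int = 1,
    index: TransformedIndex | None = None,
) -> pd.DataFrame:
    """Realign unmapped reads in A->G transformed space.

    ``reads`` is a SAM path (unmapped records) or a list of (read_id,
    sequence) pairs in sequencing orientation.  A hit is reported iff the
    transformed placement is unique (strictly fewer transformed mismatches
    than any alternative placement) and the original-space non-A-to-G
    mismatch count is at most ``max_other_mm``.  Reads without a hit are
    dropped with a logged count.
    """
    if index is None:
        index = TransformedIndex(ref, k=k)
    k = index.k

    if isinstance(reads, str):
        pairs = []
        with pysam.AlignmentFile(reads, "r", check_sq=False) as fh:
            for r in fh.fetch(until_eof=True):
                pairs.append((r.query_name, r.query_sequence))
    else:
        pairs = list(reads)

    rows = []
    n_unaligned = 0
    n_ambiguous = 0
    for read_id, seq in pairs:
        row = _realign_one(read_id, seq, ref, index, max_other_mm)
        if row is None:
            n_unaligned += 1
        elif row == "ambiguous":
            n_ambiguous += 1
        else:
            rows.append(row)
    if n_unaligned or n_ambiguous:
        log.info(
            "hyper realignment: %d reads placed, %d with no hit, %d ambiguous",
            len(rows), n_unaligned, n_ambiguous,
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _realign_one(read_id, seq, ref, index: TransformedIndex, max_other_mm):
    L = len(seq)
    k = index.k
    if L < k:
        return None
    rcodes = _read_codes(seq)
    queries = {
        "+": _transform_codes(rcodes, 0, 2),  # read A->G vs A->G genome
        "-": _transform_codes(_COMP_CODE[rcodes[::-1]], 3, 1),  # revcomp, T->C
    }
    candidates: list[tuple[str, str, int, int]] = []  # (strand, chrom, start, t_mm)
    seen = set()
    for strand, q in queries.items():
        space = index.spaces[strand]
        qbuf = q.tobytes()
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        for off in offsets:
            for chrom, i in space.index.get(qbuf[off : off + k], ()):
                start = i - off
                if start < 0 or start + L > len(space.codes[chrom]):
                    continue
                key = (strand, chrom, start)
                if key in seen:
                    continue
                seen.add(key)
                t_mm = int((space.codes[chrom][start : start + L] != q).sum())
                candidates.append((strand, chrom, start, t_mm))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[3])
    if len(candidates) > 1 and candidates[1][3] == candidates[0][3]:
        return "ambiguous"
    strand, chrom, start, _ = candidates[0]

    g = ref.codes[chrom][start : start + L]
    aligned = rcodes if strand == "+" else _COMP_CODE[rcodes[::-1]]
    mism = aligned != g
    if strand == "+":
        edits = mism & (g == 0) & (aligned == 2)  # genome A, read G
        n_a_span = int((g == 0).sum())
    else:
        edits = mism & (g == 3) & (aligned == 1)  # genome T, revcomp-read C
        n_a_span = int((g == 3).sum())
    n_other = int(mism.sum() - edits.sum())
    if n_other > max_other_mm:
        return None
    edit_pos = tuple(int(p) + start + 1 for p in np.flatnonzero(edits))  # 1-based
    return {
        "read_id": read_id,
        "chrom": chrom,
        "pos": start + 1,
        "strand": strand,
        "n_AtoG": int(edits.sum()),
        "n_other": n_other,
        "n_A_span": n_a_span,
        "edit_pos": edit_pos,
    }


def cluster_filter(
    hits: pd.DataFrame,
    ref: ReferenceBundle,
    min_edits_per_read: int = 5,
    min_edit_fraction: float = 0.05,
    read_length: int | None = None,
) -> pd.DataFrame:
    """Keep densely edited reads and aggregate them into hyper EditSite rows.

    A read survives iff it carries at least ``min_edits_per_read`` recovered
    edits and its edits cover at least ``min_edit_fraction`` of the
    adenosines in its span.  Per-position edited/total counts over the kept
    reads become EditSite rows with mode='hyper'.
    """
    if len(hits) == 0:
        return pd.DataFrame(columns=SITE_COLUMNS)
    frac = hits["n_AtoG"] / hits["n_A_span"].clip(lower=1)
    kept = hits[(hits["n_AtoG"] >= min_edits_per_read) & (frac >= min_edit_fraction)]
    if len(kept) == 0:
        return pd.DataFrame(columns=SITE_COLUMNS)

    rlen = read_length if read_length is not None else _infer_read_length(kept)
    # per (chrom, strand): coverage and edited counts over kept reads
    cov: dict[tuple[str, str], np.ndarray] = {}
    edited: dict[tuple[str, str], np.ndarray] = {}
    for _, h in kept.iterrows():
        key = (h["chrom"], h["strand"])
        if key not in cov:
            L = len(ref.chroms[h["chrom"]])
            cov[key] = np.zeros(L, dtype=np.int64)
            edited[key] = np.zeros(L, dtype=np.int64)
        start0 = int(h["pos"]) - 1
        cov[key][start0 : start0 + rlen] += 1
        for p in h["edit_pos"]:
            edited[key][p - 1] += 1

    rows = []
    for (chrom, strand), e in edited.items():
        c = cov[(chrom, strand)]
        for p0 in np.flatnonzero(e):
            n_ed = int(e[p0])
            depth = int(c[p0])
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(p0) + 1,
                    "strand": strand,
                    "ref": "A",
                    "alt": "G",
                    "edit_type": "A-to-G",
                    "n_edited": n_ed,
                    "n_ref": depth - n_ed,
                    "depth": depth,
                    "level": n_ed / depth,
                    "p": np.nan,
                    "q": np.nan,
                    "mode": "hyper",
                }
            )
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def _infer_read_length(hits: pd.DataFrame) -> int:
    # span of recovered edits never exceeds the read length; the aggregation
    # only needs a consistent coverage window, so use the widest edit extent
    # when the caller does not pass the true read length
    widths = [
        (max(ep) - (row_pos - 1)) if ep else 1
        for ep, row_pos in zip(hits["edit_pos"], hits["pos"])
    ]
    return max(widths + [1])


def merge_modes(res: pd.DataFrame, rhes: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Merge normal and hyper site tables; sites found by both methods get
    mode='common' (counted once, normal-mode counts kept).

    Returns the unified table and the overlap summary
    ``{normal_only, hyper_only, common, union, conflicts}`` satisfying
    inclusion-exclusion exactly.
    """
    def keyed(df):
        return {
            (r["chrom"], int(r["pos"]), r["strand"]): r for _, r in df.iterrows()
        }

    res_k = keyed(res)
    rhes_k = keyed(rhes)
    common_keys = set(res_k) & set(rhes_k)
    conflicts = {
        k for k in common_keys
        if (res_k[k]["ref"], res_k[k]["alt"]) != (rhes_k[k]["ref"], rhes_k[k]["alt"])
    }
    if conflicts:
        log.warning("%d sites with conflicting alleles across modes excluded", len(conflicts))
    common_keys -= conflicts

    rows = []
    for k, r in res_k.items():
        if k in conflicts:
            continue
        row = dict(r)
        row["mode"] = "common" if k in common_keys else "normal"
        rows.append(row)
    for k, r in rhes_k.items():
        if k in common_keys or k in conflicts:
            continue
        rows.append(dict(r))
    unified = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if len(unified):
        unified = unified.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    counts = {
        "normal_only": len(res_k) - len(common_keys) - len(conflicts),
        "hyper_only": len(rhes_k) - len(common_keys) - len(conflicts),
        "common": len(common_keys),
        "union": len(unified),
        "conflicts": len(conflicts),
    }
    return unified, counts
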