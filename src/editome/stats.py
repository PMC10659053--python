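"""Editome quantification: levels, densities, indexes, annotation, motifs.

Level-type statistics enforce the minimum-coverage-10 rule; plain site
counts do not.  The overall editing level is the pooled ratio
sum(G)/sum(A+G), algebraically identical to the coverage-weighted mean of
per-site levels.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference import COMPLEMENT, FEAT_NAMES, ReferenceBundle, RepeatInterval
from . import recoding as _recoding

log = logging.getLogger(__name__)

REGION_CLASSES = ["5UTR", "CDS-syn", "CDS-nonsyn", "intron", "intergenic", "3UTR"]


def editing_level(g: int, a: int) -> float:
    """Per-site editing level G/(G+A)."""
    if g + a == 0:
        raise ValueError("editing level undefined at zero A+G coverage")
    return g / (g + a)


def overall_editing_level(sites: pd.DataFrame, min_coverage: int = 10) -> float:
    """Pooled level sum(G)/sum(A+G) over sites meeting the coverage floor."""
    if len(sites) == 0:
        raise ValueError("overall editing level undefined on an empty site table")
    ag = sites["n_edited"] + sites["n_ref"]
    kept = sites[ag >= min_coverage]
    if len(kept) == 0:
        raise ValueError(f"no sites with A+G coverage >= {min_coverage}")
    return float(kept["n_edited"].sum() / (kept["n_edited"] + kept["n_ref"]).sum())


def sites_per_mb(n_sites: int, mapped_bases: int) -> float:
    """Edited-site density normalised by sequencing effort (sites per Mb of
    mapped bases)."""
    if mapped_bases <= 0:
        raise ValueError("sites_per_mb undefined for zero mapped bases")
    return n_sites / (mapped_bases / 1e6)


def editing_index(
    rna_pileup,
    ref: ReferenceBundle,
    intervals: Iterable[RepeatInterval] | None = None,
    region: str = "te",
    denominator: str = "ag",
) -> float:
    """Site-list-free global editing measure over repeat regions.

    Over every transcript-strand reference-adenosine position inside the
    intervals: the ratio of G reads to A+G reads (``denominator='ag'``) or to
    total filtered depth (``denominator='total'``).  Genome '+' positions use
    the '+' strand pileup (A vs G counts); genome 'T' positions use the '-'
    strand pileup (T vs C counts, which are transcript A vs G).
    """
    if denominator not in ("ag", "total"):
        raise ValueError("denominator must be 'ag' or 'total'")
    num = den = 0
    for chrom, arr in rna_pileup.counts.items():
        if intervals is None:
            mask = ref.te_mask[chrom] if region == "te" else ref.repeat_mask[chrom]
        else:
            mask = np.zeros(len(ref.chroms[chrom]), dtype=bool)
            for iv in intervals:
                if iv.chrom == chrom:
                    mask[iv.start : iv.end] = True
        codes = ref.codes[chrom]
        depth = arr.sum(axis=1)  # (n_strands, L)
        # '+' strand transcripts over genome A
        plus = mask & (codes == 0)
        num += int(arr[0, 2, plus].sum())  # G reads
        if denominator == "ag":
            den += int(arr[0, 0, plus].sum() + arr[0, 2, plus].sum())
        else:
            den += int(depth[0, plus].sum())
        # '-' strand transcripts over genome T
        minus = mask & (codes == 3)
        num += int(arr[1, 1, minus].sum())  # genome C = transcript G
        if denominator == "ag":
            den += int(arr[1, 3, minus].sum() + arr[1, 1, minus].sum())
        else:
            den += int(depth[1, minus].sum())
    if den == 0:
        raise ValueError("editing index undefined: no covered adenosines in regions")
    return num / den


def annotate_features(
    sites: pd.DataFrame, ref: ReferenceBundle
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assign each site a single feature class and repeat/TE flags.

    Precedence across overlapping transcripts is CDS > UTR > intron >
    intergenic.  A-to-G CDS sites are subdivided into synonymous and
    non-synonymous via codon-consequence annotation (stop gain/loss counts as
    non-synonymous at the region level).  Returns the annotated table and
    region fractions summing to 1.
    """
    out = sites.copy()
    feats, tes, reps = [], [], []
    for _, row in out.iterrows():
        chrom, pos0 = row["chrom"], int(row["pos"]) - 1
        if pos0 < 0 or pos0 >= len(ref.chroms[chrom]):
            raise ValueError(f"site {chrom}:{row['pos']} beyond chromosome bounds")
        fname = FEAT_NAMES[int(ref.feat[chrom][pos0])]
        if fname == "CDS":
            if row.get("edit_type") == "A-to-G":
                ev = _recoding.codon_consequence_at(ref, chrom, pos0, row["strand"])
                fname = "CDS-syn" if (ev is not None and ev.synonymous) else "CDS-nonsyn"
            else:
                fname = "CDS-nonsyn"
        feats.append(fname)
        tes.append(bool(ref.te_mask[chrom][pos0]))
        reps.append(bool(ref.repeat_mask[chrom][pos0]))
    out["feature"] = feats
    out["te"] = tes
    out["repeat"] = reps
    n = len(out)
    fractions = {
        c: (float((out["feature"] == c).sum()) / n if n else 0.0) for c in REGION_CLASSES
    }
    return out, fractions


def intersection_sets(per_tissue: Mapping[str, pd.DataFrame | Iterable]) -> pd.DataFrame:
    """Exclusive UpSet-style intersection counts of per-tissue site sets.

    Every distinct site is assigned to exactly one of the 2^k - 1 non-empty
    membership classes; class counts therefore sum to the union size.
    """
    if len(per_tissue) < 2:
        raise ValueError("intersection_sets needs at least two tissues")

    def to_keys(v):
        if isinstance(v, pd.DataFrame):
            return {
                (r["chrom"], int(r["pos"]), r["strand"]) for _, r in v.iterrows()
            }
        return set(v)

    sets = {t: to_keys(v) for t, v in per_tissue.items()}
    tissues = list(sets)
    union = set().union(*sets.values())
    classes: dict[tuple[str, ...], int] = {}
    for key in union:
        members = tuple(t for t in tissues if key in sets[t])
        classes[members] = classes.get(members, 0) + 1
    rows = [
        {"tissues": ",".join(members), "degree": len(members), "count": c}
        for members, c in sorted(classes.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["tissues", "degree", "count"])


def motif_matrix(sites: pd.DataFrame, ref: ReferenceBundle) -> pd.DataFrame:
    """Neighbour-nucleotide frequency matrix at positions -1, 0, +1 in
    transcript orientation.

    Position 0 is the edited adenosine itself.  Sites at a sequence boundary
    contribute no neighbour on the missing side (skipped with a logged
    count); frequencies are normalised per position.
    """
    counts = {p: {b: 0 for b in "ACGT"} for p in (-1, 0, 1)}
    skipped = 0
    for _, row in sites.iterrows():
        chrom, pos0, strand = row["chrom"], int(row["pos"]) - 1, row["strand"]
        seq = ref.chroms[chrom]
        counts[0][ref.transcript_base(chrom, pos0, strand)] += 1
        for rel in (-1, 1):
            gpos = pos0 + rel if strand == "+" else pos0 - rel
            if 0 <= gpos < len(seq):
                b = seq[gpos]
                counts[rel][COMPLEMENT[b] if strand == "-" else b] += 1
            else:
                skipped += 1
    if skipped:
        log.info("motif matrix: %d boundary neighbours skipped", skipped)
    mat = pd.DataFrame(counts).T[list("ACGT")]
    totals = mat.sum(axis=1)
    mat = mat.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    mat.index.name = "position"
    return mat
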