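"""Codon consequences of A-to-I editing in coding sequence.

A-to-I editing is read as A->G by the ribosome, so a CDS edit substitutes G
for A at one codon position in transcript orientation.  Consequences are
computed against the standard genetic code; stop gains and losses are
labelled distinctly rather than collapsed into "nonsynonymous".  When a site
is covered by several transcripts, the representative is the one with the
longest CDS.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .reference import ReferenceBundle, Transcript

AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY") + ["*"]


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class RecodingEvent:
    chrom: str
    pos: int  # 1-based genomic
    strand: str
    transcript_id: str
    codon_index: int  # 0-based codon number within the CDS
    codon_position: int  # 1-3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str  # synonymous | nonsynonymous | stop_gained | stop_lost

    @property
    def synonymous(self) -> bool:
        return self.consequence == "synonymous"


def codon_consequence(
    ref: ReferenceBundle, tx: Transcript, chrom: str, pos0: int
) -> RecodingEvent | None:
    """Consequence of an A->G edit at a genomic position within a CDS.

    Returns None when the position is not in this transcript's CDS.  Raises
    if the reference base at the position is not adenosine in transcript
    orientation (A-to-I editing is only defined at adenosines).
    """
    if chrom != tx.chrom:
        return None
    cds_off = tx.genomic_to_cds(pos0)
    if cds_off is None:
        return None
    cds = tx.cds_sequence(ref.chroms)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS of {tx.tx_id} is not a multiple of 3")
    if cds[cds_off] != "A":
        raise ValueError(
            f"{chrom}:{pos0 + 1} is {cds[cds_off]} in transcript orientation, not A"
        )
    ci = cds_off // 3
    cp = cds_off % 3
    ref_codon = cds[3 * ci : 3 * ci + 3]
    alt_codon = ref_codon[:cp] + "G" + ref_codon[cp + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*":
        consequence = "stop_lost"
    else:
        consequence = "nonsynonymous"
    return RecodingEvent(
        chrom=chrom,
        pos=pos0 + 1,
        strand=tx.strand,
        transcript_id=tx.tx_id,
        codon_index=ci,
        codon_position=cp + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )


def representative_transcript(
    ref: ReferenceBundle, chrom: str, pos0: int
) -> Transcript | None:
    """Longest-CDS transcript whose CDS contains the position."""
    best = None
    for tx in ref.transcripts:
        if tx.chrom != chrom or tx.genomic_to_cds(pos0) is None:
            continue
        if best is None or tx.cds_len > best.cds_len:
            best = tx
    return best


def codon_consequence_at(
    ref: ReferenceBundle, chrom: str, pos0: int, strand: str
) -> RecodingEvent | None:
    """Consequence at a site using its representative transcript, or None
    when the site is not in any CDS on the given strand."""
    tx = representative_transcript(ref, chrom, pos0)
    if tx is None or tx.strand != strand:
        return None
    return codon_consequence(ref, tx, chrom, pos0)


def events_for_sites(
    sites: pd.DataFrame, ref: ReferenceBundle, all_transcripts: bool = False
) -> pd.DataFrame:
    """Recoding events for every A-to-G site that falls in annotated CDS.

    By default one event per site via the representative transcript; with
    ``all_transcripts`` one event per (site, transcript).  When transcripts
    disagree, the site-level consequence reported downstream is the worst
    case (non-synonymous beats synonymous).
    """
    rows = []
    for _, row in sites.iterrows():
        if row.get("edit_type", "A-to-G") != "A-to-G":
            continue
        chrom, pos0, strand = row["chrom"], int(row["pos"]) - 1, row["strand"]
        if all_transcripts:
            txs = [
                t
                for t in ref.transcripts
                if t.chrom == chrom and t.strand == strand and t.genomic_to_cds(pos0) is not None
            ]
        else:
            tx = representative_transcript(ref, chrom, pos0)
            txs = [tx] if tx is not None and tx.strand == strand else []
        for tx in txs:
            ev = codon_consequence(ref, tx, chrom, pos0)
            if ev is not None:
                rows.append(ev.__dict__ | {"synonymous": ev.synonymous})
    cols = [
        "chrom", "pos", "strand", "transcript_id", "codon_index", "codon_position",
        "ref_codon", "alt_codon", "ref_aa", "alt_aa", "consequence", "synonymous",
    ]
    return pd.DataFrame(rows, columns=cols)


def substitution_matrix(events: pd.DataFrame) -> pd.DataFrame:
    """Amino-acid substitution count matrix (rows: reference aa, columns:
    edited aa; diagonal holds synonymous events)."""
    mat = pd.DataFrame(0, index=AA_ORDER, columns=AA_ORDER, dtype=int)
    for _, ev in events.iterrows():
        mat.loc[ev["ref_aa"], ev["alt_aa"]] += 1
    return mat
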