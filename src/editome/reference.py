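"""Synthetic reference bundle: genome sequence, gene models, repeat intervals.

The bundle is the single coordinate authority for the whole pipeline.
Conventions: internal coordinates are 0-based half-open; emitted GTF is
1-based closed, emitted BED is 0-based half-open, SAM POS is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# feature codes used in per-chromosome annotation arrays
FEAT_INTERGENIC = 0
FEAT_UTR5 = 1
FEAT_CDS = 2
FEAT_INTRON = 3
FEAT_UTR3 = 4
FEAT_NAMES = {
    FEAT_INTERGENIC: "intergenic",
    FEAT_UTR5: "5UTR",
    FEAT_CDS: "CDS",
    FEAT_INTRON: "intron",
    FEAT_UTR3: "3UTR",
}
FEAT_CODES = {v: k for k, v in FEAT_NAMES.items()}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class SizingError(ValueError):
    """Requested gene/feature layout does not fit on the chromosome."""


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the synthetic genome and its gene models.

    All lengths are in bp.  ``cds_length`` must be divisible by 3 so that
    every coding sequence translates in frame.  ``te_fraction`` is the target
    fraction of intergenic bp covered by repeat intervals.
    """

    n_chroms: int = 1
    chrom_length: int = 200_000
    gc_content: float = 0.42
    n_genes: int = 20
    exons_per_gene: int = 3
    utr5_length: int = 150
    cds_length: int = 900
    intron_length: int = 300
    utr3_length: int = 400
    te_fraction: float = 0.30
    simple_repeat_fraction: float = 0.2  # fraction of repeat bp not flagged TE
    min_intergenic_gap: int = 500
    seed: int = 7

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "chrom_length",
            "n_genes",
            "exons_per_gene",
            "utr5_length",
            "cds_length",
            "intron_length",
            "utr3_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.te_fraction < 1.0:
            raise ValueError("te_fraction must be in [0, 1)")
        if self.cds_length % 3 != 0:
            raise ValueError(f"cds_length must be divisible by 3, got {self.cds_length}")

    @property
    def gene_span(self) -> int:
        return (
            self.utr5_length
            + self.cds_length
            + (self.exons_per_gene - 1) * self.intron_length
            + self.utr3_length
        )


@dataclass
class Transcript:
    """One transcript model; exactly one per synthetic gene.

    Interval lists are genomic, 0-based half-open, sorted by start.
    """

    tx_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    utr5: tuple[int, int]
    cds_exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    utr3: tuple[int, int]

    @property
    def start(self) -> int:
        return min(self.utr5[0], self.utr3[0], self.cds_exons[0][0])

    @property
    def end(self) -> int:
        return max(self.utr5[1], self.utr3[1], self.cds_exons[-1][1])

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    def exons(self) -> list[tuple[int, int]]:
        """Genomic exon blocks (UTR+CDS merged, introns excluded)."""
        pieces = sorted([self.utr5, self.utr3] + list(self.cds_exons))
        merged: list[list[int]] = []
        for s, e in pieces:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def cds_sequence(self, genome: dict[str, str]) -> str:
        """Spliced CDS in transcript (5'->3') orientation."""
        seq = "".join(genome[self.chrom][s:e] for s, e in self.cds_exons)
        return revcomp(seq) if self.strand == "-" else seq

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a genomic 0-based position to a 0-based CDS offset, or None."""
        off = 0
        exons = self.cds_exons if self.strand == "+" else self.cds_exons[::-1]
        for s, e in exons:
            if s <= pos0 < e:
                if self.strand == "+":
                    return off + (pos0 - s)
                return off + (e - 1 - pos0)
            off += e - s
        return None


@dataclass
class RepeatInterval:
    chrom: str
    start: int
    end: int
    name: str  # 'TE' or 'Simple_repeat'

    @property
    def is_te(self) -> bool:
        return self.name == "TE"


@dataclass
class ReferenceBundle:
    """Genome sequence plus annotation, held fully in memory.

    ``feat``/``gene_strand`` are per-chromosome arrays giving, for every
    position, its feature class code and the strand of the covering gene
    (0 none, 1 '+', 2 '-').  ``repeat_mask``/``te_mask`` are boolean arrays.
    """

    chroms: dict[str, str]
    transcripts: list[Transcript]
    repeats: list[RepeatInterval]
    spec: GenomeSpec | None = None
    codes: dict[str, np.ndarray] = field(default_factory=dict)
    feat: dict[str, np.ndarray] = field(default_factory=dict)
    gene_strand: dict[str, np.ndarray] = field(default_factory=dict)
    repeat_mask: dict[str, np.ndarray] = field(default_factory=dict)
    te_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.codes:
            self._build_arrays()

    def _build_arrays(self) -> None:
        table = np.full(256, 255, dtype=np.uint8)
        for b, i in BASE_TO_CODE.items():
            table[ord(b)] = i
        for name, seq in self.chroms.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            self.codes[name] = table[arr]
            L = len(seq)
            self.feat[name] = np.zeros(L, dtype=np.uint8)
            self.gene_strand[name] = np.zeros(L, dtype=np.int8)
            self.repeat_mask[name] = np.zeros(L, dtype=bool)
            self.te_mask[name] = np.zeros(L, dtype=bool)
        # ranked passes enforce CDS > UTR > intron precedence across
        # overlapping transcripts
        for tx in self.transcripts:
            f = self.feat[tx.chrom]
            for s, e in tx.introns:
                f[s:e] = FEAT_INTRON
        for tx in self.transcripts:
            f = self.feat[tx.chrom]
            s5, e5 = tx.utr5
            f[s5:e5] = FEAT_UTR5
            s3, e3 = tx.utr3
            f[s3:e3] = FEAT_UTR3
        for tx in self.transcripts:
            f = self.feat[tx.chrom]
            gs = self.gene_strand[tx.chrom]
            for s, e in tx.cds_exons:
                f[s:e] = FEAT_CDS
            gs[tx.start : tx.end] = 1 if tx.strand == "+" else 2
        for rp in self.repeats:
            self.repeat_mask[rp.chrom][rp.start : rp.end] = True
            if rp.is_te:
                self.te_mask[rp.chrom][rp.start : rp.end] = True

    # -- queries ---------------------------------------------------------

    def base(self, chrom: str, pos0: int) -> str:
        return self.chroms[chrom][pos0]

    def transcript_base(self, chrom: str, pos0: int, strand: str) -> str:
        b = self.chroms[chrom][pos0]
        return COMPLEMENT[b] if strand == "-" else b

    def feature_at(self, chrom: str, pos0: int) -> str:
        return FEAT_NAMES[int(self.feat[chrom][pos0])]

    def transcripts_at(self, chrom: str, pos0: int) -> list[Transcript]:
        return [
            t for t in self.transcripts if t.chrom == chrom and t.start <= pos0 < t.end
        ]

    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    # -- writers ---------------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        """1-based, closed intervals; gene/transcript/exon/CDS/UTR lines."""

        def line(chrom, kind, s0, e0, strand, gid, tid=None):
            attrs = f'gene_id "{gid}";'
            if tid:
                attrs += f' transcript_id "{tid}";'
            return f"{chrom}\teditome\t{kind}\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attrs}\n"

        with open(path, "w") as fh:
            for tx in self.transcripts:
                fh.write(line(tx.chrom, "gene", tx.start, tx.end, tx.strand, tx.gene_id))
                fh.write(
                    line(tx.chrom, "transcript", tx.start, tx.end, tx.strand, tx.gene_id, tx.tx_id)
                )
                for s, e in tx.exons():
                    fh.write(line(tx.chrom, "exon", s, e, tx.strand, tx.gene_id, tx.tx_id))
                for s, e in tx.cds_exons:
                    fh.write(line(tx.chrom, "CDS", s, e, tx.strand, tx.gene_id, tx.tx_id))
                s, e = tx.utr5
                fh.write(line(tx.chrom, "five_prime_utr", s, e, tx.strand, tx.gene_id, tx.tx_id))
                s, e = tx.utr3
                fh.write(line(tx.chrom, "three_prime_utr", s, e, tx.strand, tx.gene_id, tx.tx_id))

    def write_repeats_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rp in self.repeats:
                fh.write(f"{rp.chrom}\t{rp.start}\t{rp.end}\t{rp.name}\n")

    def save(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": str(outdir / "genome.fa"),
            "gtf": str(outdir / "genes.gtf"),
            "bed": str(outdir / "repeats.bed"),
        }
        self.write_fasta(paths["fasta"])
        self.write_gtf(paths["gtf"])
        self.write_repeats_bed(paths["bed"])
        return paths

    # -- readers ---------------------------------------------------------

    @classmethod
    def from_files(cls, fasta: str | Path, gtf: str | Path, bed: str | Path | None = None) -> "ReferenceBundle":
        """Rebuild a bundle from FASTA + GTF (+ optional repeat BED)."""
        from pyfaidx import Fasta

        fa = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
        chroms = {name: str(fa[name][:]) for name in fa.keys()}

        per_tx: dict[str, dict] = {}
        with open(gtf) as fh:
            for raw in fh:
                if not raw.strip() or raw.startswith("#"):
                    continue
                f = raw.rstrip("\n").split("\t")
                chrom, kind, s1, e1, strand, attrs = f[0], f[2], int(f[3]), int(f[4]), f[6], f[8]
                if kind not in ("CDS", "five_prime_utr", "three_prime_utr"):
                    continue
                tid = gid = None
                for part in attrs.split(";"):
                    part = part.strip()
                    if part.startswith("gene_id"):
                        gid = part.split('"')[1]
                    elif part.startswith("transcript_id"):
                        tid = part.split('"')[1]
                rec = per_tx.setdefault(
                    tid, {"gene": gid, "chrom": chrom, "strand": strand, "CDS": [], "utr5": None, "utr3": None}
                )
                iv = (s1 - 1, e1)
                if kind == "CDS":
                    rec["CDS"].append(iv)
                elif kind == "five_prime_utr":
                    rec["utr5"] = iv
                else:
                    rec["utr3"] = iv

        transcripts = []
        for tid, rec in per_tx.items():
            cds = sorted(rec["CDS"])
            introns = [(cds[i][1], cds[i + 1][0]) for i in range(len(cds) - 1)]
            transcripts.append(
                Transcript(
                    tx_id=tid,
                    gene_id=rec["gene"],
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    utr5=rec["utr5"],
                    cds_exons=cds,
                    introns=introns,
                    utr3=rec["utr3"],
                )
            )
        transcripts.sort(key=lambda t: (t.chrom, t.start))

        repeats = []
        if bed is not None:
            with open(bed) as fh:
                for raw in fh:
                    if not raw.strip():
                        continue
                    f = raw.split("\t")
                    name = f[3].strip() if len(f) > 3 else "TE"
                    repeats.append(RepeatInterval(f[0], int(f[1]), int(f[2]), name))
        return cls(chroms=chroms, transcripts=transcripts, repeats=repeats)


def build_reference(spec: GenomeSpec) -> ReferenceBundle:
    """Generate a random genome with non-overlapping gene models and repeats.

    Deterministic under ``spec.seed``.  Raises :class:`SizingError` when the
    requested genes plus minimum intergenic gaps exceed the chromosome length.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    chroms: dict[str, str] = {}
    transcripts: list[Transcript] = []
    repeats: list[RepeatInterval] = []

    # split genes across chromosomes as evenly as possible
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1

    gene_no = 0
    for ci in range(spec.n_chroms):
        name = f"chr{ci + 1}"
        codes = rng.choice(4, size=spec.chrom_length, p=probs)
        seq = "".join(BASES[c] for c in codes)
        chroms[name] = seq

        n_genes = per_chrom[ci]
        span = spec.gene_span
        free = spec.chrom_length - n_genes * span
        min_gap = spec.min_intergenic_gap
        if free < (n_genes + 1) * min_gap:
            raise SizingError(
                f"{n_genes} genes of span {span} bp plus {min_gap} bp gaps "
                f"do not fit in {spec.chrom_length} bp"
            )
        extra = rng.multinomial(free - (n_genes + 1) * min_gap, np.full(n_genes + 1, 1 / (n_genes + 1)))
        gaps = extra + min_gap

        pos = 0
        intergenic: list[tuple[int, int]] = []
        for gi in range(n_genes):
            intergenic.append((pos, pos + gaps[gi]))
            pos += gaps[gi]
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(_layout_gene(f"g{gene_no}", name, pos, strand, spec))
            pos += span
        intergenic.append((pos, pos + gaps[n_genes]))

        repeats.extend(_place_repeats(name, intergenic, spec, rng))

    return ReferenceBundle(chroms=chroms, transcripts=transcripts, repeats=repeats, spec=spec)


def _layout_gene(gene_id: str, chrom: str, start: int, strand: str, spec: GenomeSpec) -> Transcript:
    # transcript-order segments: utr5, cds/intron alternation, utr3
    n_ex = spec.exons_per_gene
    ex_sizes = [spec.cds_length // n_ex] * n_ex
    for i in range(spec.cds_length % n_ex):
        ex_sizes[i] += 1
    segs: list[tuple[str, int]] = [("utr5", spec.utr5_length)]
    for i, sz in enumerate(ex_sizes):
        segs.append(("cds", sz))
        if i < n_ex - 1:
            segs.append(("intron", spec.intron_length))
    segs.append(("utr3", spec.utr3_length))
    if strand == "-":
        segs = segs[::-1]

    pos = start
    utr5 = utr3 = None
    cds_exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    for kind, sz in segs:
        iv = (pos, pos + sz)
        if kind == "utr5":
            utr5 = iv
        elif kind == "utr3":
            utr3 = iv
        elif kind == "cds":
            cds_exons.append(iv)
        else:
            introns.append(iv)
        pos += sz
    return Transcript(
        tx_id=f"{gene_id}.t1",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        utr5=utr5,
        cds_exons=sorted(cds_exons),
        introns=sorted(introns),
        utr3=utr3,
    )


def _place_repeats(
    chrom: str, intergenic: list[tuple[int, int]], spec: GenomeSpec, rng: np.random.Generator
) -> list[RepeatInterval]:
    """Cover ~te_fraction of intergenic bp with repeat intervals."""
    total_inter = sum(e - s for s, e in intergenic)
    target = int(round(spec.te_fraction * total_inter))
    repeats: list[RepeatInterval] = []
    placed = 0
    # lay repeats left-to-right inside each gap, skipping random spacers,
    # so intervals never overlap and coverage tracks the target closely
    for s, e in intergenic:
        if placed >= target:
            break
        gap_quota = int(round((e - s) / total_inter * target))
        pos = s
        got = 0
        while got < gap_quota and pos < e - 50:
            spacer = int(rng.integers(20, 200))
            length = int(rng.integers(150, 600))
            start = pos + spacer
            end = min(start + length, e, start + (gap_quota - got))
            if end <= start:
                break
            name = "Simple_repeat" if rng.random() < spec.simple_repeat_fraction else "TE"
            repeats.append(RepeatInterval(chrom, start, end, name))
            got += end - start
            pos = end
        placed += got
    return repeats
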