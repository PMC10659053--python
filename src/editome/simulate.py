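"""Planted-truth simulation: edit/SNP scenarios and stranded read generation.

The generator emulates the study design this package analyses: a small
homozygous-reference genome carrying heterozygous/homozygous SNPs, A-to-I
editing sites with per-condition editing levels across genomic feature
classes, clustered hyper-edited reads dense enough to defeat a mismatch-capped
aligner, a dinucleotide-context bias around edits, and a replicate structure
of several acclimation temperatures and tissues.

Reads are emitted pre-aligned with correct coordinates (ungapped, M-only
CIGAR); upstream alignment is simulated, not computed, so the downstream
filters are exercised in isolation.  Reads whose mismatch count exceeds the
aligner cap are emitted as unmapped records — the hyper-editing premise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .reference import BASES, COMPLEMENT, FEAT_CODES, FEAT_NAMES, ReferenceBundle

# default allocation of edit sites to feature classes; proportions follow the
# genomic-region distribution typical of a vertebrate editome, where most
# sites fall in intergenic repeats and introns
DEFAULT_FEATURE_WEIGHTS = {
    "intergenic": 0.5113,
    "intron": 0.2716,
    "3UTR": 0.1910,
    "CDS": 0.0195,
    "5UTR": 0.0066,
}

DEFAULT_CONDITIONS = ("T27", "T18", "T13")
DEFAULT_TISSUES = ("brain", "ovary")


class PlacementError(ValueError):
    """An edit was requested at a position that is not an adenosine on the
    transcript strand."""


class CollisionError(ValueError):
    """An edit and a SNP were requested at the same position."""


@dataclass(frozen=True)
class PlannedEdit:
    chrom: str
    pos: int  # 0-based
    strand: str
    levels: dict[str, float]  # condition -> true editing level
    tissues: tuple[str, ...]
    in_hyper: bool = False


@dataclass(frozen=True)
class PlannedSNP:
    chrom: str
    pos: int  # 0-based
    alt: str
    genotype: str  # 'het' | 'hom'


@dataclass(frozen=True)
class HyperCluster:
    cluster_id: int
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    positions: tuple[int, ...]  # 0-based genomic positions of cluster adenosines
    per_read_edit_prob: float
    n_reads: int


@dataclass
class EditScenario:
    """A fully explicit experimental scenario: which sites are edited, at what
    level per condition, which positions are SNPs, and where hyper-edited
    clusters sit."""

    sites: list[PlannedEdit]
    snps: list[PlannedSNP]
    hyper_clusters: list[HyperCluster]
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    upstream_A_bias: float = 0.9
    downstream_G_bias: float = 0.5


@dataclass(frozen=True)
class ReadSimParams:
    """Read-generation parameters.

    ``base_quality`` is the constant Phred score written for every base (the
    quality model maps the nominal error rate to a single score; errors are
    injected independently at ``base_error_rate``).  Under the ``forward``
    strandedness protocol the alignment strand of a read equals the transcript
    strand of its source.  ``aligner_mismatch_cap`` is the mismatch count
    above which a read is emitted unmapped, mimicking aligner failure on
    hyper-edited reads.
    """

    read_length: int = 150
    coverage_dna: float = 30.0
    coverage_rna: float = 50.0
    base_error_rate: float = 0.001
    base_quality: int = 37
    strandedness: str = "forward"
    aligner_mismatch_cap: int = 4
    paired: bool = False
    seed: int = 7

    def __post_init__(self) -> None:
        if self.coverage_dna <= 0 or self.coverage_rna <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.base_error_rate <= 0.05:
            raise ValueError("base_error_rate must be in [0, 0.05]")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")


@dataclass
class ScenarioTruth:
    """The evaluation oracle: every planted SNP and edit with its true level
    per condition, plus hyper-cluster membership."""

    edits: pd.DataFrame
    snps: pd.DataFrame
    hyper_sites: pd.DataFrame
    conditions: tuple[str, ...]
    tissues: tuple[str, ...]
    replicates_per_condition: int
    hyper_clusters: list[HyperCluster] = field(default_factory=list)
    n_rejected_collisions: int = 0

    def write_tsv(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "edits": str(outdir / "truth_edits.tsv"),
            "snps": str(outdir / "truth_snps.tsv"),
            "hyper": str(outdir / "truth_hyper_sites.tsv"),
        }
        self.edits.to_csv(paths["edits"], sep="\t", index=False)
        self.snps.to_csv(paths["snps"], sep="\t", index=False)
        self.hyper_sites.to_csv(paths["hyper"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# scenario generation
# ---------------------------------------------------------------------------


def _context_masks(ref: ReferenceBundle, chrom: str, strand: str):
    """Boolean masks over a chromosome: is-A, upstream-A and downstream-G in
    transcript orientation for the given strand."""
    c = ref.codes[chrom]
    L = len(c)
    ok = np.zeros(L, dtype=bool)
    ok[1 : L - 1] = True  # keep a neighbour on both sides
    if strand == "+":
        is_a = c == 0
        up_a = np.roll(c, 1) == 0  # genome pos-1 is A
        down_g = np.roll(c, -1) == 2  # genome pos+1 is G
    else:
        is_a = c == 3  # genome T is transcript A
        up_a = np.roll(c, -1) == 3  # transcript upstream = genome pos+1, comp(T)=A
        down_g = np.roll(c, 1) == 1  # transcript downstream = genome pos-1, comp(C)=G
    return is_a & ok, up_a, down_g


class _Pools:
    """Shuffled candidate-position pools keyed by
    (feature, transcript strand, in-TE, upstream-A, downstream-G)."""

    def __init__(self, ref: ReferenceBundle, rng: np.random.Generator):
        self.pools: dict[tuple, list] = {}
        for chrom in ref.chroms:
            feat = ref.feat[chrom]
            gstrand = ref.gene_strand[chrom]
            te = ref.te_mask[chrom] | ref.repeat_mask[chrom]
            for strand in "+-":
                is_a, up_a, down_g = _context_masks(ref, chrom, strand)
                scode = 1 if strand == "+" else 2
                for fname, fcode in FEAT_CODES.items():
                    if fcode == 0:
                        base = is_a & (feat == 0)
                    else:
                        base = is_a & (feat == fcode) & (gstrand == scode)
                    for u in (False, True):
                        for d in (False, True):
                            for t in (False, True):
                                m = base & (up_a == u) & (down_g == d)
                                if fcode == 0:
                                    m = m & (te == t)
                                elif t:
                                    continue  # genic pools carry t=False only
                                idx = np.flatnonzero(m)
                                if idx.size:
                                    key = (fname, strand, t, u, d)
                                    lst = self.pools.setdefault(key, [])
                                    lst.extend((chrom, int(p)) for p in idx)
        for lst in self.pools.values():
            rng.shuffle(lst)

    def draw(self, feature, strand_pref, te, u, d, used: set, accept=None):
        """Pop an unused candidate, relaxing constraints (te, then motif, then
        strand) when the exact pool is exhausted.  ``accept(chrom, pos,
        strand)`` can veto candidates (e.g. spacing constraints)."""
        strands = [strand_pref] if strand_pref else ["+", "-"]
        trials = []
        for s in strands:
            trials.append((feature, s, te, u, d))
        for s in strands:  # relax TE
            trials.append((feature, s, not te, u, d))
        for s in strands:  # relax motif
            for uu in (u, not u):
                for dd in (d, not d):
                    for tt in (te, not te):
                        trials.append((feature, s, tt, uu, dd))
        for key in trials:
            lst = self.pools.get(key)
            while lst:
                chrom, pos = lst.pop()
                if (chrom, pos) in used:
                    continue
                if accept is not None and not accept(chrom, pos, key[1]):
                    continue
                used.add((chrom, pos))
                return chrom, pos, key[1]
        return None


def random_scenario(
    ref: ReferenceBundle,
    n_sites: int = 1000,
    n_snps: int = 100,
    n_hyper_clusters: int = 10,
    hyper_cluster_size: int = 8,
    hyper_reads_per_cluster: int = 20,
    hyper_per_read_edit_prob: float = 0.9,
    hyper_common_fraction: float = 0.25,
    level_range: tuple[float, float] = (0.1, 0.9),
    differential_fraction: float = 0.3,
    feature_weights: dict[str, float] | None = None,
    intergenic_te_fraction: float = 0.5,
    upstream_A_bias: float = 0.9,
    downstream_G_bias: float = 0.5,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    replicates_per_condition: int = 3,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    tissue_presence: float = 0.75,
    min_site_spacing: int = 30,
    seed: int = 7,
) -> EditScenario:
    """Draw a random scenario consistent with the reference annotation.

    Sites are placed at transcript-strand adenosines only; the upstream
    neighbour is adenosine with probability ``upstream_A_bias`` and the
    downstream neighbour guanosine with probability ``downstream_G_bias``.
    With probability ``differential_fraction`` a site's true level is drawn
    independently per condition (a temperature-responsive site); otherwise the
    same level is shared by all conditions.

    Normal sites on the same transcript strand keep at least
    ``min_site_spacing`` bp between them, so that a read carrying them stays
    below the aligner mismatch cap — densely edited regions that defeat
    alignment are modelled explicitly as ``hyper_clusters``, never by
    accident.
    """
    rng = np.random.default_rng(seed)
    weights = dict(feature_weights or DEFAULT_FEATURE_WEIGHTS)
    names = list(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    probs /= probs.sum()

    pools = _Pools(ref, rng)
    used: set[tuple[str, int]] = set()
    lo, hi = level_range

    # per-(chrom, strand) spacing bins for normal sites
    bins: dict[tuple[str, str], dict[int, list[int]]] = {}

    def spacing_ok(chrom: str, pos: int, strand: str) -> bool:
        if min_site_spacing <= 0:
            return True
        d = bins.setdefault((chrom, strand), {})
        b = pos // min_site_spacing
        return not any(
            abs(q - pos) < min_site_spacing
            for bb in (b - 1, b, b + 1)
            for q in d.get(bb, ())
        )

    def spacing_add(chrom: str, pos: int, strand: str) -> None:
        if min_site_spacing > 0:
            bins.setdefault((chrom, strand), {}).setdefault(pos // min_site_spacing, []).append(pos)

    def draw_levels() -> dict[str, float]:
        if rng.random() < differential_fraction:
            return {c: float(rng.uniform(lo, hi)) for c in conditions}
        lv = float(rng.uniform(lo, hi))
        return {c: lv for c in conditions}

    def draw_tissues() -> tuple[str, ...]:
        if len(tissues) == 1:
            return tuple(tissues)
        while True:
            picked = tuple(t for t in tissues if rng.random() < tissue_presence)
            if picked:
                return picked

    sites: list[PlannedEdit] = []
    for _ in range(n_sites):
        feature = names[rng.choice(len(names), p=probs)]
        u = bool(rng.random() < upstream_A_bias)
        d = bool(rng.random() < downstream_G_bias)
        te = feature == "intergenic" and rng.random() < intergenic_te_fraction
        if feature == "intergenic":
            strand_pref = "+" if rng.random() < 0.5 else "-"
            got = pools.draw(feature, strand_pref, te, u, d, used, accept=spacing_ok)
        else:
            got = pools.draw(feature, None, False, u, d, used, accept=spacing_ok)
        if got is None:
            continue
        chrom, pos, strand = got
        spacing_add(chrom, pos, strand)
        sites.append(
            PlannedEdit(chrom=chrom, pos=pos, strand=strand, levels=draw_levels(), tissues=draw_tissues())
        )

    # hyper-edited clusters inside genes (dense dsRNA-like windows)
    clusters: list[HyperCluster] = []
    genes = list(ref.transcripts)
    window = 90
    attempts = 0
    while len(clusters) < n_hyper_clusters and attempts < n_hyper_clusters * 20 and genes:
        attempts += 1
        tx = genes[int(rng.integers(len(genes)))]
        span = tx.end - tx.start - window
        if span <= 0:
            continue
        w0 = tx.start + int(rng.integers(span))
        c = ref.codes[tx.chrom][w0 : w0 + window]
        a_code = 0 if tx.strand == "+" else 3
        cand = np.flatnonzero(c == a_code) + w0
        cand = np.array([p for p in cand if (tx.chrom, int(p)) not in used])
        if cand.size < hyper_cluster_size:
            continue
        chosen = np.sort(rng.choice(cand, size=hyper_cluster_size, replace=False))
        for p in chosen:
            used.add((tx.chrom, int(p)))
        clusters.append(
            HyperCluster(
                cluster_id=len(clusters) + 1,
                chrom=tx.chrom,
                start=w0,
                end=w0 + window,
                strand=tx.strand,
                positions=tuple(int(p) for p in chosen),
                per_read_edit_prob=hyper_per_read_edit_prob,
                n_reads=hyper_reads_per_cluster,
            )
        )
        # a fraction of cluster positions are also normally edited -> common
        for p in chosen:
            if rng.random() < hyper_common_fraction:
                sites.append(
                    PlannedEdit(
                        chrom=tx.chrom,
                        pos=int(p),
                        strand=tx.strand,
                        levels=draw_levels(),
                        tissues=tuple(tissues),
                        in_hyper=True,
                    )
                )

    # SNPs anywhere, never colliding with a planted edit or cluster position
    snps: list[PlannedSNP] = []
    chrom_names = list(ref.chroms)
    while len(snps) < n_snps:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(1, len(ref.chroms[chrom]) - 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref_base = ref.chroms[chrom][pos]
        alt = BASES[int(rng.integers(4))]
        while alt == ref_base:
            alt = BASES[int(rng.integers(4))]
        genotype = "het" if rng.random() < 0.5 else "hom"
        snps.append(PlannedSNP(chrom=chrom, pos=pos, alt=alt, genotype=genotype))

    return EditScenario(
        sites=sites,
        snps=snps,
        hyper_clusters=clusters,
        conditions=tuple(conditions),
        replicates_per_condition=replicates_per_condition,
        tissues=tuple(tissues),
        upstream_A_bias=upstream_A_bias,
        downstream_G_bias=downstream_G_bias,
    )


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------


def plant_truth(
    ref: ReferenceBundle, scenario: EditScenario, on_collision: str = "error"
) -> ScenarioTruth:
    """Validate a scenario against the reference and freeze it into truth
    tables.

    Every edit must sit on a transcript-strand adenosine (genome A on '+',
    genome T on '-'); violating sites raise :class:`PlacementError`.  An edit
    co-located with a SNP raises :class:`CollisionError`, or is dropped and
    counted when ``on_collision='drop'``.
    """
    if on_collision not in ("error", "drop"):
        raise ValueError("on_collision must be 'error' or 'drop'")
    snp_positions = {(s.chrom, s.pos) for s in scenario.snps}

    rows = []
    rejected = 0
    for site in scenario.sites:
        L = len(ref.chroms[site.chrom])
        if not 0 <= site.pos < L:
            raise PlacementError(f"edit position {site.chrom}:{site.pos + 1} outside genome")
        tx_base = ref.transcript_base(site.chrom, site.pos, site.strand)
        if tx_base != "A":
            raise PlacementError(
                f"edit at {site.chrom}:{site.pos + 1}({site.strand}) is reference "
                f"{tx_base} on the transcript strand, not A"
            )
        if (site.chrom, site.pos) in snp_positions:
            if on_collision == "error":
                raise CollisionError(
                    f"edit and SNP both requested at {site.chrom}:{site.pos + 1}"
                )
            rejected += 1
            continue
        up = down = "N"
        if 0 < site.pos < L - 1:
            if site.strand == "+":
                up = ref.chroms[site.chrom][site.pos - 1]
                down = ref.chroms[site.chrom][site.pos + 1]
            else:
                up = COMPLEMENT[ref.chroms[site.chrom][site.pos + 1]]
                down = COMPLEMENT[ref.chroms[site.chrom][site.pos - 1]]
        row = {
            "chrom": site.chrom,
            "pos": site.pos + 1,
            "strand": site.strand,
            "genome_ref": ref.chroms[site.chrom][site.pos],
            "feature": FEAT_NAMES[int(ref.feat[site.chrom][site.pos])],
            "repeat": bool(ref.repeat_mask[site.chrom][site.pos]),
            "te": bool(ref.te_mask[site.chrom][site.pos]),
            "upstream": up,
            "downstream": down,
            "tissues": ",".join(site.tissues),
            "in_hyper": site.in_hyper,
        }
        for cond in scenario.conditions:
            row[f"level_{cond}"] = site.levels[cond]
        rows.append(row)

    edit_cols = [
        "chrom", "pos", "strand", "genome_ref", "feature", "repeat", "te",
        "upstream", "downstream", "tissues", "in_hyper",
    ] + [f"level_{c}" for c in scenario.conditions]
    edits = pd.DataFrame(rows, columns=edit_cols)
    if len(edits):
        edits = edits.sort_values(["chrom", "pos"]).reset_index(drop=True)

    snps = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos + 1,
                "ref": ref.chroms[s.chrom][s.pos],
                "alt": s.alt,
                "genotype": s.genotype,
            }
            for s in scenario.snps
        ],
        columns=["chrom", "pos", "ref", "alt", "genotype"],
    )

    hyper_rows = []
    for cl in scenario.hyper_clusters:
        for p in cl.positions:
            if ref.transcript_base(cl.chrom, p, cl.strand) != "A":
                raise PlacementError(
                    f"hyper-cluster position {cl.chrom}:{p + 1}({cl.strand}) is not a "
                    "transcript-strand adenosine"
                )
            hyper_rows.append(
                {
                    "cluster": cl.cluster_id,
                    "chrom": cl.chrom,
                    "pos": p + 1,
                    "strand": cl.strand,
                    "per_read_prob": cl.per_read_edit_prob,
                    "n_reads": cl.n_reads,
                }
            )
    hyper_sites = pd.DataFrame(
        hyper_rows, columns=["cluster", "chrom", "pos", "strand", "per_read_prob", "n_reads"]
    )

    return ScenarioTruth(
        edits=edits,
        snps=snps,
        hyper_sites=hyper_sites,
        conditions=tuple(scenario.conditions),
        tissues=tuple(scenario.tissues),
        replicates_per_condition=scenario.replicates_per_condition,
        hyper_clusters=list(scenario.hyper_clusters),
        n_rejected_collisions=rejected,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReads:
    rna_sam: str | None = None
    unmapped_sam: str | None = None
    dna_sam: str | None = None
    counts: dict = field(default_factory=dict)


def _derive_seed(base: int, *labels) -> np.random.SeedSequence:
    parts = [int(base) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            parts.append(zlib.crc32(lab.encode()))
        else:
            parts.append(int(lab) & 0x7FFFFFFF)
    return np.random.SeedSequence(parts)


def _sam_header(ref: ReferenceBundle) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in ref.chroms.items()],
        }
    )


_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(row: np.ndarray) -> str:
    return _BASE_BYTES[row].tobytes().decode()


class _SamEmitter:
    def __init__(self, path: str, header: pysam.AlignmentHeader, base_quality: int, read_length: int):
        self.fh = pysam.AlignmentFile(path, "w", header=header)
        self.header = header
        self.qual = pysam.qualitystring_to_array(chr(base_quality + 33) * read_length)

    def aligned(self, name: str, chrom: str, start0: int, codes: np.ndarray, reverse: bool):
        a = pysam.AlignedSegment(self.header)
        a.query_name = name
        a.query_sequence = _codes_to_str(codes)
        a.flag = 16 if reverse else 0
        a.reference_id = self.header.get_tid(chrom)
        a.reference_start = start0
        a.mapping_quality = 60
        a.cigartuples = [(0, len(codes))]
        a.query_qualities = self.qual[: len(codes)]
        self.fh.write(a)

    def unmapped(self, name: str, codes: np.ndarray, reverse_source: bool):
        # SEQ of an unmapped read is in sequencing orientation: reads from a
        # '-' strand source are reverse-complemented relative to the genome
        if reverse_source:
            codes = _COMP_CODE[codes[::-1]]
        a = pysam.AlignedSegment(self.header)
        a.query_name = name
        a.query_sequence = _codes_to_str(codes)
        a.flag = 4
        a.mapping_quality = 0
        a.query_qualities = self.qual[: len(codes)]
        self.fh.write(a)

    def close(self):
        self.fh.close()


def _transcription_units(ref: ReferenceBundle, truth: ScenarioTruth, tissue: str | None):
    """Gene spans plus intergenic windows around orphan edits, each with a
    transcript strand; every planted edit lies in exactly one unit of its
    strand."""
    pad = 250
    units: list[dict] = []
    for tx in ref.transcripts:
        units.append({"chrom": tx.chrom, "start": tx.start, "end": tx.end, "strand": tx.strand})

    def in_gene_unit(chrom, pos0, strand):
        return any(
            u["chrom"] == chrom and u["start"] <= pos0 < u["end"] and u["strand"] == strand
            for u in units[: len(ref.transcripts)]
        )

    extra: dict[tuple[str, str], list[list[int]]] = {}
    for _, row in truth.edits.iterrows():
        pos0 = int(row["pos"]) - 1
        if in_gene_unit(row["chrom"], pos0, row["strand"]):
            continue
        key = (row["chrom"], row["strand"])
        L = len(ref.chroms[row["chrom"]])
        iv = [max(0, pos0 - pad), min(L, pos0 + pad + 1)]
        extra.setdefault(key, []).append(iv)
    for (chrom, strand), ivs in extra.items():
        ivs.sort()
        merged = [ivs[0]]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            units.append({"chrom": chrom, "start": s, "end": e, "strand": strand})
    return units


def _active_edits(truth: ScenarioTruth, tissue: str | None, condition: str):
    """(chrom, pos0, strand) -> (target genome base code, true level)."""
    out: dict[tuple[str, int, str], tuple[int, float]] = {}
    for _, row in truth.edits.iterrows():
        if tissue is not None and row["tissues"]:
            if tissue not in str(row["tissues"]).split(","):
                continue
        # A->G on the transcript strand: genome A->G on '+', genome T->C on '-'
        target = 2 if row["strand"] == "+" else 1
        out[(row["chrom"], int(row["pos"]) - 1, row["strand"])] = (
            target,
            float(row[f"level_{condition}"]),
        )
    return out


def _apply_errors(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    if error_rate <= 0:
        return
    err = rng.random(reads.shape) < error_rate
    idx = np.nonzero(err)
    if idx[0].size:
        shift = rng.integers(1, 4, size=idx[0].size).astype(np.uint8)
        reads[idx] = (reads[idx] + shift) % 4


def simulate_rna_reads(
    ref: ReferenceBundle,
    truth: ScenarioTruth,
    params: ReadSimParams,
    condition: str,
    replicate: int,
    tissue: str | None = None,
    outdir: str | Path = ".",
) -> SimulatedReads:
    """Simulate one stranded RNA library for (condition, replicate[, tissue]).

    Each read covering an edit site carries the edited base independently with
    probability equal to the site's true level in that condition; reads also
    carry SNP alleles per genotype and uniform base errors.  Reads exceeding
    the aligner mismatch cap are written unmapped (hyper-edited reads by
    construction); all others are written pre-aligned.
    """
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}; scenario has {truth.conditions}")
    if params.strandedness != "forward":
        raise ValueError(f"unknown strandedness protocol {params.strandedness!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{tissue + '.' if tissue else ''}{condition}.r{replicate}"
    rng = np.random.default_rng(_derive_seed(params.seed, "rna", condition, replicate, tissue or ""))
    header = _sam_header(ref)
    L = params.read_length

    rna_path = str(outdir / f"rna.{tag}.sam")
    unmapped_path = str(outdir / f"unmapped.{tag}.sam")
    em = _SamEmitter(rna_path, header, params.base_quality, L)
    em_un = _SamEmitter(unmapped_path, header, params.base_quality, L)

    edits = _active_edits(truth, tissue, condition)
    snps = [
        (row["chrom"], int(row["pos"]) - 1, BASES.index(row["alt"]), row["genotype"])
        for _, row in truth.snps.iterrows()
    ]

    counts = {"aligned": 0, "unmapped": 0, "mapped_bases": 0}
    read_no = 0
    for unit in _transcription_units(ref, truth, tissue):
        chrom, us, ue, strand = unit["chrom"], unit["start"], unit["end"], unit["strand"]
        clen = len(ref.chroms[chrom])
        if ue - us < L:  # pad short units so full-length reads fit
            mid = (us + ue) // 2
            us, ue = max(0, mid - L), min(clen, mid + L)
        n_reads = int(round(params.coverage_rna * (ue - us) / L))
        if n_reads == 0:
            continue
        starts = rng.integers(us, ue - L + 1, size=n_reads)
        seg = ref.codes[chrom]
        orig = seg[starts[:, None] + np.arange(L)[None, :]]
        reads = orig.copy()
        for (echrom, epos, estrand), (target, level) in edits.items():
            if echrom != chrom or estrand != strand:
                continue
            col = epos - starts
            covered = (col >= 0) & (col < L)
            if not covered.any():
                continue
            flip = covered & (rng.random(n_reads) < level)
            reads[flip, col[flip]] = target
        for schrom, spos, alt_code, genotype in snps:
            if schrom != chrom:
                continue
            col = spos - starts
            covered = (col >= 0) & (col < L)
            if not covered.any():
                continue
            carry = covered if genotype == "hom" else covered & (rng.random(n_reads) < 0.5)
            reads[carry, col[carry]] = alt_code
        _apply_errors(reads, params.base_error_rate, rng)
        mm = (reads != orig).sum(axis=1)
        reverse = strand == "-"
        for i in range(n_reads):
            read_no += 1
            name = f"rna.{tag}.{read_no}"
            if mm[i] > params.aligner_mismatch_cap:
                em_un.unmapped(name, reads[i], reverse)
                counts["unmapped"] += 1
            else:
                em.aligned(name, chrom, int(starts[i]), reads[i], reverse)
                counts["aligned"] += 1
                counts["mapped_bases"] += L

    # hyper-edited cluster reads: dense A->G within a window, per-read edits
    for cl in truth.hyper_clusters:
        seg = ref.codes[cl.chrom]
        clen = len(ref.chroms[cl.chrom])
        span = cl.end - cl.start
        if span <= L:
            lo = max(0, cl.end - L)
            hi = min(cl.start, clen - L)
            hi = max(hi, lo)
        else:
            lo, hi = cl.start, cl.end - L
        starts = rng.integers(lo, hi + 1, size=cl.n_reads)
        orig = seg[starts[:, None] + np.arange(L)[None, :]]
        reads = orig.copy()
        target = 2 if cl.strand == "+" else 1
        for p in cl.positions:
            col = p - starts
            covered = (col >= 0) & (col < L)
            flip = covered & (rng.random(cl.n_reads) < cl.per_read_edit_prob)
            reads[flip, col[flip]] = target
        _apply_errors(reads, params.base_error_rate, rng)
        mm = (reads != orig).sum(axis=1)
        reverse = cl.strand == "-"
        for i in range(cl.n_reads):
            read_no += 1
            name = f"rna.{tag}.hc{cl.cluster_id}.{read_no}"
            if mm[i] > params.aligner_mismatch_cap:
                em_un.unmapped(name, reads[i], reverse)
                counts["unmapped"] += 1
            else:
                em.aligned(name, cl.chrom, int(starts[i]), reads[i], reverse)
                counts["aligned"] += 1
                counts["mapped_bases"] += L

    em.close()
    em_un.close()
    return SimulatedReads(rna_sam=rna_path, unmapped_sam=unmapped_path, counts=counts)


def simulate_dna_reads(
    ref: ReferenceBundle,
    truth: ScenarioTruth,
    params: ReadSimParams,
    outdir: str | Path = ".",
) -> SimulatedReads:
    """Simulate genomic DNA-seq: uniform coverage, SNP alleles per genotype,
    base errors, never any edit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_derive_seed(params.seed, "dna"))
    header = _sam_header(ref)
    L = params.read_length
    dna_path = str(outdir / "dna.sam")
    em = _SamEmitter(dna_path, header, params.base_quality, L)
    snps = [
        (row["chrom"], int(row["pos"]) - 1, BASES.index(row["alt"]), row["genotype"])
        for _, row in truth.snps.iterrows()
    ]
    counts = {"aligned": 0, "mapped_bases": 0}
    read_no = 0
    for chrom, seq in ref.chroms.items():
        clen = len(seq)
        n_reads = int(round(params.coverage_dna * clen / L))
        starts = rng.integers(0, clen - L + 1, size=n_reads)
        seg = ref.codes[chrom]
        reads = seg[starts[:, None] + np.arange(L)[None, :]].copy()
        for schrom, spos, alt_code, genotype in snps:
            if schrom != chrom:
                continue
            col = spos - starts
            covered = (col >= 0) & (col < L)
            carry = covered if genotype == "hom" else covered & (rng.random(n_reads) < 0.5)
            reads[carry, col[carry]] = alt_code
        _apply_errors(reads, params.base_error_rate, rng)
        rev = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            read_no += 1
            em.aligned(f"dna.{read_no}", chrom, int(starts[i]), reads[i], bool(rev[i]))
            counts["aligned"] += 1
            counts["mapped_bases"] += L
    em.close()
    return SimulatedReads(dna_sam=dna_path, counts=counts)


def simulate_reads(
    ref: ReferenceBundle,
    truth: ScenarioTruth,
    params: ReadSimParams,
    condition: str,
    replicate: int,
    tissue: str | None = None,
    outdir: str | Path = ".",
    include_dna: bool = True,
) -> SimulatedReads:
    """Convenience wrapper: one RNA library plus (optionally) the DNA set."""
    rna = simulate_rna_reads(ref, truth, params, condition, replicate, tissue, outdir)
    if include_dna:
        dna = simulate_dna_reads(ref, truth, params, outdir)
        rna.dna_sam = dna.dna_sam
        rna.counts["dna_aligned"] = dna.counts["aligned"]
        rna.counts["dna_mapped_bases"] = dna.counts["mapped_bases"]
    return rna
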