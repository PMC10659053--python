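# Methods

This note documents the models and procedures implemented in `editome`, the
parameters that matter, what the synthetic data does and does not emulate,
and the design choices made where the design was genuinely open.

## Detection model

### Read-level filters (pileup)

Every aligned base contributes to the per-position, per-strand base counts
iff

1. its 1-based offset within the read lies in `[trim_bases+1, L−trim_bases]`
   (default `trim_bases = 6`) — read ends are enriched for alignment and
   chemistry artifacts;
2. its Phred quality is ≥ `min_base_quality` (default 30, i.e. a nominal
   0.1% error floor);
3. the read is uniquely aligned: mapping quality > 0 and not flagged
   secondary/supplementary (`unique_only = true`). This is the conventional
   operationalisation of "unique alignment"; the flag is configurable.

The 6-base trim is applied to DNA reads as well as RNA for symmetry; this is
configurable. Transcript strand is decoded from the stranded library
protocol; the implemented protocol (`forward`) equates the alignment strand
of a single-end read with the transcript strand. Counts for genes on the
`−` strand are kept in genome base space and complemented at interpretation
time, so a genomic T→C pile on a `−` strand transcript is an A→G event in
transcript space.

### SNP masking from DNA

A position is **masked** (treated as genomic variation, never an edit) iff
its filtered DNA depth is ≥ `min_dna_depth` (default 10) *and* some
non-reference base has ≥ `min_alt_reads` (default 2) supporting reads. A
position with DNA depth below the floor is **uncallable** and likewise
excluded — its genotype cannot be confirmed, which is the conservative
choice. Defaults quantify "supported by a sufficient number of reads" and
are echoed into the run manifest.

### Normal site calling

A candidate site must: not be masked or uncallable; have RNA depth ≥
`min_rna_depth` (default 10); show exactly one alternate base; and carry ≥
`min_edited_reads` (default 3) alternate reads. A second alternate base
counts as "observed" (triggering the multi-variant exclusion) only at ≥
`noise_alt_threshold` (default 2) reads — a literal "any second variant"
rule degenerates at high depth, where a single sequencing error at one read
would veto a real site. Surviving candidates are tested one-sided against
the sequencing error rate, `P(X ≥ k | n = depth, p = error_rate)` with
`error_rate = 0.001` matching the Phred-30 floor, and the candidate set is
thinned by Benjamini–Hochberg at `fdr = 0.05`.

Calls are then re-checked at the read level: an internal k-mer
seed-and-extend aligner (exact 16-mers, ungapped extension, both
orientations) realigns every supporting read; a read is ambiguous when a
second locus scores ≥ 95% of its best locus. Ambiguous reads stop counting
as support, and a site is dropped when its unique support falls below
`min_edited_reads`. Setting the margin to `None` disables the filter. This
replaces an external BLAT dependency while preserving the contract (drop
calls supported only by multi-mapping reads).

### Hyper-editing recovery

Reads that fail normal alignment are realigned in a transformed space:
every A in the read and in the genome is rewritten to G, which erases A→G
mismatches while leaving others visible. Both transcript strands are
searched — the read itself against the A→G genome (`+` transcripts) and its
reverse complement, T→C-transformed, against the T→C genome (`−`
transcripts; transcript A→G appears as genomic T→C on the minus strand).
Placement uses exact k-mer seeds (default k = 16) with ungapped extension
and must be unique (strictly fewer transformed mismatches than any other
seeded placement). The original read is then compared with the original
genome: transcript-space genome-A/read-G differences are recovered edits;
anything else counts against `max_other_mm` (default 1).

A read survives the cluster filter iff it carries ≥ `min_edits_per_read`
(default 5) recovered edits covering ≥ `min_edit_fraction` (default 0.05)
of the adenosines in its span; kept reads are aggregated into per-position
hyper (RHES) site rows. These defaults make planted clusters recoverable
while the error-only null stays empty; they are configurable and logged.
Merging with normal calls marks sites found by both routes `common`
(counted once, normal-mode counts kept); the reported triple satisfies
`|union| = |RES| + |RHES| − |common|` exactly, and same-position calls with
conflicting alleles across modes are excluded and logged.

## Quantification

* **Editing level** per site: `G/(G+A)` read counts.
* **Overall editing level** of a site set: `ΣG/Σ(A+G)` — algebraically the
  coverage-weighted mean of per-site levels; the identity is asserted in
  tests to machine precision. All level-type statistics enforce a minimum
  A+G coverage of 10; plain site counts do not.
* **Sites per Mb**: `n_sites / (mapped_bases / 10⁶)` — sequencing-effort
  normalised density.
* **Editing index** over repeats: `ΣG/Σ(A+G)` across *all* transcript-strand
  adenosine positions inside repeat (or TE-only) intervals, a site-list-free
  global measure. The denominator uses A+G reads for consistency with the
  level definition; a `denominator="total"` flag switches to total filtered
  depth, since published descriptions are ambiguous on this point.
* **Feature annotation**: one class per site with precedence
  CDS > UTR > intron > intergenic across overlapping transcripts; A→G CDS
  sites are split synonymous/non-synonymous via codon consequence (stop
  gain/loss counts as non-synonymous at region level). Repeat and TE flags
  are independent of the class; "repeat" means any interval in the repeat
  BED, "TE" the subset so named.
* **Motif matrix**: −1/0/+1 neighbour frequencies in transcript orientation
  (reverse-complemented for `−` strand sites); position 0 is the edited A by
  construction. Boundary sites contribute no neighbour on the missing side.
* **Intersections**: every distinct site goes to exactly one of the 2ᵏ−1
  exclusive tissue-membership classes (UpSet semantics), so class counts sum
  to the union size.

## Differential editing

Per site, edited counts are modelled as binomial with
`logit p = β₀ + β₁·group`; replicates within a group share the group
proportion and no overdispersion term is fitted. With a single binary
covariate the MLEs are the pooled group proportions, so the LRT
`D = 2(ℓ₁ − ℓ₀)` has a closed form on the per-group summed counts
(sufficient statistics); `p` comes from the χ²(1) upper tail, with boundary
configurations (all-zero / all-edited in both groups) yielding `D = 0,
p = 1`. Tests validate the closed form against an independent bounded
likelihood maximisation and, for single replicates, the 2×2 G-test.

Sites are testable only when every replicate meets the coverage floor
(default 10) in both groups. Δ is the difference of pooled group levels
(`Σk/Σn` per group), matching the count-based model; a replicate-mean
variant is available behind `delta_mode="mean"`. Classification requires
both BH-FDR `q < 0.05` and `|Δ|` at or above the 10%/20% threshold
("10p"/"20p"); 20p calls are a subset of 10p calls by construction.
Condition comparisons run pairwise.

## Recoding

For an A→G edit in annotated CDS the codon is reconstructed in transcript
orientation (reverse-complemented for `−` strand genes) and translated under
the standard genetic code. Stop gains and losses are labelled distinctly
rather than folded into "non-synonymous" — they are biologically different
events. When several transcripts cover a site the representative is the
longest CDS (an all-transcript report is available; with disagreement the
worst case, non-synonymous, is reported at site level). The substitution
matrix counts (reference aa, edited aa) events; every emitted pair must be
reachable by a single A→G codon change, which an exhaustive 64-codon
enumeration oracle verifies in the tests.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the structure of a temperature-acclimation editome
study: three conditions (default labels T27/T18/T13), three replicates, two
tissues, a homozygous-reference genome with planted het/hom SNPs, edit sites
distributed over 5′UTR/CDS/intron/3′UTR/intergenic/TE space (default
weights ≈ 51% intergenic, 27% intron, 19% 3′UTR, 2% CDS, 0.7% 5′UTR — the
region distribution typical of a vertebrate editome), an upstream-adenosine
context bias (default 0.9) with a milder downstream-G preference (0.5), and
clustered hyper-edited regions dense enough that reads from them exceed the
aligner mismatch cap (default 4 per 150 bp read) and are emitted unmapped.
About 30% of sites draw their level independently per condition
(temperature-responsive); the rest share one level across conditions.

Reads are emitted pre-aligned with correct coordinates (ungapped, M-only
CIGAR): upstream alignment is simulated, not computed, which isolates the
pipeline's own filters from aligner behaviour. Each RNA read covering a
site carries the edited base independently with probability equal to the
site's true level — the binomial sampling model the estimators assume.
Planted normal sites keep ≥ 30 bp spacing per transcript strand so that
reads carrying them stay below the mismatch cap; regions dense enough to
defeat alignment are modelled explicitly as hyper clusters, never by
accident. Default read simulation: 150 bp single-end, 50× RNA / 30× DNA
coverage, 0.1% uniform base error at constant Phred 37, deterministic under
a seed (identical seeds give byte-identical outputs).

Not emulated: indels and splice junctions (the detectors operate on
substitutions; splice handling belongs to the upstream aligner), PCR
duplicates, quality-score miscalibration, paired-end fragment geometry
(pairing would add read-naming bookkeeping, no new math), expression-level
variation between genes, and overdispersion of editing levels between
replicates beyond binomial sampling. Consequently, passing tests demonstrate
correctness of the statistical machinery and filter contracts under the
assumed error model — not robustness to aligner artifacts or
library-preparation biases in real data.

## Problem sizes and numerical choices

The default benchmark (200 kb genome, 20 genes, 1,000 edit sites, 100 SNPs,
10 eight-site hyper clusters, 50×/30× coverage) is sized so that a full
end-to-end run with evaluation completes in well under a minute; the
differential calibration uses 2,000 null sites × 10 simulations and a
4 × 3 power grid at 1,500 sites per cell. Calibration and power use direct
binomial count simulation rather than reads — the LRT consumes only counts,
so read-level simulation would add cost without adding coverage.

Ties and degenerate inputs: a site with zero A+G coverage has no level
(error, not NaN); an empty candidate set is an empty table, not an error;
`error_rate ≤ 0` is a configuration error since the binomial null would be
degenerate; hyper placements tied in transformed mismatch count are
ambiguous and dropped; BH q-values come from the standard step-up
implementation in statsmodels.

## Known limitations

* The k-mer realignment filter and transformed-space index hold the genome
  in dictionaries; they are designed for the package's megabase-scale
  synthetic genomes, not chromosome-scale references.
* The differential model fits no overdispersion term; with strong
  between-replicate heterogeneity its p-values will be anticonservative.
  A beta-binomial extension is out of scope.
* The hyper-editing route reports biased level estimates (conditioning on
  densely edited reads); levels should be interpreted from the normal-mode
  counts, which `merge_modes` keeps for common sites.
* Coordinates follow SAM/GTF convention (1-based) at every external
  interface; BED input is converted on read. Mixed-convention inputs from
  other tools must be converted first.
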