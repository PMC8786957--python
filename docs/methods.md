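# Methods

## The artefact mechanism

A short-read aligner scores each candidate placement of a read by its
matches, mismatches and gaps and reports the highest-scoring placement as
primary. The scoring function knows nothing about population genetics: a
correct alignment that crosses common polymorphisms accrues mismatches,
and an incorrect alignment to a paralogous locus with fewer mismatches
beats it. Gene/pseudogene pairs are the canonical trap. If the pseudogene
segregates a haplotype of SNPs whose alleles make it locally *more similar
to the gene than to its own reference*, reads from that haplotype
(i) cannot be distinguished from gene reads carrying "somatic mutations"
while they lie inside the homologous segment, and (ii) actually score
higher at the gene. Piled up, they produce well-supported candidate
somatic calls at the gene. If, additionally, the tumor library has shorter
reads than the matched normal (typical for FFPE tumor vs whole-blood
normal), the trapped fraction is higher in the tumor, the normal pileup
stays clean, and the artefact survives somatic subtraction.

This package implements the demonstration and the screen as a reusable
pipeline over synthetic data whose ground truth is known exactly.

## Models and procedures

### Local alignment (`pairwise_align`)

Exact Smith-Waterman with affine gaps (Gotoh three-state recurrence), no
banding or seeding: the loci involved are at most a few kb and exactness
is part of the contract. Scoring defaults follow the convention of
widely used short-read aligners: match +1, mismatch −4, gap open −6, gap
extend −1, with a length-*k* gap costing `open + k·extend`; `N` never
matches anything (conservative ambiguity handling). The implementation
fills the three dynamic-programming matrices row by row with numpy; the
horizontal gap state is closed in one pass per row using the identity
`E[i,j] = open + ext·j + max_{k<j}(H°[i,k] − ext·k)`, which is exact
whenever `gap_open < 0` (a second gap opening is then never profitable
inside an open gap). Traceback tie-breaks are fixed — diagonal over
vertical over horizontal, gap closure preferred over extension, start cell
at the first score maximum in row-major order — so the reported alignment
is deterministic. The suite certifies score equality against an
independently written plain-Python dynamic program on 1,000 seeded random
pairs.

### Homology envelope

`derive_envelope` aligns the second locus in both orientations, keeps the
better alignment, and accepts it as a homology envelope when it has at
least `min_length` = 50 columns and at least `min_identity` = 80% matching
columns. The length floor is necessary: unrelated random DNA always
contains short perfect local matches (identity 1.0), and an envelope must
in any case be long enough to trap a read. The identity floor excludes
random-homology hits (random DNA aligns locally at ~55% identity under
these penalties). Positions project between the loci by walking the
envelope's alignment path; positions opposite a gap column project to
"gapped" (`None`). For an inverted envelope the projected position is on
the opposite strand and allele comparisons complement accordingly.

Derived envelope boundaries are fuzzy by one or a few columns: chance
matches in the flanks extend the alignment whenever the net score gain is
positive. This is inherent to local alignment, harmless downstream (a
slightly wider envelope makes the errorless-extension criterion slightly
more conservative), and the fixture tests therefore assert core
containment rather than exact boundary equality.

### Read simulation (`read_sim`)

Single-end, error-free reads (an optional uniform substitution rate
exists, default 0): the misalignment argument concerns where *perfect*
reads go, and per-read reasoning never involves mate pairs. Two stock
length models encode the library contrast that drives leak-through:

| model | kind | parameters | emulates |
|---|---|---|---|
| `FFPE_MODEL` | truncated normal | mean 90, sd 10, range [50, 100] | fragmented FFPE tumor DNA, reads capped under ~100 bp |
| `BLOOD_MODEL` | fixed | 125 bp | whole-blood germline libraries |

The FFPE mean/sd and floor are package choices (only the <~100 bp cap and
the 125 bp normal length are externally given). Start positions are
uniform over valid starts, optionally restricted to a window or pinned.
Variant injection refuses a reference-allele mismatch, which catches
coordinate bookkeeping errors early.

### Multi-locus alignment and ambiguity (`multi_locus_aligner`)

Each read is aligned against every candidate locus in both orientations
and the per-locus best alignments are ranked (score descending, then locus
name — deterministic). The primary is the top alignment; a read is
`ambiguous` when best minus second-best score ≤ `tie_margin` (default 5,
i.e. exactly one mismatch-versus-match swing: a read that differs from two
loci by a single mismatch must count as non-unique). Mismatch columns of
an alignment convert to SNV calls in genomic coordinates; gap columns
never do. `pileup_variants` aggregates the primary alignments of a read
set into depth-annotated candidate calls.

### LD statistics (`ld_stats`)

Computed from phased haplotype panels only — the generator emits phase, so
the statistic is an exact tabulation and no EM estimation from genotypes
is needed. `pair_ld` uses exact rational arithmetic on the four haplotype
counts, so the structural identities (D′ = 1 under perfect coupling, D = 0
under exact independence) hold exactly rather than to within epsilon. The
triplet co-occurrence verdict requires every pairwise D′ ≥ 0.99 and
r² ≥ 0.94 (defaults mirror a near-perfect published LD report while
tolerating floating point in user-supplied thresholds).

### Decision layer (`artefact_decision`)

Criterion 1 (*encodes*): every target variant position is covered by an
aligned column whose read base equals the alt allele. The target set
defaults to the candidate variant itself; callers reproducing a
two-variant hotspot can pass both, in which case a single read must carry
both (the interpretation under which the trapped read is one molecule).

Criterion 2 (*errorless extension*): the alignment must contain at least
`min_flank` aligned columns beyond an envelope boundary, and every
extension region must be free of mismatches and gap columns. `min_flank`
defaults to 10 columns: "beyond the envelope" is not quantified
externally, and 10 errorless columns make a chance extension through
diverged flank (~25% per-base match probability) vanishingly unlikely
while remaining configurable down to 1.

Verdict: `confirmed` iff at least one supporting read satisfies both
criteria *simultaneously* (the criteria are per-alignment statements; one
unambiguous read is decisive evidence of gene origin). `artefact_suspect`
iff no supporting read escapes the envelope and the cross-locus pattern is
complete — the supporting read's paralog alignment has ≥ 1 mismatch and
every non-gapped mismatch is a catalogued common SNP with matching
alleles. Everything else, including variants with no supporting reads, is
`indeterminate`. The stored per-criterion booleans are any-read
aggregates, so both can be true while the variant remains unconfirmed if
no single read satisfies the conjunction. `maf_flag` marks candidates
annotated as catalogued SNPs with MAF ≥ 0.1% — a conservative floor for
"too common to be a plausible recurrent driver"; the flag is informational
and does not enter the verdict.

The leak-through model is a probability statement, not a caller
simulation: for read length *L*, envelope length *E* and a variant at
offset *v* inside it, the trapped probability is
`#{starts covering v with the whole read inside the envelope} / L` by
exact enumeration (flanks are assumed longer than the read, so exactly *L*
starts cover the variant). Fixed-length models are evaluated exactly;
stochastic models are Monte-Carlo averaged over 10,000 seeded length draws.
`risk_flag` is raised when the tumor probability is positive and exceeds
the normal's.

`screen_cohort` chains the stages: align all reads, pile up gene-primary
mismatches (requiring ≥ 2 supporting reads per candidate — singleton
mismatch columns can arise from chance soft-clip extensions and standard
callers discard singletons too), subtract candidates whose alt allele
appears in the normal pileup, then classify each survivor using the
supporting read with the best paralog alignment for the pattern test.

### Synthetic data (`synthetic_data`)

`generate_locus_pair` plants a shared core (default 141 bp, the length of
the homologous interval the screen is designed around) inside independent
uniform-random flanks (default 500 bp), with a SNP triplet of two kinds:

* **call sites** (default core offsets 14 and 31, the offsets of the two
  candidate hotspot variants from the start of the homologous interval):
  gene and pseudogene share the reference base and the SNP alt is a third
  allele — these surface as the false somatic calls;
* **mimic sites** (default offset 75): the pseudogene base differs from
  the gene and the SNP alt *equals* the gene base, hiding the divergence —
  these are exactly the positions where the two loci differ.

This mixed structure is what makes the trap spring: a pseudogene read
carrying the full haplotype has 2 mismatches against the gene but 3
against its own locus, so the gene wins by one mismatch, and that read is
byte-identical to a gene read carrying both candidate variants (the
generator's tests assert this identity). Catalogue records carry allele
counts 1386/117782 per site (MAF 1.18%, comfortably "common"). Panels
come in `perfect` (alt alleles only jointly, on `round(freq·n)`
haplotypes), `independent` and `custom`-frequency modes.

`generate_cohort` defaults: 800 tumor and 300 normal reads targeted at
the locus (starts restricted to the window from which a maximum-length
read overlaps the core — the screen examines the pileup at the locus of
interest, and coverage elsewhere is irrelevant); 20% of reads carry the
pseudogene SNP haplotype in both tumor and normal (it is a germline
carrier state); the non-carrier background splits evenly between wild-type
gene and pseudogene molecules; optionally, 30% of gene-origin tumor reads
carry planted true-somatic variants. These sizes give every planted
variant an expected supporting depth ≥ ~6 at the smallest site, so the
truth sweep is statistically stable. The default normal model is the
125 bp blood model; the end-to-end truth-sweep datasets instead use fixed
150 bp normals (longer than the 141 bp core) so that germline reads escape
the envelope deterministically — with 125 bp normals a carrier's normal
reads land wholly inside the envelope with probability ≈ 0.14 per covering
read, in which case the artefact also surfaces in the normal pileup and is
subtracted; that probabilistic regime is exactly what
`leak_through_assessment` quantifies, but it would make a fixed-seed truth
sweep depend on sampling luck rather than on the mechanism under test.

What the generator does *not* emulate: sequencing errors and quality
spread, FFPE C>T deamination chemistry, paired-end inserts, indel
polymorphism inside the core, more than two homologous loci, and real
human sequence context. Passing tests therefore show that the decision
logic is correct *given* the misalignment geometry, not that the screen's
operating characteristics (e.g. false-negative rate under sequencing
noise) transfer to any particular real dataset.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (numpy Generator);
identical seeds give byte-identical datasets. The test suite uses loci
with 200 bp flanks (541 bp total) and cohorts of 800 + 300 reads; the
truth sweep covers 20 seeded datasets and asserts zero disagreements
between verdicts and truth labels. The alignment oracle check runs 1,000
random pairs at lengths ≤ 50. The acceptance script touches only the
LD panel and the MAF example and completes in seconds.

## Known limitations

* The aligner is O(mn) and intended for locus-scale references, not
  genomes; the package is a screen for a *given* gene/paralog pair, not a
  paralog discovery tool.
* Ambiguity is operationalised as a score gap against an explicit margin;
  it is a transparent stand-in for, not a model of, any particular
  production aligner's multi-mapping heuristics.
* Only single-nucleotide variants are called from mismatch columns;
  indel artefacts would need the gap columns to be interpreted as calls.
* The two-criterion verdict is deliberately per-read and conservative: a
  variant whose supporting reads all end inside the envelope but whose
  cross-locus pattern is incomplete stays `indeterminate` rather than
  being forced into either class.
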