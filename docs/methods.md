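# Methods

This note documents the models and procedures `dscamkit` implements, the
parameters that matter, the numerical conventions, and what the synthetic
data do and do not establish.

## Gene models and conventions

A gene model consists of constitutive (constant-region) exons, an
optional tandem array of 5′ variable cassette repeats, optional internal
mutually-exclusive exon cluster sizes, and a protein domain architecture
(ordered LEADER/IG/FN3/TM/CYTO tokens with amino-acid coordinates).
Domain calls are an *input* (a TSV), not computed: domain prediction is a
solved upstream problem and out of scope here.

All internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive, and the conversion is an involution covered by tests. Cassette
membership travels as GFF3 exon attributes (`region=constant|variable`,
`cassette_index`, `ig_count`, `exon_role=ig` for the Ig-encoding exon
used in cassette-level quantification), because no standard GFF3
vocabulary exists for tandem promoter cassettes. Cassette indices follow
genomic (linear) order — the same order heatmap labels use. Minus-strand
sequence extraction reverse-complements, and spliced sequences on the
minus strand reverse the exon order.

## Classification

Rule order is structural first: a gene with a cassette array is sDscamα
(1-Ig units) or sDscamβ (2-Ig units) regardless of domain counts, because
the short constant region of an α/β gene would otherwise satisfy the
sDscamγ test. Without an array: sDscamγ when the architecture is
short-form (IG count within ±1 of 3, FN3 within ±1 of 3, and a TM
present); LDscam when exactly 10 IG + 6 FN3 with an IG token between the
4th and 5th FN3 (the canonical bilaterian layout); mDscam when IG ∈
[8, 9] and FN3 ∈ [3, 4] with no IG between FN3 tokens. The mDscam window
spans one Ig because the intermediate form is described both as the
canonical architecture minus Ig10/FNIII3–4 (9 Ig) and as carrying the
same eight N-terminal Ig domains; accepting both readings costs nothing
since no other class sits in that window. A gene matching nothing is
`unclassified` — classification is total and deterministic.

Repertoire sizes: one isoform per cassette for α/β (alternative promoter
choice); the product of cluster sizes for mutually-exclusive-splicing
genes (12 × 48 × 33 × 2 = 38,016 for the canonical fly gene, whose 95
alternative exons are the summed cluster sizes); 1 otherwise.

## Percent identity and duplication blocks

Pairwise cassette identity uses global alignment with affine gaps
(Gotoh): BLOSUM62, gap open −10 charged on the first residue of a gap,
−0.5 per extension; a match/mismatch scheme (+2/−3) for the nucleotide
option. Identity is **100 × identical columns / alignment columns,
including gap columns** — stated explicitly because conventions differ.

Optimal alignments are not unique and co-optimal alignments can disagree
on identity, so the aligner optimises lexicographically: maximal score,
then maximal identical columns, then minimal alignment length. All three
objectives are additive along an alignment path, so a single dynamic
programme (three-state Gotoh over value triples) computes the optimum; it
is symmetric in its arguments, independent of any traceback order, and
equals an exhaustive enumeration of all alignments on short sequences
(tested, and recomputed by `scripts/acceptance.py`). This is the precise
form of "prefer matches over gaps on ties". The DP is JIT-compiled with
numba; the oracle is deliberately pure Python.

Translation of a cassette takes its spliced exons and picks the first
forward frame without an internal stop; a cassette with stops in every
frame is excluded with a warning (`keep_untranslatable=True` retains it
for nucleotide-level analyses, where a premature stop is irrelevant).
Whether identities are computed on amino acids or nucleotides is an
option: amino acid is the default for heatmaps; block detection and tree
recovery in the validation suites run on nucleotide identity, since
duplication blocks are genomic structures and a single nonsense
substitution should not eject a cassette from one.

A **duplication block** is a maximal run of consecutive cassettes (in
genomic order, within one gene) in which every adjacent pair has identity
≥ a threshold, default 80% (exposed as a flag; no canonical value
exists). Singletons are not blocks. Mean within-block identity averages
all pairwise values inside the block.

## Duplication statistics

* Inverse correlation: Pearson *r* (two-sided *p*) between per-species
  gene-duplicate count and per-species mean cassette count per gene,
  per subfamily; per-gene pairing is an option. Raw counts by default
  (a log–log view is one line away and the noiseless hyperbola is tested
  on logs). Zero variance ⇒ NA.
* Power law: `repeat_unit_size ≈ c·x^b` fitted by OLS of log10 on log10;
  exact (≤1e−9 on the exponent, R² = 1) on noiseless power-law data.
  `repeat_unit_size` is the mean genomic span of one cassette repeat
  within a gene, introns included.
* Genome size: Pearson *r* between per-species mean repeat-unit size and
  genome size (Mb); species without a size are dropped with a warning,
  n = 2 computed but flagged low-power. The output table carries total
  cassette count per species as the plotting-size annotation.
* Intron loss: a gene is flagged when the modal per-cassette intron count
  falls below its subfamily's modal count. Modes are robust to single
  mis-annotated cassettes but presuppose that losses are a minority of
  the subfamily — with majority loss the reference mode flips, which the
  tests exercise only in the valid regime. Constant-region intron counts
  are reported separately and never flag.
* α vs β: mean ± SD of cassette counts and per-species gene counts with a
  pooled-variance two-tailed Student's *t*; significance read at
  α = 0.05 throughout.

## Expression quantification

Reads are tiled into non-overlapping 25-nt fragments from the 5′ end
(trailing remainder discarded; a 150-nt read gives 6 fragments); a
full-length pass treats each read as one fragment, and both resulting
tables are reported side by side — no merge rule is defined, so none is
invented. Matching is exact substring search on a hash index over the
reference regions, both strands; this is the literal meaning of retaining
only perfectly mapped fragments, and it keeps the whole pipeline
desk-testable without an external aligner. A fragment matching L loci
contributes weight 1/L to each, never rounded, so per sample the summed
fractional counts equal the retained-fragment count exactly and RPM sums
to 10⁶. Gene-level rows use the spliced constitutive exons; cassette rows
use each cassette's Ig-encoding variable exon. Regions shorter than the
fragment length are flagged `unmappable`; regions none of whose k-mers is
unique within the reference are flagged `ambiguous` (identical cassette
duplicates necessarily split counts equally — the flag is the honest
signal that they are indistinguishable). RPM = count/total × 10⁶;
RPKM = count/(kb)/(10⁻⁶ × total mapped). FASTQ qualities are ignored
(quality control is upstream); a minimum-length filter is available.

The bias test is a two-tailed Student's *t* on log2(RPKM+1) between gene
groups (≥2 each), with a Welch fallback when a group's variance
degenerates; fully degenerate groups resolve analytically (equal means →
t = 0, p = 1).

## Forward simulator

The generator emulates the family structure the analyses assume: a
star phylogeny (independent branches from one ancestor — adequate because
no analysis here conditions on between-species tree shape), adjacent
insertion of duplicated cassettes, whole-gene duplication, uniform
per-site substitutions to one of the three alternative bases
(Jukes–Cantor-like; no rate heterogeneity or selection), and per-gene
loss of all cassette-internal introns. Default study conditions: 6
species; an ancestor of one canonical, two intermediate and three short
genes (α with 5 × 1-Ig cassettes, β with 4 × 2-Ig cassettes — two more
exons per unit than α — and a cassette-less γ); 3 expected cassette
duplications, 0.7 expected gene duplications and 2% substitutions per
site per branch. A `CENSUS_ANCESTRAL_GENES` preset (1 + 4 + 5 genes)
emulates the larger census scale of a cassette-rich genome and is used
where group sizes matter (expression bias). Coding sequence is drawn
codon-wise from the 61 sense codons so ancestral cassettes translate
cleanly; subsequent substitutions may create stops, which the translation
stage then reports and excludes, as with real annotations.

Every random draw flows from one seeded `numpy` generator, and every
choice is materialised into an event log; replaying the log against the
stored ancestor reproduces the emitted FASTA/GFF3 byte for byte, which is
the invariant the truth-based tests rest on. Reads are sampled uniformly
within isoforms at configured per-isoform read fractions (default
uniform), 150 nt, error-free by default; the truth table records each
isoform's fraction and length. Isoform sequences are cassette exons plus
the spliced constant region (one isoform per cassette), or the constant
region alone.

The isoform-budget scenario fixes a per-species isoform total T, draws a
gene count g uniformly from 1–8 per species, and assigns ≈T/g cassettes
per gene with lognormal noise (σ = 0.1); repeat-unit sizes follow a
power law in cassette count (exponent −0.5). This is the generative form
of the conserved-budget hypothesis and feeds the inverse-correlation
recovery test.

**What passing tests do not show about real data:** the simulator has no
sequencing-error profiles, no splice-site or promoter sequence realism,
no within-genome base composition structure, no selection, no gene loss,
and a star phylogeny; recovery rates measured on it certify the
*algorithms* (block detection, apportionment, statistics), not
performance on noisy genome annotations.

## Trees

Identity converts to distance d = (100 − identity)/100. Trees are
neighbor-joining (via scikit-bio), exact on additive matrices (path
distances reproduced to ≤1e−9, tested), with negative branch lengths
clamped to zero and optional rooting on an outgroup tip. NJ is a
deliberate surrogate for maximum-likelihood inference with bootstrap —
the questions asked of trees here (is a burst monophyletic; are cassette
trees shallower than gene trees) are distance-scale questions, and full
ML belongs to external tooling. Depth comparison reports mean root-to-tip
length per tree and their ratio (<1 ⇒ faster cassette turnover).

## Problem sizes and determinism

Validation experiments use: 100 seeded runs for each stochastic recovery
rate (budget-scenario correlation, burst block/monophyly, bias-test
power; 40 in the routine test suite), depth 100,000 reads for the RPKM
recovery check — sized so that binomial sampling error (≈1% per gene)
sits well inside the 5% assertion — and depth 3,000 for the bias power
runs. The expected per-region fragment count used as the RPKM reference
is computed from first principles (uniform read starts, fixed tiling
offsets), independent of the matching code. All statistics are
bit-reproducible given the same seed; every CLI output TSV carries the
tool version, seed and config hash as header comments.

## Known limitations

* Classification trusts the input domain calls; no sequence-based rescue.
* Exact matching means a single SNP between a read and the reference
  drops a fragment — faithful to the perfect-match rule, but real-data
  use should pre-correct reads or accept the sensitivity cost; an
  interface for pre-computed alignments is the natural extension.
* The intron-loss flag is relative to the subfamily mode (see above).
* Percent identity is defined by the lexicographic optimum; other tools'
  identity values can differ on gapped pairs even at equal alignment
  score.
* The 25-nt and 150-nt expression tables are complementary views, not a
  single estimate.
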