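# Methods

This note documents the models, conventions and numerical choices behind
`igrec`, in the spirit of a methods supplement: what each stage assumes,
which parameters matter, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinate convention for the Ig loci

The five built-in GRCh38 loci are stored as half-open intervals with an
*exclusive* start: a 1-based alignment position `p` overlaps an interval
iff `start < p <= end`, equivalently `(start, end)` is a 0-based half-open
interval (the BED/pysam convention), and `length = end − start` exactly.
The two unlocalized-contig loci span their entire contigs and are stored
with start 0 (the contig's first base, 1-based position 1, equals exclusive
start 0). Under this single convention the five stored lengths are
1,329,999 / 480,000 / 2,019,999 / 43,739 / 1,872,759 nt. A one-basepair
ambiguity at interval edges is immaterial for read extraction: the loci are
megabase-scale and reads overlap by ≥ 1 bp.

Extraction emits a pair iff at least one mate's primary alignment overlaps
a locus, and always emits both mates (mate rescue), because assembly of
junction-spanning fragments needs both; duplicate-flagged reads are kept
(clonal Ig transcripts are legitimately ultra-high-coverage), secondary and
supplementary alignments are ignored. The implementation is a full scan of
the alignment file and therefore also works on plain unindexed SAM.

## Alignment core

Alignments are optimal (non-heuristic) affine-gap Smith–Waterman, computed
by Biopython's `PairwiseAligner` (C implementation) under match +1,
mismatch −2, gap open −5, gap extend −2; a gap of length L costs
`open + (L−1)·extend`. Both query strands are tried; score ties resolve to
the plus strand. The test suite checks exact score agreement against an
independent pure-Python Gotoh dynamic program on hundreds of random pairs.

Percent identity is `100 · matches / alignment_length` with gap columns in
the denominator, and mutation % is exactly its complement. Identity is
computed over the aligned V segment only — the clinical convention — and is
rounded to one decimal only in user-facing output.

E-values use the Karlin–Altschul form `E = K·m·n·e^(−λS)` with defaults
λ = 1.28, K = 0.46 (approximate ungapped blastn values for this scoring).
They are configuration, not constants: the screening threshold E ≤ 20 is so
permissive that small parameter changes are irrelevant.

### Screening needs a seed, not just a threshold

E ≤ 20 alone cannot reject random contigs: the best chance local alignment
of a 300-nt random contig against a kilobase-scale V database scores ~9–10,
i.e. E ≈ 1. What rejects them in practice is the word-size requirement of
seed-and-extend search. The screen therefore nominates candidate alleles by
exact shared words of 16 nt (either strand) and scores every nominated
candidate by full dynamic programming. Word size 16 is chosen so that (a) a
random 300-nt contig shares a 16-mer with a small V database with
probability ~10⁻⁴, and (b) a genuine V segment at 10% SHM still contains a
clean 16-mer with probability > 0.997 (a 28-mer word — the megablast
default — would miss ~20% of such contigs; an 11-mer word would pass ~12%
of random ones).

### Recovering clipped 5' columns

Local alignment trims terminal mutation clusters as net-negative, biasing
mutation % downward. When the unaligned 5' prefixes of contig and germline
V have equal length, the clipped region lies on the alignment diagonal and
is forced homology (both sequences begin together), so the annotator
reinstates those columns. The 3' end is deliberately left to the local
alignment: germline overhang there is confounded with exonucleolytic
junction trimming, and extension would misalign untemplated nucleotides.
A consequence worth stating precisely: SHM on the last one or two retained
V bases is information-theoretically indistinguishable from trimming, so no
method can count it; this bounds achievable mutation-percent accuracy by
roughly `100 · 2/|V|` ≈ 0.7 points in the (rare, ~p² per end) worst case.

## Assembler

A single-k de Bruijn graph (default k = 25, odd so no k-mer is its own
reverse complement) over canonical k-mers replaces a general-purpose
transcriptome assembler. This is the package's largest simplification
relative to full RNA-seq practice and is justified by the use case: after
locus extraction the read set is small and dominated by one clonal
transcript at 10²–10³× coverage, with no alternative splicing to untangle.

Graph cleaning, in order:

1. **Absolute floor** — k-mers seen fewer than `min_kmer_count` (2) times
   are dropped (singleton sequencing errors).
2. **Relative floor** — k-mers below `rel_abundance_floor` (0.005) times
   the *instance-weighted median* k-mer count are dropped. At clonal
   coverage in the thousands, individual sequencing errors recur 2–3 times
   and pass the absolute floor; genuine k-mers carry almost all of the
   count mass, so the weighted median tracks the dominant clone's coverage
   even when *distinct* error k-mers outnumber genuine ones. The default
   keeps minor clones two orders of magnitude below the dominant one.
3. **Branch thinning** — at any graph fork, outgoing k-mers with coverage
   below `branch_thin_ratio` (0.2) of the best sibling are removed. This
   handles overlapping error bubbles, which defeat classical same-anchor
   bubble detection because the parallel true path is itself subdivided by
   neighbouring bubbles. Limitation: at a junction genuinely shared by
   clones more than 5× apart in abundance (the constant-region entry
   point), the minor clone's branch into the shared segment is thinned,
   truncating minor-clone contigs at the shared-segment boundary; their
   V-D-J content is unaffected.
4. **Tip pruning** — dead-end branches shorter than 2k whose coverage is
   under `tip_coverage_ratio` (0.25) of the best sibling branch.
5. **Bubble collapse** — parallel unitigs sharing anchors merge to the
   higher-coverage branch when their edit distance fits the
   `bubble_identity` (0.98) budget; at least one edit is always allowed,
   since a single-substitution bubble has branch length 2k−1 = 49 and
   identity 48/49 < 0.98 for any threshold of that form.

Contigs are maximal unambiguous paths ≥ `min_contig_length` (200 nt),
emitted once in canonical orientation (lexicographic minimum of sequence
and reverse complement), deterministically ordered.

## Quantification and dominant-clone selection

Read pairs are pseudo-assigned by 31-mer vote: a pair goes (fractionally,
on ties) to the contigs sharing the most k-mers with it. Rates are assigned
pairs over effective length `max(L − mean_fragment + 1, 1)` and normalized
to TPM summing to 10⁶. This replaces a full probabilistic quantifier; with
one dominant clone and a handful of well-separated minor transcripts,
equivalence-class refinements and EM re-allocation change nothing material.

The dominant clone is the *productive* transcript with the highest TPM;
when no productive transcript exists the overall top transcript is used and
flagged. Exact TPM ties resolve to the lexicographically smaller id and are
flagged. Transcripts with TPM ≥ max/10 are co-reported ("within one log10",
read as a closed boundary).

## Annotation

V assignment: best-scoring allele over both contig strands (ties: higher
identity, then allele name); the contig is reoriented to the V-coding
strand. J: best allele constrained downstream of the V; a minimum score of
15 rejects chance hits in V-only fragments (chance local hits score ~8).
D: best alignment wholly inside the V–J window carrying at least
`min_d_match` = 5 consecutive matching columns, else NA — with a toy-sized
D database, 5 nt is the shortest defensible evidence, and a true D trimmed
below 5 nt is genuinely undecidable (a short window shares a 5-mer with
*some* allele by chance with non-trivial probability). N1/N2 are the contig
bases strictly between the aligned segments.

Productivity = V and J in order on the V-coding strand, V→J span
frame-preserving relative to the germline V reading frame (frame 0 of the
ungapped allele), and no stop codon in the translated V-through-J region.
SHM sites are reported 1-based on the ungapped germline V.

## Classification and reporting

`unmutated ⟺ identity > 98.0` (strict, the stated clinical definition); an
inclusive `≥` variant is selectable, and calls within ±0.5 points of the
cutoff carry a borderline flag since the two conventions and assay noise
can flip them. Clonotype = exact (V gene, J gene, junction nucleotide
string); an identity-threshold merge is available but off by default.
Concordance metrics treat *unmutated* as the positive class (the
prognostically adverse call); Pearson's r is computed on paired mutation
percentages.

## Simulator: what it emulates and what it does not

The generative model: uniform choice of V/D/J alleles (distinct across
clones while the database allows, so each rearrangement assembles
independently); junctional trimming uniform on 0..5 nt per joined end;
untemplated N insertions uniform on 0..10 nt with uniform base composition;
substitution-only SHM on the V segment at `shm_rate` per base, multiplied
by `cdr_multiplier` (3) inside CDR intervals; a fixed 60-nt synthetic
constant-region stub; one dominant clone at `depth` = 10⁴ read pairs
(the coverage regime where dominant-transcript assembly is reliable) plus
2 minor clones with TPMs spread down 2 log10; fragments
Normal(200, 30) nt; read pairs of 75 nt with uniform substitution errors at
10⁻³ and constant Q30 qualities. By default the dominant rearrangement is
rejection-sampled to be productive — an expressed dominant clone is — so
that productive-first selection targets the intended clone; the synthetic D
and J fixture alleles avoid stop trinucleotides in every frame to keep that
sampler efficient. All randomness flows from one mandatory seed, and every
transcript carries a truth record from which its sequence reconstructs
byte-for-byte.

Not emulated: indel SHM (the identity arithmetic here is defined on
substitution-dominated alignments), class switching, light chains,
empirical quality/error profiles, positional/GC bias, intronic or
off-locus background reads, allele-length polymorphism. Passing tests on
simulated data therefore demonstrate the pipeline's internal correctness
and its statistical behaviour under a clonal, substitution-SHM model — not
robustness to every artifact of real libraries.

## Problem sizes used by the test suite

End-to-end recovery runs 20 simulated samples (seeds 1–20; shm_rate spread
over [0, 1%] and [3, 10%]; 75-bp pairs; 10⁴ dominant-clone pairs).
Assembler fidelity uses a 160-nt transcript with ~150-nt fragments — an
amplicon-like overlapping-pair library — so that 100× depth also samples
the transcript ends; with fragments much shorter than the transcript,
terminal k-mer coverage scales as depth/(L − fragment), and exact
end-to-end reconstruction at 100× is a property of libraries whose
fragments approach the transcript length. Aligner equivalence uses 500
random pairs ≤ 30 nt against the exhaustive DP oracle.

## Known limitations

* Minor clones far below the dominant one (≥ 2 log10) sit near the
  relative abundance floor and may fragment or lose their shared
  constant-region tail; the dominant clone's call is unaffected.
* Mutation % inherits local-alignment boundary behaviour at the V 3' end
  (see above); deviations beyond ±0.5 points require SHM on the final
  retained V columns.
* The quantifier does not model multi-mapping between near-identical SHM
  variants of the *same* clone; the simulator does not generate such
  variant mixtures within a clone.
* E-values are compatible-in-spirit with blastn, not bit-identical.
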