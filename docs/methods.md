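# Methods

This note documents the models and procedures `virolink` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Sequence-comparison kernels

### Local nucleotide alignment

`seqmatch.local_align` is a seed-and-extend heuristic in the megablast
family. Exact k-mer seeds (default `seed_k = 13`) between query and
subject are grouped into diagonal-banded chains (`band = 100` bp of
diagonal drift, `chain_gap = 1000` bp between consecutive seeds); each
chain defines a candidate window, padded by 400 bp. The window is aligned
by edit distance (edlib, infix mode) and the resulting path is trimmed to
its maximal-scoring contiguous sub-path under the scoring system
(match +1, mismatch −2, gap open −2.5, gap extend −1). Because cigar runs
are homogeneous, run-granularity Kadane trimming is exact for this
scoring. Raw scores convert to bit scores and e-values with ungapped
Karlin–Altschul constants λ = 1.28, K = 0.46 (E = K·m·n·e^(−λS)). The
thresholds the pipeline applies downstream are stated by the analysis
design in identity / coverage / bit-score / e-value units, not in terms
of a specific scoring system, so all scoring parameters are overridable
through `AlignScoring`.

Two protections keep the heuristic robust on low-complexity or
compositionally biased inputs: subject k-mers occurring more than
`max_kmer_hits = 8` times are masked (repeat protection, as BLAST's
soft-masking does), and chains need at least `min_group_seeds = 2` seeds.
Without these, sequence pairs emitted from the same biased Markov chain
(the generator's host-derived viruses vs their hosts) produce quadratic
seed explosions and occasional spurious merged-coverage links.

Edit-distance alignment is not score-optimal alignment; on a planted 25 %
substitution signal the trimmed-path identity sits within ±0.02 of a full
dynamic-programming alignment (tested against an independent quadratic DP
oracle), which is well inside the 5-percentage-point granularity of every
identity threshold in the pipeline.

Coordinates are 1-based inclusive; minus-strand hits are reported on the
plus strand of the subject; equal-scoring hits tie-break leftmost
(q_start, then s_start). Query coverage for multi-hit gates is the merged
union of query intervals across hits to the same subject bin — the
per-HSP alternative is stricter and can be emulated by filtering hits
first.

### Fuzzy spacer matching

`find_spacer_matches` reports every full-length, indel-free occurrence of
a spacer on either strand with at most `max_mm` substitutions (default 1),
by vectorized per-offset mismatch counting. It is exhaustively equivalent
to a sliding-window scan (tested on randomized pairs with planted 0/1/2
mismatch copies). Spacers shorter than 20 bp are rejected — below that
length chance matches in a metagenome become likely.

### ONF profiles and d2*

`onf_profile` counts k-words (default k = 6) over the sequence and its
reverse complement pooled, and estimates expected word frequencies from an
order-r Markov chain (default r = 2) fit to the same pooled sequence:
p(w) = p(w₁..w_r) · Π P(w_{i+r} | w_i..w_{i+r−1}), with transitions
row-normalized from (r+1)-mer counts so the expectations sum to exactly 1.
`d2star` centres counts by expectation (X̃_w = X_w − N·p_w), standardizes
by √(N·p_w), and returns (1 − cosine similarity)/2 ∈ [0, 1]; words with
zero expectation in a profile are excluded from that profile's terms. The
k = 6 / order-2 / both-strand defaults are the conventional settings of
alignment-free virus–host matching tools. Implementation is vectorized
over all 4⁶ words; tests pin it to an independent dict-based direct
summation at 10⁻⁹ absolute tolerance.

## vOTU construction

Screening consumes upstream caller scores as a table (the callers
themselves are out of scope): a contig is retained at ≥5 kb when the
VirSorter2-like score exceeds 0.9, or the VIBRANT-like caller called it at
all, or the DeepVirFinder-like score exceeds 0.9 with P < 0.05. Exact
dedup collapses byte-identical and reverse-complement-identical records
(toggleable), keeping the lexicographically smallest id.

Clustering is greedy centroid clustering: contigs sorted by length
descending (ties by id) join the first representative they match at
≥95 % ANI over ≥85 % of the shorter sequence, where ANI is the
alignment-length-weighted mean identity over retained local hits.
Greedy member-vs-representative linkage matches the anicalc/aniclust
approach; it is deterministic and idempotent on representatives. Clusters
whose representative is under 10 kb carry a failing verdict rather than
vanishing, preserving the audit trail. The host-contamination filter
fails a vOTU when *any* of its three criteria fires (no viral genes;
host-gene span >30 % of the representative length; host:viral count ratio
>10:1) — the disjunctive reading is the conservative one, and the span
criterion is computed on the representative, the only member with gene
coordinates guaranteed.

## Virus–host prediction

Channels are collected exhaustively at the host-bin level (any contig of
a bin counts) and resolution is deferred entirely to the consensus:

1. **CRISPR** — a (vOTU, bin) pair links when one spacer matches both the
   virus and a bin contig, each full-length with ≤1 mismatch. Score is
   the mismatch count (lower = stronger).
2. **tRNA** — viral tRNA vs host tRNA at ≥90 % identity over ≥90 % of the
   viral query. tRNA detection is upstream; sequences are inputs.
3. **Nucleotide homology** — individual hits filtered at e ≤ 10⁻³, ≥70 %
   identity, ≥50 bits; the bin links when the merged query coverage
   exceeds 70 % (strict) and the query is ≥10 kb. Score is the best bit
   score. Co-binning evidence, if supplied, would enter at this rank.
4. **ONF** — every (vOTU, host) pair at d2* ≤ 0.2 (inclusive). All
   sub-threshold pairs are kept; no best-n truncation.

Consensus ranks candidate hosts by (number of distinct supporting
methods, best robustness rank among them) with crispr = 0,
trna = nucleotide = 1, onf = 2. Residual ties: ONF-only ties go to the
lowest d2* (an exact d2* tie is unresolved); ties in which two or more
hosts carry tRNA support are returned UNRESOLVED (multi-host tRNA matches
are known false-positive territory — tRNAs are horizontally mobile); a
tRNA-vs-nucleotide tie is broken by the higher bit score when nucleotide
evidence exists, else unresolved. The assignment is a pure function of
the evidence multiset (permutation-tested), and every decision is logged
in `rule_trace`. Host-range summaries (single-MAG specialist /
single-phylum / multi-phylum / cross-domain) use the full pre-consensus
evidence, since consensus deliberately discards breadth.

## AMG classification

The rule engine mirrors the two-caller design: the DRAM-v-like caller
provides `auxiliary_score` and single-letter flags; the VIBRANT-like
caller provides bare calls. Filter: score ≤ 3, metabolic flag `M`
present, none of T/F/V/A/P/B. Transposon-scaffold and scaffold-end
exclusions arrive as upstream booleans and reject. The flanking check
requires a viral-annotated gene strictly before and strictly after the
candidate on its contig; flankers need not be adjacent (the strict
adjacency reading is available via `require_adjacent=True`), since
operonic unknowns between viral genes are common. Confidence: filter-pass
and both callers ⇒ high; callerA only ⇒ low; callerB-only calls are
recorded as `unclassified` — the filter operates on callerA metadata, so
they can be neither confirmed nor rejected. Host homology uses local
BLOSUM62 alignment (gap open −11, extend −1): identical means 100 %
identity over ≥50 % of the viral query span, homologous >30 % over ≥50 %.

## Abundance, activity, ecology

Coverage is summed mapped read length / genome length; cross-sample
normalization multiplies by reference_library / sample_library with the
**mean library** as reference (configurable — the normalization constant
is a convention, and any fixed reference gives identical correlation
structure). Presence/activity is strict: mapped length must exceed 10 %
of genome length; exactly 10 % is absent. Modified TPM is
count·(1000/length)·(10⁶/library) after zeroing singleton counts
(count = 1), which are treated as mapping noise. Richness counts present
entities; Shannon uses natural log; Bray–Curtis comes from scipy with
all-zero sample pairs reported as 0 with a warning. The environment
screen computes per-entity Pearson r and two-sided p against each
parameter, with pairwise missing-data exclusion and zero-variance vectors
skipped; **no multiple-testing correction by default** — each test is
judged at α = 0.05 alone, matching the analysis design this package
models — with Benjamini–Hochberg available as an option. A host–virus
pair "co-correlates" with a parameter when both members are significant
with the same sign; the pair's abundance–abundance regression is reported
alongside.

## Synthetic community generator

The generator emulates the target study design at desk scale: 20 host
bins (one 50 kb contig each — a stand-in for ~1 Mb MAGs), 30 viruses of
12–15 kb, 16 metagenome samples and 6 metatranscriptome samples, with all
randomness flowing through one seeded generator (identical configs give
byte-identical files).

**Composition.** Each host lineage draws its own order-2 transition
matrix with rows from Dirichlet(α = 1) — uniform on the probability
simplex — and `lineage_divergence` mixes it with a shared base chain
(default 1.0: fully lineage-specific). α = 1 is the natural
non-degenerate choice: much smaller α yields low-complexity, repetitive
genomes no real prokaryote resembles (and which break alignment
statistics for reasons unrelated to the science), while large α collapses
the compositional signal that makes the ONF channel work at all.
Host-derived viruses are emitted from their source host's chain;
"unrelated" viruses from an independent chain. Inter-lineage d2*
increases monotonically with the divergence knob (tested at 0.25 / 0.5 /
1.0).

**Planted signals.** CRISPR: a repeat–spacer–repeat array (28 bp constant
repeat, 5 spacers) is inserted into the host, one spacer copied from a
viral protospacer with the configured number of substitutions; decoy
arrays carry 2-mismatch spacers that the ≤1-mismatch matcher must reject.
tRNA: a 75 bp segment inserted into both genomes at the configured
identity. Prophage: a contiguous region of the configured fraction
(default 0.8) of the virus copied into the host at the configured
identity (defaults 0.75–0.90 across the planted set). The default link
set is 8 CRISPR (0–1 mismatches), 5 prophages, 4 tRNA links.

**Tables.** Coupled entities follow coverage = intercept + slope ·
z-scored covariate + N(0, 0.15), truncated at zero, with both members of
a host–virus pair coupled to the same covariate with same-signed slopes;
uncoupled entities get entity-specific baselines with
environment-independent noise, so they false-flag at ≈ α in the
correlation screen. Environmental parameters are drawn uniformly from
plausible groundwater ranges (DO 0.2–9 mg/l, nitrate 0.05–6 mg/l, ...).
Gene-level transcript counts are Poisson with per-gene Gamma rates;
counts of exactly 1 are reserved for explicitly planted singletons so the
singleton-removal path is deterministic. The abundance–environment
generative process is a modelling convenience, not an estimate of any
real aquifer: slopes, intercepts and noise are free parameters.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no read-level noise or assembly artifacts
(mapping summaries are emitted directly), no ambiguity codes, no strain
microdiversity within a vOTU beyond planted variants, single-contig hosts
(real MAGs are fragmented, which weakens CRISPR/tRNA recall), no
horizontal transfer between lineages (which confounds ONF in reality),
and genomes ~20× shorter than real MAGs (d2* noise scales with 1/√N, so
real-data compositional assignment is easier at equal divergence, but
real inter-lineage divergence is far smaller than the planted one).
Recovery rates here are upper bounds under clean conditions; thresholds
and rules, not field performance, are what the tests certify.

## Problem sizes and determinism

Default test/acceptance sizes: 20 hosts × 50 kb, 30 viruses × 12–15 kb,
16 + 6 samples; the clustering check uses 10 planted species × 3 variants
plus 5 singletons and 2 sub-10 kb contigs; kernel oracles run on 200
spacer/contig pairs and 20 × 2 kb d2* pairs; ONF top-1 accuracy and the
coupling screen average over 5 independent seeds. These sizes were chosen
so the full suite and the acceptance script each complete in minutes on a
single CPU while every planted signal remains individually auditable.
All stochastic tests fix their seeds; hypothesis-based property tests run
derandomized.

## Known limitations

* The local aligner's e-values use ungapped Karlin–Altschul constants
  with gapped scoring; e-values are therefore conservative rankings, not
  calibrated probabilities. Every downstream gate also requires identity,
  coverage and bit-score, so this has no practical effect here.
* `pairwise_ani` seeds with exact 13-mers, so ANI below ~85 % between
  short sequences may be reported as no alignment; the clustering
  threshold (95 %) sits far above this floor.
* d2* on sequences shorter than ~1 kb is noisy (few hexamer counts);
  `onf_profile` warns below 4^order · 10 bp.
* CallerB-only AMG candidates are recorded but never classified; a
  VIBRANT-score-based filter could be added if such metadata existed.
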