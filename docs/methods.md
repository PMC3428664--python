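# Methods

This note documents the models and procedures implemented in `homeocure`,
the parameter choices that matter, the conventions adopted where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Alignment model

Reads are placed ungapped and fully contained on unigene sequences, on
either strand, at the position minimising the Hamming mismatch count,
subject to a cap (`max_mismatches`, default 3). N in the read or the
reference always counts as a mismatch. Among equally good placements one
is chosen uniformly at random (reservoir sampling over candidates in a
fixed scan order, driven by a per-batch seed) and flagged `tie_broken`;
this random assignment is load-bearing downstream, because it is what
splits reads from identical A/C tracts evenly between the two versions.

The search is a pigeonhole-seeded exact method, not a heuristic: a read
of length L placed with at most m mismatches must contain an exact window
of length `L // (m + 1)`, so exact k-mer lookups at the `L // k` disjoint
window offsets enumerate every placement within the cap. Seed length is
capped at 31 so window codes stay exact in 64-bit integers; the cap only
binds when `L // (m + 1) > 31`, in which case `L // 31 >= m + 1` windows
still guarantee completeness. Reference windows containing N are absent
from the index, which is safe because a zero-mismatch window cannot
contain N. The test suite asserts equality with an independent exhaustive
scan over all offsets and strands on randomized instances. Candidate
verification runs in a numba kernel; `max_mismatches >= L` is rejected
(such degenerate placements would need no seed at all).

Deliberately not modelled: indels (the curing operation substitutes
single bases and never changes lengths, so gapped alignment has no
consumer), base-quality-aware mapping scores, and multi-mapping lists
(one best placement per read matches the downstream counting semantics).

## Consensus rule

For a pileup column, the winning base is the one with the highest summed
Phred quality (a tie, or N winning, fails the call). Its consensus
quality is the winner's summed quality minus the summed quality of all
other non-N bases, floored at 0 and capped at 93. A base is called only
when its supporting read count is strictly greater than
`min_depth_exclusive` (default 3) and the consensus quality is strictly
greater than `min_consensus_quality` (default 40); otherwise the call is
N and the reference base is left alone. The two thresholds are the
pipeline's defining confidence knobs; the difference-of-summed-qualities
form is this package's own definition of consensus quality — it penalises
contested columns while reducing to the summed quality of a clean column.

## Curing

`cure_reference` splits each 80-base progenitor read once into its first
and last 40 bases (reads shorter than 80 are dropped and counted), then
iterates: align both half-sets to the current reference, merge them into
one pileup (qualities summed across both), call the consensus, and
substitute every confidently called base that differs. Defaults: 6
cycles, fixed, with an optional early stop on a zero-change cycle (off by
default so runs are comparable). Positions that never reach the
thresholds keep the naive base — the only non-destructive choice.
Tie-breaking is reseeded deterministically from `rng_seed`, the cycle
index and the half index, so whole runs are byte-reproducible. The change
log records (unigene, position, old, new, cycle) for every substitution,
which supports per-cycle statistics and the concerted-change counter
(positions changed identically in both genome runs; these reflect shared
assembly artefacts and never become IHPs).

Why split to 40 bases: at ~3% divergence an 80-base read expects ~2.4
divergent sites plus sequencing error, frequently exceeding a cap of 3,
while a 40-base half expects ~1.2 — splitting is what lets the first
cycle get a foothold in moderately diverged regions, and iteration then
extends the reach into denser clusters as flanking corrections accumulate.

## IHP calling

The A-cured and C-cured references (same identifiers, same lengths by
construction) are compared position by position; differing, non-N base
pairs are IHPs. Positions where either genome remained N are silently
non-comparable rather than errors — N means "curing had no confident
evidence", not "conflict". Per-unigene density uses the full unigene
length as denominator (covered-length normalisation would require keeping
alignment state in a pure sequence comparison; the choice is exposed in
the table, which stores counts and lengths separately). The summary's
mean density is taken over unigenes with at least one IHP.

## Apportioning and RPKM

The combined reference holds `<unigene>_A` and `<unigene>_C` entries.
Each polyploid read increments exactly one version's count, so per-pair
counts conserve the reads mapped to the pair exactly. No fractional or
EM-style reassignment is attempted: the random tie-break is the model,
and its consequence — unigene pairs with no IHP in the covered window
regress to a 50:50 split, underestimating true bias — is an accepted,
predictable attenuation rather than a bias amplifier. RPKM is
`count * 1e9 / (length_bases * total_mapped)` with the sample's total
mapped reads counted over the whole combined reference; zero count gives
RPKM 0 even when the sample has no mapped reads, and a positive count
with zero total is an invalid state. Qualitative calls over replicates:
expressed iff every replicate has ≥ 1 read, non-expressed iff all are
zero, inconsistent otherwise.

## Paired quasi-Poisson test

Per unigene, the 2n observations (A and C over n replicates) are fit with
a log-link GLM with Poisson variance function; predictors are an
intercept, n − 1 replicate indicators (the paired blocking) and a genome
indicator. The fit is quasi-likelihood, so non-integer RPKM responses are
legitimate; fitting RPKM directly (rather than counts with offsets) is
the default because both genome versions of a unigene share a length and
each sample a depth, making the transformation monotone within the
comparison of interest. Dispersion Phi is the Pearson statistic divided
by the residual degrees of freedom (2n − (n + 1) = n − 1), estimated per
unigene — the natural reading of one GLM per paired series; a pooled
estimate would borrow strength but blur genuinely heterogeneous unigenes.
Inference on the genome coefficient is a Wald t test with n − 1 degrees
of freedom and Phi-scaled standard errors. Degenerate cases: fewer than 2
replicates or an all-zero series raise (and are dropped-but-reported by
the table-level driver); a (near-)perfect fit (Pearson chi2 ~ 0) makes
the scaled standard error meaningless, so a zero coefficient is reported
as p = 1 — perfectly symmetric data carry no evidence. A genome with all
zeros separates perfectly; the resulting huge scaled standard error makes
the test conservative there, which is accepted.

Benjamini–Hochberg adjustment is applied over the tested family only
(unigenes containing IHPs — pairs without IHPs are structurally unable to
show bias and would only dilute the family), and adjusted p < alpha
(default 0.05) with the coefficient's sign yields the A-higher /
C-higher call.

## Synthetic data: what it emulates, and what it does not

`simdata` plants a known truth: i.i.d. uniform ancestral sequences; each
position independently divergent with probability `divergence_rate`
(default 0.03), mutated in exactly one genome so the ancestral base
always matches the other; 80-base reads at Poisson coverage (default
30x), uniform starts and strands, independent substitution errors
(default 1%) and a flat-Q30 quality profile decaying toward Q20 after
base 60; four replicates of polyploid samples whose per-unigene A:C mix
follows planted expression levels, with observation-level gamma-Poisson
noise calibrated so counts have variance Phi times their mean (default
Phi 3) plus a shared lognormal replicate factor that the paired blocking
absorbs. The default fixture scale — 200 unigenes of 1 kb — was chosen
as the smallest universe at which the per-cycle curing dynamics, IHP
density distribution and apportioning statistics are all well resolved;
the full pipeline on it runs in well under a minute per stage on one CPU.

Real transcriptomes differ in ways the generator does not model: biased
codon/GC composition and repeat structure (which create more alignment
ties than uniform sequences), paralogue families at ~15% divergence,
expression-level heterogeneity across unigenes, length variation,
indels, and quality-dependent error profiles. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated generative model, not the field performance of the pipeline on any
particular organism.

## Numerical and interface conventions

- All in-memory coordinates are 0-based half-open; all file-facing
  coordinates (IHP/pileup/change-log TSV, SAM) are 1-based inclusive.
  Converters live only in the writers/readers.
- Quality encodings are explicit, never sniffed: Sanger (offset 33) is
  the internal standard; legacy Illumina-1.3 (offset 64) input is decoded
  on load. Phred values are validated into [0, 93].
- Sequences are uppercased on load; ambiguity codes other than N are
  rejected, because every downstream rule is defined over {A, C, G, T, N}.
- Every stochastic component (tie-breaking, simulation) takes an explicit
  seed, and derived seeds are reduced modulo 2^31; reruns with equal
  seeds are byte-identical, which the test suite asserts at pipeline
  level.
- The `simulate` CLI can add independent noise to the ancestral copy
  (`--naive-noise`) to emulate co-assembly artefacts shared by neither
  genome; the default is 0 so that planted divergence is the only signal.

## Known limitations

- Substitution-only: a real indel between homoeologues shifts the frame
  of every downstream IHP in that unigene and is invisible to the curing
  model.
- Unigene pairs without IHPs cannot be tested and near-identical pairs
  are attenuated toward 50:50; the method bounds bias estimates from
  below in such regions.
- Per-unigene Phi with n = 4 replicates is a noisy dispersion estimate;
  the t reference distribution compensates on average but individual
  p-values at very low counts are discrete and conservative.
- The aligner holds the k-mer index and pileup arrays for the whole
  reference in memory; it targets transcript-scale references (tens of
  Mb), not whole genomes.
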