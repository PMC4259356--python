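# Methods

This note documents the models, parameter choices and numerical conventions
behind `xenostroma`, and what the synthetic-data tests do and do not show
about real arrays.

## The measurement problem

A human-cancer-in-mouse-bone xenograft yields mixed RNA: mouse stroma
transcripts plus human cancer-cell transcripts at a model-dependent ratio
(1:1 for C4-2B, 1:5 for VCaP, 1:9 for PC-3 intra-osseous xenografts; 4:1
subcutaneous; 1:2 orthotopic — these measured ratios are the package
defaults). On a mouse array the human fraction contributes signal only
through probes whose sequences happen to match human transcripts. The
pipeline therefore (a) removes cross-hybridizing probes, (b) summarizes the
species-specific survivors, and (c) applies the downstream statistics to the
cleaned expression matrix.

## Probe masking

A probe is flagged when its longest contiguous exact match to the off-target
transcript set is at least `l_min` (default 15 nt) **or** its best ungapped
full-length identity at any offset is at least `i_min` (default 0.80), on
either strand; probes containing N are flagged conservatively. The exact
computational criterion of the emulated study is not published, so these
thresholds are explicit, config-exposed stand-ins in the range used by
short-oligo cross-hybridization heuristics. Probe-sets retaining fewer than
`min_probes` (default 4) species-specific probes are dropped.

Both scores are computed exactly, not heuristically: contiguous matches by
packed 2-bit k-mer membership tested at every word size from the probe
length downward (a shared substring of length k implies a shared k-word, so
the first word size with a hit is the exact longest match), and identity by
XOR/popcount comparison of each probe and its reverse complement against
every off-target window. The test suite pins both against brute-force
substring-set and sliding-window oracles. Probes longer than 32 nt are not
supported by the packed scanner.

At the default thresholds a 25-mer can reach 80% identity to a random window
by chance (~1e-8 per window pair), so a full-scale chip acquires a handful
of chance identity flags against a ~120 kb off-target set; this bounds
specificity near, but not at, 1.

## Synthetic data generator

Transcripts are i.i.d. uniform ACGT: codon structure, GC bias and repeats
are irrelevant to the masking and statistics under test, and uniform
sequences make the species-specificity guarantee constructive. Mouse
transcripts are the concatenation of their 11 probes (exact 25-nt
substrings) with 5-nt random spacers; human transcripts are 120 nt. Every
probe is rejection-sampled to share no 12-mer, on either strand, with the
human set or any other probe, so unplanted probes have off-target matches
< 12 nt — a clean margin below the 15-nt flag threshold. Planted
cross-hybridizing probes copy a contiguous window of recorded length
(uniform on [15, 25]) into one human transcript at a random position and
strand; the junction sequence is re-checked so no other probe gains an
off-target word, which makes the planted set *exactly* the set of probes
with a contiguous off-target match at the threshold.

Cross-hybridization is planted gene-clustered by default (genes are visited
in random order and each of their probes planted with probability 0.5 until
the budget `frac_crosshyb_probes` — default 5% of probes — is spent). This
mirrors the biology (a mouse gene with a close human homolog has many
affected probes, which is why the emulated study excluded whole probe-sets)
and makes the contamination bias visible through a median summarizer; a
uniform per-probe mode is config-exposed.

Intensities are log-normal: linear signal = mouse abundance (2^N(8, 1.5),
shifted by the true log2FC in the osteoinductive xenograft groups only)
plus, for planted probes, `contamination_coef` (default 0.25) × the
sample's human:mouse ratio × the partner transcript's abundance; Gaussian
noise (default sd 0.25) is added on the log2 scale. Mouse abundance is not
rescaled per sample — the emulated protocol equalized loaded cRNA — so with
no contamination and no noise the summarized group difference equals the
planted log2FC exactly, which the tests assert to machine precision.

True DE genes are 10% of the mouse genes by default, 64% up-regulated (the
direction split reported for the stroma response), with |log2FC| ~
max(0.5, N(1.5, 0.3)). Replicates follow the study: three per group except
sham bones and Ep156T control xenografts (two). The Ep156T mixing ratio is
not reported and is set to 1:9 (non-tumorigenic cells, minor human
content).

What the generator does **not** emulate: probe affinity effects, scanner
artifacts and saturation, background, RNA degradation, correlated biological
variability, gapped or thermodynamic hybridization. Passing tests therefore
demonstrate the correctness of the algorithms under the stated generative
model, not the preprocessing fidelity of any specific real-array protocol.

## Expression

Quantile normalization maps every array onto the mean of the sorted columns
(average-rank ties), then probe-sets are summarized as the median of log2
intensities over retained probes. Median polish was rejected because the
generator has no probe-affinity terms; a mean summarizer and a
constant-offset background subtraction exist as options. Normalization is
applied **after** masking, to retained probes only: contaminated probes
distort the rank mapping of clean probes if left in the matrix. Quantile
normalization slightly compresses fold changes when differential expression
is asymmetric (64% up); at loose lfdr thresholds this inflates the false
discovery proportion of the end-to-end pipeline, which is one reason the
emulated study used very stringent per-model thresholds.

## Differential expression

Moderated t per the empirical-Bayes variance hierarchy; hyperparameters by
moment matching on log s² with the trigamma-inverse Newton iteration. When
the dispersion of log s² does not exceed its sampling value trigamma(d/2),
d0 = ∞ and s0² is the plain mean of the sample variances (the convention of
the reference implementation, against which the suite verifies t-statistics
to 1e-8 on a shared fixture); the t statistic is then referenced to the
normal limit. With d0 = 0 the statistic reduces to the classical pooled t.
Genes with zero variance and d0 = 0 get an undefined statistic (NaN), not a
crash.

Local FDR uses the two-component mixture on two-sided p-values: f is the
Grenander (nonincreasing) density — the left derivative of the least concave
majorant of the p-value ECDF — and π₀ is the larger of the Storey count
estimate on [0.75, 1] and the terminal Grenander slope. Taking the max
guarantees lfdr(1) = 1 while keeping the count estimator's recovery accuracy
(π₀ = 0.8 mixtures recovered within ±0.07 in the tests); lfdr is
nondecreasing in p because f is nonincreasing. The study's thresholds
(1e-5 for C4-2B, 3e-5 for VCaP, 0.2 for control contrasts) are named presets;
whether the original values were local-fdr or tail-area quantities is not
determinable from the text, and a Benjamini–Hochberg option is provided for
comparison. An empirical null on z-scores is out of scope — the simulator
satisfies the theoretical uniform null.

## Curation

The combined stroma transcriptome is the union of the per-model DE lists; a
gene is "common" if present in both lists regardless of direction, with
direction disagreements flagged (not removed) — cross-model concordance is
near-total (R² ≈ 0.99 in simulation), so discordance is a rare, log-worthy
event. Subtraction matches symbols only, in the order
inflammatory/wound/desmoplastic → non-osteotropic cancers → osteotropic
primary tumors, over the union gene set (a per-model mode is possible by
curating each list separately). The ledger records each stage's removed set
and asserts exact conservation: core ⊎ stage-removals = starting set. The
component *union* is order-invariant; per-component membership is
order-sensitive by design. Ortholog harmonization defaults to the
mouse↔human casing convention with an override table; collisions resolve to
the first canonical pair and are logged.

## Enrichment

Signature overlap uses the one-sided hypergeometric upper tail with the
signature restricted to the measured universe; coverage is reported as the
percentage of the signature contained in the query. The test suite checks
the p-value against exhaustive enumeration of all C(15,6) draws at N = 15.

Motif "frequency" is binary per gene — the fraction of genes with ≥ 1
promoter hit — matching the convention of promoter-scanning tools (a
hit-density variant would count windows). A window is a hit when its
log-odds score (uniform 0.25 background, 1e-3 pseudocount) reaches 80% of
the motif's maximum score, on either strand; N-containing windows never hit.
Promoters are fixed 2-kb windows upstream of the TSS, so background draws
are cardinality-matched without GC or length matching. Resampling draws
gene sets of the cluster's size from the background pool **with
replacement** (bootstrap): the package's reference configuration uses a
background pool the same size as the cluster, where without-replacement
draws would be degenerate (every draw the whole pool). The p-value uses the
add-one convention, p = (1 + #{resample ≥ observed})/(n + 1), never exactly
zero, resolution 1/(n+1). A result is marked reportable when EF ≥ 1.2 and
p < 1e-4 (the band's upper edge is treated as a lower bound, not a cap).
The packaged PWMs in `data/motifs.meme` are synthetic constructs (named
SYN_*) built for the planted-motif tests; licensed motif databases are not
redistributed.

## Problem sizes and determinism

Default study scale is 1000 genes per species × 11 probes (11,000 probes,
~120 kb off-target sequence); the packaged `run-all` fixture uses 150 genes
so the end-to-end demo completes in seconds, and the masking-benefit
comparison uses 200 genes at 20% planted cross-hybridization, noise-free
(the comparison targets the systematic error component; with probe noise on,
both arms share the same noise floor). All randomness flows through
`numpy.random.default_rng` seeded from the config, and identical configs
produce byte-identical outputs; the committed fixture outputs are verified
byte-for-byte in the test suite.

## Known limitations

- Masking is exact-match/ungapped only; no thermodynamic model, no gapped
  alignment. Probes > 32 nt are unsupported.
- The lfdr estimator requires ≥ 100 p-values and assumes a uniform null;
  heavy discreteness or correlation between genes will miscalibrate it.
- Quantile normalization assumes comparable distributions across arrays;
  under strong asymmetric DE it compresses fold changes (documented above).
- The ortholog map is a casing convention plus overrides — adequate for the
  synthetic symbol space, a simplification for real genomes (no paralogy
  resolution beyond first-pair collision handling).
- The generator's planted overlap structure makes curation exact by
  construction; real signature subtraction inherits symbol-mapping noise
  that has no analog here.
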