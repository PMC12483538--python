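# Methods

## Problem and approach

Some bacterial antiphage defence systems carry reverse transcriptases that,
upon infection, synthesize long untemplated single-stranded DNA homopolymers —
poly-dA with a minority complementary poly-dT strand. In immunoprecipitation
sequencing (cDIP-seq) of such systems these products do not align anywhere on
the host/phage reference and so hide inside the *unmapped* read fraction.
`polyscan` implements the computational procedure for discovering and
quantifying them: stringent trimming so that no residual adapter can mimic a
low-complexity signal, partitioning reads into mapped/unmapped, scanning the
unmapped set for mismatch-tolerant homopolymer windows and dA/dT junction
chimeras, normalising counts per million filtered reads, quantifying the
orientation asymmetry of the chimeras, and calibrating the poly-dA capture
bias with spike-in oligos. A synthetic read generator with per-read ground
truth drives every validation, so no external data are needed.

## Pattern model

A read *contains a homopolymer* of base `b` when some window of `L`
consecutive positions differs from `b` at no more than `m` positions
(defaults `L = 25`, `m = 1`). A read contains a *chimeric junction* when a
window of `2h` positions (default `h = 10`) is poly-dA in its first half and
poly-dT in its second half (orientation AT), or the reverse (TA), within the
same mismatch budget. `N` never matches any target base.

Presence is a per-read, per-class indicator: a read counts once per class
regardless of how many windows qualify, and classes are not mutually
exclusive (a read with both an A₂₅ run and an A₁₀T₁₀ junction contributes to
both; the overlap is reported separately). For hit reporting, overlapping
qualifying windows of one class are merged into maximal intervals, each
carrying the minimal mismatch count of its constituent windows — this avoids
the double counting that per-window reporting of a long run would produce.

Under a uniform-base null the per-read probability of a (25, 1) homopolymer
call is bounded by `4 · 126 · (1 + 25·3) · 0.25²⁵ < 10⁻⁹` for 150-nt reads,
so any call on a run-free background is diagnostic of a real product or a
pipeline defect; the acceptance suite verifies zero calls on 10⁶ error-free
background reads.

## Trimming

Quality trimming removes the 3′ suffix starting at the index `i*` that
maximises `Σ_{j≥i}(q − quality_j)` (the classic partial-sum cut; default
`q = 30`), keeping more bases on ties. Adapter removal finds the leftmost
qualifying match of the 3′ adapter stem `AGATCGGAAGAGC`: a full internal
occurrence removes the adapter and everything 3′ of it (this achieves what
tiling the adapter across offsets achieves); a partial occurrence must abut
the 3′ end with matched length `ℓ ≥ O` (default `O = 10`). The mismatch
budget is `floor(e·ℓ)` with `e = 0.2`, Hamming only — indels are not
modelled, which keeps the matcher exactly checkable against brute-force
enumeration and matches a substitution-dominated short-read error profile.

The pipeline iterates quality → adapter trimming to a fixpoint before the
length filter (45 nt for unmapped-read analysis, 15 nt for the plain mapping
pass). Iteration is deliberate: a cut can expose a new qualifying 3′ suffix,
and the pipeline's contract — audited by brute force in the tests — is that
*no* retained read carries a qualifying residual adapter match and that the
pipeline is idempotent. A single pass satisfies neither. One consequence the
tests make explicit: a genomic insert that by chance ends in an adapter-like
stretch is trimmed deeper than its true insert boundary; no sequence-based
trimmer can avoid this, and at default settings it affects well under 1% of
reads.

## Mapped/unmapped partition

Instead of a production aligner, reads are partitioned with an exact
canonical k-mer classifier: the reference's k-mers (default `k = 31`,
canonicalised as min(k-mer, reverse complement) so both strands are covered)
are indexed, and a read is *mapped* when at least `tau = 0.5` of its k-mers
are present. On synthetic data this reproduces an aligner's partition
deterministically: verbatim background fragments hit fraction 1.0, and
homopolymer/spike reads share no k-mer with a reference that contains no long
single-base run. Reads shorter than k are unmapped by definition (they cannot
occur at the default 45-nt length minimum). At the default 0.002/base
substitution rate, two well-separated errors can destroy just over half of a
150-nt read's 120 k-mers, so background recall is slightly above 0.99 rather
than 1; the tests assert the 0.99 floor pooled over five seeds. The
correspondence between aligner-unmapped and k-mer-unmapped is exact only on
synthetic data; replicating the analysis on real data would require an
aligner and is out of scope.

## Synthetic data generator

The generator emulates the features the statistics depend on, with defaults:

| parameter | default | rationale |
|---|---|---|
| read_length | 150 nt | standard short-read length |
| background_genome_length | 100 kb | large enough for diverse k-mers, fast to index |
| gc_fraction | 0.5 | neutral composition |
| homopolymer_read_fraction `f` | 0.02 | a few percent of the library, the regime where the discovery statistic matters |
| second_strand_fraction `s` | 0.3 | poly-dT minority among homopolymer molecules |
| capture_bias `beta` | 1.0 | unbiased unless an experiment sets otherwise |
| chimera_read_fraction `c` | 0.005 | junction reads are ~10× rarer than homopolymer reads |
| chimera_orientation_ratio `rho` | 4.0 | AT excess, the direction implied by poly-dA-first synthesis |
| molecule_length | log-uniform 1,000–10,000 nt | spans the observed decade evenly in log space; no distribution is known |
| substitution_error_rate | 0.002/base | typical modern short-read platform |
| adapter_read_through_fraction | 0.2 | minority of short inserts |
| quality model | mean 36, −0.02/base, sd 2, clamped [2, 40] | mild 3′ decline |

Design choices where the design was genuinely open:

* **Capture bias as pre-sequencing thinning at fixed depth.** Poly-dA
  molecules are retained with probability ∝ `beta` before the pool is
  sequenced to `n_reads`; at fixed depth this enters as renormalised origin
  weights `(1−f−c, f·(1−s)·beta, f·s, c)`. With `beta = 1` the realized
  homopolymer fraction equals `f` exactly. Chimeric molecules are not
  thinned — they carry both strands and there is no basis for assigning them
  either species' retention.
* **Chimeric reads carry exactly one junction**, placed uniformly within the
  insert with a 10-nt margin on each side so every chimera read is in
  principle detectable at the default half-length; orientation is drawn with
  odds `rho`.
* **Second-strand poly-dT reads are independent molecules**, not paired
  duplexes; nothing downstream uses pairing, and reads are single-end
  throughout (a paired protocol adds nothing to a per-read presence
  statistic; each mate would simply be an independent read).
* **Read-through inserts are uniform on [40, read_length − 13]**, so a
  read-through read always contains the full adapter stem followed by random
  filler. This makes the ground-truth round trip well defined (after
  trimming, the retained read *is* the insert) and exercises the 45-nt
  length filter with the 40–44-nt tail.
* **Background genomes contain no single-base run ≥ 25 nt** (violating
  windows are resampled), so false positives can arise only from sequencing
  error and the null is analytically checkable.

The generator does **not** model PCR duplicates, indels, paired-end
geometry, flow-cell artifacts, or single-strand library chemistry beyond the
capture thinning. Passing tests therefore demonstrate the pipeline's
correctness and calibration under this generative model, not performance on
real libraries, where aligner behaviour, duplicated reads and indel errors
would add variance the tests do not probe.

Everything is driven by one `numpy` `Generator` seeded from the config, so
identical configurations give byte-identical FASTQ output.

## Quantification

* **Per-million normalisation**: `count / total_filtered_reads × 10⁶`, where
  the denominator is the reads passing the prep pipeline in the same mode
  that produced the scanned set; computed in exact rational arithmetic
  before float conversion.
* **Orientation asymmetry**: `ratio = (AT + 0.5)/(TA + 0.5)`
  (Haldane–Anscombe correction, flagged when a raw count is zero) and its
  log₂. The delta-method 99% CI half-width used in validation is
  `2.5758·sqrt(1/AT + 1/TA)/ln 2`.
* **Capture bias**: from a two-species spike-in design,
  `beta_hat = (observed dA / observed dT) / (input dA fmol / input dT fmol)`,
  with observed counts taken as detected dA₂₅- and dT₂₅-containing reads.
  Single-species arms are specificity controls and return counts only.
  `correct_counts` divides the dA-derived classes (homopolymer_A and both
  chimera classes, whose captured molecule carries a dA block) by
  `beta_hat`.
* **TPM**: `count/length`, rescaled to 10⁶ per sample; conservation holds to
  1 part in 10⁶.
* **Condition contrasts** stop at per-condition means and a log₂ fold change
  with a 0.1-per-million pseudocount; model-based differential testing is
  deliberately out of scope.

## Validation experiment sizes

The validation suite (and `scripts/acceptance.py`) uses: 10,000 reads for
scanner-vs-oracle equivalence; 10⁶ reads for the analytic null (simulated in
10⁵-read chunks); 200,000 reads for end-to-end truth recovery (f = 0.02,
s = 0.3, beta = 0.1, error 0.002); spike depth 10⁵ × 3 seeds per bias level;
8,000 reads for the trimming audit; 60,000 reads (~3,000 chimeras) for
orientation recovery. These sizes put 3-SD binomial tolerances well below
the effect sizes being recovered while keeping a full run in a few minutes
on one CPU.

## Known limitations

* The magnitude of the real poly-dA capture bias is not known numerically;
  `beta` is a free simulator parameter and bias recovery is validated on
  simulation only.
* The k-mer classifier is not an aligner; coordinates, CIGARs and coverage
  tracks are out of scope.
* Homopolymer counting is per read, with no mate deduplication; the mismatch
  allowance applies per window occurrence.
* Adapter matching is Hamming-only; an indel inside a real adapter would
  shift the frame and can leave a residual partial match shorter than `O`.
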