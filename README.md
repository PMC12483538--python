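# polyscan

Mine sequencing reads for homopolymeric cDNA products.

Some bacterial antiphage defence systems carry reverse transcriptases that,
on infection, synthesize long untemplated single-stranded DNA — predominantly
poly-dA, with a minority complementary poly-dT strand and rare chimeric
molecules where a dA block abuts a dT block. Because these products match
nothing in the host or phage genome, they surface in immunoprecipitation
sequencing (cDIP-seq) only as *unmapped* reads, where they are easy to
dismiss as adapter dimer or low-quality noise. `polyscan` implements the
analysis that turns that unmapped fraction into evidence:

1. **`simulate`** — a synthetic cDIP-seq read generator with per-read ground
   truth (origin labels, insert lengths, junction positions), used to
   validate every downstream step.
2. **`prep`** — stringent trimming (partial-sum quality cut at Q30,
   Hamming adapter matching at error rate 0.2 with minimum overlap 10,
   iterated to a fixpoint, 45-nt length floor) so that no residual adapter
   can masquerade as a low-complexity signal.
3. **`classify`** — a canonical k-mer (k = 31) mapped/unmapped partition
   against a reference; a read is mapped when ≥ 50% of its k-mers occur in
   the reference on either strand.
4. **`scan`** — per-read detection of homopolymer windows (≥ 25 bases, ≤ 1
   mismatch) and dA₁₀→dT₁₀ / dT₁₀→dA₁₀ chimeric junctions.
5. **`quantify`** — per-million normalisation, chimera orientation asymmetry
   with the Haldane–Anscombe correction, spike-in estimation of the poly-dA
   capture bias `beta_hat`, bias-corrected counts, TPM, and condition
   contrasts.

See [docs/methods.md](docs/methods.md) for the statistical model, parameter
rationale and known limitations.

## Worked example

Simulate a 20,000-read sample (2% homopolymer molecules, 0.5% chimeras) and
run the full pipeline from the shell:

```sh
polyscan simulate --seed 42 --n-reads 20000 --out-dir sim
polyscan prep --fastq sim/reads.fastq.gz --out prepped.fastq.gz
# -> retained 19791 reads
polyscan classify --ref sim/reference.fa --fastq prepped.fastq.gz \
    --out-tsv classified.tsv --unmapped-fastq unmapped.fastq.gz
# -> unmapped fraction: 0.037391
polyscan scan --fastq unmapped.fastq.gz --counts-out counts.json
polyscan quantify --counts counts.json --total-reads 19791 --out quant.json
```

`quant.json` then contains (abridged):

```json
{
  "class_counts": {"homopolymer_A": 354, "homopolymer_T": 237,
                   "chimera_AT": 89, "chimera_TA": 26},
  "class_per_million": {"homopolymer_A": 17886.92, "homopolymer_T": 11975.14},
  "chimera_orientation": {"ratio": 3.377, "log2_ratio": 1.756, "flagged": false}
}
```

The same analysis as a library call:

```python
from polyscan import (SimConfig, simulate_sample, generate_background_genome,
                      PipelineParams, analyze_sample)

genome = generate_background_genome(100_000, seed=7)
reads, truth = simulate_sample(SimConfig(seed=42, n_reads=20_000), genome)
result = analyze_sample(reads, {"chr": genome}, PipelineParams(), "demo")
print(result.summary.per_million["homopolymer_A"])
```

## Validation and reproducing the results

Every statistical guarantee the package makes is encoded as a test in
`tests/test_acceptance.py`, backed by the shared experiment implementations
in `polyscan.experiments` (which use independent brute-force oracles, never
the scanner under test, to define expected behaviour):

* the window scanners agree exactly with brute-force enumeration on 10,000
  random reads;
* one million error-free reads from a run-free background produce **zero**
  homopolymer calls, as the analytic union bound (< 10⁻⁹ per read) predicts;
* on a 200,000-read sample with known composition, the pipeline's
  per-million homopolymer counts land within 3 binomial SDs of the
  ground-truth expectation, and every truth-labelled homopolymer read ends
  up unmapped;
* an equimolar spike-in recovers a simulated capture bias of 1.0 and 0.1
  within ±20%;
* after trimming, a brute-force audit finds no residual adapter match, no
  read under 45 nt, and the pipeline is idempotent;
* a simulated 4:1 chimera orientation ratio is recovered within the 99%
  confidence interval;
* TPM sums to 10⁶ and the two-feature worked example splits exactly in half;
* pattern counts are monotone in the mismatch allowance and window length.

Run them with `pytest tests/test_acceptance.py` (about five minutes), or
recompute the headline numbers directly:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which re-runs all experiments from fresh seeds derived from `--seed` and
writes each measured quantity as `{"name": {"value": ..., "n": ...}}`.

## Layout

```
src/polyscan/
  io.py           FASTQ/FASTA I/O, Read record, base encoding
  prep.py         quality/adapter trimming, length filter, PipelineParams
  classify.py     canonical k-mer reference index and mapped/unmapped calls
  scan.py         homopolymer and chimera window scanners, per-class counts
  simulate.py     synthetic read generator + ground truth, spike-in simulator
  report.py       normalisation, asymmetry, bias estimation, TPM, contrasts
  pipeline.py     analyze_sample: prep -> classify -> scan -> summarise
  experiments.py  validation experiments shared by tests and scripts/
  cli.py          click command-line interface
```
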