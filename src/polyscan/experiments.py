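"""Reproducible synthetic validation experiments.

Each function runs one self-contained in-silico experiment against the
simulator's ground truth and returns plain dictionaries of the measured
quantities: scanner agreement with a brute-force window oracle, the analytic
null (zero homopolymer calls on run-free background), end-to-end recovery of
truth-table pattern frequencies through the full pipeline, spike-in
capture-bias recovery, trimming audits, and orientation-asymmetry recovery.

The brute-force scanner oracle here enumerates every window with plain string
operations and shares no code with the vectorised scanner it checks.
"""

from __future__ import annotations

import math

import numpy as np

from .classify import build_index, classify_reads, extract_unmapped
from .io import Read
from .prep import PipelineParams, prep_pipeline
from .report import estimate_capture_bias, orientation_asymmetry
from .scan import count_reads_with_patterns, scan_chimera, scan_homopolymer
from .simulate import (
    SimConfig,
    SpikeInDesign,
    generate_background_genome,
    simulate_sample,
    simulate_spikein,
    truth_pattern_read_ids,
)

__all__ = [
    "oracle_agreement",
    "null_false_positives",
    "end_to_end_recovery",
    "spikein_bias_recovery",
    "trimming_audit",
    "orientation_recovery",
    "count_monotonicity_violations",
]


def _brute_homopolymer_windows(seq: str, base: str, L: int, m: int):
    return [
        (p, L - seq[p : p + L].count(base))
        for p in range(len(seq) - L + 1)
        if L - seq[p : p + L].count(base) <= m
    ]


def _brute_chimera_windows(seq: str, half: int, m: int, first: str, second: str):
    out = []
    for p in range(len(seq) - 2 * half + 1):
        mm = (half - seq[p : p + half].count(first)) + (
            half - seq[p + half : p + 2 * half].count(second)
        )
        if mm <= m:
            out.append((p, mm))
    return out


def _merge_brute(windows, width):
    merged = []
    for p, mm in windows:
        if merged and p < merged[-1][0] + merged[-1][1]:
            s, ln, best = merged[-1]
            merged[-1] = (s, p + width - s, min(best, mm))
        else:
            merged.append((p, width, mm))
    return merged


def oracle_agreement(n_reads: int = 10_000, read_length: int = 150, seed: int = 1) -> dict:
    """Compare scanner output with brute-force window enumeration.

    Scans ``n_reads`` seeded uniform-random reads with the homopolymer scanner
    at (L=25, m in {0,1}) for all four bases and the chimera scanner at
    half_len=10, m in {0,1}; counts reads on which merged hit intervals differ
    from the oracle's.
    """
    rng = np.random.default_rng(seed)
    disagreements = 0
    for _ in range(n_reads):
        seq = "".join(rng.choice(list("ACGT"), read_length))
        ok = True
        for m in (0, 1):
            for base in "ACGT":
                _, hits = scan_homopolymer(seq, base, 25, m)
                got = [(h.start, h.length, h.mismatches) for h in hits]
                want = _merge_brute(_brute_homopolymer_windows(seq, base, 25, m), 25)
                ok &= got == want
            at, ta = scan_chimera(seq, 10, m)
            for hits, (first, second) in ((at, ("A", "T")), (ta, ("T", "A"))):
                got = [(h.start, h.length, h.mismatches) for h in hits]
                want = _merge_brute(
                    _brute_chimera_windows(seq, 10, m, first, second), 20
                )
                ok &= got == want
        disagreements += not ok
    return {"n_reads": n_reads, "disagreements": disagreements}


def null_false_positives(
    n_total: int = 1_000_000, seed: int = 1, chunk: int = 100_000
) -> dict:
    """Homopolymer calls at (L=25, m=1) on error-free background-only reads.

    The background genome is constructed without native >= 25-nt runs, so the
    union-bound false-positive probability is below 1e-9 per read and the
    observed call count should be exactly zero.
    """
    genome = generate_background_genome(100_000, 0.5, seed=seed)
    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(-(-n_total // chunk))]
    calls = 0
    scanned = 0
    params = PipelineParams()
    for sub in sub_seeds:
        n = min(chunk, n_total - scanned)
        cfg = SimConfig(
            seed=sub,
            n_reads=n,
            homopolymer_read_fraction=0.0,
            chimera_read_fraction=0.0,
            substitution_error_rate=0.0,
            adapter_read_through_fraction=0.0,
        )
        reads, _ = simulate_sample(cfg, genome)
        counts = count_reads_with_patterns(reads, params)
        calls += sum(
            counts.counts[f"homopolymer_{b}"] for b in "ACGT"
        )
        scanned += n
    return {"n_reads": scanned, "homopolymer_calls": calls}


def end_to_end_recovery(
    seed: int = 777,
    n_reads: int = 200_000,
    homopolymer_read_fraction: float = 0.02,
    second_strand_fraction: float = 0.3,
    capture_bias: float = 0.1,
    substitution_error_rate: float = 0.002,
) -> dict:
    """Full pipeline on one simulated sample, scored against ground truth.

    Returns observed and truth-expected per-class counts among filtered reads,
    the per-million values, the 3-binomial-SD tolerance for each class, the
    unmapped fraction, and whether every truth-labelled homopolymer read that
    survived filtering sits in the unmapped partition.
    """
    genome = generate_background_genome(100_000, 0.5, seed=seed)
    cfg = SimConfig(
        seed=seed,
        n_reads=n_reads,
        homopolymer_read_fraction=homopolymer_read_fraction,
        second_strand_fraction=second_strand_fraction,
        capture_bias=capture_bias,
        substitution_error_rate=substitution_error_rate,
    )
    reads, truth = simulate_sample(cfg, genome)
    params = PipelineParams()
    filtered, _, total = prep_pipeline(reads, params)
    index = build_index([("background", genome)], k=params.kmer_k)
    classified = classify_reads(filtered, index, tau=params.mapped_kmer_fraction)
    unmapped = list(extract_unmapped(filtered, classified))
    counts = count_reads_with_patterns(unmapped, params)

    filtered_ids = {r.read_id for r in filtered}
    unmapped_ids = {r.read_id for r in unmapped}
    origin = truth.set_index("read_id")["origin"].astype(str)
    hp_ids = set(origin[origin.isin(["polyA_molecule", "polyT_molecule"])].index)
    hp_filtered = hp_ids & filtered_ids
    expected_sets = truth_pattern_read_ids(truth, L=params.homopolymer_min_len)

    result: dict = {
        "n_reads": n_reads,
        "total_filtered_reads": total,
        "unmapped_reads": len(unmapped),
        "unmapped_fraction": len(unmapped) / total,
        "all_homopolymer_reads_unmapped": hp_filtered <= unmapped_ids,
        "observed": {},
        "expected": {},
        "per_million_observed": {},
        "per_million_expected": {},
        "tolerance_3sd": {},
    }
    for cls in ("homopolymer_A", "homopolymer_T", "chimera_AT", "chimera_TA"):
        expected = len(expected_sets[cls] & filtered_ids)
        observed = counts.counts[cls]
        p_hat = expected / total
        sd = math.sqrt(total * p_hat * (1 - p_hat))
        result["observed"][cls] = observed
        result["expected"][cls] = expected
        result["per_million_observed"][cls] = observed / total * 1e6
        result["per_million_expected"][cls] = expected / total * 1e6
        result["tolerance_3sd"][cls] = 3 * sd
    return result


def spikein_bias_recovery(
    true_beta: float,
    seeds: tuple[int, ...] = (1, 2, 3),
    depth: int = 100_000,
    background_reads: int = 20_000,
) -> dict:
    """Estimate beta from an equimolar 50:50 fmol spike-in experiment.

    For each seed: simulate a clean background sample (no homopolymer
    molecules, mimicking lysate from cells with an inactive polymerase), mix
    in ``depth`` spike reads thinned by ``true_beta``, run prep + scanning,
    and estimate beta from the detected dA25 vs dT25 read counts.
    """
    design = SpikeInDesign("equimolar", 50.0, 50.0)
    params = PipelineParams()
    estimates = []
    for seed in seeds:
        genome = generate_background_genome(100_000, 0.5, seed=seed)
        cfg = SimConfig(
            seed=seed,
            n_reads=background_reads,
            homopolymer_read_fraction=0.0,
            chimera_read_fraction=0.0,
        )
        bg, _ = simulate_sample(cfg, genome)
        mixed, _ = simulate_spikein(
            design, depth, true_beta, bg, seed=seed, config=cfg
        )
        filtered, _, _ = prep_pipeline(mixed, params)
        counts = count_reads_with_patterns(filtered, params)
        est = estimate_capture_bias(
            counts.counts["homopolymer_A"], counts.counts["homopolymer_T"], design
        )
        estimates.append(est.beta_hat)
    return {
        "true_beta": true_beta,
        "depth": depth,
        "beta_hats": estimates,
        "mean_beta_hat": float(np.mean(estimates)),
    }


def trimming_audit(seed: int = 99, n_reads: int = 8_000) -> dict:
    """Brute-force residual-adapter and length audit of the prep output."""
    genome = generate_background_genome(100_000, 0.5, seed=seed)
    cfg = SimConfig(seed=seed, n_reads=n_reads, adapter_read_through_fraction=0.5)
    reads, _ = simulate_sample(cfg, genome)
    params = PipelineParams()
    filtered, _, total = prep_pipeline(reads, params)
    adapter = params.adapter_sequence
    e, O, alen = params.max_error_rate, params.min_overlap, len(adapter)
    residual = 0
    for r in filtered:
        seq, n = r.sequence, len(r)
        bad = False
        for ell in range(O, min(alen, n) + 1):
            p = n - ell
            mm = sum(a != b or a == "N" for a, b in zip(seq[p:], adapter[:ell]))
            if mm <= int(e * ell):
                bad = True
                break
        if not bad:
            for p in range(0, n - alen + 1):
                mm = sum(
                    a != b or a == "N" for a, b in zip(seq[p : p + alen], adapter)
                )
                if mm <= int(e * alen):
                    bad = True
                    break
        residual += bad
    refiltered, _, retotal = prep_pipeline(filtered, params)
    return {
        "n_reads": n_reads,
        "retained": total,
        "residual_adapter_reads": residual,
        "short_retained_reads": sum(len(r) < params.min_length_unmapped for r in filtered),
        "idempotent": retotal == total
        and all(a.sequence == b.sequence for a, b in zip(filtered, refiltered)),
    }


def orientation_recovery(
    seed: int = 11, rho: float = 4.0, n_reads: int = 60_000
) -> dict:
    """Recover the chimera orientation ratio from a simulated sample.

    Simulates a chimera-rich sample (about 3,000 junction reads), runs prep
    and scanning, and returns the continuity-corrected log2 orientation ratio
    with its 99% normal-approximation confidence half-width around log2(rho).
    """
    genome = generate_background_genome(100_000, 0.5, seed=seed)
    cfg = SimConfig(
        seed=seed,
        n_reads=n_reads,
        homopolymer_read_fraction=0.0,
        chimera_read_fraction=0.05,
        chimera_orientation_ratio=rho,
    )
    reads, _ = simulate_sample(cfg, genome)
    params = PipelineParams()
    filtered, _, _ = prep_pipeline(reads, params)
    counts = count_reads_with_patterns(filtered, params)
    n_at, n_ta = counts.counts["chimera_AT"], counts.counts["chimera_TA"]
    _, log2_ratio, _ = orientation_asymmetry(n_at, n_ta)
    # delta-method SE of log2(AT/TA) for independent Poisson-like counts
    ci99_halfwidth = 2.5758 * math.sqrt(1 / n_at + 1 / n_ta) / math.log(2)
    return {
        "rho": rho,
        "chimera_AT": n_at,
        "chimera_TA": n_ta,
        "log2_ratio": log2_ratio,
        "log2_rho": math.log2(rho),
        "ci99_halfwidth": ci99_halfwidth,
    }


def count_monotonicity_violations(
    n_sets: int = 100, reads_per_set: int = 200, seed: int = 21
) -> dict:
    """Check count monotonicity in (L, m) over random A-rich read sets."""
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_sets):
        probs = rng.dirichlet([4, 1, 1, 2])
        reads = [
            Read(
                f"x{i}",
                "".join(rng.choice(list("ACGT"), 150, p=probs)),
                np.full(150, 38),
            )
            for i in range(reads_per_set)
        ]

        def n_calls(L, m):
            params = PipelineParams(homopolymer_min_len=L, max_mismatch=m)
            c = count_reads_with_patterns(reads, params)
            return sum(c.counts[f"homopolymer_{b}"] for b in "ACGT")

        base = n_calls(25, 1)
        if not (n_calls(25, 0) <= base <= n_calls(25, 2)):
            violations += 1
        if not (n_calls(26, 1) <= base <= n_calls(24, 1)):
            violations += 1
    return {"n_sets": n_sets, "violations": violations}
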