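"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive string operations (window enumeration with
``str.count``, exhaustive cut-position search) so they share no code with the
vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from polyscan import Read, SimConfig, generate_background_genome, simulate_sample

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_homopolymer(seq: str, base: str, L: int, m: int):
    """Enumerate every length-L window; merge qualifying ones naively."""
    qualifying = []
    for p in range(len(seq) - L + 1):
        mm = L - seq[p : p + L].count(base)
        if mm <= m:
            qualifying.append((p, mm))
    return bool(qualifying), _merge(qualifying, L)


def brute_chimera(seq: str, half: int, m: int):
    """Enumerate every 2*half window for both junction orientations."""
    out = {}
    for name, first, second in (("AT", "A", "T"), ("TA", "T", "A")):
        qualifying = []
        for p in range(len(seq) - 2 * half + 1):
            mm = (half - seq[p : p + half].count(first)) + (
                half - seq[p + half : p + 2 * half].count(second)
            )
            if mm <= m:
                qualifying.append((p, mm))
        out[name] = _merge(qualifying, 2 * half)
    return out["AT"], out["TA"]


def _merge(qualifying: list[tuple[int, int]], width: int):
    """Naive merge of overlapping (start, mismatches) windows."""
    merged = []
    for p, mm in qualifying:
        if merged and p < merged[-1][0] + merged[-1][1]:
            s, ln, best = merged[-1]
            merged[-1] = (s, p + width - s, min(best, mm))
        else:
            merged.append((p, width, mm))
    return [(s, ln, mm) for s, ln, mm in merged]


def brute_quality_cut(qualities, q: int) -> int:
    """Best suffix-cut index by exhaustive search; ties keep more bases."""
    n = len(qualities)
    best_i, best_sum = n, 0
    for i in range(n + 1):
        total = sum(q - qual for qual in qualities[i:])
        if total > best_sum or (total == best_sum and i > best_i):
            best_i, best_sum = i, total
    return best_i


def residual_adapter_match(seq: str, adapter: str, e: float, O: int) -> bool:
    """True when any qualifying adapter match remains (suffix or internal)."""
    n, alen = len(seq), len(adapter)
    for ell in range(O, min(alen, n) + 1):
        p = n - ell
        mm = sum(a != b or a == "N" for a, b in zip(seq[p:], adapter[:ell]))
        if mm <= int(e * ell):
            return True
    for p in range(0, n - alen + 1):
        mm = sum(a != b or a == "N" for a, b in zip(seq[p : p + alen], adapter))
        if mm <= int(e * alen):
            return True
    return False


def qualifying_match_at(seq: str, p: int, adapter: str, e: float, O: int) -> bool:
    """True when a qualifying adapter match starts at position p of seq."""
    n, alen = len(seq), len(adapter)
    ell = min(alen, n - p)
    if ell == alen or (n - p >= O and p + ell == n):
        mm = sum(a != b or a == "N" for a, b in zip(seq[p : p + ell], adapter[:ell]))
        return mm <= int(e * ell)
    return False


def random_read(rng: np.random.Generator, length: int = 150, probs=None) -> Read:
    bases = rng.choice(list("ACGT"), size=length, p=probs)
    return Read(
        f"rand{rng.integers(1 << 30)}",
        "".join(bases),
        rng.integers(2, 41, size=length),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def genome() -> str:
    return generate_background_genome(50_000, 0.5, seed=101)


@pytest.fixture(scope="session")
def small_sample(genome):
    """A modest simulated sample with every origin represented."""
    cfg = SimConfig(
        seed=202,
        n_reads=8_000,
        homopolymer_read_fraction=0.05,
        second_strand_fraction=0.4,
        chimera_read_fraction=0.02,
    )
    reads, truth = simulate_sample(cfg, genome)
    return cfg, reads, truth
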