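"""Synthetic cDIP-seq-like read sets with per-read ground truth.

The generator emulates the statistical structure the analysis assumes:

* background reads drawn verbatim from a reference genome constructed without
  any native single-base run of >= 25 nt, so that under zero sequencing error
  the homopolymer scanner's null is exactly zero;
* reads derived from long single-stranded poly-dA molecules (lengths drawn
  log-uniformly over ~1,000-10,000 nt, the decade observed by sizing the
  products on a blot) with a minority second-strand poly-dT fraction ``s``;
* chimeric reads carrying exactly one dA-block/dT-block junction placed
  uniformly within the insert, orientation dA->dT vs dT->dA drawn with odds
  ``rho``;
* a capture bias thinning poly-dA molecules relative to poly-dT by a factor
  ``beta`` before the pool is sequenced to the configured depth (``beta`` = 1
  means unbiased);
* 100-nt spike-in oligos sampled with molar-input x ``beta`` weights;
* 3' adapter read-through followed by random filler, an i.i.d. substitution
  error model, and a linearly decaying Phred quality model.

Sequenced reads are single-end fragments; at fixed depth the thinning enters
as renormalised origin weights (1-f-c, f*(1-s)*beta, f*s, c), so with beta=1
the realized homopolymer read fraction equals ``f`` exactly. Every sampling
decision is recorded in a ground-truth table keyed by read id.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Read, decode, encode
from .prep import DEFAULT_ADAPTER

__all__ = [
    "SimConfig",
    "SpikeInDesign",
    "TRUTH_COLUMNS",
    "generate_background_genome",
    "simulate_sample",
    "simulate_spikein",
    "truth_pattern_read_ids",
    "write_truth",
    "read_truth",
]

TRUTH_COLUMNS = [
    "read_id",
    "origin",
    "molecule_length",
    "true_insert_length",
    "adapter_bases_appended",
    "junction_pos",
]

# shortest read-through insert emitted; below the stringent length filter so
# truncated inserts exercise the filter without dominating the sample
_MIN_INSERT = 40


@dataclass
class SimConfig:
    """Parameters of one synthetic cDIP-seq sample.

    Fractions ``homopolymer_read_fraction`` (f) and ``chimera_read_fraction``
    (c) partition the pre-bias molecule pool with the background taking the
    remainder; ``second_strand_fraction`` (s) is the poly-dT share of the
    homopolymer molecules; ``capture_bias`` (beta) is the relative retention
    of a poly-dA molecule vs a poly-dT one; ``chimera_orientation_ratio``
    (rho) is the expected dA10->dT10 : dT10->dA10 count ratio.
    """

    seed: int = 0
    n_reads: int = 10_000
    read_length: int = 150
    background_genome_length: int = 100_000
    gc_fraction: float = 0.5
    homopolymer_read_fraction: float = 0.02
    second_strand_fraction: float = 0.3
    capture_bias: float = 1.0
    chimera_read_fraction: float = 0.005
    chimera_orientation_ratio: float = 4.0
    molecule_length_min: int = 1_000
    molecule_length_max: int = 10_000
    substitution_error_rate: float = 0.002
    adapter_sequence: str = DEFAULT_ADAPTER
    adapter_read_through_fraction: float = 0.2
    quality_mean: float = 36.0
    quality_decay: float = 0.02
    quality_sd: float = 2.0

    def __post_init__(self) -> None:
        f, c = self.homopolymer_read_fraction, self.chimera_read_fraction
        fracs = {
            "gc_fraction": self.gc_fraction,
            "homopolymer_read_fraction": f,
            "second_strand_fraction": self.second_strand_fraction,
            "chimera_read_fraction": c,
            "substitution_error_rate": self.substitution_error_rate,
            "adapter_read_through_fraction": self.adapter_read_through_fraction,
        }
        for name, value in fracs.items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if f + c > 1:
            raise ValueError("homopolymer_read_fraction + chimera_read_fraction > 1")
        if self.capture_bias <= 0:
            raise ValueError("capture_bias must be > 0")
        if self.chimera_orientation_ratio <= 0:
            raise ValueError("chimera_orientation_ratio must be > 0")
        if self.molecule_length_min > self.molecule_length_max:
            raise ValueError("molecule_length_min > molecule_length_max")
        if self.read_length - len(self.adapter_sequence) < _MIN_INSERT:
            raise ValueError("read_length too short for insert + adapter model")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SpikeInDesign:
    """One spike-in condition: molar inputs of the two 100-nt oligos."""

    condition_label: str
    input_dA_fmol: float
    input_dT_fmol: float
    oligo_length: int = 100

    def __post_init__(self) -> None:
        if self.input_dA_fmol < 0 or self.input_dT_fmol < 0:
            raise ValueError("spike inputs must be nonnegative")
        if self.input_dA_fmol == 0 and self.input_dT_fmol == 0:
            raise ValueError("at least one spike input must be positive")
        if self.oligo_length < 1:
            raise ValueError("oligo_length must be >= 1")


def generate_background_genome(
    length: int, gc_fraction: float = 0.5, seed: int = 0
) -> str:
    """Random genome of the requested length with no single-base run >= 25 nt.

    Bases are i.i.d. with P(G)+P(C) = ``gc_fraction``; any window violating
    the run constraint is resampled until none remains, so background reads
    can never trigger the default homopolymer call exactly.
    """
    if length < 1_000:
        raise ValueError("background genome must be >= 1,000 nt")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    probs = np.array([at, gc, gc, at])
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    while True:
        boundaries = np.flatnonzero(codes[1:] != codes[:-1]) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [length]))
        bad = ends - starts >= 25
        if not bad.any():
            break
        for s, e in zip(starts[bad], ends[bad]):
            codes[s:e] = rng.choice(4, size=e - s, p=probs)
    return decode(codes)


def _insert_lengths(rng, n: int, cfg: SimConfig) -> np.ndarray:
    """Read-through reads get a short insert; the full adapter stem always fits."""
    ins = np.full(n, cfg.read_length, dtype=np.int64)
    rt = rng.random(n) < cfg.adapter_read_through_fraction
    hi = cfg.read_length - len(cfg.adapter_sequence)
    ins[rt] = rng.integers(_MIN_INSERT, hi + 1, size=int(rt.sum()))
    return ins


def _molecule_lengths(rng, n: int, cfg: SimConfig) -> np.ndarray:
    lo, hi = np.log(cfg.molecule_length_min), np.log(cfg.molecule_length_max)
    return np.rint(np.exp(rng.uniform(lo, hi, size=n))).astype(np.int64)


def _finalize_reads(
    rng, mat: np.ndarray, ins: np.ndarray, cfg: SimConfig, id_prefix: str, id_start: int = 0
) -> list[Read]:
    """Append adapter + random filler, apply substitution errors and qualities."""
    n, rl = mat.shape
    acodes = encode(cfg.adapter_sequence)
    offset = np.arange(rl)[None, :] - ins[:, None]
    in_adapter = (offset >= 0) & (offset < len(acodes))
    mat[in_adapter] = acodes[offset[in_adapter]]
    filler = offset >= len(acodes)
    mat[filler] = rng.integers(0, 4, size=int(filler.sum()), dtype=np.uint8)
    if cfg.substitution_error_rate > 0:
        err = rng.random((n, rl)) < cfg.substitution_error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shift) % 4
    qual = (
        cfg.quality_mean
        - cfg.quality_decay * np.arange(rl)
        + rng.normal(0.0, cfg.quality_sd, size=(n, rl))
    )
    qual = np.clip(np.rint(qual), 2, 40).astype(np.int16)
    ascii_rows = mat  # codes are already 0..3; decode row-wise
    return [
        Read(f"{id_prefix}{id_start + i:08d}", decode(ascii_rows[i]), qual[i])
        for i in range(n)
    ]


_ORIGINS = ["background", "polyA_molecule", "polyT_molecule", "chimera_AT", "chimera_TA"]


def simulate_sample(
    config: SimConfig, reference: str
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate one cDIP-seq sample against a background reference.

    Returns the reads and a ground-truth table with one row per read
    (columns ``read_id, origin, molecule_length, true_insert_length,
    adapter_bases_appended, junction_pos``).
    """
    cfg = config
    if len(reference) < cfg.read_length:
        raise ValueError("reference shorter than read_length")
    rng = np.random.default_rng(cfg.seed)
    n, rl = cfg.n_reads, cfg.read_length
    f, s, c = (
        cfg.homopolymer_read_fraction,
        cfg.second_strand_fraction,
        cfg.chimera_read_fraction,
    )
    rho, beta = cfg.chimera_orientation_ratio, cfg.capture_bias
    weights = np.array(
        [
            1 - f - c,  # background
            f * (1 - s) * beta,  # polyA molecules, thinned by capture bias
            f * s,  # polyT (second-strand) molecules
            c * rho / (1 + rho),  # chimera dA->dT
            c / (1 + rho),  # chimera dT->dA
        ]
    )
    origin = rng.choice(5, size=n, p=weights / weights.sum())
    ins = _insert_lengths(rng, n, cfg)
    gcodes = encode(reference)
    mat = np.empty((n, rl), dtype=np.uint8)

    bg = origin == 0
    starts = rng.integers(0, len(reference) - rl + 1, size=int(bg.sum()))
    mat[bg] = gcodes[starts[:, None] + np.arange(rl)]

    mat[origin == 1] = 0  # poly-dA
    mat[origin == 3] = 0  # chimera AT: A-block first, T-block written below
    mat[(origin == 2) | (origin == 4)] = 3  # poly-dT / chimera TA leading T-block

    molecule_length = np.full(n, -1, dtype=np.int64)
    hp = origin > 0
    molecule_length[hp] = _molecule_lengths(rng, int(hp.sum()), cfg)

    # chimeric junction: uniform within the insert, >= 10 nt on each side so
    # the dA10/dT10 junction window always fits
    junction = np.full(n, -1, dtype=np.int64)
    chim = (origin == 3) | (origin == 4)
    if chim.any():
        jc = rng.integers(10, ins[chim] - 10 + 1)
        junction[chim] = jc
        sub = mat[chim]
        oo = origin[chim]
        block = np.arange(rl)[None, :] >= jc[:, None]
        sub[block & (oo == 3)[:, None]] = 3  # dA->dT: tail block is T
        sub[block & (oo == 4)[:, None]] = 0  # dT->dA: tail block is A
        mat[chim] = sub

    reads = _finalize_reads(rng, mat, ins, cfg, id_prefix="r")
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "origin": pd.Categorical.from_codes(
                origin, categories=_ORIGINS + ["spike_dA", "spike_dT"]
            ),
            "molecule_length": np.where(molecule_length < 0, np.nan, molecule_length),
            "true_insert_length": ins,
            "adapter_bases_appended": np.where(
                ins < rl, len(cfg.adapter_sequence), 0
            ),
            "junction_pos": np.where(junction < 0, np.nan, junction),
        }
    )
    return reads, truth


def simulate_spikein(
    design: SpikeInDesign,
    depth: int,
    beta: float,
    background: list[Read],
    seed: int = 0,
    config: SimConfig | None = None,
) -> tuple[list[Read], pd.DataFrame]:
    """Mix ``depth`` spike-in oligo reads into background records.

    Spike reads are error-perturbed copies of the 100-nt homopolymer oligos,
    adapter-extended to the read length; per-read species is drawn with
    weights ``input_dA_fmol * beta`` vs ``input_dT_fmol``. Returns the
    shuffled combined read list and a ground-truth table for the spike reads.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    cfg = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    w_da = design.input_dA_fmol * beta
    w_dt = design.input_dT_fmol
    p_da = w_da / (w_da + w_dt)
    is_da = rng.random(depth) < p_da
    rl = cfg.read_length
    mat = np.empty((depth, rl), dtype=np.uint8)
    mat[is_da] = 0
    mat[~is_da] = 3
    ins = np.full(depth, min(design.oligo_length, rl), dtype=np.int64)
    spikes = _finalize_reads(rng, mat, ins, cfg, id_prefix="spike")
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in spikes],
            "origin": pd.Categorical.from_codes(
                np.where(is_da, 5, 6), categories=_ORIGINS + ["spike_dA", "spike_dT"]
            ),
            "molecule_length": float(design.oligo_length),
            "true_insert_length": ins,
            "adapter_bases_appended": np.where(
                ins < rl, len(cfg.adapter_sequence), 0
            ),
            "junction_pos": np.nan,
        }
    )
    combined = list(background) + spikes
    order = rng.permutation(len(combined))
    return [combined[i] for i in order], truth


def truth_pattern_read_ids(
    truth: pd.DataFrame, L: int = 25
) -> dict[str, set[str]]:
    """Ground-truth read-id sets expected to contain each pattern class.

    Derived from construction: poly-dA/poly-dT (and spike) reads carry a
    full-insert run; a chimeric read contributes an A-run when its A block is
    at least ``L`` nt, symmetrically for T; every chimeric read carries its
    junction by construction.
    """
    t = truth
    ins = t["true_insert_length"].to_numpy()
    j = t["junction_pos"].to_numpy()
    origin = t["origin"].astype(str).to_numpy()
    ids = t["read_id"].to_numpy()
    a_block = np.where(origin == "chimera_AT", j, np.where(origin == "chimera_TA", ins - j, 0))
    t_block = np.where(origin == "chimera_TA", j, np.where(origin == "chimera_AT", ins - j, 0))
    out = {
        "homopolymer_A": set(
            ids[np.isin(origin, ["polyA_molecule", "spike_dA"]) | (a_block >= L)]
        ),
        "homopolymer_T": set(
            ids[np.isin(origin, ["polyT_molecule", "spike_dT"]) | (t_block >= L)]
        ),
        "homopolymer_C": set(),
        "homopolymer_G": set(),
        "chimera_AT": set(ids[origin == "chimera_AT"]),
        "chimera_TA": set(ids[origin == "chimera_TA"]),
    }
    return out


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
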