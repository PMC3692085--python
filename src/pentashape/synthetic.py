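"""Synthetic ground-truth models and structural-record corpora.

The real training data for a pentamer shape table are conformational-ensemble
analyses of thousands of short DNA fragments; those trajectories are not
something a test suite can carry.  This module generates a *known* pentamer
parameter set and mints structural records from it, so that mining,
prediction and cross-validation can be verified against ground truth:

* At zero noise, mining a generated corpus reproduces the generating
  parameters to full floating-point agreement, and leave-one-out
  cross-validation returns Spearman 1.0 (given redundant coverage).
* With i.i.d. Gaussian noise of sd sigma and n occurrences per pentamer
  class, the recovered table entries scatter around truth with sd sigma/sqrt(n).

Consistency design: a bp step is covered by two overlapping pentamers (as
step 2 of the left one and step 1 of the right one).  For a single physical
ground-truth value to exist at each step, Roll and HelT are drawn per
canonical *tetramer* (the step plus one flanking bp each side) and expanded
into the pentamer step entries; MGW and ProT are drawn per canonical
pentamer.  Without this, zero-noise round-trip identity and exact LOOCV
could not hold simultaneously.

Parameter ranges are centred on B-DNA norms and stay strictly inside the
deformation-filter thresholds: MGW uniform on [4.5, 7.0] Angstrom (~5.8 in
B-DNA; filter cuts at 1.5/8.5), ProT uniform on [-20, 0] degrees, Roll
uniform on [-12, 15] degrees (~0 in B-DNA; filter at |20|), HelT uniform on
[29, 41] degrees (~35 in B-DNA; filter at 45).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmer import CANON_CODE, N_PENTAMER_CODES, encode, window_codes
from .records import StructuralRecord
from .table_builder import CANONICAL_PENTAMERS, QueryTable

__all__ = ["FeatureNoise", "SyntheticModel", "make_model", "make_corpus", "de_bruijn"]

MGW_RANGE = (4.5, 7.0)
PROT_RANGE = (-20.0, 0.0)
ROLL_RANGE = (-12.0, 15.0)
HELT_RANGE = (29.0, 41.0)

# Ground-truth draws are snapped to multiples of 2**-20.  All sums and
# differences of such values (at these magnitudes) are exact in doubles, and
# x/2, x/3, sum(n copies)/n are correctly rounded onto representable results,
# so zero-noise mining and groove-level reconstruction recover the model
# parameters bit for bit rather than to ~1e-14.
_GRID = 2.0**20


def _snap(x: np.ndarray) -> np.ndarray:
    return np.round(x * _GRID) / _GRID


@dataclass(frozen=True)
class FeatureNoise:
    """Per-feature Gaussian noise standard deviations (Angstrom / degrees)."""

    mgw: float = 0.0
    prot: float = 0.0
    roll: float = 0.0
    helt: float = 0.0

    def __post_init__(self) -> None:
        if min(self.mgw, self.prot, self.roll, self.helt) < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class SyntheticModel:
    """Ground-truth pentamer parameters plus the noise model and seed."""

    seed: int
    noise: FeatureNoise
    # oriented-code lookup arrays, length 1024; step entries already oriented
    mgw: np.ndarray = field(repr=False)
    prot: np.ndarray = field(repr=False)
    roll1: np.ndarray = field(repr=False)
    roll2: np.ndarray = field(repr=False)
    helt1: np.ndarray = field(repr=False)
    helt2: np.ndarray = field(repr=False)
    # per-tetramer step functions (oriented 4-mer code -> value)
    tet_roll: np.ndarray = field(repr=False)
    tet_helt: np.ndarray = field(repr=False)

    @property
    def pentamer_params(self) -> pd.DataFrame:
        """Canonical 512-row parameter table (same layout as a QueryTable)."""
        canonical = list(CANONICAL_PENTAMERS)
        idx = [_pent_code(p) for p in canonical]
        return pd.DataFrame(
            {
                "MGW": self.mgw[idx],
                "ProT": self.prot[idx],
                "Roll1": self.roll1[idx],
                "Roll2": self.roll2[idx],
                "HelT1": self.helt1[idx],
                "HelT2": self.helt2[idx],
            },
            index=pd.Index(canonical, name="pentamer"),
        )

    def as_table(self) -> QueryTable:
        """Ground truth as a QueryTable (count 1 per entry), for diffing."""
        df = self.pentamer_params.copy()
        df.insert(0, "count", 1)
        return QueryTable(data=df, provenance=f"synthetic ground truth (seed={self.seed})")

    def luts(self) -> dict[str, np.ndarray]:
        return {
            "mgw": self.mgw,
            "prot": self.prot,
            "roll1": self.roll1,
            "roll2": self.roll2,
            "helt1": self.helt1,
            "helt2": self.helt2,
        }


def _pent_code(p: str) -> int:
    e = encode(p)
    return int(e[0]) * 256 + int(e[1]) * 64 + int(e[2]) * 16 + int(e[3]) * 4 + int(e[4])


def _tet_codes_of_pentamers() -> tuple[np.ndarray, np.ndarray]:
    """For every oriented pentamer code: the 4-mer codes of its two steps'
    contexts (positions 1-4 and 2-5)."""
    codes = np.arange(N_PENTAMER_CODES)
    left = codes >> 2          # drop last base
    right = codes & (4**4 - 1)  # drop first base
    return left, right


def _canon_tet() -> tuple[np.ndarray, np.ndarray]:
    """Canonical code and total class list for 4-mers."""
    codes = np.arange(4**4, dtype=np.int64)
    digits = np.stack([(codes >> (2 * (3 - j))) & 3 for j in range(4)], axis=1)
    rc_digits = 3 - digits[:, ::-1]
    rc = np.zeros(4**4, dtype=np.int64)
    for j in range(4):
        rc = rc * 4 + rc_digits[:, j]
    return np.minimum(codes, rc), codes


_TET_CANON, _ = _canon_tet()
_PENT_LEFT_TET, _PENT_RIGHT_TET = _tet_codes_of_pentamers()


def make_model(seed: int, noise_sd: FeatureNoise | None = None) -> SyntheticModel:
    """Draw a deterministic, strand-consistent ground-truth pentamer model.

    MGW and ProT are drawn per canonical pentamer; Roll and HelT per
    canonical tetramer (step context), expanded to pentamer step entries.
    All values lie inside B-DNA-like ranges that pass the deformation
    filter.  Same seed, same model, bit for bit.
    """
    noise = noise_sd or FeatureNoise()
    rng = np.random.default_rng(seed)

    # per canonical pentamer class: MGW, ProT
    mgw_c = np.full(N_PENTAMER_CODES, np.nan)
    prot_c = np.full(N_PENTAMER_CODES, np.nan)
    canon_codes = np.unique(CANON_CODE)
    mgw_c[canon_codes] = _snap(rng.uniform(*MGW_RANGE, size=canon_codes.size))
    prot_c[canon_codes] = _snap(rng.uniform(*PROT_RANGE, size=canon_codes.size))
    mgw = mgw_c[CANON_CODE]
    prot = prot_c[CANON_CODE]

    # per canonical tetramer: step Roll / HelT
    tet_canon_codes = np.unique(_TET_CANON)
    tet_roll_c = np.full(4**4, np.nan)
    tet_helt_c = np.full(4**4, np.nan)
    tet_roll_c[tet_canon_codes] = _snap(rng.uniform(*ROLL_RANGE, size=tet_canon_codes.size))
    tet_helt_c[tet_canon_codes] = _snap(rng.uniform(*HELT_RANGE, size=tet_canon_codes.size))
    tet_roll = tet_roll_c[_TET_CANON]
    tet_helt = tet_helt_c[_TET_CANON]

    return SyntheticModel(
        seed=int(seed),
        noise=noise,
        mgw=mgw,
        prot=prot,
        roll1=tet_roll[_PENT_LEFT_TET],
        roll2=tet_roll[_PENT_RIGHT_TET],
        helt1=tet_helt[_PENT_LEFT_TET],
        helt2=tet_helt[_PENT_RIGHT_TET],
        tet_roll=tet_roll,
        tet_helt=tet_helt,
    )


def de_bruijn(k: int = 5) -> str:
    """Cyclic de Bruijn sequence of order k over ACGT (length 4**k)."""
    alphabet = "ACGT"
    n = 4
    a = [0] * n * k
    out: list[int] = []

    def db(t: int, p: int) -> None:
        if t > k:
            if k % p == 0:
                out.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, n):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return "".join(alphabet[i] for i in out)


def _fragment_cover(rng: np.random.Generator, length_range: tuple[int, int], trim: int) -> list[str]:
    """Chop an order-5 de Bruijn cycle into fragments that jointly place every
    pentamer inside the minable (trimmed) interior of some fragment."""
    lo, hi = length_range
    overlap = 4 + 2 * trim
    if lo <= overlap:
        raise ValueError(
            f"minimum fragment length {lo} cannot cover pentamers with trim={trim}; "
            f"need > {overlap}"
        )
    cycle = de_bruijn(5)
    extended = cycle + cycle[: hi + overlap]
    frags = []
    pos = 0
    while pos < len(cycle):
        f = int(rng.integers(lo, hi + 1))
        frags.append(extended[pos : pos + f])
        pos += f - overlap
    return frags


def _random_fragments(rng: np.random.Generator, n: int, length_range: tuple[int, int]) -> list[str]:
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    return [
        "".join("ACGT"[b] for b in rng.integers(0, 4, size=int(f))) for f in lengths
    ]


def _record_from_sequence(
    seq: str, model: SyntheticModel, rng: np.random.Generator, record_id: str
) -> StructuralRecord:
    """Mint one structural record whose features follow the model plus noise.

    Interior bp (full pentamer window) carry the model's central-bp values;
    interior steps (full tetramer context) carry the tetramer step values.
    Terminal positions without full context receive B-DNA anchor values —
    they are never mined (no full window) nor compared (predictions are
    undefined there), but the record must still carry numbers everywhere.

    Groove levels are synthesized so the three-level bp average is exactly
    the target at zero noise: shared levels (each nucleotide's second level,
    which two adjacent windows both see) are set to the mean of the two
    adjacent targets, and each first level absorbs the remainder.  Level
    noise has sd sqrt(3) * sigma_mgw, giving the three-level mean an sd of
    sigma_mgw.
    """
    e = encode(seq)
    L = e.size
    codes = window_codes(e)  # centers 2..L-3
    noise = model.noise

    # per-bp targets; terminal filler anchors are exactly representable
    mgw_t = np.full(L, 5.75)
    prot_t = np.full(L, -10.0)
    mgw_t[2 : L - 2] = model.mgw[codes]
    prot_t[2 : L - 2] = model.prot[codes]

    # per-step targets from the tetramer function (steps 1..L-3 have context)
    roll_t = np.full(L - 1, 2.0)
    helt_t = np.full(L - 1, 35.0)
    tet = e[:-3] * 64 + e[1:-2] * 16 + e[2:-1] * 4 + e[3:]  # 4-mer starting at i
    # step s (0-based) has context bases s-1..s+2 -> tetramer starting at s-1
    roll_t[1 : L - 2] = model.tet_roll[tet]
    helt_t[1 : L - 2] = model.tet_helt[tet]

    # groove levels: seconds are shared between adjacent windows
    seconds = np.empty(L)
    seconds[:-1] = (mgw_t[:-1] + mgw_t[1:]) / 2.0
    seconds[-1] = mgw_t[-1]
    firsts = np.empty(L)
    firsts[0] = mgw_t[0]
    firsts[1:] = 3.0 * mgw_t[1:] - seconds[:-1] - seconds[1:]
    levels = np.empty((L, 2))
    levels[:, 0] = firsts
    levels[:, 1] = seconds
    if noise.mgw > 0:
        levels += rng.normal(0.0, noise.mgw * np.sqrt(3.0), size=levels.shape)
    levels = np.maximum(levels, 0.01)  # groove widths are positive

    prot = prot_t + (rng.normal(0.0, noise.prot, size=L) if noise.prot > 0 else 0.0)
    roll = roll_t + (rng.normal(0.0, noise.roll, size=L - 1) if noise.roll > 0 else 0.0)
    helt = helt_t + (rng.normal(0.0, noise.helt, size=L - 1) if noise.helt > 0 else 0.0)

    return StructuralRecord(
        sequence=seq,
        groove_levels=levels,
        prot=prot,
        roll=roll,
        helt=helt,
        record_id=record_id,
    )


def make_corpus(
    model: SyntheticModel,
    n_fragments: int = 2121,
    length_range: tuple[int, int] = (12, 27),
    trim: int = 2,
    seed: int | None = None,
) -> list[StructuralRecord]:
    """Generate a corpus of structural records with full pentamer coverage.

    The first fragments chop an order-5 de Bruijn cycle (with overlaps wide
    enough that every pentamer class lands in some fragment's minable
    interior at the given ``trim``); the remainder are random fragments that
    raise per-class occurrence counts.  Defaults mirror a realistic training
    design: 2121 fragments of 12-27 bp, which yields ~44 occurrences per
    pentamer class.  Regeneration from the same model and seed is
    bit-identical.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(model.seed + 1 if seed is None else seed)
    frags = _fragment_cover(rng, length_range, trim)
    if len(frags) > n_fragments:
        warnings.warn(
            f"{n_fragments} fragments cannot cover all 512 pentamer classes; "
            f"{len(frags)} needed — corpus coverage will be incomplete",
            stacklevel=2,
        )
        frags = frags[:n_fragments]
    else:
        frags = frags + _random_fragments(rng, n_fragments - len(frags), length_range)
    return [
        _record_from_sequence(s, model, rng, record_id=f"frag_{i + 1:05d}")
        for i, s in enumerate(frags)
    ]
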