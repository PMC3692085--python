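"""Sliding-pentamer prediction of DNA structural features.

Given a query table, every bp of an input sequence takes the central-bp
features (MGW, ProT) of the pentamer centered on it, and every bp step takes
the mean of the step entries of the (at most two) pentamers whose two central
steps cover it.  Features are undefined at the two terminal bp and the one
terminal step at each end, and wherever the pentamer window contains a
non-ACGT letter or an unrepresented table class.  Undefined values are NaN in
memory and the literal "NA" on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmer import SequenceTooShortError, encode, window_codes
from .table_builder import QueryTable

__all__ = [
    "ShapeProfile",
    "AggregateProfile",
    "BatchResult",
    "predict",
    "predict_batch",
    "aggregate_profiles",
    "DEFAULT_MAX_LENGTH",
]

DEFAULT_MAX_LENGTH = 1_000_000

BP_FEATURES = ("mgw", "prot")
STEP_FEATURES = ("roll", "helt")


@dataclass
class ShapeProfile:
    """Predicted structural features of one sequence.

    ``mgw``/``prot`` have length L (per bp), ``roll``/``helt`` length L-1
    (per step; index s, 0-based, is the step joining bp s+1 and s+2 in
    1-based coordinates).  NaN marks undefined positions.
    """

    sequence: str
    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray
    sequence_id: str = field(default="")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> np.ndarray:
        return getattr(self, name.lower())

    def defined_bp_positions(self) -> np.ndarray:
        """1-based bp positions where MGW is defined."""
        return np.nonzero(np.isfinite(self.mgw))[0] + 1

    def defined_steps(self) -> np.ndarray:
        """1-based step indices (step s joins bp s and s+1) where Roll is defined."""
        return np.nonzero(np.isfinite(self.roll))[0] + 1


def _predict_arrays(
    encoded: np.ndarray, luts: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core prediction kernel on an encoded sequence.

    ``luts`` maps mgw/prot/roll1/roll2/helt1/helt2 to arrays indexed by
    oriented pentamer code (NaN for missing classes).
    """
    L = encoded.size
    codes = window_codes(encoded)  # window j centered at j+2
    valid = codes >= 0
    safe = np.where(valid, codes, 0)

    def central(lut: np.ndarray) -> np.ndarray:
        out = np.full(L, np.nan)
        vals = lut[safe]
        vals[~valid] = np.nan
        out[2 : L - 2] = vals
        return out

    mgw = central(luts["mgw"])
    prot = central(luts["prot"])

    def steps(lut1: np.ndarray, lut2: np.ndarray) -> np.ndarray:
        # pentamer centered at c covers step c-1 (its step 1) and step c (its
        # step 2); an interior step averages its two covering pentamers, a
        # boundary step takes its single covering pentamer's value.
        v1 = lut1[safe]
        v1[~valid] = np.nan
        v2 = lut2[safe]
        v2[~valid] = np.nan
        a = np.full(L - 1, np.nan)
        b = np.full(L - 1, np.nan)
        a[1 : L - 3] = v1  # centers 2..L-3 -> steps 1..L-4
        b[2 : L - 2] = v2  # centers 2..L-3 -> steps 2..L-3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(np.stack([a, b]), axis=0)

    roll = steps(luts["roll1"], luts["roll2"])
    helt = steps(luts["helt1"], luts["helt2"])
    return mgw, prot, roll, helt


def predict(
    seq: str,
    table: QueryTable,
    max_len: int = DEFAULT_MAX_LENGTH,
    sequence_id: str = "",
) -> ShapeProfile:
    """Predict MGW, ProT, Roll and HelT profiles for one sequence.

    The sequence must be 5 bp to ``max_len`` bp; letters outside ACGT (e.g.
    N gaps in genomic FASTA) yield undefined values at every position whose
    pentamer window touches them rather than an error.
    """
    s = seq.upper()
    if len(s) < 5:
        raise SequenceTooShortError(f"need at least 5 bp to predict, got {len(s)}")
    if max_len is not None and len(s) > max_len:
        raise ValueError(f"sequence of {len(s)} bp exceeds the {max_len} bp limit")
    if not table.is_complete:
        warnings.warn(
            "query table is incomplete; some positions will be undefined",
            stacklevel=2,
        )
    mgw, prot, roll, helt = _predict_arrays(encode(s), table.luts())
    return ShapeProfile(
        sequence=s, mgw=mgw, prot=prot, roll=roll, helt=helt, sequence_id=sequence_id
    )


@dataclass
class BatchResult:
    """Profiles in input order; failed entries are None with a recorded reason."""

    profiles: list  # ShapeProfile | None, aligned with the input
    failures: list  # (index, sequence_id, message)

    def ok(self) -> list:
        return [p for p in self.profiles if p is not None]


def predict_batch(
    seqs: Sequence,
    table: QueryTable,
    max_len: int = DEFAULT_MAX_LENGTH,
) -> BatchResult:
    """Predict profiles for many sequences without aborting on bad entries.

    ``seqs`` may contain plain strings or ``(id, sequence)`` pairs.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty sequence collection")
    profiles: list = []
    failures: list = []
    for idx, item in enumerate(seqs):
        sid, s = item if isinstance(item, tuple) else (f"seq_{idx + 1}", item)
        try:
            profiles.append(predict(s, table, max_len=max_len, sequence_id=sid))
        except (SequenceTooShortError, ValueError) as exc:
            profiles.append(None)
            failures.append((idx, sid, str(exc)))
    return BatchResult(profiles=profiles, failures=failures)


@dataclass
class AggregateProfile:
    """Position-wise mean over equal-length profiles, with per-position n."""

    length: int
    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray
    n: dict

    def feature(self, name: str) -> np.ndarray:
        return getattr(self, name.lower())


def aggregate_profiles(profiles: Sequence[ShapeProfile]) -> AggregateProfile:
    """Position-wise arithmetic mean over equal-length profiles.

    A position's mean is taken over the profiles in which it is defined and
    is NaN only where it is undefined in every profile.  Used for e.g. the
    average groove-width signature of aligned binding-site collections.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to aggregate")
    L = len(profiles[0])
    for p in profiles:
        if len(p) != L:
            raise ValueError(f"profiles must share one length; got {len(p)} != {L}")
    means: dict[str, np.ndarray] = {}
    n: dict[str, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for f in BP_FEATURES + STEP_FEATURES:
            stack = np.stack([p.feature(f) for p in profiles])
            means[f] = np.nanmean(stack, axis=0)
            n[f] = np.isfinite(stack).sum(axis=0)
    return AggregateProfile(
        length=L,
        mgw=means["mgw"],
        prot=means["prot"],
        roll=means["roll"],
        helt=means["helt"],
        n=n,
    )
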