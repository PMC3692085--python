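"""Nucleotide sequence algebra for the sliding-pentamer shape model.

Double-stranded DNA has no intrinsic reading direction: a k-mer and its
Watson-Crick reverse complement describe the same duplex segment seen from
opposite strands.  The shape model therefore works with reverse-complement
equivalence classes of pentamers; there are 512 such classes (every odd-length
k-mer differs from its reverse complement, so each class has two members).

Public coordinates are 1-based and inclusive, matching the way base-pair
profiles are indexed in structural biology plots.  Internally, arrays are
0-based NumPy arrays; every function that crosses the boundary documents it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlphabetError",
    "SequenceTooShortError",
    "Pentamer",
    "revcomp",
    "normalize",
    "encode",
    "canonical",
    "count_rc_classes",
    "sliding_pentamers",
    "class_occurrences",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 2-bit code; anything outside {A,C,G,T} (any case) maps to -1
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

BASES = "ACGT"
N_PENTAMER_CODES = 4**5  # 1024 oriented pentamers, 512 canonical classes


class AlphabetError(ValueError):
    """A sequence contains a character outside the {A,C,G,T} alphabet."""


class SequenceTooShortError(ValueError):
    """A sequence is shorter than the minimum the operation requires."""


def normalize(seq: str) -> str:
    """Uppercase ``seq`` and verify it is pure A/C/G/T.

    Raises :class:`AlphabetError` naming the first offending (1-based)
    position.  Use :func:`encode` instead when ambiguity codes such as N
    should flow through as undefined positions rather than errors.
    """
    s = seq.upper()
    arr = _ENC[np.frombuffer(s.encode("ascii", errors="replace"), dtype=np.uint8)]
    bad = np.nonzero(arr < 0)[0]
    if bad.size:
        pos = int(bad[0]) + 1
        raise AlphabetError(
            f"non-ACGT character {s[pos - 1]!r} at position {pos}"
        )
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0, C=1, G=2, T=3; non-ACGT -> -1."""
    return _ENC[np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Watson-Crick reverse complement; an involution on valid sequences."""
    s = normalize(seq)
    return s.translate(_COMPLEMENT)[::-1]


def count_rc_classes(k: int) -> int:
    """Number of reverse-complement equivalence classes of k-mers over ACGT.

    Odd k: 4**k / 2 (no odd-length k-mer is its own reverse complement).
    Even k: (4**k + 4**(k//2)) / 2 (reverse-complement palindromes are
    singleton classes).  k=2 -> 10, k=4 -> 136, k=5 -> 512.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if k % 2:
        return 4**k // 2
    return (4**k + 4 ** (k // 2)) // 2


# ---------------------------------------------------------------------------
# Precomputed pentamer code tables.
#
# A pentamer maps to a base-4 integer code (first residue = most significant
# digit).  For all 1024 codes we tabulate the reverse-complement code, the
# canonical (lexicographic min) code, and whether canonicalization flipped
# the orientation.  These arrays drive both mining and prediction.
# ---------------------------------------------------------------------------

def _build_code_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = np.arange(N_PENTAMER_CODES, dtype=np.int64)
    digits = np.stack([(codes >> (2 * (4 - j))) & 3 for j in range(5)], axis=1)
    rc_digits = 3 - digits[:, ::-1]
    rc = np.zeros(N_PENTAMER_CODES, dtype=np.int64)
    for j in range(5):
        rc = rc * 4 + rc_digits[:, j]
    canon = np.minimum(codes, rc)
    flipped = rc < codes
    return rc, canon, flipped


RC_CODE, CANON_CODE, FLIPPED = _build_code_tables()


def code_to_str(code: int) -> str:
    """Decode a base-4 pentamer code back to its 5-letter string."""
    return "".join(BASES[(code >> (2 * (4 - j))) & 3] for j in range(5))


def str_to_code(pent: str) -> int:
    arr = encode(pent)
    if arr.size != 5 or (arr < 0).any():
        raise AlphabetError(f"not a valid ACGT pentamer: {pent!r}")
    return int(arr[0]) * 256 + int(arr[1]) * 64 + int(arr[2]) * 16 + int(arr[3]) * 4 + int(arr[4])


@dataclass(frozen=True)
class Pentamer:
    """A 5-mer with its reverse-complement canonical form.

    ``flipped`` records whether canonicalization reverse-complemented the
    residues; consumers that store step-wise quantities (Roll, HelT) must
    swap step order when it did.
    """

    residues: str
    canonical_form: str
    flipped: bool

    @classmethod
    def from_str(cls, pent: str) -> "Pentamer":
        s = normalize(pent)
        if len(s) != 5:
            raise ValueError(f"pentamer must have length 5, got {len(s)}")
        rc = s.translate(_COMPLEMENT)[::-1]
        if rc < s:
            return cls(residues=s, canonical_form=rc, flipped=True)
        return cls(residues=s, canonical_form=s, flipped=False)


def canonical(pent: str) -> str:
    """Canonical class representative: lexicographic min of {p, revcomp(p)}."""
    return Pentamer.from_str(pent).canonical_form


def window_codes(encoded: np.ndarray) -> np.ndarray:
    """Pentamer codes for all windows of an encoded sequence.

    Returns an int64 array of length L-4; entry j is the code of the window
    starting at 0-based offset j (center at offset j+2), or -1 if the window
    contains a non-ACGT base.
    """
    e = encoded.astype(np.int64)
    if e.size < 5:
        return np.empty(0, dtype=np.int64)
    c = e[:-4] * 256 + e[1:-3] * 64 + e[2:-2] * 16 + e[3:-1] * 4 + e[4:]
    ok = (e[:-4] >= 0) & (e[1:-3] >= 0) & (e[2:-2] >= 0) & (e[3:-1] >= 0) & (e[4:] >= 0)
    return np.where(ok, c, -1)


def sliding_pentamers(seq: str) -> list[tuple[int, Pentamer]]:
    """Decompose ``seq`` into its overlapping pentamers.

    Returns one ``(center, Pentamer)`` pair per bp position ``i`` from 3 to
    L-2 (1-based); the pentamer covers residues ``i-2 .. i+2``.  The list has
    length L-4.  Raises :class:`SequenceTooShortError` for L < 5.
    """
    s = normalize(seq)
    if len(s) < 5:
        raise SequenceTooShortError(
            f"need at least 5 bp for a pentamer window, got {len(s)}"
        )
    return [(i + 3, Pentamer.from_str(s[i : i + 5])) for i in range(len(s) - 4)]


def class_occurrences(seqs: "list[str]") -> np.ndarray:
    """Count pentamer-class occurrences over a collection of sequences.

    Counts every full A/C/G/T pentamer window once on the forward strand,
    merged into canonical classes.  Returns an int64 array indexed by
    pentamer code; only canonical codes carry counts.  This is the
    sequence-only corpus statistic (coverage, mean occurrence) used to audit
    a training-set design.
    """
    counts = np.zeros(N_PENTAMER_CODES, dtype=np.int64)
    for s in seqs:
        codes = window_codes(encode(s))
        codes = codes[codes >= 0]
        if codes.size:
            counts += np.bincount(CANON_CODE[codes], minlength=N_PENTAMER_CODES)
    return counts
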