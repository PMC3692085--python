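"""Per-position structural measurements for one DNA fragment.

A :class:`StructuralRecord` holds what a helical-parameter analysis of a
conformational ensemble reports for a single duplex fragment: two minor-groove
width levels per nucleotide (in Angstrom), a propeller twist per base pair
(degrees), and roll / helix twist per base-pair step (degrees, length L-1).
The record is the unit that gets mined into the pentamer query table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmer import normalize, revcomp

__all__ = ["StructuralRecord"]


@dataclass
class StructuralRecord:
    sequence: str
    groove_levels: np.ndarray  # shape (L, 2), Angstrom
    prot: np.ndarray           # shape (L,), degrees
    roll: np.ndarray           # shape (L-1,), degrees
    helt: np.ndarray           # shape (L-1,), degrees
    record_id: str = field(default="")

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        L = len(self.sequence)
        self.groove_levels = np.asarray(self.groove_levels, dtype=float)
        self.prot = np.asarray(self.prot, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        self.helt = np.asarray(self.helt, dtype=float)
        if self.groove_levels.shape != (L, 2):
            raise ValueError(
                f"groove_levels must have shape ({L}, 2), got {self.groove_levels.shape}"
            )
        if self.prot.shape != (L,):
            raise ValueError(f"prot must have length {L}, got {self.prot.shape}")
        if self.roll.shape != (L - 1,) or self.helt.shape != (L - 1,):
            raise ValueError(f"roll and helt must have length {L - 1}")
        if not (self.groove_levels > 0).all():
            raise ValueError("groove widths must be positive")
        for name in ("groove_levels", "prot", "roll", "helt"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def flat_levels(self) -> np.ndarray:
        """Groove levels as one ladder along the helix, length 2L.

        0-based: nucleotide i owns flat positions 2i (its first level) and
        2i+1 (its second level); the three-level window of bp i (i >= 1) is
        flat[2i-1 : 2i+2].
        """
        return self.groove_levels.reshape(-1)

    def reverse_complement(self) -> "StructuralRecord":
        """The same duplex read from the opposite strand.

        ProT reverses per bp; Roll/HelT reverse per step (these four
        parameters are invariant under strand exchange, so no sign flips).
        The groove-level ladder reverses with a one-position shift
        (flat'[g] = flat[2L-g]) so that the three-level window of each bp
        maps exactly onto the window of its partner bp; the single leftover
        terminal level pads a position whose three-level mean is undefined
        on the original strand anyway.
        """
        L = len(self)
        flat = self.flat_levels
        new_flat = np.empty_like(flat)
        # 0-based: new_flat[g] = flat[2L-1-g] would be a plain reversal;
        # the window-preserving map is new_flat[g] = flat[2L-2-g].
        new_flat[: 2 * L - 1] = flat[: 2 * L - 1][::-1]
        new_flat[2 * L - 1] = flat[2 * L - 1]
        return StructuralRecord(
            sequence=revcomp(self.sequence),
            groove_levels=new_flat.reshape(L, 2),
            prot=self.prot[::-1].copy(),
            roll=self.roll[::-1].copy(),
            helt=self.helt[::-1].copy(),
            record_id=self.record_id,
        )
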