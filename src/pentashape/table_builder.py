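"""Mine structural records with a sliding pentamer window into a query table.

Each occurrence of a pentamer in a record contributes the record's measured
features at the occurrence site to the pentamer's reverse-complement
equivalence class: minor groove width (three-level mean) and propeller twist
of the central bp, and roll / helix twist of the two central bp steps
(step 1 between pentamer positions 2-3, step 2 between positions 3-4).
When canonicalization reverse-complements an occurrence, step order is
swapped; MGW, ProT, Roll and HelT themselves are invariant under strand
exchange, so no values change sign.  The table entry is the arithmetic mean
over all contributions.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmer import (
    CANON_CODE,
    FLIPPED,
    N_PENTAMER_CODES,
    code_to_str,
    count_rc_classes,
    encode,
    str_to_code,
    window_codes,
)
from .records import StructuralRecord

__all__ = [
    "QueryTable",
    "mgw_at_bp",
    "mgw_profile",
    "build_query_table",
    "table_coverage",
]

logger = logging.getLogger(__name__)

FEATURES = ("MGW", "ProT", "Roll1", "Roll2", "HelT1", "HelT2")
TABLE_COLUMNS = ("count",) + FEATURES

N_CLASSES = count_rc_classes(5)  # 512
_CANONICAL_CODES = np.unique(CANON_CODE)
CANONICAL_PENTAMERS = tuple(code_to_str(int(c)) for c in _CANONICAL_CODES)


def mgw_profile(record: StructuralRecord) -> np.ndarray:
    """Per-bp minor groove width of a record, length L, 0-based array.

    The MGW assigned to a bp is the mean of three consecutive groove-width
    levels surrounding the bp plane: the last level of the preceding
    nucleotide and the two levels of the nucleotide itself.  Position 1
    (index 0) has no preceding level and is NaN.  This three-level window
    makes the value independent of which strand is taken as leading.
    """
    flat = record.flat_levels
    L = len(record)
    out = np.full(L, np.nan)
    # window of bp i (0-based, i>=1) is flat[2i-1 : 2i+2]; the two outer
    # levels are summed first so the result is bitwise identical when the
    # record is read from the opposite strand (which swaps the outer pair)
    out[1:] = ((flat[1:-2:2] + flat[3::2]) + flat[2:-1:2]) / 3.0
    return out


def mgw_at_bp(record: StructuralRecord, i: int) -> float:
    """Three-level minor groove width at 1-based bp position ``i``.

    Valid for 2 <= i <= L; position 1 has no level -1.
    """
    L = len(record)
    if not 2 <= i <= L:
        raise IndexError(f"bp position must satisfy 2 <= i <= {L}, got {i}")
    return float(mgw_profile(record)[i - 1])


@dataclass
class QueryTable:
    """Pentamer class -> average structural features.

    ``data`` is indexed by canonical pentamer string with columns
    ``count, MGW, ProT, Roll1, Roll2, HelT1, HelT2``.  A complete table has
    512 rows; pentamers never observed are absent, not zero-filled.
    """

    data: pd.DataFrame
    provenance: str = field(default="")

    def __post_init__(self) -> None:
        missing_cols = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing_cols:
            raise ValueError(f"table missing columns: {sorted(missing_cols)}")
        if (self.data["count"] < 1).any():
            raise ValueError("table entries must have count >= 1")
        self._luts: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, pent: str) -> bool:
        code = str_to_code(pent)
        return code_to_str(int(CANON_CODE[code])) in self.data.index

    @property
    def is_complete(self) -> bool:
        return len(self.data) == N_CLASSES

    def entry(self, pent: str) -> dict[str, float]:
        """Feature values for a pentamer in its *written* orientation.

        Looks up the canonical class and, when the written pentamer is the
        reverse-complemented member, swaps step 1 and step 2 so the values
        refer to the steps of the pentamer as written.
        """
        code = str_to_code(pent)
        canon = code_to_str(int(CANON_CODE[code]))
        row = self.data.loc[canon]
        out = {
            "MGW": float(row["MGW"]),
            "ProT": float(row["ProT"]),
            "Roll1": float(row["Roll1"]),
            "Roll2": float(row["Roll2"]),
            "HelT1": float(row["HelT1"]),
            "HelT2": float(row["HelT2"]),
            "count": float(row["count"]),
        }
        if FLIPPED[code]:
            out["Roll1"], out["Roll2"] = out["Roll2"], out["Roll1"]
            out["HelT1"], out["HelT2"] = out["HelT2"], out["HelT1"]
        return out

    # -- fast lookup ------------------------------------------------------
    def luts(self) -> dict[str, np.ndarray]:
        """Lookup arrays indexed by oriented pentamer code (length 1024).

        Step entries are already swapped for reverse-complemented members,
        so ``luts()['roll1'][code]`` is the Roll of the written pentamer's
        positions 2-3 step.  Missing classes are NaN.
        """
        if self._luts is None:
            canon_vals = {f: np.full(N_PENTAMER_CODES, np.nan) for f in FEATURES}
            idx = np.array([str_to_code(p) for p in self.data.index], dtype=np.int64)
            for f in FEATURES:
                canon_vals[f][idx] = self.data[f].to_numpy(dtype=float)
            c = CANON_CODE
            fl = FLIPPED
            self._luts = {
                "mgw": canon_vals["MGW"][c],
                "prot": canon_vals["ProT"][c],
                "roll1": np.where(fl, canon_vals["Roll2"][c], canon_vals["Roll1"][c]),
                "roll2": np.where(fl, canon_vals["Roll1"][c], canon_vals["Roll2"][c]),
                "helt1": np.where(fl, canon_vals["HelT2"][c], canon_vals["HelT1"][c]),
                "helt2": np.where(fl, canon_vals["HelT1"][c], canon_vals["HelT2"][c]),
            }
        return self._luts

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "pentamer"
        with open(path, "w") as fh:
            if self.provenance:
                fh.write(f"# provenance: {self.provenance}\n")
            df.to_csv(fh, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "QueryTable":
        provenance = ""
        with open(path) as fh:
            text = fh.read()
        lines = text.splitlines(keepends=True)
        body = []
        for ln in lines:
            if ln.startswith("# provenance:"):
                provenance = ln.split(":", 1)[1].strip()
            elif not ln.startswith("#"):
                body.append(ln)
        df = pd.read_csv(io.StringIO("".join(body)), sep="\t", index_col="pentamer")
        table = cls(data=df, provenance=provenance)
        if not table.is_complete:
            warnings.warn(
                f"query table covers {len(table)}/{N_CLASSES} pentamer classes; "
                "predictions for missing classes will be undefined",
                stacklevel=2,
            )
        return table


# ---------------------------------------------------------------------------
# Mining
# ---------------------------------------------------------------------------

def class_sums(canon: np.ndarray, vals: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-class feature sums, order-insensitive at the bit level.

    Contributions are sorted by (class, value) before summation, so mining a
    record and mining its reverse complement — which visit the same
    (class, value) multiset in opposite position order — produce bitwise
    identical sums.
    """
    out = {}
    for f in FEATURES:
        order = np.lexsort((vals[f], canon))
        out[f] = np.bincount(
            canon[order], weights=vals[f][order], minlength=N_PENTAMER_CODES
        )
    return out


def _accumulate(
    records: Iterable[StructuralRecord], trim: int
) -> tuple[dict[str, np.ndarray], np.ndarray, int]:
    """Sufficient statistics of mining: per-class feature sums and counts."""
    sums = {f: np.zeros(N_PENTAMER_CODES) for f in FEATURES}
    counts = np.zeros(N_PENTAMER_CODES, dtype=np.int64)
    n_skipped = 0
    for rec in records:
        canon, vals = _record_contributions(rec, trim)
        if canon is None:
            n_skipped += 1
            continue
        counts += np.bincount(canon, minlength=N_PENTAMER_CODES)
        for f, s in class_sums(canon, vals).items():
            sums[f] += s
    return sums, counts, n_skipped


def _record_contributions(rec: StructuralRecord, trim: int):
    """Canonical class codes and per-feature values for one record's windows.

    Window centers run (0-based) from 2+trim to L-3-trim.  Step order is
    swapped for occurrences that canonicalization reverse-complemented.
    Returns (None, None) for records too short to contribute.
    """
    L = len(rec)
    if L < 2 * trim + 5:
        logger.info("record %r (%d bp) shorter than 2*trim+5, skipped", rec.record_id, L)
        return None, None
    codes = window_codes(encode(rec.sequence))  # window j has center j+2
    lo, hi = trim, L - 5 - trim  # inclusive window-start offsets
    codes = codes[lo : hi + 1]
    centers = np.arange(lo + 2, hi + 3)
    ok = codes >= 0
    codes, centers = codes[ok], centers[ok]
    if codes.size == 0:
        return None, None
    mgwp = mgw_profile(rec)
    fl = FLIPPED[codes]
    r1, r2 = rec.roll[centers - 1], rec.roll[centers]
    h1, h2 = rec.helt[centers - 1], rec.helt[centers]
    vals = {
        "MGW": mgwp[centers],
        "ProT": rec.prot[centers],
        "Roll1": np.where(fl, r2, r1),
        "Roll2": np.where(fl, r1, r2),
        "HelT1": np.where(fl, h2, h1),
        "HelT2": np.where(fl, h1, h2),
    }
    return CANON_CODE[codes], vals


def _table_from_stats(
    sums: dict[str, np.ndarray], counts: np.ndarray, provenance: str
) -> QueryTable:
    present = np.nonzero(counts)[0]
    data = pd.DataFrame(
        {
            "count": counts[present],
            **{f: sums[f][present] / counts[present] for f in FEATURES},
        },
        index=pd.Index([code_to_str(int(c)) for c in present], name="pentamer"),
    )
    return QueryTable(data=data.sort_index(), provenance=provenance)


def build_query_table(
    records: Sequence[StructuralRecord],
    trim: int = 2,
    both_strands: bool = False,
    provenance: str = "",
) -> QueryTable:
    """Assemble the pentamer query table from structural records.

    Parameters
    ----------
    records:
        Structural records (non-empty).  Records shorter than ``2*trim + 5``
        contribute nothing and are logged.
    trim:
        Terminal bp excluded at each record end during mining (default 2;
        simulated fragment ends show end-fraying).
    both_strands:
        Also mine every record's reverse complement.  This exactly doubles
        every count and leaves the means unchanged (canonical-class merging
        already supplies strand symmetry); off by default so counts stay
        interpretable as forward-strand occurrences.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a query table from an empty record collection")
    if trim < 0:
        raise ValueError("trim must be >= 0")
    if both_strands:
        records = records + [r.reverse_complement() for r in records]
    sums, counts, n_skipped = _accumulate(records, trim)
    if n_skipped:
        logger.info("%d records too short to contribute", n_skipped)
    if not counts.any():
        raise ValueError("no record was long enough to contribute any window")
    return _table_from_stats(sums, counts, provenance)


def table_coverage(table: QueryTable) -> dict:
    """Coverage report: classes present, mean occurrences, missing classes."""
    present = set(table.data.index)
    missing = [p for p in CANONICAL_PENTAMERS if p not in present]
    return {
        "n_classes": len(table),
        "mean_occurrences": float(table.data["count"].mean()) if len(table) else 0.0,
        "missing": missing,
    }
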