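"""Quantitative validation of shape predictions.

This module implements the comparison machinery used to judge a pentamer
query table against per-position structural measurements:

* palindromic symmetrization of profiles (crystal-packing asymmetry of a
  self-reverse-complementary duplex is averaged out);
* deformation filtering — positions of experimental structures with extreme
  MGW, HelT or Roll (crystal packing, protein-induced bending) are masked
  together with 3-bp flanks before any correlation is computed;
* concatenation of per-structure feature vectors into one global vector per
  feature, and Spearman rank correlation between predicted and measured
  vectors;
* per-dinucleotide Roll/HelT summaries of a query table;
* leave-one-out cross-validation: rebuild the table without one record,
  predict that record's sequence, and correlate predictions with the
  record's own measurements, concatenated over all rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kmer import (
    CANON_CODE,
    N_PENTAMER_CODES,
    count_rc_classes,
    encode,
    revcomp,
)
from .predictor import _predict_arrays
from .records import StructuralRecord
from .table_builder import (
    FEATURES,
    QueryTable,
    _record_contributions,
    class_sums,
    mgw_profile,
)

__all__ = [
    "DeformationThresholds",
    "FeatureVector",
    "symmetrize",
    "deformation_mask",
    "concatenate",
    "spearman",
    "dinucleotide_summary",
    "loocv",
    "LoocvResult",
    "validate_predictions",
    "ValidationReport",
]

FEATURE_NAMES = ("mgw", "prot", "roll", "helt")


# ---------------------------------------------------------------------------
# Symmetrization
# ---------------------------------------------------------------------------

def symmetrize(values: np.ndarray, seq: str) -> np.ndarray:
    """Average a profile with its mirror, valid only for palindromic duplexes.

    ``values`` is bp-indexed (length L) or step-indexed (length L-1); element
    i is averaged with element n+1-i (1-based; for steps the mirror step of
    step s is step L-s).  The result is exactly mirror-symmetric.  Where one
    member of a pair is undefined the defined value is kept (so the output
    stays symmetric); pairs undefined on both sides stay undefined.
    """
    s = seq.upper()
    if s != revcomp(s):
        raise ValueError(
            "symmetrization requires a palindromic (self-reverse-complementary) sequence"
        )
    v = np.asarray(values, dtype=float)
    L = len(s)
    if v.shape not in {(L,), (L - 1,)}:
        raise ValueError(
            f"profile length {v.shape} matches neither bp ({L}) nor step ({L - 1}) indexing"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(np.stack([v, v[::-1]]), axis=0)


# ---------------------------------------------------------------------------
# Deformation filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeformationThresholds:
    """Cutoffs marking structurally deformed regions of experimental data.

    Defaults: MGW outside (1.5, 8.5) Angstrom, HelT above 45 degrees,
    |Roll| above 20 degrees, each with a 3-bp flank removed on both sides.
    B-DNA norms (~5.8 Angstrom, ~35 degrees, ~0 degrees) violate nothing.
    """

    mgw_hi: float = 8.5
    mgw_lo: float = 1.5
    helt_hi: float = 45.0
    roll_abs: float = 20.0
    flank: int = 3

    def __post_init__(self) -> None:
        if not self.mgw_lo < self.mgw_hi:
            raise ValueError("mgw_lo must be below mgw_hi")
        if min(self.mgw_lo, self.helt_hi, self.roll_abs) <= 0 or self.flank < 0:
            raise ValueError("thresholds must be positive and flank >= 0")


def _dilate(bad: np.ndarray, flank: int) -> np.ndarray:
    if flank == 0 or not bad.any():
        return bad
    out = bad.copy()
    for d in range(1, flank + 1):
        out[:-d] |= bad[d:]
        out[d:] |= bad[:-d]
    return out


def deformation_mask(
    mgw: np.ndarray | None = None,
    roll: np.ndarray | None = None,
    helt: np.ndarray | None = None,
    thresholds: DeformationThresholds = DeformationThresholds(),
    length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Validity masks (bp, step) after deformation filtering of one structure.

    An element is invalid if it triggers any criterion — (i) MGW above
    ``mgw_hi`` or below ``mgw_lo``, (ii) HelT above ``helt_hi``,
    (iii) |Roll| above ``roll_abs`` — or lies within ``flank`` bp of one that
    does.  A deformed step invalidates both bp it joins; flank dilation acts
    on bp; a step is valid only when both its bp are.  The mask covers all
    four features of the structure; missing feature arrays skip their
    criterion.  Flanks never extend past the structure's own ends (callers
    concatenate masks per structure).  Returns boolean arrays where True
    means *valid*.
    """
    if length is None:
        if mgw is not None:
            length = len(mgw)
        elif roll is not None:
            length = len(roll) + 1
        elif helt is not None:
            length = len(helt) + 1
        else:
            raise ValueError("need at least one feature array or an explicit length")
    L = int(length)
    bad_bp = np.zeros(L, dtype=bool)
    if mgw is not None:
        m = np.asarray(mgw, dtype=float)
        with np.errstate(invalid="ignore"):
            bad_bp |= (m > thresholds.mgw_hi) | (m < thresholds.mgw_lo)
    for step_arr, hi, use_abs in ((helt, thresholds.helt_hi, False), (roll, thresholds.roll_abs, True)):
        if step_arr is None:
            continue
        a = np.asarray(step_arr, dtype=float)
        with np.errstate(invalid="ignore"):
            bad_step = (np.abs(a) > hi) if use_abs else (a > hi)
        bad_bp[:-1] |= bad_step
        bad_bp[1:] |= bad_step
    bad_bp = _dilate(bad_bp, thresholds.flank)
    bp_mask = ~bad_bp
    step_mask = bp_mask[:-1] & bp_mask[1:]
    return bp_mask, step_mask


# ---------------------------------------------------------------------------
# Feature vectors, concatenation, Spearman
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """Position-ordered values from one or many structures, with validity."""

    values: np.ndarray
    labels: list = field(default_factory=list)  # (source_id, feature, position)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & np.isfinite(self.values)
        if self.labels and len(self.labels) != self.values.size:
            raise ValueError("labels and values must have equal length")
        if self.mask.size != self.values.size:
            raise ValueError("mask and values must have equal length")

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def __len__(self) -> int:
        return int(self.values.size)


def concatenate(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate per-source vectors, in source order."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("nothing to concatenate")
    return FeatureVector(
        values=np.concatenate([v.values for v in vectors]),
        labels=[lbl for v in vectors for lbl in v.labels],
        mask=np.concatenate([v.mask for v in vectors]),
    )


def paired_valid(x: FeatureVector, y: FeatureVector) -> tuple[np.ndarray, np.ndarray]:
    """Drop elements invalid in either vector, keeping the pairing aligned."""
    if len(x) != len(y):
        raise ValueError(f"paired vectors differ in length: {len(x)} != {len(y)}")
    keep = x.mask & y.mask
    return x.values[keep], y.values[keep]


def spearman(x, y) -> float:
    """Spearman's rank correlation with fractional (mean-rank) tie handling.

    Accepts :class:`FeatureVector` pairs (masked jointly) or plain arrays
    (NaN pairs dropped).  Returns NaN, with a warning, when fewer than three
    valid pairs remain or a side has zero rank variance.
    """
    if isinstance(x, FeatureVector) and isinstance(y, FeatureVector):
        xv, yv = paired_valid(x, y)
    else:
        xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        if xa.shape != ya.shape:
            raise ValueError("x and y must have equal length")
        keep = np.isfinite(xa) & np.isfinite(ya)
        xv, yv = xa[keep], ya[keep]
    if xv.size < 3:
        warnings.warn(f"spearman undefined: only {xv.size} valid pairs", stacklevel=2)
        return float("nan")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn("spearman undefined: zero rank variance", stacklevel=2)
        return float("nan")
    rx, ry = stats.rankdata(xv), stats.rankdata(yv)
    # rank-identical vectors are exactly (anti)correlated; the generic
    # cov/sqrt(var*var) route can land 1 ulp below +-1 on such input
    if np.array_equal(rx, ry):
        return 1.0
    if np.array_equal(rx, rx.size + 1 - ry):
        return -1.0
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Dinucleotide summary
# ---------------------------------------------------------------------------

_DINUC = [a + b for a in "ACGT" for b in "ACGT"]


def _canon_dinuc(d: str) -> str:
    rc = revcomp(d)
    return min(d, rc)


CANONICAL_DINUCLEOTIDES = tuple(sorted({_canon_dinuc(d) for d in _DINUC}))
assert len(CANONICAL_DINUCLEOTIDES) == count_rc_classes(2)


def dinucleotide_summary(table: QueryTable) -> tuple[pd.DataFrame, dict]:
    """Mean Roll and HelT per dinucleotide class, plus the grand mean.

    Every pentamer entry contributes its step-1 value to the dinucleotide
    realized at pentamer positions 2-3 and its step-2 value to positions 3-4
    (classes merged under reverse complement; the two members of a pentamer
    class realize the same dinucleotide classes with steps exchanged, so
    enumerating canonical entries is sufficient).  The grand mean is the
    unweighted mean over the 10 classes present.
    """
    acc: dict[str, dict[str, list]] = {
        d: {"Roll": [], "HelT": []} for d in CANONICAL_DINUCLEOTIDES
    }
    for pent, row in table.data.iterrows():
        for dinuc, roll_col, helt_col in (
            (pent[1:3], "Roll1", "HelT1"),
            (pent[2:4], "Roll2", "HelT2"),
        ):
            cls = _canon_dinuc(dinuc)
            acc[cls]["Roll"].append(float(row[roll_col]))
            acc[cls]["HelT"].append(float(row[helt_col]))
    rows = []
    for d in CANONICAL_DINUCLEOTIDES:
        n = len(acc[d]["Roll"])
        rows.append(
            {
                "dinucleotide": d,
                "n": n,
                "Roll": float(np.mean(acc[d]["Roll"])) if n else np.nan,
                "HelT": float(np.mean(acc[d]["HelT"])) if n else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("dinucleotide")
    present = df[df["n"] > 0]
    if len(present) < len(df):
        warnings.warn(
            f"dinucleotide classes without data: {sorted(set(df.index) - set(present.index))}",
            stacklevel=2,
        )
    grand = {
        "Roll": float(present["Roll"].mean()),
        "HelT": float(present["HelT"].mean()),
    }
    return df, grand


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LoocvResult:
    rho: dict            # feature -> Spearman coefficient over concatenated rounds
    n_pairs: dict        # feature -> number of paired elements
    n_rounds: int
    uncovered_positions: int   # predictions undefined because the held-out
                               # table lacked a pentamer class
    rounds_with_gaps: int

    def __repr__(self) -> str:  # compact report
        rhos = ", ".join(f"{k}={v:.4g}" for k, v in self.rho.items())
        return (
            f"LoocvResult({rhos}; rounds={self.n_rounds}, "
            f"uncovered={self.uncovered_positions})"
        )


def loocv(records: Sequence[StructuralRecord], trim: int = 2) -> LoocvResult:
    """Leave-one-out cross-validation of the pentamer model on its own corpus.

    For each record the query table is recompiled from all other records
    (by subtracting the record's contributions from precomputed sufficient
    statistics), the held-out sequence is predicted, and predicted values
    are paired with the record's own measured features at every defined
    position.  Pairs are concatenated across rounds per feature and
    compared by Spearman rank correlation.  Positions whose pentamer class
    is absent from the held-out table are counted as uncovered and masked,
    never fabricated.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("leave-one-out cross-validation needs at least 2 records")

    per_record = []
    total_sums = {f: np.zeros(N_PENTAMER_CODES) for f in FEATURES}
    total_counts = np.zeros(N_PENTAMER_CODES, dtype=np.int64)
    for rec in records:
        canon, vals = _record_contributions(rec, trim)
        if canon is None:
            per_record.append(None)
            continue
        cnt = np.bincount(canon, minlength=N_PENTAMER_CODES)
        sums = class_sums(canon, vals)
        per_record.append((cnt, sums))
        total_counts += cnt
        for f in FEATURES:
            total_sums[f] += sums[f]

    pred_parts: dict[str, list] = {f: [] for f in FEATURE_NAMES}
    meas_parts: dict[str, list] = {f: [] for f in FEATURE_NAMES}
    uncovered = 0
    rounds_with_gaps = 0

    for rec, contrib in zip(records, per_record):
        held_counts = total_counts - (contrib[0] if contrib else 0)
        held_means = {}
        with np.errstate(invalid="ignore", divide="ignore"):
            for f in FEATURES:
                s = total_sums[f] - (contrib[1][f] if contrib else 0.0)
                held_means[f] = np.where(held_counts > 0, s / held_counts, np.nan)
        luts = _luts_from_canonical_means(held_means)
        mgw_p, prot_p, roll_p, helt_p = _predict_arrays(encode(rec.sequence), luts)
        measured = {
            "mgw": mgw_profile(rec),
            "prot": rec.prot,
            "roll": rec.roll,
            "helt": rec.helt,
        }
        predicted = {"mgw": mgw_p, "prot": prot_p, "roll": roll_p, "helt": helt_p}

        L = len(rec)
        defined_bp = np.zeros(L, dtype=bool)
        defined_bp[2 : L - 2] = True
        defined_step = np.zeros(L - 1, dtype=bool)
        defined_step[1 : L - 2] = True
        gap_here = 0
        for f in FEATURE_NAMES:
            should = defined_bp if f in ("mgw", "prot") else defined_step
            p, m = predicted[f], measured[f]
            gap = should & ~np.isfinite(p)
            gap_here += int(gap.sum())
            keep = should & np.isfinite(p) & np.isfinite(m)
            pred_parts[f].append(p[keep])
            meas_parts[f].append(m[keep])
        uncovered += gap_here
        if gap_here:
            rounds_with_gaps += 1

    rho = {}
    n_pairs = {}
    for f in FEATURE_NAMES:
        p = np.concatenate(pred_parts[f]) if pred_parts[f] else np.empty(0)
        m = np.concatenate(meas_parts[f]) if meas_parts[f] else np.empty(0)
        n_pairs[f] = int(p.size)
        rho[f] = spearman(p, m)
    return LoocvResult(
        rho=rho,
        n_pairs=n_pairs,
        n_rounds=len(records),
        uncovered_positions=uncovered,
        rounds_with_gaps=rounds_with_gaps,
    )


def _luts_from_canonical_means(means: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Expand canonical-slot mean arrays to oriented-code lookup arrays."""
    c = CANON_CODE
    from .kmer import FLIPPED  # local alias for clarity

    return {
        "mgw": means["MGW"][c],
        "prot": means["ProT"][c],
        "roll1": np.where(FLIPPED, means["Roll2"][c], means["Roll1"][c]),
        "roll2": np.where(FLIPPED, means["Roll1"][c], means["Roll2"][c]),
        "helt1": np.where(FLIPPED, means["HelT2"][c], means["HelT1"][c]),
        "helt2": np.where(FLIPPED, means["HelT1"][c], means["HelT2"][c]),
    }


# ---------------------------------------------------------------------------
# Prediction-vs-measurement validation with deformation filtering
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    rho: dict          # feature -> Spearman over the concatenated global vector
    n_pairs: dict      # feature -> paired elements retained
    removed: dict      # criterion -> bp invalidated by it (before flanking)
    n_structures: int

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "n_pairs": self.n_pairs,
            "removed": self.removed,
            "n_structures": self.n_structures,
        }


def validate_predictions(
    table: QueryTable,
    records: Iterable[StructuralRecord],
    thresholds: DeformationThresholds = DeformationThresholds(),
) -> ValidationReport:
    """Correlate table predictions with measured records, after filtering.

    Deformation criteria are evaluated on the *measured* values only (their
    purpose is to excise crystal-packing / binding artifacts); the resulting
    masks are applied to both the predicted and measured sides, per
    structure, before concatenation into one global vector per feature.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to validate against")
    luts = table.luts()
    pred_parts: dict[str, list] = {f: [] for f in FEATURE_NAMES}
    meas_parts: dict[str, list] = {f: [] for f in FEATURE_NAMES}
    removed = {"mgw_range": 0, "helt_hi": 0, "roll_abs": 0, "flank": 0}
    for rec in records:
        measured = {
            "mgw": mgw_profile(rec),
            "prot": rec.prot,
            "roll": rec.roll,
            "helt": rec.helt,
        }
        mgw_p, prot_p, roll_p, helt_p = _predict_arrays(encode(rec.sequence), luts)
        predicted = {"mgw": mgw_p, "prot": prot_p, "roll": roll_p, "helt": helt_p}
        bp_mask, step_mask = deformation_mask(
            mgw=measured["mgw"], roll=measured["roll"], helt=measured["helt"],
            thresholds=thresholds,
        )
        _audit_criteria(measured, thresholds, bp_mask, removed)
        for f in FEATURE_NAMES:
            mask = bp_mask if f in ("mgw", "prot") else step_mask
            keep = mask & np.isfinite(predicted[f]) & np.isfinite(measured[f])
            pred_parts[f].append(predicted[f][keep])
            meas_parts[f].append(measured[f][keep])
    rho, n_pairs = {}, {}
    for f in FEATURE_NAMES:
        p = np.concatenate(pred_parts[f])
        m = np.concatenate(meas_parts[f])
        n_pairs[f] = int(p.size)
        rho[f] = spearman(p, m)
    return ValidationReport(
        rho=rho, n_pairs=n_pairs, removed=removed, n_structures=len(records)
    )


def _audit_criteria(measured, thresholds, bp_mask, removed) -> None:
    """Count bp invalidated by each criterion (flank-attributed separately)."""
    m = measured["mgw"]
    with np.errstate(invalid="ignore"):
        bad_mgw = (m > thresholds.mgw_hi) | (m < thresholds.mgw_lo)
        bad_helt_step = measured["helt"] > thresholds.helt_hi
        bad_roll_step = np.abs(measured["roll"]) > thresholds.roll_abs
    removed["mgw_range"] += int(bad_mgw.sum())
    removed["helt_hi"] += int(bad_helt_step.sum())
    removed["roll_abs"] += int(bad_roll_step.sum())
    direct = bad_mgw.copy()
    direct[:-1] |= bad_helt_step | bad_roll_step
    direct[1:] |= bad_helt_step | bad_roll_step
    removed["flank"] += int((~bp_mask & ~direct).sum())
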