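"""Readers and writers: sequences, structural-record archives, profiles.

Sequence input is multi-record FASTA or plain one-sequence-per-line text,
auto-detected by a leading ``>``.  Profile output is one TSV per feature
with undefined values spelled ``NA``, plus a JSON manifest.  A structural-
record archive is a single TSV with one row per nucleotide: ``record_id,
position, base, groove_level_1, groove_level_2, ProT, Roll_to_next,
HelT_to_next`` — the last two empty on each record's final row (there is no
step past the last bp).
"""

from __future__ import annotations

import json
import math
import os
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .predictor import ShapeProfile
from .records import StructuralRecord

__all__ = [
    "read_sequences",
    "write_profiles",
    "write_records",
    "read_records",
]

_NA = "NA"


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def read_sequences(path, fmt: str = "auto") -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or plain line-oriented text.

    FASTA ids come from the headers (first whitespace-delimited token);
    line-mode ids are ``seq_1 .. seq_n``.  Wrapped FASTA bodies are joined;
    case is normalized to upper.  Order is preserved.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    if fmt == "auto":
        fmt = "fasta" if text.lstrip().startswith(">") else "lines"
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no parseable FASTA records")
        out = [(r.id, str(r.seq).upper()) for r in records]
        for rid, s in out:
            if not s:
                raise ValueError(f"{path}: FASTA record {rid!r} has an empty body")
        return out
    if fmt == "lines":
        out = []
        for ln_no, line in enumerate(text.splitlines(), start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                raise ValueError(
                    f"{path}:{ln_no}: FASTA header in line-oriented input"
                )
            out.append((f"seq_{len(out) + 1}", s.upper()))
        return out
    raise ValueError(f"unknown sequence format {fmt!r}")


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return _NA if not math.isfinite(x) else f"{x:.4f}"


_FEATURE_FILES = {"MGW": "mgw", "ProT": "prot", "Roll": "roll", "HelT": "helt"}


def write_profiles(
    profiles: Sequence[ShapeProfile],
    output_dir,
    fmt: str = "tsv",
    plot: bool = False,
) -> dict:
    """Write one TSV per feature; return the manifest (also saved as JSON).

    ``tsv`` (long) format: columns sequence_id, position (bp index, or step
    label ``s-s+1``), value.  ``wide`` format: one row per sequence with all
    positions tab-separated.  Undefined values are the literal ``NA``.
    """
    if fmt not in {"tsv", "wide"}:
        raise ValueError(f"unknown output format {fmt!r}")
    os.makedirs(output_dir, exist_ok=True)
    manifest: dict = {"format": fmt, "files": {}}
    for feature, attr in _FEATURE_FILES.items():
        fname = f"{feature}.tsv"
        fpath = os.path.join(output_dir, fname)
        n_rows = 0
        with open(fpath, "w") as fh:
            if fmt == "tsv":
                fh.write("sequence_id\tposition\tvalue\n")
                for p in profiles:
                    vals = p.feature(attr)
                    step_wise = attr in ("roll", "helt")
                    for i, v in enumerate(vals, start=1):
                        label = f"{i}-{i + 1}" if step_wise else str(i)
                        fh.write(f"{p.sequence_id}\t{label}\t{_fmt(v)}\n")
                        n_rows += 1
            else:
                fh.write("sequence_id\tvalues\n")
                for p in profiles:
                    body = "\t".join(_fmt(v) for v in p.feature(attr))
                    fh.write(f"{p.sequence_id}\t{body}\n")
                    n_rows += 1
        manifest["files"][fname] = n_rows
    if plot and profiles:
        manifest["plots"] = _plot_profiles(profiles, output_dir)
    with open(os.path.join(output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _plot_profiles(profiles: Sequence[ShapeProfile], output_dir) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    units = {"MGW": "Å", "ProT": "deg", "Roll": "deg", "HelT": "deg"}
    written = []
    for p in profiles:
        fig, axes = plt.subplots(4, 1, figsize=(max(6, len(p) / 10), 9), sharex=True)
        for ax, (feature, attr) in zip(axes, _FEATURE_FILES.items()):
            vals = p.feature(attr)
            x = np.arange(1, len(vals) + 1)
            ax.plot(x, vals, marker="o", markersize=2, lw=1)
            ax.set_ylabel(f"{feature} ({units[feature]})")
        axes[-1].set_xlabel("bp position / step")
        fig.suptitle(p.sequence_id or "sequence")
        fname = f"{p.sequence_id or 'sequence'}.png"
        fig.savefig(os.path.join(output_dir, fname), dpi=100)
        plt.close(fig)
        written.append(fname)
    return written


# ---------------------------------------------------------------------------
# Structural-record archives
# ---------------------------------------------------------------------------

_REC_HEADER = (
    "record_id\tposition\tbase\tgroove_level_1\tgroove_level_2\tProT\t"
    "Roll_to_next\tHelT_to_next\n"
)


def write_records(records: Iterable[StructuralRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_REC_HEADER)
        for rec in records:
            L = len(rec)
            for i in range(L):
                roll = f"{rec.roll[i]:.6g}" if i < L - 1 else ""
                helt = f"{rec.helt[i]:.6g}" if i < L - 1 else ""
                fh.write(
                    f"{rec.record_id}\t{i + 1}\t{rec.sequence[i]}\t"
                    f"{rec.groove_levels[i, 0]:.6g}\t{rec.groove_levels[i, 1]:.6g}\t"
                    f"{rec.prot[i]:.6g}\t{roll}\t{helt}\n"
                )


def read_records(path) -> list[StructuralRecord]:
    """Read a structural-record archive written by :func:`write_records`."""
    groups: dict[str, list[list[str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record_id"):
            raise ValueError(f"{path}: not a structural-record archive")
        for ln_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                raise ValueError(f"{path}:{ln_no}: expected 8 columns, got {len(parts)}")
            rid = parts[0]
            if rid not in groups:
                groups[rid] = []
                order.append(rid)
            groups[rid].append(parts)
    records = []
    for rid in order:
        rows = sorted(groups[rid], key=lambda r: int(r[1]))
        seq = "".join(r[2] for r in rows)
        L = len(rows)
        levels = np.array([[float(r[3]), float(r[4])] for r in rows])
        prot = np.array([float(r[5]) for r in rows])
        roll = np.array([float(r[6]) for r in rows[:-1]])
        helt = np.array([float(r[7]) for r in rows[:-1]])
        if rows[-1][6] or rows[-1][7]:
            raise ValueError(
                f"{path}: record {rid!r} has step values on its final row"
            )
        records.append(
            StructuralRecord(
                sequence=seq,
                groove_levels=levels,
                prot=prot,
                roll=roll,
                helt=helt,
                record_id=rid,
            )
        )
    return records
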