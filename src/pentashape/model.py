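"""Estimator-style front end for the pentamer shape model.

:class:`PentamerShapeModel` follows scikit-learn conventions: ``fit`` mines a
collection of structural records into the pentamer query table (stored as the
fitted attribute ``table_``), ``predict`` turns nucleotide sequences into
per-position shape profiles, and ``get_params``/``set_params``/``clone`` work
as usual.  The module-level functions ``build_query_table`` and ``predict``
elsewhere in the package are thin wrappers over this class.
"""

from __future__ import annotations

from typing import Sequence

from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import predictor as _predictor
from . import table_builder as _tb
from .records import StructuralRecord

__all__ = ["PentamerShapeModel"]


class PentamerShapeModel(BaseEstimator):
    """Sliding-pentamer predictor of DNA structural features.

    Parameters
    ----------
    trim : int, default=2
        Terminal bp excluded at each record end when mining (fragment ends
        of simulated DNA show end-fraying).
    both_strands : bool, default=False
        Mine each record's reverse complement as well.  Doubles every count
        and leaves table means unchanged.
    max_len : int, default=1_000_000
        Per-sequence length cap at prediction time.

    Attributes
    ----------
    table_ : QueryTable
        The mined pentamer query table.
    coverage_ : dict
        Class coverage report (n_classes, mean_occurrences, missing).
    n_records_ : int
        Number of records mined.
    """

    def __init__(
        self,
        trim: int = 2,
        both_strands: bool = False,
        max_len: int = _predictor.DEFAULT_MAX_LENGTH,
    ):
        self.trim = trim
        self.both_strands = both_strands
        self.max_len = max_len

    def fit(self, X: Sequence[StructuralRecord], y=None) -> "PentamerShapeModel":
        """Mine structural records into the pentamer query table."""
        records = list(X)
        self.table_ = _tb.build_query_table(
            records,
            trim=self.trim,
            both_strands=self.both_strands,
            provenance=f"mined from {len(records)} structural records (trim={self.trim})",
        )
        self.coverage_ = _tb.table_coverage(self.table_)
        self.n_records_ = len(records)
        return self

    @classmethod
    def from_table(cls, table: _tb.QueryTable, **params) -> "PentamerShapeModel":
        """A ready-to-predict model around an existing query table."""
        model = cls(**params)
        model.table_ = table
        model.coverage_ = _tb.table_coverage(table)
        model.n_records_ = 0
        return model

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise NotFittedError(
                "this PentamerShapeModel has no query table; call fit() or from_table()"
            )

    def predict(self, X) -> list:
        """Shape profiles for sequences (strings or (id, sequence) pairs).

        A single string is accepted and yields a single :class:`ShapeProfile`;
        a collection yields a list of profiles in input order.
        """
        self._check_fitted()
        if isinstance(X, str):
            return _predictor.predict(X, self.table_, max_len=self.max_len)
        return [
            _predictor.predict(s, self.table_, max_len=self.max_len, sequence_id=sid)
            for sid, s in _as_pairs(X)
        ]

    def predict_batch(self, X) -> _predictor.BatchResult:
        """Like :meth:`predict` but per-sequence failures do not abort."""
        self._check_fitted()
        return _predictor.predict_batch(list(X), self.table_, max_len=self.max_len)


def _as_pairs(seqs):
    for idx, item in enumerate(seqs):
        if isinstance(item, tuple):
            yield item
        else:
            yield f"seq_{idx + 1}", item
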