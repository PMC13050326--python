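"""Scored-cohort data model and file I/O.

The universal input of every analysis is a :class:`ScoredCohort`: an ordered
collection of cases, each carrying a unique identifier, a continuous risk
score in the closed interval [0, 1], a binary ground-truth label
(1 = positive / diseased, 0 = negative / healthy), and optionally the
human reader's binary call for the same case.

Cohorts are read from CSV/TSV files with columns
``case_id,score,label[,reader_call]`` (names remappable via ``column_map``).
Labels and reader calls are accepted as ``{0,1}``, ``{neg,pos}``,
``{negative,positive}`` or ``{C0,C1}``, case-insensitively.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import is_dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ConfigurationError, UsageError

__all__ = [
    "ScoredCohort",
    "ReaderOutcome",
    "read_cohort",
    "summarize_cohort",
    "write_results",
]

_POSITIVE_TOKENS = {"1", "pos", "positive", "c1", "true", "malignant"}
_NEGATIVE_TOKENS = {"0", "neg", "negative", "c0", "false", "benign"}


class ReaderOutcome(enum.Enum):
    """Outcome of the human reader's call against the reference standard."""

    TP = "TP"
    TN = "TN"
    FP = "FP"
    FN = "FN"

    @staticmethod
    def from_call(reader_call: int, label: int) -> "ReaderOutcome":
        if reader_call == 1:
            return ReaderOutcome.TP if label == 1 else ReaderOutcome.FP
        return ReaderOutcome.FN if label == 1 else ReaderOutcome.TN


def _as_binary_number(token: str) -> float | None:
    """Parse '0'/'1' written as numbers (e.g. '1.0'); None otherwise."""
    try:
        x = float(token)
    except ValueError:
        return None
    return x if x in (0.0, 1.0) else None


def _normalize_binary(values: pd.Series, colname: str) -> np.ndarray:
    """Map a column of binary tokens to int8 {0,1}; NaN stays NaN (float)."""
    out = np.full(len(values), np.nan)
    for k, v in enumerate(values):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        token = str(v).strip().lower()
        if token in _POSITIVE_TOKENS:
            out[k] = 1
        elif token in _NEGATIVE_TOKENS:
            out[k] = 0
        elif token in ("", "nan", "na", "none"):
            continue
        elif _as_binary_number(token) is not None:
            out[k] = _as_binary_number(token)
        else:
            raise CohortValidationError(
                f"unrecognized {colname} value {v!r} (row {k}); expected one of "
                f"{sorted(_POSITIVE_TOKENS | _NEGATIVE_TOKENS)}"
            )
    return out


class ScoredCohort:
    """Ordered per-case records: id, risk score in [0,1], label, reader call.

    Parameters
    ----------
    case_ids, scores, labels : array-like, equal length
    reader_calls : array-like of float or None
        1/0 per case, ``nan`` where the reader call is missing; ``None`` if
        the cohort carries no reader column at all.
    validate : bool
        Skip validation for trusted internal construction (bootstrap loops).
    """

    def __init__(self, case_ids, scores, labels, reader_calls=None, *, validate=True):
        self.case_ids = np.asarray(case_ids, dtype=object)
        self.scores = np.asarray(scores, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int8)
        self.reader_calls = (
            None if reader_calls is None else np.asarray(reader_calls, dtype=np.float64)
        )
        if validate:
            self._validate()
        self._fingerprint: str | None = None

    def _validate(self) -> None:
        n = len(self.case_ids)
        if n == 0:
            raise CohortValidationError("cohort is empty")
        if len(self.scores) != n or len(self.labels) != n:
            raise CohortValidationError("case_ids, scores and labels differ in length")
        if self.reader_calls is not None and len(self.reader_calls) != n:
            raise CohortValidationError("reader_calls length mismatch")
        if np.isnan(self.scores).any():
            bad = self.case_ids[np.isnan(self.scores)][0]
            raise CohortValidationError(f"non-numeric score for case_id {bad!r}")
        out = (self.scores < 0.0) | (self.scores > 1.0)
        if out.any():
            bad = self.case_ids[out][0]
            raise CohortValidationError(
                f"score {self.scores[out][0]} outside [0, 1] for case_id {bad!r}"
            )
        if len(set(self.case_ids.tolist())) != n:
            seen, dup = set(), None
            for cid in self.case_ids:
                if cid in seen:
                    dup = cid
                    break
                seen.add(cid)
            raise CohortValidationError(f"duplicate case_id {dup!r}")
        if not np.isin(self.labels, (0, 1)).all():
            raise CohortValidationError("labels must be binary (0/1)")
        if self.reader_calls is not None:
            rc = self.reader_calls[~np.isnan(self.reader_calls)]
            if not np.isin(rc, (0.0, 1.0)).all():
                raise CohortValidationError("reader_call values must be binary (0/1)")

    # -- basic properties ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.n

    @property
    def two_class(self) -> bool:
        return self.n_pos > 0 and self.n_neg > 0

    @property
    def has_reader_calls(self) -> bool:
        return self.reader_calls is not None and not np.isnan(self.reader_calls).all()

    def require_two_class(self) -> None:
        if not self.two_class:
            raise CohortValidationError(
                "cohort must contain at least one positive and one negative case"
            )

    @property
    def fingerprint(self) -> str:
        """Opaque content hash of (scores, labels); ties boundaries to data."""
        if self._fingerprint is None:
            h = hashlib.sha256()
            h.update(np.ascontiguousarray(self.scores).tobytes())
            h.update(np.ascontiguousarray(self.labels).tobytes())
            self._fingerprint = h.hexdigest()[:16]
        return self._fingerprint

    # -- reader outcomes ----------------------------------------------------
    def reader_outcomes(self) -> list[ReaderOutcome | None]:
        """Per-case reader outcome; ``None`` where the call is missing."""
        if self.reader_calls is None:
            raise CohortValidationError("cohort has no reader_call column")
        out: list[ReaderOutcome | None] = []
        for call, label in zip(self.reader_calls, self.labels):
            out.append(None if math.isnan(call) else ReaderOutcome.from_call(int(call), int(label)))
        return out

    # -- conversion ---------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        data = {"case_id": self.case_ids, "score": self.scores, "label": self.labels}
        if self.reader_calls is not None:
            data["reader_call"] = self.reader_calls
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, column_map: Mapping[str, str] | None = None):
        cmap = {"case_id": "case_id", "score": "score", "label": "label",
                "reader_call": "reader_call"}
        if column_map:
            cmap.update(column_map)
        for canonical in ("case_id", "score", "label"):
            if cmap[canonical] not in df.columns:
                raise ConfigurationError(
                    f"required column {cmap[canonical]!r} (for {canonical!r}) not found; "
                    f"available: {list(df.columns)}"
                )
        scores = pd.to_numeric(df[cmap["score"]], errors="coerce").to_numpy(dtype=float)
        labels_raw = _normalize_binary(df[cmap["label"]], "label")
        if np.isnan(labels_raw).any():
            bad = df[cmap["case_id"]].to_numpy(dtype=object)[np.isnan(labels_raw)][0]
            raise CohortValidationError(f"missing label for case_id {bad!r}")
        reader = None
        if cmap["reader_call"] in df.columns:
            reader = _normalize_binary(df[cmap["reader_call"]], "reader_call")
        return cls(
            df[cmap["case_id"]].to_numpy(dtype=object),
            scores,
            labels_raw.astype(np.int8),
            reader,
        )

    def subset(self, indices: np.ndarray) -> "ScoredCohort":
        """Row subset / resample by positional indices (no validation)."""
        return ScoredCohort(
            self.case_ids[indices],
            self.scores[indices],
            self.labels[indices],
            None if self.reader_calls is None else self.reader_calls[indices],
            validate=False,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScoredCohort):
            return NotImplemented
        same_reader = (
            (self.reader_calls is None and other.reader_calls is None)
            or (
                self.reader_calls is not None
                and other.reader_calls is not None
                and np.allclose(self.reader_calls, other.reader_calls, equal_nan=True)
            )
        )
        return (
            bool((self.case_ids == other.case_ids).all())
            and np.allclose(self.scores, other.scores, rtol=1e-12, atol=0)
            and bool((self.labels == other.labels).all())
            and same_reader
        )

    def __repr__(self) -> str:
        return f"ScoredCohort(n={self.n}, n_pos={self.n_pos}, n_neg={self.n_neg})"


def read_cohort(path, dialect: str | None = None,
                column_map: Mapping[str, str] | None = None) -> ScoredCohort:
    """Read a cohort from a CSV/TSV file.

    ``dialect`` is ``"csv"``, ``"tsv"`` or ``None`` (infer from suffix,
    default comma).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"cohort file not found: {path}")
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ConfigurationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = pd.read_csv(path, sep=sep)
    cohort = ScoredCohort.from_dataframe(df, column_map)
    # re-check score parse failures with a named case
    raw = df[(column_map or {}).get("score", "score")]
    bad = np.isnan(cohort.scores)
    if bad.any():
        cid = cohort.case_ids[bad][0]
        raise CohortValidationError(f"score {raw[bad][0]!r} does not parse for case_id {cid!r}")
    return cohort


def summarize_cohort(cohort: ScoredCohort) -> dict:
    """Basic counts. Prevalence is exact (``n_pos / n``); single-class cohorts
    are summarized but flagged as unusable for zone computations."""
    if cohort.n == 0:
        raise CohortValidationError("cohort is empty")
    return {
        "n": cohort.n,
        "n_pos": cohort.n_pos,
        "n_neg": cohort.n_neg,
        "prevalence": cohort.prevalence,
        "score_min": float(cohort.scores.min()),
        "score_max": float(cohort.scores.max()),
        "zone_computation_available": cohort.two_class,
    }


def _jsonable(obj):
    """Recursively convert result objects to JSON-serializable structures."""
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _jsonable(float(obj))
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if hasattr(obj, "to_record"):
        return _jsonable(obj.to_record())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    raise UsageError(f"object of type {type(obj).__name__} is not serializable")


def write_results(obj, path, format: str | None = None) -> None:
    """Serialize a result object to ``path`` as CSV or JSON.

    CSV targets tabular objects (cohorts, partitions, profiles, DataFrames);
    JSON serializes anything with a documented record form. Floats are
    written with 17 significant digits so that read-back round-trips.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format not in ("csv", "json"):
        raise UsageError(f"unknown format {format!r}")
    try:
        if format == "csv":
            if isinstance(obj, pd.DataFrame):
                df = obj
            elif hasattr(obj, "to_dataframe"):
                df = obj.to_dataframe()
            else:
                raise UsageError(
                    f"{type(obj).__name__} has no tabular form; use format='json'"
                )
            df.to_csv(path, index=False, float_format="%.17g")
        else:
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(_jsonable(obj), fh, indent=2)
                fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
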