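"""Phoneme annotations and binary phonological-feature lexica.

A :class:`FeatureLexicon` maps phoneme labels (e.g. German SAMPA symbols) to
binary bundles of the 17 Chomsky–Halle phonological features used throughout
this package.  A :class:`PhonemeAnnotation` is a timed, non-overlapping
sequence of labelled phoneme intervals, typically produced by forced
alignment; gaps between intervals are silence.

:func:`expand_features` converts an annotation into per-feature spans by
merging maximal runs of temporally adjacent phonemes that carry the feature.
A silence that immediately follows a span is appended to that span's
duration (no new phonological information arrives during the pause), up to
the next phoneme onset.
"""

from __future__ import annotations

import csv
import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Canonical feature order used for predictors, statistics and tie-breaking.
FEATURES: tuple[str, ...] = (
    "voiced", "continuant", "sonorant", "low", "tense", "back", "strident",
    "consonantal", "long", "syllabic", "round", "high", "coronal",
    "anterior", "nasal", "labial", "lateral",
)

#: Labels treated as silence/pause when reading annotations.
PAUSE_LABELS = {"", "<p:>", "<p>", "sil", "sp", "_", "#", "pause", "<sil>"}

#: Boundary gaps below this are treated as exact abutment (float noise guard).
ADJACENCY_TOL_S = 1e-3


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent phoneme annotations."""


class LexiconError(KeyError):
    """Raised when a phoneme label is missing from a lexicon."""


@dataclass(frozen=True)
class FeatureLexicon:
    """Mapping from phoneme label to a binary feature bundle.

    Parameters
    ----------
    features
        Ordered feature names (must equal :data:`FEATURES` by default).
    table
        Phoneme label -> 0/1 vector of ``len(features)``.
    """

    features: tuple[str, ...]
    table: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for label, vec in self.table.items():
            v = np.asarray(vec)
            if v.shape != (len(self.features),):
                raise ValueError(
                    f"feature vector for {label!r} has shape {v.shape}, "
                    f"expected ({len(self.features)},)"
                )
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"non-binary feature value for {label!r}")

    def __contains__(self, label: str) -> bool:
        return label in self.table

    def bundle(self, label: str) -> np.ndarray:
        try:
            return np.asarray(self.table[label], dtype=int)
        except KeyError:
            raise LexiconError(f"phoneme label not in lexicon: {label!r}") from None

    def positive_features(self, label: str) -> list[str]:
        vec = self.bundle(label)
        return [f for f, v in zip(self.features, vec) if v]

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureLexicon":
        """Read a lexicon CSV: header ``phoneme,<feature names...>``."""
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            features = tuple(h.strip() for h in header[1:])
            table = {
                row[0]: np.array([int(x) for x in row[1:]], dtype=int)
                for row in reader
                if row
            }
        return cls(features=features, table=table)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(("phoneme",) + tuple(self.features))
            for label, vec in self.table.items():
                writer.writerow([label] + [int(v) for v in vec])

    @classmethod
    def german(cls) -> "FeatureLexicon":
        """Built-in German SAMPA lexicon with Chomsky–Halle assignments.

        The table is shipped as a versioned, user-overridable CSV; diphthongs
        are single labels with their own bundles.
        """
        ref = importlib.resources.files("phonotrf.data") / "german_sampa_features.csv"
        with importlib.resources.as_file(ref) as path:
            lex = cls.from_csv(path)
        if lex.features != FEATURES:
            raise ValueError("shipped lexicon does not match canonical feature order")
        return lex


@dataclass(frozen=True)
class Interval:
    label: str
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PhonemeAnnotation:
    """Sorted, non-overlapping phoneme intervals over ``[0, total_duration]``."""

    intervals: list[Interval]
    total_duration: float

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.onset)
        prev: Interval | None = None
        for iv in self.intervals:
            if iv.offset <= iv.onset:
                raise AnnotationError(
                    f"interval {iv.label!r} has offset {iv.offset} <= onset {iv.onset}"
                )
            if prev is not None and iv.onset < prev.offset - ADJACENCY_TOL_S:
                raise AnnotationError(
                    f"overlapping intervals: {prev.label!r} "
                    f"({prev.onset}-{prev.offset}) and {iv.label!r} "
                    f"({iv.onset}-{iv.offset})"
                )
            prev = iv
        if self.intervals:
            self.total_duration = max(self.total_duration, self.intervals[-1].offset)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]


#: Per-feature active spans: feature name -> list of (onset, offset) pairs.
FeatureIntervalSet = dict[str, list[tuple[float, float]]]


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def _is_pause(label: str) -> bool:
    return label.strip().lower() in PAUSE_LABELS


def _read_tsv(path: Path) -> PhonemeAnnotation:
    intervals: list[Interval] = []
    total = 0.0
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = re.split(r"[\t,]", line)
            if len(parts) < 3:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 3 columns (label, onset, offset)"
                )
            label = parts[0].strip()
            try:
                onset, offset = float(parts[1]), float(parts[2])
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise AnnotationError(f"{path}:{lineno}: non-numeric times") from None
            total = max(total, offset)
            if not _is_pause(label):
                intervals.append(Interval(label, onset, offset))
    return PhonemeAnnotation(intervals=intervals, total_duration=total)


def _read_textgrid(path: Path, tier: str | None) -> PhonemeAnnotation:
    """Parse a Praat TextGrid (long or short text format)."""
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text:
        raise AnnotationError(f"{path}: not a Praat TextGrid")

    # Tokenize: quoted strings and bare numbers/words.  Bracketed indices
    # ("item [1]:") are long-format decoration and must not read as numbers.
    text = re.sub(r"\[[^\]]*\]", " ", text)
    tokens = re.findall(r'"(?:[^"]|"")*"|[^\s=]+', text)

    # Walk tokens collecting IntervalTiers. Both formats serialize each tier
    # as: "IntervalTier" <name> <xmin> <xmax> <n> then n * (xmin xmax label).
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    i = 0

    def unquote(tok: str) -> str:
        return tok[1:-1].replace('""', '"') if tok.startswith('"') else tok

    def next_number(j: int) -> tuple[float, int]:
        while j < len(tokens):
            tok = tokens[j]
            try:
                return float(tok), j + 1
            except ValueError:
                j += 1
        raise AnnotationError(f"{path}: truncated TextGrid")

    while i < len(tokens):
        if unquote(tokens[i]) == "IntervalTier":
            i += 1
            # next quoted token is the tier name
            while i < len(tokens) and not tokens[i].startswith('"'):
                i += 1
            name = unquote(tokens[i]); i += 1
            _, i = next_number(i)          # tier xmin
            _, i = next_number(i)          # tier xmax
            n, i = next_number(i)          # interval count
            items: list[tuple[float, float, str]] = []
            for _ in range(int(n)):
                xmin, i = next_number(i)
                xmax, i = next_number(i)
                while i < len(tokens) and not tokens[i].startswith('"'):
                    i += 1
                if i >= len(tokens):
                    raise AnnotationError(f"{path}: truncated interval text")
                label = unquote(tokens[i]); i += 1
                items.append((xmin, xmax, label))
            tiers[name] = items
        else:
            i += 1

    if not tiers:
        raise AnnotationError(f"{path}: no IntervalTier found")
    if tier is None:
        tier = next(iter(tiers))
    if tier not in tiers:
        raise AnnotationError(
            f"{path}: tier {tier!r} not found (have {sorted(tiers)})"
        )

    items = tiers[tier]
    total = max((xmax for _, xmax, _ in items), default=0.0)
    intervals = [
        Interval(label.strip(), xmin, xmax)
        for xmin, xmax, label in items
        if not _is_pause(label)
    ]
    return PhonemeAnnotation(intervals=intervals, total_duration=total)


def read_annotation(path: str | Path, tier: str | None = None) -> PhonemeAnnotation:
    """Read a phoneme annotation from a TextGrid interval tier or a TSV.

    TSV rows are ``label<TAB>onset<TAB>offset`` (seconds); pause labels
    (empty, ``<p:>``, ``sil`` ...) become silence gaps.  The file dialect is
    detected from the content, not the extension.
    """
    path = Path(path)
    head = path.read_text(encoding="utf-8", errors="replace")[:200]
    if "ooTextFile" in head:
        return _read_textgrid(path, tier)
    return _read_tsv(path)


def write_annotation(ann: PhonemeAnnotation, path: str | Path) -> None:
    """Write an annotation as a 3-column TSV (label, onset, offset)."""
    with open(path, "w", newline="") as fh:
        for iv in ann.intervals:
            fh.write(f"{iv.label}\t{iv.onset:.6f}\t{iv.offset:.6f}\n")


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

def expand_features(
    ann: PhonemeAnnotation,
    lex: FeatureLexicon,
    append_silence: bool = True,
) -> FeatureIntervalSet:
    """Merge feature-positive phoneme runs into per-feature spans.

    For each feature, maximal runs of temporally adjacent phonemes (boundary
    gap < 1 ms) carrying the feature are merged into one span.  A span ends
    at the last feature-positive phoneme; with ``append_silence`` the silence
    following that phoneme (up to the next phoneme onset, capped at
    ``total_duration``) is added to the span.
    """
    bundles = np.array([lex.bundle(iv.label) for iv in ann.intervals], dtype=int) \
        if ann.intervals else np.zeros((0, len(lex.features)), dtype=int)

    spans: FeatureIntervalSet = {f: [] for f in lex.features}
    n = len(ann.intervals)
    for fi, feat in enumerate(lex.features):
        run_start: float | None = None
        run_end = 0.0
        for k in range(n):
            iv = ann.intervals[k]
            if bundles[k, fi] != 1:
                if run_start is not None:  # adjacent feature-negative phoneme
                    spans[feat].append((run_start, run_end))
                    run_start = None
                continue
            if run_start is None:
                run_start = iv.onset
            run_end = iv.offset
            nxt = ann.intervals[k + 1].onset if k + 1 < n else ann.total_duration
            if nxt - iv.offset > ADJACENCY_TOL_S:
                # silence follows: the run ends here; the pause is appended
                # to its duration (up to the next onset / end of file)
                if append_silence:
                    run_end = min(nxt, ann.total_duration)
                spans[feat].append((run_start, run_end))
                run_start = None
        if run_start is not None:
            spans[feat].append((run_start, run_end))
    return spans


def span_durations_ms(spans: Iterable[tuple[float, float]]) -> np.ndarray:
    """Span durations in milliseconds."""
    arr = np.asarray(list(spans), dtype=float)
    if arr.size == 0:
        return np.empty(0)
    return (arr[:, 1] - arr[:, 0]) * 1000.0
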