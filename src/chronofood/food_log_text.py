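"""Free-text food-log normalization and vocabulary consolidation.

Smartphone food logs carry short free-text annotations ("2 slices of pizza,
coke") that must be reduced to a clean vocabulary of food items before any
food-processing annotation is possible.  The pipeline applies four fixed
steps, in order: (1) split comma-separated multi-item entries; (2) strip
numbers, semi-quantitative terms and units; (3) count unique entries and
merge typo variants at Levenshtein distance one into the more frequent
spelling; (4) drop items recorded only once from annotation (their
timestamps still count as ingestion events).
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import edlib
import pandas as pd

__all__ = [
    "IngestionEvent",
    "VocabularyTable",
    "PreprocessResult",
    "split_entries",
    "normalize_item",
    "levenshtein",
    "consolidate_vocabulary",
    "preprocess_log",
    "load_stopterms",
]

_WS = re.compile(r"\s+")
_DIGITS = re.compile(r"\d+")


@dataclass(frozen=True)
class IngestionEvent:
    """One timestamped consumption record from the smartphone log."""

    participant_id: str
    timestamp: pd.Timestamp
    text: str = ""
    phase: str = "observation"

    def __post_init__(self) -> None:
        ts = pd.Timestamp(self.timestamp)
        object.__setattr__(self, "timestamp", ts)
        if self.phase not in ("observation", "intervention"):
            raise ValueError(f"unknown phase {self.phase!r}")


def load_stopterms(path: str | Path | None = None) -> frozenset[str]:
    """Load the stop-term list (units and semi-quantitative terms).

    The packaged default covers English, French and German terms such as
    "slice", "glass", "grams", "decilitres"; pass a path to override.
    """
    if path is None:
        text = resources.files("chronofood").joinpath("data/stopterms.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    terms = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().casefold()
        if line:
            terms.add(line)
    return frozenset(terms)


def split_entries(text: str) -> list[str]:
    """Split a comma-separated annotation into individual item strings."""
    if not isinstance(text, str):
        return []
    return [frag.strip() for frag in text.split(",") if frag.strip()]


def _strip_accents(s: str) -> str:
    return "".join(
        c for c in unicodedata.normalize("NFKD", s) if not unicodedata.combining(c)
    )


def normalize_item(
    text: str,
    stopterms: Iterable[str] = frozenset(),
    strip_accents: bool = True,
) -> str:
    """Normalize one item string: case-fold, drop digits and stop-terms.

    Runs of whitespace collapse to a single space and the result is trimmed;
    accent stripping (on by default) makes "café"/"cafe" comparable before
    any distance computation.
    """
    s = text.casefold()
    if strip_accents:
        s = _strip_accents(s)
    s = _DIGITS.sub(" ", s)
    stop = {t.casefold() for t in stopterms}
    tokens = [t for t in s.split() if t not in stop]
    return _WS.sub(" ", " ".join(tokens)).strip()


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (substitutions, insertions, deletions)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b)["editDistance"]


def _within_distance_one(a: str, b: str) -> bool:
    if abs(len(a) - len(b)) > 1:
        return False
    return edlib.align(a, b, k=1)["editDistance"] != -1


@dataclass
class VocabularyTable:
    """Consolidated item vocabulary: canonical entry counts plus merge map.

    ``merge_map`` sends every original entry to its canonical spelling;
    canonical entries map to themselves (fixed points of the merge).
    """

    counts: dict[str, int] = field(default_factory=dict)
    merge_map: dict[str, str] = field(default_factory=dict)

    def canonical(self, entry: str) -> str:
        return self.merge_map.get(entry, entry)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entry": orig, "canonical": canon, "count": self.counts[canon]}
            for orig, canon in sorted(self.merge_map.items())
        ]
        return pd.DataFrame(rows, columns=["entry", "canonical", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def consolidate_vocabulary(counts: Mapping[str, int]) -> VocabularyTable:
    """Merge distance-one typo variants into their more frequent spelling.

    Entries are processed once, in descending count order (ties broken
    lexicographically).  Each entry either joins an already-frozen canonical
    entry at Levenshtein distance one — the highest-count such canonical,
    which absorbs its count — or becomes canonical itself.  Canonical entries
    are never remapped afterwards, so cascades (a -> b -> c) cannot collapse
    chains of near-miss spellings into one item.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    order = sorted(counts, key=lambda e: (-counts[e], e))
    table = VocabularyTable()
    by_length: dict[int, list[str]] = {}
    for entry in order:
        candidates = [
            c
            for ln in (len(entry) - 1, len(entry), len(entry) + 1)
            for c in by_length.get(ln, ())
            if _within_distance_one(entry, c)
        ]
        if candidates:
            target = max(candidates, key=lambda c: (table.counts[c], c))
            table.counts[target] += counts[entry]
            table.merge_map[entry] = target
        else:
            table.counts[entry] = counts[entry]
            table.merge_map[entry] = entry
            by_length.setdefault(len(entry), []).append(entry)
    return table


@dataclass
class PreprocessResult:
    """Outcome of the full split/normalize/merge/filter pipeline."""

    events: pd.DataFrame
    vocabulary: VocabularyTable
    n_excluded_entries: int
    n_excluded_occurrences: int


def preprocess_log(
    events: pd.DataFrame,
    stopterms: Iterable[str] | None = None,
    min_count: int = 2,
    strip_accents: bool = True,
) -> PreprocessResult:
    """Run the full text pipeline over an event log.

    ``events`` needs columns ``participant_id``, ``timestamp`` and ``text``.
    The returned frame keeps every event (timestamps always count for
    eating-window analysis) and adds ``items`` — the canonical item list —
    and ``items_excluded`` — parallel flags marking items whose post-merge
    count fell below ``min_count`` and which are therefore withheld from
    annotation.
    """
    if stopterms is None:
        stopterms = load_stopterms()
    per_event_items: list[list[str]] = []
    counter: Counter[str] = Counter()
    for text in events["text"].fillna(""):
        items = [
            norm
            for frag in split_entries(text)
            if (norm := normalize_item(frag, stopterms, strip_accents))
        ]
        per_event_items.append(items)
        counter.update(items)

    if counter:
        vocab = consolidate_vocabulary(counter)
    else:
        vocab = VocabularyTable()

    canon_items = [[vocab.canonical(i) for i in items] for items in per_event_items]
    excluded = [
        [vocab.counts.get(i, 0) < min_count for i in items] for items in canon_items
    ]
    out = events.copy()
    out["items"] = canon_items
    out["items_excluded"] = excluded

    excl_entries = {c for c, n in vocab.counts.items() if n < min_count}
    n_excl_occ = sum(vocab.counts[c] for c in excl_entries)
    return PreprocessResult(out, vocab, len(excl_entries), n_excl_occ)
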