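"""Extended-NOVA annotation of normalized food-log entries.

The NOVA taxonomy ranks foods by processing level (NOVA1 unprocessed or
minimally processed, NOVA2 processed culinary ingredients, NOVA3 processed,
NOVA4 ultra-processed).  Drinks additionally carry multi-label flags:
A alcohol-containing, C caffeinated, S sweet, D other drinks — so a cola is
NOVA4-CS while a black tea is NOVA1-C.  Entries are labelled by exact lookup
in a curated lexicon; multi-reviewer label sets are resolved by a minimum
agreement rule, and a multi-item dish takes the highest NOVA category of its
components.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NovaLabel",
    "Lexicon",
    "load_lexicon",
    "annotate_entry",
    "consensus_labels",
    "composite_dish_category",
    "annotate_events",
    "category_proportions",
    "category_counts",
    "NOVA_ORDER",
    "DRINK_FLAGS",
]

NOVA_ORDER = ("NOVA1", "NOVA2", "NOVA3", "NOVA4")
DRINK_FLAGS = ("A", "C", "S", "D")
SPECIALS = ("water", "medication", "uninformative")


@dataclass(frozen=True)
class NovaLabel:
    """One entry's extended-NOVA assignment.

    At most one NOVA category; drink flags may overlap.  A special marker
    (water / medication / uninformative) excludes any NOVA category or flag.
    """

    nova: str = "none"
    drink_flags: frozenset[str] = frozenset()
    special: str = "none"

    def __post_init__(self) -> None:
        if self.nova not in NOVA_ORDER + ("none",):
            raise ValueError(f"invalid nova category {self.nova!r}")
        flags = frozenset(self.drink_flags)
        if not flags <= set(DRINK_FLAGS):
            raise ValueError(f"invalid drink flags {self.drink_flags!r}")
        object.__setattr__(self, "drink_flags", flags)
        if self.special not in SPECIALS + ("none",):
            raise ValueError(f"invalid special marker {self.special!r}")
        if self.special != "none" and (self.nova != "none" or flags):
            raise ValueError("special entries carry no NOVA category or drink flags")

    @property
    def is_special(self) -> bool:
        return self.special != "none"

    def abbreviation(self) -> str:
        """Compact form, e.g. 'NOVA4-CS' for an ultra-processed sweet caffeinated drink."""
        if self.is_special:
            return self.special
        flags = "".join(f for f in DRINK_FLAGS if f in self.drink_flags)
        return f"{self.nova}-{flags}" if flags else self.nova


@dataclass
class Lexicon:
    """Mapping from normalized canonical entries to their labels."""

    entries: dict[str, NovaLabel] = field(default_factory=dict)

    def __contains__(self, entry: str) -> bool:
        return entry in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, entry: str) -> NovaLabel:
        return self.entries[entry]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls.from_frame(frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Lexicon":
        entries = {}
        for row in frame.itertuples(index=False):
            nova = str(getattr(row, "nova", "") or "").strip()
            flags = str(getattr(row, "flags", "") or "").strip()
            special = str(getattr(row, "special", "") or "").strip() or "none"
            if nova in ("", "NA", "nan"):
                label = NovaLabel(special=special)
            else:
                label = NovaLabel(nova=f"NOVA{int(float(nova))}", drink_flags=frozenset(flags))
            entries[str(row.entry).strip()] = label
        return cls(entries)


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load a lexicon TSV (columns entry, nova, flags, special).

    Without a path, the packaged starter lexicon is used; it covers common
    items (coffee variants, teas, pizza, croissants, plant-based drinks,
    colas, water, medications) and is meant to be extended for real studies.
    """
    if path is not None:
        return Lexicon.from_tsv(path)
    with resources.as_file(resources.files("chronofood").joinpath("data/lexicon.tsv")) as p:
        return Lexicon.from_tsv(p)


def annotate_entry(entry: str, lexicon: Lexicon) -> NovaLabel:
    """Exact lexicon lookup; unknown entries are marked uninformative."""
    if entry in lexicon:
        return lexicon[entry]
    return NovaLabel(special="uninformative")


def consensus_labels(
    reviewer_labels: Sequence[NovaLabel], min_agree: int = 3
) -> tuple[NovaLabel, bool]:
    """Resolve independent reviewer assignments by minimum agreement.

    A NOVA category or drink flag is kept iff at least ``min_agree`` reviewers
    assigned it.  When no NOVA category (and no special marker) reaches the
    threshold the entry is returned unresolved; ties between two qualifying
    NOVA categories are likewise unresolved.
    """
    if not reviewer_labels:
        raise ValueError("at least one reviewer label is required")
    if min_agree > len(reviewer_labels):
        raise ValueError(
            f"min_agree={min_agree} exceeds the {len(reviewer_labels)} reviewers"
        )
    special_votes = Counter(l.special for l in reviewer_labels if l.is_special)
    if special_votes:
        top_special, n = special_votes.most_common(1)[0]
        if n >= min_agree:
            return NovaLabel(special=top_special), True
    nova_votes = Counter(l.nova for l in reviewer_labels if l.nova != "none")
    flags = frozenset(
        f
        for f in DRINK_FLAGS
        if sum(f in l.drink_flags for l in reviewer_labels) >= min_agree
    )
    qualifying = {cat: n for cat, n in nova_votes.items() if n >= min_agree}
    if not qualifying:
        return NovaLabel(drink_flags=flags), False
    best = max(qualifying.values())
    winners = [cat for cat, n in qualifying.items() if n == best]
    if len(winners) > 1:
        return NovaLabel(drink_flags=flags), False
    return NovaLabel(nova=winners[0], drink_flags=flags), True


def composite_dish_category(component_labels: Sequence[NovaLabel]) -> NovaLabel:
    """Label a multi-item dish by its most processed component.

    The NOVA category is the maximum over components (NOVA1 < ... < NOVA4)
    and drink flags are pooled.  Special-only component lists cannot be
    ranked and raise.
    """
    novas = [l.nova for l in component_labels if l.nova != "none"]
    if not novas:
        raise ValueError("no component carries a NOVA category")
    top = max(novas, key=NOVA_ORDER.index)
    flags = frozenset().union(*(l.drink_flags for l in component_labels if not l.is_special))
    return NovaLabel(nova=top, drink_flags=flags)


def _event_label(item_labels: Sequence[NovaLabel]) -> NovaLabel:
    """Event-level label: composite over items, specials dominated by food."""
    if any(l.nova != "none" for l in item_labels):
        return composite_dish_category(item_labels)
    specials = [l.special for l in item_labels if l.is_special]
    for marker in ("water", "medication"):
        if specials and all(s == marker for s in specials):
            return NovaLabel(special=marker)
    return NovaLabel(special="uninformative")


def annotate_events(events: pd.DataFrame, lexicon: Lexicon) -> pd.DataFrame:
    """Annotate a preprocessed event log (one output row per event).

    Expects the frame produced by :func:`chronofood.food_log_text.preprocess_log`
    (columns ``items`` and ``items_excluded``).  Items excluded from
    annotation (singletons) are skipped; events left without any annotatable
    item are marked uninformative but keep their timestamps.
    """
    out = events.copy()
    labels = []
    for items, excl in zip(out["items"], out["items_excluded"]):
        kept = [annotate_entry(i, lexicon) for i, x in zip(items, excl) if not x]
        informative = [l for l in kept if l.special != "uninformative"]
        labels.append(_event_label(informative) if informative else NovaLabel(special="uninformative"))
    out["nova"] = [l.nova for l in labels]
    out["drink_flags"] = ["".join(sorted(l.drink_flags)) for l in labels]
    out["special"] = [l.special for l in labels]
    return out


def _eligible(events: pd.DataFrame) -> pd.DataFrame:
    return events[~events["special"].isin(SPECIALS)]


def category_proportions(events: pd.DataFrame) -> pd.DataFrame:
    """Per-participant proportion of events in each NOVA category and drink flag.

    The denominator counts annotated events only — water, medication and
    uninformative entries are excluded.  NOVA proportions sum to one when
    every remaining event carries a NOVA category; drink-flag proportions
    may overlap.  Participants with zero eligible events get NaN.
    """
    cols = [f"p_{c}" for c in NOVA_ORDER] + [f"p_{f}" for f in DRINK_FLAGS]
    rows = {}
    for pid, grp in events.groupby("participant_id", sort=True):
        elig = _eligible(grp)
        n = len(elig)
        if n == 0:
            rows[pid] = {c: np.nan for c in cols}
            continue
        row = {f"p_{c}": float((elig["nova"] == c).sum()) / n for c in NOVA_ORDER}
        row.update(
            {f"p_{f}": float(elig["drink_flags"].str.contains(f).sum()) / n for f in DRINK_FLAGS}
        )
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "participant_id"
    return out


def category_counts(events: pd.DataFrame) -> pd.DataFrame:
    """Per-participant raw event counts per NOVA category and drink flag.

    These counts (not proportions) are the eating-behaviour covariates of
    the metabolic regression.
    """
    cols = [f"n_{c}" for c in NOVA_ORDER] + [f"n_{f}" for f in DRINK_FLAGS]
    rows = {}
    for pid, grp in events.groupby("participant_id", sort=True):
        elig = _eligible(grp)
        row = {f"n_{c}": int((elig["nova"] == c).sum()) for c in NOVA_ORDER}
        row.update({f"n_{f}": int(elig["drink_flags"].str.contains(f).sum()) for f in DRINK_FLAGS})
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols).fillna(0).astype(int)
    out.index.name = "participant_id"
    return out
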