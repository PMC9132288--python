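"""Corpus-based age-of-acquisition estimates from per-child first occurrences.

The corpus AoA of a word is derived from the age at which each child is first
attested producing it in a longitudinal corpus.  Because different children
attest different words, estimates are formed under a *k-child rule*: a word
enters the k-child variant only if at least ``k`` children attest it.  The
1-child variant takes the earliest attested age across children; multi-child
variants average the per-child first ages, which trades coverage (fewer words
survive the threshold) against reliability (more raters per word).

First occurrences are lower-bounded by the true acquisition age — a word can
only appear after it has been acquired — but are biased late for rare words,
which may go unsampled for many sessions after acquisition.  The frequency
adjustment for that bias lives in :mod:`aoacorpus.norms`.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chat_io import ChatSession

__all__ = [
    "FirstOccurrenceTable",
    "extract_first_occurrences",
    "kchild_aoa",
    "corpus_summary",
]

logger = logging.getLogger(__name__)

AGGREGATORS = ("min", "mean")


class FirstOccurrenceTable:
    """Per-(child, word) age in months of the earliest attested production.

    Thin wrapper around a tidy DataFrame with columns ``child_id``, ``word``,
    ``age_months`` and ``censored`` (True when the word already appears in the
    child's first session, so the true first production may predate the
    recording window).
    """

    COLUMNS = ["child_id", "word", "age_months", "censored"]

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"first-occurrence table missing columns: {missing}")
        if data.duplicated(["child_id", "word"]).any():
            raise ValueError("at most one entry per (child, word) is allowed")
        self.data = data.loc[:, self.COLUMNS].reset_index(drop=True)

    @property
    def children(self) -> list[str]:
        return sorted(self.data["child_id"].unique())

    @property
    def words(self) -> list[str]:
        return sorted(self.data["word"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def rating_matrix(self) -> pd.DataFrame:
        """Words-by-children matrix of first ages (NaN where unattested)."""
        return self.data.pivot(index="word", columns="child_id", values="age_months")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FirstOccurrenceTable":
        return cls(pd.read_csv(path))


def extract_first_occurrences(
    sessions_by_child: Mapping[str, Sequence[ChatSession]] | Iterable[ChatSession],
) -> FirstOccurrenceTable:
    """Find each child's earliest attested production age for every word.

    Accepts either a mapping ``child_id -> sessions`` or a flat iterable of
    sessions (grouped by their ``child_id`` field).  Duplicate
    (child, session_index) pairs are an error: they would make "earliest"
    ambiguous for a corrupted corpus tree.
    """
    if isinstance(sessions_by_child, Mapping):
        flat = [s for ss in sessions_by_child.values() for s in ss]
    else:
        flat = list(sessions_by_child)

    seen: set[tuple[str, int]] = set()
    for s in flat:
        key = (s.child_id, s.session_index)
        if key in seen:
            raise ValueError(f"duplicate session for child {key[0]!r}, index {key[1]}")
        seen.add(key)

    rows = []
    by_child: dict[str, list[ChatSession]] = {}
    for s in flat:
        by_child.setdefault(s.child_id, []).append(s)
    for child, sess in by_child.items():
        sess = sorted(sess, key=lambda s: s.session_index)
        first_age = min(s.child_age_months for s in sess)
        earliest: dict[str, float] = {}
        for s in sess:
            for w in s.child_word_types:
                age = s.child_age_months
                if w not in earliest or age < earliest[w]:
                    earliest[w] = age
        for w, age in earliest.items():
            rows.append((child, w, age, age <= first_age))

    df = pd.DataFrame(rows, columns=FirstOccurrenceTable.COLUMNS)
    return FirstOccurrenceTable(df.sort_values(["child_id", "word"]).reset_index(drop=True))


def kchild_aoa(
    table: FirstOccurrenceTable,
    k: int,
    aggregator: str | None = None,
) -> pd.DataFrame:
    """The k-child corpus AoA: words attested in >= k children, aggregated.

    ``aggregator`` defaults to ``"min"`` for k=1 (earliest occurrence in any
    child) and ``"mean"`` for k>=2 (mean first age over *all* attesting
    children, not just k of them).

    Returns a DataFrame with columns ``word``, ``variant``, ``n_children``,
    ``aoa_months``; empty (with a warning) when ``k`` exceeds the number of
    children in the table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) == 0:
        raise ValueError("first-occurrence table is empty")
    if aggregator is None:
        aggregator = "min" if k == 1 else "mean"
    if aggregator not in AGGREGATORS:
        raise ValueError(f"aggregator must be one of {AGGREGATORS}, got {aggregator!r}")

    n_children_total = len(table.children)
    if k > n_children_total:
        logger.warning(
            "k=%d exceeds the %d children in the table; returning an empty result",
            k, n_children_total,
        )
        return pd.DataFrame(columns=["word", "variant", "n_children", "aoa_months"])

    grouped = table.data.groupby("word")["age_months"].agg(
        n_children="size", aoa_months=aggregator
    )
    out = grouped[grouped["n_children"] >= k].reset_index()
    out.insert(1, "variant", k)
    out["aoa_months"] = out["aoa_months"].round(2)
    return out.sort_values("word").reset_index(drop=True)


def corpus_summary(table: FirstOccurrenceTable, k_list: Sequence[int]) -> pd.DataFrame:
    """Word and first-occurrence counts under each k-child threshold.

    For each k: the number of distinct words attested in >= k children, and
    the total number of (child, word) first occurrences among those words.
    """
    if len(table) == 0:
        raise ValueError("first-occurrence table is empty")
    counts = table.data.groupby("word")["child_id"].size()
    rows = []
    for k in k_list:
        kept = counts[counts >= k]
        rows.append((k, len(kept), int(kept.sum())))
    return pd.DataFrame(rows, columns=["k", "n_words", "n_first_occurrences"])
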