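"""Reliability of corpus AoA: ICC(2,k) and split-half correlation.

Children act as raters and words as rated subjects.  Internal consistency is
quantified by the intraclass correlation from a two-way random-effects model
for the *average* of k raters,

    ICC(2,k) = (BMS - EMS) / (BMS + (JMS - EMS) / n),

where BMS, JMS and EMS are the between-subject (word), between-rater (child)
and residual mean squares of the two-way ANOVA decomposition, n the number of
words and k the number of raters.  Split-half reliability randomly partitions
the children into two halves and correlates the per-word mean first ages
between halves, averaged over many seeded partitions.

The canonical ICC path requires a complete words-by-raters matrix and is
therefore computed on the complete-case submatrix (rows observed for every
rater).  An alternative path estimates the variance components on all
available cells with a crossed random-effects fit; it is non-canonical and
intended for sensitivity analyses on sparse variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .corpus_aoa import FirstOccurrenceTable

__all__ = ["ReliabilityReport", "icc2k", "icc2k_unbalanced", "split_half"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReliabilityReport:
    """Reliability summary for one k-child corpus AoA variant."""

    variant: int
    icc2k: float  # NaN when undefined for the variant
    split_half_r: float
    n_words_used: int
    n_splits: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def icc2k(matrix: pd.DataFrame) -> float:
    """ICC(2,k) of a words-by-raters matrix via the two-way ANOVA mean squares.

    Rows with any missing cell are dropped (complete-case path).  Returns NaN
    with a warning when fewer than 2 complete rows remain or the between-word
    variance is zero.
    """
    m = matrix.dropna(axis=0, how="any")
    values = np.asarray(m, dtype=float)
    n, k = values.shape
    if n < 2 or k < 2:
        logger.warning("ICC(2,k) needs >= 2 complete words and >= 2 raters; got %dx%d", n, k)
        return float("nan")

    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)

    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))

    if bms <= 0:
        logger.warning("zero between-word variance; ICC(2,k) undefined")
        return float("nan")
    return (bms - ems) / (bms + (jms - ems) / n)


def icc2k_unbalanced(matrix: pd.DataFrame) -> float:
    """Non-canonical ICC(2,k) over all available cells of a sparse matrix.

    Estimates crossed word/rater variance components by restricted maximum
    likelihood (statsmodels ``MixedLM`` with two variance components) and
    forms ICC(2,k) with k taken as the mean number of raters per word.  Slower
    and model-based; use :func:`icc2k` whenever a complete submatrix exists.
    """
    import statsmodels.formula.api as smf

    long = (
        matrix.stack().rename("value").reset_index()
        .set_axis(["word", "rater", "value"], axis=1)
    )
    if long["word"].nunique() < 2 or long["rater"].nunique() < 2:
        return float("nan")
    long["one"] = 1
    model = smf.mixedlm(
        "value ~ 1",
        data=long,
        groups="one",
        vc_formula={"word": "0 + C(word)", "rater": "0 + C(rater)"},
    )
    fit = model.fit(reml=True, method="lbfgs")
    var_word = float(fit.vcomp[fit.model.exog_vc.names.index("word")])
    var_rater = float(fit.vcomp[fit.model.exog_vc.names.index("rater")])
    var_err = float(fit.scale)
    k_mean = long.groupby("word")["rater"].size().mean()
    denom = var_word + (var_rater + var_err) / k_mean
    if denom <= 0:
        return float("nan")
    return var_word / denom


def split_half(
    table: FirstOccurrenceTable,
    min_children: int = 2,
    n_splits: int = 100,
    seed: int | None = None,
    spearman_brown: bool = False,
) -> float:
    """Split-half reliability of per-word mean first ages across children.

    Children are randomly partitioned into two halves (sizes differ by at most
    one for odd counts); within each half every word attested there gets the
    mean first age over that half's attesting children; the Pearson
    correlation over words with a value in both halves is averaged over
    ``n_splits`` seeded partitions.  Words attested by fewer than
    ``min_children`` children are excluded up front (a word needs at least two
    attestations to ever have a value in both halves).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible splits")
    children = table.children
    if len(children) < 2:
        raise ValueError("split-half reliability needs at least 2 children")

    counts = table.data.groupby("word")["child_id"].size()
    usable_words = counts[counts >= max(min_children, 2)].index
    data = table.data[table.data["word"].isin(usable_words)]
    matrix = data.pivot(index="word", columns="child_id", values="age_months")

    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_splits):
        perm = rng.permutation(len(children))
        half_a = matrix.iloc[:, perm[: len(children) // 2]]
        half_b = matrix.iloc[:, perm[len(children) // 2:]]
        mean_a = half_a.mean(axis=1)
        mean_b = half_b.mean(axis=1)
        both = mean_a.notna() & mean_b.notna()
        if both.sum() < 3:
            continue
        r = float(np.corrcoef(mean_a[both], mean_b[both])[0, 1])
        if spearman_brown:
            r = 2 * r / (1 + r)
        rs.append(r)
    if not rs:
        raise ValueError("fewer than 3 words shared between halves in every split")
    return float(np.mean(rs))
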