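"""Word norms: parent-report AoA50, rating/test/frequency/RT tables, joins.

Four independent operationalizations of a word's age of acquisition meet
here: the corpus first-occurrence estimate, adult retrospective ratings (in
years), the school-grade level at which a word is known from test data, and
the parent-report AoA50 — the age at which a logistic curve fitted to
CDI-style "does your child say this word" proportions crosses 50%.  A fifth
variable, child word frequency, drives the sampling bias of the corpus
estimate and is used to residualize it.

Units are deliberately not harmonized (years, grades, months, log counts):
every downstream analysis is correlational or standardized, hence scale-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CdiCurve",
    "AoA50Result",
    "fit_aoa50",
    "fit_aoa50_table",
    "cdi_from_wide",
    "merge_test_meanings",
    "child_log_frequency",
    "adjust_for_frequency",
    "join_norms",
]

logger = logging.getLogger(__name__)

#: School-grade levels admissible in test-based AoA norms.
TEST_GRADES = frozenset({2, 4, 6, 8, 10, 12, 13, 14})

#: Default admissible range for AoA50, in months.  Crossing points extrapolated
#: far outside the observed CDI age window come from near-flat curves and are
#: not meaningful acquisition ages.
AOA50_RANGE = (6.0, 60.0)


@dataclass(frozen=True)
class CdiCurve:
    """Per-word parent-report observations: (age, n saying it, n asked)."""

    word: str
    observations: tuple[tuple[float, int, int], ...]

    def __post_init__(self) -> None:
        ages = {a for a, _, _ in self.observations}
        if len(ages) < 2:
            raise ValueError(f"{self.word!r}: need observations at >= 2 distinct ages")
        for age, n_say, n_tot in self.observations:
            if n_tot < 1 or n_say < 0 or n_say > n_tot:
                raise ValueError(
                    f"{self.word!r}: invalid counts ({n_say}/{n_tot}) at age {age}"
                )


@dataclass(frozen=True)
class AoA50Result:
    """Fitted 50%-acquisition age for one word, with exclusion bookkeeping."""

    word: str
    aoa50_months: float  # NaN unless converged, slope > 0 and within range
    slope: float
    converged: bool
    excluded_reason: str  # none | no_convergence | non_positive_slope | out_of_range

    def to_dict(self) -> dict:
        return asdict(self)


def fit_aoa50(curve: CdiCurve, admissible_range: tuple[float, float] = AOA50_RANGE) -> AoA50Result:
    """Fit logit(p saying) = b0 + b1*age by binomial ML; AoA50 = -b0/b1.

    The crossing of the fitted curve with p = 0.5 (logit zero) is the
    estimated acquisition age.  Words whose fit fails to converge, has a
    non-positive age slope, or crosses outside ``admissible_range`` are
    excluded (AoA50 = NaN) with the reason recorded.
    """
    obs = np.array(curve.observations, dtype=float)
    ages, n_say, n_tot = obs[:, 0], obs[:, 1], obs[:, 2]
    endog = np.column_stack([n_say, n_tot - n_say])
    exog = sm.add_constant(ages)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=100)
        converged = bool(fit.converged) and np.all(np.isfinite(fit.params))
    except Exception:  # separation, singular design
        converged = False
    if not converged:
        return AoA50Result(curve.word, float("nan"), float("nan"), False, "no_convergence")

    b0, b1 = (float(p) for p in fit.params)
    if b1 <= 0:
        return AoA50Result(curve.word, float("nan"), b1, True, "non_positive_slope")
    aoa50 = -b0 / b1
    lo, hi = admissible_range
    if not lo <= aoa50 <= hi:
        return AoA50Result(curve.word, float("nan"), b1, True, "out_of_range")
    return AoA50Result(curve.word, aoa50, b1, True, "none")


def fit_aoa50_table(
    cdi_long: pd.DataFrame, admissible_range: tuple[float, float] = AOA50_RANGE
) -> pd.DataFrame:
    """Fit AoA50 for every word of a long-format CDI table.

    Expects columns ``word``, ``age_months``, ``n_saying``, ``n_total``;
    returns one row per word with the fit outcome and exclusion reason.
    """
    results = []
    for word, grp in cdi_long.groupby("word", sort=True):
        curve = CdiCurve(
            word=str(word),
            observations=tuple(
                (float(r.age_months), int(r.n_saying), int(r.n_total))
                for r in grp.itertuples()
            ),
        )
        results.append(fit_aoa50(curve, admissible_range).to_dict())
    return pd.DataFrame(results)


def cdi_from_wide(wide: pd.DataFrame) -> pd.DataFrame:
    """Reshape a Wordbank-style wide export to the long CDI format.

    Wide layout: one row per word, columns ``prop_<age>`` with the proportion
    saying at that age and ``n_<age>`` with the sample size.  Counts are
    recovered as ``round(prop * n)``.
    """
    prop_cols = {c: float(c.split("_", 1)[1]) for c in wide.columns if c.startswith("prop_")}
    rows = []
    for _, rec in wide.iterrows():
        for col, age in prop_cols.items():
            n = int(rec[f"n_{col.split('_', 1)[1]}"])
            rows.append(
                (rec["word"], age, int(round(float(rec[col]) * n)), n)
            )
    return pd.DataFrame(rows, columns=["word", "age_months", "n_saying", "n_total"])


def merge_test_meanings(entries: pd.DataFrame) -> pd.Series:
    """Collapse multi-meaning test-AoA entries to one grade per word (minimum).

    ``entries`` has columns ``word``, ``meaning``, ``grade``; the earliest
    (lowest) grade over meanings is kept, the convention for polysemous items.
    """
    bad = set(entries["grade"].unique()) - TEST_GRADES
    if bad:
        raise ValueError(f"grades outside the admissible set {sorted(TEST_GRADES)}: {sorted(bad)}")
    return entries.groupby("word")["grade"].min().rename("test_aoa_grade")


def child_log_frequency(freq: pd.DataFrame) -> pd.Series:
    """Natural log of the mean of the two child-frequency age bands.

    ``freq`` has columns ``word``, ``freq_preschool`` and ``freq_primary``
    (per-million counts for the 0-6 and 6-12 year bands).  Words whose mean
    frequency is zero get NaN (log undefined) rather than a smoothed value.
    """
    if (freq[["freq_preschool", "freq_primary"]] < 0).any().any():
        raise ValueError("negative frequencies are not allowed")
    mean_f = freq.set_index("word")[["freq_preschool", "freq_primary"]].mean(axis=1)
    with np.errstate(divide="ignore"):
        out = np.log(mean_f)
    return out.replace(-np.inf, np.nan).rename("child_log_freq")


def adjust_for_frequency(aoa: pd.Series, log_freq: pd.Series) -> pd.Series:
    """Residualize corpus AoA on child log-frequency over the full fit set.

    Removes the sampling advantage of frequent words: an OLS of AoA on
    log-frequency is fitted on *all* words with both values, and the residual
    is the frequency-adjusted AoA.  Any subset analysis must take residuals
    from this single full-set fit — refitting within subsets would reintroduce
    subset-specific frequency structure.
    """
    joint = pd.concat([aoa.rename("aoa"), log_freq.rename("lf")], axis=1).dropna()
    if len(joint) < 3:
        raise ValueError("need >= 3 complete (AoA, log-frequency) pairs")
    if np.isclose(joint["lf"].var(ddof=0), 0.0):
        raise ValueError("log-frequency has zero variance; residualization undefined")
    X = sm.add_constant(joint["lf"].to_numpy())
    fit = sm.OLS(joint["aoa"].to_numpy(), X).fit()
    resid = pd.Series(fit.resid, index=joint.index, name="adjusted_aoa")
    return resid.reindex(aoa.index)


def join_norms(sources: dict[str, pd.Series], required: list[str] | None = None) -> pd.DataFrame:
    """Case-insensitive word-keyed outer join of norm columns.

    ``sources`` maps column name -> word-indexed Series.  Words are folded to
    lower case and joined by exact string match; duplicate words within one
    source (after folding) are an error.  If ``required`` is given, rows are
    restricted to complete cases on those columns; rows missing every column
    are always dropped.
    """
    folded: dict[str, pd.Series] = {}
    for name, s in sources.items():
        s = s.copy()
        s.index = s.index.astype(str).str.lower()
        dupes = s.index[s.index.duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate words in source {name!r}: {dupes}")
        folded[name] = s.rename(name)
    table = pd.concat(folded.values(), axis=1)
    table.index.name = "word"
    table = table.dropna(how="all")
    if required:
        table = table.dropna(subset=required)
    return table
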