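"""Synthetic longitudinal-corpus worlds with known ground truth.

Emulates the study design this package analyses: a dense longitudinal corpus
(by default 12 children recorded on 36 days roughly 10-14 days apart across
the third year of life), CDI-style parent-report acquisition curves, adult
AoA ratings, child frequency norms and adult lexical decision times — all
generated from a latent truth so that every pipeline stage can be tested as
a parameter-recovery problem.

The generative model:

* each word w has a latent mean acquisition age A_w ~ lognormal
  (median 22 months, 0.25 log-units), and each child c a deviation so that
  the pair acquires w at A_cw = max(A_w + N(0, child_sd), 10 months);
* word usage rates are Zipfian: the expected token count of the rank-r word
  in one session is proportional to r^(-s), scaled to an expected session
  token budget; tokens per (child, session, word) are Poisson, and are zero
  before A_cw — so a word can never be attested before it is acquired, while
  rare words are attested *late* relative to acquisition (the frequency bias
  of first-occurrence estimates);
* parent-report curves: the probability a child of age t is reported to say
  w is logistic(slope * (t - A_w)), so the 50% crossing equals A_w;
* adult ratings are an affine image of A_w in years plus a frequency
  contamination term and Gaussian noise; lexical decision RT is linear in
  A_w (positive coefficient) and log frequency (negative coefficient) plus
  noise, matching the sign pattern such data show.

Usage rates are assigned independently of acquisition age; real lexicons
couple the two, but independence gives the cleanest attribution of any
AoA-frequency correlation in the pipeline output to the sampling mechanism
itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chat_io import ChatSession, write_chat

__all__ = [
    "WorldParams",
    "SyntheticWorld",
    "simulate_world",
    "simulate_corpus",
    "simulate_cdi",
    "simulate_ratings_freq_rt",
    "first_occurrence_delays",
    "write_world",
]

DAYS_PER_MONTH = 30.44

# substream tags so each generator is an independent pure function of (params, seed)
_TAG_WORLD, _TAG_CORPUS, _TAG_CDI, _TAG_NORMS = 1, 2, 3, 4


@dataclass(frozen=True)
class WorldParams:
    """Parameters of a synthetic world; defaults mirror the emulated study design."""

    n_children: int = 12
    n_sessions: int = 36
    session_gap_days: tuple[float, float] = (10.0, 14.0)
    age_start_months: float = 24.0
    n_words: int = 500
    aoa_median_months: float = 22.0
    aoa_log_sd: float = 0.25
    child_sd_months: float = 2.5
    child_aoa_floor_months: float = 10.0
    zipf_exponent: float = 1.0
    tokens_per_session: float = 400.0
    cdi_slope: float = 0.5  # logits per month
    rating_noise_sd: float = 0.75  # years
    rating_contamination_weight: float = 0.3  # years per unit of -log usage share
    rt_coeffs: tuple[float, float, float, float] = (600.0, 4.0, -25.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.session_gap_days
        if lo <= 0 or hi < lo:
            raise ValueError("session_gap_days must satisfy 0 < lo <= hi")
        if self.cdi_slope <= 0:
            raise ValueError("cdi_slope must be > 0")
        if self.child_sd_months < 0 or self.rating_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        _, aoa_c, freq_c, noise = self.rt_coeffs
        if aoa_c <= 0 or freq_c >= 0 or noise < 0:
            raise ValueError("rt_coeffs must have aoa_coeff > 0, freq_coeff < 0, noise_sd >= 0")


@dataclass(frozen=True)
class SyntheticWorld:
    """Latent truth for one simulated study."""

    params: WorldParams
    words: tuple[str, ...]
    true_word_aoa: np.ndarray  # (n_words,) months
    true_child_aoa: np.ndarray  # (n_children, n_words) months
    usage_share: np.ndarray  # (n_words,) Zipf probabilities, sums to 1
    session_ages: np.ndarray  # (n_children, n_sessions) months

    @property
    def children(self) -> list[str]:
        return [f"child{c:02d}" for c in range(self.params.n_children)]

    @property
    def session_rates(self) -> np.ndarray:
        """Expected Poisson token count per word in one session."""
        return self.usage_share * self.params.tokens_per_session

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": self.words,
                "true_aoa_months": self.true_word_aoa,
                "usage_share": self.usage_share,
            }
        )


def _rng(params: WorldParams, tag: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, tag])


def simulate_world(params: WorldParams) -> SyntheticWorld:
    """Draw the latent truth: acquisition ages, usage rates, schedules."""
    rng = _rng(params, _TAG_WORLD)
    words = tuple(f"w{i:04d}" for i in range(params.n_words))

    true_word_aoa = np.exp(
        rng.normal(np.log(params.aoa_median_months), params.aoa_log_sd, params.n_words)
    )
    dev = rng.normal(0.0, params.child_sd_months, (params.n_children, params.n_words)) \
        if params.child_sd_months > 0 else np.zeros((params.n_children, params.n_words))
    true_child_aoa = np.maximum(true_word_aoa[None, :] + dev, params.child_aoa_floor_months)

    ranks = rng.permutation(params.n_words) + 1  # random word <-> rank assignment
    raw = ranks.astype(float) ** (-params.zipf_exponent)
    usage_share = raw / raw.sum()

    lo, hi = params.session_gap_days
    gaps = rng.uniform(lo, hi, (params.n_children, params.n_sessions - 1)) / DAYS_PER_MONTH
    ages = np.concatenate(
        [np.zeros((params.n_children, 1)), np.cumsum(gaps, axis=1)], axis=1
    ) + params.age_start_months
    ages = np.round(ages, 2)

    return SyntheticWorld(params, words, true_word_aoa, true_child_aoa, usage_share, ages)


def simulate_corpus(world: SyntheticWorld) -> dict[str, list[ChatSession]]:
    """Simulate recording sessions: Poisson token counts for acquired words.

    A word contributes tokens to a session only once the child's true
    acquisition age has passed, so every observed first occurrence is at or
    after acquisition, with a lag that shrinks as the usage rate grows.
    """
    p = world.params
    rng = _rng(p, _TAG_CORPUS)
    rates = world.session_rates
    out: dict[str, list[ChatSession]] = {}
    for c, child in enumerate(world.children):
        sessions = []
        for s in range(p.n_sessions):
            age = float(world.session_ages[c, s])
            acquired = world.true_child_aoa[c] <= age
            counts = np.zeros(p.n_words, dtype=np.int64)
            if acquired.any():
                counts[acquired] = rng.poisson(rates[acquired])
            produced = frozenset(world.words[i] for i in np.nonzero(counts > 0)[0])
            sessions.append(
                ChatSession(
                    child_id=child,
                    session_index=s + 1,
                    child_age_months=age,
                    child_word_types=produced,
                )
            )
        out[child] = sessions
    return out


def simulate_cdi(
    world: SyntheticWorld,
    ages: np.ndarray | list[float] | None = None,
    n_per_age: int = 50,
) -> pd.DataFrame:
    """Parent-report counts: n saying each word at each age, binomial-logistic.

    The success probability at age t is logistic(cdi_slope * (t - A_w)), so
    the latent curve crosses 50% exactly at the word's true acquisition age.
    """
    p = world.params
    rng = _rng(p, _TAG_CDI)
    if ages is None:
        ages = np.arange(16.0, 31.0)
    ages = np.asarray(ages, dtype=float)
    from scipy.special import expit

    logits = p.cdi_slope * (ages[:, None] - world.true_word_aoa[None, :])
    prob = expit(logits)
    n_say = rng.binomial(n_per_age, prob)
    rows = []
    for ai, age in enumerate(ages):
        for wi, word in enumerate(world.words):
            rows.append((word, age, int(n_say[ai, wi]), n_per_age))
    return pd.DataFrame(rows, columns=["word", "age_months", "n_saying", "n_total"])


def simulate_ratings_freq_rt(
    world: SyntheticWorld,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Adult rating, child-frequency and lexical-decision tables.

    Ratings (years) are affine in true AoA, contaminated by word frequency
    (raters judge frequent words as earlier than they were learned) plus
    noise.  The frequency table reports per-million rates for two age bands
    whose mean is exactly proportional to the usage rate.  RT (ms) is linear
    in true AoA (slowing for late-acquired words) and log frequency
    (speeding for frequent words) plus noise.
    """
    p = world.params
    rng = _rng(p, _TAG_NORMS)
    neg_log_share = -np.log(world.usage_share)
    rating_years = (
        0.5
        + world.true_word_aoa / 12.0
        + p.rating_contamination_weight * (neg_log_share - neg_log_share.mean())
        + rng.normal(0.0, p.rating_noise_sd, p.n_words)
    )
    ratings = pd.DataFrame({"word": world.words, "rating_aoa_years": rating_years})

    per_million = world.usage_share * 1e6
    freq = pd.DataFrame(
        {
            "word": world.words,
            "freq_preschool": per_million * 1.2,
            "freq_primary": per_million * 0.8,
        }
    )

    intercept, aoa_c, freq_c, noise_sd = p.rt_coeffs
    rt = (
        intercept
        + aoa_c * world.true_word_aoa
        + freq_c * np.log(per_million)
        + rng.normal(0.0, noise_sd, p.n_words)
    )
    rt_table = pd.DataFrame({"word": world.words, "rt_ms": rt})
    return ratings, freq, rt_table


def first_occurrence_delays(
    world: SyntheticWorld, first_occurrences: pd.DataFrame
) -> pd.DataFrame:
    """Observed-minus-true first-occurrence lag per attested (child, word).

    Negative delays are impossible by construction (anti-precedence); the
    mean delay quantifies the sampling bias and shrinks with usage rate.
    """
    child_idx = {c: i for i, c in enumerate(world.children)}
    word_idx = {w: i for i, w in enumerate(world.words)}
    df = first_occurrences.copy()
    ci = df["child_id"].map(child_idx).to_numpy()
    wi = df["word"].map(word_idx).to_numpy()
    df["true_aoa_months"] = world.true_child_aoa[ci, wi]
    df["delay_months"] = df["age_months"] - df["true_aoa_months"]
    return df


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Serialize a world: .cha tree per child plus CSV norm tables and truth."""
    outdir = Path(outdir)
    corpus_dir = outdir / "corpus"
    for child, sessions in simulate_corpus(world).items():
        child_dir = corpus_dir / child
        child_dir.mkdir(parents=True, exist_ok=True)
        for s in sessions:
            (child_dir / f"{child}_{s.session_index:02d}.cha").write_text(
                write_chat(s), encoding="utf-8"
            )
    simulate_cdi(world).to_csv(outdir / "cdi.csv", index=False)
    ratings, freq, rt = simulate_ratings_freq_rt(world)
    ratings.to_csv(outdir / "ratings.csv", index=False)
    freq.to_csv(outdir / "freq.csv", index=False)
    rt.to_csv(outdir / "rt.csv", index=False)
    world.truth_frame().to_csv(outdir / "truth.csv", index=False)
    (outdir / "params.json").write_text(json.dumps(asdict(world.params), indent=2))
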