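"""End-to-end orchestration: extract → corpus AoA → reliability → norms → validation.

A single :class:`RunConfig` drives the whole analysis on either a directory of
CHAT transcripts plus norm CSVs, or a fully synthetic world.  Every stage
writes its artifacts under the output directory and contributes row/word
counts to a JSON run manifest, so word-set sizes after every filter leave an
auditable trail.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chat_io import read_chat_dir
from .corpus_aoa import FirstOccurrenceTable, extract_first_occurrences, kchild_aoa, corpus_summary
from .norms import adjust_for_frequency, child_log_frequency, fit_aoa50_table, join_norms
from .reliability import ReliabilityReport, icc2k, split_half
from .synthetic import WorldParams, simulate_cdi, simulate_corpus, simulate_ratings_freq_rt, simulate_world
from .validation import correlation_matrix, cross_validate, standardized_regression

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    seed: int
    out_dir: str
    chat_dir: str | None = None  # mutually exclusive with synthetic
    synthetic: dict | None = None  # WorldParams overrides
    ratings_csv: str | None = None
    freq_csv: str | None = None
    rt_csv: str | None = None
    cdi_csv: str | None = None
    test_csv: str | None = None
    target_speaker: str = "CHI"
    k_thresholds: tuple[int, ...] = (1, 6, 12)
    correlation_method: str = "pearson"
    rt_outcome: str = "rt_ms"
    cv_folds: int = 5
    cv_repeats: int = 4
    n_splits: int = 100

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        ks = tuple(self.k_thresholds)
        if list(ks) != sorted(ks):
            raise ValueError("k_thresholds must be sorted ascending")
        self.k_thresholds = ks
        if (self.chat_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of chat_dir / synthetic must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _load_tables(config: RunConfig):
    """Load or simulate the sessions and norm tables."""
    if config.synthetic is not None:
        params = WorldParams(**{**config.synthetic, "seed": config.seed})
        world = simulate_world(params)
        sessions = simulate_corpus(world)
        cdi = simulate_cdi(world)
        ratings, freq, rt = simulate_ratings_freq_rt(world)
        test = None
        return sessions, cdi, ratings, freq, rt, test
    sessions = read_chat_dir(config.chat_dir, config.target_speaker)
    read = lambda p: pd.read_csv(p) if p else None
    return (
        sessions,
        read(config.cdi_csv),
        read(config.ratings_csv),
        read(config.freq_csv),
        read(config.rt_csv),
        read(config.test_csv),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write artifacts plus a JSON manifest.

    Returns the manifest.  Any stage failure raises :class:`PipelineError`
    with the stage name; artifacts written before the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "counts": {},
        "warnings": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ------------------------------------------------------------ extraction
    name = stage("extract")
    try:
        sessions, cdi, ratings, freq, rt, test = _load_tables(config)
        table = extract_first_occurrences(sessions)
        table.to_csv(out / "first_occurrences.csv")
        manifest["counts"]["children"] = len(table.children)
        manifest["counts"]["first_occurrences"] = len(table)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(name, str(e)) from e

    # ------------------------------------------------------------ corpus AoA
    name = stage("aoa")
    try:
        summary = corpus_summary(table, config.k_thresholds)
        summary.to_csv(out / "corpus_summary.csv", index=False)
        aoa_by_k: dict[int, pd.DataFrame] = {}
        for k in config.k_thresholds:
            est = kchild_aoa(table, k)
            est.to_csv(out / f"corpus_aoa_k{k}.csv", index=False)
            aoa_by_k[k] = est
            manifest["counts"][f"words_k{k}"] = len(est)
    except Exception as e:
        raise PipelineError(name, str(e)) from e

    # ------------------------------------------------------------ reliability
    name = stage("reliability")
    try:
        reports = []
        matrix = table.rating_matrix()
        for k in config.k_thresholds:
            words_k = aoa_by_k[k]["word"]
            sub = matrix.loc[matrix.index.intersection(words_k)]
            icc = icc2k(sub) if k >= 2 else float("nan")
            shr = split_half(
                table, min_children=max(k, 2), n_splits=config.n_splits, seed=config.seed
            )
            n_used = int(sub.dropna().shape[0]) if k >= 2 else int(len(words_k))
            reports.append(
                ReliabilityReport(k, icc, shr, n_used, config.n_splits, config.seed).to_dict()
            )
        with open(out / "reliability.json", "w", encoding="utf-8") as fh:
            json.dump(reports, fh, indent=2)
        manifest["reliability"] = reports
    except Exception as e:
        raise PipelineError(name, str(e)) from e

    # ------------------------------------------------------------ norms
    name = stage("norms")
    try:
        sources: dict[str, pd.Series] = {}
        if ratings is not None:
            sources["rating_aoa_years"] = ratings.set_index("word")["rating_aoa_years"]
        if freq is not None:
            sources["child_log_freq"] = child_log_frequency(freq)
        if rt is not None:
            sources["rt_ms"] = rt.set_index("word")["rt_ms"]
        if test is not None:
            from .norms import merge_test_meanings

            sources["test_aoa_grade"] = merge_test_meanings(test)
        if cdi is not None:
            aoa50 = fit_aoa50_table(cdi)
            aoa50.to_csv(out / "aoa50.csv", index=False)
            manifest["counts"]["aoa50_fitted"] = int(aoa50["aoa50_months"].notna().sum())
            sources["parent_aoa50_months"] = aoa50.set_index("word")["aoa50_months"]
        for k in config.k_thresholds:
            sources[f"corpus_aoa_k{k}"] = aoa_by_k[k].set_index("word")["aoa_months"]
        norm_table = join_norms(sources)
        # frequency adjustment: one full-set fit per corpus variant
        if "child_log_freq" in norm_table:
            for k in config.k_thresholds:
                norm_table[f"adjusted_corpus_aoa_k{k}"] = adjust_for_frequency(
                    norm_table[f"corpus_aoa_k{k}"], norm_table["child_log_freq"]
                )
        norm_table.to_csv(out / "word_norms.csv")
        manifest["counts"]["norm_table_rows"] = len(norm_table)
    except Exception as e:
        raise PipelineError(name, str(e)) from e

    # ------------------------------------------------------------ validation
    name = stage("validation")
    try:
        validation: dict = {"correlations": {}, "regressions": {}}
        for k in config.k_thresholds:
            variables = [
                v
                for v in (
                    "rating_aoa_years",
                    f"corpus_aoa_k{k}",
                    f"adjusted_corpus_aoa_k{k}",
                    "parent_aoa50_months",
                    "test_aoa_grade",
                    "child_log_freq",
                )
                if v in norm_table.columns
            ]
            try:
                cm = correlation_matrix(norm_table, variables, config.correlation_method)
                cm.r.to_csv(out / f"correlations_k{k}.csv")
                validation["correlations"][f"k{k}"] = cm.to_json_dict()
            except ValueError as e:
                manifest["warnings"].append(f"correlations k={k}: {e}")

            if config.rt_outcome not in norm_table.columns:
                continue
            base = [v for v in ("rating_aoa_years", "test_aoa_grade", "child_log_freq")
                    if v in norm_table.columns]
            models = {
                "rt_unadjusted": [f"corpus_aoa_k{k}"] + base,
                "rt_adjusted": [f"adjusted_corpus_aoa_k{k}"] + base,
            }
            if "parent_aoa50_months" in norm_table.columns:
                models["rt_with_parent_report"] = (
                    [f"corpus_aoa_k{k}", "parent_aoa50_months"] + base
                )
            for label, preds in models.items():
                preds = [p for p in preds if p in norm_table.columns]
                try:
                    res = standardized_regression(norm_table, config.rt_outcome, preds)
                    rmse = cross_validate(
                        norm_table, config.rt_outcome, preds,
                        folds=config.cv_folds, repeats=config.cv_repeats, seed=config.seed,
                    )
                    d = res.to_json_dict()
                    d["cv_rmse"] = rmse
                    validation["regressions"][f"k{k}_{label}"] = d
                except ValueError as e:
                    manifest["warnings"].append(f"regression k={k} {label}: {e}")
        with open(out / "validation.json", "w", encoding="utf-8") as fh:
            json.dump(validation, fh, indent=2)
        manifest["validation"] = validation
    except Exception as e:
        raise PipelineError(name, str(e)) from e

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
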