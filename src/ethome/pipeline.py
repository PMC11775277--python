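"""End-to-end orchestration: simulate → features → train → classify → stats.

A :class:`RunConfig` fully determines a run; one global seed is fanned out
to per-stage child seeds through ``numpy.random.SeedSequence``, so a run
is deterministic and its CSV outputs byte-identical across repeats.  The
configuration is serialized into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, stats
from .features import compute_frame_features
from .io import StimulusProtocol, TrackSet, write_track_table
from .synth import (
    NoiseParams,
    PopulationConfig,
    default_protocol,
    simulate_population,
    truth_to_frame,
)

__all__ = [
    "RunConfig",
    "run_experiment",
    "StageError",
    "compute_series",
    "recovery_experiment",
    "REFINED_TARGET_CLASSES",
]

#: the five classes produced by the two-layer refinement
REFINED_TARGET_CLASSES = ["HeadCast", "StaticBend", "Hunch", "HeadAndTail", "CShape"]

_FLOAT_FMT = "%.10g"

ACTIONS_REPORTED = [
    "Crawl",
    "HeadCast",
    "StaticBend",
    "Hunch",
    "HeadAndTail",
    "CShape",
    "Roll",
    "BackUp",
    "Stop",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "ethome_run"
    n_larvae_train: int = 60
    n_larvae_test: int = 60
    noise_point_jitter_mm: float = 0.01
    noise_heading_drift_sd: float = 0.0
    dropout: float = 0.1
    total_s: float = 100.0
    frame_rate: float = 10.0
    base_mode: str = "passthrough"  # or "rules"
    layer1_classes: int = 3
    n_estimators: int = 300
    min_per_class: int = 20
    windows_preset: list[str] = field(default_factory=lambda: ["first_1s", "first_3s", "first_5s"])
    transition_window_s: float = 3.0
    ethogram_bin_s: float = 0.5
    write_tracks: bool = True
    protocol: StimulusProtocol | None = None

    def validate(self) -> None:
        if self.n_larvae_train <= 0 or self.n_larvae_test <= 0:
            raise ValueError("n_larvae must be positive")
        if self.total_s <= 0 or self.frame_rate <= 0:
            raise ValueError("total_s and frame_rate must be positive")
        for w in self.windows_preset:
            if w not in stats.WINDOW_PRESETS:
                raise ValueError(f"unknown window preset {w!r}")
        if self.base_mode not in ("passthrough", "rules"):
            raise ValueError("base_mode must be 'passthrough' or 'rules'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = (self.protocol or default_protocol()).to_dict()
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        proto = d.pop("protocol", None)
        cfg = cls(**d)
        if proto is not None:
            cfg.protocol = StimulusProtocol.from_dict(proto)
        return cfg


def _child_seeds(seed: int, n: int) -> list[int]:
    """Per-stage child seeds below 2**31, derived from one global seed."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def compute_series(trackset: TrackSet) -> dict[str, pd.DataFrame]:
    """Per-frame feature tables keyed by larva id."""
    return {tr.larva_id: compute_frame_features(tr) for tr in trackset.tracks}


def coarse_from_truth(truth: pd.DataFrame) -> list[classify.ActionInterval]:
    """Pass-through coarse intervals derived from generator ground truth."""
    out = []
    for row in truth.itertuples(index=False):
        out.append(
            classify.ActionInterval(
                larva_id=row.larva_id,
                start=float(row.start),
                end=float(row.end),
                coarse_label=classify.coarsen_label(row.label),
            )
        )
    return out


def _population_config(cfg: RunConfig, n: int, seed: int) -> PopulationConfig:
    return PopulationConfig(
        n_larvae=n,
        noise=NoiseParams(
            point_jitter_mm=cfg.noise_point_jitter_mm,
            heading_drift_sd=cfg.noise_heading_drift_sd,
        ),
        dropout=cfg.dropout,
        total_s=cfg.total_s,
        frame_rate=cfg.frame_rate,
        seed=seed,
    )


def _training_set(cfg, trackset, truth_df, series, protocol, seed):
    coarse = coarse_from_truth(truth_df)
    by_larva: dict[str, list] = {}
    for iv in coarse:
        by_larva.setdefault(iv.larva_id, []).append(iv)
    tagged = classify.auto_tag_training(
        coarse, series, protocol, seed=seed, truth=truth_df
    )
    examples = []
    from .features import aggregate_action_features

    seen = set()
    for iv, lab in tagged:
        key = (iv.larva_id, iv.start, iv.end, lab)
        if key in seen:
            continue
        seen.add(key)
        examples.append((aggregate_action_features(series[iv.larva_id], iv), lab))
    return examples


def recovery_experiment(
    seed: int,
    n_train: int = 60,
    n_test: int = 200,
    noise_jitter_mm: float = 0.0,
    total_s: float = 100.0,
    protocol: StimulusProtocol | None = None,
    n_estimators: int = 300,
) -> dict:
    """Label-recovery experiment: train the refinement on one synthetic
    population and score it on a seed-disjoint one.

    Returns per-class recall and macro-F1 restricted to the five refined
    classes the two-layer ensemble produces, plus the full evaluation.
    """
    protocol = protocol or default_protocol()
    seeds = _child_seeds(seed, 4)
    noise = NoiseParams(point_jitter_mm=noise_jitter_mm)
    train_ts, train_truth = simulate_population(
        PopulationConfig(n_larvae=n_train, noise=noise, total_s=total_s, seed=seeds[0]),
        protocol,
    )
    test_ts, test_truth = simulate_population(
        PopulationConfig(n_larvae=n_test, noise=noise, total_s=total_s, seed=seeds[1]),
        protocol,
    )
    train_truth_df = truth_to_frame(train_truth)
    test_truth_df = truth_to_frame(test_truth)
    train_series = compute_series(train_ts)
    test_series = compute_series(test_ts)

    from .features import aggregate_action_features

    coarse_train = coarse_from_truth(train_truth_df)
    tagged = classify.auto_tag_training(
        coarse_train, train_series, protocol, seed=seeds[2], truth=train_truth_df
    )
    examples = [
        (aggregate_action_features(train_series[iv.larva_id], iv), lab)
        for iv, lab in tagged
    ]
    model = classify.train_refinement(
        examples, hyperparams={"n_estimators": n_estimators}, seed=seeds[3]
    )
    refined = classify.refine(coarse_from_truth(test_truth_df), test_series, model)
    full = classify.evaluate(refined, test_truth_df)
    recall = {c: float(full["recall"][c]) for c in REFINED_TARGET_CLASSES}
    f1 = [full["f1"][c] for c in REFINED_TARGET_CLASSES]
    return {
        "recall": recall,
        "macro_f1": float(np.mean(f1)),
        "min_recall": float(min(recall.values())),
        "n_test_intervals": sum(
            1 for iv in refined if iv.coarse_label in ("Bend", "Hunch")
        ),
        "evaluation": full,
        "model": model,
        "refined": refined,
        "test_trackset": test_ts,
        "test_truth": test_truth_df,
        "test_series": test_series,
    }


def run_experiment(config: RunConfig) -> dict:
    """Run the full pipeline; returns a result bundle and writes the report
    directory.  Any stage failure raises :class:`StageError` naming the
    stage, with partial outputs preserved on disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = config.protocol or default_protocol()
    seeds = _child_seeds(config.seed, 5)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    stage = "simulate"
    try:
        train_ts, train_truth = simulate_population(
            _population_config(config, config.n_larvae_train, seeds[0]), protocol
        )
        test_ts, test_truth = simulate_population(
            _population_config(config, config.n_larvae_test, seeds[1]), protocol
        )
        train_truth_df = truth_to_frame(train_truth)
        test_truth_df = truth_to_frame(test_truth)
        log(f"simulate: {len(train_ts)} train + {len(test_ts)} test larvae, "
            f"{config.total_s} s at {config.frame_rate} Hz")
        if config.write_tracks:
            write_track_table(test_ts, out / "tracks.tsv")
        test_truth_df.to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FMT)

        stage = "features"
        train_series = compute_series(train_ts)
        test_series = compute_series(test_ts)
        log(f"features: {sum(len(s) for s in test_series.values())} test frames")

        stage = "base_classify"
        if config.base_mode == "passthrough":
            test_coarse = coarse_from_truth(test_truth_df)
        else:
            test_coarse = []
            for tr in test_ts.tracks:
                test_coarse += classify.base_classify(
                    test_series[tr.larva_id], tr.larva_id, mode="rules"
                )
        log(f"base_classify({config.base_mode}): {len(test_coarse)} coarse intervals")

        stage = "train"
        examples = _training_set(
            config, train_ts, train_truth_df, train_series, protocol, seeds[2]
        )
        model = classify.train_refinement(
            examples,
            hyperparams={"n_estimators": config.n_estimators},
            seed=seeds[3],
            layer1_classes=config.layer1_classes,
            min_per_class=config.min_per_class,
        )
        log(f"train: {len(examples)} labeled actions, "
            f"classes {sorted(model.class_counts)}")

        stage = "classify"
        refined = classify.refine(test_coarse, test_series, model)
        classify.intervals_to_frame(refined).to_csv(
            out / "intervals.csv", index=False, float_format=_FLOAT_FMT
        )
        metrics = classify.evaluate(refined, test_truth_df, frame_rate=config.frame_rate)
        log(f"classify: {len(refined)} refined intervals, "
            f"macro-F1 {metrics['macro_f1']:.3f}")

        stage = "stats"
        etho = stats.build_ethogram(refined, test_ts, bin_s=config.ethogram_bin_s)
        etho.to_long().to_csv(out / "ethogram.csv", index=False, float_format=_FLOAT_FMT)

        onset = protocol.onset
        cum_rows = []
        pvals, pv_meta = [], []
        for preset in config.windows_preset:
            w0, w1 = stats.WINDOW_PRESETS[preset]
            window = (onset + w0, onset + w1)
            base_window = (onset - (w1 - w0), onset)
            for action in ACTIONS_REPORTED:
                p, n = stats.cumulative_probability(refined, test_ts, action, window)
                pb, nb = stats.cumulative_probability(refined, test_ts, action, base_window)
                cum_rows.append((preset, action, p, n, pb, nb))
                table = [
                    [round(p * n), n - round(p * n)],
                    [round(pb * nb), nb - round(pb * nb)],
                ]
                if min(sum(r) for r in table) > 0 and min(sum(c) for c in zip(*table)) > 0:
                    chi2, df, pval = stats.chi2_compare(table)
                    pvals.append(pval)
                    pv_meta.append((preset, action, chi2, df))
        cum_df = pd.DataFrame(
            cum_rows,
            columns=["window", "action", "p_stim", "n_stim", "p_baseline", "n_baseline"],
        )
        cum_df.to_csv(out / "cumulative.csv", index=False, float_format=_FLOAT_FMT)
        if pvals:
            p_adj, reject = stats.bh_adjust(pvals)
            tests_df = pd.DataFrame(
                [
                    (*meta, raw, adj, rej)
                    for meta, raw, adj, rej in zip(pv_meta, pvals, p_adj, reject)
                ],
                columns=["window", "action", "chi2", "df", "p_raw", "p_fdr", "significant"],
            )
            tests_df.to_csv(out / "tests.csv", index=False, float_format=_FLOAT_FMT)

        tm = stats.transition_matrix(
            refined, window=(onset, onset + config.transition_window_s)
        )
        tm.counts.to_csv(out / "transitions_counts.csv", float_format=_FLOAT_FMT)
        tm.probabilities.to_csv(out / "transitions_probs.csv", float_format=_FLOAT_FMT)

        try:
            speed = stats.crawl_speed_comparison(
                test_ts,
                refined,
                window_before=(0.0, onset),
                window_during=(onset, onset + 30.0),
                series_by_larva=test_series,
            )
            speed_summary = {
                "ks_D": speed["ks_D"],
                "ks_p": speed["ks_p"],
                "mean_before": speed["mean_before"],
                "mean_during": speed["mean_during"],
            }
        except ValueError:
            speed_summary = None
        log("stats: cumulative probabilities, transitions, chi2+BH, crawl speed")

        bundle = {
            "metrics": {
                "macro_f1": metrics["macro_f1"],
                "recall": metrics["recall"],
                "precision": metrics["precision"],
            },
            "crawl_speed": speed_summary,
            "n_refined_intervals": len(refined),
            "holdout_report": model.holdout_report,
        }
        (out / "metrics.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        bundle["out_dir"] = str(out)
        bundle["refined"] = refined
        bundle["model"] = model
        bundle["test_trackset"] = test_ts
        bundle["test_truth"] = test_truth_df
        return bundle
    except StageError:
        raise
    except Exception as exc:
        (out / "log.txt").write_text("\n".join(log_lines + [f"FAILED at stage {stage}: {exc}"]) + "\n")
        raise StageError(stage, exc) from exc
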