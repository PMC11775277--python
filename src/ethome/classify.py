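"""Hierarchical action-refinement classification.

A pluggable coarse base layer tiles each track with the legacy vocabulary
{Crawl, Bend, Hunch, Back, Stop, Roll}; a two-layer random-forest
refinement then recasts every coarse Bend/Hunch interval into the refined
vocabulary.  Layer 1 separates coarse Bends/Hunches into {newHunch,
StaticBend, HeadCast}; layer 2 splits the new Hunches into {Hunch,
HeadAndTail, CShape}.  (A ``layer1_classes=4`` option adds CShape as a
layer-1 output for the alternative reading in which Bends can map directly
to C-shapes.)  Coarse labels other than Bend/Hunch pass through unchanged:
Crawl→Crawl, Back→BackUp, Stop→Stop, Roll→Roll.

Training labels come from the auto-tagging rules (Head Cast sampled from
pre-stimulus Bends; Static Bend from the during-stimulus low-motion rule)
plus ground-truth tags for Hunch/Head-and-Tail/C-shape supplied by the
synthetic generator, standing in for manual annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .features import aggregate_action_features, feature_schema, vector_from_aggregate
from .io import StimulusProtocol

__all__ = [
    "COARSE_LABELS",
    "REFINED_LABELS",
    "ActionInterval",
    "RefinementModel",
    "coarsen_label",
    "base_classify",
    "auto_tag_training",
    "train_refinement",
    "refine",
    "evaluate",
    "save_model",
    "load_model",
    "intervals_to_frame",
    "intervals_from_frame",
]

COARSE_LABELS = ["Crawl", "Bend", "Hunch", "Back", "Stop", "Roll"]
REFINED_LABELS = [
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

_COARSE_OF_REFINED = {
    "Crawl": "Crawl",
    "FastCrawl": "Crawl",
    "HeadCast": "Bend",
    "StaticBend": "Bend",
    "CShape": "Bend",
    "Hunch": "Hunch",
    "HeadAndTail": "Hunch",
    "Roll": "Roll",
    "BackUp": "Back",
    "Stop": "Stop",
}
_PASSTHROUGH = {"Crawl": "Crawl", "Back": "BackUp", "Stop": "Stop", "Roll": "Roll"}


def coarsen_label(refined: str) -> str:
    """Map a refined (or generator) label onto the legacy coarse vocabulary."""
    try:
        return _COARSE_OF_REFINED[refined]
    except KeyError:
        raise ValueError(f"unknown refined label {refined!r}") from None


@dataclass
class ActionInterval:
    """A contiguous behavioral span ``[start, end)`` for one larva."""

    larva_id: str
    start: float
    end: float
    coarse_label: str
    refined_label: str | None = None
    headcast_subtype: str = "none"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")
        if self.coarse_label not in COARSE_LABELS:
            raise ValueError(f"unknown coarse label {self.coarse_label!r}")

    @property
    def label(self) -> str:
        return self.refined_label or self.coarse_label


def _check_exclusive(intervals: list[ActionInterval]) -> None:
    by_larva: dict[str, list[ActionInterval]] = {}
    for iv in intervals:
        by_larva.setdefault(iv.larva_id, []).append(iv)
    for larva, ivs in by_larva.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"overlapping intervals for {larva} at t={b.start}")


def intervals_to_frame(intervals: list[ActionInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (iv.larva_id, iv.start, iv.end, iv.coarse_label, iv.label, iv.headcast_subtype)
            for iv in intervals
        ],
        columns=["larva_id", "start", "end", "coarse", "refined", "subtype"],
    )


def intervals_from_frame(df: pd.DataFrame) -> list[ActionInterval]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ActionInterval(
                larva_id=row.larva_id,
                start=float(row.start),
                end=float(row.end),
                coarse_label=row.coarse,
                refined_label=None if pd.isna(row.refined) else row.refined,
                headcast_subtype=getattr(row, "subtype", "none"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# base layer


def _frame_coarse_rules(series: pd.DataFrame, config: dict) -> np.ndarray:
    """Stand-in per-frame coarse labeling from threshold rules on the
    minimal feature set (speeds, bend angle, length-change rate)."""
    stop_speed = config.get("stop_speed", 0.02)
    bend_deg = config.get("bend_deg", 30.0)
    hunch_dlen = config.get("hunch_dlen", -0.3)
    roll_motion = config.get("roll_motion", 0.15)
    roll_bend = config.get("roll_bend", 45.0)
    back_speed = config.get("back_speed", 0.02)

    v_motion = series["v_motion"].to_numpy()
    v_head = series["v_head"].to_numpy()
    v_tail = series["v_tail"].to_numpy()
    bend = series["bend_deg"].to_numpy()
    dlen = series["dlen"].to_numpy()
    v_forward = series["v_forward"].to_numpy()

    labels = np.full(len(series), "Crawl", dtype=object)
    is_bend = bend > bend_deg
    labels[is_bend] = "Bend"
    labels[(bend > roll_bend) & (v_motion > roll_motion)] = "Roll"
    labels[dlen < hunch_dlen] = "Hunch"
    # rearward motion: CoM travels tail-ward while the body is straight
    labels[(v_forward < -back_speed) & (bend < bend_deg) & (dlen > hunch_dlen)] = "Back"
    still = (v_motion < stop_speed) & (v_head < stop_speed) & (v_tail < stop_speed)
    labels[still & (bend < bend_deg)] = "Stop"
    labels[still & (bend >= bend_deg)] = "Bend"
    labels[~series["valid"].to_numpy()] = ""
    return labels


def base_classify(
    series: pd.DataFrame,
    larva_id: str,
    config: dict | None = None,
    mode: str = "rules",
    coarse_intervals: list[ActionInterval] | None = None,
    min_duration: float = 0.3,
) -> list[ActionInterval]:
    """Coarse base layer: threshold rules or externally supplied labels.

    ``mode="passthrough"`` returns ``coarse_intervals`` unchanged (the hook
    for precomputed coarse labels from an upstream pipeline); ``"rules"``
    tiles the track's valid span from the stand-in per-frame rules, merging
    runs and absorbing runs shorter than ``min_duration`` into their left
    neighbor.
    """
    if mode == "passthrough":
        if coarse_intervals is None:
            raise ValueError("passthrough mode requires coarse_intervals")
        return list(coarse_intervals)
    config = config or {}
    labels = _frame_coarse_rules(series, config)
    t = series["t"].to_numpy()
    dt = np.median(np.diff(t)) if len(t) > 1 else 0.1
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i]:
            runs.append((i, j, labels[i]))
        i = j
    # absorb short runs into the previous run
    merged: list[list] = []
    for s, e, lab in runs:
        if merged and (e - s) * dt < min_duration and merged[-1][1] == s:
            merged[-1][1] = e
        elif merged and merged[-1][2] == lab and merged[-1][1] == s:
            merged[-1][1] = e
        else:
            merged.append([s, e, lab])
    out = []
    for s, e, lab in merged:
        end = t[e - 1] + dt if e == n else t[e]
        out.append(ActionInterval(larva_id, float(t[s]), float(end), lab))
    return out


# ---------------------------------------------------------------------------
# auto-tagging of training data


def auto_tag_training(
    intervals: list[ActionInterval],
    series_by_larva: dict[str, pd.DataFrame],
    protocol: StimulusProtocol,
    seed: int = 0,
    truth: pd.DataFrame | None = None,
    n_headcast: int | None = None,
    speed_threshold: float = 0.02,
    frame_fraction: float = 0.5,
) -> list[tuple[ActionInterval, str]]:
    """Provisional training labels from the auto-tagging rules.

    * Head Cast: sampled randomly (``n_headcast``, default all) from coarse
      Bends that end before the first stimulus onset.
    * Static Bend: coarse Bends during stimulation whose length-normalized
      motion speed is below ``speed_threshold`` (0.02 s⁻¹) on at least
      ``frame_fraction`` of the action's frames — a deliberately low
      threshold so erroneous tags do not steer the ensembles.
    * Hunch / Head-and-Tail / C-shape: looked up in ``truth`` (generator
      ground truth standing in for manual tags), majority-overlap rule.
    """
    rng = np.random.default_rng(seed)
    onset = protocol.onset
    labeled: list[tuple[ActionInterval, str]] = []

    # manually tagged classes (here: generator truth) take precedence; the
    # auto-tag rules only apply to intervals without such a tag
    manual = {"Hunch", "HeadAndTail", "CShape"}
    manual_keys: set[tuple] = set()
    if truth is not None:
        for iv in intervals:
            if iv.coarse_label not in ("Bend", "Hunch"):
                continue
            lab = _majority_truth_label(iv, truth)
            if lab in manual:
                labeled.append((iv, lab))
                manual_keys.add((iv.larva_id, iv.start, iv.end))

    prestim_bends = [
        iv
        for iv in intervals
        if iv.coarse_label == "Bend"
        and iv.end <= onset
        and (iv.larva_id, iv.start, iv.end) not in manual_keys
    ]
    if not prestim_bends:
        warnings.warn("no pre-stimulus Bends available for Head Cast tagging")
    chosen = prestim_bends
    if n_headcast is not None and n_headcast < len(prestim_bends):
        pick = rng.choice(len(prestim_bends), size=n_headcast, replace=False)
        chosen = [prestim_bends[i] for i in sorted(pick)]
    labeled += [(iv, "HeadCast") for iv in chosen]

    in_stim = protocol.in_stimulus
    for iv in intervals:
        if iv.coarse_label != "Bend":
            continue
        if (iv.larva_id, iv.start, iv.end) in manual_keys:
            continue
        mid = 0.5 * (iv.start + iv.end)
        if not bool(in_stim(mid)):
            continue
        series = series_by_larva[iv.larva_id]
        t = series["t"].to_numpy()
        sel = (t >= iv.start) & (t < iv.end)
        v = series["v_motion"].to_numpy()[sel]
        v = v[np.isfinite(v)]
        if len(v) and np.mean(v < speed_threshold) >= frame_fraction:
            labeled.append((iv, "StaticBend"))
    return labeled


def _majority_truth_label(iv: ActionInterval, truth: pd.DataFrame) -> str | None:
    sub = truth[truth["larva_id"] == iv.larva_id]
    best, best_ov = None, 0.0
    for row in sub.itertuples(index=False):
        ov = min(iv.end, row.end) - max(iv.start, row.start)
        if ov > best_ov:
            best, best_ov = row.label, ov
    return best


# ---------------------------------------------------------------------------
# refinement model


@dataclass
class RefinementModel:
    """Two trained random-forest layers plus their feature schema."""

    layer1: RandomForestClassifier
    layer2: RandomForestClassifier
    schema: list[str]
    seed: int
    layer1_classes: int = 3
    class_counts: dict[str, int] = field(default_factory=dict)
    holdout_report: dict = field(default_factory=dict)


_LAYER1_OF_REFINED_3 = {
    "HeadCast": "HeadCast",
    "StaticBend": "StaticBend",
    "Hunch": "newHunch",
    "HeadAndTail": "newHunch",
    "CShape": "newHunch",
}
_LAYER1_OF_REFINED_4 = {**_LAYER1_OF_REFINED_3, "CShape": "CShape"}


def _default_forest(seed: int, hyper: dict) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=hyper.get("n_estimators", 300),
        max_depth=hyper.get("max_depth", None),
        max_features=hyper.get("max_features", "sqrt"),
        random_state=seed,
        n_jobs=1,
    )


def train_refinement(
    training: list[tuple[dict, str]],
    hyperparams: dict | None = None,
    seed: int = 0,
    layer1_classes: int = 3,
    min_per_class: int = 20,
    holdout_fraction: float = 0.25,
) -> RefinementModel:
    """Fit the two refinement layers from (feature-aggregate, label) pairs.

    Labels must cover all five refined classes {HeadCast, StaticBend,
    Hunch, HeadAndTail, CShape}; a missing or under-represented class is an
    error naming it.  A held-out fraction is scored per class and stored in
    ``holdout_report``.
    """
    hyper = hyperparams or {}
    schema = feature_schema()
    labels = [lab for _, lab in training]
    counts = pd.Series(labels).value_counts().to_dict()
    required = {"HeadCast", "StaticBend", "Hunch", "HeadAndTail", "CShape"}
    missing = sorted(required - set(counts))
    if missing:
        raise ValueError(f"missing training classes: {missing}")
    thin = sorted(c for c in required if counts.get(c, 0) < min_per_class)
    if thin:
        raise ValueError(
            f"classes below min_per_class={min_per_class}: "
            + ", ".join(f"{c} ({counts[c]})" for c in thin)
        )

    X = np.stack([vector_from_aggregate(agg, schema) for agg, _ in training])
    y = np.array(labels)
    rng = np.random.default_rng(seed)
    n = len(y)
    holdout = np.zeros(n, dtype=bool)
    if holdout_fraction > 0:
        k = int(round(holdout_fraction * n))
        holdout[rng.choice(n, size=k, replace=False)] = True
        for cls in required:  # keep every class represented in the training split
            if not np.any((y == cls) & ~holdout):
                holdout[np.where(y == cls)[0][0]] = False

    l1_map = _LAYER1_OF_REFINED_4 if layer1_classes == 4 else _LAYER1_OF_REFINED_3
    y1 = np.array([l1_map[lab] for lab in y])
    tr = ~holdout
    layer1 = _default_forest(seed, hyper).fit(X[tr], y1[tr])
    new_hunch = np.array([l1_map[lab] == "newHunch" for lab in y])
    sel2 = new_hunch & tr
    layer2 = _default_forest(seed + 1, hyper).fit(X[sel2], y[sel2])

    model = RefinementModel(
        layer1=layer1,
        layer2=layer2,
        schema=schema,
        seed=seed,
        layer1_classes=layer1_classes,
        class_counts=counts,
    )
    if np.any(holdout):
        pred = _predict_refined(model, X[holdout])
        p, r, f, _ = precision_recall_fscore_support(
            y[holdout], pred, labels=sorted(required), zero_division=0
        )
        model.holdout_report = {
            "classes": sorted(required),
            "precision": p.tolist(),
            "recall": r.tolist(),
            "macro_f1": float(np.mean(f)),
            "n_holdout": int(holdout.sum()),
        }
    return model


def _predict_refined(model: RefinementModel, X: np.ndarray) -> np.ndarray:
    l1 = model.layer1.predict(X)
    out = l1.astype(object)
    nh = l1 == "newHunch"
    if np.any(nh):
        out[nh] = model.layer2.predict(X[nh])
    return np.asarray(out, dtype=object)


def refine(
    intervals: list[ActionInterval],
    series_by_larva: dict[str, pd.DataFrame],
    model: RefinementModel,
    tail_speed_fast: float = 0.10,
) -> list[ActionInterval]:
    """Refine every coarse Bend/Hunch interval through the two layers.

    Other coarse labels map one-to-one.  Head Casts get a slow/fast
    subtype from the mean length-normalized tail speed over the action
    (threshold ``tail_speed_fast`` s⁻¹).  Output intervals tile the input
    intervals exactly and stay mutually exclusive.
    """
    _check_exclusive(intervals)
    out: list[ActionInterval] = []
    to_refine: list[tuple[int, dict]] = []
    for idx, iv in enumerate(intervals):
        if iv.coarse_label in ("Bend", "Hunch"):
            agg = aggregate_action_features(series_by_larva[iv.larva_id], iv)
            to_refine.append((idx, agg))
            out.append(
                ActionInterval(iv.larva_id, iv.start, iv.end, iv.coarse_label)
            )
        else:
            out.append(
                ActionInterval(
                    iv.larva_id,
                    iv.start,
                    iv.end,
                    iv.coarse_label,
                    refined_label=_PASSTHROUGH[iv.coarse_label],
                )
            )
    if to_refine:
        X = np.stack([vector_from_aggregate(agg, model.schema) for _, agg in to_refine])
        if X.shape[1] != model.layer1.n_features_in_:
            raise ValueError("feature schema mismatch between model and intervals")
        pred = _predict_refined(model, X)
        for (idx, agg), lab in zip(to_refine, pred):
            out[idx].refined_label = str(lab)
            if lab == "HeadCast":
                vt = agg.get("v_tail_mean", np.nan)
                out[idx].headcast_subtype = (
                    "fast" if np.isfinite(vt) and vt > tail_speed_fast else "slow"
                )
    return out


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    predicted: list[ActionInterval],
    truth: pd.DataFrame,
    frame_rate: float = 10.0,
    labels: list[str] | None = None,
) -> dict:
    """Frame-weighted confusion matrix and per-class precision/recall/F1.

    Predicted intervals and the truth table must cover the same larvae;
    both are sampled on a common frame grid and compared frame by frame
    over the refined vocabulary.
    """
    pred_ids = {iv.larva_id for iv in predicted}
    truth_ids = set(truth["larva_id"])
    if pred_ids != truth_ids:
        raise ValueError("predicted and truth cover different larvae")
    labels = labels or REFINED_LABELS
    y_true: list[str] = []
    y_pred: list[str] = []
    dt = 1.0 / frame_rate
    pred_by_larva: dict[str, list[ActionInterval]] = {}
    for iv in predicted:
        pred_by_larva.setdefault(iv.larva_id, []).append(iv)
    for larva in sorted(pred_ids):
        p_ivs = sorted(pred_by_larva[larva], key=lambda x: x.start)
        t_sub = truth[truth["larva_id"] == larva].sort_values("start")
        t0 = max(min(iv.start for iv in p_ivs), t_sub["start"].min())
        t1 = min(max(iv.end for iv in p_ivs), t_sub["end"].max())
        grid = np.arange(t0 + dt / 2, t1, dt)
        if not len(grid):
            continue

        def lookup(starts, ends, labs, tm):
            idx = np.searchsorted(starts, tm, side="right") - 1
            ok = (idx >= 0) & (tm < ends[np.clip(idx, 0, len(ends) - 1)])
            return idx, ok

        p_starts = np.array([iv.start for iv in p_ivs])
        p_ends = np.array([iv.end for iv in p_ivs])
        p_labs = np.array([iv.label for iv in p_ivs], dtype=object)
        t_starts = t_sub["start"].to_numpy()
        t_ends = t_sub["end"].to_numpy()
        t_labs = t_sub["label"].to_numpy(dtype=object)
        pi, pok = lookup(p_starts, p_ends, p_labs, grid)
        ti, tok = lookup(t_starts, t_ends, t_labs, grid)
        both = pok & tok
        tl = t_labs[np.clip(ti, 0, len(t_labs) - 1)][both]
        tl[tl == "FastCrawl"] = "Crawl"  # speed subtype, same refined class
        y_true.extend(tl.tolist())
        y_pred.extend(p_labs[np.clip(pi, 0, len(p_labs) - 1)][both].tolist())
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    p, r, f, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    present = support > 0
    return {
        "labels": labels,
        "confusion": pd.DataFrame(cm, index=labels, columns=labels),
        "precision": dict(zip(labels, p)),
        "recall": dict(zip(labels, r)),
        "f1": dict(zip(labels, f)),
        "support": dict(zip(labels, support)),
        "macro_f1": float(np.mean(f[present])) if np.any(present) else float("nan"),
    }


def save_model(model: RefinementModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> RefinementModel:
    return joblib.load(path)
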