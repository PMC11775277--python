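"""ΔF/F0 computation, repetition averaging and the pre-stimulus-activity
exclusion rule for fluorescence traces.

``ΔF/F0(t) = (F(t) − F0)/F0`` with ``F0`` the mean fluorescence over the
baseline window (by default the full pre-stimulus segment).  Averages use
the same number of repetitions per larva (extra repetitions are dropped by
a seeded subsample); traces showing activity before stimulation —
baseline |ΔF/F0| above a configurable threshold — are excluded and
logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "dff",
    "average_repetitions",
    "exclude_prestim_active",
    "read_traces_csv",
    "write_traces_csv",
]


@dataclass
class FluorescenceTrace:
    """One ROI intensity time series for one stimulation repetition."""

    larva_id: str
    repetition: int
    t: np.ndarray  # (n,) s
    f: np.ndarray  # (n,) fluorescence, arbitrary units, > 0
    stim_onset: float
    stim_duration: float
    baseline_window: tuple[float, float] | None = None  # defaults to (0, onset)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if len(self.t) != len(self.f):
            raise ValueError("t and f must have equal length")
        if self.baseline_window is None:
            self.baseline_window = (float(self.t[0]), float(self.stim_onset))
        lo, hi = self.baseline_window
        if hi > self.stim_onset + 1e-12:
            raise ValueError("baseline window must precede stimulus onset")

    @property
    def baseline_mask(self) -> np.ndarray:
        lo, hi = self.baseline_window
        return (self.t >= lo) & (self.t < hi)


def dff(trace: FluorescenceTrace) -> np.ndarray:
    """Per-timestep ΔF/F0 with F0 the baseline-window mean fluorescence."""
    mask = trace.baseline_mask
    if not np.any(mask):
        raise ValueError("baseline window contains no samples")
    f0 = float(np.mean(trace.f[mask]))
    if f0 <= 0:
        raise ValueError(f"nonpositive baseline F0 = {f0}")
    return (trace.f - f0) / f0


def average_repetitions(
    traces: list[FluorescenceTrace],
    seed: int = 0,
    sem_across: str = "larvae",
) -> dict:
    """Time-aligned mean ΔF/F0 and dispersion across larvae.

    Every larva contributes exactly ``r`` repetitions, ``r`` being the
    minimum repetition count over larvae (a seeded subsample drops the
    excess).  Returns the grand mean over larvae of per-larva repetition
    means, with the s.e.m. across larvae (default) or across all retained
    repetitions.
    """
    if not traces:
        raise ValueError("no traces")
    t0 = traces[0].t
    for tr in traces:
        if len(tr.t) != len(t0) or not np.allclose(tr.t, t0):
            raise ValueError("traces are not on a common time grid")
    by_larva: dict[str, list[FluorescenceTrace]] = {}
    for tr in traces:
        by_larva.setdefault(tr.larva_id, []).append(tr)
    r = min(len(v) for v in by_larva.values())
    rng = np.random.default_rng(seed)
    per_larva_means = []
    kept_reps = []
    subsampled = {}
    for larva in sorted(by_larva):
        reps = sorted(by_larva[larva], key=lambda x: x.repetition)
        if len(reps) > r:
            keep = sorted(rng.choice(len(reps), size=r, replace=False).tolist())
            subsampled[larva] = [reps[i].repetition for i in keep]
            reps = [reps[i] for i in keep]
        d = np.stack([dff(tr) for tr in reps])
        kept_reps.append(d)
        per_larva_means.append(d.mean(axis=0))
    means = np.stack(per_larva_means)
    mean = means.mean(axis=0)
    if sem_across == "larvae":
        sem = means.std(axis=0, ddof=1) / np.sqrt(len(means)) if len(means) > 1 else np.zeros_like(mean)
    elif sem_across == "repetitions":
        allreps = np.concatenate(kept_reps, axis=0)
        sem = allreps.std(axis=0, ddof=1) / np.sqrt(len(allreps)) if len(allreps) > 1 else np.zeros_like(mean)
    else:
        raise ValueError("sem_across must be 'larvae' or 'repetitions'")
    return {
        "t": t0,
        "mean": mean,
        "sem": sem,
        "n_larvae": len(by_larva),
        "repetitions_per_larva": r,
        "subsampled": subsampled,
    }


def exclude_prestim_active(
    traces: list[FluorescenceTrace], threshold: float = 0.3
) -> tuple[list[FluorescenceTrace], list[dict]]:
    """Drop traces whose baseline |ΔF/F0| exceeds ``threshold`` at any
    pre-stimulus timestep; returns the kept traces and an exclusion log."""
    kept: list[FluorescenceTrace] = []
    log: list[dict] = []
    for tr in traces:
        d = dff(tr)
        base = np.abs(d[tr.baseline_mask])
        peak = float(base.max()) if len(base) else 0.0
        if peak > threshold:
            log.append(
                {"larva_id": tr.larva_id, "repetition": tr.repetition, "peak_baseline_dff": peak}
            )
        else:
            kept.append(tr)
    return kept, log


def read_traces_csv(path: str | Path) -> list[FluorescenceTrace]:
    """Read traces from the flat CSV dialect:
    larva_id,repetition,t,F,stim_onset,stim_duration."""
    df = pd.read_csv(path)
    traces = []
    for (larva, rep), sub in df.groupby(["larva_id", "repetition"]):
        sub = sub.sort_values("t")
        traces.append(
            FluorescenceTrace(
                larva_id=str(larva),
                repetition=int(rep),
                t=sub["t"].to_numpy(),
                f=sub["F"].to_numpy(),
                stim_onset=float(sub["stim_onset"].iloc[0]),
                stim_duration=float(sub["stim_duration"].iloc[0]),
            )
        )
    return traces


def write_traces_csv(traces: list[FluorescenceTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for t, f in zip(tr.t, tr.f):
            rows.append((tr.larva_id, tr.repetition, t, f, tr.stim_onset, tr.stim_duration))
    pd.DataFrame(
        rows, columns=["larva_id", "repetition", "t", "F", "stim_onset", "stim_duration"]
    ).to_csv(path, index=False)
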