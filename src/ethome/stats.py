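"""Population-level behavioral statistics.

Ethograms (per-larva action timelines), cumulative behavioral
probabilities, inter-action transition matrices, chi-square comparisons
with Benjamini–Hochberg FDR control, and velocity-distribution comparisons
(two-sample Kolmogorov–Smirnov test and Gaussian-kernel density
estimates).

Conventions baked in here:

* cumulative probabilities condition on larvae tracked at the start of the
  analysis window (the stimulus-onset denominator rule);
* a transition is a pair of consecutive distinct intervals, timestamped at
  the start of the destination interval; display hides rows below a 3 %
  threshold while retaining the underlying counts;
* chi-square tests are plain Pearson, two-sided, no continuity correction
  (a flag restores Yates' correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import ActionInterval
from .io import TrackSet, tracked_at

__all__ = [
    "Ethogram",
    "TransitionMatrix",
    "WINDOW_PRESETS",
    "build_ethogram",
    "cumulative_probability",
    "transition_matrix",
    "chi2_compare",
    "bh_adjust",
    "ks_two_sample",
    "kde_density",
    "crawl_speed_comparison",
]

#: analysis windows used by the figure-style summaries, in seconds relative
#: to stimulus onset
WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "first_1s": (0.0, 1.0),
    "first_3s": (0.0, 3.0),
    "first_5s": (0.0, 5.0),
    "within_10_30s": (10.0, 30.0),
}

UNTRACKED = "untracked"


@dataclass
class Ethogram:
    """Per-larva, per-bin refined labels; ``untracked`` where no data."""

    bin_s: float
    bins: np.ndarray  # bin start times (s)
    table: pd.DataFrame  # index larva_id, columns bin starts, values labels

    def to_long(self) -> pd.DataFrame:
        long = self.table.reset_index().melt(
            id_vars="larva_id", var_name="bin_start", value_name="label"
        )
        return long.sort_values(["larva_id", "bin_start"]).reset_index(drop=True)


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame  # source x destination integer counts
    probabilities: pd.DataFrame  # row-normalized; NaN rows where no transitions
    window: tuple[float, float]
    display_threshold: float = 0.03
    hidden: pd.DataFrame | None = None  # True where below display threshold

    def displayed(self) -> pd.DataFrame:
        """Probabilities with sub-threshold cells masked (data retained)."""
        return self.probabilities.mask(self.hidden)


def _intervals_by_larva(intervals: list[ActionInterval]) -> dict[str, list[ActionInterval]]:
    out: dict[str, list[ActionInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.larva_id, []).append(iv)
    for k in out:
        ivs = sorted(out[k], key=lambda x: x.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"overlapping intervals for larva {k}")
        out[k] = ivs
    return out


def build_ethogram(
    intervals: list[ActionInterval], trackset: TrackSet, bin_s: float = 0.5
) -> Ethogram:
    """Discretize refined intervals onto a uniform time grid.

    Each bin takes the label of the interval covering its midpoint; bins
    whose midpoint has no valid tracking (or no interval) are
    ``untracked``.
    """
    by_larva = _intervals_by_larva(intervals)
    t0 = min(tr.t[0] for tr in trackset.tracks)
    t1 = max(tr.t[-1] for tr in trackset.tracks)
    bins = np.arange(t0, t1, bin_s)
    rows = {}
    for tr in trackset.tracks:
        labels = []
        ivs = by_larva.get(tr.larva_id, [])
        for b in bins:
            mid = b + bin_s / 2
            i = tr.nearest_frame(mid)
            tracked = abs(tr.t[i] - mid) <= 0.5 / tr.frame_rate and tr.valid[i]
            lab = next((iv.label for iv in ivs if iv.start <= mid < iv.end), None)
            rows.setdefault(tr.larva_id, labels)
            labels.append(lab if (tracked and lab is not None) else UNTRACKED)
        rows[tr.larva_id] = labels
    table = pd.DataFrame.from_dict(rows, orient="index", columns=bins)
    table.index.name = "larva_id"
    return Ethogram(bin_s=bin_s, bins=bins, table=table)


def cumulative_probability(
    intervals: list[ActionInterval],
    trackset: TrackSet,
    action: str,
    window: tuple[float, float],
) -> tuple[float, int]:
    """Fraction of larvae tracked at the window start that perform
    ``action`` at least once overlapping the window.

    Returns ``(p, n)`` with ``n`` the tracked-at-onset denominator.
    """
    t0, t1 = window
    denom_ids = tracked_at(trackset, t0)
    if not denom_ids:
        raise ValueError(f"no larvae tracked at t={t0}")
    performers = set()
    for iv in intervals:
        if iv.larva_id in denom_ids and iv.label == action and iv.start < t1 and iv.end > t0:
            performers.add(iv.larva_id)
    return len(performers) / len(denom_ids), len(denom_ids)


def transition_matrix(
    intervals: list[ActionInterval],
    window: tuple[float, float] | None = None,
    threshold: float = 0.03,
    first_transition_only: bool = False,
) -> TransitionMatrix:
    """Counts of consecutive distinct actions with in-window timestamps.

    The transition time is the start of the destination interval.  Rows
    are normalized over observed transitions; rows with zero counts have
    NaN probabilities.  Cells below ``threshold`` are flagged hidden for
    display but retained in the data.
    """
    by_larva = _intervals_by_larva(intervals)
    labels = sorted({iv.label for iv in intervals})
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for larva, ivs in by_larva.items():
        seen_first = False
        for a, b in zip(ivs, ivs[1:]):
            if a.label == b.label:
                continue
            tt = b.start
            if window is not None and not (window[0] <= tt < window[1]):
                continue
            if first_transition_only and seen_first:
                continue
            counts.loc[a.label, b.label] += 1
            seen_first = True
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts.div(row_sums.where(row_sums > 0), axis=0)
    hidden = probs < threshold
    return TransitionMatrix(
        counts=counts,
        probabilities=probs,
        window=window if window is not None else (-np.inf, np.inf),
        display_threshold=threshold,
        hidden=hidden,
    )


def chi2_compare(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test on an r×c count table.

    Returns ``(chi2, df, p)``; two-sided p from the chi-square
    distribution, no continuity correction by default.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("count table must hold nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("count table has a zero margin")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def bh_adjust(
    pvalues, alpha: float = 0.05, adjust: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(adjusted_p, reject)``.  ``adjust=False`` is the
    planned-comparison mode: raw p-values are returned and compared
    directly to ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not adjust:
        return p.copy(), p <= alpha
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def ks_two_sample(x, y, method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    ``D = sup_x |F_n(x) − G_m(x)|`` over the pooled sample points, with an
    asymptotic two-sided p-value by default (``method="exact"`` for the
    small-sample distribution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kde_density(
    sample,
    bandwidth_rule: str | float = "scott",
    grid: np.ndarray | None = None,
    n_grid: int = 512,
    pad_sd: float = 4.0,
):
    """Gaussian-kernel density estimate evaluated on a grid.

    Returns ``(grid, density)``.  A zero-variance sample falls back to a
    small fixed bandwidth with a warning rather than failing.
    """
    import warnings

    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("sample must be nonempty")
    sd = sample.std()
    if sd == 0:
        warnings.warn("zero-variance sample; using fixed minimal bandwidth")
        h = 0.01 if isinstance(bandwidth_rule, str) else float(bandwidth_rule)
        if grid is None:
            c = sample[0]
            grid = np.linspace(c - pad_sd * h * 2, c + pad_sd * h * 2, n_grid)
        dens = np.exp(-0.5 * ((grid - sample[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
        return grid, dens
    kde = sps.gaussian_kde(sample, bw_method=bandwidth_rule)
    if grid is None:
        lo = sample.min() - pad_sd * sd
        hi = sample.max() + pad_sd * sd
        grid = np.linspace(lo, hi, n_grid)
    return grid, kde(grid)


def crawl_speed_comparison(
    trackset: TrackSet,
    intervals: list[ActionInterval],
    window_before: tuple[float, float],
    window_during: tuple[float, float],
    series_by_larva: dict[str, pd.DataFrame],
    crawl_labels: tuple[str, ...] = ("Crawl", "FastCrawl"),
) -> dict:
    """Per-larva mean normalized crawl speed before vs during stimulation.

    For each window, each larva contributes the mean length-normalized
    centre-of-mass speed over its Crawl-interval frames inside the window;
    the two per-larva samples are compared with the two-sample KS test.
    """
    samples: dict[str, list[float]] = {"before": [], "during": []}
    for name, window in (("before", window_before), ("during", window_during)):
        for tr in trackset.tracks:
            series = series_by_larva[tr.larva_id]
            t = series["t"].to_numpy()
            v = series["v_motion"].to_numpy()
            mask = np.zeros(len(t), dtype=bool)
            for iv in intervals:
                if iv.larva_id != tr.larva_id or iv.label not in crawl_labels:
                    continue
                lo = max(iv.start, window[0])
                hi = min(iv.end, window[1])
                if hi > lo:
                    mask |= (t >= lo) & (t < hi)
            vals = v[mask]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                samples[name].append(float(np.mean(vals)))
        if not samples[name]:
            raise ValueError(f"no Crawl frames in the {name!r} window")
    D, p = ks_two_sample(samples["before"], samples["during"])
    return {
        "before": np.array(samples["before"]),
        "during": np.array(samples["during"]),
        "ks_D": D,
        "ks_p": p,
        "mean_before": float(np.mean(samples["before"])),
        "mean_during": float(np.mean(samples["during"])),
    }
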