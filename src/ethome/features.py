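"""Per-frame posture/kinematic features and per-action aggregates.

All speeds are normalized by the instantaneous larval length, so every
feature is scale-free:

* ``v_head``, ``v_motion``, ``v_tail`` — length-normalized speeds (s⁻¹) of
  the head point, the centre of mass G, and the tail point.
* ``S`` — the spine order parameter ``½(3⟨cos²θ⟩ − 1)`` where θ is the
  angle between each spine segment and the body axis; 1 for a straight
  body, −0.5 when every segment is orthogonal to the axis.
* ``lam`` — the movement shape factor ``(λ₁ − λ₂)/(λ₁ + λ₂)`` from the
  eigenvalues of the covariance of centre-of-mass displacements over a
  short sliding window; 0 isotropic wiggling, 1 purely linear motion.
* ``len_ratio`` — ‖HG‖/‖TG‖, head-to-centroid over tail-to-centroid
  distance (head retraction pushes this below 1).
* ``proj_head``, ``proj_tail`` — component of the head (tail) velocity
  along the nearest spine segment (closest-point rule), length-normalized,
  positive toward the tail.
* ``cos_head``, ``cos_tail`` — cosine between the head (tail) velocity and
  the first (last) spine segment, oriented outward (toward the body end),
  so forward crawling gives ``cos_head ≈ +1``.
* ``bend_deg`` — 180° minus the angle between H−G and T−G, in degrees
  (0 straight, large for C-shaped postures).
* ``rel_length`` — length over the track's median length (captures the
  body contraction of Hunches and Head-and-Tail retractions).
* ``dlen`` — length-normalized rate of length change (s⁻¹).
* ``v_forward`` — signed centre-of-mass velocity component along the
  tail→head body axis (s⁻¹); negative during rearward motion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import Track

__all__ = [
    "FRAME_FEATURES",
    "spine_order_parameter",
    "shape_factor",
    "length_ratio",
    "velocity_spine_projection",
    "velocity_segment_cosine",
    "bend_angle_deg",
    "compute_frame_features",
    "aggregate_action_features",
    "feature_schema",
    "vector_from_aggregate",
]

FRAME_FEATURES = [
    "v_head",
    "v_motion",
    "v_tail",
    "S",
    "lam",
    "len_ratio",
    "proj_head",
    "proj_tail",
    "cos_head",
    "cos_tail",
    "bend_deg",
    "rel_length",
    "dlen",
    "v_forward",
]


def spine_order_parameter(spine_points: np.ndarray, body_axis: np.ndarray) -> float:
    """Nematic-style order parameter of spine segments vs the body axis.

    ``S = ½(3⟨cos²θ⟩ − 1)`` with the mean over spine segments; zero-length
    segments are skipped.
    """
    pts = np.asarray(spine_points, dtype=float)
    axis = np.asarray(body_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("body axis vector must be nonzero")
    axis = axis / nrm
    segs = np.diff(pts, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    keep = lens > 0
    if not np.any(keep):
        raise ValueError("all spine segments have zero length")
    cos = (segs[keep] / lens[keep, None]) @ axis
    return float(0.5 * (3.0 * np.mean(cos**2) - 1.0))


def shape_factor(cov: np.ndarray) -> float:
    """Eigenvalue anisotropy (λ₁−λ₂)/(λ₁+λ₂) of a 2×2 movement covariance."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("covariance must be 2x2")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    l2, l1 = np.sort(np.linalg.eigvalsh(cov))
    tot = l1 + l2
    if tot <= 0:
        return 0.0  # degenerate: no movement at all
    return float((l1 - l2) / tot)


def length_ratio(spine_points: np.ndarray) -> float:
    """‖HG‖/‖TG‖ with H the first point, T the last, G the spine centroid."""
    pts = np.asarray(spine_points, dtype=float)
    g = pts.mean(axis=0)
    tg = np.linalg.norm(pts[-1] - g)
    if tg == 0:
        raise ValueError("degenerate posture: tail coincides with centroid")
    return float(np.linalg.norm(pts[0] - g) / tg)


def _closest_segment(point: np.ndarray, pts: np.ndarray) -> int:
    """Index of the spine segment whose closest point to ``point`` is nearest."""
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom = np.where(denom == 0, 1.0, denom)
    s = np.clip(((point - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + s[:, None] * ab
    return int(np.argmin(((point - proj) ** 2).sum(axis=1)))


def velocity_spine_projection(
    velocity: np.ndarray,
    spine_points: np.ndarray,
    end: str = "head",
    mode: str = "component",
) -> float:
    """Project an end-point velocity onto the nearest spine segment.

    The velocity vector is anchored at the head (or tail) point; the spine
    segment closest to the vector's endpoint is selected (closest-point
    rule), and the signed component of the velocity along that segment's
    head→tail direction is returned, normalized by the spine length.
    ``mode="residual"`` returns the normalized orthogonal remainder instead.
    """
    pts = np.asarray(spine_points, dtype=float)
    v = np.asarray(velocity, dtype=float)
    segs = np.diff(pts, axis=0)
    length = np.linalg.norm(segs, axis=1).sum()
    if length == 0:
        raise ValueError("zero-length spine")
    anchor = pts[0] if end == "head" else pts[-1]
    idx = _closest_segment(anchor + v, pts)
    seg = segs[idx]
    seg_len = np.linalg.norm(seg)
    if seg_len == 0:
        return float("nan")
    u = seg / seg_len  # head→tail orientation: positive component points tail-ward
    comp = float(v @ u)
    if mode == "component":
        return comp / length
    if mode == "residual":
        return float(np.linalg.norm(v - comp * u)) / length
    raise ValueError(f"unknown mode {mode!r}")


def velocity_segment_cosine(velocity: np.ndarray, segment: np.ndarray) -> float:
    """cosθ between a velocity vector and a spine segment; NaN if either is zero."""
    v = np.asarray(velocity, dtype=float)
    s = np.asarray(segment, dtype=float)
    nv, ns = np.linalg.norm(v), np.linalg.norm(s)
    if nv == 0 or ns == 0:
        return float("nan")
    return float(np.clip(v @ s / (nv * ns), -1.0, 1.0))


def bend_angle_deg(spine_points: np.ndarray) -> float:
    """Body bend: 180° minus the angle between head−centroid and tail−centroid."""
    pts = np.asarray(spine_points, dtype=float)
    g = pts.mean(axis=0)
    hg = pts[0] - g
    tg = pts[-1] - g
    nh, nt = np.linalg.norm(hg), np.linalg.norm(tg)
    if nh == 0 or nt == 0:
        return float("nan")
    ang = np.degrees(np.arccos(np.clip(hg @ tg / (nh * nt), -1.0, 1.0)))
    return float(180.0 - ang)


def _central_diff(arr: np.ndarray, t: np.ndarray, stencil: int) -> np.ndarray:
    """Central difference d(arr)/dt with one-sided stencils at the edges."""
    n = len(t)
    out = np.full(arr.shape, np.nan)
    s = stencil
    if n <= s:
        raise ValueError(f"track shorter than velocity stencil ({n} <= {s})")
    dt = t[2 * s :] - t[: -2 * s] if n > 2 * s else None
    if dt is not None:
        out[s:-s] = (arr[2 * s :] - arr[: -2 * s]) / _expand(dt, arr.ndim)
    out[:s] = (arr[s : 2 * s] - arr[:s]) / _expand(t[s : 2 * s] - t[:s], arr.ndim)
    out[-s:] = (arr[-s:] - arr[-2 * s : -s]) / _expand(t[-s:] - t[-2 * s : -s], arr.ndim)
    return out


def _expand(dt: np.ndarray, ndim: int) -> np.ndarray:
    return dt.reshape(dt.shape + (1,) * (ndim - 1))


def compute_frame_features(
    track: Track, cov_window: int = 5, stencil: int = 1
) -> pd.DataFrame:
    """Full per-frame feature table for one track.

    Velocities use a central difference over ``stencil`` frames; the
    movement covariance for ``lam`` is taken over a centred sliding window
    of ``cov_window`` centre-of-mass displacements.  Invalid frames (and
    frames whose velocity stencil touches one) yield NaN.
    """
    pts = np.where(track.valid[:, None, None], track.points, np.nan)
    t = track.t
    n, K, _ = pts.shape
    if n <= stencil:
        raise ValueError("track shorter than velocity stencil")
    g = pts.mean(axis=1)  # centre of mass (n, 2)
    head = pts[:, 0]
    tail = pts[:, -1]
    segs = np.diff(pts, axis=1)  # (n, K-1, 2) head→tail
    seg_len = np.linalg.norm(segs, axis=2)
    length = seg_len.sum(axis=1)

    v_head_vec = _central_diff(head, t, stencil)
    v_tail_vec = _central_diff(tail, t, stencil)
    v_g_vec = _central_diff(g, t, stencil)
    dlen = _central_diff(length, t, stencil)

    with np.errstate(invalid="ignore", divide="ignore"):
        v_head = np.linalg.norm(v_head_vec, axis=1) / length
        v_tail = np.linalg.norm(v_tail_vec, axis=1) / length
        v_motion = np.linalg.norm(v_g_vec, axis=1) / length

        # order parameter: segments vs tail→head body axis
        axis = head - tail
        axis_n = np.linalg.norm(axis, axis=1, keepdims=True)
        axis_u = axis / axis_n
        seg_u = segs / np.where(seg_len[:, :, None] == 0, np.nan, seg_len[:, :, None])
        cos2 = np.einsum("nkd,nd->nk", seg_u, axis_u) ** 2
        cos2[~track.valid] = 0.0  # invalid rows are overwritten with NaN below
        S = 0.5 * (3.0 * np.nanmean(cos2, axis=1) - 1.0)

        hg = head - g
        tg = tail - g
        nh = np.linalg.norm(hg, axis=1)
        nt = np.linalg.norm(tg, axis=1)
        len_ratio = nh / nt
        bend = 180.0 - np.degrees(
            np.arccos(np.clip(np.einsum("nd,nd->n", hg, tg) / (nh * nt), -1.0, 1.0))
        )

        # cosines vs the outward-oriented terminal segments
        first_seg = pts[:, 0] - pts[:, 1]  # toward the head
        last_seg = pts[:, -1] - pts[:, -2]  # toward the tail
        cos_head = _cosine_rows(v_head_vec, first_seg)
        cos_tail = _cosine_rows(v_tail_vec, last_seg)

        rel_length = length / np.nanmedian(length)
        dlen_norm = dlen / length
        # signed CoM velocity along the tail→head body axis (forward > 0)
        v_forward = np.einsum("nd,nd->n", v_g_vec, axis_u) / length

    proj_head = _projection_series(v_head_vec, pts, segs, seg_len, length, end="head")
    proj_tail = _projection_series(v_tail_vec, pts, segs, seg_len, length, end="tail")
    lam = _lambda_series(g, cov_window)

    df = pd.DataFrame(
        {
            "t": t,
            "valid": track.valid,
            "length": length,
            "v_head": v_head,
            "v_motion": v_motion,
            "v_tail": v_tail,
            "S": S,
            "lam": lam,
            "len_ratio": len_ratio,
            "proj_head": proj_head,
            "proj_tail": proj_tail,
            "cos_head": cos_head,
            "cos_tail": cos_tail,
            "bend_deg": bend,
            "rel_length": rel_length,
            "dlen": dlen_norm,
            "v_forward": v_forward,
        }
    )
    df.loc[~track.valid, FRAME_FEATURES] = np.nan
    return df


def _projection_series(
    v: np.ndarray,
    pts: np.ndarray,
    segs: np.ndarray,
    seg_len: np.ndarray,
    length: np.ndarray,
    end: str,
) -> np.ndarray:
    """Vectorized closest-segment velocity projection for every frame."""
    n = len(pts)
    anchor = pts[:, 0] if end == "head" else pts[:, -1]
    target = anchor + v  # (n, 2) endpoint of the velocity vector
    a = pts[:, :-1]  # (n, K-1, 2)
    ab = segs
    denom = np.where(seg_len == 0, 1.0, seg_len**2)
    rel = target[:, None, :] - a
    s = np.clip(np.einsum("nkd,nkd->nk", rel, ab) / denom, 0.0, 1.0)
    closest = a + s[:, :, None] * ab
    d2 = ((target[:, None, :] - closest) ** 2).sum(axis=2)
    with np.errstate(invalid="ignore"):
        allnan = np.all(np.isnan(d2), axis=1)
        idx = np.where(allnan, 0, np.nanargmin(np.where(np.isnan(d2), np.inf, d2), axis=1))
    rows = np.arange(n)
    seg = segs[rows, idx]
    sl = seg_len[rows, idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.einsum("nd,nd->n", v, seg) / sl
        out = comp / length
    out[allnan | (sl == 0) | (length == 0)] = np.nan
    return out


def _lambda_series(g: np.ndarray, cov_window: int) -> np.ndarray:
    """Sliding-window movement shape factor via rolling covariance sums."""
    n = len(g)
    disp = np.diff(g, axis=0)
    m = len(disp)
    lam = np.full(n, np.nan)
    if m == 0:
        return lam
    finite = np.all(np.isfinite(disp), axis=1)
    x = np.where(finite, disp[:, 0], 0.0)
    y = np.where(finite, disp[:, 1], 0.0)
    w = finite.astype(float)
    half = cov_window // 2

    def rolling_sum(arr):
        c = np.concatenate([[0.0], np.cumsum(arr)])
        lo = np.clip(np.arange(n) - half, 0, m)
        hi = np.clip(np.arange(n) + half + 1, 0, m)
        return c[hi] - c[lo]

    cnt = rolling_sum(w)
    sx, sy = rolling_sum(x), rolling_sum(y)
    sxx, syy, sxy = rolling_sum(x * x), rolling_sum(y * y), rolling_sum(x * y)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx, my = sx / cnt, sy / cnt
        a = sxx / cnt - mx * mx  # biased covariance entries
        c = syy / cnt - my * my
        b = sxy / cnt - mx * my
        spread = np.sqrt((a - c) ** 2 + 4 * b * b)
        tot = a + c
        vals = spread / tot
    enough = cnt >= 2
    lam[enough] = np.clip(np.where(tot[enough] > 0, vals[enough], 0.0), 0.0, 1.0)
    single = cnt == 1
    lam[single] = np.where((sxx + syy)[single] > 0, 1.0, 0.0)
    return lam


def _cosine_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.clip(np.einsum("nd,nd->n", a, b) / denom, -1.0, 1.0)
    return np.where(denom == 0, np.nan, out)


def aggregate_action_features(
    series: pd.DataFrame, interval, context: int = 5
) -> dict:
    """Aggregate per-frame features over one action interval.

    Returns mean/max/min per feature over the interval's frames plus mean
    context over ``context`` frames immediately before and after the
    action (truncated at track edges and flagged), and the duration.
    ``interval`` is anything with ``start``/``end`` attributes (seconds,
    half-open).
    """
    t = series["t"].to_numpy()
    lo = int(np.searchsorted(t, interval.start - 1e-9, side="left"))
    hi = int(np.searchsorted(t, interval.end - 1e-9, side="left"))
    if hi <= lo:
        raise ValueError(f"empty interval [{interval.start}, {interval.end})")
    mat = series[FRAME_FEATURES].to_numpy()
    pre_lo = max(0, lo - context)
    post_hi = min(len(t), hi + context)
    out: dict = {"duration": float(interval.end - interval.start)}

    def nanstat(fn, block):
        if block.size == 0:
            return np.full(mat.shape[1], np.nan)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return fn(block, axis=0)

    means = nanstat(np.nanmean, mat[lo:hi])
    maxs = nanstat(np.nanmax, mat[lo:hi])
    mins = nanstat(np.nanmin, mat[lo:hi])
    pres = nanstat(np.nanmean, mat[pre_lo:lo])
    posts = nanstat(np.nanmean, mat[hi:post_hi])
    for j, f in enumerate(FRAME_FEATURES):
        out[f + "_mean"] = float(means[j])
        out[f + "_max"] = float(maxs[j])
        out[f + "_min"] = float(mins[j])
        out[f + "_pre"] = float(pres[j])
        out[f + "_post"] = float(posts[j])
    out["pre_truncated"] = bool((lo - pre_lo) < context)
    out["post_truncated"] = bool((post_hi - hi) < context)
    return out


def feature_schema(context: bool = True) -> list[str]:
    """Ordered names of the flattened per-action feature vector."""
    names = ["duration"]
    stats = ["mean", "max", "min"] + (["pre", "post"] if context else [])
    for f in FRAME_FEATURES:
        names += [f"{f}_{s}" for s in stats]
    return names


def vector_from_aggregate(agg: dict, schema: list[str] | None = None) -> np.ndarray:
    """Flatten an aggregate dict to the fixed schema; NaNs become 0."""
    schema = schema or feature_schema()
    return np.nan_to_num(np.array([agg.get(k, np.nan) for k in schema], dtype=float))
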