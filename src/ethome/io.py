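"""Track data model and tab-separated spine/contour table I/O.

The on-disk dialect is modeled on Multi-Worm-Tracker/Choreography exports:
one row per (larva, frame), tab-separated, with columns

    larva_id  t  x1 y1 ... xK yK  [contour]

where the K spine points run head to tail in millimetres, ``t`` is in
seconds, and ``contour`` (optional) is a semicolon-joined list of ``x,y``
pairs describing the body outline.  A frame where the larva was not tracked
keeps its row but leaves every spine cell blank.

Stimulus protocols (air-puff / light epochs) are read from YAML or JSON
mappings with an ``epochs`` list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SpineFrame",
    "Track",
    "StimulusEpoch",
    "StimulusProtocol",
    "TrackSet",
    "read_track_table",
    "write_track_table",
    "tracked_at",
]

_FMT = "%.12g"  # coordinate formatting; round-trips mm-scale values to <1e-9


@dataclass
class SpineFrame:
    """A single tracked frame: time, ordered head→tail midline, outline."""

    t: float
    points: np.ndarray  # (K, 2), head first
    contour: np.ndarray | None = None  # (M, 2) closed polygon, optional
    valid: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("spine points must be an (K, 2) array")
        if self.points.shape[0] < 3:
            raise ValueError("a spine needs at least 3 points")
        if self.valid and not np.all(np.isfinite(self.points)):
            raise ValueError("valid frame contains non-finite spine points")


@dataclass
class Track:
    """One larva's time series of spine frames.

    ``points`` rows for invalid frames may be NaN.  Frames are sorted by
    time on construction; duplicate timestamps are rejected.
    """

    larva_id: str
    t: np.ndarray  # (n,) seconds
    points: np.ndarray  # (n, K, 2) mm
    valid: np.ndarray  # (n,) bool
    frame_rate: float = 10.0
    contours: list[np.ndarray | None] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise ValueError("points must be (n_frames, K, 2)")
        if self.points.shape[1] < 3:
            raise ValueError("spine resolution K must be >= 3")
        if not (len(self.t) == len(self.points) == len(self.valid)):
            raise ValueError("t, points and valid must have equal length")
        order = np.argsort(self.t, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.t = self.t[order]
            self.points = self.points[order]
            self.valid = self.valid[order]
            if self.contours is not None:
                self.contours = [self.contours[i] for i in order]
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.larva_id!r}: timestamps not strictly increasing")
        bad = self.valid & ~np.all(np.isfinite(self.points), axis=(1, 2))
        if np.any(bad):
            raise ValueError(
                f"track {self.larva_id!r}: non-finite spine on valid frames {np.where(bad)[0][:5]}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def K(self) -> int:
        return self.points.shape[1]

    @property
    def length_series(self) -> np.ndarray:
        """Midline polyline length per frame (mm); NaN on invalid frames."""
        seg = np.diff(self.points, axis=1)
        length = np.sqrt((seg**2).sum(axis=2)).sum(axis=1)
        length = np.where(self.valid, length, np.nan)
        return length

    def frame(self, i: int) -> SpineFrame:
        contour = self.contours[i] if self.contours is not None else None
        return SpineFrame(
            t=float(self.t[i]),
            points=self.points[i] if self.valid[i] else np.full_like(self.points[i], np.nan),
            contour=contour,
            valid=bool(self.valid[i]),
        )

    def nearest_frame(self, t: float) -> int:
        return int(np.argmin(np.abs(self.t - t)))


@dataclass(frozen=True)
class StimulusEpoch:
    modality: str  # "air_puff" or "light"
    onset: float  # s
    duration: float  # s
    intensity: float = 0.0  # m/s (air puff) or mW/cm^2 (light)

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusProtocol:
    """Stimulation epochs; non-overlapping within each modality."""

    epochs: list[StimulusEpoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_mod: dict[str, list[StimulusEpoch]] = {}
        for ep in self.epochs:
            if ep.onset < 0:
                raise ValueError("epoch onset must be >= 0")
            if ep.duration <= 0:
                raise ValueError("epoch duration must be > 0")
            by_mod.setdefault(ep.modality, []).append(ep)
        for mod, eps in by_mod.items():
            eps = sorted(eps, key=lambda e: e.onset)
            for a, b in zip(eps, eps[1:]):
                if b.onset < a.end:
                    raise ValueError(f"overlapping {mod} epochs at t={b.onset}")

    @property
    def onset(self) -> float:
        """Onset of the first epoch (the stimulus time used by the analyses)."""
        if not self.epochs:
            raise ValueError("protocol has no epochs")
        return min(ep.onset for ep in self.epochs)

    def in_stimulus(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for ep in self.epochs:
            out |= (t >= ep.onset) & (t < ep.end)
        return out

    def to_dict(self) -> dict:
        return {
            "epochs": [
                {
                    "modality": ep.modality,
                    "onset": ep.onset,
                    "duration": ep.duration,
                    "intensity": ep.intensity,
                }
                for ep in self.epochs
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(epochs=[StimulusEpoch(**ep) for ep in d.get("epochs", [])])

    @classmethod
    def from_file(cls, path: str | Path) -> "StimulusProtocol":
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class TrackSet:
    """A population of tracks recorded under one condition and protocol."""

    tracks: list[Track]
    protocol: StimulusProtocol | None = None
    condition_label: str = ""

    def __post_init__(self) -> None:
        ids = [tr.larva_id for tr in self.tracks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate larva_ids in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def get(self, larva_id: str) -> Track:
        for tr in self.tracks:
            if tr.larva_id == larva_id:
                return tr
        raise KeyError(larva_id)

    @property
    def larva_ids(self) -> list[str]:
        return [tr.larva_id for tr in self.tracks]


def _fmt_pt(x: float) -> str:
    return _FMT % x


def write_track_table(trackset: TrackSet, path: str | Path) -> None:
    """Write a TrackSet in the tab-separated spine dialect.

    Invalid frames are written with blank spine cells; contours (if any)
    are written as a semicolon-joined list of ``x,y`` pairs.
    """
    path = Path(path)
    ks = {tr.K for tr in trackset.tracks}
    if len(ks) > 1:
        raise ValueError("all tracks in one table must share the same spine resolution K")
    K = ks.pop() if ks else 11
    has_contour = any(tr.contours is not None for tr in trackset.tracks)
    cols = ["larva_id", "t"]
    for i in range(1, K + 1):
        cols += [f"x{i}", f"y{i}"]
    if has_contour:
        cols.append("contour")
    lines = ["\t".join(cols)]
    for tr in trackset.tracks:
        for i in range(tr.n_frames):
            row = [tr.larva_id, _fmt_pt(tr.t[i])]
            if tr.valid[i]:
                row += [_fmt_pt(v) for v in tr.points[i].ravel()]
            else:
                row += [""] * (2 * K)
            if has_contour:
                c = tr.contours[i] if tr.contours is not None else None
                row.append(
                    ";".join(f"{_fmt_pt(x)},{_fmt_pt(y)}" for x, y in c) if c is not None else ""
                )
            lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_track_table(
    path: str | Path,
    frame_rate: float = 10.0,
    protocol: StimulusProtocol | None = None,
    condition_label: str = "",
) -> TrackSet:
    """Read the tab-separated spine dialect into a TrackSet.

    Frames with blank spine cells are kept, flagged ``valid=False``.
    Malformed rows raise ``ValueError`` naming the 1-based line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["larva_id", "t"]:
        raise ValueError(f"{path}: line 1: expected header starting 'larva_id\\tt'")
    coord_cols = [c for c in header if c[0] in "xy" and c[1:].isdigit()]
    K = len(coord_cols) // 2
    if K < 3:
        raise ValueError(f"{path}: header defines K={K} spine points; need >= 3")
    has_contour = header[-1] == "contour"
    ncols = len(header)
    per_larva: dict[str, dict[str, list]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != ncols:
            raise ValueError(f"{path}: line {lineno}: expected {ncols} fields, got {len(cells)}")
        larva_id = cells[0]
        try:
            t = float(cells[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: bad time value {cells[1]!r}") from exc
        coord_cells = cells[2 : 2 + 2 * K]
        blank = [c == "" for c in coord_cells]
        if any(blank) and not all(blank):
            raise ValueError(f"{path}: line {lineno}: partially blank spine")
        if all(blank):
            pts = np.full((K, 2), np.nan)
            valid = False
        else:
            try:
                vals = np.array([float(c) for c in coord_cells])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinate") from exc
            pts = vals.reshape(K, 2)
            valid = bool(np.all(np.isfinite(pts)))
        contour = None
        if has_contour:
            raw = cells[2 + 2 * K]
            if raw:
                try:
                    contour = np.array(
                        [[float(u) for u in pair.split(",")] for pair in raw.split(";")]
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: bad contour") from exc
        d = per_larva.setdefault(larva_id, {"t": [], "pts": [], "valid": [], "contour": []})
        d["t"].append(t)
        d["pts"].append(pts)
        d["valid"].append(valid)
        d["contour"].append(contour)
    tracks = []
    for larva_id, d in per_larva.items():
        contours = d["contour"] if any(c is not None for c in d["contour"]) else None
        tracks.append(
            Track(
                larva_id=larva_id,
                t=np.array(d["t"]),
                points=np.stack(d["pts"]),
                valid=np.array(d["valid"]),
                frame_rate=frame_rate,
                contours=contours,
            )
        )
    return TrackSet(tracks=tracks, protocol=protocol, condition_label=condition_label)


def tracked_at(trackset: TrackSet, t: float) -> set[str]:
    """Larvae with a valid frame at time ``t``.

    The nearest frame is accepted if it lies within half a frame period of
    ``t`` — the "tracked at the beginning of the stimulus" denominator rule
    used by the cumulative-probability statistics.
    """
    out = set()
    for tr in trackset.tracks:
        if tr.n_frames == 0:
            continue
        i = tr.nearest_frame(t)
        if abs(tr.t[i] - t) <= 0.5 / tr.frame_rate and tr.valid[i]:
            out.add(tr.larva_id)
    return out
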