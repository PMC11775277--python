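"""Synthetic larval trajectories, connectomes and fluorescence traces.

The trajectory generator realizes each action of the refined behavioral
vocabulary as a short midline motif with the kinematics that define it:

* ``Crawl`` — straight body, forward centre-of-mass motion with sinusoidal
  peristaltic length modulation (±8 %); ``FastCrawl`` is the same at 1.5×
  centre-of-mass speed.
* ``HeadCast`` — the anterior half of the body sweeps laterally about a
  mid-body pivot (head speed ≳3× the centre-of-mass speed); the ``fast``
  subtype adds a counter-sweep of the posterior half (elevated tail speed).
* ``StaticBend`` — a held bend (≈65°) with essentially no motion
  (normalized motion speed < 0.02 s⁻¹ by construction).
* ``Hunch`` — head retraction: the anterior half contracts toward the
  centroid (head–centroid distance drops ≥20 % within ~0.4 s), body
  straight.
* ``HeadAndTail`` — simultaneous retraction of both ends; the total length
  drop exceeds a Hunch's.
* ``CShape`` — a strong static body arc (total turning ≈240°), head and
  tail nearly still.
* ``Roll`` — side-alternating bend at ~2 Hz with lateral centre-of-mass
  translation (a planar proxy; true rolling is three-dimensional).
* ``BackUp`` — rearward centre-of-mass motion; ``Stop`` — no motion.

These amplitudes are synthetic conventions chosen so that the defining
inequality of each action holds on every zero-noise frame; they are not
measurements.  All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import StimulusEpoch, StimulusProtocol, Track, TrackSet

__all__ = [
    "MOTIF_LABELS",
    "BehaviorScript",
    "NoiseParams",
    "PopulationConfig",
    "simulate_larva",
    "simulate_population",
    "ConnectomeParams",
    "simulate_connectome",
    "FluorescenceParams",
    "simulate_fluorescence",
    "default_protocol",
]

MOTIF_LABELS = [
    "Crawl",
    "FastCrawl",
    "HeadCast",
    "StaticBend",
    "Hunch",
    "HeadAndTail",
    "CShape",
    "Roll",
    "BackUp",
    "Stop",
]


def default_protocol() -> StimulusProtocol:
    """The study's standard assay: a 4 m/s air puff from t=60 s for 30 s."""
    return StimulusProtocol(
        epochs=[StimulusEpoch(modality="air_puff", onset=60.0, duration=30.0, intensity=4.0)]
    )


@dataclass(frozen=True)
class Motif:
    label: str
    duration: float  # s
    subtype: str = "none"  # HeadCast: "slow" | "fast"

    def __post_init__(self):
        if self.label not in MOTIF_LABELS:
            raise ValueError(f"unknown motif label {self.label!r}")
        if self.duration <= 0:
            raise ValueError("motif duration must be > 0")


@dataclass
class BehaviorScript:
    """Time-ordered motif list driving one synthetic larva."""

    motifs: list[Motif]

    @classmethod
    def of(cls, *items) -> "BehaviorScript":
        """Build from (label, duration[, subtype]) tuples."""
        return cls(motifs=[Motif(*it) for it in items])


@dataclass(frozen=True)
class NoiseParams:
    point_jitter_mm: float = 0.0  # iid Gaussian SD added to every spine point
    heading_drift_sd: float = 0.0  # rad/sqrt(s) random-walk drift of the heading


@dataclass
class TruthInterval:
    """Ground-truth action span emitted by the generator."""

    larva_id: str
    start: float
    end: float
    label: str
    subtype: str = "none"


# ---------------------------------------------------------------------------
# posture construction


def _chain_from_angles(angles: np.ndarray, seg_lens: np.ndarray) -> np.ndarray:
    """Polyline from per-segment orientation angles, tail at the origin,
    returned head→tail."""
    steps = np.stack([np.cos(angles), np.sin(angles)], axis=1) * seg_lens[:, None]
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])  # tail→head
    return pts[::-1].copy()


def _center_at(pts: np.ndarray, com: np.ndarray) -> np.ndarray:
    return pts - pts.mean(axis=0) + com


class _LarvaState:
    def __init__(self, com: np.ndarray, heading: float, L0: float, K: int):
        self.com = np.asarray(com, dtype=float)
        self.heading = float(heading)
        self.L0 = L0
        self.K = K


def _motif_frames(state: _LarvaState, motif: Motif, times: np.ndarray) -> np.ndarray:
    """Frames (m, K, 2) realizing one motif, starting from ``state``;
    updates the state in place.  ``times`` are seconds from motif onset."""
    K, L0, h = state.K, state.L0, state.heading
    nseg = K - 1
    m = len(times)
    base_angles = np.full(nseg, h)
    seg0 = np.full(nseg, L0 / nseg)
    half = nseg // 2  # segments [half:] form the anterior (head) half
    frames = np.empty((m, K, 2))
    label = motif.label

    if label in ("Crawl", "FastCrawl", "BackUp", "Stop"):
        speed = {
            "Crawl": 0.06,
            "FastCrawl": 0.09,  # 1.5× Crawl
            "BackUp": -0.04,
            "Stop": 0.0,
        }[label] * L0  # mm/s
        mod = 0.08 if label in ("Crawl", "FastCrawl") else 0.0
        f_peri = 0.4  # Hz; slow enough that |dL/dt|/L stays well below a Hunch's
        for i, t in enumerate(times):
            length = L0 * (1.0 + mod * np.sin(2 * np.pi * f_peri * t))
            segl = np.full(nseg, length / nseg)
            com = state.com + speed * t * np.array([np.cos(h), np.sin(h)])
            frames[i] = _center_at(_chain_from_angles(base_angles, segl), com)
        state.com = state.com + speed * times[-1] * np.array([np.cos(h), np.sin(h)])

    elif label == "StaticBend":
        bend = np.deg2rad(100.0)  # kink; chord-based bend angle comes out ≈50°
        ang = base_angles.copy()
        ang[half:] += bend
        pts = _center_at(_chain_from_angles(ang, seg0), state.com)
        frames[:] = pts

    elif label == "CShape":
        total_turn = np.deg2rad(240.0)
        ang = h + np.linspace(0, total_turn, nseg)
        pts = _center_at(_chain_from_angles(ang, seg0), state.com)
        frames[:] = pts

    elif label == "HeadCast":
        # anterior half sweeps about a fixed mid-body pivot; the "fast"
        # subtype counter-sweeps the posterior half (elevated tail speed),
        # the "slow" subtype keeps the tail still.
        amp = np.deg2rad(60.0)
        f = 0.75
        tail_amp = np.deg2rad(35.0) if motif.subtype == "fast" else 0.0
        pivot_idx = K - 1 - half  # chain index (head→tail order) of the pivot
        ref = _center_at(_chain_from_angles(base_angles, seg0), state.com)
        pivot = ref[pivot_idx]
        for i, t in enumerate(times):
            phi = amp * np.sin(2 * np.pi * f * t)
            ang = base_angles.copy()
            ang[half:] += phi
            ang[:half] -= tail_amp * np.sin(2 * np.pi * f * t)
            pts = _chain_from_angles(ang, seg0)
            frames[i] = pts - pts[pivot_idx] + pivot

    elif label in ("Hunch", "HeadAndTail"):
        # contraction of the anterior (and for HeadAndTail also posterior)
        # segment lengths to 0.6x within 0.4 s, held thereafter; the tail tip
        # (Hunch) or midpoint (HeadAndTail) stays anchored.
        for i, t in enumerate(times):
            c = 1.0 - 0.4 * min(t / 0.4, 1.0)
            segl = seg0.copy()
            segl[half:] *= c
            if label == "HeadAndTail":
                segl[:half] *= c
            pts = _chain_from_angles(base_angles, segl)
            if label == "Hunch":
                # anchor the tail point at its pre-motif position
                ref = _chain_from_angles(base_angles, seg0)
                full = _center_at(ref, state.com)
                pts = pts - pts[-1] + full[-1]
            else:
                pts = _center_at(pts, state.com)
            frames[i] = pts

    elif label == "Roll":
        amp = np.deg2rad(110.0)
        f_roll = 2.0
        lat = 0.15 * L0  # mm/s lateral CoM translation
        perp = np.array([-np.sin(h), np.cos(h)])
        for i, t in enumerate(times):
            ang = base_angles.copy()
            ang[half:] += amp * np.sin(2 * np.pi * f_roll * t)
            com = state.com + lat * t * perp
            frames[i] = _center_at(_chain_from_angles(ang, seg0), com)
        state.com = state.com + lat * times[-1] * perp

    else:  # pragma: no cover - guarded by Motif validation
        raise ValueError(f"unknown motif label {label!r}")

    return frames


def simulate_larva(
    script: BehaviorScript,
    protocol: StimulusProtocol | None = None,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    larva_id: str = "larva0",
    frame_rate: float = 10.0,
    K: int = 11,
    body_length_mm: float = 4.0,
    start_com: tuple[float, float] = (0.0, 0.0),
    heading: float = 0.0,
    start_time: float = 0.0,
    untracked_until: float | None = None,
) -> tuple[Track, list[TruthInterval]]:
    """Simulate one larva executing ``script``; returns the track and the
    ground-truth intervals, which exactly tile the scripted spans.

    ``untracked_until`` marks all frames before that time invalid
    (emulating a larva not yet picked up by the tracker).
    """
    rng = np.random.default_rng(seed)
    state = _LarvaState(np.array(start_com, dtype=float), heading, body_length_mm, K)
    dt = 1.0 / frame_rate
    all_frames = []
    truth: list[TruthInterval] = []
    f0 = 0  # frame offset; integer bookkeeping avoids float drift in spans
    for motif in script.motifs:
        n = max(1, int(round(motif.duration * frame_rate)))
        times = np.arange(n) * dt
        frames = _motif_frames(state, motif, times)
        all_frames.append(frames)
        truth.append(
            TruthInterval(
                larva_id,
                start_time + f0 * dt,
                start_time + (f0 + n) * dt,
                motif.label,
                motif.subtype,
            )
        )
        f0 += n
    pts = np.concatenate(all_frames, axis=0)
    n_total = len(pts)
    t = start_time + np.arange(n_total) * dt
    if noise.heading_drift_sd > 0:
        drift = np.cumsum(rng.normal(0.0, noise.heading_drift_sd * np.sqrt(dt), n_total))
        com = pts.mean(axis=1, keepdims=True)
        c, s = np.cos(drift), np.sin(drift)
        rot = np.empty((n_total, 2, 2))
        rot[:, 0, 0], rot[:, 0, 1] = c, -s
        rot[:, 1, 0], rot[:, 1, 1] = s, c
        pts = np.einsum("nij,nkj->nki", rot, pts - com) + com
    if noise.point_jitter_mm > 0:
        pts = pts + rng.normal(0.0, noise.point_jitter_mm, pts.shape)
    valid = np.ones(n_total, dtype=bool)
    if untracked_until is not None:
        valid &= t >= untracked_until
    track = Track(
        larva_id=larva_id,
        t=t,
        points=np.where(valid[:, None, None], pts, np.nan),
        valid=valid,
        frame_rate=frame_rate,
    )
    return track, truth


# ---------------------------------------------------------------------------
# population


def _default_baseline_kernel() -> dict[str, float]:
    return {"Crawl": 0.45, "HeadCast": 0.30, "Stop": 0.15, "BackUp": 0.10}


def _default_stimulus_kernel() -> dict[str, float]:
    return {
        "Hunch": 0.18,
        "HeadAndTail": 0.14,
        "CShape": 0.14,
        "StaticBend": 0.16,
        "HeadCast": 0.10,
        "Roll": 0.08,
        "FastCrawl": 0.08,
        "Crawl": 0.07,
        "Stop": 0.05,
    }


def _default_durations() -> dict[str, tuple[float, float]]:
    return {
        "Crawl": (2.0, 5.0),
        "FastCrawl": (2.0, 4.0),
        "HeadCast": (1.0, 3.0),
        "StaticBend": (1.5, 3.0),
        "Hunch": (0.6, 1.2),
        "HeadAndTail": (0.6, 1.2),
        "CShape": (1.0, 2.0),
        "Roll": (1.0, 2.0),
        "BackUp": (1.0, 2.0),
        "Stop": (1.0, 3.0),
    }


@dataclass
class PopulationConfig:
    """Population-level generator settings.

    The motif kernels are categorical distributions over next-action labels,
    switched at stimulus onset/offset; ``dropout`` is the probability that a
    larva is not yet tracked at stimulus onset (its frames before a random
    post-onset pickup time are invalid).
    """

    n_larvae: int = 50
    baseline_kernel: dict[str, float] = field(default_factory=_default_baseline_kernel)
    stimulus_kernel: dict[str, float] = field(default_factory=_default_stimulus_kernel)
    durations: dict[str, tuple[float, float]] = field(default_factory=_default_durations)
    noise: NoiseParams = NoiseParams()
    dropout: float = 0.0
    total_s: float = 100.0
    frame_rate: float = 10.0
    K: int = 11
    body_length_mm: float = 4.0
    headcast_fast_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_larvae <= 0:
            raise ValueError("n_larvae must be positive")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability")
        for name, kernel in (
            ("baseline_kernel", self.baseline_kernel),
            ("stimulus_kernel", self.stimulus_kernel),
        ):
            if not kernel:
                raise ValueError(f"{name} is empty")
            probs = np.array(list(kernel.values()), dtype=float)
            if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"{name} probabilities must be >= 0 and sum to 1")
            unknown = set(kernel) - set(MOTIF_LABELS)
            if unknown:
                raise ValueError(f"{name} has unknown labels {sorted(unknown)}")


def _draw_motif(rng, kernel, durations, prev_label, headcast_fast_fraction):
    labels = list(kernel)
    probs = np.array([kernel[c] for c in labels])
    for _ in range(20):
        lab = labels[rng.choice(len(labels), p=probs)]
        if lab != prev_label or len(labels) == 1:
            break
    lo, hi = durations[lab]
    dur = float(rng.uniform(lo, hi))
    sub = "none"
    if lab == "HeadCast":
        sub = "fast" if rng.random() < headcast_fast_fraction else "slow"
    return Motif(lab, dur, sub)


def _script_for_larva(rng, config: PopulationConfig, protocol: StimulusProtocol):
    """Motif sequence: baseline kernel before onset, stimulus kernel during
    the epoch, baseline again afterwards.  The running motif is truncated at
    onset so the first in-stimulus motif starts exactly at stimulus onset."""
    fr = config.frame_rate
    onset_f = int(round(protocol.onset * fr))
    stim_end_f = int(round(max(ep.end for ep in protocol.epochs) * fr))
    total_f = int(round(config.total_s * fr))
    motifs: list[Motif] = []
    f = 0  # current frame index; integer bookkeeping keeps epochs aligned
    prev = None
    while f < total_f:
        if f < onset_f:
            kernel, boundary = config.baseline_kernel, min(onset_f, total_f)
        elif f < stim_end_f:
            kernel, boundary = config.stimulus_kernel, min(stim_end_f, total_f)
        else:
            kernel, boundary = config.baseline_kernel, total_f
        m = _draw_motif(rng, kernel, config.durations, prev, config.headcast_fast_fraction)
        dur_f = min(max(1, int(round(m.duration * fr))), boundary - f)
        motifs.append(Motif(m.label, dur_f / fr, m.subtype))
        prev = m.label
        f += dur_f
    return BehaviorScript(motifs=motifs)


def simulate_population(
    config: PopulationConfig, protocol: StimulusProtocol | None = None
) -> tuple[TrackSet, list[TruthInterval]]:
    """Simulate a population of larvae under one stimulus protocol."""
    protocol = protocol or default_protocol()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_larvae + 1)
    master = np.random.default_rng(children[0])
    tracks = []
    truth: list[TruthInterval] = []
    width = len(str(config.n_larvae - 1))
    for i in range(config.n_larvae):
        rng = np.random.default_rng(children[i + 1])
        script = _script_for_larva(rng, config, protocol)
        untracked_until = None
        if master.random() < config.dropout:
            untracked_until = protocol.onset + float(master.uniform(0.5, 3.0))
        larva_id = f"larva{i:0{width}d}"
        track, iv = simulate_larva(
            script,
            protocol=protocol,
            noise=config.noise,
            seed=int(rng.integers(2**31)),
            larva_id=larva_id,
            frame_rate=config.frame_rate,
            K=config.K,
            body_length_mm=config.body_length_mm,
            start_com=tuple(master.uniform(-20, 20, 2)),
            heading=float(master.uniform(0, 2 * np.pi)),
            untracked_until=untracked_until,
        )
        tracks.append(track)
        truth.extend(iv)
    return TrackSet(tracks=tracks, protocol=protocol, condition_label="synthetic"), truth


def truth_to_frame(truth: list[TruthInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(iv.larva_id, iv.start, iv.end, iv.label, iv.subtype) for iv in truth],
        columns=["larva_id", "start", "end", "label", "subtype"],
    )


# ---------------------------------------------------------------------------
# connectome


def _default_class_fractions() -> dict[str, float]:
    return {
        "sensory": 0.15,
        "local": 0.35,
        "brain": 0.10,
        "SEZ": 0.05,
        "ascending": 0.10,
        "descending": 0.10,
        "unreconstructed": 0.15,
    }


@dataclass
class ConnectomeParams:
    """Synthetic hemilateral-paired connectome around a target pair.

    ``class_fractions`` is the ground-truth share of the target's input
    synapses per presynaptic class (``unreconstructed`` becomes fragment
    neurons below the node threshold); ``constructed=True`` realizes those
    fractions exactly, otherwise synapse counts are drawn multinomially.
    """

    class_fractions: dict[str, float] = field(default_factory=_default_class_fractions)
    pairs_per_class: int = 3
    total_input_synapses: int = 1000
    constructed: bool = True
    fragment_fraction: float = 0.0  # extra fraction of non-sensory partners fragmented
    node_threshold: int = 1500
    n_motor_pairs: int = 4

    def __post_init__(self) -> None:
        fr = np.array(list(self.class_fractions.values()))
        if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
            raise ValueError("class fractions must be >= 0 and sum to 1")


def simulate_connectome(params: ConnectomeParams, seed: int = 0):
    """Build a synapse table with known input-fraction ground truth.

    Returns ``(SynapseTable, truth)`` where ``truth`` holds the class
    fractions of the target's input and the motor-pathway layout used by
    the distance analyses.
    """
    from .connectome import SynapseTable

    rng = np.random.default_rng(seed)
    neurons = []
    edges = []

    def add_pair(name, cls, node_count, neuromere="a1"):
        for side in ("l", "r"):
            other = "r" if side == "l" else "l"
            neurons.append(
                {
                    "id": f"{name}_{side}",
                    "name": name,
                    "cell_class": cls,
                    "side": side,
                    "partner_id": f"{name}_{other}",
                    "node_count": node_count,
                    "neuromere": neuromere,
                }
            )

    add_pair("target", "local", 12000)
    classes = list(params.class_fractions)
    partner_ids: dict[str, list[str]] = {}
    for cls in classes:
        partner_ids[cls] = []
        for j in range(params.pairs_per_class):
            name = f"{cls}{j}"
            if cls == "unreconstructed":
                nodes = int(rng.integers(100, params.node_threshold))
                real_cls = "local"
            else:
                nodes = int(rng.integers(params.node_threshold + 500, 20000))
                real_cls = cls
            if cls != "unreconstructed" and cls != "sensory" and rng.random() < params.fragment_fraction:
                nodes = int(rng.integers(100, params.node_threshold))
            add_pair(name, real_cls, nodes)
            partner_ids[cls].append(name)

    # distribute the target's input synapses over classes then over partners
    counts_per_class = {}
    if params.constructed:
        for cls in classes:
            counts_per_class[cls] = int(round(params.class_fractions[cls] * params.total_input_synapses))
        # fix rounding so totals match exactly
        diff = params.total_input_synapses - sum(counts_per_class.values())
        counts_per_class[classes[0]] += diff
    else:
        draw = rng.multinomial(params.total_input_synapses, [params.class_fractions[c] for c in classes])
        counts_per_class = dict(zip(classes, draw))
    for cls in classes:
        total = counts_per_class[cls]
        names = partner_ids[cls]
        base = total // len(names)
        rem = total - base * len(names)
        for j, name in enumerate(names):
            cnt = base + (1 if j < rem else 0)
            if cnt == 0:
                continue
            left = cnt // 2
            for side, c in (("l", left), ("r", cnt - left)):
                if c > 0:
                    edges.append(
                        {
                            "pre_id": f"{name}_{side}",
                            "post_id": "target_l",
                            "synapse_count": c,
                            "connection_type": "axo-dendritic",
                        }
                    )

    # downstream motor pathways: target -> premotor -> motor, one direct edge
    add_pair("premotor0", "local", 8000)
    add_pair("seed2", "local", 9000)
    for j in range(params.n_motor_pairs):
        add_pair(f"motor{j}", "motor", 15000)
    edges.append({"pre_id": "target_l", "post_id": "motor0_l", "synapse_count": 16, "connection_type": "axo-dendritic"})
    edges.append({"pre_id": "target_l", "post_id": "premotor0_l", "synapse_count": 8, "connection_type": "axo-dendritic"})
    edges.append({"pre_id": "premotor0_l", "post_id": "motor1_l", "synapse_count": 5, "connection_type": "axo-dendritic"})
    edges.append({"pre_id": "seed2_l", "post_id": "premotor0_l", "synapse_count": 4, "connection_type": "axo-axonic"})
    if params.n_motor_pairs > 2:
        edges.append({"pre_id": "seed2_l", "post_id": "motor2_l", "synapse_count": 6, "connection_type": "axo-dendritic"})

    table = SynapseTable(edges=pd.DataFrame(edges), neurons=pd.DataFrame(neurons))
    truth = {
        "target_ids": ["target_l", "target_r"],
        "class_fractions": {c: counts_per_class[c] / params.total_input_synapses for c in classes},
        "seeds": {"target": ["target_l", "target_r"], "seed2": ["seed2_l", "seed2_r"]},
    }
    return table, truth


# ---------------------------------------------------------------------------
# fluorescence


@dataclass
class FluorescenceParams:
    """Repeated-trial fluorescence traces with a known ΔF/F0 ground truth.

    The assay emulated is 5 s baseline, 5 s stimulation, 5 s recovery; the
    response ramps to a plateau whose true ΔF/F0 equals ``amplitude``.  A
    ``prestim_active_fraction`` of traces get an injected baseline
    transient (the ones the exclusion rule should remove).
    """

    n_larvae: int = 6
    reps_per_larva: int = 4
    baseline_f0: float = 100.0
    amplitude: float = 1.0
    noise_sd: float = 0.0
    prestim_active_fraction: float = 0.0
    prestim_transient: float = 0.5  # ΔF/F0 units
    dt: float = 0.5
    pre_s: float = 5.0
    stim_s: float = 5.0
    post_s: float = 5.0


def simulate_fluorescence(params: FluorescenceParams, seed: int = 0):
    """Returns ``(traces, truth)``: a list of FluorescenceTrace and a dict
    with the injected amplitude and the ids flagged pre-stimulus-active."""
    from .calcium import FluorescenceTrace

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.pre_s + params.stim_s + params.post_s, params.dt)
    onset = params.pre_s
    n_traces = params.n_larvae * params.reps_per_larva
    n_flagged = int(round(params.prestim_active_fraction * n_traces))
    flagged_idx = set(rng.choice(n_traces, size=n_flagged, replace=False).tolist()) if n_flagged else set()
    traces = []
    flagged_ids = []
    idx = 0
    for li in range(params.n_larvae):
        for rep in range(params.reps_per_larva):
            shape = np.zeros_like(t)
            in_stim = (t >= onset) & (t < onset + params.stim_s)
            rise = np.minimum((t[in_stim] - onset) / 1.0, 1.0)  # 1 s linear rise to plateau
            shape[in_stim] = rise
            post = t >= onset + params.stim_s
            shape[post] = np.exp(-(t[post] - (onset + params.stim_s)) / 2.0)
            f = params.baseline_f0 * (1.0 + params.amplitude * shape)
            if idx in flagged_idx:
                bump = (t < onset) & (t >= onset - 2 * params.dt)
                f = f + params.baseline_f0 * params.prestim_transient * bump
                flagged_ids.append((f"larva{li}", rep))
            if params.noise_sd > 0:
                f = f + rng.normal(0.0, params.noise_sd, f.shape)
            traces.append(
                FluorescenceTrace(
                    larva_id=f"larva{li}",
                    repetition=rep,
                    t=t.copy(),
                    f=f,
                    stim_onset=onset,
                    stim_duration=params.stim_s,
                )
            )
            idx += 1
    truth = {"amplitude": params.amplitude, "flagged": flagged_ids}
    return traces, truth
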