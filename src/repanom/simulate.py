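"""Synthetic repetitive-exercise sessions with ground truth.

The generator emulates a seated unilateral upper-limb exercise recorded at a
fixed frame rate: a latent phase oscillator advances through repetitions at
per-repetition speeds drawn from a slow/medium/fast mix, occasionally pausing
mid-cycle (phase rate drops to zero — a pause is recorded data, not a gap),
and every feature channel is a smooth band-limited function of that phase
(low-order Fourier series for scalars; closed loops on the unit sphere for
the two pointing-direction channels) plus subject-specific amplitude/offset
variation and additive Gaussian noise.

Anomalies are injected as *extra* repetitions carrying a labeled perturbation
window: transient oscillations (jerk, shake), amplitude scaling (overshoot,
undershoot, restricted range of motion), torso offsets (compensation), or a
blend toward an alternative movement template (path deviation).  The latent
phase is the single source of truth, so every downstream stage can be scored
against exact period boundaries and event windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import DEFAULT_SCHEMA, ChannelSchema, FeatureSequence

__all__ = [
    "AnomalySpec",
    "SimConfig",
    "LabeledSession",
    "SubjectParams",
    "draw_subject",
    "generate_session",
    "generate_cohort",
    "generate_benchmark",
    "count_true_periods",
    "true_boundaries",
    "DEFAULT_ANOMALY_SPEC",
    "ANOMALY_TYPES",
]

TWO_PI = 2.0 * np.pi

ANOMALY_TYPES = (
    "jerk",
    "shake",
    "overshoot",
    "undershoot",
    "restricted_rom",
    "compensation",
    "path_deviation",
)

# ---------------------------------------------------------------------------
# The exercise "prescription": fixed channel templates
# ---------------------------------------------------------------------------

# scalar channels, schema order: ts_ffx, ts_turn, ts_lfx, fa_pron, wr_x, wr_y, wr_z
# each entry: (offset a0, list of (harmonic k, cos coeff, sin coeff))
_SCALAR_TEMPLATES: dict[str, tuple[float, list[tuple[int, float, float]]]] = {
    "ts_ffx": (0.10, [(1, 0.0, 0.06), (2, 0.02, 0.0)]),
    "ts_turn": (0.00, [(1, 0.05, 0.0)]),
    "ts_lfx": (0.00, [(1, 0.014, 0.026)]),
    "fa_pron": (0.10, [(1, 0.258, 0.306), (2, 0.0, 0.08)]),
    "wr_x": (0.00, [(1, 0.25, 0.0), (2, 0.04, 0.0)]),
    "wr_y": (0.10, [(1, 0.0, 0.15), (2, 0.0, 0.03)]),
    "wr_z": (0.20, [(1, 0.059, 0.191)]),
}

# alternative templates for the path_deviation anomaly (a different movement)
_SCALAR_ALT: dict[str, tuple[float, list[tuple[int, float, float]]]] = {
    "ts_ffx": (0.16, [(1, 0.05, 0.0)]),
    "ts_turn": (0.06, [(1, 0.0, 0.05)]),
    "ts_lfx": (0.03, [(1, 0.03, 0.0)]),
    "fa_pron": (-0.05, [(1, -0.2, 0.15)]),
    "wr_x": (0.05, [(1, 0.0, 0.25)]),
    "wr_y": (0.05, [(1, 0.12, 0.0)]),
    "wr_z": (0.10, [(2, 0.0, 0.15)]),
}


def _sphere_basis(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = mu / np.linalg.norm(mu)
    helper = np.array([0.0, 1.0, 0.0])
    if abs(mu @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, mu)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    return mu, e1, e2


# sphere channels: loop mu + A(phi) e1 + B(phi) e2, renormalized to unit length
_SPHERE_TEMPLATES = {
    "ua_point": {"mu": np.array([0.3, -0.5, 0.8]), "r": (0.25, 0.15)},
    "fa_point": {"mu": np.array([0.2, 0.3, 0.9]), "r": (0.45, 0.30)},
}
_SPHERE_ALT = {
    "ua_point": {"r": (0.10, 0.28), "swap": True},
    "fa_point": {"r": (0.20, 0.50), "swap": True},
}


def _scalar_amp(name: str) -> float:
    _, harm = _SCALAR_TEMPLATES[name]
    return float(np.sqrt(sum(a * a + b * b for _, a, b in harm)))


def _eval_fourier(tmpl, phi: np.ndarray, amp: float = 1.0, off: float = 0.0) -> np.ndarray:
    a0, harm = tmpl
    y = np.full_like(phi, a0 + off, dtype=float)
    for k, a, b in harm:
        y += amp * (a * np.cos(k * phi) + b * np.sin(k * phi))
    return y


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnomalySpec:
    """One injected anomalous repetition."""

    type: str
    magnitude: float = 1.0  # relative strength (see per-type defaults below)
    duration_frac: float = 0.4  # fraction of the cycle covered by the event

    def __post_init__(self):
        if self.type not in ANOMALY_TYPES:
            raise ValueError(f"unknown anomaly type {self.type!r}")
        if not 0.0 < self.duration_frac <= 1.0:
            raise ValueError("duration_frac must be in (0, 1]")


# Default magnitudes: chosen once so events perturb the signal by roughly
# half to one channel amplitude — clearly present yet not caricatural.
DEFAULT_MAGNITUDES = {
    "jerk": 0.8,
    "shake": 0.6,
    "overshoot": 0.7,
    "undershoot": 0.6,
    "restricted_rom": 0.5,
    "compensation": 0.25,
    "path_deviation": 0.8,
}

#: Six anomalous repetitions mirroring the study protocol (jerks, shaking,
#: overshoot, undershoot, limited range of motion, torso compensation).
DEFAULT_ANOMALY_SPEC = tuple(
    AnomalySpec(t, DEFAULT_MAGNITUDES[t])
    for t in ("jerk", "shake", "overshoot", "undershoot", "restricted_rom", "compensation")
)


@dataclass(frozen=True)
class SimConfig:
    n_repetitions: int = 40
    frame_rate: float = 30.0
    nominal_periods: tuple[float, ...] = (1.5, 2.0, 3.0)  # seconds: fast/medium/slow
    period_jitter: float = 0.08  # per-repetition fractional jitter
    pause_probability: float = 0.05  # per repetition
    pause_duration: tuple[float, float] = (0.3, 1.0)  # seconds
    noise_sd: float = 0.02
    subject_offset_sd: float = 0.05
    subject_amplitude_sd: float = 0.10
    anomaly_spec: tuple[AnomalySpec, ...] = ()
    schema: ChannelSchema = field(default=DEFAULT_SCHEMA)

    def __post_init__(self):
        if not 0.0 <= self.pause_probability <= 1.0:
            raise ValueError("pause_probability must be in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if any(p <= 0 for p in self.nominal_periods):
            raise ValueError("nominal periods must be positive")
        if self.pause_duration[0] <= 0 or self.pause_duration[1] < self.pause_duration[0]:
            raise ValueError("invalid pause_duration range")
        if self.period_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise_sd must be non-negative")


@dataclass
class LabeledSession:
    features: FeatureSequence
    true_phase: np.ndarray  # wrapped to [0, 2*pi)
    true_phase_unwrapped: np.ndarray
    anomaly_events: list[tuple[int, int, str]]  # (start, end-exclusive, type)
    subject_id: str

    def __len__(self):
        return len(self.features)


@dataclass(frozen=True)
class SubjectParams:
    scalar_amp: dict[str, float]
    scalar_off: dict[str, float]
    sphere_amp: dict[str, float]
    sphere_tilt: dict[str, np.ndarray]  # small offsets added to mu before renormalizing


def draw_subject(config: SimConfig, rng: np.random.Generator) -> SubjectParams:
    """Between-subject variation: one amplitude factor and offset per channel."""
    scalar_amp, scalar_off, sphere_amp, sphere_tilt = {}, {}, {}, {}
    for ch in config.schema:
        a = float(np.clip(1.0 + config.subject_amplitude_sd * rng.standard_normal(), 0.5, 1.5))
        if ch.kind == "sphere3":
            sphere_amp[ch.name] = a
            sphere_tilt[ch.name] = config.subject_offset_sd * rng.standard_normal(3)
        else:
            scalar_amp[ch.name] = a
            scalar_off[ch.name] = float(config.subject_offset_sd * rng.standard_normal())
    return SubjectParams(scalar_amp, scalar_off, sphere_amp, sphere_tilt)


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------


def _phase_track(config: SimConfig, rng: np.random.Generator):
    """Latent phase per frame plus per-repetition bookkeeping.

    Returns (phase_unwrapped, rep_index, rep_slots) where rep_slots maps each
    repetition to its frame range.  All RNG draws are made for every
    repetition regardless of outcome, so two configs differing only in
    anomaly magnitudes consume identical random streams.
    """
    n_total = config.n_repetitions + len(config.anomaly_spec)
    fps = config.frame_rate
    phases, rep_idx, rep_slots = [], [], []
    phi0 = 0.0
    for r in range(n_total):
        period = float(rng.choice(np.asarray(config.nominal_periods)))
        period *= max(0.2, 1.0 + config.period_jitter * rng.standard_normal())
        n_frames = max(4, int(round(period * fps)))
        dphi = TWO_PI / n_frames
        local = phi0 + dphi * np.arange(n_frames)
        # pause draws happen unconditionally (stream stability)
        do_pause = rng.uniform() < config.pause_probability
        pause_len = int(round(rng.uniform(*config.pause_duration) * fps))
        pause_at = int(rng.integers(1, n_frames))
        if do_pause and pause_len > 0:
            local = np.concatenate([local[:pause_at], np.full(pause_len, local[pause_at - 1]), local[pause_at:]])
        start = len(phases)
        phases.extend(local.tolist())
        rep_idx.extend([r] * len(local))
        rep_slots.append((start, len(phases)))
        phi0 += TWO_PI
    return np.asarray(phases), np.asarray(rep_idx), rep_slots


def _event_weight(local_phase: np.ndarray, phi_a: float, phi_b: float) -> np.ndarray:
    """Raised-cosine window over the event's phase span (smooth on/offset)."""
    w = np.zeros_like(local_phase)
    inside = (local_phase >= phi_a) & (local_phase <= phi_b)
    span = max(phi_b - phi_a, 1e-9)
    x = (local_phase[inside] - phi_a) / span
    ramp = 0.1
    wi = np.ones_like(x)
    wi = np.where(x < ramp, 0.5 - 0.5 * np.cos(np.pi * x / ramp), wi)
    wi = np.where(x > 1 - ramp, 0.5 - 0.5 * np.cos(np.pi * (1 - x) / ramp), wi)
    w[inside] = wi
    return w


_WRIST = ("wr_x", "wr_y", "wr_z")
_TORSO = ("ts_ffx", "ts_turn", "ts_lfx")


def generate_session(
    config: SimConfig,
    subject_id: str = "S00",
    seed: int | np.random.Generator = 0,
    subject: SubjectParams | None = None,
) -> LabeledSession:
    """Generate one labeled session (n_repetitions normal + one extra
    repetition per anomaly_spec entry, inserted at random interior slots)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if subject is None:
        subject = draw_subject(config, rng)

    phi_un, rep_idx, rep_slots = _phase_track(config, rng)
    T = phi_un.size
    phi = np.mod(phi_un, TWO_PI)

    n_total = config.n_repetitions + len(config.anomaly_spec)
    # anomalous repetitions occupy random interior slots
    if config.anomaly_spec:
        if n_total < len(config.anomaly_spec) + 2:
            raise ValueError("too few repetitions to host the requested anomalies")
        slots = rng.choice(np.arange(1, n_total - 1), size=len(config.anomaly_spec), replace=False)
        slots = np.sort(slots)
    else:
        slots = np.array([], dtype=int)
    # per-event random window placement (drawn regardless of magnitude)
    window_starts = rng.uniform(0.0, 1.0, size=len(config.anomaly_spec))
    osc_phases = rng.uniform(0.0, TWO_PI, size=len(config.anomaly_spec))

    # clean pre-signal: scalars directly, spheres as in-plane coords (A, B)
    scalars: dict[str, np.ndarray] = {}
    spheres: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ch in config.schema:
        if ch.kind == "sphere3":
            r1, r2 = _SPHERE_TEMPLATES[ch.name]["r"]
            a = subject.sphere_amp[ch.name]
            A = a * (r1 * np.cos(phi) + 0.03 * np.cos(2 * phi))
            B = a * r2 * np.sin(phi)
            spheres[ch.name] = (A, B)
        else:
            scalars[ch.name] = _eval_fourier(
                _SCALAR_TEMPLATES[ch.name], phi,
                subject.scalar_amp[ch.name], subject.scalar_off[ch.name],
            )

    events: list[tuple[int, int, str]] = []
    for k, (slot, spec) in enumerate(zip(slots, config.anomaly_spec)):
        s0, s1 = rep_slots[slot]
        local = phi_un[s0:s1] - phi_un[s0]
        phi_a = float(window_starts[k]) * (TWO_PI * (1 - spec.duration_frac))
        phi_b = phi_a + TWO_PI * spec.duration_frac
        w = _event_weight(local, phi_a, phi_b)
        idx = np.nonzero(w > 0)[0]
        if idx.size == 0:
            continue
        t_local = np.arange(s1 - s0) / config.frame_rate
        m = spec.magnitude
        typ = spec.type
        if typ in ("jerk", "shake"):
            freq = 4.5 if typ == "jerk" else 7.0
            osc = np.sin(TWO_PI * freq * t_local + osc_phases[k]) * w
            for name in _WRIST + ("fa_pron",):
                scalars[name][s0:s1] += m * _scalar_amp(name) * osc
            for name, (A, B) in spheres.items():
                r1, r2 = _SPHERE_TEMPLATES[name]["r"]
                A[s0:s1] += m * 0.6 * r1 * osc
                B[s0:s1] += m * 0.6 * r2 * osc
        elif typ in ("overshoot", "undershoot", "restricted_rom"):
            gain = 1.0 + m * w if typ == "overshoot" else 1.0 - m * w
            targets = _WRIST + ("fa_pron",) if typ != "restricted_rom" else tuple(
                c.name for c in config.schema if c.kind == "scalar")
            for name in targets:
                a0 = _SCALAR_TEMPLATES[name][0] + subject.scalar_off[name]
                y = scalars[name][s0:s1]
                scalars[name][s0:s1] = a0 + gain * (y - a0)
            for name, (A, B) in spheres.items():
                A[s0:s1] *= gain
                B[s0:s1] *= gain
        elif typ == "compensation":
            for name in _TORSO:
                scalars[name][s0:s1] += m * w
        elif typ == "path_deviation":
            lam = m * w
            for name in scalars:
                alt = _eval_fourier(_SCALAR_ALT[name], local,
                                    subject.scalar_amp[name], subject.scalar_off[name])
                scalars[name][s0:s1] = (1 - lam) * scalars[name][s0:s1] + lam * alt
            for name, (A, B) in spheres.items():
                r1a, r2a = _SPHERE_ALT[name]["r"]
                a = subject.sphere_amp[name]
                A_alt = a * r1a * np.sin(local)
                B_alt = a * r2a * np.cos(local)
                A[s0:s1] = (1 - lam) * A[s0:s1] + lam * A_alt
                B[s0:s1] = (1 - lam) * B[s0:s1] + lam * B_alt
        if spec.magnitude > 0:
            events.append((s0 + int(idx[0]), s0 + int(idx[-1]) + 1, typ))

    # additive noise (always drawn; magnitude-independent stream)
    cols = []
    for ch in config.schema:
        if ch.kind == "sphere3":
            A, B = spheres[ch.name]
            A = A + config.noise_sd * rng.standard_normal(T)
            B = B + config.noise_sd * rng.standard_normal(T)
            mu, e1, e2 = _sphere_basis(
                _SPHERE_TEMPLATES[ch.name]["mu"] + subject.sphere_tilt[ch.name]
            )
            V = mu[None, :] + A[:, None] * e1[None, :] + B[:, None] * e2[None, :]
            V /= np.linalg.norm(V, axis=1, keepdims=True)
            cols.append(V)
        else:
            y = scalars[ch.name] + config.noise_sd * rng.standard_normal(T)
            cols.append(y[:, None])
    samples = np.concatenate(cols, axis=1)
    feats = FeatureSequence(samples, config.schema, config.frame_rate)
    return LabeledSession(feats, phi, phi_un, events, subject_id)


def generate_cohort(
    config: SimConfig,
    n_subjects: int,
    reps_per_subject: int | None = None,
    seed: int = 0,
) -> list[LabeledSession]:
    """One session per subject; subject-level parameters drawn once each."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if reps_per_subject is not None:
        config = replace(config, n_repetitions=reps_per_subject)
    root = np.random.SeedSequence(seed)
    sessions = []
    for s, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        subject = draw_subject(config, rng)
        sessions.append(generate_session(config, f"S{s:02d}", rng, subject))
    return sessions


def generate_benchmark(
    n_subjects: int = 12,
    train_reps: int = 25,
    test_normal_reps: int = 40,
    anomaly_spec: tuple[AnomalySpec, ...] = DEFAULT_ANOMALY_SPEC,
    seed: int = 0,
    **config_overrides,
) -> list[dict]:
    """Paired normal (training) and mixture (test) sessions per subject.

    Mirrors the study protocol: every subject contributes a normal session to
    model building and a mixture session of ``test_normal_reps`` normal
    repetitions with the anomalous repetitions of ``anomaly_spec`` inserted.
    """
    base = SimConfig(**config_overrides) if config_overrides else SimConfig()
    train_cfg = replace(base, n_repetitions=train_reps, anomaly_spec=())
    test_cfg = replace(base, n_repetitions=test_normal_reps, anomaly_spec=tuple(anomaly_spec))
    root = np.random.SeedSequence(seed)
    cohort = []
    for s, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        subject = draw_subject(train_cfg, rng)
        sid = f"S{s:02d}"
        cohort.append(
            {
                "subject_id": sid,
                "train": [generate_session(train_cfg, sid, rng, subject)],
                "test": [generate_session(test_cfg, sid, rng, subject)],
            }
        )
    return cohort


def boundary_deviations(session: LabeledSession, detected_starts: np.ndarray) -> np.ndarray:
    """Sample distance of detected period boundaries from latent-phase crossings.

    The unsupervised phase carries an arbitrary global offset, so detected
    boundaries sit at some fixed latent phase c rather than at 0.  c is
    estimated as the circular mean of the latent phase at the detected
    boundaries; deviations are measured against the latent crossings of c
    (with c = 0 this reduces to the plain 2*pi-crossing comparison).
    """
    detected = np.asarray(detected_starts, dtype=int)
    tp = session.true_phase_unwrapped
    ang = session.true_phase[detected]
    c = float(np.mod(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()), TWO_PI))
    crossings = np.nonzero(np.diff((tp - c) // TWO_PI) > 0)[0] + 1
    if crossings.size == 0:
        return np.full(detected.size, np.inf)
    return np.abs(detected[:, None] - crossings[None, :]).min(axis=1).astype(float)


def true_boundaries(session: LabeledSession) -> np.ndarray:
    """Sample indices where the latent phase wraps past 2*pi."""
    return np.nonzero(np.diff(session.true_phase_unwrapped // TWO_PI) > 0)[0] + 1


def count_true_periods(session: LabeledSession) -> int:
    """Completed repetitions (2*pi-crossings of the latent phase, + final round)."""
    return len(true_boundaries(session)) + 1
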