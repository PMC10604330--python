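"""Synthetic labelled joint-kinematic sessions.

Generates IMU-like sagittal-plane joint-angle streams (pelvis, right
hip, right knee, right ankle, in degrees) for a scripted activity
protocol, together with a per-sample ground-truth label track over the
seven posture/transition classes.  The signal model:

* standing / sitting: quasi-constant joint poses plus Gaussian sensor
  noise (knee near 0 deg standing, near 90 deg sitting);
* walking: quasi-periodic waveforms, one or two sinusoidal harmonics
  per joint with joint-specific phase offsets and a ~1.1 s stride;
* sitting down / standing up (``sd``/``su``): minimum-jerk (quintic)
  blends between the standing and sitting poses over about one second;
* starting / stopping walking (``stw``/``spw``): the oscillation
  amplitude ramps linearly up from, or down to, the standing pose while
  the gait phase runs continuously across the whole locomotion bout.

All randomness is driven by explicit seeds, so a session is a pure
function of (protocol, parameters, rate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .labels import Label, LABEL_NAMES, STEADY
from .protocol import ProtocolScript, make_protocol

JOINTS = ("pelvis", "hip", "knee", "ankle")
CSV_COLUMNS = ("time_s", "pelvis_deg", "hip_deg", "knee_deg", "ankle_deg", "label")


@dataclass(frozen=True)
class GaitParameters:
    """Morphology of the synthetic signals.

    Amplitudes are in degrees, the stride period in seconds.
    ``subject_scale`` multiplies every amplitude and pose excursion, so
    a cohort of subjects differs in overall range of motion.
    """

    stride_period: float = 1.1
    hip_amp: float = 25.0
    knee_amp: float = 60.0
    ankle_amp: float = 15.0
    pelvis_sway_amp: float = 4.0
    phase_offsets: tuple[float, float, float, float] = (0.5, 0.0, 0.4, 2.2)
    sit_knee_excursion: float = 90.0
    noise_sd: float = 0.5
    subject_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hip_amp", "knee_amp", "ankle_amp", "pelvis_sway_amp", "sit_knee_excursion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.stride_period <= 0:
            raise ValueError("stride_period must be > 0")


@dataclass(frozen=True)
class KinematicSession:
    """One subject session: angles, labels and the sampling rate."""

    rate: float
    angles: np.ndarray  # (n, 4) degrees, columns pelvis, hip, knee, ankle
    labels: np.ndarray  # (n,) int codes over the 7-class scheme
    subject_id: str = "S01"

    def __post_init__(self) -> None:
        if self.angles.ndim != 2 or self.angles.shape[1] != 4:
            raise ValueError("angles must be an (n, 4) matrix")
        if self.labels.shape != (self.angles.shape[0],):
            raise ValueError("labels must align with angles")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 6):
            raise ValueError("labels must be 7-class codes in 0..6")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


def _stand_pose(p: GaitParameters) -> np.ndarray:
    return p.subject_scale * np.array([2.0, 0.0, 0.0, 0.0])


def _sit_pose(p: GaitParameters) -> np.ndarray:
    k = p.sit_knee_excursion
    return p.subject_scale * np.array([15.0, 0.85 * k, k, 5.0])


def _walk_waveform(t: np.ndarray, p: GaitParameters) -> np.ndarray:
    """Joint angles (len(t), 4) at gait phase times ``t`` (s from bout start)."""
    s = p.subject_scale
    w = 2.0 * np.pi / p.stride_period
    ph_p, ph_h, ph_k, ph_a = p.phase_offsets
    pelvis = s * (2.0 + p.pelvis_sway_amp * np.sin(w * t + ph_p))
    hip = s * p.hip_amp * np.sin(w * t + ph_h)
    # knee: raised-cosine main flexion bump plus a second harmonic for
    # the characteristic double-knee-flexion shape
    knee = s * p.knee_amp * (0.5 * (1.0 - np.cos(w * t + ph_k)) + 0.15 * np.sin(2.0 * w * t + ph_k))
    ankle = s * p.ankle_amp * np.sin(w * t + ph_a)
    return np.stack([pelvis, hip, knee, ankle], axis=1)


def _quintic(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk blend: 0 -> 1 with zero velocity/acceleration at the ends."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def sample_boundaries(protocol: ProtocolScript, rate: float) -> np.ndarray:
    """Sample index of each segment boundary (len = n_segments + 1).

    Boundaries are cumulative-time rounded, so the runs exactly tile
    ``round(rate * total_time)`` samples.
    """
    edges = np.concatenate([[0.0], np.cumsum([d for _, d in protocol.timeline])])
    return np.rint(rate * edges).astype(int)


def synthesize_session(
    protocol: ProtocolScript,
    params: GaitParameters,
    rate: float = 100.0,
    subject_id: str = "S01",
) -> KinematicSession:
    """Render a protocol into a sampled, labelled joint-angle session."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    bounds = sample_boundaries(protocol, rate)
    if np.any(np.diff(bounds) < 1):
        raise ValueError(
            "sampling rate too low: a segment shorter than one sample "
            f"(rate={rate} Hz, shortest segment "
            f"{min(d for _, d in protocol.timeline):.3f} s)"
        )
    n = int(bounds[-1])
    t = np.arange(n) / rate
    angles = np.empty((n, 4))
    labels = np.empty(n, dtype=np.int8)

    stand = _stand_pose(params)
    sit = _sit_pose(params)

    # start time of the locomotion bout each stw/walk/spw segment belongs to
    bout_start: list[float] = []
    t0 = 0.0
    cum = 0.0
    prev_in_bout = False
    for lab, dur in protocol.timeline:
        in_bout = lab in (Label.STW, Label.WALKING, Label.SPW)
        if in_bout and not prev_in_bout:
            t0 = cum
        bout_start.append(t0)
        prev_in_bout = in_bout
        cum += dur

    seg_starts = np.concatenate([[0.0], np.cumsum([d for _, d in protocol.timeline])])[:-1]
    for i, (lab, dur) in enumerate(protocol.timeline):
        lo, hi = bounds[i], bounds[i + 1]
        ts = t[lo:hi]
        labels[lo:hi] = int(lab)
        if lab == Label.STANDING:
            angles[lo:hi] = stand
        elif lab == Label.SITTING:
            angles[lo:hi] = sit
        elif lab in (Label.SD, Label.SU):
            tau = np.clip((ts - seg_starts[i]) / dur, 0.0, 1.0)
            blend = _quintic(tau)[:, None]
            a, b = (stand, sit) if lab == Label.SD else (sit, stand)
            angles[lo:hi] = a + blend * (b - a)
        else:  # stw / walk / spw: standing pose + ramped gait deviation
            wav = _walk_waveform(ts - bout_start[i], params)
            if lab == Label.WALKING:
                ramp = np.ones(hi - lo)
            else:
                tau = np.clip((ts - seg_starts[i]) / dur, 0.0, 1.0)
                ramp = tau if lab == Label.STW else 1.0 - tau
            angles[lo:hi] = stand + ramp[:, None] * (wav - stand)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        angles = angles + rng.normal(0.0, params.noise_sd, size=angles.shape)
    return KinematicSession(rate=rate, angles=angles, labels=labels, subject_id=subject_id)


def cohort_seeds(seed: int, index: int) -> tuple[int, int, int]:
    """Deterministic (protocol, jitter, noise) seeds for subject ``index``."""
    state = np.random.SeedSequence([seed, index]).generate_state(3)
    return tuple(int(s) % (2**31) for s in state)  # type: ignore[return-value]


def jitter_parameters(base: GaitParameters, jitter: float, jitter_seed: int, noise_seed: int) -> GaitParameters:
    """Per-subject parameter variation: multiplicative factors ~ N(1, jitter)."""
    rng = np.random.default_rng(jitter_seed)

    def f() -> float:
        return float(np.clip(rng.normal(1.0, jitter), 0.7, 1.3)) if jitter > 0 else 1.0

    return replace(
        base,
        stride_period=base.stride_period * f(),
        hip_amp=base.hip_amp * f(),
        knee_amp=base.knee_amp * f(),
        ankle_amp=base.ankle_amp * f(),
        pelvis_sway_amp=base.pelvis_sway_amp * f(),
        subject_scale=base.subject_scale * f(),
        seed=noise_seed,
    )


def generate_cohort(
    n_subjects: int,
    base_params: GaitParameters = GaitParameters(),
    seed: int = 0,
    n_cycles: int = 6,
    rate: float = 100.0,
    jitter: float = 0.1,
    walk_duration_range: tuple[float, float] = (15.0, 20.0),
) -> list[KinematicSession]:
    """Simulate ``n_subjects`` independent subjects on the same protocol
    family, each with jittered gait parameters and their own walk/
    transition duration draws.  Fully reproducible from ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    sessions = []
    for i in range(n_subjects):
        proto_seed, jit_seed, noise_seed = cohort_seeds(seed, i)
        protocol = make_protocol(n_cycles, rng_seed=proto_seed, walk_duration_range=walk_duration_range)
        params = jitter_parameters(base_params, jitter, jit_seed, noise_seed)
        sessions.append(synthesize_session(protocol, params, rate, subject_id=f"S{i + 1:02d}"))
    return sessions


# ---------------------------------------------------------------------------
# I/O: tidy CSV sessions and YAML-compatible configs


def session_to_frame(session: KinematicSession) -> pd.DataFrame:
    df = pd.DataFrame(session.angles, columns=[f"{j}_deg" for j in JOINTS])
    df.insert(0, "time_s", session.times)
    df["label"] = [LABEL_NAMES[k] for k in session.labels]
    return df


def write_session_csv(session: KinematicSession, path) -> None:
    session_to_frame(session).to_csv(path, index=False)


def read_session_csv(path, subject_id: str = "S01") -> KinematicSession:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy()
    rate = float(np.round((len(t) - 1) / (t[-1] - t[0]))) if len(t) > 1 else 1.0
    name_to_code = {name: i for i, name in enumerate(LABEL_NAMES)}
    labels = np.array([name_to_code[s] for s in df["label"]], dtype=np.int8)
    angles = df[[f"{j}_deg" for j in JOINTS]].to_numpy(dtype=float)
    return KinematicSession(rate=rate, angles=angles, labels=labels, subject_id=subject_id)


def params_to_dict(p: GaitParameters) -> dict:
    return {
        "stride_period": p.stride_period,
        "hip_amp": p.hip_amp,
        "knee_amp": p.knee_amp,
        "ankle_amp": p.ankle_amp,
        "pelvis_sway_amp": p.pelvis_sway_amp,
        "phase_offsets": list(p.phase_offsets),
        "sit_knee_excursion": p.sit_knee_excursion,
        "noise_sd": p.noise_sd,
        "subject_scale": p.subject_scale,
        "seed": p.seed,
    }


def params_from_dict(d: dict) -> GaitParameters:
    d = dict(d)
    if "phase_offsets" in d:
        d["phase_offsets"] = tuple(d["phase_offsets"])
    return GaitParameters(**d)


def protocol_to_dict(p: ProtocolScript) -> dict:
    return {"timeline": [[lab.name.lower(), float(d)] for lab, d in p.timeline]}


def protocol_from_dict(d: dict) -> ProtocolScript:
    name_to_lab = {lab.name.lower(): lab for lab in Label}
    return ProtocolScript(timeline=tuple((name_to_lab[n], float(dur)) for n, dur in d["timeline"]))
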