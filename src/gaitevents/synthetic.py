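"""Synthetic treadmill-running cycles with known contact phases.

Every downstream stage (labelling, QC, model training, agreement statistics,
sensitivity analysis) is exercisable against ground truth that is known by
construction: each generated cycle records the exact contact start/end times
its vertical ground reaction force (vGRF) encodes.

Waveform family
---------------
The vGRF is a raised-cosine active peak spanning the contact phase, scaled so
that it crosses the 50 N contact threshold exactly at the recorded contact
boundaries, plus an optional short impact transient in early stance for
rearfoot strikers. Kinematic channels are smooth piecewise-cosine/spline
curves phase-locked to the contact phase: the foot and tibia move backwards at
belt speed during stance and swing forward between toe-off and the next
foot-strike; the foot centre of mass reaches its vertical apex exactly at the
cycle boundary (the segmentation convention). Cycles therefore start and end
mid-swing at the foot-height apex, where the foot vertical velocity crosses
zero from positive to negative.

Speeds modulate cycle duration (0.9 s at 2.5 m/s down to 0.6 s at 5 m/s) and
duty factor (contact fraction 0.45 down to 0.30) inversely, which is the
physiological trend in distance running.

Ground truth is constructed first; measurement noise is added afterwards and
never touches the truth record. Contact boundary times are snapped to the
force sampling grid so that thresholding the noise-free vGRF at 50 N recovers
them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .cycles import FEATURE_CHANNELS, MAX_CYCLE_LEN, FeatureSequence, GaitCycle, nearest_frame
from .events import StepEvents
from .signals import TimeSeries, lowpass_zero_lag

__all__ = [
    "SyntheticConfig",
    "SyntheticCycleTruth",
    "SyntheticDataset",
    "CycleTooLongError",
    "generate_cycle",
    "generate_dataset",
    "generate_trial",
    "truth_events",
]

#: All kinematic channels the generator produces (mocap rate).
KINEMATIC_CHANNELS = FEATURE_CHANNELS + ("hip_angle", "knee_angle")

_STRIKE_PATTERNS = ("rearfoot", "midfoot", "forefoot")
# participant-level foot-strike angle ranges (deg): positive = dorsiflexed rearfoot landing
_FSA_RANGE = {"rearfoot": (8.0, 20.0), "midfoot": (-3.0, 5.0), "forefoot": (-18.0, -6.0)}


class CycleTooLongError(ValueError):
    """A requested cycle would exceed the fixed padded length of 200 mocap frames."""


@dataclass
class SyntheticConfig:
    """Generation conditions for a synthetic treadmill-running dataset.

    ``noise_sd`` is either a single relative level (Gaussian SD as a fraction
    of each kinematic channel's RMS) or a mapping of channel name to absolute
    SD in channel units. ``vgrf_noise_sd`` (N) is kept separate and defaults to
    zero: the QC rule operates on frame-to-frame force differences, which
    broadband noise at kilohertz force rates would dominate.
    """

    n_participants: int = 14
    cycles_per_participant: int = 25
    speed_range: tuple[float, float] = (2.5, 5.0)
    strike_mix: tuple[float, float, float] = (0.7, 0.1, 0.2)  # rearfoot, midfoot, forefoot
    incline_range: tuple[float, float] = (0.0, 0.0)
    mocap_rate: float = 200.0
    force_rate: float = 1000.0
    noise_sd: float | Mapping[str, float] = 0.0
    vgrf_noise_sd: float = 0.0
    qc_violation_rate: float = 0.05
    n_datasets: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.strike_mix) - 1.0) > 1e-9:
            raise ValueError(f"strike_mix must sum to 1, got {sum(self.strike_mix)}")
        ratio = self.force_rate / self.mocap_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("force_rate must be an integer multiple of mocap_rate")
        if not 0.0 <= self.qc_violation_rate <= 1.0:
            raise ValueError("qc_violation_rate must lie in [0, 1]")
        if self.speed_range[0] > self.speed_range[1]:
            raise ValueError("speed_range must be (low, high)")
        if self.n_participants < 1 or self.cycles_per_participant < 1:
            raise ValueError("need at least one participant and one cycle")


@dataclass(frozen=True)
class SyntheticCycleTruth:
    """Exact ground truth for one generated cycle.

    Contact times are seconds from cycle start and, when produced by
    `generate_dataset`, lie exactly on the force sampling grid.
    """

    cycle_duration: float
    contact_start_time: float
    contact_end_time: float
    speed: float
    strike_pattern: str
    foot_strike_angle: float
    incline: float = 0.0
    has_qc_violation: bool = False
    body_mass: float = 70.0

    def __post_init__(self) -> None:
        if not 0.0 < self.contact_start_time < self.contact_end_time < self.cycle_duration:
            raise ValueError(
                "need 0 < contact_start < contact_end < cycle_duration, got "
                f"({self.contact_start_time}, {self.contact_end_time}, {self.cycle_duration})"
            )
        duty = (self.contact_end_time - self.contact_start_time) / self.cycle_duration
        if not 0.2 <= duty <= 0.5:
            raise ValueError(f"duty factor {duty:.3f} outside [0.2, 0.5]")
        if self.strike_pattern not in _STRIKE_PATTERNS:
            raise ValueError(f"unknown strike pattern {self.strike_pattern!r}")

    @property
    def duty_factor(self) -> float:
        return (self.contact_end_time - self.contact_start_time) / self.cycle_duration


def truth_events(truth: SyntheticCycleTruth, mocap_rate: float) -> StepEvents:
    """Ground-truth contact times mapped to nearest mocap frames (round-half-up)."""
    return StepEvents(
        foot_strike_index=nearest_frame(truth.contact_start_time, mocap_rate),
        toe_off_index=nearest_frame(truth.contact_end_time, mocap_rate),
        rate=mocap_rate,
    )


@dataclass
class SyntheticDataset:
    """Generated cycles with their aligned ground-truth records."""

    cycles: list[GaitCycle]
    truths: list[SyntheticCycleTruth]
    config: SyntheticConfig

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self) -> Iterator[GaitCycle]:
        return iter(self.cycles)


# ---------------------------------------------------------------------------
# waveform construction


def _swing_phase(t: np.ndarray, truth: SyntheticCycleTruth) -> np.ndarray:
    """Normalised swing phase: 0 at toe-off, 1 at next foot-strike; >= 1 in stance."""
    T = truth.cycle_duration
    S = T - (truth.contact_end_time - truth.contact_start_time)
    xi = np.mod(t - truth.contact_end_time, T) / S
    # stance samples map into (1, T/S]; clamp so callers can test xi < 1 for swing
    return xi


def _foot_lift_profile(xi: np.ndarray, xi_apex: float) -> tuple[np.ndarray, np.ndarray]:
    """Foot-height bump over the swing and its derivative wrt xi.

    Rises 0 -> 1 on [0, xi_apex] and falls 1 -> 0 on [xi_apex, 1] with zero
    slope at both ends and at the apex, which sits exactly on the cycle
    boundary so the segmentation convention (apex-to-apex) holds.
    """
    z = np.zeros_like(xi)
    dz = np.zeros_like(xi)
    up = xi < xi_apex
    down = (xi >= xi_apex) & (xi < 1.0)
    z[up] = 0.5 * (1 - np.cos(np.pi * xi[up] / xi_apex))
    dz[up] = 0.5 * np.pi / xi_apex * np.sin(np.pi * xi[up] / xi_apex)
    u = (xi[down] - xi_apex) / (1.0 - xi_apex)
    z[down] = 0.5 * (1 + np.cos(np.pi * u))
    dz[down] = -0.5 * np.pi / (1.0 - xi_apex) * np.sin(np.pi * u)
    return z, dz


def _periodic_spline(T: float, knots: list[tuple[float, float]]) -> CubicSpline:
    ts = np.array([k[0] % T for k in knots])
    vs = np.array([k[1] for k in knots])
    order = np.argsort(ts)
    ts, vs = ts[order], vs[order]
    ts = np.append(ts, ts[0] + T)
    vs = np.append(vs, vs[0])
    return CubicSpline(ts, vs, bc_type="periodic")


def _kinematic_waveforms(
    truth: SyntheticCycleTruth, t: np.ndarray, lift: float | None = None
) -> dict[str, np.ndarray]:
    """Noise-free kinematic channels (plus foot height) on time grid ``t``.

    ``lift`` fixes the swing foot-COM lift (m); trials spanning several cycles
    share one lift so every cycle boundary is the trial-wide local maximum.
    """
    T, ts_c, te_c = truth.cycle_duration, truth.contact_start_time, truth.contact_end_time
    L = te_c - ts_c
    S = T - L
    v = truth.speed
    fsa = truth.foot_strike_angle
    xi = _swing_phase(t, truth)
    swing = xi < 1.0
    xi_apex = (T - te_c) / S  # cycle boundary position within the swing

    out: dict[str, np.ndarray] = {}

    # anteroposterior velocities: -belt speed in stance, forward peak mid-swing
    bump = np.zeros_like(t)
    bump[swing] = np.sin(np.pi * xi[swing]) ** 2
    out["foot_ap_vel"] = -v + 3.4 * v * bump
    bump_t = np.zeros_like(t)
    bump_t[swing] = np.sin(np.pi * np.clip(xi[swing], 0, 1) ** 0.85) ** 2
    out["tibia_ap_vel"] = -v + 2.4 * v * bump_t

    # foot height and vertical velocity; apex exactly at the cycle boundary
    if lift is None:
        lift = 0.10 + 0.02 * v  # metres of foot-COM lift during swing
    z, dz = _foot_lift_profile(xi, xi_apex)
    out["foot_z"] = lift * z
    vz = lift * dz / S
    vz = vz - vz.mean()  # remove sampling-induced drift; periodic channel integrates to 0
    out["foot_vert_vel"] = vz

    # sagittal joint angles: periodic splines through physiologic keypoints,
    # phase-locked to foot-strike and toe-off. Dorsiflexion positive.
    tilt = 0.4 * truth.incline
    ankle = _periodic_spline(
        T,
        [
            (ts_c, fsa + tilt),
            (ts_c + 0.45 * L, 0.2 * fsa + 12.0 + tilt),
            (ts_c + 0.8 * L, -5.0 + tilt),
            (te_c, -18.0 + tilt),
            (te_c + 0.35 * S, 0.0 + tilt),
            (te_c + 0.7 * S, 0.5 * fsa + 3.0 + tilt),
        ],
    )
    out["ankle_angle"] = ankle(t % T)
    hip = _periodic_spline(
        T,
        [
            (ts_c, 28.0 + tilt),
            (ts_c + 0.6 * L, 2.0 + tilt),
            (te_c, -8.0 - v + tilt),
            (te_c + 0.55 * S, 32.0 + 1.5 * v + tilt),
        ],
    )
    out["hip_angle"] = hip(t % T)
    knee = _periodic_spline(
        T,
        [
            (ts_c, 12.0 + 0.1 * fsa),
            (ts_c + 0.45 * L, 38.0),
            (te_c, 14.0),
            (te_c + 0.45 * S, 70.0 + 5.0 * v),
        ],
    )
    out["knee_angle"] = knee(t % T)
    return out


def _vgrf_waveform(truth: SyntheticCycleTruth, t: np.ndarray) -> np.ndarray:
    """Noise-free vGRF: raised-cosine active peak crossing 50 N exactly at the
    contact boundaries, plus an impact transient for rearfoot strikers."""
    ts_c, te_c = truth.contact_start_time, truth.contact_end_time
    L = te_c - ts_c
    fmax = truth.body_mass * 9.81 * (1.7 + 0.25 * truth.speed)
    # widen the bell support so F(contact boundary) == 50 N; the tiny surplus
    # keeps the boundary samples robustly on the contact side of the threshold
    # under floating-point evaluation
    q = np.arcsin(np.sqrt((50.0 + 1e-9) / fmax)) / np.pi
    W = L / (1.0 - 2.0 * q)
    delta = q * W
    f = np.zeros_like(t)
    u = (t - ts_c + delta) / W
    on = (u > 0) & (u < 1)
    f[on] = fmax * np.sin(np.pi * u[on]) ** 2
    if truth.strike_pattern == "rearfoot":
        # early-stance impact transient, confined strictly inside the contact phase
        t0, w = ts_c + 0.02 * L, 0.12 * L
        ui = (t - t0) / w
        oni = (ui > 0) & (ui < 1)
        f[oni] += 0.30 * fmax * np.sin(np.pi * ui[oni]) ** 2
    return f


def _inject_qc_violation(f: np.ndarray, force_rate: float) -> np.ndarray:
    """Insert a small positive step into the terminal 100->50 N descent.

    Emulates the aberrant plateaus/bumps instrumented treadmills show near
    toe-off. The modified samples stay within (50, 100) N so the contact
    phase and the QC interval anchors are unchanged, while the step's
    loading rate exceeds the 200 N/s rejection bound.
    """
    f = f.copy()
    peak = int(np.argmax(f))
    tail = np.flatnonzero((f[peak:] < 92.0) & (f[peak:] > 58.0)) + peak
    if tail.size < 3:  # extremely short descent; place it anyway on the last viable frame
        raise ValueError("unloading tail too short to host a QC violation")
    k = int(tail[tail.size // 3])
    step = 400.0 / force_rate  # 400 N/s, comfortably above the 200 N/s bound
    f[k + 1] = f[k] + step
    return f


def _noise_sd_for(channel: str, values: np.ndarray, noise_sd) -> float:
    if isinstance(noise_sd, Mapping):
        return float(noise_sd.get(channel, 0.0))
    rms = float(np.sqrt(np.mean(values**2)))
    return float(noise_sd) * rms


def generate_cycle(
    config: SyntheticConfig,
    truth: SyntheticCycleTruth,
    rng: np.random.Generator | None = None,
    *,
    participant_id: str = "",
    dataset_id: str = "default",
    cycle_id: str = "",
) -> GaitCycle:
    """Generate one labelled gait cycle from its ground-truth record.

    The noise-free vGRF is >= 50 N exactly on
    ``[contact_start_time, contact_end_time]``; kinematic channels are smooth
    and phase-locked to the contact phase, with the ankle dorsiflexed
    (positive) at contact for rearfoot strikers and plantar-flexed (negative)
    for forefoot strikers. Noise, when configured, is added after the ground
    truth is fixed and the noisy kinematics are re-smoothed with the standard
    10 Hz zero-lag filter (emulating preprocessed mocap channels).

    Raises
    ------
    CycleTooLongError
        If the cycle would exceed 200 mocap frames.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_mocap = round(truth.cycle_duration * config.mocap_rate)
    if n_mocap > MAX_CYCLE_LEN:
        raise CycleTooLongError(
            f"cycle of {n_mocap} mocap frames exceeds the padded length {MAX_CYCLE_LEN} "
            f"({truth.cycle_duration:.3f} s at {config.mocap_rate:g} Hz)"
        )
    ratio = round(config.force_rate / config.mocap_rate)
    t_m = np.arange(n_mocap) / config.mocap_rate
    t_f = np.arange(n_mocap * ratio) / config.force_rate

    kin = _kinematic_waveforms(truth, t_m)
    f = _vgrf_waveform(truth, t_f)
    if truth.has_qc_violation:
        f = _inject_qc_violation(f, config.force_rate)

    # measurement noise, after ground-truth construction
    noisy = False
    for name in KINEMATIC_CHANNELS:
        sd = _noise_sd_for(name, kin[name], config.noise_sd)
        if sd > 0:
            kin[name] = kin[name] + rng.normal(0.0, sd, size=n_mocap)
            noisy = True
    if noisy:
        for name in KINEMATIC_CHANNELS:
            kin[name] = lowpass_zero_lag(
                TimeSeries(kin[name], config.mocap_rate, name)
            ).values
    if config.vgrf_noise_sd > 0:
        f = np.clip(f + rng.normal(0.0, config.vgrf_noise_sd, size=f.size), 0.0, None)

    feats = np.column_stack([kin[name] for name in FEATURE_CHANNELS])
    return GaitCycle(
        features=FeatureSequence(feats, config.mocap_rate),
        vgrf=TimeSeries(f, config.force_rate, "vgrf"),
        participant_id=participant_id,
        dataset_id=dataset_id,
        cycle_id=cycle_id,
        speed=truth.speed,
        incline=truth.incline,
        foot_strike_angle=truth.foot_strike_angle,
        strike_pattern=truth.strike_pattern,
        angles={
            "hip_angle": kin["hip_angle"].copy(),
            "knee_angle": kin["knee_angle"].copy(),
            "ankle_angle": kin["ankle_angle"].copy(),
        },
    )


def _draw_truth(
    config: SyntheticConfig,
    rng: np.random.Generator,
    speed: float,
    strike_pattern: str,
    fsa_mean: float,
    incline: float,
    body_mass: float,
) -> SyntheticCycleTruth:
    """One cycle's ground truth; durations snapped to the mocap grid and contact
    times snapped to the force grid, so frame mapping is exact."""
    u = (speed - 2.5) / 2.5
    T = float(np.clip(0.9 - 0.3 * u + rng.normal(0.0, 0.02), 0.6, 0.9))
    T = round(T * config.mocap_rate) / config.mocap_rate
    duty = float(np.clip(0.45 - 0.15 * u + rng.normal(0.0, 0.012), 0.28, 0.47))
    start_frac = 0.22 + rng.normal(0.0, 0.012)
    ts_c = round(start_frac * T * config.force_rate) / config.force_rate
    te_c = round((start_frac + duty) * T * config.force_rate) / config.force_rate
    return SyntheticCycleTruth(
        cycle_duration=T,
        contact_start_time=ts_c,
        contact_end_time=te_c,
        speed=speed,
        strike_pattern=strike_pattern,
        foot_strike_angle=float(fsa_mean + rng.normal(0.0, 1.0)),
        incline=incline,
        has_qc_violation=bool(rng.random() < config.qc_violation_rate),
        body_mass=body_mass,
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full multi-participant dataset, deterministic given the seed.

    Participants carry distinct identifiers and constant metadata (dataset,
    strike pattern, body mass); the strike-pattern mix follows
    ``config.strike_mix`` as closely as rounding allows (largest-remainder
    allocation of participants to patterns).
    """
    rng = np.random.default_rng(config.seed)
    # largest-remainder allocation of participants to strike patterns
    quotas = np.array(config.strike_mix) * config.n_participants
    counts = np.floor(quotas).astype(int)
    rem = config.n_participants - counts.sum()
    for i in np.argsort(quotas - counts)[::-1][:rem]:
        counts[i] += 1
    patterns = [p for p, c in zip(_STRIKE_PATTERNS, counts) for _ in range(c)]
    patterns = [patterns[i] for i in rng.permutation(len(patterns))]

    cycles: list[GaitCycle] = []
    truths: list[SyntheticCycleTruth] = []
    lo, hi = config.speed_range
    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        ds = f"D{p % config.n_datasets}"
        pattern = patterns[p]
        fsa_mean = rng.uniform(*_FSA_RANGE[pattern])
        mass = float(np.clip(rng.normal(70.0, 8.0), 50.0, 95.0))
        pref_speed = rng.uniform(lo, hi)
        for k in range(config.cycles_per_participant):
            speed = float(np.clip(pref_speed + rng.normal(0.0, 0.15), lo, hi))
            incline = float(rng.uniform(*config.incline_range))
            truth = _draw_truth(config, rng, speed, pattern, fsa_mean, incline, mass)
            cycle = generate_cycle(
                config,
                truth,
                rng,
                participant_id=pid,
                dataset_id=ds,
                cycle_id=f"{pid}:{k:03d}",
            )
            cycles.append(cycle)
            truths.append(truth)
    return SyntheticDataset(cycles=cycles, truths=truths, config=config)


def generate_trial(
    config: SyntheticConfig,
    truths: list[SyntheticCycleTruth],
    rng: np.random.Generator | None = None,
) -> tuple[TimeSeries, dict[str, TimeSeries], TimeSeries]:
    """Concatenate cycles into one continuous noise-free trial for segmentation.

    Returns the foot-COM vertical position, the kinematic channel dictionary
    and the vGRF trace. The trial starts at a foot-height apex and a short
    descending tail is appended after the final apex so that every interior
    cycle boundary is a detectable local maximum.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ratio = round(config.force_rate / config.mocap_rate)
    # one shared lift so every cycle boundary is the trial-wide maximum
    lift = 0.10 + 0.02 * float(np.mean([tr.speed for tr in truths]))
    chans: dict[str, list[np.ndarray]] = {name: [] for name in KINEMATIC_CHANNELS}
    zs: list[np.ndarray] = []
    fs: list[np.ndarray] = []
    for truth in truths:
        n_mocap = round(truth.cycle_duration * config.mocap_rate)
        if n_mocap > MAX_CYCLE_LEN:
            raise CycleTooLongError(f"cycle of {n_mocap} mocap frames exceeds {MAX_CYCLE_LEN}")
        t_m = np.arange(n_mocap) / config.mocap_rate
        t_f = np.arange(n_mocap * ratio) / config.force_rate
        kin = _kinematic_waveforms(truth, t_m, lift=lift)
        zs.append(kin.pop("foot_z"))
        for name in KINEMATIC_CHANNELS:
            chans[name].append(kin[name])
        fs.append(_vgrf_waveform(truth, t_f))
    # closing tail: first few samples of a repeat of the last cycle, so the
    # final apex has a descending right neighbour
    tail = min(5, len(zs[-1]))
    last = truths[-1]
    t_m = np.arange(tail) / config.mocap_rate
    kin_tail = _kinematic_waveforms(last, t_m, lift=lift)
    zs.append(kin_tail.pop("foot_z"))
    for name in KINEMATIC_CHANNELS:
        chans[name].append(kin_tail[name])
    fs.append(_vgrf_waveform(last, np.arange(tail * ratio) / config.force_rate))

    foot_z = TimeSeries(np.concatenate(zs), config.mocap_rate, "foot_z")
    channels = {
        name: TimeSeries(np.concatenate(parts), config.mocap_rate, name)
        for name, parts in chans.items()
    }
    vgrf = TimeSeries(np.concatenate(fs), config.force_rate, "vgrf")
    return foot_z, channels, vgrf
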