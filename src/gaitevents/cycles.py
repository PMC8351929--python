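"""Gait-cycle construction: segmentation, force-based labelling, QC, batching, splits.

Continuous treadmill trials are divided into gait cycles at successive apices
of the foot centre-of-mass vertical position. Within each cycle the contact
phase is identified on the raw vertical ground reaction force (vGRF) with a
50 N threshold (contact: vGRF >= 50 N), after discarding cycles whose terminal
unloading (the drop from 100 N to 50 N) contains a positive loading rate of
200 N/s or more — an artefact of treadmill deck vibration near toe-off.
Model inputs are z-scored with training-set statistics only and zero-padded at
the start to a fixed length of 200 frames; data splits operate on participants,
never on cycles, so no runner contributes to more than one partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .events import NoContactError, StepEvents, contiguous_runs
from .signals import TimeSeries

__all__ = [
    "FEATURE_CHANNELS",
    "MAX_CYCLE_LEN",
    "FeatureSequence",
    "ContactLabelSequence",
    "GaitCycle",
    "Scaler",
    "PaddedBatch",
    "QCResult",
    "Split",
    "segment_cycles",
    "qc_filter",
    "label_contact",
    "standardise_and_pad",
    "split_participants",
    "nearest_frame",
]

#: Fixed model-input channel order.
FEATURE_CHANNELS = ("tibia_ap_vel", "ankle_angle", "foot_ap_vel", "foot_vert_vel")

#: Fixed padded sequence length; accommodates a full stride at any tested speed.
MAX_CYCLE_LEN = 200

#: Contact threshold on the raw vGRF, newtons.
CONTACT_THRESHOLD_N = 50.0

#: QC rule bounds: the unloading interval runs from the 100 N down-crossing to
#: the 50 N down-crossing; any frame-to-frame loading rate >= 200 N/s rejects.
QC_UPPER_N = 100.0
QC_LOWER_N = 50.0
QC_MAX_RATE_N_PER_S = 200.0


def nearest_frame(time_s: float, rate: float) -> int:
    """Nearest frame index to a time, round-half-up on ``time * rate``."""
    return int(np.floor(time_s * rate + 0.5))


@dataclass
class FeatureSequence:
    """Kinematic model input for one cycle: (length x 4) in `FEATURE_CHANNELS` order."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_CHANNELS):
            raise ValueError(
                f"feature matrix must be (length, {len(FEATURE_CHANNELS)}), "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class ContactLabelSequence:
    """Binary ground-truth contact labels at mocap rate: one contiguous run of 1s."""

    labels: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.labels = self.labels.astype(np.int8)
        runs = contiguous_runs(self.labels.astype(bool))
        if len(runs) != 1:
            raise ValueError(f"expected exactly one contact run, found {len(runs)}")

    def __len__(self) -> int:
        return len(self.labels)

    def to_events(self) -> StepEvents:
        start, end = contiguous_runs(self.labels.astype(bool))[0]
        return StepEvents(foot_strike_index=start, toe_off_index=end, rate=self.rate)


@dataclass
class GaitCycle:
    """One gait cycle: kinematic features, force trace, labels and metadata."""

    features: FeatureSequence
    vgrf: TimeSeries | None = None
    labels: ContactLabelSequence | None = None
    participant_id: str = ""
    dataset_id: str = "default"
    cycle_id: str = ""
    speed: float = float("nan")
    incline: float = 0.0
    foot_strike_angle: float = float("nan")
    strike_pattern: str = ""
    accepted: bool = True
    # extra sagittal angle channels at mocap rate (hip/knee/ankle), for sensitivity analysis
    angles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vgrf is not None:
            dt = abs(self.vgrf.duration - len(self.features) / self.features.rate)
            if dt > 1.0 / self.features.rate + 1e-9:
                raise ValueError(
                    f"cycle {self.cycle_id!r}: vGRF duration {self.vgrf.duration:.4f} s "
                    f"differs from feature duration by more than one mocap frame"
                )

    @property
    def mocap_rate(self) -> float:
        return self.features.rate


@dataclass
class Scaler:
    """Per-channel z-score parameters fitted on training data only."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


@dataclass
class PaddedBatch:
    """Model-ready batch: z-scored inputs zero-padded at the start to 200 frames.

    ``mask`` is 1 on real samples and 0 on padding; padded input positions are
    exactly zero. ``targets`` carry the binary contact labels (0 on padding).
    """

    inputs: np.ndarray  # (n_cycles, 200, 4)
    targets: np.ndarray  # (n_cycles, 200)
    mask: np.ndarray  # (n_cycles, 200)
    scaler: Scaler
    rate: float
    cycle_ids: list[str] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return self.inputs.shape[0]

    def lengths(self) -> np.ndarray:
        return self.mask.sum(axis=1).astype(int)


@dataclass(frozen=True)
class QCResult:
    """Outcome of the loading-rate quality-control rule for one cycle."""

    accepted: bool
    max_rate: float  # N/s, nan when the interval is absent
    interval: tuple[int, int] | None  # force-frame bounds of the 100->50 N drop
    note: str = ""


def segment_cycles(
    foot_com_vertical: TimeSeries,
    channels: dict[str, TimeSeries],
    vgrf: TimeSeries | None = None,
    *,
    prominence: float | None = None,
    min_distance: int | None = None,
    participant_id: str = "",
    dataset_id: str = "default",
    **metadata,
) -> list[GaitCycle]:
    """Divide a continuous trial into gait cycles at foot-COM vertical apices.

    Cycle ``k`` spans ``[apex_k, apex_{k+1})``. Apices are local maxima of the
    foot-COM vertical position; a plateau of equal maxima breaks the tie at its
    first index. ``channels`` must contain the four `FEATURE_CHANNELS` at the
    same rate and length as ``foot_com_vertical``; any further channels are
    kept as auxiliary angle channels. ``vgrf`` may be sampled at an integer
    multiple of the mocap rate and is sliced in proportion.

    Returns an empty list (with a warning) when fewer than two apices exist.
    """
    pos = foot_com_vertical.values
    n = len(pos)
    for name in FEATURE_CHANNELS:
        if name not in channels:
            raise ValueError(f"missing required channel {name!r}")
    for name, ch in channels.items():
        if len(ch) != n or ch.rate != foot_com_vertical.rate:
            raise ValueError(f"channel {name!r} does not share the trial time base")
    kwargs = {}
    if prominence is not None:
        kwargs["prominence"] = prominence
    if min_distance is not None:
        kwargs["distance"] = min_distance
    _, props = find_peaks(pos, plateau_size=(1, None), **kwargs)
    apices = props["left_edges"]  # first-of-equal-maxima tie-break
    if len(apices) < 2:
        warnings.warn("fewer than two foot-COM apices found; no cycles segmented")
        return []

    ratio = 1.0
    if vgrf is not None:
        ratio = vgrf.rate / foot_com_vertical.rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("vGRF rate must be an integer multiple of the mocap rate")
        ratio = round(ratio)

    cycles = []
    for k in range(len(apices) - 1):
        a, b = int(apices[k]), int(apices[k + 1])
        feats = np.column_stack([channels[name].values[a:b] for name in FEATURE_CHANNELS])
        extra = {
            name: ch.values[a:b].copy()
            for name, ch in channels.items()
            if name not in FEATURE_CHANNELS
        }
        fv = None
        if vgrf is not None:
            fv = TimeSeries(vgrf.values[a * ratio : b * ratio], vgrf.rate, vgrf.name)
        cycles.append(
            GaitCycle(
                features=FeatureSequence(feats, foot_com_vertical.rate),
                vgrf=fv,
                participant_id=participant_id,
                dataset_id=dataset_id,
                cycle_id=f"{participant_id}:{k}" if participant_id else str(k),
                angles=extra,
                **metadata,
            )
        )
    return cycles


def qc_filter(vgrf: TimeSeries) -> QCResult:
    """Apply the terminal-unloading loading-rate rule to one cycle's vGRF.

    The inspected interval runs from the last downward crossing of 100 N to the
    subsequent downward crossing of 50 N (the unloading tail approaching
    toe-off). If any frame-to-frame loading rate within it is >= 200 N/s the
    cycle is rejected. A trace that never reaches 100 N is accepted with an
    "interval absent" note (the rule is inapplicable).
    """
    f = vgrf.values
    below_upper = f < QC_UPPER_N
    # last index i with f[i] >= 100 and f[i+1] < 100
    cross = np.flatnonzero(~below_upper[:-1] & below_upper[1:])
    if cross.size == 0:
        return QCResult(True, float("nan"), None, "interval absent: vGRF never drops from 100 N")
    i = int(cross[-1])
    below_lower = f < QC_LOWER_N
    after = np.flatnonzero(below_lower[i + 1 :])
    j = int(after[0]) + i + 1 if after.size else len(f) - 1
    rates = np.diff(f[i : j + 1]) * vgrf.rate
    max_rate = float(rates.max()) if rates.size else float("-inf")
    accepted = max_rate < QC_MAX_RATE_N_PER_S
    return QCResult(accepted, max_rate, (i, j), "" if accepted else "loading-rate artefact")


def label_contact(cycle: GaitCycle) -> tuple[ContactLabelSequence, StepEvents]:
    """Build ground-truth contact labels and events from the cycle's raw vGRF.

    Force-rate frames with vGRF >= 50 N are contact. The first and last contact
    force frames are converted to times and rounded to the nearest mocap frame
    (round-half-up) to give the foot-strike and toe-off indices; the mocap-rate
    label vector is 1 on [FS, TO] inclusive. If thresholding yields more than
    one run the longest is kept with a warning.
    """
    if cycle.vgrf is None:
        raise ValueError(f"cycle {cycle.cycle_id!r} has no vGRF trace")
    contact = cycle.vgrf.values >= CONTACT_THRESHOLD_N
    runs = contiguous_runs(contact)
    if not runs:
        raise NoContactError(
            f"no contact: cycle {cycle.cycle_id!r} never reaches "
            f"{CONTACT_THRESHOLD_N} N (max {cycle.vgrf.values.max():.1f} N)"
        )
    if len(runs) > 1:
        warnings.warn(
            f"cycle {cycle.cycle_id!r}: {len(runs)} contact runs after thresholding; "
            "keeping the longest"
        )
        runs.sort(key=lambda r: r[1] - r[0], reverse=True)
    f0, f1 = runs[0]
    rate = cycle.mocap_rate
    n = len(cycle.features)
    fs = min(nearest_frame(f0 / cycle.vgrf.rate, rate), n - 1)
    to = min(nearest_frame(f1 / cycle.vgrf.rate, rate), n - 1)
    labels = np.zeros(n, dtype=np.int8)
    labels[fs : to + 1] = 1
    seq = ContactLabelSequence(labels, rate)
    return seq, StepEvents(foot_strike_index=fs, toe_off_index=to, rate=rate)


def standardise_and_pad(
    cycles: list[GaitCycle],
    scaler: Scaler | None = None,
    max_len: int = MAX_CYCLE_LEN,
) -> PaddedBatch:
    """Z-score features with the training scaler and zero-pad at the start.

    When ``scaler`` is None the collection is treated as a training set and the
    per-channel mean and SD are fitted on it; validation and test batches must
    pass the training scaler in, so no information leaks across splits.
    """
    if not cycles:
        raise ValueError("empty cycle collection")
    too_long = [c.cycle_id for c in cycles if len(c.features) > max_len]
    if too_long:
        raise ValueError(
            f"{len(too_long)} cycle(s) exceed the padded length {max_len}: {too_long[:5]}"
        )
    if scaler is None:
        stacked = np.concatenate([c.features.values for c in cycles], axis=0)
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        bad = np.flatnonzero(sd < 1e-12)
        if bad.size:
            names = [FEATURE_CHANNELS[i] for i in bad]
            raise ValueError(f"degenerate channel (zero variance in training data): {names}")
        scaler = Scaler(mean=mean, sd=sd)

    n = len(cycles)
    inputs = np.zeros((n, max_len, len(FEATURE_CHANNELS)))
    targets = np.zeros((n, max_len))
    mask = np.zeros((n, max_len))
    rate = cycles[0].mocap_rate
    ids = []
    for i, c in enumerate(cycles):
        ln = len(c.features)
        inputs[i, max_len - ln :] = scaler.transform(c.features.values)
        mask[i, max_len - ln :] = 1.0
        if c.labels is not None:
            targets[i, max_len - ln :] = c.labels.labels
        ids.append(c.cycle_id)
    return PaddedBatch(inputs=inputs, targets=targets, mask=mask, scaler=scaler, rate=rate, cycle_ids=ids)


@dataclass
class Split:
    """Participant-wise partition: one held-out test set plus k training folds."""

    test: list[GaitCycle]
    folds: list[list[GaitCycle]]
    test_participants: list[str]
    fold_participants: list[list[str]]


def split_participants(
    cycles: list[GaitCycle],
    test_fraction: float = 0.30,
    n_folds: int = 5,
    seed: int = 0,
) -> Split:
    """Participant-wise, dataset-stratified test split and cross-validation folds.

    From each dataset a ``test_fraction`` share of participants (round-half-up)
    is drawn for the test set; the remaining participants are dealt round-robin
    into ``n_folds`` folds, so each fold carries a representative number of
    participants from every dataset. Splits never separate a participant's
    cycles. Deterministic given ``seed``.
    """
    by_dataset: dict[str, list[str]] = {}
    by_participant: dict[str, list[GaitCycle]] = {}
    for c in cycles:
        by_participant.setdefault(c.participant_id, []).append(c)
        if c.participant_id not in by_dataset.setdefault(c.dataset_id, []):
            by_dataset[c.dataset_id].append(c.participant_id)

    rng = np.random.default_rng(seed)
    test_parts: list[str] = []
    fold_parts: list[list[str]] = [[] for _ in range(n_folds)]
    offset = 0
    for ds in sorted(by_dataset):
        parts = sorted(by_dataset[ds])
        order = [parts[i] for i in rng.permutation(len(parts))]
        n_test = int(np.floor(test_fraction * len(order) + 0.5))
        test_parts.extend(order[:n_test])
        remaining = order[n_test:]
        if len(remaining) < n_folds:
            raise ValueError(
                f"dataset {ds!r} has {len(remaining)} participants after the test draw; "
                f"need >= {n_folds} for stratified {n_folds}-fold cross-validation"
            )
        for i, p in enumerate(remaining):
            fold_parts[(i + offset) % n_folds].append(p)
        offset += len(remaining)

    def collect(parts: list[str]) -> list[GaitCycle]:
        return [c for p in parts for c in by_participant[p]]

    return Split(
        test=collect(test_parts),
        folds=[collect(fp) for fp in fold_parts],
        test_participants=test_parts,
        fold_participants=fold_parts,
    )
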