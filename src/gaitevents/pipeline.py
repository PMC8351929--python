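"""End-to-end orchestration: generate → QC/label → split → train → detect → evaluate.

This module ties the stages together in memory; the command-line interface in
`gaitevents.cli` exposes the same stages on files. The flow mirrors standard
practice for participant-wise model assessment: force-derived labels are the
gold standard, splits operate on participants, the scaler is fitted on
training data only, and the final model is scored on held-out participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .agreement import AgreementReport, build_report, frame_accuracy
from .cycles import GaitCycle, QCResult, Split, label_contact, qc_filter, split_participants, standardise_and_pad
from .events import EventErrors, StepEvents, event_errors, extract_events
from .model import ContactModel, CrossValResult, ModelConfig, TrainingHistory, cross_validate, train
from .sensitivity import SensitivityGrid, angle_sensitivity
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["prepare_cycles", "run_study", "StudyResult"]

log = logging.getLogger("gaitevents")


def prepare_cycles(cycles: list[GaitCycle]) -> tuple[list[GaitCycle], dict[str, QCResult]]:
    """Apply the loading-rate QC rule and build force-derived contact labels.

    Returns the accepted, labelled cycles and the per-cycle QC diagnostics.
    Rejected cycles keep ``accepted=False`` and receive no labels.
    """
    qc: dict[str, QCResult] = {}
    accepted = []
    for c in cycles:
        if c.vgrf is None:
            raise ValueError(f"cycle {c.cycle_id!r} has no vGRF; cannot build ground truth")
        res = qc_filter(c.vgrf)
        qc[c.cycle_id] = res
        c.accepted = res.accepted
        if res.accepted:
            labels, _ = label_contact(c)
            c.labels = labels
            accepted.append(c)
    return accepted, qc


@dataclass
class StudyResult:
    """Artefacts of one seeded end-to-end study on synthetic data."""

    report: AgreementReport
    errors: list[EventErrors]
    truth_events: dict[str, StepEvents]
    detected_events: dict[str, StepEvents]
    sensitivity: SensitivityGrid
    history: TrainingHistory
    split: Split
    qc: dict[str, QCResult]
    n_generated: int
    n_accepted: int
    crossval: CrossValResult | None = None
    undetected: list[str] = field(default_factory=list)

    @property
    def discard_fraction(self) -> float:
        return 1.0 - self.n_accepted / self.n_generated


def run_study(
    synth_config: SyntheticConfig,
    model_config: ModelConfig,
    test_fraction: float = 0.30,
    n_folds: int = 5,
    do_crossval: bool = False,
    threshold: float = 0.5,
) -> StudyResult:
    """Run the full protocol on a synthetic dataset.

    Generates the dataset, rejects QC-violating cycles, labels contact from
    force, splits participants (stratified by dataset) into a held-out test
    set and ``n_folds`` folds, trains the detector (either the full
    cross-validation protocol or a single fit with the last fold as the
    early-stopping monitor), and evaluates events and frame accuracy on the
    held-out participants. Deterministic given the two config seeds.
    """
    ds = generate_dataset(synth_config)
    accepted, qc = prepare_cycles(ds.cycles)
    log.info("generated %d cycles, accepted %d after QC", len(ds.cycles), len(accepted))

    split = split_participants(accepted, test_fraction=test_fraction, n_folds=n_folds,
                               seed=synth_config.seed)
    crossval = None
    if do_crossval:
        crossval = cross_validate(model_config, split.folds)
        model = crossval.final_model
        history = crossval.final_history
    else:
        train_cycles = [c for f in split.folds[:-1] for c in f]
        train_batch = standardise_and_pad(train_cycles)
        val_batch = standardise_and_pad(split.folds[-1], scaler=train_batch.scaler)
        model, history = train(model_config, train_batch, val_batch)

    scaler = model.scaler
    test_batch = standardise_and_pad(split.test, scaler=scaler)
    predictions = model.predict(test_batch)
    acc = frame_accuracy(predictions, [test_batch.targets[i] for i in range(test_batch.n_cycles)],
                         threshold=threshold)

    truth_ev: dict[str, StepEvents] = {}
    detected: dict[str, StepEvents] = {}
    errors: list[EventErrors] = []
    undetected: list[str] = []
    test_angles = []
    test_truths = []
    for cycle, pred in zip(split.test, predictions):
        truth = cycle.labels.to_events()
        truth_ev[cycle.cycle_id] = truth
        try:
            ev = extract_events(pred.probabilities, rate=cycle.mocap_rate,
                                threshold=threshold, mask=pred.mask)
        except ValueError:
            undetected.append(cycle.cycle_id)
            continue
        detected[cycle.cycle_id] = ev
        errors.append(event_errors(ev, truth))
        if cycle.angles:
            test_angles.append(cycle.angles)
            test_truths.append(truth)
    if undetected:
        log.warning("no contact detected in %d test cycles", len(undetected))

    report = build_report(errors, frame_acc=acc)
    grid = angle_sensitivity(test_angles, test_truths)
    return StudyResult(
        report=report,
        errors=errors,
        truth_events=truth_ev,
        detected_events=detected,
        sensitivity=grid,
        history=history,
        split=split,
        qc=qc,
        n_generated=len(ds.cycles),
        n_accepted=len(accepted),
        crossval=crossval,
        undetected=undetected,
    )
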