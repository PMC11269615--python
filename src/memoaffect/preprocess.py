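"""Continuous-session preprocessing into labeled 1-s segments.

Pipeline order: downsample to 128 Hz -> common average reference -> 1-50 Hz
band-pass -> epoch around recall onsets -> subtract the 1-s pre-onset
baseline from each of the ten 1-s recall segments -> per-channel z-score ->
(optionally) decompose each segment into the five EEG rhythms with zero-phase
Chebyshev type-II band-pass filters.  Class balancing randomly discards
segments above the smallest class count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import signal as sps

from .synthgen import (
    CHANNEL_NAMES,
    QUADRANTS,
    RHYTHM_BANDS,
    Annotation,
    RecordingSession,
    quadrant_of,
)

logger = logging.getLogger(__name__)

TARGET_RATE = 128
SEGMENT_LEN = 128          # samples per 1-s segment at 128 Hz
SEGMENTS_PER_TRIAL = 10


@dataclass
class Trial:
    """One epoch: 1-s baseline and 10-s recall at 128 Hz, with its label."""

    subject_id: str
    trial_id: int
    word: str
    label: str
    baseline: np.ndarray  # 14 x 128
    recall: np.ndarray    # 14 x 1280

    def __post_init__(self) -> None:
        if self.baseline.shape != (14, SEGMENT_LEN):
            raise ValueError(f"baseline must be 14x{SEGMENT_LEN}")
        if self.recall.shape != (14, SEGMENT_LEN * SEGMENTS_PER_TRIAL):
            raise ValueError(f"recall must be 14x{SEGMENT_LEN * SEGMENTS_PER_TRIAL}")


@dataclass
class LabeledSegment:
    """A baseline-corrected 14 x 128 segment with quadrant label and provenance."""

    subject_id: str
    trial_id: int
    segment_index: int
    data: np.ndarray
    label: str


@dataclass
class RhythmBank:
    """The five rhythm-band versions of one segment."""

    subject_id: str
    trial_id: int
    segment_index: int
    label: str
    bands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.bands) != set(RHYTHM_BANDS):
            raise ValueError("all five rhythm bands must be present")


@dataclass
class SegmentDataset:
    """A list of segments (or rhythm banks) plus consistent class counts."""

    segments: list

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.segments:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.segments)


def downsample(
    signal: np.ndarray, from_rate: int, to_rate: int = TARGET_RATE
) -> np.ndarray:
    """Anti-alias filtered resampling along the last axis."""
    if to_rate > from_rate:
        raise ValueError("to_rate must not exceed from_rate")
    frac = Fraction(to_rate, from_rate)
    return sps.resample_poly(signal, frac.numerator, frac.denominator, axis=-1)


def common_average_reference(signal: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean over channels from every channel."""
    if signal.shape[0] < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return signal - signal.mean(axis=0, keepdims=True)


@lru_cache(maxsize=8)
def _broadband_sos(rate: int) -> np.ndarray:
    # Order 8 keeps mains-frequency content >= 20 dB below the passband even
    # after the band edge at 50 Hz (the forward-backward pass doubles the
    # attenuation in dB).
    return sps.butter(8, [1.0, 50.0], btype="bandpass", fs=rate, output="sos")


def bandpass_1_50(signal: np.ndarray, rate: int = TARGET_RATE) -> np.ndarray:
    """Zero-phase 1-50 Hz Butterworth band-pass along the last axis."""
    if rate <= 100:
        raise ValueError("rate must exceed 100 Hz")
    return sps.sosfiltfilt(_broadband_sos(rate), signal, axis=-1)


@lru_cache(maxsize=8)
def _rhythm_sos(rate: int) -> dict[str, np.ndarray]:
    # Chebyshev type-II band-passes, 10 dB stopband attenuation as published;
    # stopband edges sit 1 Hz outside each passband edge (0.5 Hz below delta).
    edges = {
        "delta": (0.5, 5.0),
        "theta": (3.0, 9.0),
        "alpha": (7.0, 14.0),
        "beta": (12.0, 31.0),
        "gamma": (29.0, 50.0),
    }
    return {
        name: sps.cheby2(6, 10.0, list(e), btype="bandpass", fs=rate, output="sos")
        for name, e in edges.items()
    }


def extract_rhythms(
    segment: np.ndarray, rate: int = TARGET_RATE
) -> dict[str, np.ndarray]:
    """Zero-phase Chebyshev-II decomposition into delta..gamma bands.

    Constant-value edge padding keeps the low-frequency filters' edge
    transients small on 1-s windows (odd reflection injects spurious
    drift-like content into the delta band).
    """
    return {
        name: sps.sosfiltfilt(sos, segment, axis=-1, padtype="constant")
        for name, sos in _rhythm_sos(rate).items()
    }


def preprocess_session(
    session: RecordingSession,
    to_rate: int = TARGET_RATE,
    artifact_removal: Callable[[np.ndarray], np.ndarray] | None = None,
) -> RecordingSession:
    """Downsample, re-reference and band-pass one continuous session.

    ``artifact_removal`` is an optional hook applied to the continuous
    signal after filtering (identity when None); synthetic cohorts contain
    no ocular artifacts, so no implementation ships by default.
    """
    x = downsample(session.signal.astype(np.float64), session.rate, to_rate)
    x = common_average_reference(x)
    x = bandpass_1_50(x, to_rate)
    if artifact_removal is not None:
        x = artifact_removal(x)
    scale = to_rate / session.rate
    markers = [(int(round(m * scale)), w) for m, w in session.markers]
    return RecordingSession(
        subject_id=session.subject_id,
        rate=to_rate,
        signal=x,
        markers=markers,
        annotations=list(session.annotations),
    )


def epoch_trials(session: RecordingSession) -> list[Trial]:
    """Cut baseline/recall epochs around each marker of a 128 Hz session.

    Trials whose annotation sits on a valence/arousal axis (no quadrant)
    are dropped; markers too close to the recording edge are skipped with
    a warning.
    """
    if session.rate != TARGET_RATE:
        raise ValueError(f"session must be at {TARGET_RATE} Hz; got {session.rate}")
    recall_len = SEGMENT_LEN * SEGMENTS_PER_TRIAL
    n = session.signal.shape[1]
    trials: list[Trial] = []
    for trial_id, ((marker, word), ann) in enumerate(
        zip(session.markers, session.annotations)
    ):
        if marker - SEGMENT_LEN < 0 or marker + recall_len > n:
            logger.warning(
                "subject %s trial %d: marker %d too close to recording edge; skipped",
                session.subject_id, trial_id, marker,
            )
            continue
        label = quadrant_of(ann)
        if label is None:
            continue
        trials.append(
            Trial(
                subject_id=session.subject_id,
                trial_id=trial_id,
                word=word,
                label=label,
                baseline=np.asarray(session.signal[:, marker - SEGMENT_LEN : marker]),
                recall=np.asarray(session.signal[:, marker : marker + recall_len]),
            )
        )
    return trials


def baseline_correct_segments(trial: Trial) -> list[LabeledSegment]:
    """Split recall into ten 1-s segments and subtract the baseline from each."""
    out = []
    for i in range(SEGMENTS_PER_TRIAL):
        seg = trial.recall[:, SEGMENT_LEN * i : SEGMENT_LEN * (i + 1)] - trial.baseline
        out.append(
            LabeledSegment(
                subject_id=trial.subject_id,
                trial_id=trial.trial_id,
                segment_index=i,
                data=seg,
                label=trial.label,
            )
        )
    return out


def zscore(
    segment: np.ndarray, channel_names: Sequence[str] = CHANNEL_NAMES
) -> np.ndarray:
    """Per-channel standardization over the 128 samples of one segment."""
    mean = segment.mean(axis=-1, keepdims=True)
    std = segment.std(axis=-1, keepdims=True)
    zero = np.flatnonzero(std.ravel() == 0)
    if zero.size:
        names = [channel_names[i] for i in zero]
        raise ValueError(
            f"zero-variance channel(s) {names}: constant input cannot be z-scored"
        )
    return (segment - mean) / std


def sessions_to_segments(
    sessions: Iterable[RecordingSession],
    rhythms: bool = False,
    artifact_removal: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SegmentDataset:
    """Full pipeline from continuous sessions to z-scored labeled segments.

    With ``rhythms=True`` each segment is replaced by its five-band
    :class:`RhythmBank` (bands extracted from the z-scored segment).
    """
    items: list = []
    for sess in sessions:
        prep = preprocess_session(sess, artifact_removal=artifact_removal)
        for trial in epoch_trials(prep):
            for seg in baseline_correct_segments(trial):
                z = zscore(seg.data)
                if rhythms:
                    items.append(
                        RhythmBank(
                            subject_id=seg.subject_id,
                            trial_id=seg.trial_id,
                            segment_index=seg.segment_index,
                            label=seg.label,
                            bands=extract_rhythms(z),
                        )
                    )
                else:
                    seg.data = z
                    items.append(seg)
    return SegmentDataset(items)


def balance_classes(
    dataset: SegmentDataset, rng: np.random.Generator
) -> SegmentDataset:
    """Randomly discard segments so that every class matches the smallest one."""
    counts = dataset.class_counts
    missing = [q for q in QUADRANTS if counts.get(q, 0) == 0]
    if missing:
        raise ValueError(f"cannot balance: classes with zero segments {missing}")
    n_min = min(counts.values())
    keep: set[int] = set()
    by_label: dict[str, list[int]] = {}
    for i, seg in enumerate(dataset.segments):
        by_label.setdefault(seg.label, []).append(i)
    for label, idx in by_label.items():
        if len(idx) == n_min:
            keep.update(idx)
        else:
            keep.update(rng.choice(idx, size=n_min, replace=False).tolist())
    return SegmentDataset([dataset.segments[i] for i in sorted(keep)])


class SegmentArrays(NamedTuple):
    """Model-ready arrays: data, labels and the two grouping levels."""

    X: np.ndarray         # (n, 14, 128) float32
    y: np.ndarray         # integer class indices, canonical quadrant order
    subjects: np.ndarray  # subject id per segment (leave-one-subject-out folds)
    trials: np.ndarray    # "subject/trial" id per segment (leakage-safe splits)


def dataset_to_arrays(dataset: SegmentDataset, band: str | None = None) -> SegmentArrays:
    """Stack a dataset into :class:`SegmentArrays`.

    For rhythm-bank datasets ``band`` selects which band to stack.
    """
    label_idx = {q: i for i, q in enumerate(QUADRANTS)}
    data = []
    for s in dataset.segments:
        if isinstance(s, RhythmBank):
            if band is None:
                raise ValueError("band selection required for rhythm-bank datasets")
            data.append(s.bands[band])
        else:
            if band is not None:
                raise ValueError("band selection is only valid for rhythm banks")
            data.append(s.data)
    X = np.stack(data).astype(np.float32)
    y = np.array([label_idx[s.label] for s in dataset.segments], dtype=np.int64)
    subjects = np.array([s.subject_id for s in dataset.segments])
    trials = np.array([f"{s.subject_id}/{s.trial_id}" for s in dataset.segments])
    return SegmentArrays(X, y, subjects, trials)
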