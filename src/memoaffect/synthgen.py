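"""Synthetic EEG cohorts that emulate the word-cued memory-recall protocol.

The real study recorded 14-channel EEG from 69 participants while each of 16
affect-denoting words (three sessions, random order, 48 trials per subject)
cued a 10-s autobiographical memory recall, preceded by a 1-s neutral
baseline and followed by a 10-s self-annotation window on an integer
valence/arousal grid from -4 to 4.  That dataset is request-only, so this
module produces signals with the same protocol geometry and with annotation
statistics matched to the published per-word means, standard deviations and
valence-arousal quadrant counts.

The signal content is deliberately simple and fully declared: pink (1/f)
background noise everywhere, plus band-limited oscillations during recall
whose per-band amplitudes are set by the quadrant's :class:`ClassSignature`.
Inter-subject variability enters as log-normal multiplicative factors on the
band amplitudes, making subject-independent validation genuinely harder than
segment-level random splits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: 10-20 electrode labels used throughout (the 14-channel emotion montage).
CHANNEL_NAMES = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Valence/arousal quadrant labels, in the canonical class order.
QUADRANTS = ("HVHA", "HVLA", "LVHA", "LVLA")

#: Canonical EEG rhythm bands in Hz.
RHYTHM_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 49.0),
}

#: The 16 affect-denoting cue words, in published table order.
WORDS = (
    "Excited", "Cheerful", "Bored", "Unhappy", "Disappointment", "Fearful",
    "Alert", "Aroused", "Idle", "Lively", "Calm", "Relaxed", "Pleased",
    "Still", "Dulled", "Nervous",
)


class ConfigurationError(ValueError):
    """Raised when a generator configuration cannot produce a valid cohort."""


@dataclass(frozen=True)
class Annotation:
    """One self-annotation: integer valence and arousal in [-4, 4]."""

    valence: int
    arousal: int
    word: str

    def __post_init__(self) -> None:
        for name in ("valence", "arousal"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or not -4 <= int(v) <= 4:
                raise ValueError(f"{name} must be an integer in [-4, 4], got {v!r}")


def quadrant_of(a: Annotation) -> str | None:
    """Map an annotation to its valence/arousal quadrant.

    Zero on either axis does not belong to any quadrant and returns ``None``;
    such trials are excluded from the four-class dataset.
    """
    if a.valence == 0 or a.arousal == 0:
        return None
    if a.valence > 0:
        return "HVHA" if a.arousal > 0 else "HVLA"
    return "LVHA" if a.arousal > 0 else "LVLA"


@dataclass(frozen=True)
class WordAffectStats:
    """Per-word annotation statistics on the -4..4 scale plus quadrant counts."""

    word: str
    valence_mean: float
    valence_std: float
    arousal_mean: float
    arousal_std: float
    quadrant_counts: Mapping[str, int]  # keys HVHA, HVLA, LVHA, LVLA, None

    def __post_init__(self) -> None:
        if not (-4 <= self.valence_mean <= 4 and -4 <= self.arousal_mean <= 4):
            raise ValueError(f"{self.word}: means must lie in [-4, 4]")
        if self.valence_std < 0 or self.arousal_std < 0:
            raise ValueError(f"{self.word}: standard deviations must be >= 0")

    @property
    def total_trials(self) -> int:
        return sum(self.quadrant_counts.values())


def _was(word, vm, vs, am, as_, hvha, hvla, lvha, lvla, none):
    return WordAffectStats(word, vm, vs, am, as_, {
        "HVHA": hvha, "HVLA": hvla, "LVHA": lvha, "LVLA": lvla, "None": none,
    })


#: Published per-word annotation statistics (means/stds of valence and
#: arousal and quadrant memberships over 207 presentations per word).
WORD_STATS = (
    _was("Excited", 2.8213, 1.3409, 2.942, 1.3426, 191, 1, 1, 4, 10),
    _was("Cheerful", 2.8357, 1.4588, 2.8454, 1.3054, 190, 0, 1, 4, 12),
    _was("Bored", -1.6763, 1.7644, -0.8019, 2.191, 22, 14, 50, 109, 12),
    _was("Unhappy", -2.3961, 1.7003, -0.942, 2.4329, 9, 8, 52, 126, 12),
    _was("Disappointment", -2.3382, 1.8829, -0.913, 2.4834, 10, 8, 59, 118, 12),
    _was("Fearful", -2.3623, 1.6777, -2.0628, 2.6349, 14, 4, 86, 92, 11),
    _was("Alert", -0.3671, 2.3853, 2.3092, 1.6073, 85, 3, 98, 10, 11),
    _was("Aroused", 1.7778, 2.2008, 2.0676, 1.8787, 147, 9, 24, 13, 14),
    _was("Idle", -1.0773, 1.8018, -0.4251, 1.9738, 50, 12, 39, 85, 21),
    _was("Lively", 2.5942, 1.6219, 2.8406, 1.2766, 183, 0, 7, 3, 14),
    _was("Calm", 2.3671, 1.5361, 1.1304, 2.2027, 150, 37, 5, 4, 11),
    _was("Relaxed", 2.6667, 1.5201, 1.5894, 2.2856, 161, 30, 5, 4, 7),
    _was("Pleased", 2.8841, 1.5092, 2.8019, 1.4294, 186, 3, 4, 3, 11),
    _was("Still", -1.2174, 1.8424, -0.7343, 1.8518, 36, 20, 36, 98, 17),
    _was("Dulled", -1.7536, 1.6641, -0.9034, 1.941, 18, 8, 41, 125, 15),
    _was("Nervous", -2.0676, 1.7081, 0.1787, 2.611, 19, 6, 91, 81, 10),
)

_STATS_BY_WORD = {s.word: s for s in WORD_STATS}


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition-protocol geometry: who, what, when and how fast."""

    n_subjects: int = 69
    words: Sequence[str] = WORDS
    n_sessions: int = 3
    baseline_duration: float = 1.0
    recall_duration: float = 10.0
    annotation_duration: float = 10.0
    native_rate: int = 512
    channel_names: Sequence[str] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if len(self.channel_names) != 14:
            raise ConfigurationError("exactly 14 channels are required")
        for name in ("baseline_duration", "recall_duration"):
            n = getattr(self, name) * self.native_rate
            if abs(n - round(n)) > 1e-9:
                raise ConfigurationError(f"{name} x native_rate must be an integer")

    @property
    def trials_per_subject(self) -> int:
        return len(self.words) * self.n_sessions

    @property
    def trial_duration(self) -> float:
        return self.baseline_duration + self.recall_duration + self.annotation_duration


@dataclass(frozen=True)
class ClassSignature:
    """Spectral signature of one quadrant's recall activity.

    ``band_gains`` are RMS amplitudes of band-limited oscillations relative to
    a unit-variance pink-noise floor; ``subject_gain_spread`` is the sigma of
    the log-normal per-subject multiplicative factor drawn independently per
    band, which is what makes subjects differ from one another.
    """

    quadrant: str
    band_gains: Mapping[str, float]
    noise_scale: float = 1.0
    subject_gain_spread: float = 0.0
    #: optional per-band frequency window (Hz) the oscillation components are
    #: drawn from; must lie inside the named rhythm band.  Lets classes be
    #: encoded by frequency within one band at identical amplitude.
    band_freq_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        unknown = set(self.band_gains) - set(RHYTHM_BANDS)
        if unknown:
            raise ConfigurationError(f"unknown rhythm bands: {sorted(unknown)}")
        for band, (lo, hi) in self.band_freq_windows.items():
            blo, bhi = RHYTHM_BANDS[band]
            if not (blo <= lo < hi <= bhi):
                raise ConfigurationError(
                    f"frequency window {lo}-{hi} Hz outside {band} band"
                )
        if any(g < 0 for g in self.band_gains.values()):
            raise ConfigurationError("band gains must be non-negative")
        if self.noise_scale < 0 or self.subject_gain_spread < 0:
            raise ConfigurationError("scales must be non-negative")


@dataclass
class RecordingSession:
    """One subject's continuous recording plus markers and annotations."""

    subject_id: str
    rate: int
    signal: np.ndarray  # channels x samples
    markers: list[tuple[int, str]]  # (sample index of recall onset, word)
    annotations: list[Annotation]

    def __post_init__(self) -> None:
        if self.signal.shape[0] != 14:
            raise ValueError("signal must have exactly 14 channels")
        idx = [m for m, _ in self.markers]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("markers must be strictly increasing")
        if len(self.markers) != len(self.annotations):
            raise ValueError("one annotation per marker is required")


def default_signatures(
    effect_size: float = 1.0,
    noise_scale: float = 1.0,
    subject_gain_spread: float = 0.0,
) -> dict[str, ClassSignature]:
    """One dominant rhythm per quadrant, scaled by ``effect_size``.

    With ``effect_size=0`` all oscillations vanish and the cohort carries no
    class information (a null-data control).
    """
    base = {
        "HVHA": {"beta": 1.0, "gamma": 0.6},
        "HVLA": {"alpha": 1.0},
        "LVHA": {"theta": 1.0},
        "LVLA": {"delta": 1.0},
    }
    return {
        q: ClassSignature(
            quadrant=q,
            band_gains={b: g * effect_size for b, g in gains.items()},
            noise_scale=noise_scale,
            subject_gain_spread=subject_gain_spread,
        )
        for q, gains in base.items()
    }


def single_band_signatures(
    band: str = "alpha",
    gain: float = 3.0,
    noise_scale: float = 1.0,
    subject_gain_spread: float = 0.0,
) -> dict[str, ClassSignature]:
    """Signatures whose classes differ only inside one rhythm band.

    All four quadrants carry an oscillation of identical amplitude in
    ``band``, but each class draws its components from a different
    quarter of the band's frequency range.  Per-segment z-scoring leaves
    such frequency coding untouched (whereas amplitude coding would leak
    into every band through the normalization), so only the named band's
    filtered version of the data carries class information.
    """
    lo, hi = RHYTHM_BANDS[band]
    edges = np.linspace(lo, hi, 5)
    return {
        q: ClassSignature(
            quadrant=q,
            band_gains={band: gain},
            noise_scale=noise_scale,
            subject_gain_spread=subject_gain_spread,
            band_freq_windows={band: (float(edges[i]), float(edges[i + 1]))},
        )
        for i, q in enumerate(QUADRANTS)
    }


def sample_annotation(stats: WordAffectStats, rng: np.random.Generator) -> Annotation:
    """Draw one annotation: Gaussian per axis, rounded and clipped to [-4, 4]."""
    v = np.clip(np.rint(rng.normal(stats.valence_mean, stats.valence_std)), -4, 4)
    a = np.clip(np.rint(rng.normal(stats.arousal_mean, stats.arousal_std)), -4, 4)
    return Annotation(valence=int(v), arousal=int(a), word=stats.word)


def sample_annotation_categorical(
    stats: WordAffectStats, rng: np.random.Generator
) -> Annotation:
    """Draw an annotation whose quadrant follows the word's exact counts.

    Alternative sampler for exact marginal control: the quadrant (or None) is
    drawn from the published per-word quadrant counts, then an integer score
    pair consistent with that quadrant is drawn.
    """
    labels = list(stats.quadrant_counts)
    probs = np.array([stats.quadrant_counts[k] for k in labels], dtype=float)
    probs /= probs.sum()
    choice = labels[rng.choice(len(labels), p=probs)]

    def _magnitude() -> int:
        return int(rng.integers(1, 5))

    if choice == "None":
        if rng.random() < 0.5:
            v, a = 0, int(rng.integers(-4, 5))
        else:
            v, a = int(rng.integers(-4, 5)), 0
    else:
        v = _magnitude() * (1 if choice[0] == "H" else -1)
        a = _magnitude() * (1 if choice[2] == "H" else -1)
    return Annotation(valence=v, arousal=a, word=stats.word)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise per channel, generated spectrally."""
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _band_oscillation(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    rate: float,
    band: tuple[float, float],
    rms: float,
    n_components: int = 6,
) -> np.ndarray:
    """Sum of random-phase sinusoids inside ``band`` with total RMS ``rms``.

    Phases are independent across channels so that common-average
    referencing does not cancel the oscillation.
    """
    lo, hi = band
    hi = min(hi, rate / 2 * 0.98)
    t = np.arange(n_samples) / rate
    freqs = rng.uniform(lo, hi, size=n_components)
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, n_components))
    amp = rms * np.sqrt(2.0 / n_components)
    out = np.zeros((n_channels, n_samples))
    for j, f in enumerate(freqs):
        out += amp * np.sin(2 * np.pi * f * t[None, :] + phases[:, j : j + 1])
    return out


def generate_session(
    subject_seed: int,
    protocol: ProtocolConfig,
    signatures: Mapping[str, ClassSignature],
    stats: Sequence[WordAffectStats] = WORD_STATS,
) -> RecordingSession:
    """Synthesize one subject's continuous recording.

    Per trial: a 1-s neutral baseline (noise only), then a 10-s recall period
    whose oscillatory content follows the sampled quadrant's signature, then
    the annotation gap.  Deterministic given ``subject_seed``.
    """
    rng = np.random.default_rng(subject_seed)
    stats_by_word = {s.word: s for s in stats}
    missing = [w for w in protocol.words if w not in stats_by_word]
    if missing:
        raise ConfigurationError(f"no annotation statistics for words: {missing}")

    rate = protocol.native_rate
    n_ch = len(protocol.channel_names)
    trial_len = int(round(protocol.trial_duration * rate))
    base_len = int(round(protocol.baseline_duration * rate))
    recall_len = int(round(protocol.recall_duration * rate))
    n_trials = protocol.trials_per_subject
    total = n_trials * trial_len

    # Word order: an independent random permutation per session.
    order: list[str] = []
    for _ in range(protocol.n_sessions):
        order.extend(np.array(protocol.words)[rng.permutation(len(protocol.words))])

    # Per-subject, per-class, per-band multiplicative gain factors.
    subject_factors = {
        q: {
            b: float(np.exp(sig.subject_gain_spread * rng.standard_normal()))
            for b in RHYTHM_BANDS
        }
        for q, sig in signatures.items()
    }

    noise_scale = max((s.noise_scale for s in signatures.values()), default=1.0)
    if noise_scale > 0:
        signal = noise_scale * _pink_noise(rng, n_ch, total)
    else:
        signal = np.zeros((n_ch, total))

    markers: list[tuple[int, str]] = []
    annotations: list[Annotation] = []
    for t_idx, word in enumerate(order):
        start = t_idx * trial_len
        onset = start + base_len
        ann = sample_annotation(stats_by_word[word], rng)
        quad = quadrant_of(ann)
        if quad is not None:
            if quad not in signatures:
                raise ConfigurationError(f"no class signature for quadrant {quad}")
            sig = signatures[quad]
            for band, gain in sig.band_gains.items():
                eff = gain * subject_factors[quad][band]
                if eff > 0:
                    window = sig.band_freq_windows.get(band, RHYTHM_BANDS[band])
                    signal[:, onset : onset + recall_len] += _band_oscillation(
                        rng, n_ch, recall_len, rate, window, eff
                    )
        markers.append((onset, word))
        annotations.append(ann)

    return RecordingSession(
        subject_id=f"S{subject_seed}",
        rate=rate,
        signal=signal.astype(np.float32),
        markers=markers,
        annotations=annotations,
    )


def generate_cohort(
    master_seed: int,
    protocol: ProtocolConfig,
    signatures: Mapping[str, ClassSignature],
    stats: Sequence[WordAffectStats] = WORD_STATS,
) -> list[RecordingSession]:
    """One session per subject, each from a seed derived from ``master_seed``."""
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=protocol.n_subjects)
    sessions = []
    for i, s in enumerate(seeds):
        sess = generate_session(int(s), protocol, signatures, stats)
        sess.subject_id = f"S{i + 1:02d}"
        sessions.append(sess)
    return sessions


# ---------------------------------------------------------------------------
# On-disk cohort container (one HDF5 file per subject + a JSON manifest).

def save_cohort(
    sessions: Sequence[RecordingSession],
    out_dir: str | Path,
    protocol: ProtocolConfig | None = None,
    signatures: Mapping[str, ClassSignature] | None = None,
    master_seed: int | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sess in sessions:
        with h5py.File(out / f"{sess.subject_id}.h5", "w") as f:
            f.create_dataset("signal", data=sess.signal, compression="gzip")
            f.create_dataset("markers", data=np.array([m for m, _ in sess.markers]))
            f.create_dataset(
                "marker_words",
                data=np.array([w for _, w in sess.markers], dtype="S24"),
            )
            f.create_dataset(
                "annotations",
                data=np.array(
                    [(a.valence, a.arousal) for a in sess.annotations], dtype=np.int8
                ),
            )
            f.attrs["rate"] = sess.rate
            f.attrs["subject_id"] = sess.subject_id
    manifest = {
        "subjects": [s.subject_id for s in sessions],
        "master_seed": master_seed,
        "protocol": dataclasses.asdict(protocol) if protocol else None,
        "signatures": {
            q: dataclasses.asdict(sig) for q, sig in (signatures or {}).items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return out


def load_cohort(in_dir: str | Path) -> list[RecordingSession]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    sessions = []
    for sid in manifest["subjects"]:
        with h5py.File(in_dir / f"{sid}.h5", "r") as f:
            words = [w.decode() for w in f["marker_words"][()]]
            idx = f["markers"][()]
            ann = f["annotations"][()]
            sessions.append(
                RecordingSession(
                    subject_id=str(f.attrs["subject_id"]),
                    rate=int(f.attrs["rate"]),
                    signal=f["signal"][()],
                    markers=list(zip((int(i) for i in idx), words)),
                    annotations=[
                        Annotation(int(v), int(a), w)
                        for (v, a), w in zip(ann, words)
                    ],
                )
            )
    return sessions
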