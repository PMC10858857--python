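"""Synthetic polysomnography with stage-dependent spectral structure.

The generator emulates the qualitative electrophysiology that makes
real sleep stages separable: alpha-dominant wake with high muscle tone,
theta-dominant S1, spindle bursts over theta in S2, high-amplitude slow
delta in S3, and theta-like REM with the lowest EMG tone.  Hypnograms
come from a first-order Markov chain whose dwell times loosely mimic
overnight stage-bout statistics (S2-dominant).  Signals are sums of
band-limited sinusoids with random phases plus Gaussian broadband
noise; no morphological detail (K-complexes, sawtooth waves) is
attempted.  Everything is fully determined by a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from melstage.edf import write_edf
from melstage.recording import Channel, Recording
from melstage.staging import STAGES, Hypnogram, write_hypnogram

#: UCDDB-like channel layout: 128 Hz central EEG, 64 Hz chin EMG.
UCDDB_RATES: dict[str, float] = {"C3A2": 128.0, "C4A1": 128.0, "EMG": 64.0}
#: SHHS-like layout: everything at 125 Hz.
SHHS_RATES: dict[str, float] = {"C3A2": 125.0, "C4A1": 125.0, "EMG": 125.0}


@dataclass(frozen=True)
class Component:
    """One band-limited oscillation: amplitude x sin(2 pi f t + phase).

    ``burst`` amplitude-modulates the carrier with a slow raised-cosine
    envelope (spindle-like waxing/waning).
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float
    burst: bool = False


@dataclass(frozen=True)
class StageSpectrumSpec:
    """Per-stage EEG oscillatory content, EMG tone levels and noise floor."""

    eeg: dict[str, tuple[Component, ...]]
    emg_tone: dict[str, float]
    noise_level: float = 0.3
    #: stage-independent white sensor noise under the EMG; the muscle
    #: component rides on top of it with a high-frequency spectral tilt,
    #: so atonia changes the spectral shape, not just the level
    emg_floor: float = 0.25

    def __post_init__(self) -> None:
        for stage in STAGES:
            if stage not in self.eeg or stage not in self.emg_tone:
                raise ValueError(f"spectrum spec missing stage {stage}")
        for comps in self.eeg.values():
            for c in comps:
                if c.amplitude <= 0:
                    raise ValueError("component amplitudes must be positive")

    @classmethod
    def default(cls) -> "StageSpectrumSpec":
        return cls(
            eeg={
                "W": (Component(10.0, 2.0, 1.0),),                      # posterior alpha
                "S1": (Component(5.0, 2.0, 1.0),),                      # theta
                "S2": (Component(13.0, 1.0, 1.2, burst=True),          # sigma spindles
                       Component(5.0, 2.0, 0.6)),
                "S3": (Component(1.0, 0.8, 2.5),),                      # slow delta
                "REM": (Component(5.0, 2.5, 0.9),),                     # mixed theta
            },
            emg_tone={"W": 1.0, "S1": 0.6, "S2": 0.5, "S3": 0.3, "REM": 0.2},
            noise_level=0.3,
        )


@dataclass(frozen=True)
class TransitionModel:
    """Per-epoch Markov stage dynamics: 5x5 matrix + initial distribution."""

    matrix: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.matrix, dtype=float)
        if P.shape != (5, 5) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 5x5 row-stochastic")
        pi0 = np.asarray(self.initial, dtype=float)
        if pi0.shape != (5,) or np.any(pi0 < 0) or not np.isclose(pi0.sum(), 1.0):
            raise ValueError("initial distribution must be a length-5 simplex point")
        # irreducibility: every stage reachable from every stage
        reach = np.linalg.matrix_power((P > 0).astype(int) + np.eye(5, dtype=int), 5)
        if np.any(reach == 0):
            raise ValueError("transition matrix must describe an irreducible chain")

    @classmethod
    def default(cls) -> "TransitionModel":
        # mean dwell 1/(1-p_ii): W 10, S1 5, S2 10, S3 10, REM 10 epochs;
        # S2-heavy stationary mass mirrors the dominance of N2 overnight.
        P = np.array(
            [
                [0.90, 0.08, 0.01, 0.00, 0.01],
                [0.05, 0.80, 0.12, 0.00, 0.03],
                [0.01, 0.03, 0.90, 0.04, 0.02],
                [0.00, 0.01, 0.09, 0.90, 0.00],
                [0.02, 0.05, 0.03, 0.00, 0.90],
            ]
        )
        return cls(matrix=P, initial=np.array([1.0, 0.0, 0.0, 0.0, 0.0]))


def sample_hypnogram(tm: TransitionModel, n_epochs: int, seed: int,
                     subject_id: str = "") -> Hypnogram:
    """Draw a Markov stage sequence; deterministic per seed."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    stages = []
    state = int(rng.choice(5, p=tm.initial))
    for _ in range(n_epochs):
        stages.append(STAGES[state])
        state = int(rng.choice(5, p=tm.matrix[state]))
    return Hypnogram(stages=stages, subject_id=subject_id)


def _epoch_eeg(comps: Sequence[Component], fs: float, n: int, noise: float,
               rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    x = rng.normal(0.0, noise, size=n) if noise > 0 else np.zeros(n)
    for c in comps:
        f = c.center_hz + rng.uniform(-c.bandwidth_hz / 2, c.bandwidth_hz / 2)
        if f >= fs / 2:
            raise ValueError(f"component at {f:.1f} Hz is above Nyquist for fs={fs}")
        wave = c.amplitude * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if c.burst:
            env_f = rng.uniform(0.3, 0.6)  # spindle recurrence ~ every 2-3 s
            wave = wave * 0.5 * (1.0 - np.cos(2 * np.pi * env_f * t + rng.uniform(0, 2 * np.pi)))
        x = x + wave
    return x


def synth_recording(
    hyp: Hypnogram,
    spec: Optional[StageSpectrumSpec] = None,
    rates: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> Recording:
    """Render a multi-channel recording for a given hypnogram.

    Each 30-s epoch is generated independently from its stage's
    spectral recipe (real scoring transitions are discontinuous too);
    the EMG channel is broadband noise scaled by the stage's tone
    level.  Masked epochs are rendered as pure noise.
    """
    spec = spec or StageSpectrumSpec.default()
    rates = rates or UCDDB_RATES
    rng = np.random.default_rng(seed)
    ep = hyp.epoch_len_s
    channels = []
    for label, fs in rates.items():
        n = int(round(ep * fs))
        parts = []
        for stage in hyp.stages:
            if "emg" in label.lower():
                tone = spec.emg_tone.get(stage, 0.5) if stage else 0.5
                # muscle activity: first-differenced white noise (+6 dB/oct
                # high-frequency tilt) scaled by tone, over the sensor floor
                hf = np.diff(rng.normal(0.0, 1.0, size=n + 1)) / np.sqrt(2.0)
                parts.append(tone * hf + spec.emg_floor * rng.normal(0.0, 1.0, size=n))
            elif stage is None:
                parts.append(rng.normal(0.0, max(spec.noise_level, 1e-6), size=n))
            else:
                parts.append(_epoch_eeg(spec.eeg[stage], fs, n, spec.noise_level, rng))
        channels.append(Channel(label=label, samples=np.concatenate(parts), fs=fs))
    return Recording(channels=channels, subject_id=hyp.subject_id)


def make_dataset(
    n_subjects: int = 12,
    epochs_per_subject: int = 120,
    spec: Optional[StageSpectrumSpec] = None,
    tm: Optional[TransitionModel] = None,
    rates: Optional[dict[str, float]] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> list[tuple[Recording, Hypnogram]]:
    """Generate a cohort; optionally write EDF + hypnogram fixture files.

    Per-subject seeds derive deterministically from the master seed, so
    two runs with the same seed produce byte-identical files.  When
    ``out_dir`` is given, each subject gets ``<id>.edf`` and
    ``<id>.txt`` (one stage label per line) plus a ``manifest.csv``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    spec = spec or StageSpectrumSpec.default()
    tm = tm or TransitionModel.default()
    rates = rates or UCDDB_RATES
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=2 * n_subjects)
    dataset = []
    for i in range(n_subjects):
        sid = f"SYN{i + 1:03d}"
        hyp = sample_hypnogram(tm, epochs_per_subject, int(sub_seeds[2 * i]), subject_id=sid)
        rec = synth_recording(hyp, spec, rates, seed=int(sub_seeds[2 * i + 1]))
        dataset.append((rec, hyp))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = ["subject_id,edf,hypnogram,n_epochs"]
        for rec, hyp in dataset:
            write_edf(out_dir / f"{rec.subject_id}.edf", rec)
            write_hypnogram(out_dir / f"{rec.subject_id}.txt", hyp)
            rows.append(f"{rec.subject_id},{rec.subject_id}.edf,{rec.subject_id}.txt,{len(hyp)}")
        (out_dir / "manifest.csv").write_text("\n".join(rows) + "\n")
    return dataset


def band_power_baseline(
    dataset: Sequence[tuple[Recording, Hypnogram]],
    seed: int = 0,
) -> float:
    """Accuracy of a linear classifier on simple band powers.

    A deliberately trivial reference: log power in the delta/theta/
    alpha/sigma bands of one EEG channel plus EMG RMS, fed to a
    multinomial logistic regression with a held-out subject-wise split.
    Its accuracy is a floor showing the generated stages are separable
    at all.
    """
    import scipy.signal
    from sklearn.linear_model import LogisticRegression

    bands = [(0.5, 2.0), (4.0, 7.0), (8.0, 12.0), (12.0, 15.0)]
    feats, labels, groups = [], [], []
    for rec, hyp in dataset:
        eeg = next(ch for ch in rec.channels if not ch.is_emg)
        emg = next(ch for ch in rec.channels if ch.is_emg)
        n_eeg = int(round(hyp.epoch_len_s * eeg.fs))
        n_emg = int(round(hyp.epoch_len_s * emg.fs))
        for k, stage in enumerate(hyp.stages):
            if stage is None:
                continue
            seg = eeg.samples[k * n_eeg : (k + 1) * n_eeg]
            f, pxx = scipy.signal.periodogram(seg, fs=eeg.fs)
            bp = [np.log(pxx[(f >= lo) & (f < hi)].sum() + 1e-12) for lo, hi in bands]
            seg_emg = emg.samples[k * n_emg : (k + 1) * n_emg]
            bp.append(np.log(np.sqrt(np.mean(seg_emg**2)) + 1e-12))
            feats.append(bp)
            labels.append(stage)
            groups.append(rec.subject_id)
    x = np.asarray(feats)
    y = np.asarray(labels)
    g = np.asarray(groups)
    subjects = np.array(sorted(set(groups)))
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n_test = max(1, len(subjects) // 5)
    test_subj = set(subjects[:n_test])
    test = np.array([s in test_subj for s in g])
    clf = LogisticRegression(max_iter=2000)
    clf.fit(x[~test], y[~test])
    return float((clf.predict(x[test]) == y[test]).mean())
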