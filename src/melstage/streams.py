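"""Composition of per-channel cepstral maps into 2-D training streams.

One stream is the model input for one scored epoch: the L cepstral
rows of every channel are stacked along the height axis and the frames
of a symmetric window of context epochs (three by default — previous,
current, next) are concatenated along the width axis.  The stream's
label is the centre epoch's stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import scipy.signal

from melstage.mfcc import MfccParams, extract_mfcc
from melstage.recording import Channel, Recording, segment_epochs
from melstage.staging import STAGES, Hypnogram


def unify_rates(rec: Recording, target_fs: Optional[float] = None) -> Recording:
    """Polyphase-resample every channel to a common rate.

    ``target_fs=None`` selects the maximum channel rate, so EEG is left
    untouched and only the slower EMG is upsampled in the UCDDB-style
    128/64 Hz layout.  Channels already at the target are returned
    unchanged (sample-identical).
    """
    if target_fs is None:
        target_fs = max(ch.fs for ch in rec.channels)
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    out = []
    for ch in rec.channels:
        if ch.fs == target_fs:
            out.append(ch)
            continue
        frac = Fraction(target_fs / ch.fs).limit_denominator(1000)
        y = scipy.signal.resample_poly(ch.samples, frac.numerator, frac.denominator)
        out.append(Channel(label=ch.label, samples=y, fs=target_fs))
    return Recording(channels=out, subject_id=rec.subject_id)


@dataclass(frozen=True)
class StreamConfig:
    """How epoch feature maps are combined into model inputs.

    ``boundary`` controls epochs lacking full context: ``"replicate"``
    duplicates the first/last epoch into the missing slots (stream count
    equals hypnogram length), ``"drop"`` omits boundary epochs.
    ``standardize`` optionally zero-means/unit-scales each stream.
    """

    context_epochs: int = 3
    channel_order: Optional[tuple[str, ...]] = None
    boundary: str = "replicate"
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.context_epochs < 1 or self.context_epochs % 2 == 0:
            raise ValueError(f"context_epochs must be odd and >= 1, got {self.context_epochs}")
        if self.boundary not in ("replicate", "drop"):
            raise ValueError(f"boundary must be 'replicate' or 'drop', got {self.boundary!r}")


@dataclass
class FeatureStream:
    """One model input: a (L*n_channels) x (frames*context) tensor + label."""

    tensor: np.ndarray
    label: str
    subject_id: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        if self.label not in STAGES:
            raise ValueError(f"stream label {self.label!r} not a canonical stage")


def compute_epoch_features(
    rec: Recording,
    hyp: Hypnogram,
    params: MfccParams = MfccParams(),
    target_fs: Optional[float] = None,
) -> tuple[list[dict[str, np.ndarray]], list[Optional[str]], list[int]]:
    """Rate-unify, segment and extract one cepstral map per epoch per channel.

    Framing restarts at each epoch boundary, so every epoch contributes
    an identical number of frames.  Returns the per-epoch channel->map
    dicts (map shape n_frames x L), the epoch labels and epoch indices.
    """
    rec = unify_rates(rec, target_fs)
    blocks = segment_epochs(rec, hyp, include_masked=False)
    feats, labels, idx = [], [], []
    for blk in blocks:
        feats.append(
            {lab: extract_mfcc(x, rec.channels[0].fs, params).coeffs for lab, x in blk.channels.items()}
        )
        labels.append(blk.stage)
        idx.append(blk.index)
    return feats, labels, idx


def build_streams(
    epoch_features: Sequence[dict[str, np.ndarray]],
    labels: Sequence[Optional[str]],
    cfg: StreamConfig = StreamConfig(),
    subject_id: str = "",
    epoch_indices: Optional[Sequence[int]] = None,
) -> list[FeatureStream]:
    """Assemble per-epoch channel maps into labelled 2-D streams.

    For epoch k the channels are stacked along the coefficient (height)
    axis and the context epochs k-h..k+h along the frame (width) axis;
    the stream keeps epoch k's label.  Composition never relabels, so
    per-class stream counts equal per-class label counts under the
    replicate boundary policy.
    """
    n = len(epoch_features)
    if n != len(labels):
        raise ValueError(f"{n} epoch feature maps but {len(labels)} labels")
    if n == 0:
        return []
    order = cfg.channel_order or tuple(epoch_features[0].keys())
    shapes = {m.shape for feats in epoch_features for m in feats.values()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent per-channel map shapes across epochs: {sorted(shapes)}")
    if epoch_indices is None:
        epoch_indices = list(range(n))

    # per-epoch stacked map: (L * n_channels) x n_frames
    stacked = [
        np.vstack([np.asarray(feats[lab]).T for lab in order]) for feats in epoch_features
    ]
    half = cfg.context_epochs // 2
    streams: list[FeatureStream] = []
    for k in range(n):
        if labels[k] is None:
            continue
        ctx = range(k - half, k + half + 1)
        if cfg.boundary == "drop" and (k - half < 0 or k + half >= n):
            continue
        tensor = np.hstack([stacked[min(max(j, 0), n - 1)] for j in ctx])
        if cfg.standardize:
            sd = tensor.std()
            tensor = (tensor - tensor.mean()) / (sd if sd > 0 else 1.0)
        streams.append(
            FeatureStream(
                tensor=tensor.astype(np.float32),
                label=labels[k],
                subject_id=subject_id,
                epoch_index=epoch_indices[k],
            )
        )
    return streams


def streams_from_recording(
    rec: Recording,
    hyp: Hypnogram,
    params: MfccParams = MfccParams(),
    cfg: StreamConfig = StreamConfig(),
) -> list[FeatureStream]:
    """End-to-end convenience: recording + hypnogram -> feature streams."""
    feats, labels, idx = compute_epoch_features(rec, hyp, params)
    return build_streams(feats, labels, cfg, subject_id=rec.subject_id or hyp.subject_id,
                         epoch_indices=idx)


def split_subjects(
    streams: Sequence[FeatureStream],
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> tuple[list[FeatureStream], list[FeatureStream], list[FeatureStream]]:
    """Partition streams subject-wise into train/validation/test sets.

    Whole subjects are assigned to one partition each (no epoch-level
    leakage); subject counts follow the fractions by largest remainder,
    with every partition guaranteed at least one subject.  Deterministic
    given the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    subjects = sorted({st.subject_id for st in streams})
    if len(subjects) < len(fractions):
        raise ValueError(
            f"need at least {len(fractions)} subjects to split, got {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    subjects = list(rng.permutation(subjects))
    n = len(subjects)
    ideal = [f * n for f in fractions]
    counts = [max(1, int(np.floor(v))) for v in ideal]
    while sum(counts) > n:  # max(1,..) may overshoot for tiny n
        counts[int(np.argmax(counts))] -= 1
    remainders = [v - c for v, c in zip(ideal, counts)]
    while sum(counts) < n:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    parts: list[list[FeatureStream]] = []
    start = 0
    for c in counts:
        chosen = set(subjects[start : start + c])
        parts.append([st for st in streams if st.subject_id in chosen])
        start += c
    return parts[0], parts[1], parts[2]


def save_streams(path: str | Path, streams: Sequence[FeatureStream], attrs: Optional[dict] = None) -> None:
    """Persist streams to an HDF5 container (tensors, labels, subjects)."""
    if not streams:
        raise ValueError("no streams to save")
    shapes = {st.tensor.shape for st in streams}
    if len(shapes) != 1:
        raise ValueError(f"streams have inconsistent shapes: {sorted(shapes)}")
    with h5py.File(path, "w") as f:
        f.create_dataset("tensors", data=np.stack([st.tensor for st in streams]))
        f.create_dataset("labels", data=[st.label.encode() for st in streams])
        f.create_dataset("subjects", data=[st.subject_id.encode() for st in streams])
        f.create_dataset("epoch_indices", data=[st.epoch_index for st in streams])
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_streams(path: str | Path) -> tuple[list[FeatureStream], dict]:
    with h5py.File(path, "r") as f:
        tensors = f["tensors"][...]
        labels = [b.decode() for b in f["labels"][...]]
        subjects = [b.decode() for b in f["subjects"][...]]
        idx = f["epoch_indices"][...]
        attrs = dict(f.attrs)
    return (
        [
            FeatureStream(tensor=t, label=lb, subject_id=sb, epoch_index=int(i))
            for t, lb, sb, i in zip(tensors, labels, subjects, idx)
        ],
        attrs,
    )
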