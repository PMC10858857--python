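"""Multi-channel PSG signal container and 30-s epoch segmentation.

Channels keep their native sample rates (UCDDB stores 128 Hz EEG next
to 64 Hz EMG); rate unification is deferred to the feature-composition
stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from melstage.staging import Hypnogram


class ChannelNotFoundError(KeyError):
    """Requested channel label is absent from a recording or EDF file."""


class AlignmentError(ValueError):
    """Recording and hypnogram disagree by more than one 30-s epoch."""


def normalize_label(label: str) -> str:
    """Case- and separator-insensitive channel label key ('C4-A1' == 'c4a1')."""
    return re.sub(r"[^0-9a-z]", "", label.lower())


@dataclass
class Channel:
    """One signal trace with its label and native sampling rate (Hz)."""

    label: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"channel {self.label!r}: samples must be 1-D")
        if self.fs <= 0:
            raise ValueError(f"channel {self.label!r}: fs must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def is_emg(self) -> bool:
        return "emg" in self.label.lower()


@dataclass
class Recording:
    """A multi-channel PSG recording with per-channel sample rates."""

    channels: list[Channel]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a recording needs at least one channel")
        dur = self.duration_s
        for ch in self.channels:
            if abs(len(ch.samples) - round(ch.fs * dur)) > 1:
                raise ValueError(
                    f"channel {ch.label!r}: {len(ch.samples)} samples inconsistent "
                    f"with fs={ch.fs} Hz over {dur:.3f} s (off by more than one sample)"
                )

    @property
    def duration_s(self) -> float:
        """Common covered span: the shortest channel duration."""
        return min(ch.duration_s for ch in self.channels)

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    def get_channel(self, label: str) -> Channel:
        key = normalize_label(label)
        for ch in self.channels:
            if normalize_label(ch.label) == key:
                return ch
        raise ChannelNotFoundError(
            f"channel {label!r} not found; available: {self.labels}"
        )

    def select(self, labels: Iterable[str]) -> "Recording":
        return Recording(
            channels=[self.get_channel(lb) for lb in labels], subject_id=self.subject_id
        )

    def validate_roles(self) -> None:
        """Pipeline use requires at least one EEG-role and one EMG-role channel."""
        has_emg = any(ch.is_emg for ch in self.channels)
        has_eeg = any(not ch.is_emg for ch in self.channels)
        if not (has_emg and has_eeg):
            raise ValueError(
                f"pipeline needs >=1 EEG and >=1 EMG channel; got labels {self.labels}"
            )


@dataclass
class EpochBlock:
    """Samples of one 30-s scoring epoch, per channel, with its stage label."""

    index: int
    channels: dict[str, np.ndarray]
    stage: Optional[str] = None


def segment_epochs(
    rec: Recording,
    hyp: Hypnogram,
    include_masked: bool = False,
) -> list[EpochBlock]:
    """Cut a recording into labelled 30-s blocks aligned with the hypnogram.

    Epoch ``k`` holds samples ``[k*30*fs, (k+1)*30*fs)`` of each channel.
    A trailing partial epoch is dropped, never padded.  The block count is
    the smaller of the two inputs' epoch counts; a mismatch of more than
    one epoch raises :class:`AlignmentError`.  Epochs masked by the
    unknown-label policy are skipped unless ``include_masked`` is set.
    """
    ep = hyp.epoch_len_s
    n_rec = int(np.floor(rec.duration_s / ep))
    n_hyp = len(hyp)
    if abs(n_rec - n_hyp) > 1:
        raise AlignmentError(
            f"recording covers {n_rec} epochs but hypnogram has {n_hyp} "
            f"(subject {rec.subject_id!r}); misalignment exceeds one epoch"
        )
    n = min(n_rec, n_hyp)
    blocks: list[EpochBlock] = []
    for k in range(n):
        stage = hyp.stages[k]
        if stage is None and not include_masked:
            continue
        chans = {}
        for ch in rec.channels:
            spe = int(round(ep * ch.fs))  # samples per epoch at this rate
            chans[ch.label] = ch.samples[k * spe : (k + 1) * spe]
        blocks.append(EpochBlock(index=k, channels=chans, stage=stage))
    return blocks
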