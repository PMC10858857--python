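"""Canonical sleep-stage vocabulary, label maps and hypnograms.

The five-class AASM scheme is used throughout: Wake, S1 (N1), S2 (N2),
S3 (N3, slow-wave sleep; the R&K stages 3 and 4 are merged into it) and
REM.  The integer class codes ``W=0, S1=1, S2=2, S3=3, REM=4`` are fixed
package-wide because the Test Cost Index depends on the encoding.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

#: Canonical stage labels in fixed code order.
STAGES: tuple[str, ...] = ("W", "S1", "S2", "S3", "REM")

#: Stage label -> integer class code (the encoding the TCI is defined on).
STAGE_TO_CODE: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

CODE_TO_STAGE: dict[int, str] = {i: s for i, s in enumerate(STAGES)}

EPOCH_LEN_S = 30.0


class UnknownStageError(ValueError):
    """A raw hypnogram label has no entry in the stage map (strict mode)."""


@dataclass(frozen=True)
class StageMap:
    """Total lookup from a raw annotation vocabulary to the canonical stages.

    Parameters
    ----------
    mapping:
        raw label -> canonical label.  Canonical labels always map to
        themselves, so applying the map twice equals applying it once.
    on_unknown:
        ``"drop"`` masks epochs whose label is absent from the mapping
        (they survive as ``None``), ``"error"`` raises
        :class:`UnknownStageError`.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    on_unknown: str = "drop"

    def __post_init__(self) -> None:
        if self.on_unknown not in ("drop", "error"):
            raise ValueError(f"on_unknown must be 'drop' or 'error', got {self.on_unknown!r}")
        for raw, canon in self.mapping.items():
            if canon not in STAGES:
                raise ValueError(f"stage map sends {raw!r} to non-canonical label {canon!r}")

    def __call__(self, raw: str) -> Optional[str]:
        raw = raw.strip()
        if raw in self.mapping:
            return self.mapping[raw]
        if raw in STAGES:  # canonical labels are fixed points
            return raw
        if self.on_unknown == "error":
            raise UnknownStageError(f"unknown stage label {raw!r}")
        return None

    @classmethod
    def rk_numeric(cls, on_unknown: str = "drop") -> "StageMap":
        """R&K numeric codes; stage 4 merges into S3 per the AASM rules."""
        return cls(
            mapping={"0": "W", "1": "S1", "2": "S2", "3": "S3", "4": "S3", "5": "REM"},
            on_unknown=on_unknown,
        )

    @classmethod
    def aasm_text(cls, on_unknown: str = "drop") -> "StageMap":
        """Common textual AASM vocabularies (N1..N3, R, Wake ...)."""
        m = {
            "W": "W", "WAKE": "W", "Wake": "W",
            "N1": "S1", "S1": "S1", "Stage1": "S1", "1": "S1",
            "N2": "S2", "S2": "S2", "Stage2": "S2", "2": "S2",
            "N3": "S3", "N4": "S3", "S3": "S3", "S4": "S3",
            "Stage3": "S3", "Stage4": "S3", "3": "S3", "4": "S3",
            "R": "REM", "REM": "REM", "Rem": "REM", "5": "REM",
        }
        return cls(mapping=m, on_unknown=on_unknown)


@dataclass
class Hypnogram:
    """Per-30-s-epoch stage sequence aligned to a recording.

    ``stages[k]`` is a canonical label or ``None`` for epochs masked out
    by the unknown-label policy (movement time, artifact codes).
    """

    stages: list[Optional[str]]
    subject_id: str = ""
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        for s in self.stages:
            if s is not None and s not in STAGES:
                raise ValueError(f"non-canonical stage label {s!r} in hypnogram")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def n_scored(self) -> int:
        """Number of epochs carrying a valid stage label."""
        return sum(s is not None for s in self.stages)

    @property
    def codes(self) -> list[Optional[int]]:
        return [None if s is None else STAGE_TO_CODE[s] for s in self.stages]

    def class_counts(self) -> dict[str, int]:
        out = {s: 0 for s in STAGES}
        for s in self.stages:
            if s is not None:
                out[s] += 1
        return out


def read_hypnogram(
    path: str | Path,
    stage_map: StageMap,
    epoch_len_s: float = EPOCH_LEN_S,
    subject_id: str = "",
) -> Hypnogram:
    """Read a hypnogram file and map it onto the canonical vocabulary.

    Two dialects are auto-detected:

    * one raw label per line (UCDDB-style plain text);
    * CSV with ``onset,duration,stage`` columns in seconds (EDF+-style
      annotation export), expanded to the per-epoch representation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"hypnogram file not found: {path}")
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        warnings.warn(f"empty hypnogram file: {path}")
        return Hypnogram(stages=[], subject_id=subject_id, epoch_len_s=epoch_len_s)

    if "," in lines[0] or (len(lines) > 1 and "," in lines[1]):
        stages = _parse_onset_csv(lines, stage_map, epoch_len_s, path)
    else:
        stages = [stage_map(ln) for ln in lines]
    return Hypnogram(stages=stages, subject_id=subject_id, epoch_len_s=epoch_len_s)


def _parse_onset_csv(
    lines: Sequence[str], stage_map: StageMap, epoch_len_s: float, path: Path
) -> list[Optional[str]]:
    rows = list(csv.reader(lines))
    start = 0
    # tolerate a header row
    try:
        float(rows[0][0])
    except (ValueError, IndexError):
        start = 1
    intervals: list[tuple[float, float, Optional[str]]] = []
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 3:
            raise ValueError(f"{path}:{i}: malformed row {row!r}, need onset,duration,stage")
        try:
            onset, dur = float(row[0]), float(row[1])
        except ValueError as e:
            raise ValueError(f"{path}:{i}: non-numeric onset/duration in {row!r}") from e
        intervals.append((onset, dur, stage_map(row[2])))
    if not intervals:
        return []
    total = max(on + du for on, du, _ in intervals)
    n_epochs = int(math.floor(total / epoch_len_s))
    stages: list[Optional[str]] = [None] * n_epochs
    for on, du, lab in intervals:
        first = int(math.ceil(on / epoch_len_s - 1e-9))
        last = int(math.floor((on + du) / epoch_len_s + 1e-9))
        for k in range(max(first, 0), min(last, n_epochs)):
            stages[k] = lab
    return stages


def write_hypnogram(path: str | Path, hyp: Hypnogram, unknown: str = "?") -> None:
    """Write one label per line; masked epochs are written as ``unknown``."""
    Path(path).write_text("".join((s if s is not None else unknown) + "\n" for s in hyp.stages))
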