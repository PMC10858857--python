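"""Mel-frequency cepstral coefficients for low-rate biosignals.

The chain has six steps: first-order pre-emphasis, framing into
overlapping fixed-length frames, Hamming windowing, zero-padded FFT
power spectrum, log energies of a Mel-spaced triangular filter bank,
and a DCT that decorrelates the log energies into the cepstrum.

Conventions used throughout (all configurable via :class:`MfccParams`):

* frame length and stride are ``round(w*fs)`` and ``round(s*fs)``
  samples (round-half-to-even); frames that would overrun the signal
  end are not emitted;
* the filter-bank edge frequencies are Mel-uniform and snapped to
  integer FFT bins, so every triangle peaks at exactly 1 on its centre
  bin and adjacent triangles tile (sum to 1) on interior bins;
* the log has an additive floor ``eps`` so silent frames stay finite;
* the cepstrum is ``C(n) = sum_{m=1..M} s(m) cos(pi*n*(m-0.5)/M)`` for
  ``n = 1..L`` — the overall-energy term ``C(0)`` is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import scipy.fft


class MfccConfigError(ValueError):
    """Inconsistent MFCC parameterization."""


MEL_SCALE = 2595.0
MEL_BREAK_HZ = 700.0


def hz_to_mel(f):
    """Perceptual pitch in Mels: ``2595 * log10(1 + f/700)``."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = MEL_SCALE * np.log10(1.0 + f / MEL_BREAK_HZ)
    return out.item() if out.ndim == 0 else out


def mel_to_hz(mel):
    """Inverse of :func:`hz_to_mel`."""
    mel = np.asarray(mel, dtype=np.float64)
    out = MEL_BREAK_HZ * (10.0 ** (mel / MEL_SCALE) - 1.0)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class MfccParams:
    """Knobs of the extraction chain.

    Parameters
    ----------
    a:
        Pre-emphasis coefficient (0.97: each sample keeps 97% of its
        predecessor subtracted from it, boosting high frequencies).
    w, s:
        Frame length and stride in seconds (0.5 / 0.25 by default, i.e.
        50% overlap).
    n_filters:
        Number of triangular Mel filters M (40).
    n_coeffs:
        Number of cepstral coefficients L kept from the DCT (13, inside
        the conventional 12-20 range).
    nfft:
        FFT length; ``None`` selects the smallest power of two that is
        >= the frame length and >= 256.  The 256 floor gives a 40-filter
        bank distinct integer bin edges at the 64-128 Hz rates of
        central-EEG/EMG polysomnography.
    fmin, fmax:
        Filter-bank band edges in Hz; ``fmax=None`` means the Nyquist
        frequency.
    eps:
        Additive floor inside the log energy.
    """

    a: float = 0.97
    w: float = 0.5
    s: float = 0.25
    n_filters: int = 40
    n_coeffs: int = 13
    nfft: Optional[int] = None
    fmin: float = 0.0
    fmax: Optional[float] = None
    eps: float = 1e-10

    def __post_init__(self) -> None:
        if not 0.0 <= self.a < 1.0:
            raise MfccConfigError(f"pre-emphasis a must be in [0, 1), got {self.a}")
        if not 0.0 < self.s <= self.w:
            raise MfccConfigError(f"need 0 < stride <= window, got s={self.s}, w={self.w}")
        if self.n_filters < 2:
            raise MfccConfigError(f"need at least 2 mel filters, got {self.n_filters}")
        if not 1 <= self.n_coeffs <= self.n_filters:
            raise MfccConfigError(
                f"need 1 <= n_coeffs <= n_filters, got L={self.n_coeffs}, M={self.n_filters}"
            )
        if self.fmin < 0:
            raise MfccConfigError(f"fmin must be >= 0, got {self.fmin}")

    def frame_len(self, fs: float) -> int:
        return int(np.round(self.w * fs))

    def stride_len(self, fs: float) -> int:
        return int(np.round(self.s * fs))

    def resolve_nfft(self, fs: float) -> int:
        if self.nfft is not None:
            n = self.nfft
        else:
            n = 256
            while n < self.frame_len(fs):
                n *= 2
        if n < self.frame_len(fs):
            raise MfccConfigError(f"nfft={n} smaller than frame length {self.frame_len(fs)}")
        if n <= 0 or n % 2 != 0:
            raise MfccConfigError(f"nfft must be a positive even integer, got {n}")
        return n

    def resolve_fmax(self, fs: float) -> float:
        fmax = fs / 2.0 if self.fmax is None else self.fmax
        if not self.fmin < fmax <= fs / 2.0 + 1e-9:
            raise MfccConfigError(
                f"need fmin < fmax <= fs/2, got fmin={self.fmin}, fmax={fmax}, fs={fs}"
            )
        return fmax

    def with_(self, **kw) -> "MfccParams":
        return replace(self, **kw)


@dataclass
class FrameMatrix:
    """Overlapping frames of one signal: ``frames`` is n_frames x T."""

    frames: np.ndarray
    fs: float
    stride: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_len(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) * self.stride / self.fs


@dataclass
class MfccMap:
    """Cepstral coefficients per frame: ``coeffs`` is n_frames x L."""

    coeffs: np.ndarray
    times: np.ndarray
    params: MfccParams
    fs: float

    def to_csv(self, path) -> None:
        """Inspection export: one row per frame, ``time_s, C1..CL``."""
        L = self.coeffs.shape[1] if self.coeffs.size else self.params.n_coeffs
        header = "time_s," + ",".join(f"C{n}" for n in range(1, L + 1))
        data = np.column_stack([self.times, self.coeffs]) if self.coeffs.size else np.empty((0, L + 1))
        np.savetxt(path, data, delimiter=",", header=header, comments="")


def pre_emphasis(x: np.ndarray, a: float = 0.97) -> np.ndarray:
    """``y(n) = x(n) - a*x(n-1)``, with ``y(0) = x(0)``."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("pre_emphasis: empty input")
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - a * x[:-1]
    return y


def n_frames_expected(n_samples: int, frame_len: int, stride: int) -> int:
    """Closed-form frame count: ``floor((N - T)/stride) + 1`` when N >= T else 0."""
    if n_samples < frame_len:
        return 0
    return (n_samples - frame_len) // stride + 1


def frame_signal(x: np.ndarray, fs: float, w: float, s: float) -> FrameMatrix:
    """Cut a signal into overlapping frames of ``round(w*fs)`` samples.

    Frame ``k`` starts at sample ``k * round(s*fs)``; frames overrunning
    the end are dropped, so a signal shorter than one frame yields zero
    frames.
    """
    x = np.asarray(x, dtype=np.float64)
    T = int(np.round(w * fs))
    stride = int(np.round(s * fs))
    if T <= 0 or stride <= 0:
        raise MfccConfigError(f"w*fs and s*fs must round to positive integers (w={w}, s={s}, fs={fs})")
    n = n_frames_expected(len(x), T, stride)
    if n == 0:
        return FrameMatrix(frames=np.empty((0, T)), fs=fs, stride=stride)
    starts = np.arange(n) * stride
    frames = x[starts[:, None] + np.arange(T)[None, :]]
    return FrameMatrix(frames=frames, fs=fs, stride=stride)


def hamming(T: int) -> np.ndarray:
    """``w(n) = 0.54 - 0.46 cos(2 pi n / (T-1))`` for n = 0..T-1."""
    if T < 2:
        raise ValueError(f"Hamming window needs T >= 2, got {T}")
    n = np.arange(T)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (T - 1))


def power_spectrum(frames: np.ndarray, nfft: int) -> np.ndarray:
    """One-sided power spectrum ``|X(k)|^2`` for k = 0..nfft/2, zero-padded."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if nfft <= 0 or nfft % 2 != 0:
        raise MfccConfigError(f"nfft must be a positive even integer, got {nfft}")
    if frames.shape[1] > nfft:
        raise MfccConfigError(f"frame length {frames.shape[1]} exceeds nfft={nfft}")
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    return (spec.real**2 + spec.imag**2)


def mel_filterbank(
    M: int, nfft: int, fs: float, fmin: float = 0.0, fmax: Optional[float] = None
) -> np.ndarray:
    """Triangular Mel filter bank on the one-sided FFT bin grid.

    The M+2 edge frequencies are Mel-uniform between ``fmin`` and
    ``fmax`` and snapped to integer bins; filter m rises linearly from
    edge m-1 to 1 at its centre bin and falls to 0 at edge m+1.  With
    integer edges adjacent triangles tile exactly: on every bin strictly
    between the first and last centres the responses sum to 1.
    """
    if fmax is None:
        fmax = fs / 2.0
    mels = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), M + 2)
    hz = mel_to_hz(mels)
    bins = np.floor((nfft + 1) * hz / fs).astype(int)
    bins = np.minimum(bins, nfft // 2)
    if np.any(np.diff(bins) < 1):
        raise MfccConfigError(
            f"band [{fmin}, {fmax}] Hz too narrow for {M} filters at nfft={nfft}, "
            f"fs={fs}: duplicate integer bin edges"
        )
    H = np.zeros((M, nfft // 2 + 1))
    k = np.arange(nfft // 2 + 1)
    for m in range(1, M + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        up = (k - lo) / (ctr - lo)
        down = (hi - k) / (hi - ctr)
        H[m - 1] = np.clip(np.minimum(up, down), 0.0, 1.0)
    return H


def log_energies(power: np.ndarray, H: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """``s(m) = ln(sum_k |X(k)|^2 H_m(k) + eps)`` per frame."""
    power = np.atleast_2d(power)
    if power.shape[1] != H.shape[1]:
        raise MfccConfigError(
            f"spectrum has {power.shape[1]} bins but filter bank expects {H.shape[1]}"
        )
    return np.log(power @ H.T + eps)


def dct_cepstrum(s: np.ndarray, L: int) -> np.ndarray:
    """``C(n) = sum_{m=1..M} s(m) cos(pi n (m-0.5)/M)`` for n = 1..L.

    This is half the unnormalized DCT-II of the log-energy row with the
    zeroth (overall energy) coefficient discarded.
    """
    s = np.atleast_2d(np.asarray(s, dtype=np.float64))
    M = s.shape[1]
    if not 1 <= L <= M:
        raise MfccConfigError(f"need 1 <= L <= M, got L={L}, M={M}")
    full = scipy.fft.dct(s, type=2, axis=1, norm=None) / 2.0
    return full[:, 1 : L + 1]


def extract_mfcc(x: np.ndarray, fs: float, p: MfccParams = MfccParams()) -> MfccMap:
    """Run the full chain on one signal and return its cepstral map."""
    x = np.asarray(x, dtype=np.float64)
    nfft = p.resolve_nfft(fs)
    fmax = p.resolve_fmax(fs)
    y = pre_emphasis(x, p.a)
    fm = frame_signal(y, fs, p.w, p.s)
    if fm.n_frames == 0:
        return MfccMap(
            coeffs=np.empty((0, p.n_coeffs)), times=np.empty(0), params=p, fs=fs
        )
    windowed = fm.frames * hamming(fm.frame_len)[None, :]
    power = power_spectrum(windowed, nfft)
    H = mel_filterbank(p.n_filters, nfft, fs, p.fmin, fmax)
    s = log_energies(power, H, p.eps)
    C = dct_cepstrum(s, p.n_coeffs)
    return MfccMap(coeffs=C, times=fm.times, params=p, fs=fs)
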