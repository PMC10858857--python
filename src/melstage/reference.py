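"""Naive direct-sum reference implementation of the MFCC chain.

This module recomputes every step of :mod:`melstage.mfcc` from its
mathematical definition — explicit O(N^2) DFT sums, the five-case
triangle formula evaluated per bin, direct DCT cosine sums, a Python
loop for framing — sharing no code with the fast path.  It exists purely
for validation: the test suite and the acceptance script compare the
production chain against it on random signals.
"""

from __future__ import annotations

import math

import numpy as np

from melstage.mfcc import MfccParams


def naive_mel(f: float) -> float:
    return 2595.0 * math.log10(1.0 + f / 700.0)


def naive_mel_inv(mel: float) -> float:
    return 700.0 * (10.0 ** (mel / 2595.0) - 1.0)


def naive_pre_emphasis(x, a):
    x = list(map(float, x))
    return np.array([x[0]] + [x[n] - a * x[n - 1] for n in range(1, len(x))])


def naive_frames(x, fs, w, s):
    """Enumerate frame start indices one by one."""
    T = int(np.round(w * fs))
    stride = int(np.round(s * fs))
    frames = []
    start = 0
    while start + T <= len(x):
        frames.append(np.asarray(x[start : start + T], dtype=np.float64))
        start += stride
    return frames, T


def naive_hamming(T):
    return np.array([0.54 - 0.46 * math.cos(2.0 * math.pi * n / (T - 1)) for n in range(T)])


def dft_tables(nfft):
    """Cosine/sine tables of the direct DFT sum for k = 0..nfft/2."""
    k = np.arange(nfft // 2 + 1)[:, None]
    n = np.arange(nfft)[None, :]
    return np.cos(-2.0 * np.pi * k * n / nfft), np.sin(-2.0 * np.pi * k * n / nfft)


def naive_power_spectrum(frame, nfft, tables=None):
    """|X(k)|^2 for k=0..nfft/2 via the direct DFT sum (matrix form)."""
    x = np.zeros(nfft)
    x[: len(frame)] = frame
    cos_t, sin_t = dft_tables(nfft) if tables is None else tables
    re = (cos_t * x).sum(axis=1)
    im = (sin_t * x).sum(axis=1)
    return re**2 + im**2


def naive_filterbank(M, nfft, fs, fmin, fmax):
    """Five-case triangle response evaluated bin by bin on integer edges."""
    mel_lo, mel_hi = naive_mel(fmin), naive_mel(fmax)
    edges = []
    for i in range(M + 2):
        hz = naive_mel_inv(mel_lo + (mel_hi - mel_lo) * i / (M + 1))
        edges.append(min(int(math.floor((nfft + 1) * hz / fs)), nfft // 2))
    H = np.zeros((M, nfft // 2 + 1))
    for m in range(1, M + 1):
        lo, ctr, hi = edges[m - 1], edges[m], edges[m + 1]
        for k in range(nfft // 2 + 1):
            if k < lo:
                H[m - 1, k] = 0.0
            elif k < ctr:
                H[m - 1, k] = (k - lo) / (ctr - lo)
            elif k == ctr:
                H[m - 1, k] = 1.0
            elif k <= hi:
                H[m - 1, k] = (hi - k) / (hi - ctr)
            else:
                H[m - 1, k] = 0.0
    return H


def naive_log_energies(power, H, eps):
    M = H.shape[0]
    return np.array([math.log(float(np.dot(power, H[m])) + eps) for m in range(M)])


def naive_dct(s, L):
    """C(n) = sum_{m=1..M} s(m) cos(pi n (m-0.5)/M), n = 1..L."""
    M = len(s)
    return np.array(
        [
            sum(s[m - 1] * math.cos(math.pi * n * (m - 0.5) / M) for m in range(1, M + 1))
            for n in range(1, L + 1)
        ]
    )


def naive_mfcc(x, fs, p: MfccParams) -> np.ndarray:
    """Full chain by direct sums; returns the n_frames x L coefficient array."""
    nfft = p.resolve_nfft(fs)
    fmax = p.resolve_fmax(fs)
    y = naive_pre_emphasis(x, p.a)
    frames, T = naive_frames(y, fs, p.w, p.s)
    if not frames:
        return np.empty((0, p.n_coeffs))
    win = naive_hamming(T)
    H = naive_filterbank(p.n_filters, nfft, fs, p.fmin, fmax)
    tables = dft_tables(nfft)
    rows = []
    for fr in frames:
        power = naive_power_spectrum(fr * win, nfft, tables)
        s = naive_log_energies(power, H, p.eps)
        rows.append(naive_dct(s, p.n_coeffs))
    return np.vstack(rows)
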