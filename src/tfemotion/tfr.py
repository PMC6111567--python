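"""Quadratic time-frequency representations: Wigner-Ville and Choi-Williams.

A segment z[n] of length M is first made analytic, a[n] = z[n] + j*HT{z[n]},
which removes negative-frequency content and thereby the cross-terms between
positive and negative frequency images.  The discrete Wigner-Ville
distribution (WVD) is the Fourier transform, over the lag index m, of the
instantaneous autocorrelation

    K[n, m] = a[n + m] * conj(a[n - m]),

taken where both indices fall inside the segment and zero elsewhere.  Because
K[n, m] spans lags of 2m samples, a 2M-point transform over m places the N=2M
frequency bins uniformly over [0, fs/2): bin k corresponds to k*(fs/2)/N Hz.
Values are scaled by 1/N so that each time row sums exactly to |a[n]|^2 and
the whole surface sums to the analytic-signal energy.

The Choi-Williams distribution (CWD) multiplies the ambiguity function (the
Doppler transform of K over n) by the exponential kernel

    Phi(nu, tau) = exp(-nu^2 * tau^2 / beta^2),

with nu the normalized Doppler in cycles/sample in [-1/2, 1/2) and tau the
lag in samples (tau = 2m for lag index m).  The kernel equals one on both
axes, so auto-terms -- which live near nu = 0 -- are preserved, while
cross-terms, which oscillate in time at the beat frequency of the interfering
components and therefore sit at nonzero Doppler, are attenuated.  Smaller
beta means stronger suppression; as beta -> infinity the kernel tends to one
and the CWD reduces to the WVD.

Both distributions are real by symmetry (K[n, -m] = conj(K[n, m])); the tiny
imaginary residue of the finite-precision transform is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

__all__ = ["AnalyticSegment", "KernelSpec", "TFR", "analytic_signal", "wvd", "cwd"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel selection for the quadratic distribution.

    ``kind`` is ``"wvd"`` (all-ones kernel) or ``"cwd"`` (exponential kernel
    with cross-term suppression parameter ``beta > 0``, default 0.5).
    """

    kind: str = "cwd"
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("wvd", "cwd"):
            raise ValueError(f"kernel kind must be 'wvd' or 'cwd', got {self.kind!r}")
        if not self.beta > 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class AnalyticSegment:
    """Complex analytic signal of one real segment; one-sided spectrum."""

    values: np.ndarray
    fs: float

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TFR:
    """Real M x N time-frequency energy surface with its kernel metadata.

    Rows index time samples (M of them); columns index N = 2M frequency bins
    uniformly spanning [0, fs/2).  Values may be negative: quadratic
    distributions are not pointwise energy densities.
    """

    values: np.ndarray
    fs: float
    kernel: KernelSpec

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    def freqs(self) -> np.ndarray:
        """Center frequency of every bin, in Hz."""
        return np.arange(self.N) * (self.fs / 2.0) / self.N

    def times(self) -> np.ndarray:
        """Time of every row, in seconds from segment start."""
        return np.arange(self.M) / self.fs


def _segment_values(segment) -> tuple[np.ndarray, float]:
    # accept a Segment, an AnalyticSegment or a bare array + fs attribute
    values = np.asarray(segment.values if hasattr(segment, "values") else segment)
    fs = getattr(segment, "fs", None)
    if fs is None:
        raise ValueError("input must carry a sampling rate (fs)")
    return values, float(fs)


def analytic_signal(segment) -> AnalyticSegment:
    """Analytic signal via the frequency-domain Hilbert transform.

    The real part equals the input exactly; the discrete spectrum of the
    output has (numerically) no negative-frequency content.
    """
    values, fs = _segment_values(segment)
    if values.ndim != 1 or values.size < 4:
        raise ValueError("segment must be a 1-D signal with at least 4 samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("segment contains non-finite samples")
    analytic = scipy.signal.hilbert(values.astype(float))
    # guarantee the bitwise identity of the real part
    analytic = values + 1j * analytic.imag
    return AnalyticSegment(values=analytic, fs=fs)


def _instantaneous_autocorrelation(a: np.ndarray) -> np.ndarray:
    """K[n, m] = a[n+m] conj(a[n-m]) on an (M, 2M) lag-wrapped grid.

    Lag index m is stored FFT-style: column m holds lag +m, column 2M - m
    holds lag -m.  Entries whose indices fall outside [0, M) are zero.
    """
    M = a.size
    nfft = 2 * M
    K = np.zeros((M, nfft), dtype=complex)
    K[:, 0] = a * np.conj(a)
    for m in range(1, (M - 1) // 2 + 1):
        n = np.arange(m, M - m)
        prod = a[n + m] * np.conj(a[n - m])
        K[n, m] = prod
        K[n, nfft - m] = np.conj(prod)
    return K


def _check_analytic(a) -> tuple[np.ndarray, float]:
    values, fs = _segment_values(a)
    if values.ndim != 1 or values.size < 8:
        raise ValueError("analytic segment must be 1-D with at least 8 samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("analytic segment contains non-finite samples")
    return np.asarray(values, dtype=complex), fs


def wvd(a) -> TFR:
    """Discrete Wigner-Ville distribution of an analytic segment."""
    values, fs = _check_analytic(a)
    K = _instantaneous_autocorrelation(values)
    W = np.fft.fft(K, axis=1).real / K.shape[1]
    return TFR(values=W, fs=fs, kernel=KernelSpec(kind="wvd", beta=np.inf))


def cwd(a, kernel: KernelSpec | None = None) -> TFR:
    """Choi-Williams distribution of an analytic segment.

    The instantaneous autocorrelation is carried to the Doppler-lag
    (ambiguity) domain by a DFT over time, multiplied by the exponential
    kernel, brought back, and Fourier-transformed over lag.
    """
    if kernel is None:
        kernel = KernelSpec(kind="cwd", beta=0.5)
    if kernel.kind != "cwd":
        raise ValueError("cwd() requires a kernel of kind 'cwd'")
    values, fs = _check_analytic(a)
    M = values.size
    nfft = 2 * M
    K = _instantaneous_autocorrelation(values)
    ambiguity = np.fft.fft(K, axis=0)
    nu = np.fft.fftfreq(M)[:, None]            # cycles/sample in [-1/2, 1/2)
    m = np.fft.fftfreq(nfft) * nfft            # signed lag index
    tau = 2.0 * m[None, :]                     # lag in samples
    kernel_surface = np.exp(-(nu ** 2) * (tau ** 2) / kernel.beta ** 2)
    smoothed = np.fft.ifft(ambiguity * kernel_surface, axis=0)
    W = np.fft.fft(smoothed, axis=1).real / nfft
    return TFR(values=W, fs=fs, kernel=kernel)
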