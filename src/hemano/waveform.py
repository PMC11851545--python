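"""Periodic inlet velocity waveforms as truncated Fourier series.

Ultrasound-style velocity samples (cross-section mean velocity vs time over
one cardiac period) are smoothed into a truncated Fourier series

    v(t) = a0 + sum_k [ a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T) ]

by linear least squares.  The fitted series is the single representation the
flow solver consumes: its harmonics drive per-harmonic developed (Womersley)
inlet profiles, and a0 is the cycle-mean velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ContractError, DataError

WAVEFORM_COLUMNS = ("time_s", "velocity_m_per_s")


@dataclass
class Waveform:
    """Truncated Fourier series of a T-periodic velocity signal (m/s)."""

    period: float
    a0: float
    a: np.ndarray  # cosine coefficients, k = 1..K
    b: np.ndarray  # sine coefficients, k = 1..K
    residual_rms: float = 0.0
    #: original (t, v) samples retained for audit
    samples: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.period <= 0:
            raise ContractError("period must be positive")
        if len(self.a) != len(self.b) or len(self.a) < 1:
            raise ContractError("need K >= 1 harmonics with matching a, b")

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def __call__(self, t):
        """Evaluate the fitted series at time(s) t (T-periodic)."""
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi / self.period
        k = np.arange(1, self.n_harmonics + 1)
        phase = np.multiply.outer(t, k) * w
        v = self.a0 + np.cos(phase) @ self.a + np.sin(phase) @ self.b
        return float(v) if v.ndim == 0 else v

    def mean(self) -> float:
        """Cycle-mean velocity (the a0 coefficient)."""
        return self.a0

    def complex_coefficients(self) -> np.ndarray:
        """c_k = a_k - i b_k such that v = a0 + Re(sum c_k e^{i k w t})."""
        return self.a - 1j * self.b

    @classmethod
    def constant(cls, value: float, period: float = 1.0) -> "Waveform":
        return cls(period=period, a0=value, a=np.zeros(1), b=np.zeros(1))


def fit_waveform(samples, K: int = 8, period: float | None = None) -> Waveform:
    """Least-squares truncated Fourier fit of (t, v) samples.

    Parameters
    ----------
    samples : array-like of shape (n, 2)
        (time s, velocity m/s) pairs with strictly increasing time spanning
        one period.
    K : int
        Number of harmonics; requires at least 2K+1 samples.
    period : float, optional
        Fundamental period; defaults to the sample span (last t - first t
        plus one mean spacing, i.e. samples are treated as one full cycle
        without a duplicated endpoint; if the last sample closes the period
        exactly, pass ``period`` explicitly).
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2:
        raise ContractError("samples must be an (n, 2) array of (t, v) pairs")
    t, v = s[:, 0], s[:, 1]
    if np.any(np.diff(t) <= 0):
        raise ContractError("sample times must be strictly increasing")
    if K < 1:
        raise ContractError("K must be >= 1")
    if len(t) < 2 * K + 1:
        raise ContractError(
            f"need at least 2K+1={2 * K + 1} samples for K={K} harmonics, got {len(t)}"
        )
    if period is None:
        dt = np.mean(np.diff(t))
        period = float(t[-1] - t[0] + dt)
    w = 2.0 * np.pi / period
    k = np.arange(1, K + 1)
    A = np.hstack(
        [
            np.ones((len(t), 1)),
            np.cos(np.outer(t, k) * w),
            np.sin(np.outer(t, k) * w),
        ]
    )
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    resid = v - A @ coef
    return Waveform(
        period=period,
        a0=float(coef[0]),
        a=coef[1 : K + 1],
        b=coef[K + 1 :],
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        samples=s,
    )


def read_waveform_csv(path) -> np.ndarray:
    """Read (time_s, velocity_m_per_s) samples from CSV (header required)."""
    df = pd.read_csv(path)
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(
            f"waveform CSV {path} is missing required column(s) {missing}; "
            f"expected header {list(WAVEFORM_COLUMNS)}"
        )
    return df[list(WAVEFORM_COLUMNS)].to_numpy(dtype=float)


def write_waveform_csv(path, samples) -> None:
    pd.DataFrame(np.asarray(samples, dtype=float), columns=list(WAVEFORM_COLUMNS)).to_csv(
        path, index=False
    )
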