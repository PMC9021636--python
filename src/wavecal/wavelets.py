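"""Mother wavelets and the continuous wavelet transform (CWT) engine.

The CWT of a discrete signal f sampled on a unit channel grid is computed as

    W(a, b) = a^{-1/2} * sum_i f(x_i) * psi((x_i - b) / a),

i.e. a cross-correlation of the boundary-extended signal with the dilated
mother wavelet sampled at integer channel offsets.  Every mother wavelet is
centred on zero at load time, so the translation parameter ``b`` addresses
the wavelet's centre: a symmetric peak at channel c produces the extremal
(mexh) or zero (haar) coefficient exactly at b = c.

Scales are positive integers in typical use (consecutive integer scale grids
are what the scalogram reduction downstream expects), but any positive real
scale is accepted by the low-level routines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pywt
from scipy.signal import correlate

__all__ = [
    "WAVELET_NAMES",
    "MotherWavelet",
    "SignalVector",
    "Scalogram",
    "UnsupportedWaveletError",
    "ScaleTooLargeError",
    "get_wavelet",
    "evaluate_wavelet",
    "boundary_extend",
    "cwt_row",
    "cwt_scalogram",
]

#: Wavelets supported by the engine (the haar/mexh/gaus2 trio has closed
#: forms; the rest are sampled from their PyWavelets filter-bank limits).
WAVELET_NAMES = (
    "haar",
    "mexh",
    "gaus2",
    "meyr",
    "db2",
    "sym2",
    "coif1",
    "bior2.2",
    "bior2.4",
    "bior2.6",
    "bior2.8",
    "rbio2.2",
    "rbio2.4",
    "rbio2.6",
    "rbio2.8",
)

#: Values of a sampled table wavelet below this fraction of max|psi| are
#: treated as outside the effective support.
_TABLE_TRUNCATION = 1e-12


class UnsupportedWaveletError(ValueError):
    """Raised for a wavelet name outside the supported set."""


class ScaleTooLargeError(ValueError):
    """Raised when the dilated wavelet dwarfs the signal it transforms."""


@dataclass(frozen=True)
class MotherWavelet:
    """A zero-mean mother wavelet centred on the origin.

    Parameters
    ----------
    name : str
        Registry name (e.g. ``"mexh"``).
    support : tuple of float
        Interval outside which the unit-scale wavelet is (numerically) zero.
    func : callable
        Vectorised evaluation of the centred unit-scale wavelet.
    """

    name: str
    support: tuple[float, float]
    func: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    @property
    def radius(self) -> float:
        """Half-width of the effective support of the unit-scale wavelet."""
        return max(abs(self.support[0]), abs(self.support[1]))

    def __call__(self, x) -> np.ndarray:
        return self.func(np.asarray(x, dtype=float))


def _haar(x: np.ndarray) -> np.ndarray:
    # Jump points sample to 0 (midpoint convention) so the kernel is exactly
    # antisymmetric on an integer grid.
    return np.where((x > -0.5) & (x < 0.0), 1.0, 0.0) - np.where(
        (x > 0.0) & (x < 0.5), 1.0, 0.0
    )


def _mexh(x: np.ndarray) -> np.ndarray:
    # Standard L2-normalised Mexican hat (negative second derivative of a
    # Gaussian): positive at the origin, so a peak in f yields a positive
    # CWT maximum at the peak centre.
    c = 2.0 / (math.sqrt(3.0) * math.pi**0.25)
    return c * (1.0 - x**2) * np.exp(-0.5 * x**2)


def _gaus2(x: np.ndarray) -> np.ndarray:
    # L2-normalised -(d^2/dx^2) exp(-x^2); same peak-positive sign
    # convention as mexh.
    c = 1.0 / math.sqrt(3.0 * math.sqrt(math.pi / 2.0))
    return c * (2.0 - 4.0 * x**2) * np.exp(-(x**2))


@lru_cache(maxsize=None)
def _table_wavelet(pywt_name: str, decomposition: bool) -> tuple[np.ndarray, np.ndarray]:
    """Sample a discrete wavelet's psi on a fine dyadic grid, centred and
    truncated to its effective support, with an exact zero-mean correction."""
    w = pywt.Wavelet(pywt_name)
    out = w.wavefun(level=12)
    if len(out) == 3:  # orthogonal: phi, psi, x
        _, psi, x = out
    else:  # biorthogonal: phi_d, psi_d, phi_r, psi_r, x
        psi = out[1] if decomposition else out[3]
        x = out[4]
    psi = np.asarray(psi, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = np.abs(psi) > _TABLE_TRUNCATION * np.abs(psi).max()
    lo, hi = np.nonzero(keep)[0][[0, -1]]
    psi, x = psi[lo : hi + 1], x[lo : hi + 1]
    psi = psi - psi.mean()  # enforce admissibility on the sampled grid
    x = x - 0.5 * (x[0] + x[-1])  # centre the support on the origin
    return x, psi


def _make_table_func(pywt_name: str) -> tuple[tuple[float, float], Callable]:
    x, psi = _table_wavelet(pywt_name, decomposition=True)

    def func(q: np.ndarray) -> np.ndarray:
        return np.interp(q, x, psi, left=0.0, right=0.0)

    return (float(x[0]), float(x[-1])), func


@lru_cache(maxsize=None)
def get_wavelet(name: str) -> MotherWavelet:
    """Return the :class:`MotherWavelet` registered under ``name``.

    Raises
    ------
    UnsupportedWaveletError
        If ``name`` is not one of :data:`WAVELET_NAMES`.
    """
    key = name.lower()
    if key == "haar":
        return MotherWavelet("haar", (-0.5, 0.5), _haar)
    if key == "mexh":
        return MotherWavelet("mexh", (-10.0, 10.0), _mexh)
    if key == "gaus2":
        return MotherWavelet("gaus2", (-8.0, 8.0), _gaus2)
    if key == "meyr":
        support, func = _make_table_func("dmey")
        return MotherWavelet("meyr", support, func)
    if key in WAVELET_NAMES:
        support, func = _make_table_func(key)
        return MotherWavelet(key, support, func)
    raise UnsupportedWaveletError(
        f"unsupported wavelet {name!r}; choose one of {', '.join(WAVELET_NAMES)}"
    )


def _as_wavelet(wavelet) -> MotherWavelet:
    if isinstance(wavelet, MotherWavelet):
        return wavelet
    return get_wavelet(str(wavelet))


def evaluate_wavelet(wavelet, scale: float, grid) -> np.ndarray:
    """Sample the dilated wavelet psi(x / a) on ``grid`` (translation b = 0).

    The 1/sqrt(a) CWT prefactor is *not* applied here; it belongs to the
    transform (:func:`cwt_row`).
    """
    w = _as_wavelet(wavelet)
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError(f"scale must be positive and finite, got {scale!r}")
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("evaluation grid must be finite")
    return w(grid / float(scale))


@dataclass(frozen=True)
class SignalVector:
    """One spectrum: a strictly increasing channel axis plus intensities."""

    channel_axis: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        axis = np.asarray(self.channel_axis, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if axis.ndim != 1 or vals.ndim != 1 or axis.size != vals.size:
            raise ValueError("channel_axis and values must be 1-D of equal length")
        if axis.size < 2:
            raise ValueError("a signal needs at least two channels")
        if not np.all(np.diff(axis) > 0):
            raise ValueError("channel_axis must be strictly increasing")
        if not (np.all(np.isfinite(axis)) and np.all(np.isfinite(vals))):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "channel_axis", axis)
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_values(cls, values) -> "SignalVector":
        values = np.asarray(values, dtype=float)
        return cls(np.arange(values.size, dtype=float), values)

    def __len__(self) -> int:
        return self.values.size


_PAD_MODES = {"symmetric": "symmetric", "reflect": "reflect", "zero": "constant"}


def boundary_extend(signal, half_width: int, mode: str = "symmetric"):
    """Extend a signal by ``half_width`` channels on each side.

    Modes: ``symmetric`` (half-point reflection, the default for spectra),
    ``reflect`` (whole-point reflection), ``zero`` (zero padding).  Returns
    the same type as the input (:class:`SignalVector` or ndarray).
    """
    if int(half_width) != half_width or half_width < 1:
        raise ValueError(f"half_width must be an integer >= 1, got {half_width!r}")
    half_width = int(half_width)
    if mode not in _PAD_MODES:
        raise ValueError(f"unknown extension mode {mode!r}; choose from {sorted(_PAD_MODES)}")
    if isinstance(signal, SignalVector):
        ext = np.pad(signal.values, half_width, mode=_PAD_MODES[mode])
        step_lo = signal.channel_axis[1] - signal.channel_axis[0]
        step_hi = signal.channel_axis[-1] - signal.channel_axis[-2]
        axis = np.concatenate(
            [
                signal.channel_axis[0] - step_lo * np.arange(half_width, 0, -1),
                signal.channel_axis,
                signal.channel_axis[-1] + step_hi * np.arange(1, half_width + 1),
            ]
        )
        return SignalVector(axis, ext)
    values = np.asarray(signal, dtype=float)
    return np.pad(values, half_width, mode=_PAD_MODES[mode])


def _signal_values(signal) -> np.ndarray:
    if isinstance(signal, SignalVector):
        return signal.values
    values = np.asarray(signal, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("signal must be 1-D with at least two samples")
    return values


def kernel_radius(wavelet, scale: float) -> int:
    """Integer half-width of the dilated wavelet's effective support."""
    return int(math.ceil(float(scale) * _as_wavelet(wavelet).radius))


def cwt_row(signal, wavelet, scale, mode: str = "symmetric") -> np.ndarray:
    """One scalogram row: CWT coefficients W(a, b) at a single scale.

    The signal is boundary-extended by the dilated kernel's radius, cross-
    correlated with the sampled kernel, and cropped back to the original
    length, so ``len(output) == len(signal)``.
    """
    w = _as_wavelet(wavelet)
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError(f"scale must be positive, got {scale!r}")
    values = _signal_values(signal)
    n = values.size
    radius = kernel_radius(w, scale)
    if radius >= 10 * n:
        raise ScaleTooLargeError(
            f"scale {scale} dilates {w.name} to radius {radius} channels, "
            f"which buries the {n}-channel signal in its own boundary extension"
        )
    if radius > n:
        warnings.warn(
            f"dilated {w.name} at scale {scale} spans {2 * radius + 1} channels, "
            f"more than twice the signal ({n} channels); coefficients are extension-dominated",
            UserWarning,
            stacklevel=2,
        )
    offsets = np.arange(-radius, radius + 1, dtype=float)
    kernel = w(offsets / float(scale))
    ext = boundary_extend(values, radius, mode=mode)
    row = correlate(ext, kernel, mode="valid", method="auto")
    return row / math.sqrt(float(scale))


@dataclass(frozen=True)
class Scalogram:
    """CWT coefficients W(a, b) on a (scales x positions) grid."""

    scales: np.ndarray
    coefficients: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        scales = np.asarray(self.scales)
        coef = np.asarray(self.coefficients, dtype=float)
        pos = np.asarray(self.positions)
        if coef.shape != (scales.size, pos.size):
            raise ValueError(
                f"coefficient matrix shape {coef.shape} does not match "
                f"{scales.size} scales x {pos.size} positions"
            )
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "positions", pos)

    @property
    def n_scales(self) -> int:
        return self.scales.size


def cwt_scalogram(signal, wavelet, scales: Sequence[int], mode: str = "symmetric") -> Scalogram:
    """Stack :func:`cwt_row` over an increasing grid of positive scales."""
    w = _as_wavelet(wavelet)
    scales = np.asarray(scales)
    if scales.size == 0:
        raise ValueError("scales must be nonempty")
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    if scales.size > 1 and not np.all(np.diff(scales.astype(float)) > 0):
        raise ValueError("scales must be strictly increasing")
    values = _signal_values(signal)
    rows = np.empty((scales.size, values.size))
    for i, a in enumerate(scales):
        try:
            rows[i] = cwt_row(values, w, a, mode=mode)
        except ScaleTooLargeError as err:
            raise ScaleTooLargeError(f"scale {a}: {err}") from err
    if isinstance(signal, SignalVector):
        positions = signal.channel_axis
    else:
        positions = np.arange(values.size)
    return Scalogram(scales, rows, positions)
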