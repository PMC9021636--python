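"""Synthetic NIR-like signals and regression datasets.

Real NIR spectra are sums of broad, heavily overlapped overtone/combination
bands riding on a smooth baseline.  The generator emulates exactly that: a
composite signal is a sum of Gaussian (or Lorentzian) sub-bands plus a
polynomial baseline plus optional white noise.  The canonical seven-band
fixture (:func:`seven_band_spec`) is built so that several neighbouring
bands merge into single apparent maxima in the composite — the situation
the wavelet max/min reconstruction is designed to resolve.

Regression datasets draw per-sample band amplitudes and define the
reference property as a linear combination of a subset of them, so the
informative channels are known exactly (ground truth for calibration and
variable-selection tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SpectralDataset
from .wavelets import SignalVector

__all__ = [
    "SubBand",
    "SyntheticSpec",
    "compose_signal",
    "make_regression_dataset",
    "seven_band_spec",
    "recovery_spec",
]


@dataclass(frozen=True)
class SubBand:
    """One spectral sub-band."""

    center: float
    width: float  # Gaussian sigma / Lorentzian half-width, in channels
    amplitude: float = 1.0
    shape: str = "gaussian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def curve(self, axis: np.ndarray, amplitude: float | None = None) -> np.ndarray:
        a = self.amplitude if amplitude is None else amplitude
        if self.shape == "gaussian":
            return a * np.exp(-0.5 * ((axis - self.center) / self.width) ** 2)
        return a * self.width**2 / ((axis - self.center) ** 2 + self.width**2)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a composite signal."""

    bands: tuple[SubBand, ...]
    baseline: tuple[float, ...] = (0.0,)  # polynomial coefficients, low order first
    noise_sd: float = 0.0
    n_channels: int = 512
    seed: int | None = None

    def __post_init__(self):
        if self.n_channels < 32:
            raise ValueError("need at least 32 channels")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "baseline", tuple(self.baseline))

    @property
    def axis(self) -> np.ndarray:
        return np.arange(self.n_channels, dtype=float)

    def baseline_curve(self) -> np.ndarray:
        return np.polynomial.polynomial.polyval(self.axis, np.asarray(self.baseline, float))


def compose_signal(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[SignalVector, list[SignalVector]]:
    """Build the composite signal and return it with its sub-band curves.

    With ``noise_sd == 0`` the output is deterministic and seed-independent,
    and the sub-band curves plus the baseline sum exactly to the composite.
    """
    axis = spec.axis
    parts = [SignalVector(axis, band.curve(axis)) for band in spec.bands]
    total = spec.baseline_curve()
    for part in parts:
        total = total + part.values
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        total = total + rng.normal(0.0, spec.noise_sd, size=axis.size)
    return SignalVector(axis, total), parts


def seven_band_spec(n_channels: int = 512, noise_sd: float = 0.0) -> SyntheticSpec:
    """The canonical seven-band test signal.

    Seven Gaussian sub-bands on a gentle quadratic baseline; two pairs are
    separated by far less than one band width, so the composite (and any
    single smoothing scale) shows five apparent maxima while the max-channel
    reconstruction keeps a maximum within two channels of every band centre.
    """
    bands = (
        SubBand(70.0, 16.0, 1.00),
        SubBand(150.0, 13.0, 0.85),
        SubBand(153.0, 7.0, 0.45),
        SubBand(245.0, 18.0, 1.05),
        SubBand(330.0, 12.0, 0.75),
        SubBand(333.0, 6.0, 0.40),
        SubBand(432.0, 15.0, 0.90),
    )
    baseline = (0.30, 8e-4, -1.2e-6)
    return SyntheticSpec(bands, baseline, noise_sd=noise_sd, n_channels=n_channels)


def recovery_spec(n_channels: int = 512) -> SyntheticSpec:
    """Five well-separated bands used for parameter-recovery datasets.

    Bands 0, 2 and 4 drive the reference property in
    :func:`make_regression_dataset`'s default coefficients; 1 and 3 are
    amplitude-varying decoys.
    """
    bands = (
        SubBand(90.0, 12.0, 1.0),
        SubBand(180.0, 14.0, 1.0),
        SubBand(260.0, 12.0, 1.0),
        SubBand(340.0, 13.0, 1.0),
        SubBand(420.0, 12.0, 1.0),
    )
    return SyntheticSpec(bands, baseline=(0.20, 5e-4, -9e-7), noise_sd=1e-3, n_channels=n_channels)


#: Default property coefficients over the recovery_spec band amplitudes.
RECOVERY_COEFFICIENTS = (1.0, 0.0, 0.7, 0.0, -0.5)


@dataclass(frozen=True)
class RegressionTruth:
    """Ground truth attached to a generated regression dataset."""

    coefficients: np.ndarray
    amplitudes: np.ndarray  # (n_samples, n_bands) drawn amplitudes
    band_centers: np.ndarray
    band_widths: np.ndarray
    informative: np.ndarray  # band indices with nonzero coefficient
    y_noise_sd: float


def make_regression_dataset(
    spec: SyntheticSpec,
    n_samples: int,
    coefficients=RECOVERY_COEFFICIENTS,
    amplitude_rel_sd: float = 0.15,
    y_noise_sd: float = 0.02,
    seed: int | None = None,
) -> tuple[SpectralDataset, RegressionTruth]:
    """Draw a spectra/property dataset with known informative bands.

    Per sample, band j's amplitude is A_j ~ Normal(amp_j, (rel_sd * amp_j)^2)
    (truncated at 5% of amp_j so bands never vanish or invert), the spectrum
    is the composite of the realised bands, and
    y = sum_j c_j A_j + Normal(0, y_noise_sd).
    """
    if n_samples < 6:
        raise ValueError("need at least 6 samples")
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.size != len(spec.bands):
        raise ValueError("one coefficient per sub-band required")
    rng = np.random.default_rng(seed)
    base = np.array([b.amplitude for b in spec.bands])
    amps = rng.normal(base, amplitude_rel_sd * np.abs(base), size=(n_samples, base.size))
    amps = np.maximum(amps, 0.05 * np.abs(base))
    axis = spec.axis
    baseline = spec.baseline_curve()
    X = np.empty((n_samples, spec.n_channels))
    for i in range(n_samples):
        s = baseline.copy()
        for j, band in enumerate(spec.bands):
            s += band.curve(axis, amplitude=amps[i, j])
        if spec.noise_sd > 0:
            s += rng.normal(0.0, spec.noise_sd, size=axis.size)
        X[i] = s
    y = amps @ coefficients
    if y_noise_sd > 0:
        y = y + rng.normal(0.0, y_noise_sd, size=n_samples)
    truth = RegressionTruth(
        coefficients=coefficients,
        amplitudes=amps,
        band_centers=np.array([b.center for b in spec.bands]),
        band_widths=np.array([b.width for b in spec.bands]),
        informative=np.nonzero(coefficients)[0],
        y_noise_sd=y_noise_sd,
    )
    return SpectralDataset(X, y, channel_axis=axis), truth
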