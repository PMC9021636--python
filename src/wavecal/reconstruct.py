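"""Max/min scalogram reduction: the reconstructed signal used for modelling.

At a single scale the dilated wavelet cannot overlap every spectral feature
optimally: narrow sub-bands respond at small scales, broad ones at large
scales.  Collapsing the scalogram with a per-channel maximum (and minimum,
for troughs) over a range of consecutive integer scales keeps, at every
channel, the strongest wavelet response available anywhere in the range —
this is the feature vector fed to the calibration model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelets import Scalogram, cwt_scalogram

__all__ = ["LAYOUTS", "ReconstructedSignal", "maxmin_channels", "reconstruct", "reconstruct_matrix"]

LAYOUTS = ("concat", "max_only", "min_only")


@dataclass(frozen=True)
class ReconstructedSignal:
    """Per-channel extreme wavelet responses over a scale range."""

    max_channel: np.ndarray
    min_channel: np.ndarray
    scale_range: tuple[int, int]

    def __post_init__(self):
        mx = np.asarray(self.max_channel, dtype=float)
        mn = np.asarray(self.min_channel, dtype=float)
        if mx.shape != mn.shape or mx.ndim != 1:
            raise ValueError("max and min channels must be 1-D of equal length")
        if np.any(mx < mn):
            raise ValueError("max_channel must dominate min_channel everywhere")
        object.__setattr__(self, "max_channel", mx)
        object.__setattr__(self, "min_channel", mn)

    def features(self, layout: str = "concat") -> np.ndarray:
        """Assemble the channels into a modelling feature vector."""
        if layout == "concat":
            return np.concatenate([self.max_channel, self.min_channel])
        if layout == "max_only":
            return self.max_channel.copy()
        if layout == "min_only":
            return self.min_channel.copy()
        raise ValueError(f"unknown layout {layout!r}; choose from {LAYOUTS}")


def maxmin_channels(scalogram: Scalogram) -> ReconstructedSignal:
    """Reduce a scalogram to per-position max and min coefficients."""
    if scalogram.n_scales < 1:
        raise ValueError("scalogram must contain at least one scale row")
    coef = scalogram.coefficients
    lo = int(np.min(scalogram.scales))
    hi = int(np.max(scalogram.scales))
    return ReconstructedSignal(coef.max(axis=0), coef.min(axis=0), (lo, hi))


def reconstruct(
    signal,
    wavelet,
    a_min: int = 1,
    a_max: int = 40,
    layout: str = "concat",
    mode: str = "symmetric",
) -> np.ndarray:
    """Reconstruct one signal over consecutive integer scales a_min..a_max.

    Returns the feature vector for ``layout``: length 2p for ``concat``,
    p for ``max_only`` / ``min_only``.
    """
    a_min, a_max = int(a_min), int(a_max)
    if not 1 <= a_min <= a_max:
        raise ValueError(f"need 1 <= a_min <= a_max, got [{a_min}, {a_max}]")
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {LAYOUTS}")
    scalogram = cwt_scalogram(signal, wavelet, np.arange(a_min, a_max + 1), mode=mode)
    return maxmin_channels(scalogram).features(layout)


def reconstruct_matrix(
    X: np.ndarray,
    wavelet,
    a_min: int = 1,
    a_max: int = 40,
    layout: str = "concat",
    mode: str = "symmetric",
) -> np.ndarray:
    """Row-wise :func:`reconstruct` of a (samples x channels) matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x channels)")
    return np.stack([reconstruct(row, wavelet, a_min, a_max, layout, mode) for row in X])
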