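"""Calibration model: CWT max/min reconstruction + PLS, statsmodels-style.

``WaveletCalibration`` holds the training spectra and the method's tuning
knobs; ``fit`` runs the full selection procedure — reconstruct the spectra
over scale ranges [a_min, a_max] for a_max on the scale grid (default
10..40 step 5), pick the PLS factor count per range with the PRESS-ratio
rule, and keep the scale range with minimum RMSEC — and returns a
``WaveletCalibrationResults`` carrying coefficients, diagnostics and a
summary table.  Uninformative-variable elimination runs off the results
object (:meth:`WaveletCalibrationResults.uve`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import uve as _uve
from .pls import PLSCalibration, PressCurve, corr_coeff, fit_pls, press_loo, rmse, select_factor
from .reconstruct import LAYOUTS, reconstruct_matrix
from .wavelets import ScaleTooLargeError, cwt_scalogram, get_wavelet

__all__ = [
    "SpectralDataset",
    "kennard_stone",
    "prefix_feature_matrices",
    "select_scale",
    "WaveletCalibration",
    "WaveletCalibrationResults",
]

DEFAULT_SCALE_GRID = (10, 15, 20, 25, 30, 35, 40)


@dataclass
class SpectralDataset:
    """Spectra (samples x channels), reference values and an optional split.

    ``split_labels`` entries are ``"cal"`` or ``"pred"``.
    """

    X: np.ndarray
    y: np.ndarray
    channel_axis: np.ndarray | None = None
    split_labels: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x channels)")
        if self.X.shape[0] != self.y.size:
            raise ValueError("X row count must equal len(y)")
        if self.X.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset contains non-finite values")
        if self.channel_axis is not None:
            self.channel_axis = np.asarray(self.channel_axis, dtype=float)
            if self.channel_axis.size != self.X.shape[1]:
                raise ValueError("channel_axis length must equal the channel count")
        if self.split_labels is not None:
            self.split_labels = np.asarray(self.split_labels)
            if self.split_labels.size != self.X.shape[0]:
                raise ValueError("split_labels length must equal the sample count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def subset(self, label: str) -> "SpectralDataset":
        if self.split_labels is None:
            raise ValueError("dataset has no split labels")
        mask = self.split_labels == label
        return SpectralDataset(self.X[mask], self.y[mask], self.channel_axis)


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Deterministic Kennard–Stone subset selection (maximin on Euclidean
    distances).  Returns the selected row indices in pick order."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    first = np.unravel_index(np.argmax(d2), d2.shape)
    selected = [int(first[0]), int(first[1])]
    np.fill_diagonal(d2, np.inf)
    min_d = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, d2[nxt])
        min_d[nxt] = -np.inf
    return np.asarray(selected)


def ks_split(X: np.ndarray, y: np.ndarray, cal_fraction: float = 0.8) -> SpectralDataset:
    """Label a dataset with a Kennard–Stone calibration/prediction split."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_cal = max(3, int(round(cal_fraction * n)))
    if n_cal >= n:
        raise ValueError("cal_fraction leaves no prediction samples")
    labels = np.full(n, "pred", dtype=object)
    labels[kennard_stone(X, n_cal)] = "cal"
    return SpectralDataset(X, y, split_labels=labels)


def prefix_feature_matrices(
    X: np.ndarray,
    wavelet,
    a_maxes: Sequence[int],
    a_min: int = 1,
    layout: str = "concat",
    mode: str = "symmetric",
) -> dict[int, np.ndarray]:
    """Feature matrices for several scale ranges [a_min, a_max] at once.

    The scalogram over a_min..max(a_maxes) is computed once per sample and
    the per-range extremes are read off with running max/min, so the scale-
    selection loop costs one transform instead of one per grid point.
    """
    X = np.asarray(X, dtype=float)
    a_maxes = sorted(int(a) for a in a_maxes)
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    scales = np.arange(a_min, a_maxes[-1] + 1)
    idx = np.searchsorted(scales, a_maxes)  # row index of each a_max
    out = {a: [] for a in a_maxes}
    for row in X:
        coef = cwt_scalogram(row, wavelet, scales, mode=mode).coefficients
        cmax = np.maximum.accumulate(coef, axis=0)
        cmin = np.minimum.accumulate(coef, axis=0)
        for a, i in zip(a_maxes, idx):
            if layout == "concat":
                out[a].append(np.concatenate([cmax[i], cmin[i]]))
            elif layout == "max_only":
                out[a].append(cmax[i].copy())
            else:
                out[a].append(cmin[i].copy())
    return {a: np.stack(rows) for a, rows in out.items()}


def select_scale(
    X: np.ndarray,
    y: np.ndarray,
    wavelet,
    scale_grid: Sequence[int] = DEFAULT_SCALE_GRID,
    a_min: int = 1,
    layout: str = "concat",
    factor_max: int = 20,
    press_ratio: float = 0.9,
    mode: str = "symmetric",
) -> tuple[int, list[dict]]:
    """Pick the scale-range endpoint a_max minimising RMSEC over the grid.

    For each grid value the factor count comes from the leave-one-out PRESS
    curve and the ratio rule; ties on RMSEC go to the smallest a_max.
    Returns (best a_max, per-scale report dicts).
    """
    scale_grid = list(scale_grid)
    if not scale_grid:
        raise ValueError("scale grid must be nonempty")
    y = np.asarray(y, dtype=float).ravel()
    reports: list[dict] = []
    try:
        feats = prefix_feature_matrices(X, wavelet, scale_grid, a_min=a_min, layout=layout)
    except ScaleTooLargeError:
        # fall back to per-scale reconstruction so smaller grid values survive
        feats = {}
        for a in scale_grid:
            try:
                feats[a] = reconstruct_matrix(X, wavelet, a_min, a, layout, mode)
            except ScaleTooLargeError as err:
                warnings.warn(f"skipping scale {a}: {err}", UserWarning, stacklevel=2)
    for a in sorted(feats):
        F = feats[a]
        try:
            curve = press_loo(F, y, factor_max)
            k = select_factor(curve, ratio_threshold=press_ratio, k_max=factor_max)
            model = fit_pls(F, y, k)
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"skipping scale {a}: {err}", UserWarning, stacklevel=2)
            continue
        reports.append(
            {
                "scale": a,
                "n_factors": model.n_factors,
                "rmsec": rmse(y, model.fitted),
                "r_c": corr_coeff(y, model.fitted),
                "press_curve": curve,
            }
        )
    if not reports:
        raise RuntimeError("scale selection failed at every grid value")
    best = min(reports, key=lambda r: (r["rmsec"], r["scale"]))
    return best["scale"], reports


class WaveletCalibration:
    """CWT max/min reconstruction + PLS calibration model.

    Parameters
    ----------
    endog : array_like
        Reference property values, one per sample (e.g. protein %).
    spectra : array_like
        Raw spectra, shape (n_samples, n_channels).
    wavelet : str or MotherWavelet
        Mother wavelet for the transform (default ``"mexh"``).
    scale_grid : sequence of int
        Candidate scale-range endpoints a_max (default 10..40 step 5).
    a_min : int
        Fixed lower end of the scale range (default 1).
    layout : {"concat", "max_only", "min_only"}
        How the max/min channels form the feature vector.
    factor_max, press_ratio :
        Cap and ratio threshold for the PRESS factor-selection rule.

    Examples
    --------
    >>> model = WaveletCalibration(y, X, wavelet="mexh")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        endog,
        spectra,
        wavelet="mexh",
        scale_grid: Sequence[int] = DEFAULT_SCALE_GRID,
        a_min: int = 1,
        layout: str = "concat",
        factor_max: int = 20,
        press_ratio: float = 0.9,
        extension_mode: str = "symmetric",
        channel_axis=None,
    ):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.spectra = np.asarray(spectra, dtype=float)
        if self.spectra.ndim != 2 or self.spectra.shape[0] != self.endog.size:
            raise ValueError("spectra must be 2-D with one row per endog value")
        self.wavelet = get_wavelet(wavelet) if isinstance(wavelet, str) else wavelet
        self.scale_grid = tuple(int(a) for a in scale_grid)
        self.a_min = int(a_min)
        if layout not in LAYOUTS:
            raise ValueError(f"unknown layout {layout!r}")
        self.layout = layout
        self.factor_max = int(factor_max)
        self.press_ratio = float(press_ratio)
        self.extension_mode = extension_mode
        self.channel_axis = None if channel_axis is None else np.asarray(channel_axis, float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y_col: str, **kwargs) -> "WaveletCalibration":
        """Build from a DataFrame whose spectral columns are all but ``y_col``."""
        y = df[y_col].to_numpy(dtype=float)
        spec_cols = [c for c in df.columns if c != y_col]
        X = df[spec_cols].to_numpy(dtype=float)
        try:
            axis = np.asarray([float(c) for c in spec_cols])
        except (TypeError, ValueError):
            axis = None
        return cls(y, X, channel_axis=axis, **kwargs)

    @classmethod
    def from_dataset(cls, dataset: SpectralDataset, **kwargs) -> "WaveletCalibration":
        data = dataset.subset("cal") if dataset.split_labels is not None else dataset
        return cls(data.y, data.X, channel_axis=data.channel_axis, **kwargs)

    def features(self, spectra=None, a_max: int | None = None) -> np.ndarray:
        """Reconstructed feature matrix for ``spectra`` (default: training)."""
        spectra = self.spectra if spectra is None else np.atleast_2d(np.asarray(spectra, float))
        if a_max is None:
            a_max = max(self.scale_grid)
        return reconstruct_matrix(
            spectra, self.wavelet, self.a_min, a_max, self.layout, self.extension_mode
        )

    def fit(self, scale: int | None = None) -> "WaveletCalibrationResults":
        """Run scale selection (unless ``scale`` pins a_max), factor selection
        and the final PLS fit."""
        if scale is None:
            best_a, reports = select_scale(
                self.spectra,
                self.endog,
                self.wavelet,
                self.scale_grid,
                self.a_min,
                self.layout,
                self.factor_max,
                self.press_ratio,
                self.extension_mode,
            )
        else:
            best_a, reports = select_scale(
                self.spectra,
                self.endog,
                self.wavelet,
                [int(scale)],
                self.a_min,
                self.layout,
                self.factor_max,
                self.press_ratio,
                self.extension_mode,
            )
        chosen = next(r for r in reports if r["scale"] == best_a)
        F = self.features(a_max=best_a)
        pls = fit_pls(F, self.endog, chosen["n_factors"])
        return WaveletCalibrationResults(self, best_a, pls, chosen["press_curve"], reports)


@dataclass
class WaveletCalibrationResults:
    """Results of a fitted :class:`WaveletCalibration`."""

    model: WaveletCalibration
    scale: int
    pls: PLSCalibration
    press_curve: PressCurve
    scale_reports: list = field(repr=False)

    @property
    def params(self) -> np.ndarray:
        """PLS regression coefficients on the reconstructed features."""
        return self.pls.coef

    @property
    def n_factors(self) -> int:
        return self.pls.n_factors

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.pls.fitted

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rmsec(self) -> float:
        return rmse(self.model.endog, self.fittedvalues)

    @property
    def r_c(self) -> float:
        return corr_coeff(self.model.endog, self.fittedvalues)

    def predict(self, spectra) -> np.ndarray:
        """Predict the property for raw spectra (reconstruct, then PLS)."""
        return self.pls.predict(self.model.features(spectra, a_max=self.scale))

    def evaluate(self, spectra, y) -> dict:
        """RMSEP and R_p on a prediction set of raw spectra."""
        pred = self.predict(spectra)
        y = np.asarray(y, dtype=float).ravel()
        return {"rmsep": rmse(y, pred), "r_p": corr_coeff(y, pred)}

    def scale_table(self) -> pd.DataFrame:
        """Per-scale RMSEC / factor diagnostics from the selection loop."""
        return pd.DataFrame(
            [{k: r[k] for k in ("scale", "n_factors", "rmsec", "r_c")} for r in self.scale_reports]
        )

    def uve(
        self,
        repetitions: int = 100,
        seed: int | None = None,
        noise_amplitude: float | None = None,
        cutoff_mode: str = "max",
    ) -> "_uve.UveSelection":
        """Uninformative-variable elimination on the reconstructed features."""
        F = self.model.features(a_max=self.scale)
        return _uve.uve_repeat(
            F,
            self.model.endog,
            self.n_factors,
            repetitions=repetitions,
            seed=seed,
            noise_amplitude=noise_amplitude,
            cutoff_mode=cutoff_mode,
        )

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        lines = [
            "Wavelet max/min reconstruction + PLS calibration",
            "=" * 56,
            f"wavelet:            {self.model.wavelet.name}",
            f"scale range:        [{self.model.a_min}, {self.scale}] (selected a = {self.scale})",
            f"layout:             {self.model.layout}",
            f"PLS factors:        {self.n_factors} (PRESS ratio rule, "
            f"threshold {self.model.press_ratio})",
            f"n samples:          {self.model.endog.size}",
            f"n features:         {self.params.size}",
            f"RMSEC:              {self.rmsec:.6g}",
            f"R_c:                {self.r_c:.6g}",
            "-" * 56,
            "scale grid (a_max, factors, RMSEC, R_c):",
        ]
        for r in self.scale_reports:
            marker = " <- selected" if r["scale"] == self.scale else ""
            lines.append(
                f"  {r['scale']:>4d}  {r['n_factors']:>3d}  "
                f"{r['rmsec']:.6g}  {r['r_c']:.6g}{marker}"
            )
        return "\n".join(lines)

    def plot_press(self, ax=None):
        """Plot the PRESS curve of the selected scale range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.press_curve.factors, self.press_curve.press, marker="o")
        ax.axvline(self.n_factors, ls="--", color="grey")
        ax.set_xlabel("PLS factors")
        ax.set_ylabel("PRESS (leave-one-out)")
        ax.set_title(f"{self.model.wavelet.name}, a_max={self.scale}")
        return ax
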