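"""Uninformative variable elimination (UVE) for PLS calibration.

Each variable gets a *stability*: the mean of its regression coefficient
over the n leave-one-out PLS submodels divided by the standard deviation of
that coefficient.  The matrix is augmented with an equal-width block of
small-amplitude uniform noise variables; the largest noise-block |stability|
(or a percentile of it) is the cut-off, and real variables whose |stability|
does not exceed it are eliminated.  Because the noise block is random, the
whole procedure is repeated (default 100 times); the retained set with the
minimum leave-one-out PRESS wins, and the intersection of all repetitions'
sets marks the variables that are always selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import nipals_coefficients, press_loo

__all__ = ["StabilityProfile", "UveSelection", "uve_stability", "uve_cutoff", "uve_repeat"]


@dataclass(frozen=True)
class StabilityProfile:
    """Per-variable stabilities for the real and noise blocks."""

    real: np.ndarray
    noise: np.ndarray
    flagged: np.ndarray  # True where a zero-variance guard fired

    def __post_init__(self):
        if self.real.shape != self.noise.shape:
            raise ValueError("noise-block length must equal the real-block length")


def _stability(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """mean/std over submodel coefficients, with a zero-variance guard."""
    mean = block.mean(axis=0)
    std = block.std(axis=0, ddof=1)
    flagged = std == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        stab = mean / std
    stab[flagged] = np.where(mean[flagged] == 0.0, 0.0, np.sign(mean[flagged]) * np.inf)
    return stab, flagged


def uve_stability(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    noise_amplitude: float | None = None,
    rng: np.random.Generator | None = None,
) -> StabilityProfile:
    """Stability profile from leave-one-out PLS fits on the noise-augmented
    matrix.

    ``noise_amplitude`` defaults to 1e-10 * max|X| (a noise block small
    enough not to perturb the real-variable coefficients, large enough to
    carry a coefficient of its own).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 4:
        raise ValueError(f"UVE needs at least 4 samples, got {n}")
    if n_factors < 1 or n_factors > min(n - 2, 2 * p):
        raise ValueError(f"n_factors={n_factors} infeasible for n={n}, p={p}")
    if rng is None:
        rng = np.random.default_rng()
    if noise_amplitude is None:
        noise_amplitude = 1e-10 * np.abs(X).max()
    noise = rng.uniform(0.0, 1.0, size=(n, p)) * noise_amplitude
    Xa = np.hstack([X, noise])
    coefs = np.empty((n, 2 * p))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = Xa[mask], y[mask]
        b = nipals_coefficients(Xi - Xi.mean(axis=0), yi - yi.mean(), n_factors)
        coefs[i] = b[-1]
        mask[i] = True
    real_stab, real_flag = _stability(coefs[:, :p])
    noise_stab, noise_flag = _stability(coefs[:, p:])
    return StabilityProfile(real_stab, noise_stab, real_flag | noise_flag)


def uve_cutoff(profile: StabilityProfile, mode: str = "max", percentile: float = 99.0) -> float:
    """Cut-off from the noise-block stabilities.

    ``"max"`` (the strict classical convention) uses max|stability| of the
    noise block; ``"percentile"`` uses the given percentile of |stability|.
    """
    noise = np.abs(profile.noise)
    noise = noise[np.isfinite(noise)]
    if noise.size == 0:
        raise ValueError("noise block has no finite stabilities")
    if mode == "max":
        return float(noise.max())
    if mode == "percentile":
        return float(np.percentile(noise, percentile))
    raise ValueError(f"unknown cutoff mode {mode!r}")


@dataclass(frozen=True)
class UveSelection:
    """Outcome of repeated UVE: best retained set plus per-repetition data."""

    cutoff: float
    retained: np.ndarray
    press: float
    stability: StabilityProfile
    always_selected: np.ndarray
    repetition_sets: list = field(repr=False)
    repetition_press: np.ndarray = field(repr=False)
    n_samples: int = 0
    seed: int | None = None

    @property
    def rmsecv(self) -> float:
        """Cross-validated RMSE of the winning retained set."""
        return float(np.sqrt(self.press / self.n_samples))


def uve_repeat(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    repetitions: int = 100,
    seed: int | None = None,
    noise_amplitude: float | None = None,
    cutoff_mode: str = "max",
) -> UveSelection:
    """Repeat stability -> cutoff -> retention with fresh noise each time.

    Each repetition's retained set is scored by the leave-one-out PRESS of a
    PLS model restricted to it; the minimum-PRESS set is returned together
    with the intersection of all repetitions' sets (``always_selected``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    master = np.random.default_rng(seed)
    streams = master.spawn(repetitions)
    best = None
    always: np.ndarray | None = None
    rep_sets: list[dict] = []
    rep_press = np.full(repetitions, np.nan)
    for r, rng in enumerate(streams):
        profile = uve_stability(X, y, n_factors, noise_amplitude=noise_amplitude, rng=rng)
        cutoff = uve_cutoff(profile, mode=cutoff_mode)
        retained = np.nonzero(np.abs(profile.real) > cutoff)[0]
        if retained.size == 0:
            warnings.warn(f"repetition {r}: no variable above cutoff; skipped", UserWarning)
            rep_sets.append({"retained": retained, "cutoff": cutoff, "n_samples": n})
            continue
        k = min(n_factors, retained.size, n - 2)
        curve = press_loo(X[:, retained], y, k)
        press = float(curve.press[k - 1])
        rep_press[r] = press
        rep_sets.append({"retained": retained, "cutoff": cutoff, "n_samples": n})
        always = retained if always is None else np.intersect1d(always, retained)
        if best is None or press < best[0]:
            best = (press, retained, cutoff, profile)
    if best is None:
        raise RuntimeError("every UVE repetition retained zero variables")
    press, retained, cutoff, profile = best
    return UveSelection(
        cutoff=cutoff,
        retained=retained,
        press=press,
        stability=profile,
        always_selected=always,
        repetition_sets=rep_sets,
        repetition_press=rep_press,
        n_samples=n,
        seed=seed,
    )


def selection_report(selection: UveSelection, channel_axis=None) -> "pd.DataFrame":
    """Per-variable table: index, channel, stability, retained flags."""
    import pandas as pd

    p = selection.stability.real.size
    idx = np.arange(p)
    retained = np.zeros(p, dtype=bool)
    retained[selection.retained] = True
    always = np.zeros(p, dtype=bool)
    always[selection.always_selected] = True
    return pd.DataFrame(
        {
            "index": idx,
            "channel": idx if channel_axis is None else np.asarray(channel_axis)[: p],
            "stability": selection.stability.real,
            "retained": retained,
            "always_selected": always,
        }
    )
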