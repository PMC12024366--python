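"""Baseline correction and normalization.

ATR spectra of powdered coprolites carry broad baseline drift (scattering,
imperfect crystal contact), and absolute absorbance depends on contact
pressure.  Band surfaces are therefore computed on baseline-corrected and,
by default, vector-normalized spectra.  Two parameter-light baseline
estimators are provided:

* ``rubberband`` -- the lower convex hull of the spectrum, interpolated
  linearly between hull vertices (the default);
* ``asymmetric_least_squares`` -- Whittaker smoothing with asymmetric
  weights (Eilers & Boelens), for baselines that are not convex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .spectra import Spectrum

BASELINE_METHODS = ("rubberband", "asymmetric_least_squares", "none")
NORMALIZATIONS = ("vector", "max", "none")


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    ``als_lambda`` (smoothness, >0) and ``als_p`` (asymmetry, in (0,1))
    only matter for the asymmetric-least-squares method.  ``norm_window``
    restricts the normalization norm to the fingerprint region so that the
    C-H / O-H stretch region does not dominate the scale.
    """

    baseline_method: str = "rubberband"
    als_lambda: float = 1e5
    als_p: float = 0.01
    als_niter: int = 10
    normalization: str = "vector"
    norm_window: tuple[float, float] = (700.0, 1800.0)
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.baseline_method not in BASELINE_METHODS:
            raise ValueError(f"baseline_method must be one of {BASELINE_METHODS}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be > 0")
        if not 0 < self.als_p < 1:
            raise ValueError("als_p must be in (0, 1)")


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of (x, y), x ascending, as a piecewise-linear
    baseline evaluated on x (Andrew monotone-chain)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # keep turn counterclockwise for a lower hull
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def _als_baseline(y: np.ndarray, lam: float, p: float, niter: int) -> np.ndarray:
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    DTD = lam * (D @ D.T)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        W = sparse.diags(w)
        z = spsolve((W + DTD).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def estimate_baseline(s: Spectrum, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Estimated baseline on the spectrum's own (descending) grid."""
    cfg = cfg or PreprocessConfig()
    if s.wavenumbers.size < 16:
        raise ValueError("baseline under-determined: fewer than 16 points")
    if cfg.baseline_method == "none":
        return np.zeros_like(s.absorbance)
    x, y = s.ascending()
    if cfg.baseline_method == "rubberband":
        base = _lower_hull_baseline(x, y)
    else:
        base = _als_baseline(y, cfg.als_lambda, cfg.als_p, cfg.als_niter)
    return base[::-1]


def baseline_correct(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Subtract the estimated baseline; optionally clamp negatives to 0."""
    cfg = cfg or PreprocessConfig()
    base = estimate_baseline(s, cfg)
    corrected = s.absorbance - base
    if cfg.clamp_negative:
        corrected = np.maximum(corrected, 0.0)
    return s.with_absorbance(corrected, note=f"baseline {cfg.baseline_method}")


def normalize(s: Spectrum, mode: str = "vector",
              window: tuple[float, float] | None = None) -> Spectrum:
    """Scale the spectrum: unit Euclidean norm (``vector``), unit maximum
    (``max``) or identity (``none``).  The norm/max is evaluated inside
    ``window`` (cm-1) when given, but the whole spectrum is rescaled."""
    if mode == "none":
        return s
    if mode not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    a = s.absorbance
    if window is not None:
        lo, hi = min(window), max(window)
        mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
        ref = a[mask] if mask.any() else a
    else:
        ref = a
    scale = float(np.linalg.norm(ref)) if mode == "vector" else float(np.max(np.abs(ref)))
    if scale == 0.0:
        raise ValueError(f"cannot {mode}-normalize an all-zero spectrum")
    return s.with_absorbance(a / scale, note=f"{mode}-normalized")


def preprocess(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Baseline-correct then normalize, per ``cfg``."""
    cfg = cfg or PreprocessConfig()
    out = baseline_correct(s, cfg)
    if cfg.normalization != "none":
        out = normalize(out, cfg.normalization, cfg.norm_window)
    return out
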