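"""Band library and the eleven per-sample band variables.

The variables mirror standard bone/coprolite FTIR practice: six mineral
descriptors (phosphate and carbonate surfaces, a crystallinity index, two
carbonate-to-phosphate peak-height ratios) and five organic descriptors
(chitin/keratin-S cluster, aliphatic C-H "cholesterol" region, amide I,
amide II, and an amide III surface used as a collagen proxy).

A band "surface" is the trapezoidal integral of absorbance over the band
window after subtracting the local linear baseline through the window
endpoints; surfaces are floored at zero.  Three windows are exceptions
whose bounds are themselves canonical peak positions -- the phosphate nu4
doublet window (560-600 cm-1, peaks at 559/600), the aliphatic C-H
massif (2850-2935 cm-1, bands at 2850/2930) and the amide I window
(1631-1650 cm-1, upper bound on the ~1650 cm-1 maximum): there a chord
through the endpoints would cancel most of the surface by construction,
so those surfaces are integrated directly above the global
(preprocessing) baseline.
Ratio variables use peak heights ("bands at 871 and 1017 cm-1"),
searched within +-8 cm-1 of the nominal position (two 4 cm-1 resolution
steps).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum

#: Canonical variable order; also the candidate-list order used for
#: tie-breaking during variable selection.
MINERAL_VARIABLES = ["PO4", "CO3", "CO3b", "CI", "CO3PO4", "CO3PO4b"]
ORGANIC_VARIABLES = ["chitin", "cholesterol", "amideII", "amideI", "collagen"]
FEATURE_NAMES = MINERAL_VARIABLES + ORGANIC_VARIABLES

#: peak-height search halfwidth, cm-1 (two resolution steps at 4 cm-1)
DEFAULT_HALFWIDTH = 8.0

#: ratio denominators smaller than this fraction of the spectrum maximum
#: flag the ratio as undefined rather than returning a huge number
RATIO_DENOM_FLOOR = 1e-4

#: (numerator position, denominator position) of the two height ratios
RATIO_DEFS: dict[str, tuple[float, float]] = {
    "CO3PO4": (871.0, 1017.0),
    "CO3PO4b": (1415.0, 575.0),
}

#: area windows, cm-1
AREA_WINDOWS: dict[str, tuple[float, float]] = {
    "PO4": (560.0, 600.0),
    "CO3": (860.0, 880.0),
    "CO3b": (1409.0, 1425.0),
    "CI": (1010.0, 1030.0),
    "chitin": (1030.0, 1160.0),
    "cholesterol": (2850.0, 2935.0),
    "amideII": (1535.0, 1556.0),
    "amideI": (1631.0, 1650.0),
    "collagen": (1240.0, 1310.0),
}

#: windows whose bounds sit on canonical peak maxima: integrated above
#: the global baseline (no endpoint chord)
NO_CHORD_WINDOWS = frozenset({"PO4", "cholesterol", "amideI"})


class BandCoverageError(ValueError):
    """A band window falls outside the spectrum's wavenumber range."""


@dataclass(frozen=True)
class BandDefinition:
    """A named wavenumber window with its quantification mode.

    ``local_baseline`` is ``"chord"`` (subtract the line through the
    window endpoints) or ``"none"`` (integrate above the global
    baseline), see module docstring.
    """

    name: str
    lo: float
    hi: float
    mode: str = "area"  # area | peak_height | peak_position
    assignment: str = ""
    local_baseline: str = "chord"  # chord | none

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo ({self.lo}) must be < hi ({self.hi})")
        if not (400.0 <= self.lo and self.hi <= 4000.0):
            raise ValueError(f"band {self.name}: window outside 400-4000 cm-1")
        if self.mode not in ("area", "peak_height", "peak_position"):
            raise ValueError(f"band {self.name}: unknown mode {self.mode!r}")
        if self.local_baseline not in ("chord", "none"):
            raise ValueError(
                f"band {self.name}: local_baseline must be chord|none")


def load_band_library(path: str | Path | None = None) -> list[BandDefinition]:
    """Load band definitions from a CSV resource (the packaged library by
    default).  Columns: name, lo, hi, mode, assignment."""
    if path is None:
        ref = resources.files("coprofir.data") / "band_library.csv"
        with resources.as_file(ref) as p:
            return load_band_library(p)
    bands = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            bands.append(BandDefinition(
                name=row["name"].strip(),
                lo=float(row["lo"]), hi=float(row["hi"]),
                mode=row.get("mode", "area").strip(),
                assignment=row.get("assignment", "").strip(),
                local_baseline=(row.get("local_baseline") or "chord").strip(),
            ))
    return bands


# ---------------------------------------------------------------------------
# primitive quantifiers
# ---------------------------------------------------------------------------

def _window_values(s: Spectrum, lo: float, hi: float, what: str) -> tuple[np.ndarray, np.ndarray]:
    """Spline-resampled absorbance over [lo, hi].

    The native grid (typically 4 cm-1) is too coarse for accurate
    quadrature/maxima over windows a few resolution steps wide, so the
    window (plus a small margin) is interpolated with a cubic spline and
    evaluated at a fine step bounded by the native step.
    """
    if lo < s.wmin or hi > s.wmax:
        raise BandCoverageError(
            f"{what}: window {lo:g}-{hi:g} cm-1 outside spectrum range "
            f"{s.wmin:g}-{s.wmax:g} cm-1")
    from scipy.interpolate import CubicSpline

    x, y = s.ascending()
    i0 = max(int(np.searchsorted(x, lo)) - 4, 0)
    i1 = min(int(np.searchsorted(x, hi)) + 4, x.size)
    step = float(np.median(np.diff(x[i0:i1])))
    fine = min(0.25, step)
    n = max(int(np.ceil((hi - lo) / fine)) + 1, 5)
    xs = np.linspace(lo, hi, n)
    ys = CubicSpline(x[i0:i1], y[i0:i1])(xs)
    return xs, ys


def integrate_band(s: Spectrum, band: BandDefinition) -> float:
    """Trapezoidal band surface, in AU*cm-1, floored at 0.

    With ``local_baseline == "chord"`` (the default) the line through the
    absorbance at the window endpoints is subtracted first; with
    ``"none"`` the absorbance is integrated as-is (the global baseline
    having been removed by preprocessing).
    """
    xs, ys = _window_values(s, band.lo, band.hi, f"band {band.name}")
    if band.local_baseline == "chord":
        ys = ys - (ys[0] + (ys[-1] - ys[0]) * (xs - xs[0]) / (xs[-1] - xs[0]))
    area = float(np.trapezoid(ys, xs))
    return max(area, 0.0)


def peak_height(s: Spectrum, at: float, halfwidth: float = DEFAULT_HALFWIDTH) -> float:
    """Maximum absorbance within ``at +- halfwidth`` cm-1 (>= 0 on
    baseline-corrected, clamped spectra)."""
    xs, ys = _window_values(s, at - halfwidth, at + halfwidth, f"peak at {at:g}")
    return float(np.max(ys))


def peak_position(s: Spectrum, lo: float, hi: float) -> float:
    """Wavenumber of the absorbance maximum in [lo, hi], refined by a
    parabola through the three grid points around the discrete maximum."""
    if lo < s.wmin or hi > s.wmax:
        raise BandCoverageError(
            f"peak_position: window {lo:g}-{hi:g} cm-1 outside spectrum range")
    x, y = s.ascending()
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 3:
        raise ValueError("peak_position window spans fewer than 3 grid points")
    xi = np.flatnonzero(mask)
    k = xi[int(np.argmax(y[xi]))]
    if k == xi[0] or k == xi[-1]:
        return float(x[k])  # maximum at window edge: no refinement possible
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # flat or concave-up triple: keep the grid point
        return float(x[k])
    delta = 0.5 * (y0 - y2) / denom
    return float(x[k] + delta * (x[k + 1] - x[k]))


def resolved_doublet(s: Spectrum, lo: float, hi: float) -> list[tuple[float, float]]:
    """Local maxima (position, height) inside [lo, hi], strongest first.

    Used e.g. for the apatite nu4 phosphate doublet near 559/600 cm-1.
    """
    from scipy.signal import find_peaks

    x, y = s.ascending()
    mask = (x >= lo) & (x <= hi)
    idx = np.flatnonzero(mask)
    peaks, _ = find_peaks(y[idx])
    out = []
    for p in peaks:
        k = idx[p]
        pos = peak_position(s, max(lo, x[k] - 6.0), min(hi, x[k] + 6.0))
        out.append((pos, float(y[k])))
    out.sort(key=lambda t: -t[1])
    return out


# ---------------------------------------------------------------------------
# the feature vector
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The eleven band variables of one sample.

    Areas are AU*cm-1, ratios dimensionless.  Ratios whose denominator is
    below ``RATIO_DENOM_FLOOR`` x the spectrum maximum are NaN and listed
    in ``undefined``.  ``irsf`` is the conventional infrared splitting
    factor (565/605 cm-1 height sum over the valley height), reported
    alongside but not part of the canonical variable set.
    """

    sample_id: str
    values: dict[str, float]
    undefined: frozenset[str] = frozenset()
    irsf: float = math.nan
    provenance: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.sample_id)


def compute_features(s: Spectrum, library: Sequence[BandDefinition] | None = None,
                     halfwidth: float = DEFAULT_HALFWIDTH) -> FeatureVector:
    """Compute all eleven band variables from a preprocessed spectrum.

    The spectrum must cover every band window (560-2935 cm-1 overall);
    otherwise a :class:`BandCoverageError` lists the missing variables.
    """
    bands = {b.name: b for b in (library or load_band_library())}
    missing = [name for name, (lo, hi) in AREA_WINDOWS.items()
               if lo < s.wmin or hi > s.wmax]
    for name, (num, den) in RATIO_DEFS.items():
        for pos in (num, den):
            if pos - halfwidth < s.wmin or pos + halfwidth > s.wmax:
                missing.append(name)
                break
    if missing:
        raise BandCoverageError(
            f"spectrum {s.sample_id!r} ({s.wmin:g}-{s.wmax:g} cm-1) does not "
            f"cover variables: {', '.join(sorted(set(missing)))}")

    values: dict[str, float] = {}
    for name, (lo, hi) in AREA_WINDOWS.items():
        band = bands.get(name) or BandDefinition(
            name, lo, hi, "area",
            local_baseline="none" if name in NO_CHORD_WINDOWS else "chord")
        values[name] = integrate_band(s, band)

    smax = float(np.max(np.abs(s.absorbance)))
    undefined: set[str] = set()
    for name, (num_at, den_at) in RATIO_DEFS.items():
        num = peak_height(s, num_at, halfwidth)
        den = peak_height(s, den_at, halfwidth)
        if den <= RATIO_DENOM_FLOOR * smax:
            values[name] = math.nan
            undefined.add(name)
        else:
            values[name] = num / den

    # conventional splitting factor over the nu4 doublet, for reference
    try:
        h565 = peak_height(s, 565.0, halfwidth)
        h605 = peak_height(s, 605.0, halfwidth)
        valley = float(s.interp(590.0))
        irsf = (h565 + h605) / valley if valley > RATIO_DENOM_FLOOR * smax else math.nan
    except BandCoverageError:
        irsf = math.nan

    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(sample_id=s.sample_id, values=ordered,
                         undefined=frozenset(undefined), irsf=irsf,
                         provenance=f"halfwidth={halfwidth:g}")


def features_table(spectra: Iterable[Spectrum],
                   library: Sequence[BandDefinition] | None = None,
                   labels: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Feature table with one row per spectrum, indexed by sample_id.

    ``labels`` optionally maps sample_id -> species/category, added as a
    ``species`` column.
    """
    library = library or load_band_library()
    rows = [compute_features(s, library).as_series() for s in spectra]
    df = pd.DataFrame(rows)
    df.index.name = "sample_id"
    if labels is not None:
        df.insert(0, "species", [labels.get(i, "") for i in df.index])
    return df
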