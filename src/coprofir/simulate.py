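"""Synthetic ATR-FTIR spectra with full ground truth.

Real hyaenid coprolite spectra are additive mixtures of a small set of
components: bone-derived bioapatite (phosphate + structural carbonate),
secondary calcite/aragonite, residual protein, lipids (cholesterol-rich in
striped hyena feces), and insect-cuticle chitin (dominant in aardwolf
feces).  The generator emulates exactly that structure: each component is
a sum of Gaussian/Lorentzian bands at literature positions, a species is a
vector of component weights with log-normal sample-to-sample dispersion,
and each measured fragment ("replicate") adds its own polynomial baseline
drift and white noise.

Because every spectrum is built from known weights, closed-form band
shapes and a known baseline, every downstream stage (baseline recovery,
band surfaces, selection, ordination, classification) can be checked
against ground truth.

A second, feature-level "planted correlation" mode draws the eleven band
variables directly from a multivariate normal with a prescribed
correlation matrix; it is used to test the variable-selection procedure
under a controlled correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import FEATURE_NAMES, MINERAL_VARIABLES, ORGANIC_VARIABLES, compute_features
from .spectra import SPECIES, Spectrum

# ---------------------------------------------------------------------------
# component band templates
# ---------------------------------------------------------------------------

#: band = (center cm-1, FWHM cm-1, relative amplitude, shape)
Band = tuple[float, float, float, str]


@dataclass(frozen=True)
class ComponentTemplate:
    """A pure spectral component as a sum of analytic band profiles."""

    name: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        for c, w, a, shape in self.bands:
            if w <= 0:
                raise ValueError(f"{self.name}: band width must be > 0")
            if a < 0:
                raise ValueError(f"{self.name}: band amplitude must be >= 0")
            if shape not in ("gaussian", "lorentzian"):
                raise ValueError(f"{self.name}: unknown band shape {shape!r}")


def _g(center: float, fwhm: float, amp: float) -> Band:
    return (center, fwhm, amp, "gaussian")


COMPONENTS: dict[str, ComponentTemplate] = {
    # calcium carbonate polymorphs
    "calcite": ComponentTemplate("calcite", (
        _g(1429, 14, 1.00), _g(877, 12, 0.45), _g(848, 12, 0.18),
        _g(713, 8, 0.20), _g(1012, 10, 0.06),
    )),
    "aragonite": ComponentTemplate("aragonite", (
        _g(1471, 14, 1.00), _g(858, 12, 0.35), _g(844, 12, 0.20),
        _g(713, 8, 0.15), _g(700, 8, 0.10), _g(1083, 10, 0.08),
    )),
    # bone mineral, split into phosphate and structural carbonate parts;
    # nu2 CO3 centred 874 (871-878 range in bioapatites)
    "bioapatite_PO4": ComponentTemplate("bioapatite_PO4", (
        _g(1020, 24, 1.00), _g(1100, 20, 0.35), _g(961, 10, 0.30),
        _g(559, 14, 0.50), _g(600, 14, 0.30),
    )),
    "bioapatite_CO3": ComponentTemplate("bioapatite_CO3", (
        _g(1415, 14, 0.85), _g(1457, 14, 0.70), _g(874, 12, 0.50),
    )),
    # organics
    "protein": ComponentTemplate("protein", (
        _g(3300, 120, 0.35), _g(1650, 25, 1.00), _g(1550, 25, 0.75),
        _g(1275, 35, 0.30), _g(2930, 30, 0.15), _g(2870, 28, 0.08),
    )),
    "collagen_std": ComponentTemplate("collagen_std", (
        _g(3310, 120, 0.40), _g(1655, 25, 1.00), _g(1550, 25, 0.85),
        _g(1240, 30, 0.50), _g(1450, 18, 0.30), _g(1080, 20, 0.20),
    )),
    "cholesterol": ComponentTemplate("cholesterol", (
        _g(2930, 24, 1.00), _g(2866, 20, 0.90), _g(2850, 18, 0.70),
        _g(1465, 18, 0.25), _g(1375, 15, 0.15), _g(1055, 20, 0.30),
        _g(950, 20, 0.20),
    )),
    "chitin": ComponentTemplate("chitin", (
        _g(3270, 110, 0.50), _g(1655, 25, 0.70), _g(1555, 25, 0.60),
        _g(1310, 25, 0.25), _g(1045, 20, 0.60), _g(1070, 20, 1.00),
        _g(1110, 20, 0.70), _g(1150, 18, 0.45), _g(2880, 30, 0.25),
    )),
    "keratin_S": ComponentTemplate("keratin_S", (
        _g(3280, 110, 0.40), _g(1650, 25, 0.80), _g(1540, 25, 0.70),
        _g(1040, 20, 0.90), _g(1075, 22, 0.60),
    )),
}


def default_grid(step: float = 4.0, lo: float = 400.0, hi: float = 4000.0) -> np.ndarray:
    """Descending wavenumber grid, instrument-style.

    Extends to 400 cm-1 (the diamond-ATR cutoff) so that the phosphate
    nu4 window (560-600 cm-1) and its 575 cm-1 ratio denominator are
    quantifiable.
    """
    return np.arange(hi, lo - 0.5 * step, -step)


def _band_sum(grid: np.ndarray, bands: Sequence[Band]) -> np.ndarray:
    y = np.zeros_like(grid, dtype=float)
    for center, fwhm, amp, shape in bands:
        if shape == "gaussian":
            sigma = fwhm / 2.3548200450309493  # FWHM -> sigma
            y += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        else:  # lorentzian
            hwhm = fwhm / 2.0
            y += amp * hwhm**2 / ((grid - center) ** 2 + hwhm**2)
    return y


def component_spectrum(name: str, grid: np.ndarray | None = None) -> Spectrum:
    """Noise-free unit-weight spectrum of one pure component (1 cm-1 grid
    by default)."""
    if name not in COMPONENTS:
        raise KeyError(f"unknown component {name!r}; have {sorted(COMPONENTS)}")
    g = default_grid(1.0) if grid is None else np.asarray(grid, float)
    return Spectrum(g, _band_sum(g, COMPONENTS[name].bands), sample_id=name,
                    provenance="synthetic pure component")


# ---------------------------------------------------------------------------
# species profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth component weights and noise settings for one species.

    ``weight_sigma`` is the standard deviation of the log-normal
    sample-to-sample multiplier on each component weight.
    """

    species: str
    weights: Mapping[str, float]
    weight_sigma: float = 0.25
    baseline_amplitude: float = 0.05
    noise_sigma: float = 0.01
    replicates: int = 4

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"{self.species}: empty component profile")
        for k, v in self.weights.items():
            if k not in COMPONENTS:
                raise ValueError(f"{self.species}: unknown component {k!r}")
            if v < 0:
                raise ValueError(f"{self.species}: negative weight for {k}")


# Default profiles encode the qualitative compositional findings:
# spotted hyena mineral-dominant with weak organics; striped hyena
# mineral-rich but cholesterol-rich; brown hyena an organic-leaning
# intermediate; aardwolf chitin-dominant with weak-to-absent phosphate
# (small positive, so carbonate/phosphate ratios stay finite).
DEFAULT_PROFILES: dict[str, SpeciesProfile] = {
    "Crocuta crocuta": SpeciesProfile("Crocuta crocuta", {
        "bioapatite_PO4": 1.00, "bioapatite_CO3": 0.55, "calcite": 0.10,
        "protein": 0.10, "cholesterol": 0.08, "chitin": 0.01, "keratin_S": 0.02,
    }),
    "Hyaena hyaena": SpeciesProfile("Hyaena hyaena", {
        "bioapatite_PO4": 0.95, "bioapatite_CO3": 0.52, "calcite": 0.09,
        "protein": 0.12, "cholesterol": 0.14, "chitin": 0.012, "keratin_S": 0.03,
    }),
    "Parahyaena brunnea": SpeciesProfile("Parahyaena brunnea", {
        "bioapatite_PO4": 0.45, "bioapatite_CO3": 0.15, "calcite": 0.03,
        "protein": 0.45, "cholesterol": 0.12, "chitin": 0.06, "keratin_S": 0.18,
    }),
    "Proteles cristatus": SpeciesProfile("Proteles cristatus", {
        "bioapatite_PO4": 0.02, "bioapatite_CO3": 0.02,
        "protein": 0.55, "cholesterol": 0.15, "chitin": 1.00, "keratin_S": 0.10,
    }),
}

#: reference materials measured alongside the coprolites
STANDARD_WEIGHTS: dict[str, Mapping[str, float]] = {
    "Sus_bone": {"bioapatite_PO4": 1.0, "bioapatite_CO3": 0.35,
                 "protein": 0.50, "cholesterol": 0.08},
    "cholesterol_std": {"cholesterol": 1.0},
    "chitin_std": {"chitin": 1.0},
    "keratin_std": {"keratin_S": 1.0},
    "BSA_std": {"protein": 1.0},
    "collagen_type1_std": {"collagen_std": 1.0},
}


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def _baseline_drift(grid: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Degree-3 polynomial drift scaled into [0, amplitude] AU."""
    if amplitude == 0:
        return np.zeros_like(grid)
    t = np.linspace(-1.0, 1.0, grid.size)
    p = np.polyval(rng.uniform(-1.0, 1.0, size=4), t)
    span = p.max() - p.min()
    if span == 0:
        return np.zeros_like(grid)
    return amplitude * (p - p.min()) / span


def synthesize_spectrum(
    profile: SpeciesProfile | Mapping[str, float] | str,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    *,
    sample_id: str = "synthetic",
    replicate: int = 0,
    draw_weights: bool = False,
) -> tuple[Spectrum, dict]:
    """Synthesize one spectrum; return it with its ground truth.

    ``profile`` may be a :class:`SpeciesProfile` (noise, drift and
    optionally log-normal weight dispersion applied), a plain component
    weight mapping (noise-free, drift-free), or a component name.  The
    ground-truth dict carries the realized weights, the baseline array and
    the noise level.
    """
    if isinstance(profile, str):
        profile = {profile: 1.0}
    if isinstance(profile, Mapping):
        profile = SpeciesProfile("custom", dict(profile),
                                 weight_sigma=0.0, baseline_amplitude=0.0,
                                 noise_sigma=0.0)
    g = default_grid(1.0) if grid is None else np.asarray(grid, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    weights = dict(profile.weights)
    if draw_weights and profile.weight_sigma > 0:
        for k in list(weights):
            weights[k] *= float(np.exp(rng.normal(0.0, profile.weight_sigma)))
    signal = np.zeros_like(g, dtype=float)
    for name, w in weights.items():
        if w:
            signal += w * _band_sum(g, COMPONENTS[name].bands)
    baseline = _baseline_drift(g, profile.baseline_amplitude, rng)
    noise = rng.normal(0.0, profile.noise_sigma, size=g.size) if profile.noise_sigma else 0.0
    spec = Spectrum(g, signal + baseline + noise, sample_id=sample_id,
                    replicate=replicate, provenance="synthetic")
    truth = {"weights": weights, "baseline": baseline,
             "noise_sigma": profile.noise_sigma, "signal": signal}
    return spec, truth


def analytic_features(weights: Mapping[str, float], step: float = 0.5) -> pd.Series:
    """Ground-truth band variables of a noise-free mixture, evaluated on a
    fine grid so that sampling error is negligible."""
    spec, _ = synthesize_spectrum(dict(weights), grid=default_grid(step))
    fv = compute_features(spec)
    return pd.Series(fv.values)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A synthetic study: replicate spectra, labels and ground truth."""

    spectra: list[Spectrum]                 # all replicate spectra
    labels: pd.DataFrame                    # sample_id, species, category
    ground_truth: pd.DataFrame              # per-sample weights + analytic features
    seed: int | None = None

    def replicates_of(self, sample_id: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.sample_id == sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels["sample_id"])


def generate_cohort(
    profiles: Mapping[str, SpeciesProfile] | None = None,
    n_per_species: int = 12,
    seed: int | None = 0,
    *,
    include_standards: bool = False,
    grid_step: float = 4.0,
    analytic: bool = True,
) -> Cohort:
    """Generate a labelled synthetic cohort, ``replicates`` spectra per
    sample (per each species' profile), reproducible under ``seed``.

    Standards, when included, are noise-free pure/reference spectra
    labelled ``category='standard'``.  The ground-truth table holds the
    realized component weights and (when ``analytic``) the fine-grid
    analytic band variables per sample.
    """
    profiles = dict(profiles or DEFAULT_PROFILES)
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    rng = np.random.default_rng(seed)
    grid = default_grid(grid_step)
    spectra: list[Spectrum] = []
    label_rows = []
    truth_rows = []
    for species, profile in profiles.items():
        short = "".join(w[0] for w in species.split()).upper()
        for i in range(n_per_species):
            sid = f"{short}-{i:03d}"
            # one weight draw per sample; fresh drift + noise per replicate
            w = {k: v * float(np.exp(rng.normal(0.0, profile.weight_sigma)))
                 for k, v in profile.weights.items()}
            for rep in range(profile.replicates):
                spec, _ = synthesize_spectrum(
                    replace(profile, weights=w), grid, rng,
                    sample_id=sid, replicate=rep, draw_weights=False)
                spectra.append(spec)
            label_rows.append({"sample_id": sid, "species": species,
                               "category": "coprolite"})
            row = {"sample_id": sid, "species": species}
            row.update({f"w_{k}": v for k, v in w.items()})
            if analytic:
                row.update(analytic_features(w).to_dict())
            truth_rows.append(row)
    if include_standards:
        for name, w in STANDARD_WEIGHTS.items():
            spec, _ = synthesize_spectrum(dict(w), grid, rng, sample_id=name)
            spectra.append(spec)
            label_rows.append({"sample_id": name, "species": name,
                               "category": "standard"})
    labels = pd.DataFrame(label_rows)
    truth = pd.DataFrame(truth_rows).set_index("sample_id") if truth_rows else pd.DataFrame()
    return Cohort(spectra=spectra, labels=labels, ground_truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir, fmt: str = "csv") -> None:
    """Write a cohort as one spectrum file per replicate plus
    ``labels.csv`` and ``ground_truth.csv``."""
    from pathlib import Path

    from .spectra import write_spectrum

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = {"csv": ".csv", "jcamp": ".jdx"}[fmt]
    for s in cohort.spectra:
        write_spectrum(s, out / f"{s.sample_id}_r{s.replicate}{suffix}", fmt)
    cohort.labels.to_csv(out / "labels.csv", index=False)
    if len(cohort.ground_truth):
        cohort.ground_truth.to_csv(out / "ground_truth.csv")


def read_cohort(in_dir) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort` (ground
    truth optional, as real data have none)."""
    from pathlib import Path

    from .spectra import read_spectrum

    src = Path(in_dir)
    labels = pd.read_csv(src / "labels.csv")
    if "category" not in labels.columns:
        labels["category"] = "coprolite"
    spectra: list[Spectrum] = []
    for sid in labels["sample_id"]:
        files = sorted(src.glob(f"{sid}_r*.*"))
        if not files:
            raise FileNotFoundError(f"no spectrum files for sample {sid!r} in {src}")
        for path in files:
            rep = int(path.stem.rsplit("_r", 1)[1])
            spectra.append(read_spectrum(path, sample_id=sid, replicate=rep))
    gt_path = src / "ground_truth.csv"
    truth = pd.read_csv(gt_path, index_col=0) if gt_path.is_file() else pd.DataFrame()
    return Cohort(spectra=spectra, labels=labels, ground_truth=truth)


# ---------------------------------------------------------------------------
# feature-level planted-correlation mode
# ---------------------------------------------------------------------------

def _corr_from_pairs(names: Sequence[str], pairs: Mapping[tuple[str, str], float]) -> pd.DataFrame:
    R = np.eye(len(names))
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), r in pairs.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return pd.DataFrame(R, index=list(names), columns=list(names))


# Default planted correlation structure.  The three largest mineral values
# and the amide I/II value are the study's reported correlation screen;
# the remaining entries encode how the variables are constructed from the
# same bands: both height ratios share their numerator band with a
# carbonate surface window (871 in 860-880; 1415 in 1409-1425), the CI
# window contains the 1017 cm-1 ratio denominator, the two ratios co-vary,
# and the collagen (amide III) proxy tracks both backbone amides while
# chitin carries amide bands of its own.  Cholesterol (aliphatic C-H) is
# uncorrelated with the rest.
MINERAL_PLANTED_CORR: pd.DataFrame = _corr_from_pairs(MINERAL_VARIABLES, {
    ("CI", "CO3"): 0.67, ("CI", "PO4"): 0.56, ("CO3b", "CO3PO4b"): 0.50,
    ("CI", "CO3PO4"): 0.50, ("CI", "CO3b"): 0.30,
    ("CO3PO4", "CO3"): 0.45, ("CO3PO4", "PO4"): 0.05,
    ("CO3PO4", "CO3PO4b"): 0.50, ("CO3PO4", "CO3b"): 0.40,
    ("CO3b", "CO3"): 0.45, ("CO3", "PO4"): 0.05,
})

ORGANIC_PLANTED_CORR: pd.DataFrame = _corr_from_pairs(ORGANIC_VARIABLES, {
    ("amideI", "amideII"): 0.99,
    ("collagen", "amideII"): 0.86, ("collagen", "amideI"): 0.80,
    ("collagen", "chitin"): 0.45,
    ("chitin", "amideII"): 0.38, ("chitin", "amideI"): 0.30,
})

#: typical variable magnitudes for the feature-level generator
PLANTED_MEANS: dict[str, float] = {
    "PO4": 2.0, "CO3": 0.8, "CO3b": 0.9, "CI": 1.5, "CO3PO4": 1.0,
    "CO3PO4b": 1.2, "chitin": 1.0, "cholesterol": 0.6, "amideII": 0.7,
    "amideI": 0.9, "collagen": 0.5,
}


def plant_correlated_features(
    n: int,
    target: pd.DataFrame | None = None,
    seed: int | None = 0,
    *,
    cv: float = 0.2,
) -> pd.DataFrame:
    """Draw ``n`` feature vectors with a prescribed correlation matrix.

    ``target`` defaults to the block-diagonal combination of
    :data:`MINERAL_PLANTED_CORR` and :data:`ORGANIC_PLANTED_CORR`.
    Variables are Gaussian around :data:`PLANTED_MEANS` with coefficient
    of variation ``cv`` (small enough that values stay positive), so
    Pearson correlations equal the planted targets.
    """
    if target is None:
        R = np.eye(len(FEATURE_NAMES))
        df = pd.DataFrame(R, index=FEATURE_NAMES, columns=FEATURE_NAMES)
        df.loc[MINERAL_VARIABLES, MINERAL_VARIABLES] = MINERAL_PLANTED_CORR.values
        df.loc[ORGANIC_VARIABLES, ORGANIC_VARIABLES] = ORGANIC_PLANTED_CORR.values
        target = df
    names = list(target.columns)
    L = np.linalg.cholesky(target.values)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(names))) @ L.T
    means = np.array([PLANTED_MEANS.get(c, 1.0) for c in names])
    X = means * (1.0 + cv * z)
    out = pd.DataFrame(X, columns=names)
    out.index = [f"planted-{i:03d}" for i in range(n)]
    out.index.name = "sample_id"
    return out
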