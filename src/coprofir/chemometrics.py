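"""Multivariate analysis: PCA, three-step variable selection, species
domains, and nearest-centroid classification.

The selection procedure screens the band variables in three steps:

1. pairwise Pearson correlation of the full spectra (a global similarity
   screen across samples);
2. PCA on the six mineral variables, with the reference standards and
   then restricted to the coprolites, followed by a correlation screen
   among the variables and an iterative discard of the most redundant
   variable (highest mean absolute correlation to the remaining
   candidates) until three remain;
3. the same procedure on the five organic variables.

PCA is run on z-scored variables (correlation-matrix PCA), because the
variables mix band areas and dimensionless ratios of very different
magnitudes.  Species domains are convex hulls of the sample scores in the
first two components; classification assigns the nearest species centroid
by Mahalanobis distance in the selected variable space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point
from shapely.geometry.base import BaseGeometry
from sklearn.decomposition import PCA as _SkPCA

from .bands import FEATURE_NAMES, MINERAL_VARIABLES, ORGANIC_VARIABLES
from .spectra import Spectrum

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# full-spectrum correlation screen
# ---------------------------------------------------------------------------

def pairwise_correlation(spectra: Sequence[Spectrum]) -> pd.DataFrame:
    """Symmetric matrix of Pearson correlations between full spectra.

    Spectra are resampled by linear interpolation onto the intersection
    of their ranges at the coarsest step.  Constant spectra get NaN
    correlations (flagged undefined) off the unit diagonal.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    lo = max(s.wmin for s in spectra)
    hi = min(s.wmax for s in spectra)
    if lo >= hi:
        raise ValueError("spectra have disjoint wavenumber ranges")
    step = max(float(np.median(np.abs(np.diff(s.wavenumbers)))) for s in spectra)
    grid = np.arange(hi, lo - 0.5 * step, -step)
    X = np.array([s.interp(grid) for s in spectra])
    ids = [s.sample_id or f"spectrum-{i}" for i, s in enumerate(spectra)]
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    for i in np.flatnonzero(sd == 0):
        R[i, :] = np.nan
        R[:, i] = np.nan
        R[i, i] = 1.0
        logger.warning("constant spectrum %s: correlations undefined", ids[i])
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation-matrix PCA of a variable subset.

    ``loadings`` is variables x components (orthonormal columns),
    ``scores`` samples x components, ``explained_fraction`` the fraction
    of total variance per component (non-increasing).  Component signs are
    fixed so the largest-magnitude loading of each component is positive.
    """

    variable_names: list[str]
    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_fraction: np.ndarray
    centered: bool = True
    scaled: bool = True
    means: np.ndarray | None = None
    stds: np.ndarray | None = None
    n_dropped: int = 0

    def project(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project new observations (same variables) into score space."""
        Z = (X[self.variable_names].to_numpy(float) - self.means) / self.stds
        S = Z @ self.loadings.to_numpy()
        return pd.DataFrame(S, index=X.index, columns=self.loadings.columns)


def run_pca(features: pd.DataFrame, variables: Sequence[str] | None = None,
            *, standardize: bool = True) -> PCAResult:
    """Correlation-matrix PCA of ``features[variables]``.

    Rows with undefined (NaN) values among the chosen variables are
    dropped with a logged count.  Requires >= 3 complete samples and
    >= 2 variables; a zero-variance variable is an error.
    """
    variables = list(variables) if variables is not None else [
        c for c in features.columns if c in FEATURE_NAMES]
    if len(variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    X = features[variables].astype(float)
    complete = X.dropna()
    n_dropped = len(X) - len(complete)
    if n_dropped:
        logger.info("run_pca: dropped %d sample(s) with undefined variables", n_dropped)
    if len(complete) < 3:
        raise ValueError(f"PCA needs >= 3 complete samples, have {len(complete)}")
    V = complete.to_numpy()
    means = V.mean(axis=0)
    stds = V.std(axis=0, ddof=1)
    if np.any(stds == 0):
        bad = [v for v, sd in zip(variables, stds) if sd == 0]
        raise ValueError(f"zero-variance variable(s): {', '.join(bad)}")
    Z = (V - means) / stds if standardize else V - means
    k = min(Z.shape[0] - 1, Z.shape[1])
    pca = _SkPCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # variables x components
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        variable_names=variables,
        loadings=pd.DataFrame(loadings, index=variables, columns=cols),
        scores=pd.DataFrame(scores, index=complete.index, columns=cols),
        explained_fraction=pca.explained_variance_ratio_.copy(),
        scaled=standardize, means=means,
        stds=stds if standardize else np.ones_like(stds),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# three-step variable selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Every intermediate quantity of the three-step selection."""

    full_spectrum_corr: pd.DataFrame | None
    feature_corr: pd.DataFrame
    mineral_pca_with_standards: PCAResult | None
    mineral_pca: PCAResult
    organic_pca_with_standards: PCAResult | None
    organic_pca: PCAResult
    mineral_discard_order: list[str]
    organic_discard_order: list[str]
    selected_mineral: list[str]
    selected_organic: list[str]

    def strongest_correlations(self, variables: Sequence[str], k: int = 3) -> list[tuple[str, str, float]]:
        sub = self.feature_corr.loc[list(variables), list(variables)]
        out = []
        for i, a in enumerate(variables):
            for b in list(variables)[i + 1:]:
                out.append((a, b, float(sub.loc[a, b])))
        out.sort(key=lambda t: -abs(t[2]))
        return out[:k]

    def to_text(self) -> str:
        lines = ["# selection report"]
        lines.append(f"selected_mineral = {' '.join(self.selected_mineral)}")
        lines.append(f"selected_organic = {' '.join(self.selected_organic)}")
        lines.append(f"mineral_discard_order = {' '.join(self.mineral_discard_order)}")
        lines.append(f"organic_discard_order = {' '.join(self.organic_discard_order)}")
        for name, pca in (("mineral", self.mineral_pca), ("organic", self.organic_pca)):
            fr = " ".join(f"{f:.4f}" for f in pca.explained_fraction)
            lines.append(f"{name}_pca_explained_fraction = {fr}")
        for a, b, r in self.strongest_correlations(self.feature_corr.columns, k=6):
            lines.append(f"corr {a} {b} = {r:.3f}")
        return "\n".join(lines) + "\n"


def iterative_discard(corr: pd.DataFrame, candidates: Sequence[str],
                      keep: int = 3) -> tuple[list[str], list[str]]:
    """Discard the candidate with the highest mean absolute correlation to
    the remaining candidates until ``keep`` remain.

    Returns (discard order, kept).  Exact ties are broken by candidate
    list order: the later-listed variable is discarded, so canonical
    variables listed first survive perfect redundancy.
    """
    remaining = list(candidates)
    order: list[str] = []
    while len(remaining) > keep:
        sub = corr.loc[remaining, remaining].abs().to_numpy()
        mean_r = (sub.sum(axis=0) - 1.0) / (len(remaining) - 1)
        tied = np.flatnonzero(mean_r == mean_r.max())
        worst = remaining[int(tied[-1])]
        order.append(worst)
        remaining.remove(worst)
    return order, remaining


def select_variables(
    features: pd.DataFrame,
    mineral_candidates: Sequence[str] = tuple(MINERAL_VARIABLES),
    organic_candidates: Sequence[str] = tuple(ORGANIC_VARIABLES),
    *,
    spectra: Sequence[Spectrum] | None = None,
    standards: pd.DataFrame | None = None,
) -> SelectionReport:
    """Run the three-step variable selection on a feature table.

    ``features`` holds the coprolite samples; ``standards`` optionally
    holds the reference materials, concatenated for the with-standards
    PCAs only.  Inter-variable correlations (the discard criterion) are
    computed on the coprolite samples alone.
    """
    if len(mineral_candidates) < 3 or len(organic_candidates) < 3:
        raise ValueError("need at least 3 candidates in each set")
    if len(features) < 6:
        raise ValueError("need at least 6 samples for the selection to be meaningful")
    full_corr = pairwise_correlation(spectra) if spectra is not None else None

    numeric = features[[c for c in features.columns if c in FEATURE_NAMES]]
    feature_corr = numeric.corr()  # pairwise-complete Pearson

    with_std = None
    if standards is not None:
        with_std = pd.concat([numeric, standards[numeric.columns]], axis=0)

    def _pca_pair(cands: Sequence[str]) -> tuple[PCAResult | None, PCAResult]:
        pw = run_pca(with_std, cands) if with_std is not None else None
        return pw, run_pca(numeric, cands)

    m_with, m_without = _pca_pair(mineral_candidates)
    o_with, o_without = _pca_pair(organic_candidates)
    m_order, m_keep = iterative_discard(feature_corr, mineral_candidates)
    o_order, o_keep = iterative_discard(feature_corr, organic_candidates)
    return SelectionReport(
        full_spectrum_corr=full_corr,
        feature_corr=feature_corr,
        mineral_pca_with_standards=m_with,
        mineral_pca=m_without,
        organic_pca_with_standards=o_with,
        organic_pca=o_without,
        mineral_discard_order=m_order,
        organic_discard_order=o_order,
        selected_mineral=m_keep,
        selected_organic=o_keep,
    )


# ---------------------------------------------------------------------------
# species domains
# ---------------------------------------------------------------------------

@dataclass
class SpeciesDomain:
    """Convex hull of one species' scores in the first two components."""

    species: str
    hull: BaseGeometry
    centroid: tuple[float, float]
    n_samples: int

    @property
    def area(self) -> float:
        return float(self.hull.area)

    def contains_point(self, x: float, y: float) -> bool:
        return bool(self.hull.buffer(1e-12).contains(Point(x, y)))

    def vertices(self) -> list[tuple[float, float]]:
        geom = self.hull
        if geom.geom_type == "Polygon":
            return list(geom.exterior.coords)
        return list(geom.coords)


def build_domains(pca: PCAResult, labels: Mapping[str, str]) -> list[SpeciesDomain]:
    """Convex hull per species in (PC1, PC2) score space.

    ``labels`` maps sample_id -> species for every scored sample; one- or
    two-sample species yield degenerate point/segment domains of area 0.
    """
    missing = [i for i in pca.scores.index if i not in labels]
    if missing:
        raise ValueError(f"no species label for sample(s): {missing[:5]}")
    pts = pca.scores[["PC1", "PC2"]]
    domains = []
    for species in dict.fromkeys(labels[i] for i in pts.index):  # stable order
        ids = [i for i in pts.index if labels[i] == species]
        coords = [tuple(map(float, pts.loc[i])) for i in ids]
        hull = MultiPoint(coords).convex_hull
        cx = float(np.mean([c[0] for c in coords]))
        cy = float(np.mean([c[1] for c in coords]))
        domains.append(SpeciesDomain(species, hull, (cx, cy), len(ids)))
    return domains


def domain_overlaps(domains: Sequence[SpeciesDomain]) -> pd.DataFrame:
    """Pairwise hull intersection areas and containment flags."""
    rows = []
    for i, a in enumerate(domains):
        for b in domains[i + 1:]:
            inter = a.hull.intersection(b.hull)
            rows.append({
                "species_a": a.species, "species_b": b.species,
                "overlap_area": float(inter.area),
                "disjoint": bool(a.hull.disjoint(b.hull)),
                "a_contains_b": bool(a.hull.buffer(1e-12).contains(b.hull)),
                "b_contains_a": bool(b.hull.buffer(1e-12).contains(a.hull)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ReferenceModel:
    """A fitted reference: selected variables, their z-scaling, per-species
    centroids, pooled shrunk covariance, PCA and domains."""

    variables: list[str]
    means: np.ndarray
    stds: np.ndarray
    centroids: pd.DataFrame            # species x variables (z-space)
    precision: np.ndarray              # inverse pooled covariance (z-space)
    pca: PCAResult
    domains: list[SpeciesDomain]


def fit_reference(features: pd.DataFrame, labels: Mapping[str, str],
                  variables: Sequence[str], *, shrinkage: float = 0.1) -> ReferenceModel:
    """Fit the classification reference in the selected variable space.

    The covariance is pooled across species (within-species deviations)
    and shrunk toward the identity with weight ``shrinkage`` to stay
    well-conditioned for the small classes."""
    variables = list(variables)
    X = features[variables].dropna()
    if len(X) < len(set(labels.values())) + 2:
        raise ValueError("too few complete samples to fit a reference")
    means = X.to_numpy().mean(axis=0)
    stds = X.to_numpy().std(axis=0, ddof=1)
    if np.any(stds == 0):
        bad = [v for v, sd in zip(variables, stds) if sd == 0]
        raise ValueError(f"zero-variance variable(s) in reference: {', '.join(bad)}")
    Z = (X - means) / stds
    spp = pd.Series({i: labels[i] for i in Z.index})
    cents = Z.groupby(spp).mean()
    pooled = np.zeros((len(variables), len(variables)))
    dof = 0
    for sp, grp in Z.groupby(spp):
        d = grp.to_numpy() - cents.loc[sp].to_numpy()
        pooled += d.T @ d
        dof += len(grp) - 1
    pooled /= max(dof, 1)
    cov = (1.0 - shrinkage) * pooled + shrinkage * np.eye(len(variables))
    precision = np.linalg.inv(cov)
    pca = run_pca(X, variables)
    domains = build_domains(pca, {i: labels[i] for i in pca.scores.index})
    return ReferenceModel(variables, means, stds, cents, precision, pca, domains)


@dataclass
class Classification:
    sample_id: str
    species: str
    confidence: float
    distances: dict[str, float]
    in_hull: dict[str, bool]


def classify(fv: pd.Series | Mapping[str, float], reference: ReferenceModel,
             sample_id: str = "") -> Classification:
    """Assign the nearest species centroid by Mahalanobis distance.

    Confidence is the softmin of the distances; convex-hull membership in
    (PC1, PC2) is reported separately for each species domain.
    """
    if isinstance(fv, Mapping) and not isinstance(fv, pd.Series):
        fv = pd.Series(dict(fv))
    vals = []
    for v in reference.variables:
        x = float(fv.get(v, np.nan))
        if not np.isfinite(x):
            raise ValueError(f"required variable {v!r} is undefined for {sample_id or 'sample'}")
        vals.append(x)
    z = (np.array(vals) - reference.means) / reference.stds
    dists = {}
    for sp, c in reference.centroids.iterrows():
        d = z - c.to_numpy()
        dists[sp] = float(np.sqrt(d @ reference.precision @ d))
    best = min(dists, key=dists.get)
    dvals = np.array(list(dists.values()))
    w = np.exp(-(dvals - dvals.min()))
    confidence = float(np.exp(-(dists[best] - dvals.min())) / w.sum())
    score = reference.pca.project(pd.DataFrame([dict(zip(reference.variables, vals))]))
    x, y = float(score.iloc[0, 0]), float(score.iloc[0, 1])
    in_hull = {d.species: d.contains_point(x, y) for d in reference.domains}
    return Classification(sample_id=sample_id or str(getattr(fv, "name", "")),
                          species=best, confidence=confidence,
                          distances=dists, in_hull=in_hull)


def classify_table(features: pd.DataFrame, reference: ReferenceModel) -> pd.DataFrame:
    rows = []
    for sid, fv in features.iterrows():
        c = classify(fv, reference, sample_id=str(sid))
        row = {"sample_id": c.sample_id, "predicted": c.species,
               "confidence": c.confidence}
        row.update({f"d_{k}": v for k, v in c.distances.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
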