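"""Statistical anatomy atlas and virtual-cohort assembly.

A principal-component atlas is fitted to a training matrix of pooled
femur features (nodal coordinates in mm concatenated with element
densities in g/cm^3, optionally followed by scalar DXA-style features).
New anatomies are synthesised by drawing each principal-component score
from the inverse empirical CDF of the training scores, so every
stochastic variable reproduces the training distribution rather than an
assumed Gaussian.  A virtual cohort is assembled by accept/reject
thinning of sampled patients until the total-hip areal bone mineral
density (aBMD) distribution matches a clinical target (Gaussian with a
prescribed mean and SD), after which anthropometry is attached through a
Gaussian copula correlated with femoral-neck aBMD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "StatisticalAtlas",
    "VirtualPatient",
    "CohortTarget",
    "FeatureROI",
    "ProjectionROI",
    "AnthropometryParams",
    "SoftTissueParams",
    "CohortInfeasibleError",
    "fit_atlas",
    "sample_patient_features",
    "sample_features",
    "compute_aBMD",
    "build_cohort",
    "sample_anthropometry",
    "soft_tissue_thickness",
]


class CohortInfeasibleError(RuntimeError):
    """Raised when the aBMD target cannot be matched from the atlas."""


@dataclass
class StatisticalAtlas:
    """PCA atlas: mean, orthonormal modes and empirical score samples.

    Attributes
    ----------
    mean_features : (P,) array
        Feature-wise training mean.
    modes : (P, K) array
        Principal-component loadings, orthonormal columns ordered by
        decreasing explained variance.
    score_samples : (n_train, K) array
        Training scores per component; each column is the empirical
        distribution sampled at synthesis time.  Columns have zero mean
        by construction (centred training data).
    explained_variance : (K,) array
        Per-component variance of the training scores.
    feature_meta : dict
        Optional layout metadata, e.g. indices of scalar aBMD features
        (``total_hip_abmd_index``, ``neck_abmd_index``).
    """

    mean_features: np.ndarray
    modes: np.ndarray
    score_samples: np.ndarray
    explained_variance: np.ndarray
    feature_meta: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.modes.shape[1]

    @property
    def n_features(self) -> int:
        return self.mean_features.shape[0]

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Project feature vectors onto the atlas modes (PC scores)."""
        x = np.asarray(features, dtype=float)
        return (x - self.mean_features) @ self.modes

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Decode PC scores back into the feature space."""
        s = np.asarray(scores, dtype=float)
        return self.mean_features + s @ self.modes.T


def fit_atlas(features: np.ndarray, feature_meta: Optional[dict] = None) -> StatisticalAtlas:
    """Fit the principal-component atlas to a training feature matrix.

    Parameters
    ----------
    features : (n_train, P) array
        One row per training femur; requires ``n_train >= 3`` and
        ``P >= n_train`` (many more features than subjects, the usual
        shape-model regime).

    Returns
    -------
    StatisticalAtlas
        With at most ``n_train - 1`` components; rank-deficient input
        (e.g. duplicated rows) reduces the component count with a
        warning.  Any training row is exactly reconstructed from its
        own scores.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix (n_train x P)")
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 training rows, got {n}")
    if p < n:
        raise ValueError(f"expected P >= n_train, got P={p} < n_train={n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite entries")

    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD; singular values below numerical rank are dropped
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k_max = n - 1
    # relative to the data scale, so identical rows (centred residual is
    # pure floating-point noise) yield zero informative components
    scale = max(S[0] if S.size else 0.0, float(np.abs(X).max()), 1.0)
    tol = scale * max(n, p) * np.finfo(float).eps
    k = int(min(k_max, np.sum(S > tol)))
    if k < k_max:
        warnings.warn(
            f"rank-deficient training matrix: keeping {k} of {k_max} possible components",
            RuntimeWarning,
            stacklevel=2,
        )
    modes = Vt[:k].T
    scores = U[:, :k] * S[:k]
    var = S[:k] ** 2 / (n - 1)
    return StatisticalAtlas(
        mean_features=mean,
        modes=modes,
        score_samples=scores,
        explained_variance=var,
        feature_meta=dict(feature_meta or {}),
    )


def _sample_scores(atlas: StatisticalAtlas, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, K) scores from the per-component inverse empirical CDFs.

    Linear interpolation between order statistics of the training
    scores; components are sampled independently.
    """
    u = rng.uniform(size=(n, atlas.K))
    out = np.empty((n, atlas.K))
    for k in range(atlas.K):
        out[:, k] = np.quantile(atlas.score_samples[:, k], u[:, k], method="linear")
    return out


def sample_features(
    atlas: StatisticalAtlas, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Synthesise ``size`` feature vectors, shape (size, P)."""
    if atlas.K == 0:
        return np.tile(atlas.mean_features, (size, 1))
    scores = _sample_scores(atlas, size, rng)
    return atlas.reconstruct(scores)


def sample_patient_features(atlas: StatisticalAtlas, rng: np.random.Generator) -> np.ndarray:
    """Synthesise one virtual-patient feature vector (1-D, length P)."""
    return sample_features(atlas, rng, size=1)[0]


# ---------------------------------------------------------------------------
# aBMD evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureROI:
    """aBMD carried directly as an atlas feature at ``index``."""

    index: int


@dataclass(frozen=True)
class ProjectionROI:
    """DXA-style coronal projection over a meshed region.

    The feature vector is decoded as ``3 * n_nodes`` coordinates (mm,
    xyz interleaved) followed by ``n_elements`` element densities
    (g/cm^3).  Projection is along the anteroposterior (y) axis onto
    the coronal x-z plane; the projected area is the convex hull of the
    projected nodes of the selected elements.  ``window`` optionally
    restricts the region to elements whose centroid falls inside
    (xmin, xmax, zmin, zmax) in mm.
    """

    n_nodes: int
    elements: np.ndarray  # (n_elements, >=4) corner-node connectivity
    window: Optional[tuple] = None


ROISpec = Union[FeatureROI, ProjectionROI]


def _tet_volumes(coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p0 = coords[elements[:, 0]]
    e1 = coords[elements[:, 1]] - p0
    e2 = coords[elements[:, 2]] - p0
    e3 = coords[elements[:, 3]] - p0
    return np.abs(np.einsum("ij,ij->i", e1, np.cross(e2, e3))) / 6.0


def compute_aBMD(features: np.ndarray, roi: ROISpec) -> float:
    """Areal bone mineral density (g/cm^2) of a feature vector.

    For a :class:`ProjectionROI` this is the total mineral mass of the
    selected elements divided by the area of their coronal-plane
    projection; it is homogeneous of degree 1 in density and for a
    uniform slab of density rho (g/cm^3) and thickness t (cm) equals
    ``rho * t`` exactly.
    """
    x = np.asarray(features, dtype=float).ravel()
    if isinstance(roi, FeatureROI):
        return float(x[roi.index])
    from scipy.spatial import ConvexHull

    elems = np.asarray(roi.elements, dtype=int)[:, :4]
    coords = x[: 3 * roi.n_nodes].reshape(roi.n_nodes, 3)
    dens = x[3 * roi.n_nodes : 3 * roi.n_nodes + len(elems)]
    if roi.window is not None:
        cent = coords[elems].mean(axis=1)
        xmin, xmax, zmin, zmax = roi.window
        keep = (
            (cent[:, 0] >= xmin)
            & (cent[:, 0] <= xmax)
            & (cent[:, 2] >= zmin)
            & (cent[:, 2] <= zmax)
        )
        elems = elems[keep]
        dens = dens[keep]
    if len(elems) == 0:
        raise ValueError("empty ROI: no elements selected for aBMD projection")
    vol_mm3 = _tet_volumes(coords, elems)
    mass_g = float(np.sum(dens * vol_mm3)) / 1000.0  # mm^3 -> cm^3
    nodes = np.unique(elems)
    proj = coords[nodes][:, [0, 2]]  # coronal plane
    hull = ConvexHull(proj)
    area_cm2 = hull.volume / 100.0  # 2-D hull "volume" is area, mm^2 -> cm^2
    return mass_g / area_cm2


# ---------------------------------------------------------------------------
# Anthropometry and soft tissue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnthropometryParams:
    """Gaussian-copula anthropometry model for postmenopausal women.

    Height and weight are each correlated ``corr_abmd`` (Pearson, on
    the latent Gaussian scale) with femoral-neck aBMD and
    ``corr_height_weight`` with each other.  Marginals default to
    postmenopausal-women reference values.
    """

    height_mean: float = 1.60  # m
    height_sd: float = 0.06
    weight_mean: float = 66.0  # kg
    weight_sd: float = 11.0
    corr_abmd: float = 0.4
    corr_height_weight: float = 0.5
    neck_abmd_mean: float = 0.56  # g/cm^2, used to standardise neck aBMD
    neck_abmd_sd: float = 0.08

    def conditional_chol(self) -> np.ndarray:
        """Cholesky factor of cov[(z_h, z_w) | z_a]."""
        r, rhw = self.corr_abmd, self.corr_height_weight
        cov = np.array([[1 - r**2, rhw - r**2], [rhw - r**2, 1 - r**2]])
        return np.linalg.cholesky(cov)


@dataclass(frozen=True)
class SoftTissueParams:
    """Linear BMI -> trochanteric soft-tissue-thickness relationship."""

    intercept: float = -10.0  # mm
    slope: float = 1.2  # mm per kg/m^2
    floor: float = 2.0  # mm, physical lower clip


def sample_anthropometry(
    neck_aBMD,
    rng: np.random.Generator,
    params: AnthropometryParams = AnthropometryParams(),
):
    """Draw (height m, weight kg, BMI kg/m^2) correlated with neck aBMD.

    Accepts a scalar or an array of neck aBMD values; non-positive
    draws of height or weight are resampled (truncation).
    """
    a = np.atleast_1d(np.asarray(neck_aBMD, dtype=float))
    if np.any(a <= 0):
        raise ValueError("neck aBMD must be positive")
    z_a = (a - params.neck_abmd_mean) / params.neck_abmd_sd
    L = params.conditional_chol()
    n = a.shape[0]
    height = np.full(n, -1.0)
    weight = np.full(n, -1.0)
    todo = np.ones(n, dtype=bool)
    while np.any(todo):
        eps = rng.standard_normal((int(todo.sum()), 2))
        zhw = params.corr_abmd * z_a[todo, None] + eps @ L.T
        height[todo] = params.height_mean + params.height_sd * zhw[:, 0]
        weight[todo] = params.weight_mean + params.weight_sd * zhw[:, 1]
        todo = (height <= 0) | (weight <= 0)
    bmi = weight / height**2
    if np.isscalar(neck_aBMD) or np.asarray(neck_aBMD).ndim == 0:
        return float(height[0]), float(weight[0]), float(bmi[0])
    return height, weight, bmi


def soft_tissue_thickness(bmi, params: SoftTissueParams = SoftTissueParams()):
    """Trochanteric soft-tissue thickness (mm) from BMI, linear with a floor."""
    b = np.asarray(bmi, dtype=float)
    if np.any(b <= 0):
        raise ValueError("BMI must be positive")
    stt = np.maximum(params.intercept + params.slope * b, params.floor)
    return float(stt) if b.ndim == 0 else stt


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTarget:
    """Target cohort size and total-hip aBMD distribution (Gaussian)."""

    n_patients: int
    aBMD_mean: float  # g/cm^2
    aBMD_sd: float

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.aBMD_sd <= 0:
            raise ValueError("aBMD_sd must be > 0")


@dataclass
class VirtualPatient:
    """One synthetic subject of the virtual cohort."""

    id: str
    total_hip_aBMD: float  # g/cm^2
    neck_aBMD: float  # g/cm^2
    height: float  # m
    weight: float  # kg
    BMI: float  # kg/m^2
    soft_tissue_thickness: float  # mm
    strength: object = None  # StrengthSurface, attached by the surrogate
    state: str = "active"
    fracture_year: Optional[int] = None

    def __post_init__(self):
        if self.total_hip_aBMD <= 0 or self.neck_aBMD <= 0:
            raise ValueError("aBMD values must be positive")
        if self.soft_tissue_thickness <= 0:
            raise ValueError("soft tissue thickness must be positive")
        if abs(self.BMI - self.weight / self.height**2) > 1e-9:
            raise ValueError("BMI inconsistent with height and weight")
        if (self.state == "fractured") != (self.fracture_year is not None):
            raise ValueError("fracture_year must be present iff state is 'fractured'")


def _patient_abmd(features_batch: np.ndarray, roi: ROISpec) -> np.ndarray:
    if isinstance(roi, FeatureROI):
        return features_batch[:, roi.index]
    return np.array([compute_aBMD(f, roi) for f in features_batch])


def build_cohort(
    atlas: StatisticalAtlas,
    target: CohortTarget,
    rng: np.random.Generator,
    *,
    roi: Optional[ROISpec] = None,
    neck_roi: Optional[ROISpec] = None,
    neck_to_total_ratio: float = 0.82,
    anthro: AnthropometryParams = AnthropometryParams(),
    stt_params: SoftTissueParams = SoftTissueParams(),
    surrogate=None,
    n_presample: int = 2000,
    envelope: float = 1.2,
    batch_size: int = 1000,
    min_acceptance: float = 1e-4,
) -> list:
    """Assemble a virtual cohort whose total-hip aBMD matches ``target``.

    Patients are proposed from the atlas and thinned by accept/reject:
    the acceptance probability is the ratio of the Gaussian target
    density to a kernel-density estimate of the proposal aBMD density,
    bounded by an ``envelope``-inflated supremum estimated on a
    presample.  Neck aBMD comes from ``neck_roi`` if given, otherwise
    as ``neck_to_total_ratio`` times total-hip aBMD.  If ``surrogate``
    (a :class:`~silicofem.strength.SurrogateParams`) is given, a
    direction-dependent strength surface is attached to every patient.

    Raises
    ------
    CohortInfeasibleError
        If the target mean lies outside the proposal aBMD support or
        the running acceptance rate falls below ``min_acceptance``.
    """
    from .strength import surrogate_strength_surface

    if roi is None:
        if "total_hip_abmd_index" not in atlas.feature_meta:
            raise ValueError("no ROI given and atlas has no total_hip_abmd_index")
        roi = FeatureROI(atlas.feature_meta["total_hip_abmd_index"])
    if neck_roi is None and "neck_abmd_index" in atlas.feature_meta:
        neck_roi = FeatureROI(atlas.feature_meta["neck_abmd_index"])

    # proposal-density estimate and bounded envelope from a presample
    pre = sample_features(atlas, rng, size=n_presample)
    pre_abmd = _patient_abmd(pre, roi)
    if not (pre_abmd.min() <= target.aBMD_mean <= pre_abmd.max()):
        raise CohortInfeasibleError(
            f"target aBMD mean {target.aBMD_mean:.3f} outside atlas support "
            f"[{pre_abmd.min():.3f}, {pre_abmd.max():.3f}]"
        )
    kde = stats.gaussian_kde(pre_abmd)
    tgt = stats.norm(target.aBMD_mean, target.aBMD_sd)
    ratio = tgt.pdf(pre_abmd) / np.maximum(kde(pre_abmd), 1e-300)
    M = envelope * float(ratio.max())

    accepted_feats = []
    n_accepted = 0
    n_proposed = 0
    while n_accepted < target.n_patients:
        batch = sample_features(atlas, rng, size=batch_size)
        abmd = _patient_abmd(batch, roi)
        ok = abmd > 0
        p_acc = np.zeros(batch_size)
        p_acc[ok] = tgt.pdf(abmd[ok]) / (M * np.maximum(kde(abmd[ok]), 1e-300))
        keep = rng.uniform(size=batch_size) < p_acc
        accepted_feats.append(batch[keep])
        n_accepted += int(keep.sum())
        n_proposed += batch_size
        if n_proposed >= 20 * batch_size and n_accepted / n_proposed < min_acceptance:
            raise CohortInfeasibleError(
                f"acceptance rate {n_accepted / n_proposed:.2e} below {min_acceptance:.0e}; "
                "atlas incompatible with target aBMD distribution"
            )
    feats = np.concatenate(accepted_feats, axis=0)[: target.n_patients]

    total = _patient_abmd(feats, roi)
    if neck_roi is not None:
        neck = _patient_abmd(feats, neck_roi)
    else:
        neck = neck_to_total_ratio * total
    neck = np.maximum(neck, 1e-6)
    height, weight, bmi = sample_anthropometry(neck, rng, anthro)
    stt = soft_tissue_thickness(bmi, stt_params)

    patients = []
    for i in range(target.n_patients):
        surface = None
        if surrogate is not None:
            surface = surrogate_strength_surface(total[i], rng, surrogate)
        patients.append(
            VirtualPatient(
                id=f"P{i + 1:06d}",
                total_hip_aBMD=float(total[i]),
                neck_aBMD=float(neck[i]),
                height=float(height[i]),
                weight=float(weight[i]),
                BMI=float(bmi[i]),
                soft_tissue_thickness=float(stt[i]),
                strength=surface,
            )
        )
    return patients
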