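"""Synthetic inputs with built-in ground truth.

Every input the pipeline needs can be generated here with a controlled
answer key, so each downstream module has an oracle without any
external data:

* Gaussian atlas training matrices with a prescribed covariance
  spectrum and total-hip / femoral-neck aBMD features linked linearly
  to the latent scores (the stand-in for a CT-based femur training
  set);
* toy quadratic-tetrahedral box meshes carrying nodal principal-strain
  fields whose strain-criterion failure load is computed by the
  generator itself with an independent brute-force pass;
* ready-to-run trial bundles mirroring the placebo arms of two large
  osteoporosis trials (LIFT-like and FREEDOM-like).

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .atlas import CohortTarget
from .strength import (
    COMPRESSIVE_STRAIN_LIMIT,
    REFERENCE_LOAD_N,
    TENSILE_STRAIN_LIMIT,
    StrainField,
)

__all__ = [
    "FixtureSpec",
    "ToyStrainFixture",
    "TrialBundle",
    "generate_atlas_training",
    "generate_toy_strainfield",
    "make_box_tet10_mesh",
    "reference_configs",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Configuration of the synthetic generators.

    ``spectrum`` is the decreasing list of latent covariance
    eigenvalues; ``None`` selects a geometric spectrum of length
    ``n_train - 1`` (full numerical rank, so the fitted atlas keeps the
    maximal component count).  aBMD features are appended as the last
    two columns with means/SDs below and a 0.85 latent correlation
    between total-hip and neck values.
    """

    n_train: int = 94
    n_features: int = 240
    spectrum: Optional[tuple] = None
    total_abmd_mean: float = 0.72  # g/cm^2
    total_abmd_sd: float = 0.13
    neck_abmd_mean: float = 0.56
    neck_abmd_sd: float = 0.09
    neck_total_corr: float = 0.85
    mesh_cells: Tuple[int, int, int] = (2, 2, 2)
    cell_size_mm: float = 10.0
    strain_pattern: str = "constant"
    seed: int = 0

    def resolved_spectrum(self) -> np.ndarray:
        if self.spectrum is not None:
            s = np.asarray(self.spectrum, dtype=float)
        else:
            k = min(self.n_train - 1, self.n_features - 2)
            s = 4.0 * 0.92 ** np.arange(k)
            s = np.maximum(s, 1e-3)
        if np.any(s < 0) or np.any(np.diff(s) > 0):
            raise ValueError("spectrum must be non-negative and non-increasing")
        return s


def generate_atlas_training(
    spec: FixtureSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, dict]:
    """Synthesise an (n_train, n_features) training matrix plus layout metadata.

    Rows are ``mean + z @ Q.T`` with ``z ~ N(0, diag(spectrum))`` and Q
    orthonormal over the first ``n_features - 2`` (core) columns; the
    last two columns are total-hip and neck aBMD, affine in the latent
    scores, so downstream correlation recovery has known ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lam = spec.resolved_spectrum()
    k0 = lam.size
    n_core = spec.n_features - 2
    if n_core < k0:
        raise ValueError("n_features - 2 must be >= spectrum length")

    # deterministic core mean, orthonormal loadings from the generator stream
    mean_core = 50.0 + 10.0 * np.sin(np.arange(n_core) / 7.0)
    A = rng.standard_normal((n_core, k0))
    Q, _ = np.linalg.qr(A)
    z = rng.standard_normal((spec.n_train, k0)) * np.sqrt(lam)
    core = mean_core + z @ Q.T

    # aBMD latent links: weights along the leading components
    m = min(5, k0)
    w_t = np.zeros(k0)
    w_t[:m] = np.sqrt(lam[:m])
    var_t = float(np.sum(w_t**2 * lam))
    t = (z @ w_t) / np.sqrt(var_t) if var_t > 0 else np.zeros(spec.n_train)
    w_u = np.zeros(k0)
    w_u[m : min(2 * m, k0)] = np.sqrt(lam[m : min(2 * m, k0)])
    var_u = float(np.sum(w_u**2 * lam))
    u = (z @ w_u) / np.sqrt(var_u) if var_u > 0 else np.zeros(spec.n_train)

    rho = spec.neck_total_corr
    total = spec.total_abmd_mean + spec.total_abmd_sd * t
    neck = spec.neck_abmd_mean + spec.neck_abmd_sd * (rho * t + np.sqrt(1 - rho**2) * u)

    X = np.column_stack([core, total, neck])
    meta = {
        "total_hip_abmd_index": spec.n_features - 2,
        "neck_abmd_index": spec.n_features - 1,
        "n_core_features": n_core,
    }
    return X, meta


# ---------------------------------------------------------------------------
# Toy quadratic-tetrahedral meshes with strain fields
# ---------------------------------------------------------------------------

# 6-tet decomposition of a hexahedron around the 0-6 diagonal
_HEX_TO_TETS = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6), (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]
# tet10 midside order: edges (0,1),(1,2),(0,2),(0,3),(1,3),(2,3)
_TET_EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]


def make_box_tet10_mesh(cells: Tuple[int, int, int], cell_size: float):
    """Straight-edge quadratic-tet mesh of a box; returns (nodes, elements, surface_mask).

    Corner nodes on a regular grid, each cell split into six tets,
    midside nodes at edge midpoints.  Surface nodes are those lying on
    a face of the box.
    """
    nx, ny, nz = cells
    h = cell_size
    grid = np.array(
        [[i * h, j * h, k * h] for i in range(nx + 1) for j in range(ny + 1) for k in range(nz + 1)]
    )

    def gid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    nodes = [tuple(p) for p in grid]
    node_index = {p: idx for idx, p in enumerate(nodes)}
    corner_tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = [
                    gid(i, j, k),
                    gid(i + 1, j, k),
                    gid(i + 1, j + 1, k),
                    gid(i, j + 1, k),
                    gid(i, j, k + 1),
                    gid(i + 1, j, k + 1),
                    gid(i + 1, j + 1, k + 1),
                    gid(i, j + 1, k + 1),
                ]
                for tet in _HEX_TO_TETS:
                    corner_tets.append([c[v] for v in tet])

    coords = [list(p) for p in nodes]
    elements = []
    midside = {}
    for tet in corner_tets:
        conn = list(tet)
        for a, b in _TET_EDGES:
            key = tuple(sorted((tet[a], tet[b])))
            if key not in midside:
                mid = tuple((np.array(coords[key[0]]) + np.array(coords[key[1]])) / 2.0)
                if mid in node_index:
                    midside[key] = node_index[mid]
                else:
                    midside[key] = len(coords)
                    node_index[mid] = len(coords)
                    coords.append(list(mid))
            conn.append(midside[key])
        elements.append(conn)

    nodes_arr = np.asarray(coords, dtype=float)
    elements_arr = np.asarray(elements, dtype=int)
    L = np.array([nx * h, ny * h, nz * h])
    tol = 1e-9
    on_face = (np.abs(nodes_arr) < tol) | (np.abs(nodes_arr - L) < tol)
    surface_mask = on_face.any(axis=1)
    return nodes_arr, elements_arr, surface_mask


@dataclass
class ToyStrainFixture:
    """A strain field plus the generator's own answer key."""

    field: StrainField
    expected_failure_load: float  # N, brute-force/closed-form ground truth
    pattern: str


def _brute_force_failure_load(
    nodes: np.ndarray,
    surface_mask: np.ndarray,
    eps_t: np.ndarray,
    eps_c: np.ndarray,
    radius: float,
) -> float:
    """O(n^2) reference evaluation of the sphere-averaged strain criterion."""
    idx = np.flatnonzero(surface_mask)
    pts = nodes[idx]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= radius**2 + 1e-12
    best = np.inf
    for i in range(len(idx)):
        nb = within[i]
        et = eps_t[idx][nb].mean()
        ec = eps_c[idx][nb].mean()
        r_t = TENSILE_STRAIN_LIMIT / et if et > 0 else np.inf
        r_c = COMPRESSIVE_STRAIN_LIMIT / ec if ec > 0 else np.inf
        best = min(best, min(r_t, r_c))
    return REFERENCE_LOAD_N * best


def generate_toy_strainfield(
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
    radius: float = 3.0,
) -> ToyStrainFixture:
    """Build a toy strain field whose failure load is known by construction.

    Patterns:

    ``constant``
        eps_t = 0.73% everywhere, eps_c = 0: the tensile limit is hit
        exactly at the 1000 N reference load.
    ``hotspot``
        Low background tensile strain with one isolated surface node at
        eps_c = 2.08%; with the default 10 mm cells no other node lies
        within the averaging sphere, so FL = 1000 * 0.0104/0.0208 = 500 N.
    ``gradient``
        Smooth linear ramps in eps_t and eps_c; the ground truth is the
        generator's own O(n^2) brute-force pass (independent of the
        tree-based evaluator).
    """
    nodes, elements, surface = make_box_tet10_mesh(spec.mesh_cells, spec.cell_size_mm)
    n = nodes.shape[0]
    if n > 500:
        raise ValueError("toy meshes are capped at 500 nodes")
    eps_t = np.zeros(n)
    eps_c = np.zeros(n)

    if spec.strain_pattern == "constant":
        eps_t[:] = TENSILE_STRAIN_LIMIT
        expected = REFERENCE_LOAD_N
    elif spec.strain_pattern == "hotspot":
        eps_t[:] = 0.001
        hot = int(np.flatnonzero(surface)[0])
        eps_c[hot] = 2 * COMPRESSIVE_STRAIN_LIMIT
        expected = _brute_force_failure_load(nodes, surface, eps_t, eps_c, radius)
    elif spec.strain_pattern == "gradient":
        span = nodes.max(axis=0) - nodes.min(axis=0)
        eps_t = 0.002 + 0.0002 * nodes[:, 0] / max(span[0] / 20.0, 1e-12)
        eps_c = 0.001 + 0.00015 * nodes[:, 1] / max(span[1] / 20.0, 1e-12)
        expected = _brute_force_failure_load(nodes, surface, eps_t, eps_c, radius)
    else:
        raise ValueError(f"unknown strain pattern {spec.strain_pattern!r}")

    field = StrainField(
        nodes=nodes,
        elements=elements,
        surface_mask=surface,
        eps_t=eps_t,
        eps_c=eps_c,
        direction=(0, 0),
    )
    return ToyStrainFixture(field=field, expected_failure_load=float(expected), pattern=spec.strain_pattern)


# ---------------------------------------------------------------------------
# Reference trial bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialBundle:
    """A named cohort target plus follow-up configuration, ready to run."""

    name: str
    target: CohortTarget
    lam: float = 0.65
    years: int = 3
    n_realizations: int = 10
    convergence_threshold: float = 0.01

    def trial_config(self, master_seed: int = 0):
        from .trial import TrialConfig

        return TrialConfig(
            lam=self.lam,
            years=self.years,
            n_realizations=self.n_realizations,
            convergence_threshold=self.convergence_threshold,
            master_seed=master_seed,
            cohort=self.target,
        )


def reference_configs() -> dict:
    """LIFT-like and FREEDOM-like placebo-arm bundles.

    Cohort sizes and total-hip aBMD targets mirror the placebo arms of
    the LIFT (n = 1238, 0.722 +- 0.096 g/cm^2) and FREEDOM (n = 1225,
    0.709 +- 0.099 g/cm^2) osteoporosis trials, with a 0.65 falls/year
    Poisson rate, 3 years of follow-up and 10 realizations.
    """
    return {
        "LIFT": TrialBundle("LIFT", CohortTarget(1238, 0.722, 0.096)),
        "FREEDOM": TrialBundle("FREEDOM", CohortTarget(1225, 0.709, 0.099)),
    }
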