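"""Result, cohort, atlas and strain-field persistence.

Tabular outputs are CSV, summaries are JSON, the atlas is a NumPy
archive with a JSON metadata sidecar, and strain fields use a
plain-text node/element/strain triple (nodes.csv + elements.csv +
meta.json).  A run's manifest records the config snapshot, seeds and
file inventory needed to reproduce it bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .atlas import StatisticalAtlas, VirtualPatient
from .diagnostics import ConvergenceTrace
from .strength import StrainField, StrengthSurface
from .trial import FractureRecord, TrialConfig, TrialResult

__all__ = [
    "write_results",
    "read_results",
    "write_cohort_csv",
    "read_cohort_csv",
    "save_atlas",
    "load_atlas",
    "write_strainfield",
    "read_strainfield",
    "write_strength_surface_csv",
    "read_strength_surface_csv",
]

COHORT_COLUMNS = [
    "id",
    "total_hip_aBMD",
    "neck_aBMD",
    "height",
    "weight",
    "BMI",
    "soft_tissue_thickness",
    "seed",
]


def write_results(result: TrialResult, outdir, manifest_extra: Optional[dict] = None) -> dict:
    """Persist a TrialResult; returns the file inventory.

    Writes ``summary.json``, ``realizations.csv``, ``fractures.csv``
    and ``manifest.json``; :func:`read_results` reproduces the
    in-memory result exactly.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    summary = {
        "n_patients": result.n_patients,
        "n_realizations": int(result.fractures_per_realization.size),
        "fractures_mean": result.mean,
        "fractures_sd": result.sd,
        "fractures_min": result.min,
        "fractures_max": result.max,
        "incidence": result.incidence,
        "per_year_counts": result.per_year_counts.tolist(),
        "config": asdict(result.config),
    }
    if result.convergence is not None:
        summary["convergence"] = {
            "cumulative_means": result.convergence.cumulative_means.tolist(),
            "bootstrap_rel_diffs": result.convergence.bootstrap_rel_diffs.tolist(),
            "plain_rel_diffs": result.convergence.plain_rel_diffs.tolist(),
            "converged_at": result.convergence.converged_at,
            "threshold": result.convergence.threshold,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    pd.DataFrame(
        {
            "realization": np.arange(result.fractures_per_realization.size),
            "n_fractures": result.fractures_per_realization,
            "n_strength_evaluations": result.n_strength_evaluations_per_realization,
        }
    ).to_csv(out / "realizations.csv", index=False)

    pd.DataFrame(
        [asdict(r) for r in result.records],
        columns=["patient_id", "realization", "year", "alpha", "beta", "force", "failure_load"],
    ).to_csv(out / "fractures.csv", index=False, float_format="%.17g")

    inventory = {
        "summary": "summary.json",
        "realizations": "realizations.csv",
        "fractures": "fractures.csv",
        "manifest": "manifest.json",
    }
    manifest = {
        "config": asdict(result.config),
        "master_seed": result.config.master_seed,
        "files": inventory,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "package": "silicofem",
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return inventory


def read_results(outdir) -> TrialResult:
    """Rebuild a TrialResult from :func:`write_results` output."""
    out = Path(outdir)
    summary = json.loads((out / "summary.json").read_text())
    reals = pd.read_csv(out / "realizations.csv")
    fracs = pd.read_csv(out / "fractures.csv", float_precision="round_trip")

    cfg_d = summary["config"]
    cohort = cfg_d.pop("cohort")
    if cohort is not None:
        from .atlas import CohortTarget

        cohort = CohortTarget(**cohort)
    config = TrialConfig(cohort=cohort, **cfg_d)

    records = [
        FractureRecord(
            patient_id=row.patient_id,
            realization=int(row.realization),
            year=int(row.year),
            alpha=int(row.alpha),
            beta=int(row.beta),
            force=float(row.force),
            failure_load=float(row.failure_load),
        )
        for row in fracs.itertuples()
    ]
    convergence = None
    if "convergence" in summary:
        c = summary["convergence"]
        convergence = ConvergenceTrace(
            cumulative_means=np.array(c["cumulative_means"]),
            bootstrap_rel_diffs=np.array(c["bootstrap_rel_diffs"]),
            plain_rel_diffs=np.array(c["plain_rel_diffs"]),
            converged_at=c["converged_at"],
            threshold=c["threshold"],
        )
    return TrialResult(
        fractures_per_realization=reals["n_fractures"].to_numpy(),
        n_strength_evaluations_per_realization=reals["n_strength_evaluations"].to_numpy(),
        per_year_counts=np.array(summary["per_year_counts"], dtype=int),
        records=records,
        n_patients=summary["n_patients"],
        config=config,
        convergence=convergence,
    )


def write_cohort_csv(cohort: list, path, seed: Optional[int] = None) -> None:
    rows = [
        {
            "id": p.id,
            "total_hip_aBMD": p.total_hip_aBMD,
            "neck_aBMD": p.neck_aBMD,
            "height": p.height,
            "weight": p.weight,
            "BMI": p.BMI,
            "soft_tissue_thickness": p.soft_tissue_thickness,
            "seed": seed,
        }
        for p in cohort
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        VirtualPatient(
            id=str(r.id),
            total_hip_aBMD=float(r.total_hip_aBMD),
            neck_aBMD=float(r.neck_aBMD),
            height=float(r.height),
            weight=float(r.weight),
            BMI=float(r.BMI),
            soft_tissue_thickness=float(r.soft_tissue_thickness),
        )
        for r in df.itertuples()
    ]


def save_atlas(atlas: StatisticalAtlas, path) -> None:
    """Single-archive atlas (mean, modes, scores) with a JSON sidecar."""
    path = Path(path)
    np.savez(
        path,
        mean_features=atlas.mean_features,
        modes=atlas.modes,
        score_samples=atlas.score_samples,
        explained_variance=atlas.explained_variance,
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "K": atlas.K,
                "n_features": atlas.n_features,
                "n_train": int(atlas.score_samples.shape[0]),
                "feature_meta": atlas.feature_meta,
            },
            indent=2,
        )
    )


def load_atlas(path) -> StatisticalAtlas:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return StatisticalAtlas(
        mean_features=arrays["mean_features"],
        modes=arrays["modes"],
        score_samples=arrays["score_samples"],
        explained_variance=arrays["explained_variance"],
        feature_meta=meta.get("feature_meta", {}),
    )


def write_strainfield(field: StrainField, outdir) -> None:
    """Plain-text strain-field triple: nodes.csv, elements.csv, meta.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "x": field.nodes[:, 0],
            "y": field.nodes[:, 1],
            "z": field.nodes[:, 2],
            "surface": field.surface_mask.astype(int),
            "eps_t": field.eps_t,
            "eps_c": field.eps_c,
        }
    ).to_csv(out / "nodes.csv", index=False)
    pd.DataFrame(field.elements, columns=[f"n{i}" for i in range(field.elements.shape[1])]).to_csv(
        out / "elements.csv", index=False
    )
    (out / "meta.json").write_text(
        json.dumps({"direction": list(field.direction), "units": {"coords": "mm", "strain": "1"}})
    )


def read_strainfield(outdir) -> StrainField:
    out = Path(outdir)
    nodes = pd.read_csv(out / "nodes.csv")
    elements = pd.read_csv(out / "elements.csv").to_numpy(dtype=int)
    meta = json.loads((out / "meta.json").read_text())
    return StrainField(
        nodes=nodes[["x", "y", "z"]].to_numpy(),
        elements=elements,
        surface_mask=nodes["surface"].to_numpy(dtype=bool),
        eps_t=nodes["eps_t"].to_numpy(),
        eps_c=nodes["eps_c"].to_numpy(),
        direction=tuple(meta.get("direction", (0, 0))),
    )


def write_strength_surface_csv(surface: StrengthSurface, path) -> None:
    """61-row x 31-column failure-load grid with an index header."""
    from .impact import ALPHA_GRID, BETA_GRID

    df = pd.DataFrame(surface.failure_load, index=ALPHA_GRID, columns=BETA_GRID)
    df.index.name = "alpha_deg"
    df.to_csv(path)


def read_strength_surface_csv(path) -> StrengthSurface:
    df = pd.read_csv(path, index_col=0)
    return StrengthSurface(df.to_numpy(dtype=float))
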