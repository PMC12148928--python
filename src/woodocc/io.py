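"""Flat-file persistence: covariate and detection CSVs, truth bundles,
posterior arrays."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import CommunityPosterior
from .model import ModelConfig
from .predictors import StandardizationTransform
from .synthetic import DetectionHistory, SyntheticDataset, TrueParameters

__all__ = [
    "write_site_covariates",
    "read_site_covariates",
    "write_detections",
    "read_detections",
    "write_truth",
    "read_truth",
    "write_dataset",
    "write_posterior",
    "read_posterior",
]


def write_site_covariates(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_site_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_detections(det: DetectionHistory, path: str | Path) -> None:
    """Long-format CSV: one row per observed (species, site, visit) cell,
    with the visit covariates repeated. Missing visits simply have no rows."""
    S, J, K = det.y.shape
    sp, si, vi = np.meshgrid(
        np.arange(S), np.arange(J), np.arange(K), indexing="ij"
    )
    keep = np.broadcast_to(det.observed[None, :, :], det.y.shape).ravel()
    frame = pd.DataFrame(
        {
            "species_id": sp.ravel()[keep],
            "site_id": si.ravel()[keep],
            "visit": vi.ravel()[keep],
            "detected": det.y.ravel()[keep],
        }
    )
    for name, arr in det.visit_covariates.items():
        cell = np.broadcast_to(arr[None, :, :], det.y.shape).ravel()
        frame[name] = cell[keep]
    frame.to_csv(path, index=False)


def read_detections(path: str | Path) -> DetectionHistory:
    frame = pd.read_csv(path)
    S = int(frame["species_id"].max()) + 1
    J = int(frame["site_id"].max()) + 1
    K = int(frame["visit"].max()) + 1
    y = np.zeros((S, J, K), dtype=np.int8)
    observed = np.zeros((J, K), dtype=bool)
    y[frame["species_id"], frame["site_id"], frame["visit"]] = frame["detected"]
    observed[frame["site_id"], frame["visit"]] = True
    cov_cols = [
        c for c in frame.columns
        if c not in ("species_id", "site_id", "visit", "detected")
    ]
    visit_covariates = {}
    for c in cov_cols:
        arr = np.zeros((J, K))
        arr[frame["site_id"], frame["visit"]] = frame[c]
        visit_covariates[c] = arr
    return DetectionHistory(y=y, observed=observed, visit_covariates=visit_covariates)


def write_truth(truth: TrueParameters, path: str | Path) -> None:
    """Flat key=value bundle (one array element per line) for tests."""
    with open(path, "w") as fh:
        for name in ("occupancy_coeffs", "detection_coeffs", "factor_loadings",
                     "factor_scores", "latent_z"):
            arr = getattr(truth, name)
            if arr is None:
                continue
            arr = np.asarray(arr)
            for idx in np.ndindex(arr.shape):
                key = name + "[" + ",".join(map(str, idx)) + "]"
                fh.write(f"{key}={float(arr[idx])!r}\n")


def read_truth(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.strip().partition("=")
            out[key] = float(val)
    return out


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_site_covariates(dataset.site_covariates, out / "site_covariates.csv")
    write_detections(dataset.detections, out / "detections.csv")
    write_truth(dataset.truth, out / "truth.txt")


def write_posterior(posterior: CommunityPosterior, out_dir: str | Path) -> None:
    """Posterior arrays as one .npz plus a JSON index of names/shapes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {
        k: v
        for k, v in {
            "beta": posterior.beta,
            "mu_beta": posterior.mu_beta,
            "tau_beta": posterior.tau_beta,
            "alpha": posterior.alpha,
            "mu_alpha": posterior.mu_alpha,
            "tau_alpha": posterior.tau_alpha,
            "loadings": posterior.loadings,
            "scores": posterior.scores,
        }.items()
        if v is not None
    }
    np.savez_compressed(out / "posterior.npz", **arrays)
    index = {
        "arrays": {k: list(v.shape) for k, v in arrays.items()},
        "dims": "chain, draw, ...",
        "occ_terms": posterior.occ_terms,
        "det_terms": posterior.det_terms,
        "model": None
        if posterior.model is None
        else {
            "occupancy_mains": posterior.model.occupancy_mains,
            "occupancy_interactions": [
                list(p) for p in posterior.model.occupancy_interactions
            ],
            "include_country": posterior.model.include_country,
            "detection_covariates": posterior.model.detection_covariates,
            "detection_quadratic": posterior.model.detection_quadratic,
            "n_factors": posterior.model.n_factors,
            "perfect_detection": posterior.model.perfect_detection,
        },
    }
    with open(out / "posterior_index.json", "w") as fh:
        json.dump(index, fh, indent=1)
    if posterior.transform is not None:
        posterior.transform.to_frame().to_csv(
            out / "transform.csv", index=False, float_format="%.17g"
        )


def read_posterior(in_dir: str | Path) -> CommunityPosterior:
    src = Path(in_dir)
    data = np.load(src / "posterior.npz")
    with open(src / "posterior_index.json") as fh:
        index = json.load(fh)
    model = None
    if index.get("model"):
        m = index["model"]
        model = ModelConfig(
            occupancy_mains=m["occupancy_mains"],
            occupancy_interactions=[tuple(p) for p in m["occupancy_interactions"]],
            include_country=m["include_country"],
            detection_covariates=m["detection_covariates"],
            detection_quadratic=m["detection_quadratic"],
            n_factors=m["n_factors"],
            perfect_detection=m["perfect_detection"],
        )
    transform = None
    if (src / "transform.csv").exists():
        transform = StandardizationTransform.from_frame(
            pd.read_csv(src / "transform.csv", float_precision="round_trip")
        )
    get = lambda k: data[k] if k in data.files else None  # noqa: E731
    return CommunityPosterior(
        beta=data["beta"],
        mu_beta=data["mu_beta"],
        tau_beta=data["tau_beta"],
        occ_terms=index["occ_terms"],
        alpha=get("alpha"),
        mu_alpha=get("mu_alpha"),
        tau_alpha=get("tau_alpha"),
        det_terms=index["det_terms"],
        loadings=get("loadings"),
        scores=get("scores"),
        model=model,
        transform=transform,
    )
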