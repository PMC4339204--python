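"""Pipeline orchestration: simulate -> fit-surface -> train -> predict
-> report, with a validated JSON configuration and a reproducibility
manifest.

The library modules stay independent; this module provides the glue a
study run needs: building forest training examples from phantoms (or
from fitted surfaces when the fit stage has been run), stage sequencing
with artifact paths, and model (de)serialisation round-trips.
"""

from __future__ import annotations

import hashlib
import json
import time
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, edges, features as fe, forest as fo
from . import phantom as phm
from . import surface as sf
from .fitting import EnergyParams, fit_volume

STAGES = ("simulate", "fit-surface", "train", "predict", "report")


# --------------------------------------------------------------------------
# shared surface machinery
# --------------------------------------------------------------------------

@lru_cache(maxsize=4)
def cranial_surface(subdiv_level: int = 2, depth: int = 3,
                    per_face: int = 3):
    """Cached (mesh, Surface, SurfaceSampling, shrink-correction).

    The correction rescales a similarity placement so the *limit*
    surface (which contracts under subdivision) matches the target
    semi-axes on average.
    """
    mesh = sf.default_annotated_sphere(subdiv_level)
    surf = sf.Surface(mesh, depth=depth)
    samp = sf.sample_regular(mesh, per_face)
    pts, _ = surf.evaluate(samp.face_ids, samp.st, mesh.vertices)
    corr = 1.0 / float(np.linalg.norm(pts, axis=1).mean())
    return mesh, surf, samp, corr


def example_from_phantom(ph: phm.Phantom, n_points: int = 200,
                         bandpass: bool = True,
                         X: np.ndarray | None = None,
                         tt_fraction: float = 0.15) -> fo.TrainingExample:
    """Build a forest example from a phantom.

    By default the surface comes from the ground-truth similarity
    placement (scaled for subdivision shrinkage); pass fitted control
    vertices ``X`` to use a fitted surface instead.
    """
    mesh, surf, samp, corr = cranial_surface()
    vol = (edges.preprocess(ph.volume, ph.voxel_size,
                            out_spacing=ph.voxel_size)
           if bandpass else np.asarray(ph.volume, float))
    if X is None:
        a, b, c = ph.semi_axes
        X = sf.initialize(mesh, translation=ph.center,
                          scale=(corr * a, corr * b, corr * c))
    ev = sf.evaluate_sampling(surf, samp, X)
    hs = fe.hemisphere_points(ev, ph.hemisphere, n_points)
    tt = fe.make_tt_plane(ev.points, fe.tt_plane_for_ellipsoid(
        ph.center, ph.semi_axes, tt_fraction))
    return fo.TrainingExample(volume=vol, spacing=ph.voxel_size, hs=hs,
                              mesh=surf.to_trimesh(X),
                              surface_points=ev.points, tt=tt,
                              age=ph.age, hemisphere=ph.hemisphere)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 40
    age_range: tuple[float, float] = (18.0, 34.0)
    voxel_size: float = 1.2
    speckle_level: float = 0.35
    hemispheres: str = "right"


class FittingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lam1: float = 1.0
    lam2: float = 0.1
    lam3: float = 0.01
    lam4: float = 0.1
    fa_threshold: float = 0.3
    max_alternations: int = 10
    tol: float = 1e-4

    def energy_params(self) -> EnergyParams:
        return EnergyParams(self.lam1, self.lam2, self.lam3, self.lam4)


class ForestConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trees: int = 20
    max_depth: int = 15
    candidates_per_node: int = 200
    min_samples: int = 5
    min_gain: float = 1e-3
    sigma_max2: float = 1.0
    bagging_fraction: float = 0.67
    test_fraction: float = 0.2

    def hyperparams(self, seed: int) -> fo.ForestHyperparams:
        return fo.ForestHyperparams(
            n_trees=self.n_trees, max_depth=self.max_depth,
            candidates_per_node=self.candidates_per_node,
            min_samples=self.min_samples, min_gain=self.min_gain,
            sigma_max2=self.sigma_max2,
            bagging_fraction=self.bagging_fraction, seed=seed)


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected and
    the seed is propagated to every stochastic stage."""

    model_config = ConfigDict(extra="forbid")
    workdir: str = "run"
    seed: int = 0
    log_level: str = "INFO"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    forest: ForestConfig = Field(default_factory=ForestConfig)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate_json(fh.read())


# --------------------------------------------------------------------------
# model round-trip
# --------------------------------------------------------------------------

def roundtrip_model(model: fo.RegressionForest) -> fo.RegressionForest:
    """Serialise and re-load a forest; predictions are bit-identical."""
    return fo.RegressionForest.from_json(model.to_json())


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages; returns the manifest dictionary.

    Artifacts land under ``config.workdir``: phantoms/ (volumes, truth
    meshes, cohort.csv), fits/ (fitted control vertices + energy
    traces), model.json, predictions.csv and report/ outputs.  Re-running
    with the same config reproduces every stochastic stage bit-
    identically.
    """
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest_path = wd / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else
                {"version": __version__, "seed": config.seed, "stages": {}})

    phantom_dir = wd / "phantoms"
    fits_dir = wd / "fits"
    cohort_csv = phantom_dir / "cohort.csv"
    model_path = wd / "model.json"
    pred_path = wd / "predictions.csv"

    def record(stage, outputs):
        manifest["stages"][stage] = {
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {str(p): _sha256(Path(p)) for p in outputs
                        if Path(p).is_file()}}
        manifest_path.write_text(json.dumps(manifest, indent=2))

    if "simulate" in stages:
        pc = config.phantom
        _, table = phm.make_cohort(pc.n, pc.age_range, seed=config.seed,
                                   voxel_size=pc.voxel_size,
                                   speckle_level=pc.speckle_level,
                                   hemispheres=pc.hemispheres,
                                   out_dir=phantom_dir)
        record("simulate", [cohort_csv])

    if not cohort_csv.is_file():
        raise FileNotFoundError(
            f"{cohort_csv} missing: run the 'simulate' stage first")
    table = pd.read_csv(cohort_csv)

    def rebuild_phantoms():
        specs = [phm.PhantomSpec(
            age=row.age_weeks, voxel_size=row.voxel_size,
            speckle_level=config.phantom.speckle_level,
            occluded_side="left" if row.hemisphere == "right" else "right",
            seed=int(row.seed)) for row in table.itertuples()]
        return [phm.make_phantom(s) for s in specs]

    phantoms = rebuild_phantoms()

    if "fit-surface" in stages:
        fits_dir.mkdir(exist_ok=True)
        mesh, surf, samp, corr = cranial_surface()
        outs = []
        for row, ph in zip(table.itertuples(), phantoms):
            X0 = sf.initialize(mesh, translation=(row.cx, row.cy, row.cz),
                               scale=(corr * row.a * 1.05,
                                      corr * row.b * 1.05,
                                      corr * row.c * 1.05))
            res = fit_volume(ph.volume.astype(float), ph.voxel_size, surf,
                             samp, X0,
                             params=config.fitting.energy_params(),
                             fa_threshold=config.fitting.fa_threshold,
                             max_alternations=config.fitting.max_alternations,
                             tol=config.fitting.tol)
            out = fits_dir / f"{row.id}_fit.json"
            out.write_text(json.dumps({
                "X": res.X_star.tolist(), "converged": res.converged,
                "dropped_points": res.dropped_points}))
            pd.DataFrame(res.energy_trace).to_csv(
                fits_dir / f"{row.id}_trace.csv", index=False)
            outs.append(out)
        record("fit-surface", outs)

    def build_examples():
        exs = []
        for row, ph in zip(table.itertuples(), phantoms):
            fit_file = fits_dir / f"{row.id}_fit.json"
            X = (np.asarray(json.loads(fit_file.read_text())["X"])
                 if fit_file.is_file() else None)
            exs.append(example_from_phantom(ph, X=X))
        return exs

    n_test = max(1, int(round(config.forest.test_fraction * len(table))))
    if "train" in stages or "predict" in stages or "report" in stages:
        examples = build_examples()
        train_ex, test_ex = examples[:-n_test], examples[-n_test:]

    if "train" in stages:
        model = fo.train_forest(train_ex,
                                config.forest.hyperparams(config.seed))
        model.save(model_path)
        record("train", [model_path])

    if "predict" in stages or "report" in stages:
        if not model_path.is_file():
            raise FileNotFoundError(
                f"{model_path} missing: run the 'train' stage first")
        model = fo.RegressionForest.load(model_path)

    if "predict" in stages:
        rows = []
        test_ids = set(table.id.iloc[-n_test:])
        for row, ex in zip(table.itertuples(), examples):
            if row.id not in test_ids:
                continue
            pr = fo.predict(model, ex)
            rows.append(dict(id=row.id, true_age=ex.age,
                             predicted_age=pr.age,
                             used_leaves=pr.used_leaves,
                             fallback=pr.fallback_used))
        pd.DataFrame(rows).to_csv(pred_path, index=False)
        record("predict", [pred_path])

    if "report" in stages:
        if not pred_path.is_file():
            raise FileNotFoundError(
                f"{pred_path} missing: run the 'predict' stage first")
        rep = wd / "report"
        rep.mkdir(exist_ok=True)
        preds = pd.read_csv(pred_path)
        summary = {
            "rmse_weeks": fo.rmse(preds.predicted_age, preds.true_age),
            "rmse_days": 7 * fo.rmse(preds.predicted_age, preds.true_age),
            "n_test": len(preds),
        }
        fo.feature_selection_profile(model).to_csv(
            rep / "feature_profile.csv", index=False)
        fo.traversal_path_lengths(model, test_ex).to_csv(
            rep / "path_lengths.csv", index=False)
        try:
            em = fo.error_margin(preds.predicted_age, preds.true_age)
            pd.DataFrame({"age": em.age_grid,
                          "delta_w_days": em.delta_w}).to_csv(
                rep / "error_margin.csv", index=False)
            summary["delta_w_mean_days"] = float(em.delta_w.mean())
        except ValueError as err:
            summary["delta_w_note"] = str(err)
        (rep / "summary.json").write_text(json.dumps(summary, indent=2))
        record("report", [rep / "summary.json"])

    return manifest
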