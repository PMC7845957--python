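"""End-to-end orchestration: simulate, features, train, predict.

Every stage writes its artifacts under ``config.out_dir`` and logs one
structured line with the stage name, config hash, seed and timing.  Stage
errors abort with the stage name attached.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import json
import numpy as np
import pandas as pd

from . import io as bio
from .config import RunConfig
from .features import (apply_reciprocal, build_feature_matrix,
                       pairwise_correlation, select_features, standardize)
from .pca import fit_pca
from .roughness import PipelineModel, calibrate, predict_roughness
from .simulate import DEFAULT_RA_GRID_NM, OpticsConfig, SurfaceSpec, generate_dataset

__all__ = ["run_simulate", "run_features", "run_train", "run_predict",
           "run_pipeline", "StageError"]

logger = logging.getLogger("biospeckle")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage(name: str, config: RunConfig):
    class _Timer:
        def __enter__(self):
            self.start = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.start
            if exc is not None:
                logger.error("stage=%s config=%s seed=%d status=failed "
                             "elapsed=%.2fs error=%s", name,
                             config.config_hash, config.seed, elapsed, exc)
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage=%s config=%s seed=%d status=ok elapsed=%.2fs",
                        name, config.config_hash, config.seed, elapsed)
            return False
    return _Timer()


def run_simulate(config: RunConfig) -> Path:
    """Render the labelled synthetic dataset and write PNGs + labels.csv."""
    with _stage("simulate", config):
        ra_list = config.ra_list or DEFAULT_RA_GRID_NM
        images = generate_dataset(ra_list, OpticsConfig(), seed=config.seed)
        out_dir = Path(config.out_dir)
        labels = bio.write_dataset(images, out_dir)
    return labels


def _load_images(config: RunConfig):
    if config.images_dir is None:
        raise ValueError("config.images_dir is required")
    return bio.read_labelled_images(config.images_dir, roi=config.roi)


def run_features(config: RunConfig) -> Path:
    """Compute the feature matrix for the labelled images; write CSV."""
    with _stage("features", config):
        images = _load_images(config)
        ds = _build(config, images)
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "features.csv"
        ds.to_csv(path)
    return path


def _build(config: RunConfig, images):
    parameters = config.parameters
    if config.selection_mode == "explicit":
        # blocks that will be dropped anyway are never computed
        parameters = tuple(p for p in parameters
                           if p not in config.explicit_drop_blocks)
    return build_feature_matrix(
        images, distances=config.distances, directions=config.directions,
        parameters=parameters, levels=config.levels,
        symmetric=config.symmetric, log_base=config.log_base)


def run_train(config: RunConfig) -> PipelineModel:
    """Train the frozen pipeline on labelled images; write all artifacts."""
    with _stage("train", config):
        images = _load_images(config)
        if len(images) < 2:
            raise ValueError("training requires at least 2 labelled images")
        ds = _build(config, images)
        if ds.ra is None:
            raise ValueError("training images must carry ra_nm labels")
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ds.to_csv(out / "features.csv")

        rec = apply_reciprocal(ds, blocks=config.reciprocal_blocks)
        if config.selection_mode == "explicit":
            drop = [b for b in config.explicit_drop_blocks if b in rec.blocks]
            R = pairwise_correlation(rec)
            selected, report = select_features(
                rec, R, threshold=config.selection_threshold,
                mode="explicit", blocks=drop)
        else:
            R = pairwise_correlation(rec)
            selected, report = select_features(
                rec, R, threshold=config.selection_threshold, mode="block")
        with open(out / "selection.json", "w") as fh:
            json.dump(report, fh, indent=1)

        standardized, constants = standardize(selected)
        model = fit_pca(standardized, constants=constants)
        model.to_json(out / "pca_model.json")

        scores = model.scores[:, 0]
        cal = calibrate(scores, ds.ra.to_numpy())
        pipeline_model = PipelineModel(
            distances=config.distances, directions=config.directions,
            levels=config.levels, symmetric=config.symmetric,
            parameters=tuple(p for p in config.parameters
                             if any(c.startswith(f"{p}_")
                                    for c in selected.columns)),
            reciprocal_blocks=config.reciprocal_blocks,
            retained_columns=tuple(selected.columns),
            means=constants.means, stds=constants.stds,
            pc1=pd.Series(model.eigenvectors[:, 0], index=selected.columns),
            calibration=cal, log_base=config.log_base)
        pipeline_model.to_json(out / "pipeline_model.json")
    return pipeline_model


def run_predict(config: RunConfig, model_path, image_paths) -> Path:
    """Predict Ra for images through a serialised PipelineModel; write CSV."""
    with _stage("predict", config):
        model = PipelineModel.from_json(model_path)
        records = []
        for path in image_paths:
            image = bio.read_image(path, roi=config.roi)
            ra, flagged = predict_roughness(model, image)
            records.append({"image_path": str(path),
                            "ra_nm_pred": ra,
                            "extrapolated": flagged})
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "predictions.csv"
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    return path


def run_pipeline(config: RunConfig) -> PipelineModel:
    """Simulate (if no images_dir given) then train; returns the model."""
    if config.images_dir is None:
        sim_dir = Path(config.out_dir) / "images"
        run_simulate(config.replace(out_dir=str(sim_dir)))
        config = config.replace(images_dir=str(sim_dir))
    return run_train(config)
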