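"""Calibration between the first principal component and surface roughness.

Across a training set spanning the roughness range, the PC1 score decays
with Ra and is modelled as

    s(Ra) = y0 + A * exp(-B * Ra)

Prediction for a new image runs the frozen feature pipeline (same GLCM
configuration, reciprocal blocks, retained columns and standardisation
constants), projects the feature row on the stored first eigenvector and
inverts the calibration: Ra = -(1/B) * ln((s - y0) / A).  Scores outside
the fitted range are flagged as extrapolation rather than refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (ExpFit, StandardizationConstants, fit_exponential,
                       image_feature_row)
from .simulate import SpeckleImage

__all__ = ["CalibrationModel", "PipelineModel", "calibrate",
           "invert_calibration", "predict_roughness"]

_SCHEMA = "biospeckle-pipeline/1"


@dataclass(frozen=True)
class CalibrationModel:
    """Exponential PC1-versus-Ra fit with its quality metrics.

    ``rmse`` is in PC1-score units; ``ra_range`` and ``score_range`` bound
    the calibrated domain for extrapolation flagging.
    """

    exp_fit: ExpFit
    r_squared: float
    rmse: float
    ra_range: tuple[float, float]
    score_range: tuple[float, float]


def calibrate(scores: Sequence[float], ra: Sequence[float]) -> CalibrationModel:
    """Fit PC1 scores against roughness labels (nm).

    Requires >= 5 observations with distinct Ra spanning more than one
    decade.  Raises on constant scores (no roughness information) and on
    fit non-convergence.
    """
    scores = np.asarray(scores, dtype=float)
    ra = np.asarray(ra, dtype=float)
    if scores.shape != ra.shape or scores.ndim != 1:
        raise ValueError("scores and ra must be 1-D arrays of equal length")
    if scores.size < 5:
        raise ValueError("need at least 5 labelled observations")
    if np.any(ra <= 0):
        raise ValueError("Ra labels must be > 0")
    if ra.max() / ra.min() <= 10.0:
        raise ValueError("Ra labels must span more than one decade")
    if np.ptp(scores) <= 1e-12 * max(1.0, np.abs(scores).max()):
        raise ValueError("constant scores carry no roughness information")

    order = np.argsort(ra)
    ra_sorted, score_sorted = ra[order], scores[order]
    if np.any(np.diff(ra_sorted) == 0):
        raise ValueError("duplicate Ra labels are not supported")

    fit = fit_exponential(ra_sorted, score_sorted)
    if not fit.converged:
        raise RuntimeError(f"calibration fit failed: {fit.message}")
    predicted = fit.y0 + fit.A * np.exp(-fit.B * ra_sorted)
    rmse = float(np.sqrt(np.mean((predicted - score_sorted) ** 2)))
    return CalibrationModel(
        exp_fit=fit, r_squared=fit.r_squared, rmse=rmse,
        ra_range=(float(ra.min()), float(ra.max())),
        score_range=(float(scores.min()), float(scores.max())))


def invert_calibration(model: CalibrationModel, score: float) -> tuple[float, bool]:
    """Map a PC1 score back to Ra (nm); second value flags extrapolation."""
    fit = model.exp_fit
    argument = (score - fit.y0) / fit.A
    if argument <= 0:
        raise ValueError(
            f"score {score:.6g} is outside the calibration domain "
            f"((s - y0)/A = {argument:.3g} <= 0)")
    ra = -np.log(argument) / fit.B
    lo, hi = model.score_range
    score_eps = 1e-9 * max(abs(lo), abs(hi), 1.0)
    ra_eps = 1e-9 * max(abs(model.ra_range[0]), abs(model.ra_range[1]), 1.0)
    flagged = not (lo - score_eps <= score <= hi + score_eps) or not (
        model.ra_range[0] - ra_eps <= ra <= model.ra_range[1] + ra_eps)
    return float(ra), bool(flagged)


@dataclass
class PipelineModel:
    """The frozen end-to-end method: configuration, constants, calibration."""

    distances: tuple[int, ...]
    directions: tuple[int, ...]
    levels: int
    symmetric: bool
    parameters: tuple[str, ...]
    reciprocal_blocks: tuple[str, ...]
    retained_columns: tuple[str, ...]
    means: pd.Series
    stds: pd.Series
    pc1: pd.Series
    calibration: CalibrationModel
    log_base: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "schema": _SCHEMA,
            "glcm": {"distances": list(self.distances),
                     "directions": list(self.directions),
                     "levels": self.levels,
                     "symmetric": self.symmetric},
            "parameters": list(self.parameters),
            "log_base": self.log_base,
            "reciprocal_blocks": list(self.reciprocal_blocks),
            "retained_columns": list(self.retained_columns),
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "pc1": self.pc1.tolist(),
            "calibration": {
                "exp_fit": asdict(self.calibration.exp_fit),
                "r_squared": self.calibration.r_squared,
                "rmse": self.calibration.rmse,
                "ra_range": list(self.calibration.ra_range),
                "score_range": list(self.calibration.score_range),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PipelineModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != _SCHEMA:
            raise ValueError(f"unexpected model schema: {payload.get('schema')!r}")
        retained = tuple(payload["retained_columns"])
        index = pd.Index(retained)
        cal = payload["calibration"]
        calibration = CalibrationModel(
            exp_fit=ExpFit(**cal["exp_fit"]),
            r_squared=cal["r_squared"], rmse=cal["rmse"],
            ra_range=tuple(cal["ra_range"]),
            score_range=tuple(cal["score_range"]))
        return cls(
            distances=tuple(payload["glcm"]["distances"]),
            directions=tuple(payload["glcm"]["directions"]),
            levels=payload["glcm"]["levels"],
            symmetric=payload["glcm"]["symmetric"],
            parameters=tuple(payload["parameters"]),
            reciprocal_blocks=tuple(payload["reciprocal_blocks"]),
            retained_columns=retained,
            means=pd.Series(payload["means"], index=index),
            stds=pd.Series(payload["stds"], index=index),
            pc1=pd.Series(payload["pc1"], index=index),
            calibration=calibration,
            log_base=payload.get("log_base"))


def pipeline_score(model: PipelineModel,
                   image: SpeckleImage | np.ndarray) -> float:
    """PC1 score of one image under the frozen pipeline."""
    needed = sorted({c.split("_", 1)[0] for c in model.retained_columns},
                    key=list(model.parameters).index)
    row = image_feature_row(
        image, distances=model.distances, directions=model.directions,
        parameters=needed, levels=model.levels, symmetric=model.symmetric,
        log_base=model.log_base,
        name=getattr(image, "label", None) or "image")
    for parameter in model.reciprocal_blocks:
        if parameter not in needed:
            continue
        cols = [c for c in row.index if c.startswith(f"{parameter}_")]
        values = row[cols].to_numpy(dtype=float)
        if np.any(np.abs(values) < 1e-12):
            raise ValueError(f"near-zero {parameter} feature; cannot invert")
        row[cols] = 1.0 / values
    retained = row[list(model.retained_columns)]
    standardized = (retained - model.means) / model.stds
    return float(standardized.to_numpy() @ model.pc1.to_numpy())


def predict_roughness(model: PipelineModel,
                      image: SpeckleImage | np.ndarray) -> tuple[float, bool]:
    """Estimate Ra (nm) of a speckle image; flags extrapolation."""
    score = pipeline_score(model, image)
    return invert_calibration(model.calibration, score)
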