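"""Shared fixtures: the default synthetic study, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import biospeckle as bs
from biospeckle.features import (apply_reciprocal, build_feature_matrix,
                                 pairwise_correlation, select_features,
                                 standardize)
from biospeckle.pca import fit_pca
from biospeckle.roughness import calibrate

STUDY_SEED = 1
HELDOUT_SEED = 2025


@pytest.fixture(scope="session")
def study_images():
    """Twelve simulated speckle images spanning Ra = 10..2500 nm."""
    return bs.generate_dataset(bs.DEFAULT_RA_GRID_NM, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(study_images):
    """The full default analysis, stage by stage, as a namespace."""
    ds = build_feature_matrix(study_images)
    rec = apply_reciprocal(ds)
    R = pairwise_correlation(rec)
    selected, report = select_features(rec, R, mode="explicit", blocks=["CORR"])
    std_ds, consts = standardize(selected)
    model = fit_pca(std_ds, constants=consts)
    cal = calibrate(model.scores[:, 0], ds.ra.to_numpy())

    class Study:
        images = study_images
        dataset = ds
        reciprocal = rec
        correlation = R
        selected_ds = selected
        selection_report = report
        standardized = std_ds
        constants = consts
        pca = model
        calibration = cal
        ra = ds.ra.to_numpy()

    return Study


@pytest.fixture(scope="session")
def heldout_images():
    """Fresh realisations (new seeds) on the same Ra grid."""
    return bs.generate_dataset(bs.DEFAULT_RA_GRID_NM, seed=HELDOUT_SEED)


@pytest.fixture(scope="session")
def pipeline_model(study):
    """The frozen end-to-end model built from the session study."""
    import pandas as pd

    from biospeckle.roughness import PipelineModel

    sel = study.selected_ds
    return PipelineModel(
        distances=tuple(range(1, 11)), directions=(0, 45, 90, 135),
        levels=256, symmetric=True,
        parameters=tuple(p for p in bs.PARAMETERS if p != "CORR"),
        reciprocal_blocks=("ASM", "IDM", "CORR"),
        retained_columns=tuple(sel.columns),
        means=study.constants.means, stds=study.constants.stds,
        pc1=pd.Series(study.pca.eigenvectors[:, 0], index=sel.columns),
        calibration=study.calibration)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
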