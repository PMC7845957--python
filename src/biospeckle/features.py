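"""Assembly and conditioning of the GLCM statistical-feature dataset.

For every image, each Haralick parameter is evaluated on the GLCM stack
(default: distances 1..10 by four directions), and the parameter-versus-
distance curve of each direction is fitted with the exponential model
y = y0 + A * exp(-B * x).  Only the asymptote y0 is kept as an extra
feature, so with defaults each parameter contributes 4 x 10 distance
features plus 4 fit constants = 44 features, and eight parameters give
p = 352 columns.

Downstream conditioning before PCA:

1. the ASM, IDM and CORR blocks are replaced by their reciprocals so all
   features share one rating (decreasing with roughness);
2. feature blocks that correlate weakly with the rest are dropped
   (block-median rule, or an explicit block list);
3. every retained column is standardised to zero mean, unit sample variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .glcm import DEFAULT_DIRECTIONS, DEFAULT_DISTANCES, glcm_stack
from .haralick import PARAMETERS, haralick_features
from .simulate import SpeckleImage

__all__ = [
    "ExpFit", "FeatureDataset", "CorrelationMatrix", "StandardizationConstants",
    "fit_exponential", "build_feature_matrix", "apply_reciprocal",
    "pairwise_correlation", "select_features", "standardize",
    "RECIPROCAL_BLOCKS",
]

#: parameters whose rating is inverted before PCA (they grow with roughness)
RECIPROCAL_BLOCKS: tuple[str, ...] = ("ASM", "IDM", "CORR")

_RECIPROCAL_EPS = 1e-12


@dataclass(frozen=True)
class ExpFit:
    """Least-squares fit of y = y0 + A * exp(-B * x) with B > 0."""

    y0: float
    A: float
    B: float
    r_squared: float
    converged: bool
    message: str = ""


def _exp_model(x: np.ndarray, y0: float, a: float, b: float) -> np.ndarray:
    return y0 + a * np.exp(-b * x)


def fit_exponential(x: Sequence[float], y: Sequence[float]) -> ExpFit:
    """Fit the shifted exponential to (x, y) with multiple restarts.

    Initial guesses: y0 from y at the largest x, A from the first point,
    and B from a log-linear regression of |y - y0| plus a fixed grid of
    decay rates scaled to the x span.  A constant y returns y0 = y, A = 0
    and, by convention, r_squared = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 points for the exponential fit")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")

    if np.ptp(y) == 0.0:
        return ExpFit(y0=float(y[0]), A=0.0, B=1.0, r_squared=1.0,
                      converged=True, message="constant input")

    span = float(x[-1] - x[0])
    y0_init = float(y[-1])
    a_init = float(y[0] - y0_init)

    b_candidates: list[float] = []
    residual = y - y0_init
    mask = np.abs(residual) > 1e-12 * max(1.0, float(np.abs(y).max()))
    if mask.sum() >= 2 and (np.all(residual[mask] > 0) or np.all(residual[mask] < 0)):
        slope = np.polyfit(x[mask], np.log(np.abs(residual[mask])), 1)[0]
        if slope < 0:
            b_candidates.append(-slope)
    # fixed restart grid, scaled so it matches {0.1, 0.5, 1, 2} on a span of 9
    for g in (0.1, 0.5, 1.0, 2.0):
        b_candidates.append(g * 9.0 / span)

    best: tuple[float, np.ndarray] | None = None
    messages: list[str] = []
    for b0 in b_candidates:
        a0 = a_init if a_init != 0 else float(np.ptp(y))
        try:
            popt, _ = curve_fit(
                _exp_model, x, y, p0=(y0_init, a0, b0),
                bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000, xtol=1e-8, ftol=1e-12)
        except (RuntimeError, ValueError) as err:
            messages.append(str(err))
            continue
        ss_res = float(np.sum((y - _exp_model(x, *popt)) ** 2))
        if best is None or ss_res < best[0]:
            best = (ss_res, popt)

    if best is None:
        return ExpFit(y0=float(np.mean(y)), A=0.0, B=1.0,
                      r_squared=-np.inf, converged=False,
                      message="; ".join(messages) or "no restart converged")

    ss_res, popt = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot
    return ExpFit(y0=float(popt[0]), A=float(popt[1]), B=float(popt[2]),
                  r_squared=r_squared, converged=True)


def feature_column_name(parameter: str, direction: int, distance: int | None) -> str:
    """Canonical column label: ``PARAM_<theta>_d<k>`` or ``PARAM_<theta>_y0``."""
    tail = "y0" if distance is None else f"d{distance}"
    return f"{parameter}_{direction}_{tail}"


@dataclass
class FeatureDataset:
    """An n x p labelled feature matrix with per-parameter block metadata.

    ``frame`` holds the features (rows = observations); ``ra`` optionally
    carries the reference roughness labels (nm); ``blocks`` maps each
    Haralick parameter to its column labels.
    """

    frame: pd.DataFrame
    ra: pd.Series | None = None
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            bad = self.frame.columns[self.frame.isna().any()][0]
            raise ValueError(f"feature matrix contains missing values ({bad})")

    @property
    def n_observations(self) -> int:
        return self.frame.shape[0]

    @property
    def n_features(self) -> int:
        return self.frame.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def subset(self, columns: Sequence[str]) -> "FeatureDataset":
        blocks = {p: [c for c in cols if c in set(columns)]
                  for p, cols in self.blocks.items()}
        blocks = {p: cols for p, cols in blocks.items() if cols}
        return FeatureDataset(frame=self.frame[list(columns)].copy(),
                              ra=None if self.ra is None else self.ra.copy(),
                              blocks=blocks)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        if self.ra is not None:
            out.insert(0, "ra_nm", self.ra)
        out.to_csv(path, index_label="observation")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric p x p pairwise-correlation matrix with column labels."""

    values: np.ndarray
    columns: tuple[str, ...]


@dataclass
class StandardizationConstants:
    """Per-column means and sample standard deviations, plus provenance."""

    means: pd.Series
    stds: pd.Series
    reciprocal_blocks: tuple[str, ...] = ()
    retained_columns: tuple[str, ...] = ()


def image_feature_row(image: SpeckleImage | np.ndarray,
                      distances: Sequence[int] = DEFAULT_DISTANCES,
                      directions: Sequence[int] = DEFAULT_DIRECTIONS,
                      parameters: Sequence[str] = PARAMETERS,
                      levels: int = 256,
                      symmetric: bool = True,
                      log_base: float | None = None,
                      name: str = "image") -> pd.Series:
    """All features of a single image, in canonical column order."""
    distances = list(distances)
    if len(distances) < 4:
        raise ValueError("need >= 4 distances for the y0 exponential fit")
    stack = glcm_stack(image, distances=distances, directions=directions,
                       levels=levels, symmetric=symmetric)
    vectors = {key: haralick_features(g, log_base=log_base)
               for key, g in stack.items()}

    row: dict[str, float] = {}
    for parameter in parameters:
        for theta in directions:
            curve = [getattr(vectors[(d, theta)], parameter) for d in distances]
            for d, value in zip(distances, curve):
                if np.isnan(value):
                    raise ValueError(
                        f"undefined {parameter} for {name} at "
                        f"(d={d}, theta={theta}); exclude the block or fix the image")
                row[feature_column_name(parameter, theta, d)] = value
            fit = fit_exponential(distances, curve)
            if not fit.converged:
                raise ValueError(
                    f"exponential fit failed for {name}, parameter "
                    f"{parameter}, direction {theta}: {fit.message}")
            row[feature_column_name(parameter, theta, None)] = fit.y0
    return pd.Series(row, name=name)


def build_feature_matrix(images: Sequence[SpeckleImage],
                         distances: Sequence[int] = DEFAULT_DISTANCES,
                         directions: Sequence[int] = DEFAULT_DIRECTIONS,
                         parameters: Sequence[str] = PARAMETERS,
                         levels: int = 256,
                         symmetric: bool = True,
                         log_base: float | None = None) -> FeatureDataset:
    """Assemble the n x p feature dataset from a labelled image set.

    Column order is parameter-major, then direction, then distance, with the
    direction's y0 constant last.  p = #parameters x #directions x
    (#distances + 1).
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    rows = []
    labels = []
    for idx, image in enumerate(images):
        name = getattr(image, "label", None) or f"img_{idx:03d}"
        rows.append(image_feature_row(
            image, distances=distances, directions=directions,
            parameters=parameters, levels=levels, symmetric=symmetric,
            log_base=log_base, name=name))
        labels.append(name)

    frame = pd.DataFrame(rows)
    frame.index = pd.Index(labels, name="observation")

    blocks = {p: [c for c in frame.columns if c.startswith(f"{p}_")]
              for p in parameters}
    ra_values = [getattr(img, "ra_nm", None) for img in images]
    ra = None
    if all(v is not None for v in ra_values):
        ra = pd.Series(ra_values, index=frame.index, name="ra_nm", dtype=float)
    return FeatureDataset(frame=frame, ra=ra, blocks=blocks)


def apply_reciprocal(ds: FeatureDataset,
                     blocks: Sequence[str] = RECIPROCAL_BLOCKS) -> FeatureDataset:
    """Replace the listed parameter blocks cell-wise by 1/value.

    Aligns the rating of all features: parameters that grow with roughness
    (ASM, IDM, CORR) become decreasing like the rest.  Applying twice is the
    identity.
    """
    frame = ds.frame.copy()
    for parameter in blocks:
        for column in ds.blocks.get(parameter, []):
            values = frame[column].to_numpy(dtype=float)
            small = np.abs(values) < _RECIPROCAL_EPS
            if small.any():
                row = frame.index[int(np.argmax(small))]
                raise ValueError(
                    f"cannot take reciprocal of near-zero value at "
                    f"({row}, {column})")
            frame[column] = 1.0 / values
    return FeatureDataset(frame=frame,
                          ra=None if ds.ra is None else ds.ra.copy(),
                          blocks={p: list(c) for p, c in ds.blocks.items()})


def _column_stats(values: np.ndarray, columns: Sequence[str]):
    means = values.mean(axis=0)
    stds = values.std(axis=0, ddof=1)
    zero = stds <= 0
    if zero.any():
        raise ValueError(
            f"zero-variance column: {columns[int(np.argmax(zero))]}")
    return means, stds


def pairwise_correlation(ds: FeatureDataset) -> CorrelationMatrix:
    """Pairwise Pearson correlation matrix R = Z^T Z / (n - 1).

    Z is the column-standardised data (sample n-1 denominators).  Symmetric
    with unit diagonal.
    """
    values = ds.values
    if values.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    means, stds = _column_stats(values, ds.columns)
    z = (values - means) / stds
    r = z.T @ z / (values.shape[0] - 1)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(values=r, columns=tuple(ds.columns))


def select_features(ds: FeatureDataset, R: CorrelationMatrix,
                    threshold: float = 0.8, mode: str = "block",
                    blocks: Sequence[str] | None = None,
                    ) -> tuple[FeatureDataset, dict]:
    """Drop weakly-correlated feature blocks before PCA.

    mode "block" (default): for each parameter block, the median absolute
    correlation between its columns and all out-of-block columns is compared
    with ``threshold``; blocks below it are dropped.  mode "explicit": drop
    exactly the named blocks.  Returns the reduced dataset and a report.
    """
    if tuple(R.columns) != tuple(ds.columns):
        raise ValueError("correlation matrix does not match dataset columns")
    col_index = {c: k for k, c in enumerate(ds.columns)}

    per_block_stat: dict[str, float | None] = {}
    dropped_blocks: list[str] = []
    if mode == "block":
        for parameter, cols in ds.blocks.items():
            inside = [col_index[c] for c in cols]
            outside = [k for k in range(len(ds.columns)) if k not in set(inside)]
            if not outside:
                per_block_stat[parameter] = None
                continue
            sub = np.abs(R.values[np.ix_(inside, outside)])
            stat = float(np.median(sub))
            per_block_stat[parameter] = stat
            if stat < threshold:
                dropped_blocks.append(parameter)
    elif mode == "explicit":
        if blocks is None:
            raise ValueError("explicit mode requires a block list")
        unknown = [b for b in blocks if b not in ds.blocks]
        if unknown:
            raise ValueError(f"unknown blocks: {unknown}")
        dropped_blocks = list(blocks)
    else:
        raise ValueError(f"unknown selection mode: {mode!r}")

    dropped_columns = [c for b in dropped_blocks for c in ds.blocks[b]]
    retained = [c for c in ds.columns if c not in set(dropped_columns)]
    if not retained:
        raise ValueError("selection would drop every feature")

    report = {
        "mode": mode,
        "threshold": threshold,
        "per_block_statistic": per_block_stat,
        "dropped_blocks": dropped_blocks,
        "dropped_columns": dropped_columns,
        "n_retained": len(retained),
    }
    return ds.subset(retained), report


def standardize(ds: FeatureDataset) -> tuple[FeatureDataset, StandardizationConstants]:
    """Scale every column to zero mean and unit sample variance."""
    values = ds.values
    means, stds = _column_stats(values, ds.columns)
    frame = pd.DataFrame((values - means) / stds,
                         index=ds.frame.index, columns=ds.frame.columns)
    constants = StandardizationConstants(
        means=pd.Series(means, index=ds.frame.columns),
        stds=pd.Series(stds, index=ds.frame.columns),
        retained_columns=tuple(ds.columns))
    return (FeatureDataset(frame=frame,
                           ra=None if ds.ra is None else ds.ra.copy(),
                           blocks={p: list(c) for p, c in ds.blocks.items()}),
            constants)
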