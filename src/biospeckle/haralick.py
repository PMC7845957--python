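"""Haralick texture statistics of a normalised GLCM.

Eight second-order statistics are computed from the probability matrix P:

* ASM  (angular second moment)  sum P(i,j)^2          -- homogeneity
* CON  (contrast)               sum k^2 P_{x-y}(k)    -- local variation
* IDM  (inverse difference moment) sum P/(1+(i-j)^2)  -- diagonal closeness
* ENT  (entropy)                -sum P log P          -- disorder
* DA   (difference average)     sum k P_{x-y}(k)
* DV   (difference variance)    sum (k-DA)^2 P_{x-y}(k)
* DE   (difference entropy)     -sum P_{x-y} log P_{x-y}
* CORR (correlation)            sum P (i-mu_x)(j-mu_y) / (sigma_x sigma_y)

where P_{x-y}(k) = sum_{|i-j|=k} P(i,j) is the absolute-difference marginal,
and mu/sigma are the means and standard deviations of the row and column
marginals.  Logarithms are natural by default (configurable); 0*log 0 := 0.
CORR is undefined (NaN) when either marginal has zero spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glcm import GLCM, GlcmSpec

__all__ = ["PARAMETERS", "HaralickVector", "diff_marginal", "haralick_features"]

#: canonical parameter order used throughout the feature pipeline
PARAMETERS: tuple[str, ...] = ("ASM", "CON", "IDM", "ENT", "DA", "DV", "DE", "CORR")

_NORM_TOL = 1e-8


@dataclass(frozen=True)
class HaralickVector:
    """The eight texture statistics of one GLCM; CORR is NaN when undefined."""

    ASM: float
    CON: float
    IDM: float
    ENT: float
    DA: float
    DV: float
    DE: float
    CORR: float
    spec: GlcmSpec | None = None

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETERS}

    @property
    def corr_defined(self) -> bool:
        return not np.isnan(self.CORR)


def _validated(P: GLCM | np.ndarray) -> np.ndarray:
    probs = P.probabilities if isinstance(P, GLCM) else np.asarray(P, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError("GLCM must be a square 2-D matrix")
    if probs.min() < 0:
        raise ValueError("GLCM entries must be non-negative")
    if abs(probs.sum() - 1.0) > _NORM_TOL:
        raise ValueError(
            f"GLCM is not normalised (sum = {probs.sum():.6g}); "
            "call normalize_glcm first")
    return probs


def diff_marginal(P: GLCM | np.ndarray) -> np.ndarray:
    """Absolute-difference marginal P_{x-y}(k) = sum over |i-j| = k of P(i,j).

    k = 0 collects the principal diagonal; k > 0 collects the k-th diagonals
    above and below it.  Sums to one for a normalised input.
    """
    probs = _validated(P)
    levels = probs.shape[0]
    i = np.arange(levels)
    k = np.abs(i[:, None] - i[None, :])
    return np.bincount(k.ravel(), weights=probs.ravel(), minlength=levels)


def haralick_features(P: GLCM | np.ndarray, *,
                      log_base: float | None = None) -> HaralickVector:
    """Compute all eight statistics from one normalised GLCM.

    ``log_base`` rescales both entropies (natural log when None).
    """
    probs = _validated(P)
    spec = P.spec if isinstance(P, GLCM) else None
    levels = probs.shape[0]
    i = np.arange(levels, dtype=float)

    log_scale = 1.0 if log_base is None else 1.0 / np.log(log_base)

    asm = float(np.sum(probs * probs))

    diff = i[:, None] - i[None, :]
    idm = float(np.sum(probs / (1.0 + diff * diff)))

    positive = probs[probs > 0]
    ent = float(-np.sum(positive * np.log(positive)) * log_scale)

    pxy = diff_marginal(probs)
    k = np.arange(levels, dtype=float)
    con = float(np.sum(k * k * pxy))
    da = float(np.sum(k * pxy))
    dv = float(np.sum((k - da) ** 2 * pxy))
    pxy_pos = pxy[pxy > 0]
    de = float(-np.sum(pxy_pos * np.log(pxy_pos)) * log_scale)

    px = probs.sum(axis=1)  # row marginal
    py = probs.sum(axis=0)  # column marginal
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))
    denom = np.sqrt(var_x) * np.sqrt(var_y)
    if denom <= 0:
        corr = float("nan")
    else:
        cov = float(np.sum(probs * np.outer(i - mu_x, i - mu_y)))
        corr = cov / denom

    return HaralickVector(ASM=asm, CON=con, IDM=idm, ENT=ent,
                          DA=da, DV=dv, DE=de, CORR=corr, spec=spec)
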