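"""Spline bases and penalties for the GAM engine.

All smooths are low-rank penalized regression splines:

* 1-d terms: cubic B-spline basis with a second-order difference penalty
  (P-spline) whose null space (constant + linear) receives a small extra
  eigen-penalty, so heavy smoothing can shrink the whole term to zero
  ("shrinkage smooths" — the mechanism behind select-against-zero term
  selection).
* cyclic terms: B-splines on wrapped knots with a circulant difference
  penalty; f(0) = f(period) with matching derivatives by construction.
* tensor products: row-wise Kronecker of the marginal bases with one
  penalty per margin, suited to covariate pairs on different scales.
* random intercepts: indicator columns under a ridge penalty.

Smooths carry a sum-to-zero constraint (absorbed by reparameterization)
so they are identifiable next to the model intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "TermBlock",
    "SplineTerm",
    "CyclicTerm",
    "TensorTerm",
    "RandomInterceptTerm",
    "FactorTerm",
]

logger = logging.getLogger(__name__)


def _bspline_knots(x: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1.0
    inner = np.linspace(lo, hi, k - degree + 1)
    return np.concatenate([np.full(degree, lo), inner, np.full(degree, hi)])


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    xc = np.clip(x, knots[degree], knots[-degree - 1])
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _shrinkage_penalty(s: np.ndarray) -> np.ndarray:
    """Add a small eigen-penalty on the null space of ``s``.

    Null eigenvalues are replaced by 0.1x the smallest positive eigenvalue,
    making the penalty strictly positive definite so lambda -> infinity
    drives the whole term (its linear trend included) to zero.
    """
    vals, vecs = np.linalg.eigh(s)
    tol = vals.max() * 1e-10
    pos = vals[vals > tol]
    eps = 0.1 * pos.min()
    vals = np.where(vals > tol, vals, eps)
    return (vecs * vals) @ vecs.T


def _cyclic_design(x: np.ndarray, k: int, x0: float, period: float,
                   degree: int = 3) -> np.ndarray:
    h = period / k
    t = x0 + h * np.arange(-degree, k + degree + 1)
    xm = x0 + np.mod(np.asarray(x, dtype=float) - x0, period)
    b = BSpline.design_matrix(xm, t, degree).toarray()  # n x (k + degree)
    bw = b[:, :k].copy()
    bw[:, :degree] += b[:, k:k + degree]
    return bw


def _cyclic_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.zeros((k, k))
    for i in range(k):
        d[i, i] += 1.0
        d[i, (i + 1) % k] += -2.0
        d[i, (i + 2) % k] += 1.0
    return d.T @ d


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


@dataclass
class TermBlock:
    """A built (data-bound) model term: constrained design + penalties."""

    label: str
    X: np.ndarray
    penalties: list[np.ndarray]
    predictor: callable  # data -> constrained design for new data
    n_coef: int = field(init=False)

    def __post_init__(self):
        self.n_coef = self.X.shape[1]


def _constrain(X: np.ndarray, penalties: list[np.ndarray]):
    """Absorb the sum-to-zero constraint 1'Xb = 0 by reparameterization."""
    c = X.sum(axis=0, keepdims=True)
    z = null_space(c)
    return X @ z, [z.T @ s @ z for s in penalties], z


class SplineTerm:
    """1-d shrinkage P-spline smooth of a single covariate."""

    def __init__(self, var: str, k: int = 10, shrink: bool = True):
        self.var = var
        self.k = k
        self.shrink = shrink
        self.label = f"s({var})"

    def build(self, data: pd.DataFrame) -> TermBlock:
        x = np.asarray(data[self.var], dtype=float)
        k = self.k
        n_distinct = np.unique(x).size
        if k > n_distinct:
            k = max(4, n_distinct)
            logger.warning("%s: basis dimension reduced to %d (few distinct values)",
                           self.label, k)
        knots = _bspline_knots(x, k)
        s = _difference_penalty(k)
        pens = [_shrinkage_penalty(s)] if self.shrink else [s]
        X = _bspline_design(x, knots)
        Xc, pens, z = _constrain(X, pens)

        def predictor(newdata: pd.DataFrame) -> np.ndarray:
            xn = np.asarray(newdata[self.var], dtype=float)
            return _bspline_design(xn, knots) @ z

        return TermBlock(self.label, Xc, pens, predictor)


class CyclicTerm:
    """Cyclic cubic P-spline on a periodic covariate (e.g. time of day)."""

    def __init__(self, var: str, k: int = 10, period: float = 24.0, origin: float = 0.0):
        self.var = var
        self.k = k
        self.period = period
        self.origin = origin
        self.label = f"s({var},cyclic)"

    def build(self, data: pd.DataFrame) -> TermBlock:
        x = np.asarray(data[self.var], dtype=float)
        k, x0, period = self.k, self.origin, self.period
        X = _cyclic_design(x, k, x0, period)
        pens = [_shrinkage_penalty(_cyclic_penalty(k))]
        Xc, pens, z = _constrain(X, pens)

        def predictor(newdata: pd.DataFrame) -> np.ndarray:
            xn = np.asarray(newdata[self.var], dtype=float)
            return _cyclic_design(xn, k, x0, period) @ z

        return TermBlock(self.label, Xc, pens, predictor)


class TensorTerm:
    """Tensor-product smooth of two covariates with per-margin penalties."""

    def __init__(self, var1: str, var2: str, k: tuple[int, int] = (5, 5),
                 shrink: bool = True):
        self.var1, self.var2 = var1, var2
        self.k = k
        self.shrink = shrink
        self.label = f"te({var1},{var2})"

    def build(self, data: pd.DataFrame) -> TermBlock:
        x1 = np.asarray(data[self.var1], dtype=float)
        x2 = np.asarray(data[self.var2], dtype=float)
        k1, k2 = self.k
        kn1 = _bspline_knots(x1, k1)
        kn2 = _bspline_knots(x2, k2)
        b1 = _bspline_design(x1, kn1)
        b2 = _bspline_design(x2, kn2)
        s1 = _difference_penalty(k1)
        s2 = _difference_penalty(k2)
        X = _row_kron(b1, b2)
        if self.shrink:
            s1 = _shrinkage_penalty(s1)
            s2 = _shrinkage_penalty(s2)
        p1 = np.kron(s1, np.eye(k2))
        p2 = np.kron(np.eye(k1), s2)
        Xc, pens, z = _constrain(X, [p1, p2])

        def predictor(newdata: pd.DataFrame) -> np.ndarray:
            n1 = _bspline_design(np.asarray(newdata[self.var1], dtype=float), kn1)
            n2 = _bspline_design(np.asarray(newdata[self.var2], dtype=float), kn2)
            return _row_kron(n1, n2) @ z

        return TermBlock(self.label, Xc, pens, predictor)


class RandomInterceptTerm:
    """Per-level intercepts under a ridge penalty (i.i.d. random effects)."""

    def __init__(self, var: str):
        self.var = var
        self.label = f"s({var},random)"

    def build(self, data: pd.DataFrame) -> TermBlock:
        levels = sorted(pd.unique(data[self.var].astype(str)))
        index = {lv: i for i, lv in enumerate(levels)}

        def design(frame: pd.DataFrame) -> np.ndarray:
            m = np.zeros((len(frame), len(levels)))
            for r, lv in enumerate(frame[self.var].astype(str)):
                j = index.get(lv)
                if j is not None:
                    m[r, j] = 1.0
            return m

        X = design(data)
        return TermBlock(self.label, X, [np.eye(len(levels))], design)


class FactorTerm:
    """Unpenalized dummy-coded categorical effect (reference level dropped)."""

    def __init__(self, var: str, reference: str | None = None):
        self.var = var
        self.reference = reference
        self.label = f"factor({var})"
        self.level_names: list[str] = []

    def build(self, data: pd.DataFrame) -> TermBlock:
        vals = data[self.var].astype(str)
        levels = sorted(pd.unique(vals))
        ref = self.reference if self.reference is not None else levels[0]
        keep = [lv for lv in levels if lv != str(ref)]
        self.level_names = keep
        index = {lv: i for i, lv in enumerate(keep)}

        def design(frame: pd.DataFrame) -> np.ndarray:
            m = np.zeros((len(frame), len(keep)))
            for r, lv in enumerate(frame[self.var].astype(str)):
                j = index.get(lv)
                if j is not None:
                    m[r, j] = 1.0
            return m

        X = design(data)
        return TermBlock(self.label, X, [], design)
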