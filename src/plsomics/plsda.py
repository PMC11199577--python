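"""Sparse PLS discriminant analysis via NIPALS.

The model regresses a column-centered two-column class indicator matrix
(case, control) on an autoscaled feature block through successive latent
components.  Each component's feature weight vector is estimated by the
NIPALS power iteration, with an optional per-component sparsity budget
(``keep_x``): the weight vector is thresholded so that exactly ``keep_x``
entries stay nonzero.  Classification is by nearest class
centroid in the cumulative latent score space.

The first dense component's weight vector coincides (up to sign) with the
dominant left singular vector of ``X^T Y`` — the maximizer of the squared
covariance between the X-score and a direction in outcome space.

Usage follows the Model / Results pattern::

    model = PLSDA(X, y, n_components=2, keep_x=50)
    res = model.fit()
    res.predict(X_new)
    res.summary()
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PLSDA", "PLSDAResults", "dummy_outcome", "soft_threshold_keep"]

CASE, CONTROL = 1, 0


def dummy_outcome(y: np.ndarray) -> np.ndarray:
    """Column-centered samples x 2 indicator matrix (case, control).

    Before centering each row sums to 1: column 0 indicates cases (y == 1),
    column 1 controls (y == 0).
    """
    y = np.asarray(y)
    if not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("labels must be binary, coded case=1 / control=0")
    Y = np.column_stack([(y == CASE).astype(float), (y == CONTROL).astype(float)])
    return Y - Y.mean(axis=0)


def soft_threshold_keep(a: np.ndarray, keep: int | None) -> np.ndarray:
    """Zero all but the ``keep`` largest-|entry| coordinates of ``a``.

    Truncation to the top-``keep`` magnitudes (ties broken toward the lower
    feature index) is the exact maximizer of ``a . g`` over unit vectors
    with at most ``keep`` nonzeros, which keeps the block-coordinate solver
    monotone in its objective; the lasso-style shrinkage variant selects the
    identical feature set but shrinks surviving weights and can lose
    monotonicity.  ``keep=None`` or ``keep >= len(a)`` is a no-op.
    """
    if keep is None or keep >= a.size:
        return a
    if keep < 1:
        raise ValueError(f"keep_x must be >= 1, got {keep}")
    mag = np.abs(a)
    # stable ranking: ties broken by ascending index
    order = np.lexsort((np.arange(a.size), -mag))
    out = np.zeros_like(a)
    kept = order[:keep]
    out[kept] = a[kept]
    return out


@dataclass
class _Component:
    weights: np.ndarray        # a_h, ||a_h|| = 1
    scores: np.ndarray         # t_h on the training samples
    x_loadings: np.ndarray     # c_h
    y_loadings: np.ndarray     # d_h
    n_iter: int


class PLSDA:
    """Sparse PLS-DA model for a binary outcome.

    Parameters
    ----------
    X : ndarray or DataFrame, shape (n_samples, n_features)
        Autoscaled feature block (z-scored per feature).
    y : array-like of {0, 1}
        Class labels, case=1 / control=0.
    n_components : int
        Number of latent components (default 2).
    keep_x : int, sequence of int, or None
        Per-component count of features allowed a nonzero weight; ``None``
        keeps all.
    feature_ids : sequence of str, optional
        Defaults to DataFrame columns or ``f0..f{p-1}``.
    """

    def __init__(
        self,
        X,
        y,
        n_components: int = 2,
        keep_x: int | Sequence[int] | None = None,
        feature_ids: Sequence[str] | None = None,
        tol: float = 1e-9,
        max_iter: int = 500,
    ):
        if isinstance(X, pd.DataFrame):
            if feature_ids is None:
                feature_ids = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("y contains a single class; PLS-DA needs both")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        self.n_components = int(n_components)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        p = self.X.shape[1]
        if keep_x is None:
            self.keep_x: list[int | None] = [None] * self.n_components
        elif np.isscalar(keep_x):
            self.keep_x = [int(keep_x)] * self.n_components
        else:
            keep_x = list(keep_x)
            if len(keep_x) != self.n_components:
                raise ValueError("keep_x length must equal n_components")
            self.keep_x = [None if k is None else int(k) for k in keep_x]
        for k in self.keep_x:
            if k is not None and not 1 <= k <= p:
                raise ValueError(f"keep_x entries must lie in [1, {p}], got {k}")
        self.feature_ids = (
            [str(f) for f in feature_ids]
            if feature_ids is not None
            else [f"f{j}" for j in range(p)]
        )
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length must match X columns")
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, y, **kwargs) -> "PLSDA":
        return cls(frame, y, **kwargs)

    def fit(self) -> "PLSDAResults":
        Xh = self.X.copy()
        Yh = dummy_outcome(self.y)
        components: list[_Component] = []
        for h in range(self.n_components):
            comp = self._fit_component(Xh, Yh, self.keep_x[h], h)
            Xh = Xh - np.outer(comp.scores, comp.x_loadings)
            Yh = Yh - np.outer(comp.scores, comp.y_loadings)
            components.append(comp)
        return PLSDAResults(self, components)

    def _fit_component(self, Xh, Yh, keep, h) -> _Component:
        u = Yh[:, 0].copy()
        if not np.any(u):
            u = Yh[:, 1].copy()
        u_init = u.copy()
        a_old = np.zeros(Xh.shape[1])
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            a = Xh.T @ u
            a = soft_threshold_keep(a, keep)
            norm = np.linalg.norm(a)
            if norm == 0:
                raise np.linalg.LinAlgError(
                    f"component {h + 1}: zero weight vector (degenerate deflated X)"
                )
            a /= norm
            t = Xh @ a
            b = Yh.T @ t
            bnorm = np.linalg.norm(b)
            if bnorm == 0:
                raise np.linalg.LinAlgError(
                    f"component {h + 1}: outcome fully deflated"
                )
            b /= bnorm
            u = Yh @ b
            if np.linalg.norm(a - a_old) < self.tol:
                break
            a_old = a
        else:
            raise RuntimeError(
                f"component {h + 1}: NIPALS did not converge in {self.max_iter} iterations"
            )
        # sign convention: orient the component toward the case class (the
        # initial outcome direction), so scores from different fits/blocks
        # share orientation; deterministic since the fit uses no RNG
        if t @ u_init < 0:
            a = -a
            t = -t
        tt = t @ t
        c = Xh.T @ t / tt
        d = Yh.T @ t / tt
        return _Component(weights=a, scores=t, x_loadings=c, y_loadings=d, n_iter=n_iter)


class PLSDAResults:
    """Fitted sparse PLS-DA model.

    Attributes
    ----------
    weights : ndarray (n_features, n_components)
        Unit-norm sparse weight vectors ``a_h``.
    scores : ndarray (n_samples, n_components)
        Training latent scores ``t_h`` (mutually orthogonal).
    x_loadings, y_loadings : ndarray
        Regression loadings used for deflation.
    centroids : dict k -> {class -> ndarray of length k}
        Class centroids in the cumulative k-component score space.
    """

    def __init__(self, model: PLSDA, components: list[_Component]):
        self.model = model
        self.feature_ids = model.feature_ids
        self.n_components = len(components)
        self.weights = np.column_stack([c.weights for c in components])
        self.scores = np.column_stack([c.scores for c in components])
        self.x_loadings = np.column_stack([c.x_loadings for c in components])
        self.y_loadings = np.column_stack([c.y_loadings for c in components])
        self.n_iter = [c.n_iter for c in components]
        self.classes_ = np.array([CASE, CONTROL])
        self.class_counts = {
            int(c): int((model.y == c).sum()) for c in (CASE, CONTROL)
        }
        self.centroids = {
            k: {
                int(c): self.scores[model.y == c, :k].mean(axis=0)
                for c in (CASE, CONTROL)
            }
            for k in range(1, self.n_components + 1)
        }

    # -- projection ---------------------------------------------------------

    def transform(self, X_new, feature_ids: Sequence[str] | None = None) -> np.ndarray:
        """Project new (already scaled) samples into the latent space."""
        if isinstance(X_new, pd.DataFrame):
            feature_ids = [str(c) for c in X_new.columns]
            X_new = X_new.to_numpy(dtype=float)
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if feature_ids is not None:
            if list(feature_ids) != self.feature_ids:
                missing = [f for f in self.feature_ids if f not in set(feature_ids)]
                raise ValueError(
                    f"feature mismatch with the fitted model; missing {missing[:5]}"
                )
        if X_new.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"expected {len(self.feature_ids)} features, got {X_new.shape[1]}"
            )
        Xh = X_new.copy()
        T = np.empty((Xh.shape[0], self.n_components))
        for h in range(self.n_components):
            t = Xh @ self.weights[:, h]
            T[:, h] = t
            Xh = Xh - np.outer(t, self.x_loadings[:, h])
        return T

    # -- importance & selection --------------------------------------------

    def loading_importance(self) -> pd.Series:
        """Features ranked by importance = max over components of |weight|.

        Descending importance; ties broken by ascending feature index.
        """
        imp = np.max(np.abs(self.weights), axis=1)
        order = np.lexsort((np.arange(imp.size), -imp))
        return pd.Series(imp[order], index=[self.feature_ids[j] for j in order],
                         name="importance")

    def select_top_features(self, k: int) -> list[str]:
        """Top-``k`` feature IDs by :meth:`loading_importance`."""
        if k <= 0:
            raise ValueError(f"k must be positive, got {k}")
        if k > len(self.feature_ids):
            raise ValueError(f"k={k} exceeds the {len(self.feature_ids)} features")
        return list(self.loading_importance().index[:k])

    def selected_features(self) -> list[str]:
        """Features with a nonzero weight on any component (sparse fits)."""
        nz = np.any(self.weights != 0.0, axis=1)
        return [f for f, m in zip(self.feature_ids, nz) if m]

    # -- prediction ---------------------------------------------------------

    def decision_values(self, X_new, k: int | None = None) -> np.ndarray:
        """``d(control centroid) - d(case centroid)`` per sample (>0 => case)."""
        k = self.n_components if k is None else int(k)
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must lie in [1, {self.n_components}], got {k}")
        T = self.transform(X_new)[:, :k]
        cen = self.centroids[k]
        d_case = np.linalg.norm(T - cen[CASE], axis=1)
        d_control = np.linalg.norm(T - cen[CONTROL], axis=1)
        return d_control - d_case

    def predict(self, X_new, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-centroid class labels and decision values.

        Exact ties go to the majority training class.
        """
        dv = self.decision_values(X_new, k)
        majority = max(self.class_counts, key=lambda c: (self.class_counts[c], c == CONTROL))
        labels = np.where(dv > 0, CASE, CONTROL)
        labels[dv == 0] = majority
        return labels, dv

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Sparse PLS-DA results",
            "=" * 52,
            f"samples:        {self.scores.shape[0]} "
            f"({self.class_counts[CASE]} cases / {self.class_counts[CONTROL]} controls)",
            f"features:       {len(self.feature_ids)}",
            f"components:     {self.n_components}",
            f"keep_x:         {['all' if k is None else k for k in self.model.keep_x]}",
            "",
            f"{'comp':>4} {'nonzero':>8} {'var(t)':>10} {'iters':>6}",
        ]
        for h in range(self.n_components):
            nz = int(np.count_nonzero(self.weights[:, h]))
            lines.append(
                f"{h + 1:>4} {nz:>8} {self.scores[:, h].var():>10.4f} {self.n_iter[h]:>6}"
            )
        top = self.loading_importance().head(10)
        lines += ["", "top features by |loading|:"]
        for fid, v in top.items():
            lines.append(f"  {fid:<24} {v:.4f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        """Serialize weights, loadings, centroids and metadata."""
        payload = {
            "feature_ids": self.feature_ids,
            "n_components": self.n_components,
            "keep_x": self.model.keep_x,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "centroids": {
                str(k): {str(c): v.tolist() for c, v in cen.items()}
                for k, cen in self.centroids.items()
            },
            "class_counts": self.class_counts,
        }
        return json.dumps(payload)
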