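"""Multi-block sparse PLS-DA ("DIABLO-style" integration).

Each omic block receives its own sparse unit-norm weight vector per
component; the block latent scores are estimated jointly by block-coordinate
ascent on the design-weighted sum of score covariances

    sum_{i<j} c_ij <t_i, t_j>  +  sum_i c_iY <t_i, t_Y>,

where ``t_Y`` is the score of the centered class-indicator block and the
design matrix ``c`` states which block pairs (and block-outcome pairs) are
encouraged to covary.  Covariance, not correlation, is maximized; on
autoscaled blocks the two are equivalent up to scaling and covariance is
numerically stabler.

Each sample's consensus coordinate is the arithmetic mean of its per-block
scores ("the centroid of the arrows" in the arrow-plot reading);
classification is by nearest consensus class centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import OmicsBlock, check_aligned
from .plsda import CASE, CONTROL, dummy_outcome, soft_threshold_keep

__all__ = ["DesignMatrix", "BlockPLSDA", "BlockPLSDAResults"]

OUTCOME = "_outcome_"


@dataclass
class DesignMatrix:
    """Symmetric non-negative design weights over blocks and the outcome.

    ``weights[(i, j)]`` with block names ``i != j``; the outcome is addressed
    by its reserved name.  Every block must have a positive tie to the
    outcome.
    """

    block_names: list[str]
    weights: dict[tuple[str, str], float]

    @classmethod
    def full(cls, block_names: Sequence[str], inter_block: float = 1.0,
             to_outcome: float = 1.0) -> "DesignMatrix":
        """Fully-connected design: ``inter_block`` between every block pair,
        ``to_outcome`` from every block to the outcome."""
        names = list(block_names)
        w: dict[tuple[str, str], float] = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                w[(a, b)] = w[(b, a)] = float(inter_block)
            w[(a, OUTCOME)] = w[(OUTCOME, a)] = float(to_outcome)
        return cls(names, w)

    def __post_init__(self) -> None:
        for (a, b), v in self.weights.items():
            if v < 0:
                raise ValueError(f"design weight ({a},{b}) is negative")
            if abs(self.weights.get((b, a), -1.0) - v) > 1e-12:
                raise ValueError(f"design weights not symmetric at ({a},{b})")
        for name in self.block_names:
            if self.weights.get((name, OUTCOME), 0.0) <= 0:
                raise ValueError(
                    f"block {name!r} must have a positive design weight to the outcome"
                )

    def get(self, a: str, b: str) -> float:
        return self.weights.get((a, b), 0.0)


@dataclass
class _BlockComponent:
    weights: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]
    x_loadings: dict[str, np.ndarray]
    outcome_weights: np.ndarray
    n_iter: int
    objective_path: list[float]


class BlockPLSDA:
    """Multi-block sparse PLS-DA for a binary outcome.

    Parameters
    ----------
    blocks : sequence of OmicsBlock
        Autoscaled blocks sharing one ordered sample list.
    y : array-like of {0, 1}
        Case=1 / control=0 labels in the shared sample order.
    n_components : int, default 2
    keep_x : mapping block name -> int | None | sequence per component
        Sparsity budget per block; ``None`` keeps all features (the
        phenotype block conventionally runs dense).
    design : DesignMatrix, optional
        Defaults to the fully-connected design with unit weights.
    """

    def __init__(
        self,
        blocks: Sequence[OmicsBlock],
        y,
        n_components: int = 2,
        keep_x: Mapping[str, int | None | Sequence[int | None]] | None = None,
        design: DesignMatrix | None = None,
        tol: float = 1e-9,
        max_iter: int = 2000,
    ):
        self.blocks = list(blocks)
        self.sample_ids = check_aligned(self.blocks)
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("block names must be unique")
        self.block_names = names
        self.y = np.asarray(y).astype(int)
        if self.y.shape[0] != len(self.sample_ids):
            raise ValueError("y length does not match the shared sample count")
        if len(np.unique(self.y)) < 2:
            raise ValueError("y contains a single class")
        self.n_components = int(n_components)
        self.design = design if design is not None else DesignMatrix.full(names)
        missing = [n for n in names if n not in self.design.block_names]
        if missing:
            raise ValueError(f"design matrix lacks block(s) {missing}")
        keep_x = dict(keep_x or {})
        self.keep_x: dict[str, list[int | None]] = {}
        for b in self.blocks:
            spec = keep_x.get(b.name)
            if spec is None or np.isscalar(spec):
                per_comp = [None if spec is None else int(spec)] * self.n_components
            else:
                per_comp = [None if k is None else int(k) for k in spec]
                if len(per_comp) != self.n_components:
                    raise ValueError(
                        f"keep_x for block {b.name!r} must have {self.n_components} entries"
                    )
            for k in per_comp:
                if k is not None and not 1 <= k <= b.n_features:
                    raise ValueError(
                        f"keep_x={k} invalid for block {b.name!r} "
                        f"with {b.n_features} features"
                    )
            self.keep_x[b.name] = per_comp
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def fit(self) -> "BlockPLSDAResults":
        Xs = {b.name: b.values.copy() for b in self.blocks}
        Yh = dummy_outcome(self.y)
        components: list[_BlockComponent] = []
        for h in range(self.n_components):
            comp = self._fit_component(Xs, Yh, h)
            for name in self.block_names:
                t = comp.scores[name]
                c = comp.x_loadings[name]
                Xs[name] = Xs[name] - np.outer(t, c)
            # outcome deflated by the consensus score
            t_cons = np.mean([comp.scores[n] for n in self.block_names], axis=0)
            denom = t_cons @ t_cons
            if denom > 0:
                d = Yh.T @ t_cons / denom
                Yh = Yh - np.outer(t_cons, d)
            components.append(comp)
        return BlockPLSDAResults(self, components)

    def _fit_component(self, Xs, Yh, h) -> _BlockComponent:
        names = self.block_names
        u = Yh[:, 0].copy()
        if not np.any(u):
            u = Yh[:, 1].copy()
        # initialize every block score from the outcome direction
        a: dict[str, np.ndarray] = {}
        t: dict[str, np.ndarray] = {}
        for name in names:
            a[name] = self._update_weight(Xs[name], u, name, h)
            t[name] = Xs[name] @ a[name]
        a_y, t_y = self._update_outcome(Yh, t)
        objective_path = [self._objective(t, t_y)]
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            delta = 0.0
            for name in names:
                target = self.design.get(name, OUTCOME) * t_y
                for other in names:
                    if other != name:
                        target = target + self.design.get(name, other) * t[other]
                new_a = self._update_weight(Xs[name], target, name, h)
                delta = max(delta, float(np.max(np.abs(new_a - a[name]))))
                a[name] = new_a
                t[name] = Xs[name] @ new_a
            new_ay, t_y = self._update_outcome(Yh, t)
            delta = max(delta, float(np.max(np.abs(new_ay - a_y))))
            a_y = new_ay
            objective_path.append(self._objective(t, t_y))
            if delta < self.tol:
                break
        else:
            raise RuntimeError(
                f"component {h + 1}: block coordinate ascent did not converge "
                f"in {self.max_iter} iterations"
            )
        # sign convention: orient the outcome score toward the case class,
        # then align every block score with it so the consensus average
        # does not cancel across blocks
        if t_y @ u < 0:
            t_y = -t_y
            a_y = -a_y
        for name in names:
            if t[name] @ t_y < 0:
                a[name] = -a[name]
                t[name] = -t[name]
        loadings = {}
        for name in names:
            tt = t[name] @ t[name]
            loadings[name] = (
                Xs[name].T @ t[name] / tt if tt > 0 else np.zeros(Xs[name].shape[1])
            )
        return _BlockComponent(
            weights=a, scores=t, x_loadings=loadings,
            outcome_weights=a_y, n_iter=n_iter, objective_path=objective_path,
        )

    def _update_weight(self, X, target, name, h) -> np.ndarray:
        a = X.T @ target
        a = soft_threshold_keep(a, self.keep_x[name][h])
        norm = np.linalg.norm(a)
        if norm == 0:
            raise np.linalg.LinAlgError(
                f"block {name!r}: zero weight vector during component {h + 1}"
            )
        return a / norm

    def _update_outcome(self, Yh, t) -> tuple[np.ndarray, np.ndarray]:
        target = np.zeros(Yh.shape[0])
        for name in self.block_names:
            target = target + self.design.get(name, OUTCOME) * t[name]
        a_y = Yh.T @ target
        norm = np.linalg.norm(a_y)
        if norm == 0:
            raise np.linalg.LinAlgError("outcome block fully deflated")
        a_y = a_y / norm
        return a_y, Yh @ a_y

    def _objective(self, t, t_y) -> float:
        total = 0.0
        names = self.block_names
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                total += self.design.get(a, b) * float(t[a] @ t[b])
            total += self.design.get(a, OUTCOME) * float(t[a] @ t_y)
        return total


class BlockPLSDAResults:
    """Fitted multi-block sparse PLS-DA model.

    ``weights[name]`` is the (n_features x n_components) sparse weight matrix
    of a block, ``scores[name]`` its training scores; ``consensus_scores``
    averages the block scores and ``consensus_centroids[k]`` holds the class
    centroids in the cumulative k-component consensus space.
    """

    def __init__(self, model: BlockPLSDA, components: list[_BlockComponent]):
        self.model = model
        self.block_names = model.block_names
        self.n_components = len(components)
        self.weights = {
            n: np.column_stack([c.weights[n] for c in components])
            for n in self.block_names
        }
        self.scores = {
            n: np.column_stack([c.scores[n] for c in components])
            for n in self.block_names
        }
        self.x_loadings = {
            n: np.column_stack([c.x_loadings[n] for c in components])
            for n in self.block_names
        }
        self.feature_ids = {b.name: b.feature_ids for b in model.blocks}
        self.n_iter = [c.n_iter for c in components]
        self.objective_paths = [c.objective_path for c in components]
        self.consensus_scores = consensus(self.scores)
        y = model.y
        self.class_counts = {int(c): int((y == c).sum()) for c in (CASE, CONTROL)}
        self.consensus_centroids = {
            k: {
                int(c): self.consensus_scores[y == c, :k].mean(axis=0)
                for c in (CASE, CONTROL)
            }
            for k in range(1, self.n_components + 1)
        }

    # -- projection ---------------------------------------------------------

    def project(self, blocks: Sequence[OmicsBlock]) -> dict[str, np.ndarray]:
        """Per-block latent scores of new (already scaled) samples."""
        by_name = {b.name: b for b in blocks}
        missing = [n for n in self.block_names if n not in by_name]
        if missing:
            raise ValueError(f"missing block(s) {missing}")
        check_aligned([by_name[n] for n in self.block_names])
        out: dict[str, np.ndarray] = {}
        for name in self.block_names:
            b = by_name[name]
            if b.feature_ids != self.feature_ids[name]:
                raise ValueError(
                    f"block {name!r}: features do not match the fitted model"
                )
            Xh = b.values.copy()
            T = np.empty((Xh.shape[0], self.n_components))
            for h in range(self.n_components):
                t = Xh @ self.weights[name][:, h]
                T[:, h] = t
                Xh = Xh - np.outer(t, self.x_loadings[name][:, h])
            out[name] = T
        return out

    def selected_features(self) -> dict[str, list[str]]:
        """Per block, features with a nonzero weight on any component."""
        return {
            n: [f for f, nz in zip(self.feature_ids[n],
                                   np.any(self.weights[n] != 0, axis=1)) if nz]
            for n in self.block_names
        }

    # -- prediction ---------------------------------------------------------

    def decision_values(self, blocks: Sequence[OmicsBlock], k: int | None = None
                        ) -> np.ndarray:
        k = self.n_components if k is None else int(k)
        if not 1 <= k <= self.n_components:
            raise ValueError(f"k must lie in [1, {self.n_components}], got {k}")
        cons = consensus(self.project(blocks))[:, :k]
        cen = self.consensus_centroids[k]
        d_case = np.linalg.norm(cons - cen[CASE], axis=1)
        d_control = np.linalg.norm(cons - cen[CONTROL], axis=1)
        return d_control - d_case

    def predict(self, blocks: Sequence[OmicsBlock], k: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
        """Nearest consensus-centroid labels and decision values (>0 => case)."""
        dv = self.decision_values(blocks, k)
        majority = max(self.class_counts,
                       key=lambda c: (self.class_counts[c], c == CONTROL))
        labels = np.where(dv > 0, CASE, CONTROL)
        labels[dv == 0] = majority
        return labels, dv

    # -- reporting ----------------------------------------------------------

    def arrow_data(self, blocks: Sequence[OmicsBlock] | None = None,
                   y=None) -> pd.DataFrame:
        """Tidy per-sample coordinates: block scores (arrow tips) and the
        consensus (arrow base) on the first two components."""
        if blocks is None:
            scores = self.scores
            cons = self.consensus_scores
            sample_ids = self.model.sample_ids
            y = self.model.y if y is None else np.asarray(y)
        else:
            scores = self.project(blocks)
            cons = consensus(scores)
            sample_ids = blocks[0].sample_ids
            y = np.full(len(sample_ids), -1) if y is None else np.asarray(y)
        k2 = min(2, self.n_components)
        rows = []
        for i, sid in enumerate(sample_ids):
            for name in self.block_names:
                rows.append({
                    "sample": sid, "block": name,
                    "comp1": scores[name][i, 0],
                    "comp2": scores[name][i, 1] if k2 > 1 else np.nan,
                    "consensus1": cons[i, 0],
                    "consensus2": cons[i, 1] if k2 > 1 else np.nan,
                    "class": "case" if y[i] == CASE else
                             ("control" if y[i] == CONTROL else "unknown"),
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Multi-block sparse PLS-DA results",
            "=" * 56,
            f"samples:    {len(self.model.sample_ids)} "
            f"({self.class_counts[CASE]} cases / {self.class_counts[CONTROL]} controls)",
            f"blocks:     {', '.join(self.block_names)}",
            f"components: {self.n_components}",
            "",
            f"{'block':<14} {'features':>9} " +
            " ".join(f"{'nz(c' + str(h + 1) + ')':>8}" for h in range(self.n_components)),
        ]
        for name in self.block_names:
            nz = [int(np.count_nonzero(self.weights[name][:, h]))
                  for h in range(self.n_components)]
            lines.append(
                f"{name:<14} {len(self.feature_ids[name]):>9} " +
                " ".join(f"{v:>8}" for v in nz)
            )
        sep = {
            k: float(np.linalg.norm(
                self.consensus_centroids[k][CASE] - self.consensus_centroids[k][CONTROL]
            ))
            for k in self.consensus_centroids
        }
        lines += [""] + [
            f"consensus centroid separation (k={k}): {v:.4f}" for k, v in sep.items()
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "block_names": self.block_names,
            "n_components": self.n_components,
            "feature_ids": self.feature_ids,
            "weights": {n: w.tolist() for n, w in self.weights.items()},
            "x_loadings": {n: w.tolist() for n, w in self.x_loadings.items()},
            "consensus_centroids": {
                str(k): {str(c): v.tolist() for c, v in cen.items()}
                for k, cen in self.consensus_centroids.items()
            },
            "class_counts": self.class_counts,
        }
        return json.dumps(payload)


def consensus(scores: Mapping[str, np.ndarray]) -> np.ndarray:
    """Arithmetic mean of per-block score arrays (equal sample counts)."""
    arrays = list(scores.values())
    n = {a.shape[0] for a in arrays}
    if len(n) != 1:
        raise ValueError("blocks disagree on the number of samples")
    return np.mean(arrays, axis=0)
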