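"""Interpretation layers over a fitted multi-block model.

Computes the data behind the standard mixOmics-style displays:

* circle-plot coordinates — the Pearson correlation of each panel feature
  with the consensus latent components (features at the rim are the strong
  predictors, features at the center are weak);
* cross-omics association — the component-space similarity
  ``r_jk = sum_h cor(x_j, t_h) * cor(x_k, t_h)``, the latent-variable
  approximation that lets features from different blocks be related without
  ever correlating them directly (the quantity behind Circos-style link
  plots);
* correlation networks thresholded on |r|, with average-degree summaries;
* hierarchical-clustering orders for the panel heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .blocks import OmicsBlock, check_aligned
from .blockplsda import BlockPLSDAResults, consensus

__all__ = [
    "feature_component_correlations",
    "cross_omics_association",
    "AssociationMatrix",
    "FeatureNetwork",
    "build_network",
    "cluster_heatmap_order",
]

logger = logging.getLogger(__name__)


def feature_component_correlations(
    results: BlockPLSDAResults, blocks: Sequence[OmicsBlock]
) -> pd.DataFrame:
    """Pearson correlation of every block feature with each consensus component.

    ``blocks`` must be the (scaled) blocks the model was fitted on, restricted
    to the panel.  Rows are features (index ``block:feature``); columns
    ``comp1..compH``.  Zero-variance features get correlation 0 with a
    warning.  The first two columns are the circle-plot coordinates.
    """
    check_aligned(blocks)
    cons = consensus(results.project(blocks))
    n_comp = cons.shape[1]
    rows, index, block_of = [], [], []
    for b in blocks:
        X = b.values
        xc = X - X.mean(axis=0)
        sx = xc.std(axis=0)
        tc = cons - cons.mean(axis=0)
        st = tc.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc.T @ tc) / X.shape[0] / np.outer(sx, st)
        degenerate = sx == 0
        if degenerate.any():
            logger.warning(
                "%d zero-variance feature(s) in block %r: correlation set to 0",
                int(degenerate.sum()), b.name,
            )
            r[degenerate, :] = 0.0
        r = np.nan_to_num(r, nan=0.0)
        rows.append(np.clip(r, -1.0, 1.0))
        index.extend(f"{b.name}:{f}" for f in b.feature_ids)
        block_of.extend([b.name] * b.n_features)
    frame = pd.DataFrame(
        np.vstack(rows), index=index,
        columns=[f"comp{h + 1}" for h in range(n_comp)],
    )
    frame.insert(0, "block", block_of)
    return frame


@dataclass
class AssociationMatrix:
    """Symmetric feature x feature association over the pooled panel."""

    values: pd.DataFrame        # square, unit diagonal, in [-1, 1]
    blocks: pd.Series           # feature -> block name

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("association matrix must be symmetric")
        if np.abs(v).max() > 1 + 1e-9:
            raise ValueError("association values must be bounded by 1")


def cross_omics_association(correlations: pd.DataFrame) -> AssociationMatrix:
    """Component-space association between all panel-feature pairs.

    ``r_jk = sum_h cor(x_j, t_h) cor(x_k, t_h)`` over the model components,
    clipped to [-1, 1]; the diagonal is set to 1 (self-association).
    """
    comp_cols = [c for c in correlations.columns if c.startswith("comp")]
    if not comp_cols:
        raise ValueError("correlations frame has no component columns")
    C = correlations[comp_cols].to_numpy()
    M = np.clip(C @ C.T, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    values = pd.DataFrame(M, index=correlations.index, columns=correlations.index)
    return AssociationMatrix(values=values, blocks=correlations["block"])


@dataclass
class FeatureNetwork:
    """Thresholded undirected association network."""

    edges: pd.DataFrame         # columns: source, target, weight
    nodes: list[str]
    threshold: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def average_degree(self) -> float:
        """``2 |E| / |V'|`` over nodes with at least one edge."""
        if self.n_edges == 0:
            return 0.0
        connected = set(self.edges["source"]) | set(self.edges["target"])
        return 2.0 * self.n_edges / len(connected)


def build_network(
    assoc: AssociationMatrix,
    threshold: float = 0.7,
    block_pair: tuple[str, str] | None = None,
) -> FeatureNetwork:
    """Edges where ``|r| >= threshold`` (no self-edges).

    ``block_pair`` restricts edges to pairs with one endpoint in each of the
    two named blocks (the per-omic-pair network panels).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    M = assoc.values.to_numpy()
    features = list(assoc.values.index)
    blocks = assoc.blocks
    rows = []
    for i in range(len(features)):
        for j in range(i + 1, len(features)):
            if block_pair is not None:
                pair = {blocks.iloc[i], blocks.iloc[j]}
                if pair != set(block_pair):
                    continue
            if abs(M[i, j]) >= threshold:
                rows.append({"source": features[i], "target": features[j],
                             "weight": M[i, j]})
    if block_pair is None:
        nodes = features
    else:
        nodes = [f for f, b in zip(features, blocks) if b in set(block_pair)]
    return FeatureNetwork(
        edges=pd.DataFrame(rows, columns=["source", "target", "weight"]),
        nodes=nodes, threshold=threshold,
    )


def cluster_heatmap_order(
    matrix: pd.DataFrame,
) -> tuple[list[int], list[int], dict[str, np.ndarray]]:
    """Hierarchical-clustering leaf orders for a samples x features heatmap.

    Agglomerative clustering with Euclidean distance and complete linkage,
    applied independently to rows (samples) and columns (features).
    Returns ``(row order, column order, linkage records)``; orders are
    positional indices.  SciPy's deterministic tie handling (lowest cluster
    index first) fixes the leaf order.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("heatmap clustering needs at least 2 rows and 2 columns")
    row_link = linkage(X, method="complete", metric="euclidean")
    col_link = linkage(X.T, method="complete", metric="euclidean")
    return (
        [int(i) for i in leaves_list(row_link)],
        [int(i) for i in leaves_list(col_link)],
        {"rows": row_link, "columns": col_link},
    )
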