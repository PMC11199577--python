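"""Core data container for one omic layer.

An :class:`OmicsBlock` holds a dense samples x features matrix together with
its sample and feature identifiers and a block name (``expression``,
``methylation``, ``genotype`` or ``phenotype``).  All downstream modelling
operates on aligned lists of blocks that share an identical ordered sample-ID
list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["OmicsBlock", "QCReport", "check_aligned"]


@dataclass
class OmicsBlock:
    """Samples x features matrix with identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Numeric matrix; missing entries are NaN.
    sample_ids : sequence of str
        Row identifiers, unique within the block.
    feature_ids : sequence of str
        Column identifiers, unique within the block.
    name : str
        Block label, conventionally one of ``expression``, ``methylation``,
        ``genotype``, ``phenotype``.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    name: str = "block"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"block {self.name!r}: {n} rows but {len(self.sample_ids)} sample_ids"
            )
        if p != len(self.feature_ids):
            raise ValueError(
                f"block {self.name!r}: {p} columns but {len(self.feature_ids)} feature_ids"
            )
        for label, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValueError(f"block {self.name!r}: duplicate {label} ID {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return a samples x features DataFrame."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str = "block") -> "OmicsBlock":
        """Build from a samples x features DataFrame."""
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(i) for i in frame.index],
            feature_ids=[str(c) for c in frame.columns],
            name=name,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsBlock":
        """Return a block restricted to ``feature_ids`` (in the given order)."""
        index = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"block {self.name!r}: unknown feature IDs {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return OmicsBlock(
            self.values[:, cols], self.sample_ids, list(feature_ids), self.name
        )

    def subset_samples(self, rows: Sequence[int]) -> "OmicsBlock":
        rows = list(rows)
        return OmicsBlock(
            self.values[rows, :],
            [self.sample_ids[i] for i in rows],
            self.feature_ids,
            self.name,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OmicsBlock({self.name!r}, {self.n_samples} samples x {self.n_features} features)"


def check_aligned(blocks: Sequence[OmicsBlock]) -> list[str]:
    """Verify all blocks share the identical ordered sample-ID list.

    Returns the shared sample-ID list; raises ``ValueError`` on mismatch.
    """
    if not blocks:
        raise ValueError("no blocks supplied")
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValueError(
                f"sample misalignment: block {b.name!r} does not share the "
                f"sample order of block {blocks[0].name!r}"
            )
    return ref


@dataclass
class QCReport:
    """Bookkeeping of feature-level quality-control filters.

    ``removed`` maps filter name -> number of features removed by that
    filter; ``thresholds`` records the cutoffs used.  ``n_in`` and ``n_out``
    must satisfy ``n_in - sum(removed.values()) == n_out``.
    """

    block_name: str
    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_in - sum(self.removed.values()) != self.n_out:
            raise ValueError(
                f"QCReport {self.block_name!r}: removal counts {self.removed} "
                f"inconsistent with {self.n_in} -> {self.n_out} features"
            )

    def to_dict(self) -> dict:
        return {
            "block": self.block_name,
            "n_features_in": self.n_in,
            "n_features_out": self.n_out,
            "removed": dict(self.removed),
            "thresholds": dict(self.thresholds),
        }
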