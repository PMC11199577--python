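"""Hold-out resampling harness, persistence feature selection and metrics.

The study design this module implements: the cohort is split at random into
train (80%) and test (20%) sets, *unstratified* (the case/control ratio is
not preserved, which widens the confidence intervals and yields a more
conservative model); this is repeated ``n_splits`` times (default 100).
Per split, a 2-component sparse PLS-DA is fitted per omic block on the
train samples and a feature counts as "selected" when it carries a nonzero
loading on any component.  Features selected in at least 70% of splits form
the persistent panel.  Model performance on the panel is then measured per
split on the held-out samples (accuracy, ROC AUC, Matthews correlation
coefficient), summarized as mean +/- SD, and compared between models with
the Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import OmicsBlock, check_aligned
from .blockplsda import BlockPLSDA, DesignMatrix
from .plsda import CASE, CONTROL, PLSDA
from .preprocess import autoscale

__all__ = [
    "SplitPlan", "make_splits",
    "FeaturePanel", "run_persistence_selection",
    "MetricDistribution", "evaluate_over_splits",
    "accuracy", "majority_baseline", "mcc", "roc_auc",
    "mann_whitney_u", "t_test_from_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_KEEPX = {"expression": 50, "methylation": 50, "genotype": 20}


# ---------------------------------------------------------------------------
# splits

@dataclass
class SplitPlan:
    """Seeded sequence of unstratified train/test index partitions."""

    n_samples: int
    train_frac: float
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]]

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)


def make_splits(n: int, n_splits: int = 100, train_frac: float = 0.8,
                seed: int = 0) -> SplitPlan:
    """Unstratified random train/test partitions.

    Train size is ``floor(train_frac * n)``; the test set is the complement.
    Each split draws from its own stream seeded ``seed + split_index`` so
    individual splits can be regenerated in isolation.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must lie in (0, 1), got {train_frac}")
    n_train = int(math.floor(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_frac={train_frac} with n={n} leaves an empty train or test set"
        )
    splits = []
    for i in range(n_splits):
        rng = np.random.default_rng(seed + i)
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
        splits.append((train, test))
    return SplitPlan(n_samples=n, train_frac=train_frac, seed=seed, splits=splits)


# ---------------------------------------------------------------------------
# persistence selection

@dataclass
class FeaturePanel:
    """Per-feature selection frequencies across splits and the persistent set.

    ``frequencies[block]`` maps feature ID -> fraction of splits in which the
    feature carried a nonzero sparse loading.  The panel at ``threshold``
    contains features with frequency >= threshold ("at least 70%" by
    default).
    """

    frequencies: dict[str, pd.Series]
    threshold: float = 0.70
    n_splits: int = 0

    def panel(self, threshold: float | None = None) -> dict[str, list[str]]:
        thr = self.threshold if threshold is None else threshold
        return {
            name: list(freq.index[freq.to_numpy() >= thr])
            for name, freq in self.frequencies.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        panel = self.panel()
        for name, freq in self.frequencies.items():
            inside = set(panel[name])
            for fid, f in freq.items():
                rows.append({"block": name, "feature": fid, "frequency": f,
                             "in_panel": fid in inside})
        return pd.DataFrame(rows)


def run_persistence_selection(
    blocks: Sequence[OmicsBlock],
    y,
    plan: SplitPlan,
    keep_x: Mapping[str, int] | None = None,
    n_components: int = 2,
    threshold: float = 0.70,
    exempt: Sequence[str] = ("phenotype",),
) -> FeaturePanel:
    """Stability selection across the plan's train/test splits.

    Per split, each non-exempt block's train portion is autoscaled and a
    sparse PLS-DA with ``keep_x[block]`` features per component is fitted;
    a feature is "selected" when its loading is nonzero on any component.
    Blocks in ``exempt`` (the low-dimensional phenotype block) skip
    pre-selection and are reported with frequency 1 for every feature.
    """
    check_aligned(blocks)
    y = np.asarray(y).astype(int)
    keep_x = dict(DEFAULT_KEEPX if keep_x is None else keep_x)
    counts: dict[str, pd.Series] = {}
    for b in blocks:
        if b.name in exempt:
            continue
        k = keep_x.get(b.name)
        if k is not None and k > b.n_features:
            raise ValueError(
                f"keep_x={k} exceeds the {b.n_features} features of block {b.name!r}"
            )
        counts[b.name] = pd.Series(0.0, index=b.feature_ids)
    n_used = 0
    for train, _test in plan:
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            logger.warning("skipping single-class train split in selection")
            continue
        n_used += 1
        for b in blocks:
            if b.name in exempt:
                continue
            scaled, _ = autoscale(b.subset_samples(train))
            res = PLSDA(
                scaled.values, y_train, n_components=n_components,
                keep_x=min(keep_x.get(b.name) or scaled.n_features, scaled.n_features),
                feature_ids=scaled.feature_ids,
            ).fit()
            counts[b.name].loc[res.selected_features()] += 1.0
    if n_used == 0:
        raise ValueError("no usable split (all train sets single-class)")
    frequencies = {name: c / n_used for name, c in counts.items()}
    for b in blocks:
        if b.name in exempt:
            frequencies[b.name] = pd.Series(1.0, index=b.feature_ids)
    return FeaturePanel(frequencies=frequencies, threshold=threshold,
                        n_splits=n_used)


# ---------------------------------------------------------------------------
# metrics

def accuracy(pred, truth) -> float:
    """Fraction of correct binary predictions."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred and truth must be nonempty and equal-length")
    return float(np.mean(pred == truth))


def majority_baseline(truth) -> float:
    """Accuracy of always predicting the most frequent class."""
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(truth, return_counts=True)
    return float(counts.max() / truth.size)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    Defined as 0 when any factor of the denominator is 0 (the conventional
    limit, which maps the always-majority predictor to 0).
    """
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def mcc_from_labels(pred, truth) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    tp = int(np.sum((pred == CASE) & (truth == CASE)))
    tn = int(np.sum((pred == CONTROL) & (truth == CONTROL)))
    fp = int(np.sum((pred == CASE) & (truth == CONTROL)))
    fn = int(np.sum((pred == CONTROL) & (truth == CASE)))
    return mcc(tp, tn, fp, fn)


def roc_auc(decision_values, truth) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    AUC = (correctly ordered case-control pairs + half the ties) divided by
    the number of pairs.  Computed from midranks, which is algebraically
    identical to the pairwise count.
    """
    dv, truth = np.asarray(decision_values, dtype=float), np.asarray(truth)
    n_case = int(np.sum(truth == CASE))
    n_control = int(np.sum(truth == CONTROL))
    if n_case == 0 or n_control == 0:
        raise ValueError("ROC AUC requires both classes in truth")
    ranks = stats.rankdata(dv)
    rank_sum_cases = float(ranks[truth == CASE].sum())
    u = rank_sum_cases - n_case * (n_case + 1) / 2.0
    return u / (n_case * n_control)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For ``min(n_a, n_b) <= 8`` the p-value is exact, by enumeration of all
    label assignments of the pooled values (ties included); otherwise the
    normal approximation with tie and continuity correction is used.

    Returns ``(U_a, p_two_sided)`` where ``U_a`` counts pairs (a, b) with
    a > b plus half the ties.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u_a = float(np.sum(a[:, None] > b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :]))
    n_a, n_b = a.size, b.size
    if min(n_a, n_b) <= 8 and n_a + n_b <= 24:
        pooled = np.concatenate([a, b])
        mu = n_a * n_b / 2.0
        obs_dev = abs(u_a - mu)
        total = 0
        extreme = 0
        idx = np.arange(pooled.size)
        for comb in itertools.combinations(idx, n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb)] = True
            aa, bb = pooled[mask], pooled[~mask]
            u = np.sum(aa[:, None] > bb[None, :]) + 0.5 * np.sum(aa[:, None] == bb[None, :])
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        return u_a, extreme / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_a, float(res.pvalue)


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int,
                        welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics.

    Pooled-variance Student t with ``n1 + n2 - 2`` degrees of freedom by
    default; ``welch=True`` switches to the unequal-variance form.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    if not np.isfinite(t):
        logger.warning("zero pooled variance with unequal means: p set to 0")
        return math.copysign(math.inf, mean1 - mean2), 0.0
    return float(t), float(p)


# ---------------------------------------------------------------------------
# per-split evaluation

@dataclass
class MetricDistribution:
    """Per-split values of one metric at one component count, with mean/SD."""

    metric: str
    component: int
    values: np.ndarray
    model: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"MetricDistribution({self.model or 'model'}: {self.metric}, "
                f"comp {self.component}: {self.mean:.4f} +/- {self.sd:.4f}, "
                f"n={self.values.size})")


@dataclass
class EvaluationResult:
    """All metric distributions of one model over a split plan."""

    model: str
    distributions: dict[tuple[str, int], MetricDistribution]
    n_splits_used: int
    n_splits_skipped: int
    baseline: float

    def get(self, metric: str, component: int) -> MetricDistribution:
        return self.distributions[(metric, component)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (metric, comp), dist in self.distributions.items():
            for i, v in enumerate(dist.values):
                rows.append({"model": self.model, "split": i, "component": comp,
                             "metric": metric, "value": v})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Model {self.model!r}: {self.n_splits_used} splits used, "
            f"{self.n_splits_skipped} skipped; majority baseline "
            f"{100 * self.baseline:.1f}%",
            f"{'metric':<10} {'comp':>4} {'mean':>9} {'sd':>9}",
        ]
        for (metric, comp), d in sorted(self.distributions.items()):
            lines.append(f"{metric:<10} {comp:>4} {d.mean:>9.4f} {d.sd:>9.4f}")
        return "\n".join(lines)


def evaluate_over_splits(
    blocks: Sequence[OmicsBlock],
    y,
    plan: SplitPlan,
    panel: Mapping[str, Sequence[str]] | FeaturePanel | None,
    model: str = "block",
    n_components: int = 2,
    design: DesignMatrix | None = None,
    keep_x: Mapping[str, int] | None = None,
) -> EvaluationResult:
    """Fit and test a model on every split; aggregate metric distributions.

    Parameters
    ----------
    panel : mapping block -> feature IDs, FeaturePanel, or None
        Features each block is restricted to before fitting (None keeps
        everything; a block absent from the mapping is dropped unless the
        model is single-block on that block).
    model : "block" or "single:<block name>"
        The integrative multi-block model or a single-omic PLS-DA.
    keep_x : optional per-block sparsity for the evaluated model
        Default is dense (the panel already did the selection).

    Splits whose train set contains a single class are skipped with a
    warning and counted in the result.
    """
    check_aligned(blocks)
    y = np.asarray(y).astype(int)
    if isinstance(panel, FeaturePanel):
        panel = panel.panel()
    if panel is not None:
        restricted = []
        for b in blocks:
            feats = panel.get(b.name)
            if feats is None or len(feats) == 0:
                logger.info("block %r has no panel features; dropped", b.name)
                continue
            restricted.append(b.subset_features(list(feats)))
        blocks = restricted
    if not blocks:
        raise ValueError("no block retains any panel feature")
    single = None
    if model.startswith("single:"):
        single = model.split(":", 1)[1]
        blocks = [b for b in blocks if b.name == single]
        if not blocks:
            raise ValueError(f"single-block model: block {single!r} not found")

    per_split: dict[tuple[str, int], list[float]] = {
        (m, k): [] for m in ("accuracy", "auc", "mcc")
        for k in range(1, n_components + 1)
    }
    skipped = 0
    for train, test in plan:
        y_train, y_test = y[train], y[test]
        if len(np.unique(y_train)) < 2:
            skipped += 1
            logger.warning("skipping single-class train split in evaluation")
            continue
        scaled_train, scaled_test = [], []
        for b in blocks:
            st, stats_ = autoscale(b.subset_samples(train))
            sv, _ = autoscale(b.subset_samples(test), stats_)
            scaled_train.append(st)
            scaled_test.append(sv)
        if single is not None:
            res = PLSDA(
                scaled_train[0].values, y_train, n_components=n_components,
                keep_x=None if keep_x is None else keep_x.get(single),
                feature_ids=scaled_train[0].feature_ids,
            ).fit()
            predict = lambda k: res.predict(scaled_test[0].values, k=k)  # noqa: E731
        else:
            res = BlockPLSDA(
                scaled_train, y_train, n_components=n_components,
                keep_x=keep_x, design=design,
            ).fit()
            predict = lambda k: res.predict(scaled_test, k=k)  # noqa: E731
        for k in range(1, n_components + 1):
            labels, dv = predict(k)
            per_split[("accuracy", k)].append(accuracy(labels, y_test))
            per_split[("mcc", k)].append(mcc_from_labels(labels, y_test))
            if len(np.unique(y_test)) == 2:
                per_split[("auc", k)].append(roc_auc(dv, y_test))
    distributions = {
        key: MetricDistribution(metric=key[0], component=key[1],
                                values=np.asarray(vals), model=model)
        for key, vals in per_split.items()
    }
    return EvaluationResult(
        model=model,
        distributions=distributions,
        n_splits_used=plan.n_splits - skipped,
        n_splits_skipped=skipped,
        baseline=majority_baseline(y),
    )
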