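"""Per-omic preprocessing: M-values, count normalization, genotype QC, scaling.

The steps mirror the standard practice for the three omic layers feeding a
PLS model:

* DNA methylation beta values are mapped to M-values, ``M = log2(b/(1-b))``,
  the approximately homoscedastic analysis scale.
* RNA-seq counts are normalized with the median-of-ratios size-factor
  estimator (the DESeq2 estimator) after removing genes whose unnormalized
  median count across samples is below 1, then log2(x+1)-transformed.
* Genotype dosages pass missingness, Hardy-Weinberg and monomorphism
  filters; residual missing entries are mean-imputed.
* Every block is autoscaled (per-feature z-score) with train-set statistics
  before entering PLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import OmicsBlock, QCReport

__all__ = [
    "beta_to_m",
    "size_factors",
    "filter_low_expression",
    "normalize_and_log",
    "hwe_chisq",
    "qc_genotypes",
    "autoscale",
    "ScaleStats",
    "assemble_phenotype_block",
    "preprocess_expression",
]

logger = logging.getLogger(__name__)

PHENOTYPE_VARIABLES = ("sex", "age", "bmi", "stimulatory_index")


def beta_to_m(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Methylation beta -> M-value, ``M = log2(b'/(1-b'))``.

    Betas are clipped into ``[eps, 1-eps]`` first so boundary values do not
    produce infinities.

    Parameters
    ----------
    beta : array-like with entries in [0, 1]
    eps : float in (0, 0.5)
    """
    beta = np.asarray(beta, dtype=float)
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must lie in (0, 0.5), got {eps}")
    bad = np.argwhere((beta < 0) | (beta > 1) | np.isnan(beta))
    if bad.size:
        raise ValueError(
            f"beta values outside [0, 1] at coordinates {bad[:5].tolist()}"
        )
    clipped = np.clip(beta, eps, 1.0 - eps)
    return np.log2(clipped / (1.0 - clipped))


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample size factors for a genes x samples matrix.

    For each gene g with strictly positive counts in every sample, the ratio
    of each sample's count to the gene's geometric mean is formed; the size
    factor of sample j is the median of these ratios over such genes.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be genes x samples")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    all_positive = np.all(counts > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors undefined"
        )
    ref = counts[all_positive]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo_mean)
    return np.median(ratios, axis=0)


def filter_low_expression(
    counts: np.ndarray, feature_ids: list[str] | None = None, min_median: float = 1.0
) -> tuple[np.ndarray, np.ndarray, QCReport]:
    """Drop genes whose unnormalized median count across samples is < ``min_median``.

    Returns ``(filtered counts, boolean keep mask, QCReport)``; the mask is
    over the input genes.
    """
    counts = np.asarray(counts, dtype=float)
    medians = np.median(counts, axis=1)
    keep = medians >= min_median
    report = QCReport(
        block_name="expression",
        n_in=counts.shape[0],
        n_out=int(keep.sum()),
        removed={"low_expression": int((~keep).sum())},
        thresholds={"min_median_count": min_median},
    )
    report.validate()
    return counts[keep], keep, report


def normalize_and_log(counts: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """``log2(k_gj / s_j + 1)`` for a genes x samples count matrix."""
    counts = np.asarray(counts, dtype=float)
    factors = np.asarray(factors, dtype=float)
    if factors.shape[0] != counts.shape[1]:
        raise ValueError(
            f"{factors.shape[0]} size factors for {counts.shape[1]} samples"
        )
    if np.any(factors <= 0):
        raise ValueError("size factors must be strictly positive")
    return np.log2(counts / factors[None, :] + 1.0)


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg equilibrium.

    Genotype counts are (AA, Aa, aa).  The allele frequency is estimated as
    ``p = (2 n_AA + n_Aa) / 2n`` and observed counts are compared with the
    HWE-expected ``(p^2 n, 2p(1-p) n, (1-p)^2 n)``.

    Returns ``(chi2, p_value)``.  A variant with a single observed genotype
    class is degenerate here (expected counts of zero); callers should route
    such variants to the monomorphism filter instead.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2]) * n
    if np.any(expected == 0):
        raise ValueError(
            "degenerate genotype distribution (an expected class count is 0); "
            "monomorphic variants must be filtered before the HWE test"
        )
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_genotypes(
    block: OmicsBlock,
    miss_thresh: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> tuple[OmicsBlock, QCReport]:
    """Variant-level QC on a samples x variants dosage block.

    Drops, in order: variants with a missing fraction above ``miss_thresh``;
    monomorphic variants (a single observed dosage value); variants failing
    Hardy-Weinberg equilibrium at ``hwe_alpha``.  Remaining missing entries
    are imputed with the variant's mean observed dosage.  Mean-imputed
    (fractional) entries in [0, 2] are tolerated on input so the filter is
    idempotent; they are excluded from the genotype-class counts of the HWE
    test.
    """
    X = block.values
    observed_ok = np.isnan(X) | ((X >= 0) & (X <= 2))
    if not observed_ok.all():
        i, j = np.argwhere(~observed_ok)[0]
        raise ValueError(
            f"non-dosage entry {X[i, j]!r} at sample {block.sample_ids[i]!r}, "
            f"variant {block.feature_ids[j]!r}"
        )
    miss_frac = np.isnan(X).mean(axis=0)
    keep = miss_frac <= miss_thresh
    n_miss = int((~keep).sum())

    mono = np.zeros(X.shape[1], dtype=bool)
    hwe_fail = np.zeros(X.shape[1], dtype=bool)
    for j in np.flatnonzero(keep):
        col = X[:, j]
        col = col[~np.isnan(col)]
        values = np.unique(col)
        if values.size <= 1:
            mono[j] = True
            continue
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        if n_aa + n_ab + n_bb == 0 or len({v for v in values if v in (0.0, 1.0, 2.0)}) <= 1:
            # only imputed/fractional entries vary; integer dosages are
            # effectively monomorphic
            mono[j] = True
            continue
        _, p = hwe_chisq(n_aa, n_ab, n_bb)
        if p < hwe_alpha:
            hwe_fail[j] = True
    keep &= ~(mono | hwe_fail)

    out = X[:, keep].copy()
    col_means = np.nanmean(out, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(out))
    out[nan_rows, nan_cols] = col_means[nan_cols]

    report = QCReport(
        block_name=block.name,
        n_in=X.shape[1],
        n_out=int(keep.sum()),
        removed={
            "missingness": n_miss,
            "monomorphic": int(mono.sum()),
            "hwe": int(hwe_fail.sum()),
        },
        thresholds={"miss_thresh": miss_thresh, "hwe_alpha": hwe_alpha},
    )
    report.validate()
    filtered = OmicsBlock(
        out,
        block.sample_ids,
        [f for f, k in zip(block.feature_ids, keep) if k],
        block.name,
    )
    return filtered, report


@dataclass
class ScaleStats:
    """Train-set feature means/SDs used to autoscale train and test data."""

    mean: np.ndarray
    sd: np.ndarray
    feature_ids: list[str]
    dropped: list[str]


def autoscale(
    block: OmicsBlock, train_stats: ScaleStats | None = None
) -> tuple[OmicsBlock, ScaleStats]:
    """Per-feature z-scoring (autoscaling), the standard PLS preprocessing.

    Without ``train_stats``, means and SDs are estimated from ``block`` and
    features with zero SD are dropped (and recorded).  With ``train_stats``
    the stored statistics are applied — the test-set contract.
    """
    if train_stats is None:
        mean = block.values.mean(axis=0)
        sd = block.values.std(axis=0, ddof=1) if block.n_samples > 1 else np.zeros(
            block.n_features
        )
        keep = sd > 0
        dropped = [f for f, k in zip(block.feature_ids, keep) if not k]
        if dropped:
            logger.info(
                "autoscale: dropped %d zero-variance features from block %r",
                len(dropped), block.name,
            )
        stats_ = ScaleStats(
            mean=mean[keep],
            sd=sd[keep],
            feature_ids=[f for f, k in zip(block.feature_ids, keep) if k],
            dropped=dropped,
        )
        scaled = (block.values[:, keep] - stats_.mean) / stats_.sd
        return OmicsBlock(scaled, block.sample_ids, stats_.feature_ids, block.name), stats_
    sub = block.subset_features(train_stats.feature_ids)
    scaled = (sub.values - train_stats.mean) / train_stats.sd
    return OmicsBlock(scaled, block.sample_ids, train_stats.feature_ids, block.name), train_stats


def assemble_phenotype_block(table: pd.DataFrame) -> OmicsBlock:
    """Build the clinical phenotype block: sex, age, BMI, stimulatory index.

    HbA1c, if present, is discarded (it is essentially a restatement of the
    diabetes diagnosis and would leak the outcome).  Sex may be coded
    {0, 1} or as strings ``male``/``female`` (male=1).
    """
    cols = {c.lower(): c for c in table.columns}
    if "hba1c" in cols:
        logger.info("assemble_phenotype_block: dropping HbA1c (outcome-dependent)")
    missing = [v for v in PHENOTYPE_VARIABLES if v not in cols]
    if missing:
        raise ValueError(f"phenotype table lacks required column(s): {missing}")
    out = pd.DataFrame(index=table.index)
    sex = table[cols["sex"]]
    if sex.dtype == object:
        sex = sex.str.lower().map({"male": 1.0, "m": 1.0, "female": 0.0, "f": 0.0})
        if sex.isna().any():
            raise ValueError("unrecognized sex coding; expected male/female or 0/1")
    sex = sex.astype(float)
    if not set(np.unique(sex)).issubset({0.0, 1.0}):
        raise ValueError("sex must be coded {0, 1} (male=1)")
    out["sex"] = sex
    for v in ("age", "bmi", "stimulatory_index"):
        out[v] = table[cols[v]].astype(float)
    return OmicsBlock.from_frame(out, name="phenotype")


def preprocess_expression(
    counts: np.ndarray, gene_ids: list[str], sample_ids: list[str]
) -> tuple[OmicsBlock, QCReport]:
    """Full expression pipeline: low-count filter, size factors, log2(x+1).

    ``counts`` is genes x samples (the storage convention); the returned
    block is samples x features.
    """
    filtered, keep, report = filter_low_expression(counts, gene_ids)
    kept_ids = [g for g, k in zip(gene_ids, keep) if k]
    s = size_factors(filtered)
    log_norm = normalize_and_log(filtered, s)
    return OmicsBlock(log_norm.T, sample_ids, kept_ids, "expression"), report
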