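"""Synthetic multi-omics cohort with known ground truth.

Emulates the structure of a pancreatic-islet case/control study: 110
donors of whom ~29% are type-2-diabetes cases, with an RNA-seq count
block, a DNA-methylation beta block, a genotype dosage block and four
clinical phenotypes (sex, age, BMI, stimulatory index).  A small set of
planted class-discriminating features per block, recorded in
:class:`PlantedTruth`, makes recovery of the signal testable.

Generative choices (all seeded, all configurable):

* Expression: per-gene negative binomial counts with log-normal per-sample
  library factors; informative genes shift their log2 mean in cases by
  ``effect_size * sigma_log`` (``sigma_log`` approximates the per-gene
  log2-count noise SD).
* Methylation: per-CpG Beta draws parameterized by a target mean and a
  concentration; informative CpGs shift the case mean in logit space by
  ``effect_size``.
* Genotype: per-variant MAF uniform on ``maf_range``; Hardy-Weinberg
  genotypes in controls; informative variants shift the case allele
  frequency by ``effect_size * 0.1`` (clipped inside (0, 1)); a small
  fraction of entries is set missing.
* Phenotypes: class-conditional normal draws with means/SDs matching the
  cohort table of the emulated study; sex at the observed per-class ratios.

Block dimensions default to reduced-scale stand-ins (10^3, not 10^5) so
the full 100-split pipeline runs at desk scale; they scale up by config.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import OmicsBlock

__all__ = [
    "SyntheticConfig", "PlantedTruth", "SyntheticCohort",
    "simulate_cohort", "write_cohort", "read_cohort",
    "simulate_split_signal",
]

# phenotype mean/SD per class (cases, controls), study-cohort values
DEFAULT_PHENOTYPES = {
    "age": ((62.9, 7.7), (61.5, 8.0)),
    "bmi": ((27.8, 3.8), (26.0, 3.9)),
    "stimulatory_index": ((6.3, 5.2), (8.0, 7.0)),
}
SEX_MALE_FRACTION = {"case": 20 / 32, "control": 48 / 78}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator."""

    n_samples: int = 110
    case_fraction: float = 32 / 110
    n_genes: int = 2000
    n_cpgs: int = 3000
    n_snps: int = 1000
    n_informative: dict = field(
        default_factory=lambda: {"expression": 20, "methylation": 20, "genotype": 20}
    )
    effect_size: dict = field(
        default_factory=lambda: {"expression": 2.0, "methylation": 2.0, "genotype": 2.0}
    )
    library_size_range: tuple[float, float] = (0.7, 1.4)
    nb_dispersion: float = 0.2
    sigma_log: float = 0.7          # approximate per-gene log2-count noise SD
    beta_concentration: float = 50.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotype_missing_rate: float = 0.01
    phenotype_params: dict = field(default_factory=lambda: dict(DEFAULT_PHENOTYPES))
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or min(self.n_genes, self.n_cpgs, self.n_snps) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        sizes = {"expression": self.n_genes, "methylation": self.n_cpgs,
                 "genotype": self.n_snps}
        for name, k in self.n_informative.items():
            if not 0 <= k <= sizes[name]:
                raise ValueError(f"n_informative[{name}] must lie in [0, {sizes[name]}]")
        for name, e in self.effect_size.items():
            if not np.isfinite(e):
                raise ValueError(f"effect_size[{name}] must be finite")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.genotype_missing_rate < 1:
            raise ValueError("genotype_missing_rate must lie in [0, 1)")
        if self.nb_dispersion <= 0 or self.beta_concentration <= 0:
            raise ValueError("dispersion and concentration must be positive")
        g_shift = abs(self.effect_size.get("genotype", 0.0)) * 0.1
        if g_shift >= 1.0:
            raise ValueError(
                f"genotype effect shift {g_shift} would produce allele "
                "frequencies outside (0, 1)"
            )


@dataclass
class PlantedTruth:
    """Per block: informative feature IDs and their signed effect directions."""

    informative: dict[str, dict[str, int]]

    def ids(self, block: str) -> set[str]:
        return set(self.informative.get(block, {}))


@dataclass
class SyntheticCohort:
    labels: np.ndarray                    # 1 = case
    expression_counts: OmicsBlock         # samples x genes, raw NB counts
    methylation_beta: OmicsBlock          # samples x CpGs, in (0, 1)
    genotype_dosage: OmicsBlock           # samples x variants, {0,1,2}, NaN = missing
    phenotypes: pd.DataFrame              # sex, age, bmi, stimulatory_index
    truth: PlantedTruth
    config: SyntheticConfig

    @property
    def sample_ids(self) -> list[str]:
        return self.expression_counts.sample_ids


def _effect_directions(rng, ids, k):
    chosen = list(rng.choice(len(ids), size=k, replace=False))
    signs = rng.choice([-1, 1], size=k)
    return {ids[i]: int(s) for i, s in zip(sorted(chosen), signs)}


def simulate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw a fully seeded synthetic cohort from ``config``."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    n_cases = int(round(n * cfg.case_fraction))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_cases, replace=False)] = 1
    cases = labels == 1
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- expression -------------------------------------------------------
    gene_ids = [f"gene{j:05d}" for j in range(cfg.n_genes)]
    expr_truth = _effect_directions(rng, gene_ids, cfg.n_informative["expression"])
    log2_mu = rng.normal(5.0, 2.0, size=cfg.n_genes)
    lib = np.exp(rng.uniform(np.log(cfg.library_size_range[0]),
                             np.log(cfg.library_size_range[1]), size=n))
    log2_mu_matrix = np.tile(log2_mu, (n, 1))
    for fid, sign in expr_truth.items():
        j = gene_ids.index(fid)
        log2_mu_matrix[cases, j] += sign * cfg.effect_size["expression"] * cfg.sigma_log
    mu = (2.0 ** log2_mu_matrix) * lib[:, None]
    # NB with mean mu and dispersion d: var = mu + d mu^2
    r = 1.0 / cfg.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p).astype(float)
    expression = OmicsBlock(counts, sample_ids, gene_ids, "expression")

    # --- methylation ------------------------------------------------------
    cpg_ids = [f"cg{j:05d}" for j in range(cfg.n_cpgs)]
    meth_truth = _effect_directions(rng, cpg_ids, cfg.n_informative["methylation"])
    base_mean = rng.uniform(0.1, 0.9, size=cfg.n_cpgs)
    logit = np.log(base_mean / (1 - base_mean))
    logit_matrix = np.tile(logit, (n, 1))
    for fid, sign in meth_truth.items():
        j = cpg_ids.index(fid)
        logit_matrix[cases, j] += sign * cfg.effect_size["methylation"]
    mean = 1.0 / (1.0 + np.exp(-logit_matrix))
    c = cfg.beta_concentration
    beta = rng.beta(mean * c, (1.0 - mean) * c)
    beta = np.clip(beta, 1e-12, 1 - 1e-12)
    methylation = OmicsBlock(beta, sample_ids, cpg_ids, "methylation")

    # --- genotype ---------------------------------------------------------
    snp_ids = [f"rs{j:05d}" for j in range(cfg.n_snps)]
    geno_truth = _effect_directions(rng, snp_ids, cfg.n_informative["genotype"])
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    freq = np.tile(maf, (n, 1))
    for fid, sign in geno_truth.items():
        j = snp_ids.index(fid)
        shifted = maf[j] + sign * cfg.effect_size["genotype"] * 0.1
        freq[cases, j] = np.clip(shifted, 1e-3, 1 - 1e-3)
    dosage = rng.binomial(2, freq).astype(float)
    if cfg.genotype_missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.genotype_missing_rate
        dosage[miss] = np.nan
    genotype = OmicsBlock(dosage, sample_ids, snp_ids, "genotype")

    # --- phenotypes -------------------------------------------------------
    pheno = pd.DataFrame(index=sample_ids)
    sex = np.where(
        cases,
        rng.random(n) < SEX_MALE_FRACTION["case"],
        rng.random(n) < SEX_MALE_FRACTION["control"],
    )
    pheno["sex"] = sex.astype(float)
    for var, ((m_case, sd_case), (m_ctrl, sd_ctrl)) in cfg.phenotype_params.items():
        draws = np.where(
            cases,
            rng.normal(m_case, sd_case, size=n),
            rng.normal(m_ctrl, sd_ctrl, size=n),
        )
        pheno[var] = draws

    truth = PlantedTruth(informative={
        "expression": expr_truth, "methylation": meth_truth, "genotype": geno_truth,
    })
    return SyntheticCohort(
        labels=labels, expression_counts=expression, methylation_beta=methylation,
        genotype_dosage=genotype, phenotypes=pheno, truth=truth, config=cfg,
    )


def simulate_split_signal(
    n_samples: int = 110,
    case_fraction: float = 32 / 110,
    n_features: int = 200,
    n_informative: int = 20,
    latent_sd: float = 1.0,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> tuple[list[OmicsBlock], np.ndarray]:
    """Two Gaussian blocks whose class signal lives in their *sum*.

    Two latent axes ``z1, z2`` are drawn per sample and the class shifts
    ``z1 + z2`` only: each block's informative features load on one axis, so
    either block alone sees just half the class separation while the
    integrated model sees all of it — the canonical construction for why
    multi-omics integration can beat any single omic.
    """
    rng = np.random.default_rng(seed)
    n_cases = int(round(n_samples * case_fraction))
    y = np.zeros(n_samples, dtype=int)
    y[rng.choice(n_samples, size=n_cases, replace=False)] = 1
    shift = y.astype(float)  # cases shifted by +1 on each latent axis
    z1 = rng.normal(0.0, latent_sd, n_samples) + shift
    z2 = rng.normal(0.0, latent_sd, n_samples) + shift
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    blocks = []
    for b, z in (("omicA", z1), ("omicB", z2)):
        X = rng.normal(0.0, noise_sd, size=(n_samples, n_features))
        X[:, :n_informative] += z[:, None]
        blocks.append(OmicsBlock(
            X, sample_ids, [f"{b}_f{j:04d}" for j in range(n_features)], b,
        ))
    return blocks, y


# ---------------------------------------------------------------------------
# persistence to disk

def write_cohort(cohort: SyntheticCohort, directory: str,
                 write_vcf: bool = True) -> dict[str, str]:
    """Write the cohort as delimited text (features as rows) plus manifests.

    Emits per block one TSV (first column = feature ID, header = sample
    IDs), a phenotype table, a two-column label file (sample_id, status),
    the planted-truth manifest as JSON, and optionally the genotype block
    as a minimal VCFv4.2.  Returns the path map.
    """
    if not directory:
        raise ValueError("output directory must be a non-empty path")
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    def _write(block: OmicsBlock, fname: str) -> None:
        path = os.path.join(directory, fname)
        block.to_frame().T.rename_axis("feature_id").to_csv(
            path, sep="\t", float_format="%.17g"
        )
        paths[block.name] = path

    _write(cohort.expression_counts, "expression_counts.tsv")
    _write(cohort.methylation_beta, "methylation_beta.tsv")
    _write(cohort.genotype_dosage, "genotype_dosage.tsv")

    pheno_path = os.path.join(directory, "phenotypes.tsv")
    cohort.phenotypes.rename_axis("sample_id").to_csv(pheno_path, sep="\t",
                                                      float_format="%.17g")
    paths["phenotypes"] = pheno_path

    labels_path = os.path.join(directory, "labels.tsv")
    pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "status": np.where(cohort.labels == 1, "case", "control"),
    }).to_csv(labels_path, sep="\t", index=False)
    paths["labels"] = labels_path

    truth_path = os.path.join(directory, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(cohort.truth.informative, fh, indent=1)
    paths["truth"] = truth_path

    if write_vcf:
        vcf_path = os.path.join(directory, "genotypes.vcf")
        _write_vcf(cohort.genotype_dosage, vcf_path)
        paths["vcf"] = vcf_path
    return paths


def _write_vcf(block: OmicsBlock, path: str) -> None:
    """Minimal VCFv4.2 with GT-only genotypes; dosage = ALT allele count."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(block.sample_ids) + "\n")
        for j, vid in enumerate(block.feature_ids):
            gts = [
                "./." if np.isnan(v) else gt_map[float(v)]
                for v in block.values[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_cohort(directory: str) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort` (exact round trip)."""
    def _read(fname: str, name: str) -> OmicsBlock:
        frame = pd.read_csv(os.path.join(directory, fname), sep="\t",
                            index_col=0, float_precision="round_trip")
        return OmicsBlock.from_frame(frame.T, name=name)

    expression = _read("expression_counts.tsv", "expression")
    methylation = _read("methylation_beta.tsv", "methylation")
    genotype = _read("genotype_dosage.tsv", "genotype")
    pheno = pd.read_csv(os.path.join(directory, "phenotypes.tsv"), sep="\t",
                        index_col=0)
    labels_df = pd.read_csv(os.path.join(directory, "labels.tsv"), sep="\t")
    labels = (labels_df["status"] == "case").to_numpy().astype(int)
    with open(os.path.join(directory, "truth.json")) as fh:
        informative = json.load(fh)
    truth = PlantedTruth(informative={
        b: {f: int(s) for f, s in d.items()} for b, d in informative.items()
    })
    return SyntheticCohort(
        labels=labels, expression_counts=expression, methylation_beta=methylation,
        genotype_dosage=genotype, phenotypes=pheno, truth=truth,
        config=SyntheticConfig(),
    )
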