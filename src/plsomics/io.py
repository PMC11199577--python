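"""Delimited-matrix and VCF readers/writers.

Matrices are stored features-as-rows (the omics convention: first column =
feature ID, header = sample IDs); in memory everything is samples x
features, so the reader transposes.  Delimiter is inferred from the
extension (``.tsv``/``.txt`` tab, ``.csv`` comma).
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .blocks import OmicsBlock

__all__ = ["read_matrix", "write_matrix", "read_vcf_dosage", "read_labels"]

logger = logging.getLogger(__name__)


def _sep_for(path: str) -> str:
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_matrix(path: str, name: str | None = None) -> OmicsBlock:
    """Read a features x samples delimited matrix into an OmicsBlock.

    Rejects ragged rows, duplicate IDs and non-numeric cells with the
    offending line/ID in the message.
    """
    sep = _sep_for(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, header=0,
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed matrix ({exc})") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature ID {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r} "
                f"(line {int(np.flatnonzero(bad)[0]) + 2})"
            )
        frame[col] = coerced
    block_name = name or os.path.splitext(os.path.basename(path))[0]
    return OmicsBlock.from_frame(frame.T.astype(float), name=block_name)


def write_matrix(block: OmicsBlock, path: str) -> None:
    """Write an OmicsBlock as a features x samples matrix at full precision."""
    sep = _sep_for(path)
    block.to_frame().T.rename_axis("feature_id").to_csv(
        path, sep=sep, float_format="%.17g"
    )


def read_labels(path: str) -> tuple[list[str], np.ndarray]:
    """Read a two-column (sample_id, status in {case, control}) table."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    if not {"sample_id", "status"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns sample_id, status")
    bad = ~frame["status"].isin(["case", "control"])
    if bad.any():
        raise ValueError(f"{path}: unrecognized status {frame['status'][bad].iloc[0]!r}")
    return (
        [str(s) for s in frame["sample_id"]],
        (frame["status"] == "case").to_numpy().astype(int),
    )


def read_vcf_dosage(path: str, name: str = "genotype") -> OmicsBlock:
    """Parse a VCFv4.2 into an ALT-allele-count dosage block.

    Only biallelic records are used; multiallelic records are skipped with a
    warning count.  ``./.`` becomes NaN.  Variant ID is the ID field, or
    ``CHROM:POS:REF:ALT`` when missing.  Uses cyvcf2 when available, a
    minimal GT-only text parser otherwise.
    """
    try:
        import cyvcf2
    except ImportError:
        return _read_vcf_text(path, name)
    vcf = cyvcf2.VCF(path)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path}: VCF has no sample columns")
    variant_ids, rows = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        dosages = []
        for g in v.genotypes:
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                dosages.append(np.nan)
            else:
                dosages.append(float(sum(a == 1 for a in alleles)))
        variant_ids.append(vid)
        rows.append(dosages)
    vcf.close()
    if n_multi:
        logger.warning("%s: skipped %d multiallelic record(s)", path, n_multi)
    values = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return OmicsBlock(values, sample_ids, variant_ids, name)


def _read_vcf_text(path: str, name: str = "genotype") -> OmicsBlock:
    """Fallback GT-only VCF parser (biallelic records)."""
    sample_ids: list[str] | None = None
    variant_ids: list[str] = []
    rows: list[list[float]] = []
    n_multi = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}: VCF has no sample columns")
                sample_ids = fields[9:]
                continue
            if sample_ids is None:
                raise ValueError(f"{path}: data line before #CHROM header")
            fields = line.split("\t")
            chrom, pos, vid, ref, alt = fields[0:5]
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"{path}: line {line_no}: no GT field")
            if "," in alt:
                n_multi += 1
                continue
            gt_idx = fmt.index("GT")
            if vid in (".", ""):
                vid = f"{chrom}:{pos}:{ref}:{alt}"
            dosages = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(a == "1" for a in alleles)))
            variant_ids.append(vid)
            rows.append(dosages)
    if sample_ids is None:
        raise ValueError(f"{path}: no #CHROM header found")
    if n_multi:
        logger.warning("%s: skipped %d multiallelic record(s)", path, n_multi)
    values = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return OmicsBlock(values, sample_ids, variant_ids, name)
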