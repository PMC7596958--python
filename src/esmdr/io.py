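"""Readers and writers: PLINK bed/bim/fam, tabular genotypes, phenotypes.

The PLINK binary format is the de-facto genotype medium for GWAS-scale
data; the 2-bit variant-major coding is simple enough that the reader and
writer live here directly.  Dosages count the A1 allele (conventionally the
minor allele): bit-pair 00 -> 2 copies, 10 -> 1, 11 -> 0, 01 -> missing.

Phenotypes arrive as delimited text with named columns.  Age-of-onset
coding: cases contribute an event at diagnosis age, controls are censored
at interview age.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .survival import SurvivalData

__all__ = [
    "read_plink",
    "write_plink",
    "read_geno_table",
    "write_geno_table",
    "PhenoSpec",
    "read_pheno",
    "run_log",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1.9, variant-major
# bit-pair -> A1 dosage; 1 marks the missing code 0b01
_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam triple into a :class:`GenotypeMatrix`.

    Subject order follows the fam file; SNP ids come from the bim file.
    """
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None,
                         names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    n, m = len(fam_df), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{bed}: not a variant-major PLINK bed file (bad magic bytes)")
    stride = (n + 3) // 4
    body = raw[3:]
    if body.size != stride * m:
        raise ValueError(
            f"{bed}: size mismatch (expected {stride * m} data bytes for "
            f"{n} subjects x {m} SNPs, found {body.size})"
        )
    blocks = body.reshape(m, stride)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, stride * 4)[:, :n]
    geno = _DECODE[codes].T  # subjects x SNPs
    return GenotypeMatrix(geno, snp_ids=list(bim_df["snp"].astype(str)), orient_minor=False)


def write_plink(
    geno: GenotypeMatrix,
    prefix: str | Path,
    chrom: int = 1,
    positions: np.ndarray | None = None,
) -> None:
    """Write bed/bim/fam; alleles are labeled A (minor, counted) / B."""
    prefix = Path(prefix)
    n, m = geno.n, geno.m
    if positions is None:
        positions = np.arange(1, m + 1)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n):
            fh.write(f"F{i} I{i} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, (sid, pos) in enumerate(zip(geno.snp_ids, positions)):
            fh.write(f"{chrom}\t{sid}\t0\t{int(pos)}\tA\tB\n")
    stride = (n + 3) // 4
    out = np.zeros((m, stride), dtype=np.uint8)
    codes = np.empty((m, n), dtype=np.uint8)
    g = geno.geno.T
    for value, code in _ENCODE.items():
        codes[g == value] = code
    for shift_idx, shift in enumerate((0, 2, 4, 6)):
        cols = codes[:, shift_idx::4]
        out[:, : cols.shape[1]] |= cols << shift
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def write_geno_table(geno: GenotypeMatrix, path: str | Path) -> None:
    """Plain TSV (subjects x SNPs, header = SNP ids, missing = NA)."""
    df = pd.DataFrame(geno.geno, columns=geno.snp_ids).replace(MISSING, pd.NA)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_geno_table(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    geno = df.fillna(MISSING).to_numpy(dtype=np.int8)
    return GenotypeMatrix(geno, snp_ids=list(df.columns), orient_minor=False)


@dataclass
class PhenoSpec:
    """Column mapping for phenotype files.

    Either ``time``/``status`` columns, or case-control + age coding via
    ``case`` (1 = case, event at ``age``) and ``age``.
    """

    time: str | None = "time"
    status: str | None = "status"
    case: str | None = None
    age: str | None = None
    covariates: list[str] = field(default_factory=list)


def read_pheno(path: str | Path, spec: PhenoSpec | None = None):
    """Read a phenotype table into :class:`SurvivalData`.

    Rows with missing required fields (including covariates) are dropped
    and reported in the returned log dict.
    """
    spec = spec or PhenoSpec()
    df = pd.read_csv(path, sep=None, engine="python")
    n_raw = len(df)
    if spec.case is not None:
        if spec.age is None:
            raise ValueError("case/control coding requires an age column")
        needed = [spec.case, spec.age] + spec.covariates
    else:
        needed = [spec.time, spec.status] + spec.covariates
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"missing phenotype column {col!r}")
    df = df.dropna(subset=needed)
    if spec.case is not None:
        time = df[spec.age].to_numpy(dtype=float)
        status = df[spec.case].to_numpy(dtype=int)
    else:
        time = df[spec.time].to_numpy(dtype=float)
        status = df[spec.status].to_numpy(dtype=int)
    bad = time < 0
    if bad.any():
        df, time, status = df[~bad], time[~bad], status[~bad]
    cov = df[spec.covariates].to_numpy(dtype=float) if spec.covariates else None
    data = SurvivalData(time, status, cov)
    log = {"rows_read": n_raw, "rows_kept": int(len(time)),
           "rows_dropped": int(n_raw - len(time))}
    return data, log


def run_log(cfg: dict, results: dict, path: str | Path | None = None) -> dict:
    """Assemble (and optionally write) a structured run log: every seed,
    parameter and filter count that determines the outputs."""
    import esmdr

    entry = {
        "package_version": getattr(esmdr, "__version__", "unknown"),
        "config": cfg,
        "results": results,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(entry, fh, indent=2, default=_json_default)
    return entry


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
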