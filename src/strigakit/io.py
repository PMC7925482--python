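"""Readers and writers for genotype and phenotype interchange formats.

Genotypes travel as VCF (diploid unphased GT; dosage of the ALT allele),
HapMap-like TSV (two-letter or IUPAC genotype codes) or a plain lines x
markers CSV dosage matrix whose column names encode the map
(``S<chrom>_<pos>``).  Phenotypes are long-format CSV with columns
line,env,rep,block,trait,value.  All round trips preserve codes, the
missing mask, the marker map and line ids.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, GRM, PHENO_COLUMNS, validate_phenotypes

__all__ = [
    "write_vcf", "read_vcf", "write_hapmap", "read_hapmap",
    "write_csv_matrix", "read_csv_matrix",
    "write_phenotypes", "read_phenotypes",
    "write_grm", "read_grm",
]

_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}


def _marker_alleles(geno: GenotypeMatrix) -> np.ndarray:
    if geno.alleles is not None:
        return np.asarray(geno.alleles)
    return np.tile(np.array([["A", "C"]]), (geno.n_markers, 1))


# ---------------------------------------------------------------------------
# VCF

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    if geno.imputed:
        raise ValueError("cannot write fractional (imputed) dosages to VCF")
    alleles = _marker_alleles(geno)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strigakit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.line_ids) + "\n")
        vals = geno.values.astype(int)
        for k in range(geno.n_markers):
            gts = [
                "./." if geno.missing[i, k] else _GT_CODE[int(vals[i, k])]
                for i in range(geno.n_lines)
            ]
            fh.write(
                f"{geno.chrom[k]}\t{geno.pos[k]}\tS{geno.chrom[k]}_{geno.pos[k]}\t"
                f"{alleles[k, 0]}\t{alleles[k, 1]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF through cyvcf2; biallelic SNPs only (others dropped with a
    warning).  GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    line_ids = list(vcf.samples)
    rows, chroms, poss, alleles = [], [], [], []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        rows.append(np.asarray(v.gt_types).copy())
        chroms.append(v.CHROM)
        poss.append(v.POS)
        alleles.append((v.REF, v.ALT[0]))
    vcf.close()
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-biallelic-SNP records", stacklevel=2)
    if not rows:
        raise ValueError("no usable biallelic SNP records in the VCF")
    gt = np.column_stack(rows)  # lines x markers, 3 = unknown
    missing = gt == 3
    values = np.where(missing, 0, gt).astype(np.int8)
    chrom = np.array([int(c) if str(c).isdigit() else str(c) for c in chroms])
    return GenotypeMatrix(
        values=values, missing=missing, line_ids=line_ids,
        chrom=chrom, pos=np.array(poss, dtype=np.int64),
        alleles=np.array(alleles),
    )


# ---------------------------------------------------------------------------
# HapMap-like TSV

_HAPMAP_META = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


def write_hapmap(geno: GenotypeMatrix, path) -> None:
    if geno.imputed:
        raise ValueError("cannot write fractional (imputed) dosages to HapMap")
    alleles = _marker_alleles(geno)
    vals = geno.values.astype(int)
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + geno.line_ids) + "\n")
        for k in range(geno.n_markers):
            ref, alt = alleles[k]
            codes = {0: ref + ref, 1: ref + alt, 2: alt + alt}
            cells = [
                "NN" if geno.missing[i, k] else codes[int(vals[i, k])]
                for i in range(geno.n_lines)
            ]
            fh.write("\t".join(
                [f"S{geno.chrom[k]}_{geno.pos[k]}", f"{ref}/{alt}", str(geno.chrom[k]),
                 str(geno.pos[k]), "+", "NA", "NA", "NA", "NA", "NA", "NA"] + cells
            ) + "\n")


def read_hapmap(path) -> GenotypeMatrix:
    """Read HapMap-like TSV.  Cells may be two-letter diploid codes
    ("AA", "AC", ...) or single-letter IUPAC codes (het codes R/Y/S/W/K/M
    map to dosage 1); N or NN is missing."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    line_ids = list(df.columns[len(_HAPMAP_META):])
    values = np.zeros((len(line_ids), len(df)), dtype=np.int8)
    missing = np.zeros_like(values, dtype=bool)
    alleles = []
    for k, row in enumerate(df.itertuples(index=False)):
        ref, alt = str(row[1]).split("/")[:2]
        alleles.append((ref, alt))
        for i, cell in enumerate(row[len(_HAPMAP_META):]):
            c = str(cell).upper()
            if c in ("N", "NN", "NAN", ""):
                missing[i, k] = True
            elif len(c) == 1:
                if c == ref:
                    values[i, k] = 0
                elif c == alt:
                    values[i, k] = 2
                elif c in _IUPAC_HET:
                    values[i, k] = 1
                else:
                    missing[i, k] = True
            else:
                values[i, k] = sum(1 for a in c[:2] if a == alt)
                if not set(c[:2]) <= {ref, alt}:
                    missing[i, k] = True
    chrom = np.array([int(c) if str(c).isdigit() else str(c) for c in df["chrom"]])
    return GenotypeMatrix(
        values=values, missing=missing, line_ids=line_ids,
        chrom=chrom, pos=df["pos"].astype(np.int64).to_numpy(),
        alleles=np.array(alleles),
    )


# ---------------------------------------------------------------------------
# CSV dosage matrix

def write_csv_matrix(geno: GenotypeMatrix, path) -> None:
    d = pd.DataFrame(geno.dosages(), index=pd.Index(geno.line_ids, name="line"),
                     columns=geno.marker_names)
    d.to_csv(path)


def read_csv_matrix(path) -> GenotypeMatrix:
    """Lines x markers CSV with a ``line`` index column and marker columns
    named ``S<chrom>_<pos>``."""
    df = pd.read_csv(path, index_col=0)
    chrom, pos = [], []
    for name in df.columns:
        if not name.startswith("S") or "_" not in name:
            raise ValueError(f"marker column {name!r} is not of the form S<chrom>_<pos>")
        c, p = name[1:].split("_", 1)
        chrom.append(int(c) if c.isdigit() else c)
        pos.append(int(p))
    vals = df.to_numpy(float)
    missing = np.isnan(vals)
    imputed = bool((~missing & (vals != np.round(vals))).any())
    return GenotypeMatrix(
        values=np.where(missing, 0, vals), missing=missing,
        line_ids=[str(i) for i in df.index],
        chrom=np.array(chrom), pos=np.array(pos, dtype=np.int64), imputed=imputed,
    )


# ---------------------------------------------------------------------------
# phenotypes and matrices

def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    validate_phenotypes(pheno)[PHENO_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(Path(path), dtype={"line": str, "env": str,
                                                              "rep": str, "block": str}))


def write_grm(grm: GRM, path) -> None:
    pd.DataFrame(grm.matrix, index=pd.Index(grm.line_ids, name="line"),
                 columns=grm.line_ids).to_csv(path, sep="\t")


def read_grm(path) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    m = df.to_numpy(float)
    m = (m + m.T) / 2.0  # symmetrize away round-trip rounding
    return GRM(matrix=m, denominator=np.nan, allele_freqs=np.array([]),
               line_ids=[str(i) for i in df.index])
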