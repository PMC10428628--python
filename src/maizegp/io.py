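"""Readers and writers for the pipeline's on-disk formats.

Genotypes: VCF (biallelic SNPs, GT field; homozygous 0/0 and 1/1 for inbred
panels, ./. for missing) via pysam, or a dosage TSV (lines x markers) with a
companion marker-map TSV.  Phenotypes: long-format CSV with header
``line,environment,replicate,block,trait,value``.  Kinship: square TSV with
line ids as header row and index column.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .panel import GenotypePanel, KinshipMatrix, validate_phenotypes

_GT = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as an uncompressed VCF with GT calls (REF=A, ALT=G)."""
    header = pysam.VariantHeader()
    header.add_meta("source", "maizegp")
    for chrom in pd.unique(panel.chromosome):
        idx = panel.chromosome == chrom
        header.contigs.add(str(chrom), length=int(panel.position_bp[idx].max()) + 1)
    header.formats.add("GT", 1, "String", "Genotype")
    for line in panel.line_ids:
        header.add_sample(line)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j, marker in enumerate(panel.marker_ids):
            rec = vcf.new_record(
                contig=str(panel.chromosome[j]),
                start=int(panel.position_bp[j]) - 1,
                stop=int(panel.position_bp[j]),
                alleles=("A", "G"),
                id=marker,
            )
            for i, line in enumerate(panel.line_ids):
                d = panel.dosage[i, j]
                rec.samples[line]["GT"] = (None, None) if np.isnan(d) else _GT[d]
            vcf.write(rec)


def read_vcf(path: str) -> GenotypePanel:
    """Read a biallelic-SNP VCF into a panel (GT parsed to alt-allele dosage)."""
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        chroms, positions, ids, rows = [], [], [], []
        for k, rec in enumerate(vcf):
            if rec.alts is None or len(rec.alts) != 1:
                continue
            chroms.append(rec.chrom)
            positions.append(rec.pos)  # pysam .pos is 1-based
            ids.append(rec.id or f"{rec.chrom}_{rec.pos}")
            row = np.empty(len(samples))
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row[i] = np.nan
                else:
                    row[i] = float(sum(gt))
            rows.append(row)
    return GenotypePanel(
        line_ids=samples,
        marker_ids=ids,
        chromosome=np.asarray(chroms, dtype=object),
        position_bp=np.asarray(positions, dtype=np.int64),
        dosage=np.column_stack(rows) if rows else np.empty((len(samples), 0)),
    )


def write_dosage_tsv(panel: GenotypePanel, dosage_path: str, map_path: str | None = None) -> None:
    df = pd.DataFrame(panel.dosage, index=panel.line_ids, columns=panel.marker_ids)
    df.index.name = "line"
    df.to_csv(dosage_path, sep="\t", na_rep="NA")
    if map_path is not None:
        pd.DataFrame(
            {
                "marker": panel.marker_ids,
                "chromosome": panel.chromosome,
                "position_bp": panel.position_bp,
            }
        ).to_csv(map_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path: str, map_path: str | None = None) -> GenotypePanel:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=["NA"])
    markers = [str(c) for c in df.columns]
    if map_path is not None and os.path.exists(map_path):
        mp = pd.read_csv(map_path, sep="\t").set_index("marker").loc[markers]
        chrom = mp["chromosome"].to_numpy(dtype=object)
        pos = mp["position_bp"].to_numpy(dtype=np.int64)
    else:
        chrom = np.asarray(["chr1"] * len(markers), dtype=object)
        pos = np.arange(1, len(markers) + 1, dtype=np.int64)
    return GenotypePanel(
        line_ids=[str(i) for i in df.index],
        marker_ids=markers,
        chromosome=chrom,
        position_bp=pos,
        dosage=df.to_numpy(dtype=float),
    )


def write_phenotypes_csv(records: pd.DataFrame, path: str) -> None:
    validate_phenotypes(records).to_csv(path, index=False)


def read_phenotypes_csv(path: str) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_kinship_tsv(kinship: KinshipMatrix, path: str) -> None:
    df = pd.DataFrame(kinship.values, index=kinship.line_ids, columns=kinship.line_ids)
    df.index.name = kinship.method
    df.to_csv(path, sep="\t")


def read_kinship_tsv(path: str) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    method = df.index.name if df.index.name in ("IBS", "VanRaden") else "IBS"
    return KinshipMatrix(
        line_ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float), method=method
    )
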