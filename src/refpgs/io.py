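"""Readers and writers for the package's text formats.

Genotypes travel as VCF (DS or GT FORMAT field) or a plain dosage TSV
(samples x variants, header row of variant IDs, optional variant-metadata
sidecar); summary statistics as a GWAS-SSF-like TSV; PGS weights as
PGS-Catalog-style scoring files (header comments, rsID / effect_allele /
effect_weight columns); cohorts as TSV with fixed column names.  All
dialects are UTF-8, tab-separated, '.' for missing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SUMSTATS_COLUMNS, WEIGHT_COLUMNS, GenotypePanel, validate_sumstats

__all__ = [
    "write_vcf",
    "read_genotypes",
    "write_dosage_tsv",
    "read_sumstats",
    "write_sumstats",
    "read_weights",
    "write_weights",
    "read_cohort",
    "write_cohort",
    "write_loco_weights",
    "read_loco_weights",
]

log = logging.getLogger(__name__)

_MISSING = "."


def write_vcf(panel: GenotypePanel, path, field: str = "DS") -> None:
    """Write the panel as an uncompressed VCF with a DS (dosage) or GT field.

    GT requires integer dosages (the generator's binomial scheme produces
    them); DS writes the dosage as-is.
    """
    if field not in ("DS", "GT"):
        raise ValueError("field must be 'DS' or 'GT'")
    var = panel.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if field == "DS":
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        else:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(var["chromosome"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, panel.sample_ids))
            + "\n"
        )
        D = panel.dosages
        for j in range(panel.n_snps):
            row = var.iloc[j]
            # effect allele written as ALT; dosage counts ALT copies
            fields = [
                str(row["chromosome"]),
                str(row["position"]),
                str(row["variant_id"]),
                str(row["other_allele"]),
                str(row["effect_allele"]),
                ".",
                "PASS",
                f"AF={row['allele_frequency']:.6g}",
                field,
            ]
            if field == "DS":
                fields += [f"{d:.4g}" for d in D[:, j]]
            else:
                conv = {0: "0/0", 1: "0/1", 2: "1/1"}
                col = np.rint(D[:, j]).astype(int)
                if not np.allclose(D[:, j], col, atol=1e-6):
                    raise ValueError("GT output requires integer dosages; use field='DS'")
                fields += [conv[int(d)] for d in col]
            fh.write("\t".join(fields) + "\n")


def _read_vcf(path) -> GenotypePanel:
    """Read a (plain-text) VCF through cyvcf2; DS used when present, else GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    dosage_rows = []
    for v in vcf:
        ds = None
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = np.asarray(ds, float).reshape(-1)
        else:
            gts = v.genotypes
            vals = np.empty(len(gts))
            for i, gt in enumerate(gts):
                alleles = gt[:-1]  # last entry is the phasing flag
                if len(alleles) != 2:
                    raise ValueError(f"mixed ploidy rejected at {v.ID or v.POS}")
                vals[i] = np.nan if -1 in alleles else float(sum(alleles))
        dosage_rows.append(vals)
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record rejected at {v.ID or v.POS}")
        records.append(
            {
                "variant_id": v.ID or f"{v.CHROM}:{v.POS}",
                "chromosome": int(v.CHROM),
                "position": int(v.POS),
                "effect_allele": v.ALT[0],
                "other_allele": v.REF,
                "allele_frequency": float(np.nanmean(vals) / 2.0) if len(vals) else np.nan,
            }
        )
    variants = pd.DataFrame.from_records(records)
    dosages = (
        np.array(dosage_rows, dtype=np.float32).T if dosage_rows else np.empty((len(samples), 0))
    )
    order = np.lexsort((variants["position"].to_numpy(), variants["chromosome"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]
    return GenotypePanel(sample_ids=np.array(samples), variants=variants, dosages=dosages)


def write_dosage_tsv(panel: GenotypePanel, path, variants_path=None) -> None:
    """Samples x variants dosage TSV; variant metadata to an optional sidecar."""
    df = pd.DataFrame(
        panel.dosages, index=pd.Index(panel.sample_ids, name="sample_id"),
        columns=panel.variants["variant_id"],
    )
    df.to_csv(path, sep="\t", na_rep=_MISSING)
    if variants_path is not None:
        panel.variants.to_csv(variants_path, sep="\t", index=False, na_rep=_MISSING)


def read_genotypes(path, format: str = "vcf", variants_path=None) -> GenotypePanel:
    """Read a genotype panel from VCF or dosage TSV.

    For dosage TSV without a metadata sidecar, variants are placed on
    chromosome 1 at consecutive positions with A/G alleles and frequencies
    from the dosage means.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format != "dosage-tsv":
        raise ValueError(f"unknown genotype format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_MISSING)
    if variants_path is not None:
        variants = pd.read_csv(variants_path, sep="\t", na_values=_MISSING)
    else:
        variants = pd.DataFrame(
            {
                "variant_id": df.columns,
                "chromosome": 1,
                "position": np.arange(1, df.shape[1] + 1) * 1000,
                "effect_allele": "A",
                "other_allele": "G",
                "allele_frequency": df.mean(axis=0).to_numpy() / 2.0,
            }
        )
    order = np.lexsort((variants["position"].to_numpy(), variants["chromosome"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = df.to_numpy(dtype=np.float32)[:, order]
    return GenotypePanel(sample_ids=df.index.to_numpy(str), variants=variants, dosages=dosages)


def _read_tsv(path, mandatory: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=_MISSING)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    extra = [c for c in df.columns if c not in mandatory]
    if extra:
        log.info("%s: preserving extra columns %s", path, extra)
    return df


def read_sumstats(path, validate: bool = True) -> pd.DataFrame:
    ss = _read_tsv(path, SUMSTATS_COLUMNS)
    if validate:
        validate_sumstats(ss)
    return ss


def write_sumstats(ss: pd.DataFrame, path) -> None:
    ss.to_csv(path, sep="\t", index=False, na_rep=_MISSING)


_PGS_COLMAP = {"rsID": "variant_id", "chr_name": "chromosome"}


def write_weights(weights: pd.DataFrame, path) -> None:
    """PGS-Catalog-style scoring file: '#' header comments + data columns."""
    with open(path, "w") as fh:
        fh.write("### PGS scoring file\n")
        for k, v in weights.attrs.items():
            fh.write(f"#{k}={v}\n")
        out = weights.rename(columns={v: k for k, v in _PGS_COLMAP.items()})
        out.to_csv(fh, sep="\t", index=False, na_rep=_MISSING)


def read_weights(path) -> pd.DataFrame:
    meta = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line and not line.startswith("###"):
                k, v = line[1:].rstrip("\n").split("=", 1)
                meta[k] = v
            pos += len(line)
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=_MISSING)
    df = df.rename(columns=_PGS_COLMAP)
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    df.attrs.update(meta)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep=_MISSING)


def read_cohort(path) -> pd.DataFrame:
    return _read_tsv(path, ["sample_id", "avSER"])


def write_loco_weights(loco, outdir) -> None:
    """Serialize a LocoWeightSet as 22 scoring files plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for k, wv in loco.entries.items():
        name = f"loco_excl_chr{k}.txt"
        wv.attrs["excluded_chromosome"] = k
        write_weights(wv, outdir / name)
        manifest[str(k)] = name
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"excluded_chromosome_files": manifest}, fh, indent=1)


def read_loco_weights(outdir):
    from .locoinfer import LocoWeightSet

    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)["excluded_chromosome_files"]
    return LocoWeightSet({int(k): read_weights(outdir / v) for k, v in manifest.items()})
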