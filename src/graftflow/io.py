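"""File I/O: TSV dialects for all pipeline tables and VCF for variants.

All tabular artifacts are plain TSV.  Genotype variants are written as
minimal VCF v4.2 (1-based positions, GT:AD per genotype sample) and
read back with pysam.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .expression import ExpressionMatrix


# ----------------------------------------------------------------------
# TSV
# ----------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_expression(expr: ExpressionMatrix, values_path, samples_path) -> None:
    write_tsv(expr.values, values_path, index=True)
    write_tsv(expr.samples.reset_index(), samples_path)


def read_expression(values_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    return ExpressionMatrix(values, samples)


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def write_vcf(variants: pd.DataFrame, genotypes, path, contig: str = "chr1",
              contig_length: int | None = None) -> None:
    """Write the variant table as VCF v4.2 with GT:AD per genotype sample."""
    genotypes = list(genotypes)
    if contig_length is None:
        contig_length = int(variants["pos"].max()) + 1 if len(variants) else 1
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_length}>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id from the SNP-to-gene map">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes),
    ]
    for _, row in variants.iterrows():
        fields = [
            str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]), str(row["alt"]),
            ".", "PASS", f"GENE={row['gene_id']}" if row.get("gene_id") else ".", "GT:AD",
        ]
        for g in genotypes:
            gt = row[f"GT_{g}"].replace("/", "/")
            ad = f"{int(row[f'AD_ref_{g}'])},{int(row[f'AD_alt_{g}'])}"
            fields.append(f"{gt}:{ad}")
        lines.append("\t".join(fields))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF with GT:AD per sample into the variant-table layout."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
                "gene_id": rec.info.get("GENE", ""),
            }
            for g in samples:
                call = rec.samples[g]
                alleles = call.get("GT")
                gt = "/".join("." if a is None else str(a) for a in (alleles or (None, None)))
                ad = call.get("AD") or (0, 0)
                row[f"GT_{g}"] = gt
                row[f"AD_ref_{g}"] = int(ad[0] or 0)
                row[f"AD_alt_{g}"] = int(ad[1] if len(ad) > 1 and ad[1] is not None else 0)
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# whole-dataset round trip
# ----------------------------------------------------------------------

_FILES = {
    "expression": "expression.tsv",
    "samples": "samples.tsv",
    "variants": "variants.vcf",
    "variant_table": "variants.tsv",
    "gene_map": "snp_gene_map.tsv",
    "allele_counts": "allele_counts.tsv",
    "truth": "truth.tsv",
    "qpcr": "qpcr.tsv",
    "qpcr_truth": "qpcr_truth.tsv",
}


def write_dataset(ds, outdir) -> dict[str, Path]:
    """Write every simulator artifact under ``outdir``; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in _FILES.items()}
    write_expression(ds.expression, paths["expression"], paths["samples"])
    write_vcf(ds.variants, ds.params.genotypes, paths["variants"],
              contig_length=ds.params.genome_length + 1)
    write_tsv(ds.variants, paths["variant_table"])
    write_tsv(ds.gene_map, paths["gene_map"])
    write_tsv(ds.allele_counts, paths["allele_counts"])
    write_tsv(ds.truth, paths["truth"])
    write_tsv(ds.qpcr, paths["qpcr"])
    write_tsv(ds.qpcr_truth, paths["qpcr_truth"])
    return paths
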