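"""Readers and writers for the package's tabular formats.

Phenotypes, genotype matrices, chromosome sizes and QTL tables travel as
TSV; bulk allele depths as either TSV or a minimal two-sample VCF using the
AD FORMAT field (read back through cyvcf2); generative truth as JSON
sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .simulate import LineGenotypes

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bulk_tsv",
    "write_bulk_tsv",
    "read_bulk_vcf",
    "write_bulk_vcf",
    "write_truth_json",
]

PHENO_COLUMNS = ["line", "genotype_class", "year", "rep", "trait", "value"]


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_genotypes(genos: LineGenotypes, geno_path, map_path) -> None:
    """Write the lines x markers A/B/H/N matrix plus a marker-map TSV."""
    genos.to_frame().to_csv(geno_path, sep="\t", index_label="line")
    genos.markers.to_csv(map_path, sep="\t", index=False)


def read_genotypes(geno_path, map_path) -> LineGenotypes:
    frame = pd.read_csv(geno_path, sep="\t", index_col="line")
    markers = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    return LineGenotypes.from_frame(frame, markers)


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    pd.DataFrame(
        {"chrom": list(chrom_sizes), "length": list(chrom_sizes.values())}
    ).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_bulk_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_bulk_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_bulk_vcf(counts: pd.DataFrame, path, chrom_sizes: dict[str, int] | None = None) -> None:
    """Write bulk allele depths as a minimal VCF with two samples
    (HIGH_BULK, LOW_BULK) carrying AD=ref,alt per site."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=melonqtl\n")
        if chrom_sizes:
            for chrom, length in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHIGH_BULK\tLOW_BULK\n"
        )
        for row in counts.itertuples(index=False):
            ad_h = f"{row.ref_high},{row.total_high - row.ref_high}"
            ad_l = f"{row.ref_low},{row.total_low - row.ref_low}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\tA\tT\t.\tPASS\t.\tAD:DP\t"
                f"{ad_h}:{row.total_high}\t{ad_l}:{row.total_low}\n"
            )


def read_bulk_vcf(path, high_sample: str = "HIGH_BULK", low_sample: str = "LOW_BULK") -> pd.DataFrame:
    """Read a two-sample VCF with AD fields into a bulk-counts table.

    The first AD entry of each sample is taken as the reference-allele
    depth; the site total is the sum over AD entries.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        hi = samples.index(high_sample)
        lo = samples.index(low_sample)
    except ValueError as err:
        raise ValueError(
            f"VCF must contain samples {high_sample!r} and {low_sample!r}; found {samples}"
        ) from err
    rows = []
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            continue
        ref_h, tot_h = int(ad[hi][0]), int(ad[hi][ad[hi] >= 0].sum())
        ref_l, tot_l = int(ad[lo][0]), int(ad[lo][ad[lo] >= 0].sum())
        rows.append((var.CHROM, var.POS, ref_h, tot_h, ref_l, tot_l))
    vcf.close()
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref_high", "total_high", "ref_low", "total_low"]
    )


def write_truth_json(truth, path) -> None:
    """Serialize a generative-truth object (dataclass or dict) as JSON.

    Non-string dict keys (e.g. parent-pair tuples) are stringified.
    """

    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            obj = dataclasses.asdict(obj)
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if hasattr(obj, "tolist"):
            return obj.tolist()
        if hasattr(obj, "item"):
            return obj.item()
        return obj

    Path(path).write_text(json.dumps(clean(truth), indent=2) + "\n")
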