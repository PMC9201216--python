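"""Readers and writers for the pipeline's file formats.

Formats: multi-sample VCF v4.2 (read via pysam) with INFO keys DP, QD, FS
and XAMB; a variant annotation TSV (chrom, pos, ref, alt, gene, func,
polyphen2_hdiv, sift, cadd_phred, maf_ref); a phenotype TSV
(sample_id, status in {case, control}); and a STRING-style interactome edge
list handled in :mod:`cohortnet.networks`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .errors import InputError
from .variants import AnnotatedVariant, FilterReport


@dataclass
class Cohort:
    """Sample identifiers with case/control labels."""

    samples: list[str]
    status: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s: v for s, v in self.status.items() if v not in ("case", "control")}
        if bad:
            raise InputError(f"phenotype status must be case|control; offending: {bad}")
        missing = [s for s in self.samples if s not in self.status]
        if missing:
            raise InputError(f"samples without phenotype label: {missing}")

    @property
    def cases(self) -> list[str]:
        return [s for s in self.samples if self.status[s] == "case"]

    @property
    def controls(self) -> list[str]:
        return [s for s in self.samples if self.status[s] == "control"]

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_controls(self) -> int:
        return len(self.controls)


def read_cohort(phenotype_path: str | Path) -> Cohort:
    df = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if not {"sample_id", "status"} <= set(df.columns):
        raise InputError("phenotype file must have columns sample_id, status")
    return Cohort(samples=list(df["sample_id"]), status=dict(zip(df["sample_id"], df["status"])))


def _genotype_code(gt: tuple) -> int | None:
    if gt is None or any(a is None for a in gt):
        return None
    return int(sum(1 for a in gt if a != 0))


def read_variants(vcf_path: str | Path, annotation_path: str | Path | None = None) -> list[AnnotatedVariant]:
    """Read a multi-sample VCF and (optionally) join the annotation table.

    Variants absent from the annotation table keep ``None`` scores and are
    later removed by the deleteriousness filter as unannotated.
    """
    ann: dict[tuple, dict] = {}
    if annotation_path is not None:
        df = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
        for row in df.itertuples(index=False):
            ann[(str(row.chrom), int(row.pos), row.ref, row.alt)] = {
                "gene": row.gene,
                "func": row.func,
                "polyphen2_hdiv": float(row.polyphen2_hdiv),
                "sift": float(row.sift),
                "cadd_phred": float(row.cadd_phred),
                "maf_ref": float(row.maf_ref),
            }

    variants: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise InputError(f"expected biallelic records; offending site {rec.chrom}:{rec.pos}")
            genotypes = {s: _genotype_code(rec.samples[s].get("GT")) for s in samples}
            extra = ann.get((str(rec.chrom), int(rec.pos), rec.ref, rec.alts[0]), {})
            variants.append(
                AnnotatedVariant(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=rec.ref,
                    alt=rec.alts[0],
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                    depth=int(rec.info.get("DP", 0)),
                    qd=float(rec.info.get("QD", 0.0)),
                    fs=float(rec.info.get("FS", 0.0)),
                    xamb=int(rec.info.get("XAMB", 0)),
                    genotypes=genotypes,
                    rsid=None if rec.id in (None, ".") else rec.id,
                    **extra,
                )
            )
    return variants


def write_variant_table(variants: list[AnnotatedVariant], path: str | Path) -> None:
    """Write surviving variants back out in the annotation-TSV dialect."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tfunc\tpolyphen2_hdiv\tsift\tcadd_phred\tmaf_ref\n")
        for v in variants:
            def fmt(x, spec):
                return "" if x is None else format(x, spec)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene or ''}\t{v.func or ''}\t"
                f"{fmt(v.polyphen2_hdiv, '.6f')}\t{fmt(v.sift, '.6f')}\t"
                f"{fmt(v.cadd_phred, '.4f')}\t{fmt(v.maf_ref, '.6f')}\n"
            )


def write_filter_reports(reports: list[FilterReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1, sort_keys=True)
        fh.write("\n")
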