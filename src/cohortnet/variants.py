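"""Variant records and the two filtering stages of the univariate workflow.

Stage 1 (``quality_filter``) removes technically unreliable sites using the
fields carried on the variant records: local variant density (three or more
variants within any 10-bp window of one chromosome), ambiguous mapping (four
or more equally good alignments), coverage below ten reads, site quality
below 30, quality-by-depth below 1.5, and Phred-scaled strand-bias above 200.

Stage 2 (``deleteriousness_filter``) keeps putatively damaging exonic
variants: PolyPhen-2 HDIV >= 0.957, SIFT < 0.05, CADD (Phred) > 15 and
reference-population minor allele frequency < 0.05.  All inequalities are
applied with exactly this strictness.  Variants with any missing annotation
score are excluded under a distinct ``unannotated`` reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import InputError

MISSING = None  # missing genotype code

QUALITY_FILTERS = ("density", "multimapping", "low_coverage", "low_qual", "low_qd", "strand_bias")
DELETERIOUSNESS_FILTERS = ("not_exonic", "unannotated", "polyphen", "sift", "cadd", "maf")


@dataclass
class AnnotatedVariant:
    """One biallelic variant site with quality fields, genotypes and scores.

    Genotype codes per sample: 0 hom-ref, 1 het, 2 hom-alt, ``None`` missing.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    qd: float
    fs: float
    xamb: int
    genotypes: dict[str, Optional[int]]
    gene: Optional[str] = None
    func: Optional[str] = None
    polyphen2_hdiv: Optional[float] = None
    sift: Optional[float] = None
    cadd_phred: Optional[float] = None
    maf_ref: Optional[float] = None
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"position must be >= 1 (got {self.pos} at {self.chrom})")
        if self.depth < 0 or self.qual < 0:
            raise InputError(f"negative depth/quality at {self.chrom}:{self.pos}")
        bad = {g for g in self.genotypes.values() if g not in (0, 1, 2, None)}
        if bad:
            raise InputError(f"invalid genotype codes {bad} at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def has_scores(self) -> bool:
        return None not in (self.polyphen2_hdiv, self.sift, self.cadd_phred, self.maf_ref)


@dataclass
class FilterReport:
    """Audit trail of one filter stage.

    ``failures`` maps a variant key to the ordered list of filter names it
    failed; ``counts`` tallies failures per filter (a variant may appear under
    several).  ``n_input`` and ``n_survivors`` give the stage funnel.
    """

    stage: str
    n_input: int = 0
    n_survivors: int = 0
    failures: dict[str, list[str]] = field(default_factory=dict)
    counts: Counter = field(default_factory=Counter)

    def record(self, key: str, reasons: list[str]) -> None:
        if reasons:
            self.failures[key] = reasons
            self.counts.update(reasons)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_survivors": self.n_survivors,
            "counts": dict(sorted(self.counts.items())),
            "failures": {k: self.failures[k] for k in sorted(self.failures)},
        }


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _density_failures(variants: list[AnnotatedVariant], window: int = 10, count: int = 3) -> set[str]:
    """Keys of variants in any closed ``window``-bp span of one chromosome
    holding >= ``count`` variants.  Every member of a dense window fails."""
    failed: set[str] = set()
    by_chrom: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom_variants in by_chrom.values():
        vs = sorted(chrom_variants, key=lambda v: v.pos)
        n = len(vs)
        j = 0
        for i in range(n):
            if j < i + 1:
                j = i + 1
            while j < n and vs[j].pos <= vs[i].pos + window:
                j += 1
            if j - i >= count:
                failed.update(v.key for v in vs[i:j])
    return failed


def quality_filter(
    variants: Iterable[AnnotatedVariant],
    density_window: int = 10,
    density_count: int = 3,
    max_xamb: int = 3,
    min_depth: int = 10,
    min_qual: float = 30.0,
    min_qd: float = 1.5,
    max_fs: float = 200.0,
) -> tuple[list[AnnotatedVariant], FilterReport]:
    """Remove low-quality sites; returns survivors plus a per-variant report.

    Thresholds keep a variant when depth >= 10, qual >= 30, QD >= 1.5,
    FS <= 200 and xamb <= 3 (defaults); a variant also fails when it sits in
    a 10-bp window holding three or more variants.  Input need not be sorted.
    """
    vs = sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    report = FilterReport(stage="quality", n_input=len(vs))
    dense = _density_failures(vs, window=density_window, count=density_count)
    survivors = []
    for v in vs:
        reasons = []
        if v.key in dense:
            reasons.append("density")
        if v.xamb > max_xamb:
            reasons.append("multimapping")
        if v.depth < min_depth:
            reasons.append("low_coverage")
        if v.qual < min_qual:
            reasons.append("low_qual")
        if v.qd < min_qd:
            reasons.append("low_qd")
        if v.fs > max_fs:
            reasons.append("strand_bias")
        report.record(v.key, reasons)
        if not reasons:
            survivors.append(v)
    report.n_survivors = len(survivors)
    return survivors, report


def deleteriousness_filter(
    variants: Iterable[AnnotatedVariant],
    polyphen_min: float = 0.957,
    sift_max: float = 0.05,
    cadd_min: float = 15.0,
    maf_max: float = 0.05,
) -> tuple[list[AnnotatedVariant], FilterReport]:
    """Keep exonic variants passing all four deleteriousness thresholds.

    A variant survives iff func == "exonic", PolyPhen-2 HDIV >= 0.957,
    SIFT < 0.05, CADD > 15 and reference MAF < 0.05 (defaults).  The report
    lists every threshold each removed variant violated; unannotated variants
    are removed under "unannotated".
    """
    vs = list(variants)
    report = FilterReport(stage="deleteriousness", n_input=len(vs))
    survivors = []
    for v in vs:
        reasons = []
        if v.func != "exonic":
            reasons.append("not_exonic")
        if not v.has_scores():
            reasons.append("unannotated")
        else:
            if v.polyphen2_hdiv < polyphen_min:
                reasons.append("polyphen")
            if v.sift >= sift_max:
                reasons.append("sift")
            if v.cadd_phred <= cadd_min:
                reasons.append("cadd")
            if v.maf_ref >= maf_max:
                reasons.append("maf")
        report.record(v.key, reasons)
        if not reasons:
            survivors.append(v)
    report.n_survivors = len(survivors)
    return survivors, report
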