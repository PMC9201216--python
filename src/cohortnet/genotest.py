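"""Case/control genotype association testing and per-sample seed-gene choice.

Each variant yields a 2x3 contingency table of genotype counts (hom-ref,
het, hom-alt) for cases vs controls.  Under the null of no association the
table, conditioned on its margins, follows the multivariate hypergeometric
distribution; the two-sided exact p-value sums the probabilities of all
tables with the observed margins whose probability does not exceed that of
the observed table.  For tables too large to enumerate, a Monte-Carlo
estimate samples tables from the same fixed-margin null by sequential
hypergeometric draws and applies the add-one estimator
``(1 + #{prob <= observed}) / (reps + 1)``.

Probability comparisons use exact integer arithmetic on the hypergeometric
numerators (the shared denominator cancels), so ties are handled without any
floating-point tolerance.

Seed genes: for one sample, every gene in which the sample carries an
alternative allele in at least one surviving variant is ranked by the
minimum variant p-value within that gene, and the top ``k`` (default 60)
genes become the sample's network seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Iterable, Optional

import numpy as np

from .errors import ConfigurationError, InputError
from .io import Cohort
from .variants import AnnotatedVariant

GENOTYPE_ORDER = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class GenotypeTable:
    """2x3 genotype counts: rows (case, control) x columns (0/0, 0/1, 1/1)."""

    case: tuple[int, int, int]
    control: tuple[int, int, int]
    n_missing_case: int = 0
    n_missing_control: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.case + self.control):
            raise InputError("genotype counts must be non-negative")

    @property
    def rows(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        return (self.case, self.control)

    @property
    def row_margins(self) -> tuple[int, int]:
        return (sum(self.case), sum(self.control))

    @property
    def col_margins(self) -> tuple[int, int, int]:
        return tuple(a + b for a, b in zip(self.case, self.control))

    def enumeration_size(self) -> int:
        """Number of first-row compositions compatible with the margins."""
        r1 = sum(self.case)
        cols = self.col_margins
        size = 0
        for a0 in range(max(0, r1 - cols[1] - cols[2]), min(r1, cols[0]) + 1):
            rem = r1 - a0
            size += min(rem, cols[1]) - max(0, rem - cols[2]) + 1
        return size


@dataclass
class VariantTestResult:
    """Association result for one variant."""

    key: str
    gene: Optional[str]
    p_value: float
    method: str  # "exact" | "monte-carlo"
    maf_cases: float
    maf_controls: float
    mc_reps: Optional[int] = None
    mc_seed: Optional[int] = None


@dataclass
class SeedGeneSet:
    """Ordered seed genes for one sample with their best variant p-values."""

    sample_id: str
    genes: tuple[str, ...]
    gene_p: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def build_genotype_table(variant: AnnotatedVariant, cohort: Cohort) -> GenotypeTable:
    """Tally one variant's genotypes by group; missing genotypes are excluded
    from the counts and reported per group."""
    counts = {"case": [0, 0, 0], "control": [0, 0, 0]}
    missing = {"case": 0, "control": 0}
    for sample, code in variant.genotypes.items():
        group = cohort.status.get(sample)
        if group is None:
            raise InputError(f"sample {sample!r} has a genotype but no case/control label")
        if code is None:
            missing[group] += 1
        else:
            counts[group][code] += 1
    return GenotypeTable(
        case=tuple(counts["case"]),
        control=tuple(counts["control"]),
        n_missing_case=missing["case"],
        n_missing_control=missing["control"],
    )


def _iter_first_rows(r1: int, cols: tuple[int, int, int]):
    for a0 in range(max(0, r1 - cols[1] - cols[2]), min(r1, cols[0]) + 1):
        rem = r1 - a0
        for a1 in range(max(0, rem - cols[2]), min(rem, cols[1]) + 1):
            yield a0, a1, rem - a1


def _table_weight(row: tuple[int, int, int], cols: tuple[int, int, int]) -> int:
    # hypergeometric numerator: prod_j C(c_j, a_j); the denominator C(N, r1)
    # is shared by all tables with these margins and cancels in comparisons
    return comb(cols[0], row[0]) * comb(cols[1], row[1]) * comb(cols[2], row[2])


@lru_cache(maxsize=200_000)
def _exact_p(row1: tuple[int, int, int], row2: tuple[int, int, int]) -> float:
    r1, r2 = sum(row1), sum(row2)
    if r1 == 0 or r2 == 0:
        return 1.0
    cols = tuple(a + b for a, b in zip(row1, row2))
    obs = _table_weight(row1, cols)
    c0 = [comb(cols[0], a) for a in range(cols[0] + 1)]
    c1 = [comb(cols[1], a) for a in range(cols[1] + 1)]
    c2 = [comb(cols[2], a) for a in range(cols[2] + 1)]
    total = 0
    for a0, a1, a2 in _iter_first_rows(r1, cols):
        w = c0[a0] * c1[a1] * c2[a2]
        if w <= obs:
            total += w
    p = total / comb(r1 + r2, r1)
    return min(1.0, p)


def fisher_exact_table(table: GenotypeTable, cap: int = 100_000) -> float:
    """Two-sided exact p-value of the 2x3 table by full enumeration.

    Raises :class:`ConfigurationError` when the enumeration would exceed
    ``cap`` tables; use :func:`fisher_exact_mc` then.
    """
    if table.enumeration_size() > cap:
        raise ConfigurationError(
            f"enumeration size {table.enumeration_size()} exceeds cap {cap}; use fisher_exact_mc"
        )
    return _exact_p(table.case, table.control)


def _hypergeom_draw(rng: np.random.Generator, ngood: int, nbad: int, nsample) -> np.ndarray:
    nsample = np.asarray(nsample)
    out = np.zeros(nsample.shape, dtype=np.int64)
    if ngood == 0:
        return out
    if nbad == 0:
        return nsample.astype(np.int64)
    mask = nsample > 0
    if np.any(mask):
        out[mask] = rng.hypergeometric(ngood, nbad, nsample[mask])
    return out


def fisher_exact_mc(table: GenotypeTable, reps: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo p-value: sample ``reps`` tables from the fixed-margin null
    (sequential hypergeometric draws of the first row) and report the
    add-one estimate.  Deterministic given ``seed``."""
    if reps < 1000:
        raise ConfigurationError("reps must be >= 1000")
    r1, r2 = table.row_margins
    if r1 == 0 or r2 == 0:
        return 1.0
    cols = table.col_margins
    N = r1 + r2
    rng = np.random.default_rng(seed)
    nsample = np.full(reps, r1, dtype=np.int64)
    a0 = _hypergeom_draw(rng, cols[0], N - cols[0], nsample)
    a1 = _hypergeom_draw(rng, cols[1], N - cols[0] - cols[1], nsample - a0)
    a2 = nsample - a0 - a1

    obs = _table_weight(table.case, cols)
    codes = a0 * (r1 + 1) + a1
    uniq, counts = np.unique(codes, return_counts=True)
    hits = 0
    for code, count in zip(uniq, counts):
        ua0, ua1 = int(code) // (r1 + 1), int(code) % (r1 + 1)
        if _table_weight((ua0, ua1, r1 - ua0 - ua1), cols) <= obs:
            hits += int(count)
    return (1 + hits) / (reps + 1)


def _allele_freq(variant: AnnotatedVariant, samples: list[str]) -> float:
    alleles = 0
    alt = 0
    for s in samples:
        code = variant.genotypes.get(s)
        if code is None:
            continue
        alleles += 2
        alt += code
    return alt / alleles if alleles else 0.0


def test_variants(
    variants: Iterable[AnnotatedVariant],
    cohort: Cohort,
    exact_cap: int = 100_000,
    mc_reps: int = 100_000,
    mc_seed: int = 0,
) -> list[VariantTestResult]:
    """Run the genotype test on every variant (exact when the enumeration fits
    under ``exact_cap``, Monte Carlo otherwise, with a per-variant seed derived
    stably from ``mc_seed`` and the variant key)."""
    cases, controls = cohort.cases, cohort.controls
    results = []
    for v in variants:
        table = build_genotype_table(v, cohort)
        if table.enumeration_size() <= exact_cap:
            p = fisher_exact_table(table, cap=exact_cap)
            res = VariantTestResult(
                key=v.key, gene=v.gene, p_value=p, method="exact",
                maf_cases=_allele_freq(v, cases), maf_controls=_allele_freq(v, controls),
            )
        else:
            seed = (mc_seed + zlib.crc32(v.key.encode())) % (2**31)
            p = fisher_exact_mc(table, reps=mc_reps, seed=seed)
            res = VariantTestResult(
                key=v.key, gene=v.gene, p_value=p, method="monte-carlo",
                maf_cases=_allele_freq(v, cases), maf_controls=_allele_freq(v, controls),
                mc_reps=mc_reps, mc_seed=seed,
            )
        results.append(res)
    return results


def select_seed_genes(
    sample: str,
    survivors: list[AnnotatedVariant],
    results: list[VariantTestResult],
    k: int = 60,
) -> SeedGeneSet:
    """Rank the genes in which ``sample`` carries an alternative allele by the
    minimum variant p-value and keep the top ``k`` (ties: lexicographic by
    gene symbol).  A sample with no qualifying gene yields an empty set."""
    p_by_key = {r.key: r.p_value for r in results}
    missing = [v.key for v in survivors if v.key not in p_by_key]
    if missing:
        raise InputError(f"test results missing for surviving variants: {missing[:5]}")
    gene_p: dict[str, float] = {}
    for v in survivors:
        if v.gene is None:
            continue
        if v.genotypes.get(sample) in (1, 2):
            p = p_by_key[v.key]
            if v.gene not in gene_p or p < gene_p[v.gene]:
                gene_p[v.gene] = p
    ranked = sorted(gene_p, key=lambda g: (gene_p[g], g))[:k]
    return SeedGeneSet(sample_id=sample, genes=tuple(ranked), gene_p={g: gene_p[g] for g in ranked})
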