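"""Synthetic cohort generator: interactome, planted disease module, genotypes.

The generator emulates the study design the pipeline targets: a case/control
exome cohort (default 61 cases, 82 controls) in which a localized, connected
"disease module" of the interactome is preferentially hit by rare deleterious
heterozygous variants in cases.  It produces the same file formats the
pipeline consumes (multi-sample VCF, variant annotation TSV, phenotype TSV)
plus a ground-truth JSON so every downstream stage can be validated offline:

* interactome — preferential-attachment growth (scale-free-like, matching the
  hub-dominated topology of curated interactomes) with uniform integer edge
  confidences in [150, 999];
* disease module — a connected induced subgraph chosen by random-walk
  expansion from a random start node;
* variants — per-sample planted module hits (always passing the
  deleteriousness thresholds), background variants in non-module genes of
  which a configurable fraction passes those thresholds and the rest violate
  exactly one randomly chosen threshold, plus site-quality fields drawn so a
  configurable fraction of sites fails each quality filter.

All randomness flows from ``SimulationConfig.rng_seed``; identical configs
produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ConfigurationError, SimulationError
from .networks import Interactome

_BASES = "ACGT"
_QUALITY_FIELDS = ("xamb", "depth", "qual", "qd", "fs")
_SCORE_FIELDS = ("polyphen2_hdiv", "sift", "cadd_phred", "maf_ref")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults reproduce the target design: 61 cases / 82 controls, a
    1,500-gene interactome grown with 3 edges per node, a 15-gene planted
    disease module hit in 80% of cases vs 5% of controls, and a background
    variant load whose per-gene carrier rate matches a real exome (about
    7-8 deleterious background genes per sample at this interactome size).
    """

    n_cases: int = 61
    n_controls: int = 82
    n_interactome_nodes: int = 1500
    attachment_degree: int = 3
    module_size: int = 15
    case_module_hit_rate: float = 0.8
    control_module_hit_rate: float = 0.05
    # fraction_deleterious_background is calibrated so the per-gene carrier
    # rate matches a real exome: ~100 deleterious variants over ~20,000 genes
    # is ~0.005 carriers/gene/sample; 150 draws over ~1,485 background genes
    # reaches the same rate at a fraction of 0.05.
    background_variants_per_sample: int = 150
    fraction_deleterious_background: float = 0.05
    rng_seed: int = 0
    # secondary knobs: site bookkeeping and failure injection
    sites_per_gene: int = 2
    quality_fail_rate: float = 0.05
    missing_rate: float = 0.02
    n_density_clusters: int = 2

    def validate(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_interactome_nodes": self.n_interactome_nodes,
            "attachment_degree": self.attachment_degree,
            "module_size": self.module_size,
            "sites_per_gene": self.sites_per_gene,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer (got {value!r})")
        probs = {
            "case_module_hit_rate": self.case_module_hit_rate,
            "control_module_hit_rate": self.control_module_hit_rate,
            "fraction_deleterious_background": self.fraction_deleterious_background,
            "quality_fail_rate": self.quality_fail_rate,
            "missing_rate": self.missing_rate,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1] (got {value!r})")
        if self.background_variants_per_sample < 0:
            raise ConfigurationError("background_variants_per_sample must be >= 0")
        if self.n_density_clusters < 0:
            raise ConfigurationError("n_density_clusters must be >= 0")
        if self.module_size >= self.n_interactome_nodes:
            raise ConfigurationError("module_size must be < n_interactome_nodes")
        if self.n_cases + self.n_controls < 4:
            raise ConfigurationError("n_cases + n_controls must be >= 4")
        if self.n_interactome_nodes < self.attachment_degree + 1:
            raise ConfigurationError("n_interactome_nodes must be >= attachment_degree + 1")


@dataclass
class SiteTruth:
    """Ground truth for one generated variant site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    is_module: bool
    passes_deleterious: bool
    quality_fails: list[str] = field(default_factory=list)


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort: the module and who was hit where."""

    module_genes: set[str]
    hits: dict[str, set[str]]  # sample -> module genes carrying planted variants
    sites: dict[str, SiteTruth] = field(default_factory=dict)

    def passing_site_keys(self) -> set[str]:
        return {k for k, s in self.sites.items() if s.passes_deleterious}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_genes": sorted(self.module_genes),
            "hits": {s: sorted(g) for s, g in sorted(self.hits.items())},
            "sites": {k: asdict(self.sites[k]) for k in sorted(self.sites)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            module_genes=set(payload["module_genes"]),
            hits={s: set(g) for s, g in payload["hits"].items()},
            sites={k: SiteTruth(**v) for k, v in payload["sites"].items()},
        )


def _seed_for(rng_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=rng_seed, spawn_key=(stream,)))


def gene_name(index: int, n_total: int) -> str:
    width = max(4, len(str(n_total)))
    return f"G{index + 1:0{width}d}"


def generate_interactome(config: SimulationConfig) -> Interactome:
    """Grow a connected scale-free-like interactome by preferential attachment.

    Each new node attaches to ``attachment_degree`` distinct existing nodes
    with probability proportional to degree, giving exactly
    ``attachment_degree * (n - attachment_degree)`` edges.  Edge confidences
    are integers drawn uniformly from [150, 999].
    """
    config.validate()
    n, m = config.n_interactome_nodes, config.attachment_degree
    seed = int(np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(0,)).generate_state(1)[0])
    raw = nx.barabasi_albert_graph(n, m, seed=seed)
    names = {i: gene_name(i, n) for i in raw.nodes}
    rng = _seed_for(config.rng_seed, 1)
    g = nx.Graph()
    g.add_nodes_from(names[i] for i in sorted(raw.nodes))
    for u, v in sorted(tuple(sorted(e)) for e in raw.edges):
        g.add_edge(names[u], names[v], score=int(rng.integers(150, 1000)))
    return Interactome(g)


def plant_disease_module(interactome: Interactome, module_size: int, rng_seed: int) -> set[str]:
    """Pick a connected induced subgraph of ``module_size`` genes by random-walk
    expansion from a random start node (restricted to the largest component)."""
    g = interactome.graph
    if module_size > g.number_of_nodes():
        raise SimulationError("module_size exceeds interactome node count")
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    largest = sorted(components[0])
    if len(largest) < module_size:
        raise SimulationError(
            f"largest interactome component has {len(largest)} nodes; cannot hold a module of {module_size}"
        )
    rng = _seed_for(rng_seed, 2)
    current = largest[int(rng.integers(len(largest)))]
    module = {current}
    max_steps = 10_000 * module_size
    steps = 0
    while len(module) < module_size:
        steps += 1
        if steps > max_steps:
            raise SimulationError("random walk failed to reach the requested module size")
        neighbors = sorted(g[current])
        current = neighbors[int(rng.integers(len(neighbors)))]
        module.add(current)
    return module


def _draw_passing_scores(rng: np.random.Generator) -> dict[str, float]:
    # kept clear of the thresholds by one rounding unit so that the values
    # survive fixed-precision serialization unambiguously
    return {
        "polyphen2_hdiv": float(rng.uniform(0.957, 1.0)),
        "sift": float(rng.uniform(0.0, 0.0499)),
        "cadd_phred": float(rng.uniform(15.1, 40.0)),
        "maf_ref": float(rng.uniform(0.0, 0.0499)),
    }


def _draw_failing_scores(rng: np.random.Generator) -> dict[str, float]:
    scores = _draw_passing_scores(rng)
    which = _SCORE_FIELDS[int(rng.integers(len(_SCORE_FIELDS)))]
    if which == "polyphen2_hdiv":
        scores[which] = float(rng.uniform(0.0, 0.9569))
    elif which == "sift":
        scores[which] = float(rng.uniform(0.05, 1.0))
    elif which == "cadd_phred":
        scores[which] = float(rng.uniform(0.0, 15.0))
    else:
        scores[which] = float(rng.uniform(0.05, 0.5))
    return scores


def _draw_quality(rng: np.random.Generator, fail: str | None) -> dict[str, float | int]:
    q = {
        "xamb": int(rng.integers(0, 4)),
        "depth": int(rng.integers(20, 100)),
        "qual": float(rng.uniform(50.0, 2000.0)),
        "qd": float(rng.uniform(2.0, 35.0)),
        "fs": float(rng.uniform(0.0, 60.0)),
    }
    if fail == "xamb":
        q["xamb"] = int(rng.integers(4, 11))
    elif fail == "depth":
        q["depth"] = int(rng.integers(0, 10))
    elif fail == "qual":
        q["qual"] = float(rng.uniform(0.0, 29.9))
    elif fail == "qd":
        q["qd"] = float(rng.uniform(0.0, 1.49))
    elif fail == "fs":
        q["fs"] = float(rng.uniform(200.01, 400.0))
    return q


class _Site:
    __slots__ = ("chrom", "pos", "ref", "alt", "gene", "is_module", "passes", "quality_fails", "scores", "quality", "carriers")

    def __init__(self, chrom, pos, ref, alt, gene, is_module, passes, quality_fails, scores, quality):
        self.chrom, self.pos, self.ref, self.alt = chrom, pos, ref, alt
        self.gene, self.is_module, self.passes = gene, is_module, passes
        self.quality_fails, self.scores, self.quality = quality_fails, scores, quality
        self.carriers: dict[str, int] = {}

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _gene_locus(index: int) -> tuple[str, int]:
    chrom = str(index % 22 + 1)
    block = index // 22
    return chrom, 1_000_000 + block * 200_000


def generate_cohort(
    config: SimulationConfig,
    interactome: Interactome,
    module: set[str],
    out_dir: str | Path,
) -> tuple[Path, Path, Path, PlantedTruth]:
    """Simulate genotypes and write the VCF / annotation / phenotype files.

    Returns ``(vcf_path, annotation_path, phenotype_path, truth)``; the truth
    is also written as ``truth.json`` alongside.
    """
    config.validate()
    if not set(module) <= set(interactome.graph.nodes):
        raise SimulationError("module genes must be a subset of the interactome nodes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _seed_for(config.rng_seed, 3)

    genes = sorted(interactome.graph.nodes)
    gene_index = {g: i for i, g in enumerate(genes)}
    module_genes = sorted(module)
    background_genes = [g for g in genes if g not in module]

    n_total = config.n_cases + config.n_controls
    width = max(3, len(str(n_total)))
    samples = [f"S{i + 1:0{width}d}" for i in range(n_total)]
    status = {s: ("case" if i < config.n_cases else "control") for i, s in enumerate(samples)}

    sites: dict[str, _Site] = {}
    # site pools: gene -> list of site keys (lazily instantiated)
    pools: dict[str, list[str]] = {}

    def _new_site(gene: str, slot: int, is_module: bool) -> _Site:
        chrom, start = _gene_locus(gene_index[gene])
        pos = start + slot * 50
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
        if is_module:
            passes, quality_fails = True, []
            scores = _draw_passing_scores(rng)
        else:
            passes = bool(rng.random() < config.fraction_deleterious_background)
            scores = _draw_passing_scores(rng) if passes else _draw_failing_scores(rng)
            quality_fails = []
            if rng.random() < config.quality_fail_rate:
                quality_fails = [_QUALITY_FIELDS[int(rng.integers(len(_QUALITY_FIELDS)))]]
        quality = _draw_quality(rng, quality_fails[0] if quality_fails else None)
        site = _Site(chrom, pos, ref, alt, gene, is_module, passes, quality_fails, scores, quality)
        sites[site.key] = site
        return site

    def _site_for(gene: str, is_module: bool) -> _Site:
        pool = pools.get(gene)
        if pool is None:
            pool = [_new_site(gene, slot, is_module).key for slot in range(config.sites_per_gene)]
            pools[gene] = pool
        return sites[pool[int(rng.integers(len(pool)))]]

    truth_hits: dict[str, set[str]] = {s: set() for s in samples}
    hit_rate = {"case": config.case_module_hit_rate, "control": config.control_module_hit_rate}
    for s in samples:
        if module_genes and rng.random() < hit_rate[status[s]]:
            n_hits = int(rng.integers(1, min(3, len(module_genes)) + 1))
            chosen = rng.choice(module_genes, size=n_hits, replace=False)
            for gene in sorted(str(g) for g in chosen):
                site = _site_for(gene, is_module=True)
                site.carriers[s] = 1
                truth_hits[s].add(gene)
        if config.background_variants_per_sample and background_genes:
            k = min(config.background_variants_per_sample, len(background_genes))
            chosen = rng.choice(background_genes, size=k, replace=False)
            for gene in sorted(str(g) for g in chosen):
                site = _site_for(gene, is_module=False)
                site.carriers[s] = 1

    # density-failure decoys: triplets of sites within a 10-bp window
    decoy_candidates = [g for g in background_genes if g not in pools]
    for i in range(config.n_density_clusters):
        if not decoy_candidates:
            break
        gene = decoy_candidates[int(rng.integers(len(decoy_candidates)))]
        decoy_candidates.remove(gene)
        chrom, start = _gene_locus(gene_index[gene])
        for j, offset in enumerate((0, 4, 8)):
            pos = start + 150_000 + offset
            ref = _BASES[int(rng.integers(4))]
            alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            site = _Site(
                chrom, pos, ref, alt, gene, False, False, ["density"],
                _draw_failing_scores(rng), _draw_quality(rng, None),
            )
            sites[site.key] = site
            carrier = samples[int(rng.integers(len(samples)))]
            site.carriers[carrier] = 1

    # sprinkle missing genotypes over non-carriers
    ordered_sites = sorted(sites.values(), key=lambda s: (int(s.chrom), s.pos, s.ref, s.alt))
    missing: dict[str, set[str]] = {}
    if config.missing_rate > 0:
        for site in ordered_sites:
            draw = rng.random(n_total)
            missing[site.key] = {
                s for s, u in zip(samples, draw) if u < config.missing_rate and s not in site.carriers
            }

    vcf_path = out_dir / "cohort.vcf"
    ann_path = out_dir / "annotations.tsv"
    phe_path = out_dir / "phenotypes.tsv"
    _write_vcf(vcf_path, ordered_sites, samples, missing)
    _write_annotations(ann_path, ordered_sites)
    with open(phe_path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for s in samples:
            fh.write(f"{s}\t{status[s]}\n")

    truth = PlantedTruth(
        module_genes=set(module_genes),
        hits=truth_hits,
        sites={
            site.key: SiteTruth(
                chrom=site.chrom, pos=site.pos, ref=site.ref, alt=site.alt,
                gene=site.gene, is_module=site.is_module,
                passes_deleterious=site.passes, quality_fails=list(site.quality_fails),
            )
            for site in ordered_sites
        },
    )
    truth.to_json(out_dir / "truth.json")
    return vcf_path, ann_path, phe_path, truth


def _write_vcf(path: Path, ordered_sites: list[_Site], samples: list[str], missing: dict[str, set[str]]) -> None:
    gt_string = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cohortnet-simulate\n")
        for c in range(1, 23):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence / unfiltered depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand-bias Fisher p">\n')
        fh.write('##INFO=<ID=XAMB,Number=1,Type=Integer,Description="Count of equally scoring alternative alignments">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, site in enumerate(ordered_sites):
            info = (
                f"DP={site.quality['depth']};QD={site.quality['qd']:.2f};"
                f"FS={site.quality['fs']:.2f};XAMB={site.quality['xamb']}"
            )
            miss = missing.get(site.key, set())
            gts = "\t".join(
                "./." if s in miss else gt_string[site.carriers.get(s, 0)] for s in samples
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\tv{i + 1:06d}\t{site.ref}\t{site.alt}\t"
                f"{site.quality['qual']:.1f}\t.\t{info}\tGT\t{gts}\n"
            )


def _write_annotations(path: Path, ordered_sites: list[_Site]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tfunc\tpolyphen2_hdiv\tsift\tcadd_phred\tmaf_ref\n")
        for site in ordered_sites:
            s = site.scores
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{site.gene}\texonic\t"
                f"{s['polyphen2_hdiv']:.6f}\t{s['sift']:.6f}\t{s['cadd_phred']:.4f}\t{s['maf_ref']:.6f}\n"
            )
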