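"""End-to-end pipeline: simulate -> filter -> genotype test -> networks ->
cluster -> separation -> report.

Every run writes the fully resolved configuration next to its outputs, and
identical configuration + seed produce byte-identical output files (the run
log is the only timestamped artifact).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import clustering, genotest, io, networks, separation, simulate, variants
from .errors import CohortNetError, ConfigurationError, EmptyNetworkError, InputError

log = logging.getLogger("cohortnet")


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run.

    Filtering and analysis defaults are the published operating point of the
    method: quality thresholds (10-bp density window of 3, xamb <= 3,
    depth >= 10, qual >= 30, QD >= 1.5, FS <= 200), deleteriousness
    thresholds (PolyPhen-2 HDIV >= 0.957, SIFT < 0.05, CADD > 15,
    MAF < 0.05), k = 60 seed genes, maximum seed path length 2, cluster test
    at alpha = 0.05.  The interactome confidence cutoff defaults to 400
    (STRING "medium confidence").
    """

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    simulate_inputs: bool = True
    # external inputs, used when simulate_inputs is False
    vcf: Optional[str] = None
    annotations: Optional[str] = None
    phenotypes: Optional[str] = None
    interactome: Optional[str] = None
    truth: Optional[str] = None
    # quality filter
    density_window: int = 10
    density_count: int = 3
    max_xamb: int = 3
    min_depth: int = 10
    min_qual: float = 30.0
    min_qd: float = 1.5
    max_fs: float = 200.0
    # deleteriousness filter
    polyphen_min: float = 0.957
    sift_max: float = 0.05
    cadd_min: float = 15.0
    maf_max: float = 0.05
    # genotype testing / seeds
    k_seed_genes: int = 60
    exact_cap: int = 100_000
    mc_reps: int = 100_000
    # networks
    confidence_threshold: int = 400
    max_path_length: int = 2
    keep_all_components: bool = False
    include_imputed_edges: bool = False
    # clustering
    jaccard_on: str = "nodes"
    min_cluster_size: int = 3
    alpha: float = 0.05
    bonferroni: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = simulate.SimulationConfig(**self.simulation)
        self.simulation.rng_seed = self.seed

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        payload.update(overrides)
        return cls(**payload)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write the report; returns the report dict.

    On stage failure a ``manifest.json`` listing the completed stages is
    left in ``out_dir`` and the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    completed: list[str] = []
    try:
        report = _run_stages(config, out, completed)
        return report
    except Exception:
        _write_json({"stages_completed": completed, "status": "failed"}, out / "manifest.json")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path, completed: list[str]) -> dict:
    config.to_yaml(out / "config_resolved.yaml")

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.simulate_inputs:
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        full = simulate.generate_interactome(config.simulation)
        networks.write_interactome(full, inputs / "interactome.tsv")
        inter = full.thresholded(config.confidence_threshold)
        module = simulate.plant_disease_module(
            inter, config.simulation.module_size, config.simulation.rng_seed
        )
        vcf_path, ann_path, phe_path, truth = simulate.generate_cohort(
            config.simulation, inter, module, inputs
        )
        log.info("simulated cohort: %d sites, module %s", len(truth.sites), sorted(module))
    else:
        for name in ("vcf", "annotations", "phenotypes", "interactome"):
            if getattr(config, name) is None:
                raise ConfigurationError(f"simulate_inputs is false but no {name} path was given")
        inter = networks.load_interactome(config.interactome, config.confidence_threshold)
        vcf_path, ann_path, phe_path = config.vcf, config.annotations, config.phenotypes
        if config.truth:
            truth = simulate.PlantedTruth.from_json(config.truth)
    completed.append("inputs")

    cohort = io.read_cohort(phe_path)
    all_variants = io.read_variants(vcf_path, ann_path)
    log.info("cohort: %d cases / %d controls; %d variant sites", cohort.n_cases, cohort.n_controls, len(all_variants))

    # --- filtering --------------------------------------------------------
    filtered_dir = out / "filtered"
    filtered_dir.mkdir(exist_ok=True)
    q_surv, q_report = variants.quality_filter(
        all_variants,
        density_window=config.density_window,
        density_count=config.density_count,
        max_xamb=config.max_xamb,
        min_depth=config.min_depth,
        min_qual=config.min_qual,
        min_qd=config.min_qd,
        max_fs=config.max_fs,
    )
    d_surv, d_report = variants.deleteriousness_filter(
        q_surv,
        polyphen_min=config.polyphen_min,
        sift_max=config.sift_max,
        cadd_min=config.cadd_min,
        maf_max=config.maf_max,
    )
    io.write_variant_table(d_surv, filtered_dir / "survivors.tsv")
    io.write_filter_reports([q_report, d_report], filtered_dir / "filter_report.json")
    funnel = [
        {"stage": "input", "n": q_report.n_input},
        {"stage": "quality", "n": q_report.n_survivors},
        {"stage": "deleteriousness", "n": d_report.n_survivors},
    ]
    completed.append("filter")

    # --- genotype testing -------------------------------------------------
    gtest_dir = out / "gtest"
    gtest_dir.mkdir(exist_ok=True)
    results = genotest.test_variants(
        d_surv, cohort, exact_cap=config.exact_cap, mc_reps=config.mc_reps, mc_seed=config.seed
    )
    n_tests = len(results)
    by_key = {v.key: v for v in d_surv}
    with open(gtest_dir / "variant_tests.tsv", "w") as fh:
        fh.write(
            "chrom\tpos\tgene\trsid\tpolyphen2_hdiv\tsift\tcadd\tmaf_cases\tmaf_controls\tp_value\tp_bonferroni\tmethod\n"
        )
        for r in sorted(results, key=lambda r: r.p_value):
            v = by_key[r.key]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.gene}\t{v.rsid or '.'}\t{v.polyphen2_hdiv:.6f}\t"
                f"{v.sift:.6f}\t{v.cadd_phred:.4f}\t{r.maf_cases:.4f}\t{r.maf_controls:.4f}\t"
                f"{r.p_value:.6g}\t{min(1.0, r.p_value * n_tests):.6g}\t{r.method}\n"
            )
    n_nominal = sum(1 for r in results if r.p_value < 0.05)
    seeds = {
        s: genotest.select_seed_genes(s, d_surv, results, k=config.k_seed_genes)
        for s in cohort.samples
    }
    _write_json({s: list(seeds[s].genes) for s in sorted(seeds)}, gtest_dir / "seed_genes.json")
    completed.append("gtest")

    # --- per-sample networks ----------------------------------------------
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    sample_networks: dict[str, networks.SampleNetwork] = {}
    skipped: list[str] = []
    for s in cohort.samples:
        if not seeds[s].genes:
            skipped.append(s)
            log.info("sample %s: no qualifying gene; excluded", s)
            continue
        try:
            net = networks.build_sample_network(
                seeds[s],
                inter,
                max_path_length=config.max_path_length,
                keep_all_components=config.keep_all_components,
                include_imputed_edges=config.include_imputed_edges,
            )
        except EmptyNetworkError:
            skipped.append(s)
            log.info("sample %s: no seed maps onto the interactome; excluded", s)
            continue
        if net.graph.number_of_nodes() == 0:
            skipped.append(s)
            continue
        sample_networks[s] = net
        networks.write_graphml(net.graph, net_dir / f"{s}.graphml")
    completed.append("network")

    # --- clustering -------------------------------------------------------
    cluster_dir = out / "cluster"
    cluster_dir.mkdir(exist_ok=True)
    if len(sample_networks) < 2:
        raise InputError("fewer than 2 samples have a network; cannot cluster")
    dm = clustering.distance_matrix(sample_networks.values(), on=config.jaccard_on)
    with open(cluster_dir / "distances.tsv", "w") as fh:
        fh.write("sample\t" + "\t".join(dm.ids) + "\n")
        for i, s in enumerate(dm.ids):
            fh.write(s + "\t" + "\t".join(f"{x:.6f}" for x in dm.matrix[i]) + "\n")
    tree = clustering.upgma(dm)
    (cluster_dir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")

    clustered_cohort = io.Cohort(
        samples=[s for s in cohort.samples if s in sample_networks],
        status={s: cohort.status[s] for s in cohort.samples if s in sample_networks},
    )
    clusters = clustering.significant_clusters(
        tree,
        clustered_cohort,
        min_size=config.min_cluster_size,
        alpha=config.alpha,
        bonferroni=config.bonferroni,
    )
    cluster_rows = [
        {
            "node_id": c.node_id,
            "size": c.size,
            "n_cases": c.n_cases,
            "n_controls": c.n_controls,
            "p_value": c.p_value,
            "dominance": c.dominance,
            "significant": c.significant,
            "maximal": c.maximal,
        }
        for c in clusters
    ]
    _write_json(cluster_rows, cluster_dir / "clusters.json")
    with open(cluster_dir / "clusters.tsv", "w") as fh:
        fh.write("node_id\tsize\tn_cases\tn_controls\tp_value\tdominance\tsignificant\tmaximal\n")
        for row in cluster_rows:
            fh.write(
                f"{row['node_id']}\t{row['size']}\t{row['n_cases']}\t{row['n_controls']}\t"
                f"{row['p_value']:.6g}\t{row['dominance']}\t{row['significant']}\t{row['maximal']}\n"
            )
    completed.append("cluster")

    # --- headline clusters, layered networks, unique genes ----------------
    def _headline(dominance: str):
        cands = [c for c in clusters if c.maximal and c.dominance == dominance]
        if not cands:
            return None
        return max(cands, key=lambda c: (c.size, -c.node_id))

    case_cluster = _headline("case")
    control_cluster = _headline("control")
    unique_case: dict[str, str] = {}
    unique_control: dict[str, str] = {}
    sep_result = None
    ora_p = None
    comparison = None
    comparison_members: tuple[str, ...] = ()
    if case_cluster is not None:
        if control_cluster is not None:
            comparison = "control_cluster"
            comparison_members = control_cluster.members
        else:
            # no control-dominated node reached significance: compare the case
            # cluster against the remainder of the clustered cohort
            rest = tuple(s for s in sorted(sample_networks) if s not in case_cluster.members)
            if rest:
                comparison = "cohort_remainder"
                comparison_members = rest
    if case_cluster is not None and comparison is not None:
        layer_case = clustering.build_layered_network(case_cluster.members, sample_networks)
        layer_control = clustering.build_layered_network(comparison_members, sample_networks)
        networks.write_graphml(layer_case.graph, cluster_dir / "layered_case.graphml")
        networks.write_graphml(layer_control.graph, cluster_dir / "layered_control.graphml")
        unique_case, unique_control = clustering.unique_genes(layer_case, layer_control)
        other = "control" if comparison == "control_cluster" else "remainder"
        with open(cluster_dir / "unique_genes.tsv", "w") as fh:
            fh.write("gene\tcluster\timputed\n")
            for gene, role in unique_case.items():
                fh.write(f"{gene}\tcase\t{'Yes' if role == 'imputed' else 'No'}\n")
            for gene, role in unique_control.items():
                fh.write(f"{gene}\t{other}\t{'Yes' if role == 'imputed' else 'No'}\n")
        if len(set(unique_case) & set(inter.graph.nodes)) >= 2 and len(set(unique_control) & set(inter.graph.nodes)) >= 2:
            sep_result = separation.separation_score(set(unique_case), set(unique_control), inter)
            sep_result.to_json(out / "separation.json")
        if truth is not None:
            ora_p = separation.overrepresentation_test(
                set(unique_case), truth.module_genes, set(inter.graph.nodes)
            )
    completed.append("separation")

    # --- report -----------------------------------------------------------
    report = {
        "config": config.to_dict(),
        "funnel": funnel,
        "n_samples": len(cohort.samples),
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "n_samples_with_network": len(sample_networks),
        "samples_skipped": sorted(skipped),
        "genotype_tests": {"n_tested": n_tests, "n_nominal": n_nominal},
        "clusters": cluster_rows,
        "headline": {
            "case_cluster": None if case_cluster is None else cluster_rows[[c.node_id for c in clusters].index(case_cluster.node_id)],
            "control_cluster": None if control_cluster is None else cluster_rows[[c.node_id for c in clusters].index(control_cluster.node_id)],
            "comparison": comparison,
        },
        "unique_genes": {"case": unique_case, "other": unique_control},
        "separation": None if sep_result is None else asdict(sep_result),
        "module_recovery_p": ora_p,
    }
    _write_json(report, out / "report.json")
    _write_markdown_report(report, out / "report.md")
    completed.append("report")
    _write_json({"stages_completed": completed, "status": "ok"}, out / "manifest.json")
    return report


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = ["# cohortnet run report", ""]
    lines.append("## Variant funnel")
    for stage in report["funnel"]:
        lines.append(f"- {stage['stage']}: {stage['n']}")
    gt = report["genotype_tests"]
    lines.append("")
    lines.append("## Genotype testing")
    lines.append(f"- variants tested: {gt['n_tested']}; nominal (p < 0.05): {gt['n_nominal']}")
    lines.append("")
    lines.append(
        f"## Clustering ({report['n_samples_with_network']} of {report['n_samples']} samples with networks)"
    )
    lines.append("")
    lines.append("| node | size | cases | controls | p | dominance | significant | maximal |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for row in report["clusters"]:
        lines.append(
            f"| {row['node_id']} | {row['size']} | {row['n_cases']} | {row['n_controls']} | "
            f"{row['p_value']:.3g} | {row['dominance']} | {row['significant']} | {row['maximal']} |"
        )
    lines.append("")
    lines.append(f"## Unique genes (comparison: {report['headline']['comparison']})")
    for side in ("case", "other"):
        genes = report["unique_genes"][side]
        rendered = ", ".join(f"{g} ({r})" for g, r in genes.items()) or "(none)"
        lines.append(f"- {side}: {rendered}")
    sep = report["separation"]
    lines.append("")
    lines.append("## Separation")
    if sep is None:
        lines.append("- not computed (no pair of headline clusters with >= 2 mapped unique genes)")
    else:
        lines.append(
            f"- d_AA = {sep['d_aa']:.4g}, d_BB = {sep['d_bb']:.4g}, d_AB = {sep['d_ab']:.4g}, "
            f"s_AB = {sep['s_ab']:.4g}"
        )
    if report["module_recovery_p"] is not None:
        lines.append(f"- planted-module enrichment of case-unique genes: p = {report['module_recovery_p']:.3g}")
    path.write_text("\n".join(lines) + "\n")
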