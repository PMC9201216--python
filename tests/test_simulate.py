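"""Synthetic-cohort generator: interactome growth, module planting, cohorts."""

import json

import networkx as nx
import pytest

from cohortnet.errors import ConfigurationError, SimulationError
from cohortnet.simulate import (
    PlantedTruth,
    SimulationConfig,
    generate_cohort,
    generate_interactome,
    plant_disease_module,
)
from cohortnet.variants import deleteriousness_filter, quality_filter
from cohortnet import io

from conftest import make_interactome


def cfg(**kw):
    base = dict(
        n_cases=4, n_controls=4, n_interactome_nodes=50, attachment_degree=2,
        module_size=5, background_variants_per_sample=10, rng_seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateInteractome:
    def test_m1_growth_yields_tree(self):
        inter = generate_interactome(cfg(n_interactome_nodes=5, attachment_degree=1, module_size=2))
        assert inter.n_edges == 4
        assert nx.is_connected(inter.graph)
        assert nx.is_tree(inter.graph)

    def test_edge_count_follows_growth_rule(self):
        # m edges per added node: m * (n - m) edges in total
        inter = generate_interactome(cfg(n_interactome_nodes=6, attachment_degree=2))
        assert inter.n_edges == 2 * (6 - 2)
        inter = generate_interactome(cfg(n_interactome_nodes=200, attachment_degree=3))
        assert inter.n_edges == 3 * 197

    def test_connected_simple_and_scored(self):
        inter = generate_interactome(cfg(n_interactome_nodes=120, attachment_degree=3))
        assert nx.is_connected(inter.graph)
        assert not any(u == v for u, v in inter.graph.edges)
        scores = [s for _, _, s in inter.graph.edges(data="score")]
        assert all(isinstance(s, int) and 150 <= s <= 999 for s in scores)
        assert all(n.startswith("G") for n in inter.graph.nodes)

    def test_deterministic_given_seed(self):
        a = generate_interactome(cfg(rng_seed=42))
        b = generate_interactome(cfg(rng_seed=42))
        assert sorted(a.graph.edges(data="score")) == sorted(b.graph.edges(data="score"))
        c = generate_interactome(cfg(rng_seed=43))
        assert sorted(a.graph.edges(data="score")) != sorted(c.graph.edges(data="score"))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_cases", 0),
            ("n_interactome_nodes", -3),
            ("attachment_degree", 0),
            ("case_module_hit_rate", 1.5),
            ("fraction_deleterious_background", -0.1),
            ("module_size", 50),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        bad = cfg(**{field: value})
        with pytest.raises(ConfigurationError, match=field):
            generate_interactome(bad)


class TestPlantDiseaseModule:
    def test_single_gene_module(self):
        inter = generate_interactome(cfg())
        module = plant_disease_module(inter, 1, rng_seed=3)
        assert len(module) == 1

    def test_pair_on_path_graph_is_adjacent(self, path_interactome):
        # every connected 2-subset of a path graph is an adjacent pair
        for seed in range(10):
            module = plant_disease_module(path_interactome, 2, rng_seed=seed)
            a, b = sorted(module)
            assert path_interactome.graph.has_edge(a, b)

    def test_full_graph_module(self, path_interactome):
        module = plant_disease_module(path_interactome, 4, rng_seed=0)
        assert module == {"a", "b", "c", "d"}

    def test_module_induces_connected_subgraph(self):
        inter = generate_interactome(cfg(n_interactome_nodes=200, attachment_degree=3))
        for seed in range(5):
            module = plant_disease_module(inter, 12, rng_seed=seed)
            assert len(module) == 12
            assert nx.is_connected(inter.graph.subgraph(module))

    def test_component_too_small_raises(self):
        inter = make_interactome([("a", "b"), ("c", "d")])
        with pytest.raises(SimulationError):
            plant_disease_module(inter, 3, rng_seed=0)


class TestGenerateCohort:
    def test_degenerate_hit_rates(self, tmp_path):
        c = cfg(case_module_hit_rate=1.0, control_module_hit_rate=0.0)
        inter = generate_interactome(c)
        module = plant_disease_module(inter, c.module_size, c.rng_seed)
        _, _, phe, truth = generate_cohort(c, inter, module, tmp_path)
        cohort = io.read_cohort(phe)
        for s in cohort.cases:
            assert truth.hits[s], f"case {s} should carry a module hit"
        for s in cohort.controls:
            assert not truth.hits[s]

    def test_no_variants_when_everything_off(self, tmp_path):
        c = cfg(
            case_module_hit_rate=0.0, control_module_hit_rate=0.0,
            background_variants_per_sample=0, n_density_clusters=0,
        )
        # background_variants_per_sample=0 is allowed (count of extra draws)
        inter = generate_interactome(c)
        module = plant_disease_module(inter, c.module_size, c.rng_seed)
        vcf, ann, _, truth = generate_cohort(c, inter, module, tmp_path)
        assert truth.sites == {}
        assert io.read_variants(vcf, ann) == []

    def test_byte_identical_given_seed(self, tmp_path):
        c = cfg()
        inter = generate_interactome(c)
        module = plant_disease_module(inter, c.module_size, c.rng_seed)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(c, inter, module, d1)
        generate_cohort(c, inter, module, d2)
        for name in ("cohort.vcf", "annotations.tsv", "phenotypes.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_annotation_rows_match_truth_sites(self, tmp_path):
        c = cfg(rng_seed=11)
        inter = generate_interactome(c)
        module = plant_disease_module(inter, c.module_size, c.rng_seed)
        _, ann, _, truth = generate_cohort(c, inter, module, tmp_path)
        n_rows = len(open(ann).read().splitlines()) - 1
        assert n_rows == len(truth.sites)

    def test_truth_roundtrip(self, tmp_path):
        c = cfg()
        inter = generate_interactome(c)
        module = plant_disease_module(inter, c.module_size, c.rng_seed)
        generate_cohort(c, inter, module, tmp_path)
        truth = PlantedTruth.from_json(tmp_path / "truth.json")
        assert truth.module_genes == module
        assert all(set(h) <= module for h in truth.hits.values())

    def test_planted_flags_agree_with_deleteriousness_filter(self, tmp_path):
        c = cfg(rng_seed=5, background_variants_per_sample=30)
        inter = generate_interactome(c)
        module = plant_disease_module(inter, c.module_size, c.rng_seed)
        vcf, ann, _, truth = generate_cohort(c, inter, module, tmp_path)
        variants = io.read_variants(vcf, ann)
        survivors, _ = deleteriousness_filter(variants)
        assert {v.key for v in survivors} == truth.passing_site_keys()

    def test_quality_fail_flags_agree_with_quality_filter(self, tmp_path):
        c = cfg(rng_seed=9, background_variants_per_sample=60, quality_fail_rate=0.3)
        inter = generate_interactome(c)
        module = plant_disease_module(inter, c.module_size, c.rng_seed)
        vcf, ann, _, truth = generate_cohort(c, inter, module, tmp_path)
        variants = io.read_variants(vcf, ann)
        _, report = quality_filter(variants)
        flagged = {k for k, s in truth.sites.items() if s.quality_fails}
        assert set(report.failures) == flagged
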