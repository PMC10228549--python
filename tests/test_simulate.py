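"""Synthetic-data generator: determinism, identity control, clone
divergence, abundance structure."""

import numpy as np
import pytest

from cemag.community import bray_curtis
from cemag.homology import six_frame_translate
from cemag.records import GROUPS
from cemag.simulate import (
    SimConfig, make_pathway_catalog, mutate_protein, simulate_abundance,
    simulate_clone, simulate_cohort, simulate_derep_cohort, simulate_genome,
)


class TestCatalog:
    def test_fixed_roster_sizes(self, catalog):
        sizes = {p: len(r) for p, r in catalog.pathways.items()}
        assert sizes["lactic_acid_utilization"] == 3
        assert sizes["reverse_beta_oxidation"] == 4
        assert set(sizes) == {"homolactic", "phosphoketolase", "bifid_shunt",
                              "lactic_acid_utilization", "reverse_beta_oxidation"}

    def test_key_enzymes_named(self, catalog):
        lau = [e.enzyme for e in catalog.roster("lactic_acid_utilization")]
        assert lau == ["ecLDH", "EtfA", "EtfB"]
        rbo = [e.enzyme for e in catalog.roster("reverse_beta_oxidation")]
        assert "acetylCoA_C_acetyltransferase" in rbo
        assert "eb_acylCoA_dehydrogenase" in rbo

    def test_deterministic_under_seed(self):
        c1, c2 = make_pathway_catalog(9), make_pathway_catalog(9)
        assert [e.sequence for e in c1.enzymes] == [e.sequence for e in c2.enzymes]
        assert make_pathway_catalog(10).enzymes[0].sequence != c1.enzymes[0].sequence

    def test_all_enzymes_unique_across_pathways(self, catalog):
        assert all(e.is_unique for e in catalog.enzymes)


class TestSimulateGenome:
    def test_group_pathway_content(self, catalog, small_config):
        rng = np.random.default_rng(0)
        g, t = simulate_genome("ferment_to_intermediates", catalog, small_config, rng=rng)
        by_pathway = {}
        for pw, *_ in t.embedded_genes:
            by_pathway[pw] = by_pathway.get(pw, 0) + 1
        assert by_pathway.get("homolactic", 0) >= int(np.ceil(0.8 * 8))
        assert by_pathway.get("bifid_shunt", 0) >= int(np.ceil(0.8 * 10))
        assert by_pathway.get("reverse_beta_oxidation", 0) <= 1
        assert by_pathway.get("lactic_acid_utilization", 0) <= 1

    def test_uninvolved_at_most_one_per_pathway(self, catalog, small_config):
        rng = np.random.default_rng(1)
        _, t = simulate_genome("uninvolved", catalog, small_config, rng=rng)
        by_pathway = {}
        for pw, *_ in t.embedded_genes:
            by_pathway[pw] = by_pathway.get(pw, 0) + 1
        assert all(v <= 1 for v in by_pathway.values())

    def test_truth_coordinates_and_frame(self, catalog, small_config, ice_genome):
        """Every recorded gene lies within its contig, has length divisible
        by 3, and translating the recorded frame recovers a protein at the
        target identity (within 2 percentage points)."""
        genome, truth = ice_genome
        by_name = {e.enzyme: e.sequence for e in catalog.enzymes}
        by_name.update(catalog.extras)
        for pw, enzyme, contig, strand, frame, start, end, target in truth.embedded_genes:
            seq = genome.contigs[contig]
            assert 1 <= start < end <= len(seq)
            assert (end - start + 1) % 3 == 0
            gene = seq[start - 1 : end]
            prot = six_frame_translate(gene)[1 if strand == 1 else -1]
            ref = by_name[enzyme]
            assert len(prot) == len(ref)
            ident = sum(a == b for a, b in zip(prot, ref)) / len(ref)
            assert abs(100 * ident - 100 * target) <= 2.0

    def test_quality_metrics_in_study_bounds(self, catalog, small_config):
        rng = np.random.default_rng(2)
        for group in GROUPS:
            g, _ = simulate_genome(group, catalog, small_config, rng=rng)
            assert 75.0 <= g.completeness <= 100.0
            assert 0.0 <= g.contamination <= 7.5

    def test_contig_too_short_raises(self, catalog):
        cfg = SimConfig(seed=0, contig_length=900, n_contigs=1)
        with pytest.raises(ValueError, match="cannot fit"):
            simulate_genome("intermediate_ce", catalog, cfg)

    def test_unknown_group_rejected(self, catalog, small_config):
        with pytest.raises(ValueError, match="unknown group"):
            simulate_genome("methanogens", catalog, small_config)

    def test_cohort_byte_identical_under_seed(self):
        cfg = SimConfig(seed=33, n_genomes_per_group=1, contig_length=12_000, n_contigs=3)
        _, g1, t1 = simulate_cohort(cfg)
        _, g2, t2 = simulate_cohort(cfg)
        assert [g.contigs for g in g1] == [g.contigs for g in g2]
        assert [t.embedded_genes for t in t1] == [t.embedded_genes for t in t2]


class TestMutateProtein:
    def test_realized_identity_matches_target(self):
        rng = np.random.default_rng(4)
        prot = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 400))
        for target in (0.95, 0.8, 0.6, 0.4):
            mut = mutate_protein(prot, target, rng)
            ident = sum(a == b for a, b in zip(prot, mut)) / len(prot)
            assert abs(ident - target) <= 0.02


class TestSimulateClone:
    def test_zero_divergence_is_identical(self, ice_genome):
        genome, _ = ice_genome
        clone = simulate_clone(genome, 0.0, seed=1)
        assert list(clone.contigs.values()) == list(genome.contigs.values())

    def test_substitution_fraction_within_binomial_sd(self, ice_genome):
        genome, _ = ice_genome
        d = 0.005
        clone = simulate_clone(genome, d, seed=2)
        n = genome.size
        mismatches = sum(
            sum(a != b for a, b in zip(s1, s2))
            for s1, s2 in zip(genome.contigs.values(), clone.contigs.values())
        )
        sd = np.sqrt(d * (1 - d) / n)
        assert abs(mismatches / n - d) <= 3 * sd

    def test_divergence_bounds(self, ice_genome):
        with pytest.raises(ValueError):
            simulate_clone(ice_genome[0], 0.2, seed=0)


class TestDerepCohort:
    def test_counts_and_clone_ids(self):
        genomes, clone_ids = simulate_derep_cohort(
            n_total=12, n_duplicates=3, genome_length=5000, seed=5)
        assert len(genomes) == 12
        assert len(clone_ids) == 3
        assert all(cid.endswith("_dup") for cid in clone_ids)


@pytest.fixture(scope="module")
def table():
    from cemag.simulate import TruthRecord

    cfg = SimConfig(seed=8, n_genomes_per_group=3, contig_length=2000,
                    n_contigs=1, abundance_experiments=3, samples_per_experiment=4)
    truths = [TruthRecord(f"g{i}", "uninvolved") for i in range(12)]
    return simulate_abundance(truths, cfg)


class TestSimulateAbundance:
    def test_columns_sum_to_100(self, table):
        totals = table.abundance.sum(axis=0) + table.residual
        assert np.allclose(totals, 100.0, atol=1e-9)

    def test_within_experiment_bc_below_between(self, catalog):
        from cemag.simulate import TruthRecord
        truths = [TruthRecord(f"g{i}", "uninvolved") for i in range(15)]
        within_wins = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, abundance_experiments=2, samples_per_experiment=2)
            t = simulate_abundance(truths, cfg)
            cols = t.abundance.columns
            exp = t.experiment_of()
            within, between = [], []
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    bc = bray_curtis(t.abundance[cols[i]], t.abundance[cols[j]])
                    (within if exp.iloc[i] == exp.iloc[j] else between).append(bc)
            if np.mean(within) < np.mean(between):
                within_wins += 1
        assert within_wins >= 9

    def test_high_concentration_limit(self, catalog):
        from cemag.simulate import TruthRecord
        truths = [TruthRecord(f"g{i}", "uninvolved") for i in range(10)]
        cfg = SimConfig(seed=3, abundance_experiments=2, samples_per_experiment=2,
                        dirichlet_concentration=1e7, residual_range=(10.0, 10.0))
        t = simulate_abundance(truths, cfg)
        exp = t.experiment_of()
        for e in exp.unique():
            cols = exp.index[exp == e]
            bc = bray_curtis(t.abundance[cols[0]], t.abundance[cols[1]])
            assert bc < 0.02

    def test_needs_two_experiments(self):
        from cemag.simulate import TruthRecord
        cfg = SimConfig(seed=0, abundance_experiments=1)
        with pytest.raises(ValueError):
            simulate_abundance([TruthRecord("g", "uninvolved")], cfg)
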