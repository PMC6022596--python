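"""Generators: construction contracts, determinism, and sampling oracles."""

import math

import numpy as np
import pytest

from pavcomp.io import reverse_complement
from pavcomp.synthetic import (
    build_reference_panel,
    plant_annotation,
    plant_msa,
    plant_query_genome,
    simulate_reads,
)


class TestReferencePanel:
    def test_single_copy_per_species(self):
        catalog, groups = build_reference_panel(5, 300, (300, 1500), 0.05, seed=42)
        assert len(catalog.species) == 5
        assert len(groups) == 300
        assert len(catalog) == 5 * 300
        for _gid, members in groups.items():
            assert len(members) == 5
            assert all(len(genes) == 1 for genes in members.values())

    def test_zero_divergence_gives_identical_members(self):
        catalog, groups = build_reference_panel(2, 1, (300, 300), 0.0, seed=1)
        gid = next(iter(groups))
        seqs = [
            catalog.genes(sp)[genes[0]]
            for sp, genes in groups.members(gid).items()
        ]
        assert seqs[0] == seqs[1]
        assert len(seqs[0]) == 300

    def test_pairwise_divergence_matches_mutation_model(self):
        """Observed mismatch fraction within groups agrees with the i.i.d.
        substitution model: two copies mutated independently at rate d from
        one ancestor disagree per site with probability 1 - [(1-d)^2 + d^2/3].
        """
        d = 0.05
        catalog, groups = build_reference_panel(2, 300, (300, 600), d, seed=9)
        expected = 1 - ((1 - d) ** 2 + d**2 / 3)
        mismatches = sites = 0
        for gid, members in groups.items():
            (sp_a, [ga]), (sp_b, [gb]) = sorted(members.items())
            a, b = catalog.genes(sp_a)[ga], catalog.genes(sp_b)[gb]
            mismatches += sum(x != y for x, y in zip(a, b))
            sites += len(a)
        observed = mismatches / sites
        se = math.sqrt(expected * (1 - expected) / sites)
        assert abs(observed - expected) <= 3 * se

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_species=1, n_groups=10, gene_length_range=(300, 600)),
            dict(n_species=2, n_groups=0, gene_length_range=(300, 600)),
            dict(n_species=2, n_groups=10, gene_length_range=(600, 300)),
            dict(n_species=2, n_groups=10, gene_length_range=(300, 600),
                 interspecies_divergence=0.7),
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            build_reference_panel(seed=0, **kwargs)


@pytest.fixture(scope="module")
def panel():
    return build_reference_panel(3, 100, (300, 600), 0.05, seed=3)


class TestQueryGenome:

    @pytest.mark.parametrize("loss,expected", [(0.2, 20), (0.0, 0), (0.35, 35)])
    def test_planted_loss_count(self, panel, loss, expected):
        catalog, groups = panel
        _genome, truth = plant_query_genome(catalog, groups, loss, seed=5)
        assert len(truth.lost_groups) == expected
        # conservation: every group has exactly one status
        assert len(truth.present_groups) + len(truth.lost_groups) == len(groups)
        assert set(truth.group_status) == set(groups)

    def test_same_seed_is_byte_identical(self, panel):
        catalog, groups = panel
        g1, t1 = plant_query_genome(catalog, groups, 0.2, seed=11)
        g2, t2 = plant_query_genome(catalog, groups, 0.2, seed=11)
        assert g1 == g2
        assert t1.group_status == t2.group_status

    def test_retained_groups_have_homologous_sequence(self, panel):
        """At zero query divergence each retained gene appears verbatim."""
        catalog, groups = panel
        genome, truth = plant_query_genome(
            catalog, groups, 0.3, query_divergence=0.0, seed=2
        )
        for gid in sorted(truth.present_groups)[:10]:
            members = groups.members(gid)
            sp = sorted(members)[0]
            assert catalog.genes(sp)[members[sp][0]] in genome
        for gid in sorted(truth.lost_groups)[:10]:
            members = groups.members(gid)
            sp = sorted(members)[0]
            assert catalog.genes(sp)[members[sp][0]] not in genome

    def test_empty_catalog_raises(self):
        from pavcomp.cluster import OrthoGroupSet
        from pavcomp.io import CdsCatalog

        with pytest.raises(ValueError):
            plant_query_genome(CdsCatalog(), OrthoGroupSet({}), 0.2, seed=0)


class TestSimulateReads:
    @pytest.mark.parametrize(
        "glen,depth,rlen,expected",
        [(100_000, 30, 150, 10_000), (10_000, 7.5, 100, 375), (5_000, 1, 150, 17)],
    )
    def test_pair_count_formula(self, glen, depth, rlen, expected):
        genome = "AC" * (glen // 2)
        pairs = simulate_reads(genome, depth, rlen, insert_mean=400, seed=1)
        assert len(pairs) == expected == math.ceil(depth * glen / (2 * rlen))

    def test_error_free_reads_are_genome_substrings(self, rng):
        genome = rng.choice(list("ACGT"), size=20_000).tolist()
        genome = "".join(genome)
        pairs = simulate_reads(genome, 2, 150, 400, error_rate=0.0, seed=4)
        for (_, fwd, _), (_, rev, _) in pairs:
            assert fwd in genome
            assert reverse_complement(rev) in genome

    def test_mean_depth_matches_uniform_sampling_oracle(self, rng):
        """Per-base depth over interior positions is Binomial(n_pairs, p) with
        p = 2 * read_len / n_start_positions; the observed mean must sit
        within 3 standard errors of the target depth."""
        glen, depth, rlen, insert = 40_000, 30, 150, 400
        genome = "".join(rng.choice(list("ACGT"), size=glen).tolist())
        pairs = simulate_reads(genome, depth, rlen, insert, seed=8)
        cov = np.zeros(glen)
        # reconstruct fragment starts from error-free reads
        n_starts = glen - insert + 1
        p_cover = 2 * rlen / n_starts
        for (_, fwd, _), (_, rev, _) in pairs:
            s = genome.index(fwd)
            cov[s : s + rlen] += 1
            e = genome.index(reverse_complement(rev))
            cov[e : e + rlen] += 1
        interior = cov[insert : glen - insert]
        expected = len(pairs) * p_cover
        se = math.sqrt(len(pairs) * p_cover * (1 - p_cover) / interior.size)
        assert abs(interior.mean() - expected) <= 3 * se
        # genome-wide mean depth is fixed by the pair-count formula
        genome_wide = 2 * rlen * len(pairs) / glen
        assert genome_wide == pytest.approx(depth, rel=0.01)

    def test_bad_depth_raises(self):
        with pytest.raises(ValueError):
            simulate_reads("ACGT" * 1000, depth=0, read_length=150, insert_mean=400)

    def test_quality_is_constant_placeholder(self):
        pairs = simulate_reads("ACGT" * 1000, 1, 100, 200, seed=0)
        assert all(q == "I" * 100 for pair in pairs for _, _, q in pair)


class TestPlantMsa:
    def test_planted_column_count(self):
        msa, truth = plant_msa(17, 3, 120, 9, 0.0, seed=7)
        assert len(truth.planted_columns) == 9
        assert len(msa.sequences) == 20
        assert msa.length == 120
        assert all(1 <= c <= 120 for c in truth.planted_columns)

    def test_no_planted_columns(self):
        _msa, truth = plant_msa(5, 2, 50, 0, 0.0, seed=1)
        assert truth.planted_columns == []

    def test_planted_columns_have_the_signature(self):
        msa, truth = plant_msa(6, 3, 80, 5, 0.2, seed=3)
        for col in truth.planted_columns:
            residues = msa.column(col)
            bg = {residues[t] for t in msa.background}
            fg = {residues[t] for t in msa.foreground}
            assert len(bg) == 1 and len(fg) == 1 and bg != fg

    def test_zero_foreground_raises(self):
        with pytest.raises(ValueError):
            plant_msa(5, 0, 50, 2, 0.0, seed=0)

    def test_determinism(self):
        a, ta = plant_msa(8, 3, 100, 4, 0.3, seed=13)
        b, tb = plant_msa(8, 3, 100, 4, 0.3, seed=13)
        assert a.sequences == b.sequences
        assert ta.planted_columns == tb.planted_columns


class TestPlantAnnotation:
    def test_single_root(self):
        dag, _ann, _truth = plant_annotation(200, 20, 3, foreground=20, seed=2)
        assert len(dag.roots) == 1

    def test_odds_one_plants_nothing(self):
        _dag, _ann, truth = plant_annotation(
            200, 20, 3, foreground=20, enriched_terms=5, effect_odds=1.0, seed=2
        )
        assert truth.enriched_terms == {}

    def test_invalid_depth_raises(self):
        with pytest.raises(ValueError):
            plant_annotation(100, 10, 0, foreground=10, seed=0)

    def test_annotations_propagated_to_root(self):
        dag, ann, _ = plant_annotation(100, 15, 2, foreground=10, seed=5)
        root = dag.roots[0]
        for gene, terms in ann.direct.items():
            if terms:
                assert root in ann.propagated[gene]
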