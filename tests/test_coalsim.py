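"""Coalescent simulator: moments, determinism, growth, sequence embedding."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from coihap.coalsim import (
    CoalescentParams,
    SurveyConfig,
    _rng,
    drop_mutations,
    make_anchor,
    realize_sequences,
    simulate_genealogy,
    simulate_survey,
)
from coihap.haplotypes import diversity_summary
from coihap.neutrality import harmonic, tajima_d
from coihap.seqio import write_fasta, write_metadata


def tmrca_sample(n, reps, seed, growth=0.0):
    rng = _rng(seed)
    p = CoalescentParams(n=n, mode="fixed_S", S=1, growth=growth)
    return np.array([simulate_genealogy(p, rng=rng).tmrca for _ in range(reps)])


class TestGenealogy:
    def test_pair_tmrca_mean_is_one(self):
        tm = tmrca_sample(2, 20000, seed=11)
        se = tm.std() / np.sqrt(len(tm))
        assert abs(tm.mean() - 1.0) < 3 * se

    def test_n10_tmrca_mean_is_1_8(self):
        tm = tmrca_sample(10, 20000, seed=12)
        se = tm.std() / np.sqrt(len(tm))
        assert abs(tm.mean() - 1.8) < 3 * se

    def test_growth_inflates_external_branch_share(self):
        rng0, rng1 = _rng(21), _rng(22)
        p0 = CoalescentParams(n=20, mode="fixed_S", S=1, growth=0.0)
        p1 = CoalescentParams(n=20, mode="fixed_S", S=1, growth=100.0)

        def ext_share(p, rng, reps=300):
            shares = []
            for _ in range(reps):
                g = simulate_genealogy(p, rng=rng)
                ext = sum(
                    L for mask, L in g.branches if mask.sum() == 1
                )
                shares.append(ext / g.total_length)
            return np.mean(shares)

        assert ext_share(p1, rng1) > ext_share(p0, rng0)

    def test_g_zero_path_matches_small_g_limit_in_distribution(self):
        a = tmrca_sample(10, 5000, seed=31, growth=0.0)
        b = tmrca_sample(10, 5000, seed=32, growth=1e-9)
        assert ks_2samp(a, b).pvalue > 0.01

    def test_topology_bookkeeping(self):
        g = simulate_genealogy(CoalescentParams(n=8, mode="fixed_S", S=1, seed=5))
        assert len(g.events) == 7  # n-1 internal nodes
        assert len(g.branches) == 14  # 2n-2 non-root lineages
        assert g.total_length == pytest.approx(sum(L for _, L in g.branches))
        assert all(L > 0 for _, L in g.branches)

    def test_matches_msprime_tmrca_distribution(self):
        msprime = pytest.importorskip("msprime")
        ours = tmrca_sample(10, 3000, seed=41)
        theirs = np.array([
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=10, ploidy=1, population_size=1.0,
                num_replicates=3000, random_seed=99,
            )
        ])
        assert ks_2samp(ours, theirs).pvalue > 0.01


class TestMutations:
    def test_s_zero_gives_identical_haplotypes(self):
        g = simulate_genealogy(CoalescentParams(n=5, mode="fixed_S", S=0, seed=1))
        mat = drop_mutations(g, "fixed_S", 0, seed=1)
        assert mat.shape == (0, 5)
        aln = realize_sequences(mat, make_anchor(60), seed=1)
        assert len(set(aln.sequences())) == 1

    def test_fixed_s_columns_are_polymorphic(self):
        rng = _rng(8)
        for _ in range(50):
            g = simulate_genealogy(
                CoalescentParams(n=4, mode="fixed_S", S=5), rng=rng
            )
            mat = drop_mutations(g, "fixed_S", 5, rng=rng)
            x = mat.sum(axis=1)
            assert ((x >= 1) & (x <= 3)).all()

    def test_watterson_expectation_fixed_theta(self):
        theta, n, reps = 2.0, 10, 20000
        rng = _rng(13)
        p = CoalescentParams(n=n, mode="fixed_theta", theta=theta)
        S = np.empty(reps)
        for r in range(reps):
            g = simulate_genealogy(p, rng=rng)
            S[r] = drop_mutations(g, "fixed_theta", theta, rng=rng).shape[0]
        se = S.std() / np.sqrt(reps)
        assert abs(S.mean() - theta * harmonic(n)) < 3 * se


class TestRealization:
    def test_diversity_recovers_s_exactly(self):
        rng = _rng(3)
        g = simulate_genealogy(CoalescentParams(n=12, mode="fixed_S", S=15), rng=rng)
        mat = drop_mutations(g, "fixed_S", 15, rng=rng)
        aln = realize_sequences(mat, make_anchor(), seed=3)
        assert diversity_summary(aln).S == 15

    def test_statistics_equal_on_matrix_and_sequences(self):
        from coihap.neutrality import _suff_from_matrix

        rng = _rng(17)
        g = simulate_genealogy(CoalescentParams(n=10, mode="fixed_S", S=12), rng=rng)
        mat = drop_mutations(g, "fixed_S", 12, rng=rng)
        aln = realize_sequences(mat, make_anchor(), seed=17)
        ds = diversity_summary(aln)
        S, eta_s, U, k = _suff_from_matrix(mat)
        assert (ds.S, ds.eta_s) == (S, eta_s)
        assert ds.k == pytest.approx(k)
        assert sorted(ds.U) == sorted(U)

    def test_too_many_mutations_rejected(self):
        g = simulate_genealogy(CoalescentParams(n=4, mode="fixed_S", S=10, seed=2))
        mat = drop_mutations(g, "fixed_S", 10, seed=2)
        with pytest.raises(ValueError):
            realize_sequences(mat, "ACGTACGT", seed=2)

    def test_anchor_is_stop_free_in_frame_zero(self):
        from Bio.Data import CodonTable

        stops = set(CodonTable.unambiguous_dna_by_id[5].stop_codons)
        anchor = make_anchor()
        assert len(anchor) == 504
        codons = {anchor[i : i + 3] for i in range(0, 504, 3)}
        assert not codons & stops


class TestSurvey:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SurveyConfig(seed=6, sites_per_zone=3)
        for tag in ("a", "b"):
            sv = simulate_survey(cfg)
            write_fasta(sv.alignment, tmp_path / f"{tag}.fasta")
            write_metadata(sv.alignment, tmp_path / f"{tag}.tsv")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_survey(SurveyConfig(seed=1, sites_per_zone=3))
        b = simulate_survey(SurveyConfig(seed=2, sites_per_zone=3))
        assert a.alignment.sequences() != b.alignment.sequences()

    def test_pure_mixture_yields_one_label(self):
        from coihap.coalsim import SpeciesPoolConfig
        from coihap.species import assign_species

        cfg = SurveyConfig(
            seed=4, sites_per_zone=2,
            hosts={"cassava": 1.0},
            mixtures={"cassava": {"OnlyA": 1.0}},
            species=[SpeciesPoolConfig("OnlyA", S=10)],
        )
        sv = simulate_survey(cfg)
        calls = assign_species(sv.alignment, sv.panel)
        assert all(c.best_label == "OnlyA" for c in calls)

    def test_invasive_group_shows_expansion_signature(self):
        sv = simulate_survey(SurveyConfig(seed=10))
        from coihap.seqio import Alignment

        inv = Alignment([
            r for r in sv.alignment if sv.true_labels[r.id] == "SSA1-SG1"
        ])
        res = Alignment([
            r for r in sv.alignment if sv.true_labels[r.id] == "SSA1-SG2"
        ])
        d_inv = tajima_d(diversity_summary(inv)).value
        d_res = tajima_d(diversity_summary(res)).value
        assert d_inv < -1.5  # star pool: strong excess of rare variants
        assert d_inv < d_res

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SurveyConfig(mixtures={"cassava": {"A": 0.5, "B": 0.2}})
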