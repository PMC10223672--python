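import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viropan.evolstats import (
    K2PMatrix,
    core_concat_distances,
    delimit_species,
    evolve_k2p,
    identity_similarity,
    k2p,
    shuffle_protein,
    zscore,
    zscore_from_stats,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestIdentitySimilarity:
    def test_self_pair_is_100_100(self):
        assert identity_similarity("MKVLAWGHED", "MKVLAWGHED") == (100.0, 100.0)

    def test_hand_counted_ten_column_alignment(self):
        # gapless 10-column alignment: 6 identities, K/R and I/L are the
        # only positive-scoring substitutions, A/W and G/P score negative
        a = "CCWDHPKIAG"
        b = "CCWDHPRLWP"
        ident, sim = identity_similarity(a, b)
        assert ident == pytest.approx(60.0)
        assert sim == pytest.approx(80.0)

    def test_symmetry_and_ordering(self):
        rng = random.Random(42)
        for _ in range(10):
            a = "".join(rng.choice(AA) for _ in range(40))
            b = "".join(rng.choice(AA) for _ in range(35))
            ia, sa = identity_similarity(a, b)
            ib, sb = identity_similarity(b, a)
            assert ia == pytest.approx(ib)
            assert sa >= ia


class TestShuffle:
    def test_homopolymer_fixed_point(self):
        assert shuffle_protein("AAAA", seed=1) == "AAAA"

    @given(st.text(alphabet=AA, min_size=1, max_size=60), st.integers(0, 2**30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_composition_preserved(self, seq, seed):
        assert sorted(shuffle_protein(seq, seed)) == sorted(seq)

    def test_seed_reproducibility_and_difference(self):
        rng = random.Random(0)
        seq = "".join(rng.choice(AA) for _ in range(100))
        assert shuffle_protein(seq, 1) == shuffle_protein(seq, 1)
        assert shuffle_protein(seq, 1) != shuffle_protein(seq, 2)


class TestZScore:
    def test_equation_identity_zero(self):
        assert zscore_from_stats(50.0, 50.0, 3.0) == 0.0

    def test_equation_identity_one(self):
        assert zscore_from_stats(53.0, 50.0, 3.0) == 1.0

    def test_zero_sd_is_undefined(self):
        assert math.isnan(zscore_from_stats(10.0, 5.0, 0.0))

    def test_related_pair_high_unrelated_low(self, small_truth, small_genomes):
        by_qid = {
            p.qualified_id: p.aa_sequence
            for g in small_genomes
            for p in g.annotated_proteins
        }
        fam = {}
        for gene in small_truth.genes:
            if gene.label == "core" and gene.qualified_id in by_qid:
                fam.setdefault(gene.family_id, []).append(by_qid[gene.qualified_id])
        members = sorted(fam[sorted(fam)[0]])
        # same genus pair (first two sorted ids share the genus prefix)
        related = zscore(members[0], members[1], n_shuffles=50, seed=7)
        assert related.z > 5

        rng = random.Random(7)
        u1 = "".join(rng.choice(AA) for _ in range(120))
        u2 = "".join(rng.choice(AA) for _ in range(110))
        unrelated = zscore(u1, u2, n_shuffles=50, seed=7)
        assert abs(unrelated.z) < 3

    def test_self_zscore_strictly_positive(self):
        rng = random.Random(3)
        seq = "".join(rng.choice(AA) for _ in range(80))
        result = zscore(seq, seq, n_shuffles=30, seed=1)
        assert result.z > 0

    def test_seeded_reproducibility(self):
        rng = random.Random(1)
        a = "".join(rng.choice(AA) for _ in range(60))
        b = "".join(rng.choice(AA) for _ in range(60))
        r1 = zscore(a, b, n_shuffles=25, seed=11)
        r2 = zscore(a, b, n_shuffles=25, seed=11)
        assert (r1.S_natS, r1.A_shfS_natS, r1.s, r1.z) == (
            r2.S_natS,
            r2.A_shfS_natS,
            r2.s,
            r2.z,
        )

    def test_identity_links_fields(self):
        rng = random.Random(4)
        a = "".join(rng.choice(AA) for _ in range(50))
        b = "".join(rng.choice(AA) for _ in range(50))
        r = zscore(a, b, n_shuffles=20, seed=2)
        assert r.z == pytest.approx((r.S_natS - r.A_shfS_natS) / r.s)

    def test_below_zero_fraction_near_half_for_unrelated(self):
        # the shuffle null is centred: unrelated pairs fall below zero
        # about half the time
        rng = random.Random(99)
        below = 0
        n = 40
        for _ in range(n):
            a = "".join(rng.choice(AA) for _ in range(60))
            b = "".join(rng.choice(AA) for _ in range(60))
            if zscore(a, b, n_shuffles=25, seed=rng.randrange(2**30)).z < 0:
                below += 1
        assert 0.25 <= below / n <= 0.75


class TestK2P:
    def test_identical_sequences(self):
        res = k2p("ACGTACGT", "ACGTACGT")
        assert (res.P, res.Q, res.d) == (0.0, 0.0, 0.0)

    def test_single_transition_closed_form(self):
        res = k2p("AAAA", "GAAA")
        assert res.P == pytest.approx(0.25)
        assert res.Q == 0.0
        assert res.d == pytest.approx(-0.5 * math.log(0.5), abs=1e-9)

    def test_gaps_and_ambiguity_excluded(self):
        res = k2p("A-GTN", "AAGTA")
        assert res.n_sites == 3

    def test_saturated_pair_is_undefined(self):
        res = k2p("AAAA", "GGGG")
        assert math.isnan(res.d)

    def test_estimator_consistency_at_d_03(self):
        rng = np.random.default_rng(1234)
        length = 100_000
        anc = "".join(rng.choice(list("ACGT"), size=length))
        evolved = evolve_k2p(anc, d=0.3, kappa=2.0, rng=rng)
        res = k2p(anc, evolved)
        assert res.d == pytest.approx(0.3, abs=0.01)

    def test_first_order_taylor_limit(self):
        # at tiny divergence, d -> P + Q
        n = 1_000_000
        n_ts, n_tv = 60, 40  # P + Q = 1e-4
        a = "A" * n
        b = "G" * n_ts + "C" * n_tv + "A" * (n - n_ts - n_tv)
        res = k2p(a, b)
        assert res.d == pytest.approx((n_ts + n_tv) / n, abs=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            k2p("ACGT", "ACG")


def _matrix_from_dense(ids, d):
    d = np.asarray(d, dtype=float)
    return K2PMatrix(
        ids=list(ids),
        d=d,
        P=np.zeros_like(d),
        Q=np.zeros_like(d),
        n_sites=np.full(d.shape, 100, dtype=int),
    )


class TestDelimitSpecies:
    def test_all_zero_distances_one_species(self):
        m = _matrix_from_dense("abc", np.zeros((3, 3)))
        part = delimit_species(m, low=0.015, high=0.05)
        assert part.n_species == 1

    def test_two_distant_clusters(self):
        d = np.array(
            [
                [0.0, 0.001, 0.9, 0.9],
                [0.001, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.001],
                [0.9, 0.9, 0.001, 0.0],
            ]
        )
        part = delimit_species(_matrix_from_dense("wxyz", d), low=0.015, high=0.05)
        assert part.n_species == 2
        assert part.assignment["w"] == part.assignment["x"]
        assert part.assignment["y"] == part.assignment["z"]
        assert not part.borderline

    def test_all_distant_singletons(self):
        d = np.full((4, 4), 0.8)
        np.fill_diagonal(d, 0.0)
        part = delimit_species(_matrix_from_dense("wxyz", d), low=0.015, high=0.05)
        assert part.n_species == 4

    def test_borderline_band_is_flagged(self):
        d = np.array([[0.0, 0.03], [0.03, 0.0]])
        part = delimit_species(_matrix_from_dense("ab", d), low=0.015, high=0.05)
        assert part.n_species == 2
        assert part.borderline == [("a", "b")]

    def test_isolate_order_invariance(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 0.2, size=(6, 6))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = list("abcdef")
        p1 = delimit_species(_matrix_from_dense(ids, d))
        perm = [3, 1, 5, 0, 2, 4]
        d2 = d[np.ix_(perm, perm)]
        p2 = delimit_species(_matrix_from_dense([ids[i] for i in perm], d2))
        clusters1 = {frozenset(c) for c in p1.clusters()}
        clusters2 = {frozenset(c) for c in p2.clusters()}
        assert clusters1 == clusters2


class TestCoreConcatDistances:
    def test_matrix_is_symmetric_zero_diagonal(self, small_run, small_genomes):
        catalogue, _ = small_run
        mat = core_concat_distances(catalogue, small_genomes)
        assert np.allclose(mat.d, mat.d.T)
        assert np.allclose(np.diag(mat.d), 0.0)

    def test_between_genus_exceeds_within(self, small_run, small_genomes):
        catalogue, _ = small_run
        mat = core_concat_distances(catalogue, small_genomes)
        taxa = {g.genome_id: g.taxon for g in small_genomes}
        summary = mat.taxon_summary(taxa)
        within = summary[summary.kind == "within"]["median"].max()
        between = summary[summary.kind == "between"]["median"].min()
        assert between > within

    def test_missing_core_member_raises(self, small_run, small_genomes):
        catalogue, _ = small_run
        broken = catalogue.core_groups[0].copy()
        victim = sorted(broken.members)[0]
        del broken.members[victim]
        with pytest.raises(ValueError, match=victim):
            core_concat_distances(catalogue, small_genomes, core_ids=None) \
                if False else core_concat_distances(
                    type(catalogue)(
                        groups=[broken],
                        unique_genes=[],
                        n_genomes=catalogue.n_genomes,
                        taxa=catalogue.taxa,
                        proteins=catalogue.proteins,
                    ),
                    small_genomes,
                    core_ids=[broken.group_id],
                )

    def test_identical_genomes_zero_distance(self, small_run, small_genomes):
        catalogue, _ = small_run
        mat = core_concat_distances(catalogue, small_genomes)
        # same-species isolates differ only by silent substitutions
        i = mat.ids.index("alpha_sp1_i1")
        j = mat.ids.index("alpha_sp1_i2")
        assert mat.d[i, j] < 0.015

    def test_newick_output_contains_all_ids(self, small_run, small_genomes):
        catalogue, _ = small_run
        mat = core_concat_distances(catalogue, small_genomes)
        newick = mat.neighbor_joining_newick()
        assert all(gid in newick for gid in mat.ids)
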