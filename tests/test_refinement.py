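import math

import pytest

from viropan.groups import OrthoGroup
from viropan.refinement import (
    ProfileCache,
    ProteinIndex,
    _set_members,
    classify_catalogue,
    iterate_pr2,
    iterate_pr4,
    merge_by_profile,
    merge_groups,
    partition_ok,
    rescue_by_search,
    synteny_support,
    tblastn_like,
)
from viropan.similarity import AlignmentScorer
from viropan.synthetic_data import SimulationConfig, simulate_dataset
from oracles import transitive_closure_groups


def _group(gid, members, stage="PR2"):
    grp = OrthoGroup(group_id=gid)
    for genome, pid in members.items():
        grp.members[genome] = pid
    grp.tag(stage, "fixture")
    return grp


def _index_for(pids):
    """A minimal stand-in index: genome of 'G|p' is 'G'."""

    class FakeIndex:
        def genome_of(self, qid):
            return qid.split("|")[0]

    return FakeIndex()


def _truth_groups(truth, index, labels=("core", "genus")):
    groups = []
    for family, members in sorted(truth.families().items()):
        present = [
            m for m in members if m.label in labels and m.qualified_id in index.records
        ]
        if len(present) < 2:
            continue
        grp = OrthoGroup(group_id=family)
        _set_members(grp, [m.qualified_id for m in present], index)
        grp.tag("PR1", "truth")
        groups.append(grp)
    return groups


class TestMergeGroups:
    def test_shared_protein_chain_merges(self):
        g1 = _group("OG1", {"A": "A|1", "B": "B|1"})
        g2 = _group("OG2", {"B": "B|1", "C": "C|1"})
        merged = merge_groups([g1, g2], _index_for(None))
        assert len(merged) == 1
        assert merged[0].protein_ids == {"A|1", "B|1", "C|1"}

    def test_duplicate_genome_blocks_merge(self):
        g1 = _group("OG1", {"A": "A|1", "B": "B|1"})
        g2 = _group("OG2", {"A": "A|2", "B": "B|1", "C": "C|1"})
        merged = merge_groups([g1, g2], _index_for(None))
        # never combined: the union would carry two A-proteins
        assert all(
            len([p for p in g.protein_ids if p.startswith("A|")]) <= 1 for g in merged
        )
        assert len(merged) == 2
        # the shared protein stays with the lexicographically first group
        claims = [g for g in merged if "B|1" in g.protein_ids]
        assert len(claims) == 1 and claims[0].group_id == "OG1"

    def test_closure_matches_bruteforce(self):
        chains = [
            {"A|1", "B|1"},
            {"B|1", "C|1"},
            {"C|1", "D|1"},
            {"E|1", "F|1"},
        ]
        groups = []
        for i, members in enumerate(chains):
            grp = OrthoGroup(group_id=f"OG{i}")
            for pid in sorted(members):
                grp.members[pid.split("|")[0]] = pid
            grp.tag("PR2", "fixture")
            groups.append(grp)
        merged = merge_groups(groups, _index_for(None))
        expected = {frozenset(s) for s in transitive_closure_groups(chains)}
        assert {frozenset(g.protein_ids) for g in merged} == expected


@pytest.fixture(scope="module")
def refined_setup(small_genomes, small_truth):
    index = ProteinIndex(small_genomes)
    cache = ProfileCache(index)
    groups = _truth_groups(small_truth, index)
    return index, cache, groups


class TestIteratePr2:
    def test_consistent_groups_are_fixed_points(self, refined_setup):
        index, cache, groups = refined_setup
        out = iterate_pr2(groups, index, cache=cache)
        assert {g.group_id for g in out} == {g.group_id for g in groups}
        for before, after in zip(
            sorted(groups, key=lambda g: g.group_id),
            sorted(out, key=lambda g: g.group_id),
        ):
            assert after.protein_ids >= before.protein_ids
            assert after.stage_tag == "PR2"

    def test_empty_input_is_empty_output(self, refined_setup):
        index, cache, _ = refined_setup
        assert iterate_pr2([], index, cache=cache) == []

    def test_group_with_unrecoverable_founder_is_discarded(self, small_genomes):
        from viropan.genomes import ProteinRecord

        # a private index so the planted fragment does not leak into the
        # module-scoped fixtures
        index = ProteinIndex(small_genomes)
        cache = ProfileCache(index)
        truth_like = None
        for pid in sorted(index.records):
            if "core00" in pid:
                truth_like = pid
                break
        group = OrthoGroup(group_id="OGBAD")
        members = sorted(p for p in index.records if "core00" in p)
        _set_members(group, members, index)
        group.tag("PR1", "fixture")
        # an 8-residue fragment cannot be recovered at e-value 0.01 even by
        # a profile that includes it, so the founder check must fire
        fragment = ProteinRecord(
            protein_id="frag", genome_id="zz_art", aa_sequence="MWHQCKDE",
            cds_start=1, cds_end=27, strand="+",
        )
        index.genomes["zz_art"] = index.genomes[sorted(index.genomes)[0]]
        index.add(fragment)
        group.members["zz_art"] = fragment.qualified_id
        out = iterate_pr2([group], index, cache=cache)
        assert out == []


class TestIteratePr4:
    def test_full_coverage_stops_immediately(self, refined_setup):
        index, cache, groups = refined_setup
        full = [g for g in groups if len(g.members) == index.n_genomes][0].copy()
        before = set(full.protein_ids)
        out = iterate_pr4([full], index, cache=cache)
        assert out[0].protein_ids == before
        assert out[0].history[-1] == ("PR4", "full coverage")

    def test_missing_members_are_added_back(self, refined_setup):
        index, cache, groups = refined_setup
        full = [g for g in groups if len(g.members) == index.n_genomes][0].copy()
        removed = sorted(full.members)[-2:]
        expected = dict(full.members)
        for genome in removed:
            del full.members[genome]
        out = iterate_pr4([full], index, cache=cache)
        assert out[0].members == expected

    def test_groups_never_shrink(self, refined_setup):
        index, cache, groups = refined_setup
        out = iterate_pr4([g.copy() for g in groups], index, cache=cache)
        before = {g.group_id: set(g.protein_ids) for g in groups}
        for g in out:
            assert g.protein_ids >= before[g.group_id]


class TestMergeByProfile:
    def test_split_family_halves_are_reunited(self, refined_setup):
        index, cache, groups = refined_setup
        family = [g for g in groups if len(g.members) == index.n_genomes][0]
        members = sorted(family.members.items())
        half_a = _group("OGa", dict(members[: len(members) // 2]))
        half_b = _group("OGb", dict(members[len(members) // 2 :]))
        merged = merge_by_profile([half_a, half_b], index, cache=cache)
        assert len(merged) == 1
        assert merged[0].protein_ids == family.protein_ids

    def test_same_genome_conflict_blocks_merge(self, refined_setup):
        index, cache, groups = refined_setup
        family = [g for g in groups if len(g.members) == index.n_genomes][0]
        members = sorted(family.members.items())
        half_a = _group("OGa", dict(members[:4]))
        half_b_members = dict(members[4:])
        # give the second half a DIFFERENT protein from a genome the first
        # half already covers: the union would break one-per-genome
        conflict_genome = members[0][0]
        other_protein = sorted(
            pid
            for pid in index.records
            if pid.startswith(conflict_genome + "|") and pid != members[0][1]
        )[0]
        half_b_members[conflict_genome] = other_protein
        half_b = _group("OGb", half_b_members)
        merged = merge_by_profile([half_a, half_b], index, cache=cache)
        assert len(merged) == 2

    def test_infinite_threshold_never_merges(self, refined_setup):
        index, cache, groups = refined_setup
        family = [g for g in groups if len(g.members) == index.n_genomes][0]
        members = sorted(family.members.items())
        half_a = _group("OGa", dict(members[: len(members) // 2]))
        half_b = _group("OGb", dict(members[len(members) // 2 :]))
        merged = merge_by_profile(
            [half_a, half_b], index, threshold=math.inf, cache=cache
        )
        assert len(merged) == 2


@pytest.fixture(scope="module")
def omission_corpus():
    cfg = SimulationConfig(
        n_genera=2,
        genomes_per_genus=(3, 3),
        n_core_families=4,
        n_genus_families=1,
        n_unique_per_genome=1.0,
        paralog_rate=0.0,
        annotation_omission_rate=0.25,
        mean_gene_len_aa=90,
        anchor_families=(0, 1),
        seed=19,
    )
    return simulate_dataset(cfg)


class TestRescue:
    def test_omitted_members_recovered_via_orf_prediction(self, omission_corpus):
        genomes, truth = omission_corpus
        index = ProteinIndex(genomes)
        cache = ProfileCache(index)
        groups = _truth_groups(truth, index, labels=("core",))
        incomplete = [g for g in groups if len(g.members) < index.n_genomes]
        assert incomplete, "fixture must contain omissions in core families"
        out = rescue_by_search(groups, index, cache=cache)
        truth_keys = {
            g.family_id: {m.gene_key() for m in truth.families()[g.family_id]}
            for g in truth.genes
            if g.label == "core"
        }
        for grp in out:
            got = {index.records[p].gene_key() for p in grp.protein_ids}
            assert got == truth_keys[grp.group_id]
            assert len(grp.members) == index.n_genomes

    def test_genome_without_family_is_not_polluted(self, refined_setup, small_truth):
        index, cache, groups = refined_setup
        genus_groups = [g for g in groups if len(g.members) < index.n_genomes]
        out = rescue_by_search([g.copy() for g in genus_groups], index, cache=cache)
        for before, after in zip(genus_groups, out):
            # genus-restricted families must not gain members from the
            # other genus: those genomes genuinely lack the gene
            truth_genomes = before.genomes
            assert after.genomes == truth_genomes

    def test_tblastn_finds_planted_gene_location(self, omission_corpus):
        genomes, truth = omission_corpus
        omitted = next(g for g in truth.genes if g.omitted and g.label == "core")
        genome = next(g for g in genomes if g.genome_id == omitted.genome_id)
        relatives = [
            m
            for m in truth.families()[omitted.family_id]
            if not m.omitted and m.genome_id != omitted.genome_id
        ]
        index = ProteinIndex(genomes)
        query = index.sequence(relatives[0].qualified_id)
        hit = tblastn_like(query, genome, AlignmentScorer(), evalue_max=0.01)
        assert hit is not None
        assert hit.strand == omitted.strand
        assert hit.start >= omitted.start - 30
        assert hit.end <= omitted.end + 30


class TestSynteny:
    def test_conserved_neighbourhood_is_syntenic(self, refined_setup):
        index, cache, groups = refined_setup
        full = [g for g in groups if len(g.members) == index.n_genomes]
        anchors, candidate = full[:2], full[2]
        decision = synteny_support(candidate, anchors, index)
        assert decision.decision == "syntenic"
        assert all(decision.per_genome.values())

    def test_randomized_gene_order_is_not_syntenic(self):
        cfg = SimulationConfig(
            n_genera=2,
            genomes_per_genus=(3, 3),
            n_core_families=8,
            n_genus_families=0,
            n_unique_per_genome=4.0,
            paralog_rate=0.0,
            annotation_omission_rate=0.0,
            mean_gene_len_aa=80,
            anchor_families=(0,),
            shuffle_gene_order=True,
            seed=23,
        )
        genomes, truth = simulate_dataset(cfg)
        index = ProteinIndex(genomes)
        groups = _truth_groups(truth, index, labels=("core",))
        anchors = [g for g in groups if g.group_id == "core00"]
        candidate = [g for g in groups if g.group_id == "core07"][0]
        decision = synteny_support(candidate, anchors, index, window=2)
        assert decision.decision == "not_syntenic"

    def test_single_genome_candidate_is_undetermined(self, refined_setup):
        index, cache, groups = refined_setup
        full = [g for g in groups if len(g.members) == index.n_genomes]
        lone_genome = sorted(full[2].members)[0]
        candidate = _group("OGlone", {lone_genome: full[2].members[lone_genome]})
        decision = synteny_support(candidate, full[:2], index)
        assert decision.decision == "undetermined"


class TestClassifyCatalogue:
    def test_planted_bookkeeping(self):
        cfg = SimulationConfig(
            n_genera=2,
            genomes_per_genus=(2, 2),
            n_core_families=5,
            n_genus_families=3,
            n_unique_per_genome=1.5,
            paralog_rate=0.0,
            annotation_omission_rate=0.0,
            mean_gene_len_aa=80,
            anchor_families=(0,),
            seed=31,
        )
        genomes, truth = simulate_dataset(cfg)
        index = ProteinIndex(genomes)
        groups = _truth_groups(truth, index)
        catalogue = classify_catalogue(groups, index)
        assert len(catalogue.core_groups) == 5
        genus_restricted = [
            g for g in catalogue.groups if len(g.members) < len(genomes)
        ]
        assert len(genus_restricted) == 6  # 3 families per genus
        assert len(catalogue.unique_genes) == 6
        assert partition_ok(catalogue, index)

    def test_second_same_genome_copy_is_paralog_flagged(self):
        cfg = SimulationConfig(
            n_genera=2,
            genomes_per_genus=(3, 3),
            n_core_families=4,
            n_genus_families=0,
            n_unique_per_genome=0.0,
            paralog_rate=0.6,
            annotation_omission_rate=0.0,
            mean_gene_len_aa=80,
            anchor_families=(0,),
            seed=37,
        )
        genomes, truth = simulate_dataset(cfg)
        index = ProteinIndex(genomes)
        # seed groups WITHOUT the paralogous copies; classification must
        # attach them as paralog-flagged members, not unique genes
        groups = []
        for family, members in sorted(truth.families().items()):
            primary = [m for m in members if m.label == "core"]
            grp = OrthoGroup(group_id=family)
            _set_members(grp, [m.qualified_id for m in primary], index)
            grp.tag("PR1", "truth")
            groups.append(grp)
        catalogue = classify_catalogue(groups, index)
        planted_paralogs = {
            m.qualified_id for m in truth.genes if m.label == "paralog"
        }
        assert planted_paralogs
        flagged = set().union(*(g.paralog_flags for g in catalogue.groups))
        assert planted_paralogs <= flagged
        assert not catalogue.unique_genes
        assert partition_ok(catalogue, index)

    def test_empty_groups_make_everything_unique(self, small_genomes):
        index = ProteinIndex(small_genomes)
        catalogue = classify_catalogue([], index)
        assert not catalogue.groups
        assert set(catalogue.unique_genes) == set(index.records)
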