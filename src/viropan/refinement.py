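"""Iterative refinement of ortholog groups and gene classification.

Stage-1 clusters (reciprocal-hit graph components) are refined by:

* profile re-search with member filtering (stage 2),
* merging groups that share proteins, one-per-genome permitting (stage 3),
* iterative profile enrichment until coverage, fixed point or member
  loss (stage 4; a loss reverts to the last good membership),
* profile-profile merging above a score threshold plus one relaxed
  search pass (stage 5),
* translated-genome search against genomes absent from a group, using
  annotated ORFs when the hit lands in one and de-novo ORF prediction
  otherwise (stage 6), then a relaxed profile search over the predicted
  ORF complement of still-missing genomes (stage 7),
* synteny support around anchor groups plus optional curated overrides
  (stage 8).

Finally every protein is classified core / taxon-shared / unique, with
extra same-genome copies of a family attached as paralogs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genomes import (
    DEFAULT_MIN_AA,
    GenomeRecord,
    ProteinRecord,
    find_orfs,
    reverse_complement,
    translate_orf,
)
from .groups import GeneCatalogue, OrthoGroup
from .profiles import (
    Msa,
    ProfileModel,
    ProteinDatabase,
    build_msa,
    build_profile,
    profile_alignment_coverage,
    profile_search,
    profile_vs_profile,
)
from .similarity import AlignmentScorer

logger = logging.getLogger(__name__)

DEFAULT_PR2_EVALUE = 0.01
DEFAULT_PR4_EVALUE = 0.001
DEFAULT_MERGE_SCORE = 20.0
DEFAULT_RELAXED_EVALUE = 10.0
DEFAULT_SYNTENY_WINDOW = 5
DEFAULT_SYNTENY_FRACTION = 0.8
#: minimum fraction of profile columns an adopted remote member must span
DEFAULT_MIN_PROFILE_COVERAGE = 0.5


class ProteinIndex:
    """All proteins of a genome set, addressable by qualified id.

    Grows as ORF rescue predicts new proteins; the database object used
    for profile searches is rebuilt lazily when that happens.
    """

    def __init__(self, genomes: Sequence[GenomeRecord]) -> None:
        self.genomes: dict[str, GenomeRecord] = {g.genome_id: g for g in genomes}
        self.records: dict[str, ProteinRecord] = {}
        for g in genomes:
            for p in g.annotated_proteins:
                self.records[p.qualified_id] = p
        self._db: ProteinDatabase | None = None
        self._orf_cache: dict[tuple[str, int], list] = {}

    def add(self, record: ProteinRecord) -> str:
        qid = record.qualified_id
        if qid not in self.records:
            self.records[qid] = record
            self._db = None
        return qid

    def orfs(self, genome_id: str, min_aa: int) -> list:
        key = (genome_id, min_aa)
        if key not in self._orf_cache:
            self._orf_cache[key] = find_orfs(self.genomes[genome_id], min_aa)
        return self._orf_cache[key]

    def genome_of(self, qid: str) -> str:
        return self.records[qid].genome_id

    def sequence(self, qid: str) -> str:
        return self.records[qid].aa_sequence

    def sequences(self) -> dict[str, str]:
        return {qid: r.aa_sequence for qid, r in self.records.items()}

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def database(self) -> ProteinDatabase:
        if self._db is None:
            self._db = ProteinDatabase(self.sequences())
        return self._db

    def find_by_key(self, key: tuple[str, str, int]) -> ProteinRecord | None:
        for rec in self.records.values():
            if rec.gene_key() == key:
                return rec
        return None


class ProfileCache:
    """Memoize profiles by membership so unchanged groups are not re-aligned."""

    def __init__(self, index: ProteinIndex, pseudocount_weight: float = 5.0) -> None:
        self.index = index
        self.pseudocount_weight = pseudocount_weight
        self._cache: dict[frozenset, ProfileModel] = {}

    def msa(self, pids: Iterable[str]) -> Msa:
        return build_msa({pid: self.index.sequence(pid) for pid in pids})

    def profile(self, group: OrthoGroup) -> ProfileModel:
        key = frozenset(group.protein_ids)
        if key not in self._cache:
            msa = self.msa(key)
            self._cache[key] = build_profile(
                msa, pseudocount_weight=self.pseudocount_weight, group_id=group.group_id
            )
        prof = self._cache[key]
        return ProfileModel(
            group_id=group.group_id,
            scores=prof.scores,
            probs=prof.probs,
            gap_open=prof.gap_open,
            gap_extend=prof.gap_extend,
            n_seqs=prof.n_seqs,
        )


def _set_members(group: OrthoGroup, pids: Iterable[str], index: ProteinIndex) -> None:
    """Assign members one-per-genome (lexicographic representative);
    extra same-genome proteins become paralog flags."""
    group.members = {}
    group.paralog_flags = set()
    for pid in sorted(pids):
        genome = index.genome_of(pid)
        if genome in group.members:
            group.paralog_flags.add(pid)
        else:
            group.members[genome] = pid


# ---------------------------------------------------------------------------
# stage 2


def iterate_pr2(
    groups_pr1: Sequence[OrthoGroup],
    index: ProteinIndex,
    rounds: int = 3,
    evalue: float = DEFAULT_PR2_EVALUE,
    min_profile_coverage: float = DEFAULT_MIN_PROFILE_COVERAGE,
    cache: ProfileCache | None = None,
) -> list[OrthoGroup]:
    """Profile re-search of stage-1 clusters.

    Round 1 restricts each group's profile hits to proteins that belong
    to some stage-1 cluster; later rounds rebuild and re-search, and a
    group is discarded when one of its founding members is no longer
    recovered.  Hits from outside the group must span at least
    ``min_profile_coverage`` of the profile columns — marginal-e-value
    matches over short segments are not membership evidence.
    """
    cache = cache or ProfileCache(index)
    clustered = set().union(*(g.protein_ids for g in groups_pr1)) if groups_pr1 else set()
    db = index.database()
    out: list[OrthoGroup] = []
    for group in sorted(groups_pr1, key=lambda g: g.group_id):
        founders = set(group.protein_ids)

        def membership(profile, hits: set, insiders: set) -> set:
            kept = set()
            for pid in hits & clustered:
                if pid in insiders or profile_alignment_coverage(
                    profile, index.sequence(pid)
                ) >= min_profile_coverage:
                    kept.add(pid)
            return kept

        profile = cache.profile(group)
        hits = {h.protein_id for h in profile_search(profile, db, evalue)}
        current = membership(profile, hits, founders)
        survived = len(current) >= 2
        if survived:
            work = group.copy()
            _set_members(work, current, index)
            for _ in range(max(0, rounds - 1)):
                profile = cache.profile(work)
                hits = {h.protein_id for h in profile_search(profile, db, evalue)}
                if not founders <= hits:
                    survived = False
                    break
                new = membership(profile, hits, set(work.protein_ids))
                if len(new) < 2:
                    survived = False
                    break
                if new != set(work.protein_ids):
                    _set_members(work, new, index)
        if survived and len(work.genomes) >= 2:
            work.tag("PR2", "profile-validated")
            out.append(work)
        else:
            logger.info("stage 2: group %s discarded", group.group_id)
    return out


# ---------------------------------------------------------------------------
# stage 3


def merge_groups(
    groups: Sequence[OrthoGroup],
    index: ProteinIndex,
    require_one_per_genome: bool = True,
    stage_tag: str = "PR3",
) -> list[OrthoGroup]:
    """Merge groups sharing at least one protein, under the one-protein-
    per-genome constraint (transitive closure where permitted).

    Merges are attempted in ascending group-id order; a blocked merge is
    logged and the groups stay separate.  Residual double-assignments of
    a protein are resolved to the lexicographically first group.
    """
    ordered = sorted((g.copy() for g in groups), key=lambda g: g.group_id)
    parent = {g.group_id: g.group_id for g in ordered}
    by_id = {g.group_id: g for g in ordered}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    protein_to_groups: dict[str, list[str]] = {}
    for g in ordered:
        for pid in g.protein_ids:
            protein_to_groups.setdefault(pid, []).append(g.group_id)

    candidate_pairs = sorted(
        {
            tuple(sorted((a, b)))
            for gids in protein_to_groups.values()
            for a in gids
            for b in gids
            if a != b
        }
    )
    merged_members: dict[str, set] = {g.group_id: set(g.protein_ids) for g in ordered}
    for a, b in candidate_pairs:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        union = merged_members[ra] | merged_members[rb]
        if require_one_per_genome:
            genomes = [index.genome_of(p) for p in union]
            if len(genomes) != len(set(genomes)):
                logger.info("stage 3: merge %s+%s blocked (duplicate genome)", a, b)
                continue
        ra, rb = sorted((ra, rb))
        parent[rb] = ra
        merged_members[ra] = union
        merged_members[rb] = set()

    taken: set[str] = set()
    out: list[OrthoGroup] = []
    for g in ordered:
        root = find(g.group_id)
        if root != g.group_id:
            continue
        members = {p for p in merged_members[root] if p not in taken}
        taken |= members
        if len(members) < 2:
            continue
        merged = OrthoGroup(group_id=g.group_id, history=list(g.history))
        _set_members(merged, members, index)
        merged.tag(stage_tag, "share-protein merge")
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# stage 4


def iterate_pr4(
    groups: Sequence[OrthoGroup],
    index: ProteinIndex,
    n_genomes: int | None = None,
    evalue: float = DEFAULT_PR4_EVALUE,
    max_rounds: int = 10,
    min_profile_coverage: float = DEFAULT_MIN_PROFILE_COVERAGE,
    cache: ProfileCache | None = None,
) -> list[OrthoGroup]:
    """Iterative profile enrichment of each group.

    New proteins (not yet assigned to any group) are added until the
    group covers all genomes, membership reaches a fixed point, or a
    previously held member drops out of the hit list - in which case the
    last good membership is kept and the group flagged.
    """
    cache = cache or ProfileCache(index)
    n_genomes = n_genomes or index.n_genomes
    db = index.database()
    assigned = set().union(*(g.protein_ids for g in groups)) if groups else set()
    out = []
    for group in sorted(groups, key=lambda g: g.group_id):
        work = group.copy()
        for _ in range(max_rounds):
            if len(work.genomes) >= n_genomes:
                work.tag("PR4", "full coverage")
                break
            profile = cache.profile(work)
            hits = profile_search(profile, db, evalue)
            hit_ids = {h.protein_id for h in hits}
            if not set(work.protein_ids) <= hit_ids:
                work.tag("PR4", "member lost; reverted to last good")
                break
            additions: dict[str, str] = {}
            for h in hits:  # descending score
                if h.protein_id in assigned or h.protein_id in additions.values():
                    continue
                genome = index.genome_of(h.protein_id)
                if genome in work.genomes or genome in additions:
                    continue
                cov = profile_alignment_coverage(profile, index.sequence(h.protein_id))
                if cov < min_profile_coverage:
                    continue
                additions[genome] = h.protein_id
            if not additions:
                work.tag("PR4", "fixed point")
                break
            for genome, pid in sorted(additions.items()):
                work.members[genome] = pid
                assigned.add(pid)
        else:
            work.tag("PR4", "round limit")
        out.append(work)
    return out


# ---------------------------------------------------------------------------
# stage 5


def merge_by_profile(
    groups: Sequence[OrthoGroup],
    index: ProteinIndex,
    threshold: float = DEFAULT_MERGE_SCORE,
    relaxed_evalue: float = DEFAULT_RELAXED_EVALUE,
    min_profile_coverage: float = DEFAULT_MIN_PROFILE_COVERAGE,
    cache: ProfileCache | None = None,
) -> list[OrthoGroup]:
    """Merge groups whose profiles align above ``threshold``.

    All group pairs are scored with profile-profile alignment; merges
    run greedily in descending score order and are blocked when the
    union would carry two proteins of one genome.  A final relaxed
    profile search adds remote members to the merged groups.
    """
    cache = cache or ProfileCache(index)
    ordered = sorted((g.copy() for g in groups), key=lambda g: g.group_id)
    profiles = {g.group_id: cache.profile(g) for g in ordered}
    scored = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            score = profile_vs_profile(profiles[a.group_id], profiles[b.group_id])
            if score > threshold:
                scored.append((score, a.group_id, b.group_id))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))

    parent = {g.group_id: g.group_id for g in ordered}
    members = {g.group_id: set(g.protein_ids) for g in ordered}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for score, a, b in scored:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        union = members[ra] | members[rb]
        genomes = [index.genome_of(p) for p in union]
        if len(genomes) != len(set(genomes)):
            continue
        ra, rb = sorted((ra, rb))
        parent[rb] = ra
        members[ra] = union
        members[rb] = set()

    merged: list[OrthoGroup] = []
    for g in ordered:
        if find(g.group_id) != g.group_id:
            continue
        work = OrthoGroup(group_id=g.group_id, history=list(g.history))
        _set_members(work, members[g.group_id], index)
        merged.append(work)

    # relaxed enrichment pass
    db = index.database()
    assigned = set().union(*(m.protein_ids for m in merged)) if merged else set()
    for work in merged:
        if len(work.genomes) < index.n_genomes:
            profile = cache.profile(work)
            hits = profile_search(profile, db, relaxed_evalue)
            for h in hits:
                if h.protein_id in assigned:
                    continue
                genome = index.genome_of(h.protein_id)
                if genome in work.genomes:
                    continue
                cov = profile_alignment_coverage(profile, index.sequence(h.protein_id))
                if cov < min_profile_coverage:
                    continue
                work.members[genome] = h.protein_id
                assigned.add(h.protein_id)
        work.tag("PR5", "profile merge + relaxed search")
    return merged


# ---------------------------------------------------------------------------
# stage 6/7: translated-genome and ORF-database rescue


@dataclass
class _FrameHit:
    score: float
    evalue: float
    start: int  # 1-based nt, forward representation
    end: int
    strand: str


def _six_frame_translations(genome: GenomeRecord) -> list[tuple[str, str, int]]:
    """(translation, strand, frame_offset) for all six frames.

    Stop codons are rendered as X so local alignments can bridge them
    without ever rewarding them.
    """
    from Bio.Seq import Seq

    out = []
    n = genome.length_bp
    for strand in "+-":
        seq = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
        for frame in range(3):
            usable = n - (n - frame) % 3
            aa = str(Seq(seq[frame:usable]).translate()).replace("*", "X")
            out.append((aa, strand, frame))
    return out


def _frame_hit_location(
    genome: GenomeRecord, aln, strand: str, frame: int
) -> tuple[int, int]:
    """Map a local alignment on a frame translation to forward nt coords."""
    segs = aln.aligned[1]  # subject (frame translation) segments
    aa_start = int(segs[0][0])
    aa_end = int(segs[-1][1])  # exclusive
    nt_start0 = frame + 3 * aa_start
    nt_end0 = frame + 3 * aa_end  # exclusive
    n = genome.length_bp
    if strand == "+":
        return nt_start0 + 1, nt_end0
    return n - nt_end0 + 1, n - nt_start0


def tblastn_like(
    query: str,
    genome: GenomeRecord,
    scorer: AlignmentScorer,
    evalue_max: float,
) -> _FrameHit | None:
    """Best local alignment of a protein query against six genome frames."""
    frames = _six_frame_translations(genome)
    db_residues = sum(len(f[0]) for f in frames)
    best: _FrameHit | None = None
    for translation, strand, frame in frames:
        if not translation:
            continue
        raw = scorer.score(query, translation)
        ev = scorer.evalue(raw, len(query), db_residues)
        if ev > evalue_max:
            continue
        if best is None or raw > best.score:
            aln = scorer._aligner.align(query, translation)[0]
            start, end = _frame_hit_location(genome, aln, strand, frame)
            best = _FrameHit(score=raw, evalue=ev, start=start, end=end, strand=strand)
    return best


def _overlapping_annotated(
    genome: GenomeRecord, hit: _FrameHit
) -> ProteinRecord | None:
    """Annotated protein whose CDS overlaps the hit on the same strand."""
    best = None
    best_ov = 0
    for p in genome.annotated_proteins:
        if p.strand != hit.strand or p.cds_end < p.cds_start:
            continue
        ov = min(p.cds_end, hit.end) - max(p.cds_start, hit.start) + 1
        if ov > best_ov:
            best_ov = ov
            best = p
    return best if best_ov > 0 else None


def _rescue_orf(
    genome: GenomeRecord,
    hit: _FrameHit,
    index: ProteinIndex,
    min_aa: int,
) -> ProteinRecord | None:
    """Longest predicted ORF overlapping the hit (same strand); reuses an
    existing record when the ORF coincides with one.  The record is not
    registered in the index; the caller does that upon adoption."""
    candidates = []
    for orf in index.orfs(genome.genome_id, min_aa):
        if orf.strand != hit.strand or orf.spans_origin:
            continue
        ov = min(orf.end, hit.end) - max(orf.start, hit.start) + 1
        if ov > 0:
            candidates.append(orf)
    if not candidates:
        return None
    orf = max(candidates, key=lambda o: (o.aa_length, -o.start))
    record = translate_orf(genome, orf)
    existing = index.find_by_key(record.gene_key())
    return existing if existing is not None else record


def rescue_by_search(
    groups: Sequence[OrthoGroup],
    index: ProteinIndex,
    scorer: AlignmentScorer | None = None,
    evalue: float = DEFAULT_PR2_EVALUE,
    relaxed_evalue: float = DEFAULT_RELAXED_EVALUE,
    min_aa: int = DEFAULT_MIN_AA,
    min_profile_coverage: float = DEFAULT_MIN_PROFILE_COVERAGE,
    cache: ProfileCache | None = None,
) -> list[OrthoGroup]:
    """Recover members from genomes absent from a group.

    Stage 6: the group's longest member is searched against the six
    frames of every absent genome; a hit inside an annotated ORF adopts
    the annotated protein, a hit in unannotated sequence adopts the
    longest predicted ORF containing it.  Stage 7: group profiles are
    searched, at a relaxed e-value, against the predicted-ORF database
    of genomes still missing.
    """
    scorer = scorer or AlignmentScorer()
    cache = cache or ProfileCache(index)
    out = [g.copy() for g in sorted(groups, key=lambda g: g.group_id)]
    assigned = set().union(*(g.protein_ids for g in out)) if out else set()

    for work in out:
        absent = sorted(set(index.genomes) - work.genomes)
        if not absent:
            work.tag("PR6", "complete")
            continue
        longest_pid = max(
            sorted(work.protein_ids), key=lambda p: len(index.sequence(p))
        )
        query = index.sequence(longest_pid)
        profile = cache.profile(work)
        added = 0
        for genome_id in absent:
            genome = index.genomes[genome_id]
            hit = tblastn_like(query, genome, scorer, evalue)
            if hit is None:
                continue
            annotated = _overlapping_annotated(genome, hit)
            record = annotated or _rescue_orf(genome, hit, index, min_aa)
            if record is None or record.qualified_id in assigned:
                continue
            cov = profile_alignment_coverage(profile, record.aa_sequence)
            if cov < min_profile_coverage:
                continue
            index.add(record)
            work.members[genome_id] = record.qualified_id
            assigned.add(record.qualified_id)
            added += 1
        work.tag("PR6", f"rescued {added}")

    # stage 7: relaxed profile search over predicted ORFs of missing genomes
    still_missing = sorted(
        {
            genome_id
            for g in out
            for genome_id in set(index.genomes) - g.genomes
        }
    )
    if still_missing:
        orf_seqs: dict[str, str] = {}
        orf_records: dict[str, ProteinRecord] = {}
        for genome_id in still_missing:
            genome = index.genomes[genome_id]
            for orf in index.orfs(genome_id, min_aa):
                if orf.spans_origin:
                    continue
                rec = translate_orf(genome, orf)
                orf_seqs[rec.qualified_id] = rec.aa_sequence
                orf_records[rec.qualified_id] = rec
        if orf_seqs:
            orf_db = ProteinDatabase(orf_seqs)
            for work in out:
                missing = sorted(set(index.genomes) - work.genomes)
                if not missing:
                    work.tag("PR7", "complete")
                    continue
                profile = cache.profile(work)
                hits = profile_search(profile, orf_db, relaxed_evalue)
                added = 0
                for h in hits:
                    rec = orf_records[h.protein_id]
                    if rec.genome_id not in missing:
                        continue
                    cov = profile_alignment_coverage(profile, rec.aa_sequence)
                    if cov < min_profile_coverage:
                        continue
                    existing = index.find_by_key(rec.gene_key())
                    record = existing if existing is not None else rec
                    if record.qualified_id in assigned:
                        continue
                    if existing is None:
                        index.add(rec)
                    work.members[rec.genome_id] = record.qualified_id
                    assigned.add(record.qualified_id)
                    missing.remove(rec.genome_id)
                    added += 1
                work.tag("PR7", f"orf-db rescued {added}")
    else:
        for work in out:
            work.tag("PR7", "complete")
    return out


# ---------------------------------------------------------------------------
# stage 8: synteny


@dataclass
class SyntenyDecision:
    decision: str  # syntenic | not_syntenic | undetermined
    per_genome: dict[str, bool]
    rescue_candidates: dict[str, str]  # genome_id -> qualified protein id
    conserved_fraction: float


def _gene_ranks(index: ProteinIndex, genome_id: str) -> dict[str, int]:
    genome = index.genomes[genome_id]
    records = [r for r in index.records.values() if r.genome_id == genome_id]
    records.sort(key=lambda r: (r.cds_start, r.cds_end))
    return {r.qualified_id: i for i, r in enumerate(records)}, len(records)


def synteny_support(
    candidate: OrthoGroup,
    anchors: Sequence[OrthoGroup],
    index: ProteinIndex,
    window: int = DEFAULT_SYNTENY_WINDOW,
    fraction: float = DEFAULT_SYNTENY_FRACTION,
) -> SyntenyDecision:
    """Is the candidate group found at a conserved position near anchors?

    For each genome carrying the candidate, checks whether its member
    lies within ``window`` genes (circular order, either direction) of a
    member of any anchor group.  For genomes missing the candidate, the
    gene occupying the syntenically equivalent slot (the modal
    anchor/offset pattern) is reported as a rescue candidate.
    """
    per_genome: dict[str, bool] = {}
    offsets: dict[tuple[str, int], int] = {}
    rank_cache: dict[str, tuple[dict[str, int], int]] = {}

    def ranks(genome_id):
        if genome_id not in rank_cache:
            rank_cache[genome_id] = _gene_ranks(index, genome_id)
        return rank_cache[genome_id]

    for genome_id, pid in sorted(candidate.members.items()):
        rank_map, n_genes = ranks(genome_id)
        if pid not in rank_map or n_genes == 0:
            continue
        pos = rank_map[pid]
        found = False
        for anchor in anchors:
            a_pid = anchor.members.get(genome_id)
            if a_pid is None or a_pid not in rank_map:
                continue
            a_pos = rank_map[a_pid]
            diff = (pos - a_pos) % n_genes
            signed = diff if diff <= n_genes // 2 else diff - n_genes
            if abs(signed) <= window:
                found = True
                offsets[(anchor.group_id, signed)] = (
                    offsets.get((anchor.group_id, signed), 0) + 1
                )
        per_genome[genome_id] = found

    if len(per_genome) <= 1:
        return SyntenyDecision(
            decision="undetermined",
            per_genome=per_genome,
            rescue_candidates={},
            conserved_fraction=0.0,
        )
    conserved = sum(per_genome.values()) / len(per_genome)
    decision = "syntenic" if conserved >= fraction else "not_syntenic"

    rescue: dict[str, str] = {}
    if offsets and decision == "syntenic":
        (anchor_id, signed), _count = max(
            sorted(offsets.items()), key=lambda kv: (kv[1], kv[0])
        )
        anchor = next(a for a in anchors if a.group_id == anchor_id)
        for genome_id in sorted(set(index.genomes) - set(candidate.members)):
            rank_map, n_genes = ranks(genome_id)
            a_pid = anchor.members.get(genome_id)
            if a_pid is None or a_pid not in rank_map or n_genes == 0:
                continue
            target = (rank_map[a_pid] + signed) % n_genes
            inverse = {v: k for k, v in rank_map.items()}
            if target in inverse:
                rescue[genome_id] = inverse[target]
    return SyntenyDecision(
        decision=decision,
        per_genome=per_genome,
        rescue_candidates=rescue,
        conserved_fraction=conserved,
    )


def apply_overrides(
    groups: Sequence[OrthoGroup],
    overrides: Mapping[str, str],
    index: ProteinIndex,
) -> list[OrthoGroup]:
    """Apply a curated mapping group_id -> qualified protein id to adopt.

    This is the explicit stand-in for "previously reported biological
    function" arguments: adoption decisions are data, not inference.
    """
    out = [g.copy() for g in groups]
    by_id = {g.group_id: g for g in out}
    for group_id, pid in sorted(overrides.items()):
        group = by_id.get(group_id)
        if group is None or pid not in index.records:
            logger.warning("override %s -> %s not applicable", group_id, pid)
            continue
        genome = index.genome_of(pid)
        if genome in group.members:
            logger.warning("override %s: genome %s already covered", group_id, genome)
            continue
        group.members[genome] = pid
        group.tag("SYNTENY", f"curated adoption {pid}")
    return out


# ---------------------------------------------------------------------------
# final classification


def classify_catalogue(
    groups: Sequence[OrthoGroup],
    index: ProteinIndex,
    taxa: Mapping[str, str] | None = None,
    paralog_evalue: float = DEFAULT_PR2_EVALUE,
    min_profile_coverage: float = DEFAULT_MIN_PROFILE_COVERAGE,
    cache: ProfileCache | None = None,
) -> GeneCatalogue:
    """Partition every protein into a group, a paralog slot, or unique.

    Unassigned proteins scoring at ``paralog_evalue`` against a group
    whose genome slot is already occupied (and spanning at least
    ``min_profile_coverage`` of its profile) are attached as paralogs;
    everything else unassigned is a unique gene.
    """
    cache = cache or ProfileCache(index)
    groups = [g.copy() for g in sorted(groups, key=lambda g: g.group_id)]
    assigned = set().union(*(g.protein_ids for g in groups)) if groups else set()
    unassigned = {
        qid: index.sequence(qid) for qid in index.records if qid not in assigned
    }
    if unassigned and groups:
        db = ProteinDatabase(unassigned)
        best: dict[str, tuple[float, str]] = {}
        for group in groups:
            profile = cache.profile(group)
            for h in profile_search(profile, db, paralog_evalue):
                genome = index.genome_of(h.protein_id)
                if genome not in group.members:
                    continue  # would be an ordinary member; stages 4-7 own that
                cov = profile_alignment_coverage(profile, index.sequence(h.protein_id))
                if cov < min_profile_coverage:
                    continue
                prev = best.get(h.protein_id)
                if prev is None or h.score > prev[0]:
                    best[h.protein_id] = (h.score, group.group_id)
        by_id = {g.group_id: g for g in groups}
        for pid, (_, gid) in sorted(best.items()):
            by_id[gid].paralog_flags.add(pid)
            assigned.add(pid)
    unique = sorted(qid for qid in index.records if qid not in assigned)
    taxa = dict(taxa) if taxa else {
        gid: g.taxon for gid, g in index.genomes.items()
    }
    return GeneCatalogue(
        groups=groups,
        unique_genes=unique,
        n_genomes=index.n_genomes,
        taxa=taxa,
        proteins=dict(index.records),
    )


def partition_ok(catalogue: GeneCatalogue, index: ProteinIndex) -> bool:
    """Every protein appears exactly once across groups and unique genes."""
    seen: list[str] = []
    for g in catalogue.groups:
        seen.extend(g.protein_ids)
    seen.extend(catalogue.unique_genes)
    return len(seen) == len(set(seen)) == len(index.records)
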