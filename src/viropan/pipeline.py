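"""End-to-end ortholog pipeline orchestration.

``run_obp`` executes the eight stages in order, checkpointing the group
table after every stage so a run can be resumed from any partial result,
and returns the final gene catalogue together with a manifest that
records every threshold, seed and input hash needed to reproduce the run
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .genomes import DEFAULT_MIN_AA, GenomeRecord, find_orfs, translate_orf
from .groups import GeneCatalogue, OrthoGroup, read_groups_tsv, write_groups_tsv
from .profiles import ProteinDatabase, profile_search
from .refinement import (
    DEFAULT_MERGE_SCORE,
    DEFAULT_PR2_EVALUE,
    DEFAULT_PR4_EVALUE,
    DEFAULT_RELAXED_EVALUE,
    DEFAULT_SYNTENY_FRACTION,
    DEFAULT_SYNTENY_WINDOW,
    ProfileCache,
    ProteinIndex,
    apply_overrides,
    classify_catalogue,
    iterate_pr2,
    iterate_pr4,
    merge_by_profile,
    merge_groups,
    rescue_by_search,
    synteny_support,
)
from .similarity import (
    DEFAULT_EVALUE_MAX,
    DEFAULT_MIN_CONNECTIVITY,
    AlignmentScorer,
    all_vs_all,
    cluster_pr1,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["PR1", "PR2", "PR3", "PR4", "PR5", "PR67", "FINAL"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, echoed verbatim into the manifest."""

    evalue_pr1: float = DEFAULT_EVALUE_MAX
    min_connectivity: float = DEFAULT_MIN_CONNECTIVITY
    evalue_pr2: float = DEFAULT_PR2_EVALUE
    pr2_rounds: int = 3
    evalue_pr4: float = DEFAULT_PR4_EVALUE
    profile_merge_score: float = DEFAULT_MERGE_SCORE
    relaxed_evalue: float = DEFAULT_RELAXED_EVALUE
    rescue_evalue: float = DEFAULT_PR2_EVALUE
    min_orf_aa: int = DEFAULT_MIN_AA
    synteny_window: int = DEFAULT_SYNTENY_WINDOW
    synteny_fraction: float = DEFAULT_SYNTENY_FRACTION
    #: only near-complete groups are synteny candidates (fraction of genomes
    #: that must already carry a member)
    synteny_min_coverage: float = 0.7
    paralog_evalue: float = DEFAULT_PR2_EVALUE
    pseudocount_weight: float = 5.0
    seed: int = 0
    overrides: dict = field(default_factory=dict)  # group_id -> qualified pid

    @classmethod
    def from_key_value_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value config text (unknown keys rejected)."""
        kwargs = {}
        fields = {f: type(getattr(cls(), f)) for f in cls().__dict__}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key: {key}")
                kwargs[key] = fields[key](value.strip())
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    input_hashes: dict[str, str]
    stage_counts: dict[str, int]
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _hash_genomes(genomes: Sequence[GenomeRecord]) -> dict[str, str]:
    out = {}
    for g in sorted(genomes, key=lambda x: x.genome_id):
        h = hashlib.sha256()
        h.update(g.sequence.encode())
        for p in sorted(g.annotated_proteins, key=lambda p: p.protein_id):
            h.update(f"{p.protein_id}:{p.cds_start}:{p.cds_end}:{p.strand}".encode())
        out[g.genome_id] = h.hexdigest()[:16]
    return out


def run_obp(
    genomes: Sequence[GenomeRecord],
    config: PipelineConfig | None = None,
    checkpoint_dir: str | Path | None = None,
    resume_from: str | None = None,
) -> tuple[GeneCatalogue, RunManifest]:
    """Run the full eight-stage ortholog pipeline.

    Stage order: reciprocal-hit clustering (1), profile validation (2),
    share-a-protein merging (3), iterative enrichment (4), profile-profile
    merging plus relaxed search (5), translated-genome and ORF-database
    rescue (6/7), synteny support with curated overrides (8), and final
    classification.  Checkpoints (group TSVs) are written after each stage
    when ``checkpoint_dir`` is given; ``resume_from`` restarts after the
    named partial result ("PR1" ... "PR5", "PR67").
    """
    if len(genomes) < 2:
        raise ValueError("the pipeline requires at least two genomes")
    config = config or PipelineConfig()
    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    if resume_from is not None and resume_from not in STAGE_ORDER[:-1]:
        raise ValueError(f"resume_from must be one of {STAGE_ORDER[:-1]}")

    index = ProteinIndex(genomes)
    cache = ProfileCache(index, pseudocount_weight=config.pseudocount_weight)
    scorer = AlignmentScorer()
    stage_counts: dict[str, int] = {}
    resume_idx = STAGE_ORDER.index(resume_from) if resume_from else -1

    def checkpoint(stage: str, groups: list[OrthoGroup]) -> None:
        stage_counts[stage] = len(groups)
        logger.info("stage %s: %d groups", stage, len(groups))
        if ckpt:
            write_groups_tsv(groups, ckpt / f"{stage.lower()}_groups.tsv")

    def load(stage: str) -> list[OrthoGroup]:
        if not ckpt:
            raise ValueError("resume requested without a checkpoint directory")
        groups = read_groups_tsv(ckpt / f"{stage.lower()}_groups.tsv")
        stage_counts[stage] = len(groups)
        # re-register rescued ORF predictions referenced by the checkpoint
        for g in groups:
            for pid in g.protein_ids:
                if pid not in index.records:
                    genome_id, protein_id = pid.split("|", 1)
                    _reregister_orf(index, genome_id, protein_id, config.min_orf_aa)
        return groups

    def stage_done(stage: str) -> bool:
        return resume_idx >= STAGE_ORDER.index(stage)

    groups: list[OrthoGroup]
    if stage_done("PR1"):
        groups = load(STAGE_ORDER[resume_idx])
    if not stage_done("PR1"):
        result = all_vs_all(genomes, evalue_max=config.evalue_pr1, scorer=scorer)
        groups = cluster_pr1(
            result.cross,
            genome_of={qid: index.genome_of(qid) for qid in index.records},
            min_connectivity=config.min_connectivity,
            self_bitscores=result.self_bitscores,
        )
        checkpoint("PR1", groups)
    if not stage_done("PR2"):
        groups = iterate_pr2(
            groups, index, rounds=config.pr2_rounds, evalue=config.evalue_pr2,
            cache=cache,
        )
        checkpoint("PR2", groups)
    if not stage_done("PR3"):
        groups = merge_groups(groups, index)
        checkpoint("PR3", groups)
    if not stage_done("PR4"):
        groups = iterate_pr4(
            groups, index, evalue=config.evalue_pr4, cache=cache
        )
        checkpoint("PR4", groups)
    if not stage_done("PR5"):
        groups = merge_by_profile(
            groups,
            index,
            threshold=config.profile_merge_score,
            relaxed_evalue=config.relaxed_evalue,
            cache=cache,
        )
        checkpoint("PR5", groups)
    if not stage_done("PR67"):
        groups = rescue_by_search(
            groups,
            index,
            scorer=scorer,
            evalue=config.rescue_evalue,
            relaxed_evalue=config.relaxed_evalue,
            min_aa=config.min_orf_aa,
            cache=cache,
        )
        checkpoint("PR67", groups)

    # stage 8: synteny support for near-core groups, plus curated overrides
    n_genomes = index.n_genomes
    anchors = [g for g in groups if len(g.members) == n_genomes]
    if anchors:
        for group in sorted(groups, key=lambda g: g.group_id):
            coverage = len(group.members) / n_genomes
            if coverage >= 1.0 or coverage < config.synteny_min_coverage:
                continue
            decision = synteny_support(
                group,
                anchors,
                index,
                window=config.synteny_window,
                fraction=config.synteny_fraction,
            )
            if decision.decision != "syntenic":
                continue
            taken = set().union(*(g.protein_ids for g in groups))
            for genome_id, pid in sorted(decision.rescue_candidates.items()):
                if pid in taken or genome_id in group.members:
                    continue
                group.members[genome_id] = pid
                group.tag("SYNTENY", f"slot rescue {pid}")
    if config.overrides:
        groups = apply_overrides(groups, config.overrides, index)
    checkpoint("FINAL", groups)

    catalogue = classify_catalogue(
        groups, index, paralog_evalue=config.paralog_evalue, cache=cache
    )
    manifest = RunManifest(
        config=asdict(config),
        input_hashes=_hash_genomes(genomes),
        stage_counts=dict(stage_counts),
    )
    if ckpt:
        manifest.write(ckpt / "manifest.json")
    return catalogue, manifest


def _reregister_orf(
    index: ProteinIndex, genome_id: str, protein_id: str, min_aa: int
) -> None:
    """Recreate a rescued ORF-predicted protein named in a checkpoint."""
    genome = index.genomes[genome_id]
    if not protein_id.startswith("orf_"):
        raise ValueError(f"checkpoint references unknown protein {protein_id}")
    _, start, end, tag = protein_id.split("_")
    strand = "+" if tag == "f" else "-"
    for orf in find_orfs(genome, min_aa):
        if orf.start == int(start) and orf.end == int(end) and orf.strand == strand:
            index.add(translate_orf(genome, orf))
            return
    raise ValueError(f"checkpoint ORF {protein_id} not reproducible in {genome_id}")


# ---------------------------------------------------------------------------
# external genome scan with core profiles


def external_profile_scan(
    profiles: Sequence,
    foreign_genomes: Sequence[GenomeRecord],
    min_aa: int = DEFAULT_MIN_AA,
    evalue_max: float = DEFAULT_PR2_EVALUE,
) -> pd.DataFrame:
    """Presence/absence of core-gene homologues in foreign genomes.

    Each profile is searched against the predicted-ORF proteome of every
    foreign genome (six-frame ORF scan, minimum ``min_aa`` residues).
    """
    if not profiles:
        return pd.DataFrame()
    rows = []
    for genome in foreign_genomes:
        orf_seqs = {}
        for orf in find_orfs(genome, min_aa):
            if orf.spans_origin:
                continue
            rec = translate_orf(genome, orf)
            orf_seqs[rec.qualified_id] = rec.aa_sequence
        row = {"genome_id": genome.genome_id}
        if orf_seqs:
            db = ProteinDatabase(orf_seqs)
            for profile in profiles:
                hits = profile_search(profile, db, evalue_max)
                row[profile.group_id] = bool(hits)
        else:
            for profile in profiles:
                row[profile.group_id] = False
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")
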