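"""Ortholog-group containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

STAGES = ("PR1", "PR2", "PR3", "PR4", "PR5", "PR6", "PR7", "SYNTENY")


@dataclass
class OrthoGroup:
    """A set of putatively orthologous proteins, at most one per genome
    unless a member is explicitly flagged as a paralogous extra copy.

    ``members`` maps genome_id -> protein qualified id for the one-per-genome
    members; ``paralog_flags`` holds additional same-genome copies.
    ``history`` records (stage, action) transitions for provenance.
    """

    group_id: str
    members: dict[str, str] = field(default_factory=dict)
    paralog_flags: set[str] = field(default_factory=set)
    history: list[tuple[str, str]] = field(default_factory=list)

    @property
    def stage_tag(self) -> str:
        return self.history[-1][0] if self.history else ""

    @property
    def genomes(self) -> set[str]:
        return set(self.members)

    @property
    def protein_ids(self) -> set[str]:
        return set(self.members.values()) | set(self.paralog_flags)

    @property
    def size(self) -> int:
        return len(self.members) + len(self.paralog_flags)

    def tag(self, stage: str, action: str = "") -> "OrthoGroup":
        self.history.append((stage, action))
        return self

    def copy(self) -> "OrthoGroup":
        return OrthoGroup(
            group_id=self.group_id,
            members=dict(self.members),
            paralog_flags=set(self.paralog_flags),
            history=list(self.history),
        )


@dataclass
class GeneCatalogue:
    """Final partition of all proteins into ortholog groups and unique genes."""

    groups: list[OrthoGroup]
    unique_genes: list[str]  # qualified protein ids
    n_genomes: int
    taxa: Mapping[str, str] = field(default_factory=dict)  # genome_id -> taxon
    #: every protein in the catalogue's universe (annotated + rescued)
    proteins: dict = field(default_factory=dict)

    @property
    def core_groups(self) -> list[OrthoGroup]:
        return [g for g in self.groups if len(g.members) == self.n_genomes]

    def taxon_shared(self) -> dict[frozenset, list[OrthoGroup]]:
        """Groups keyed by the set of taxa they span (Venn accounting)."""
        out: dict[frozenset, list[OrthoGroup]] = {}
        for g in self.groups:
            key = frozenset(self.taxa.get(gid, "?") for gid in g.members)
            out.setdefault(key, []).append(g)
        return out

    def assignment(self) -> dict[str, str]:
        """protein qualified id -> group_id or 'UNIQUE'."""
        out = {}
        for g in self.groups:
            for pid in g.protein_ids:
                out[pid] = g.group_id
        for pid in self.unique_genes:
            out[pid] = "UNIQUE"
        return out


def write_groups_tsv(groups: Iterable[OrthoGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tgenome_id\tprotein_id\tstage_tag\tparalog\n")
        for g in sorted(groups, key=lambda x: x.group_id):
            for genome_id in sorted(g.members):
                fh.write(
                    f"{g.group_id}\t{genome_id}\t{g.members[genome_id]}\t{g.stage_tag}\t0\n"
                )
            for pid in sorted(g.paralog_flags):
                genome_id = pid.split("|", 1)[0]
                fh.write(f"{g.group_id}\t{genome_id}\t{pid}\t{g.stage_tag}\t1\n")


def read_groups_tsv(path: str | Path) -> list[OrthoGroup]:
    groups: dict[str, OrthoGroup] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group_id"):
            raise ValueError(f"{path}: missing groups header")
        for line in fh:
            gid, genome_id, pid, stage, paralog = line.rstrip("\n").split("\t")
            grp = groups.setdefault(gid, OrthoGroup(group_id=gid))
            if not grp.history:
                grp.tag(stage, "loaded")
            if paralog == "1":
                grp.paralog_flags.add(pid)
            else:
                grp.members[genome_id] = pid
    return [groups[k] for k in sorted(groups)]
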