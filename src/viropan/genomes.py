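"""Genome records, GenBank ingestion, ORF prediction and summary statistics.

The genomes handled here are desk-scale viral chromosomes: a single
(usually circular) dsDNA molecule carrying on the order of 100-200
protein-coding genes.  A :class:`GenomeRecord` bundles the nucleotide
sequence with its annotated protein complement; unannotated coding
potential is recovered with a six-frame ORF scan (:func:`find_orfs`)
that understands origin-spanning genes on circular molecules.

Coordinates follow the GenBank convention throughout: 1-based, inclusive,
on the forward strand; minus-strand features keep forward coordinates
plus a strand flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
VALID_AA = STANDARD_AA | {"X"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: default minimum ORF length in residues (75 nt of coding sequence)
DEFAULT_MIN_AA = 25


class GenomeParseError(ValueError):
    """Raised when a genome flat file cannot be interpreted."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein-coding gene product of a genome.

    ``cds_start``/``cds_end`` are 1-based inclusive nucleotide coordinates
    on the forward representation; for origin-spanning genes on circular
    genomes ``cds_end < cds_start``.  ``source`` records whether the
    protein came from the original annotation or from ORF prediction;
    ``inconsistent`` flags annotated translations that disagree with
    their stated coordinates (kept, not rejected).
    """

    protein_id: str
    genome_id: str
    aa_sequence: str
    cds_start: int
    cds_end: int
    strand: str  # "+" or "-"
    source: str = "annotated"  # or "orf_predicted"
    inconsistent: bool = False

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(f"empty protein sequence for {self.protein_id}")
        bad = set(self.aa_sequence) - VALID_AA
        if bad:
            raise ValueError(
                f"protein {self.protein_id} contains non-amino-acid symbols {sorted(bad)}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def qualified_id(self) -> str:
        """Globally unique id of the form ``genome_id|protein_id``."""
        return f"{self.genome_id}|{self.protein_id}"

    def gene_key(self) -> tuple[str, str, int]:
        """Canonical identity of the underlying gene.

        Two coding features that share a strand and a stop-codon position
        are the same gene even if their annotated start codons differ, so
        the key is the coordinate of the 3' end of the CDS.
        """
        three_prime = self.cds_end if self.strand == "+" else self.cds_start
        return (self.genome_id, self.strand, three_prime)


@dataclass(frozen=True)
class OrfCall:
    """A start-to-stop open reading frame on the forward representation.

    The interval includes the stop codon; ``aa_length`` excludes it.
    Origin-spanning calls on circular genomes have ``spans_origin`` set
    and ``end < start``.
    """

    start: int
    end: int
    strand: str
    frame: int
    aa_length: int
    spans_origin: bool = False


@dataclass
class GenomeRecord:
    """A single viral genome with its protein complement."""

    genome_id: str
    sequence: str
    topology: str = "circular"  # or "linear"
    taxon: str = ""
    annotated_proteins: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.genome_id}: invalid nucleotides {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology!r}")
        for p in self.annotated_proteins:
            for coord in (p.cds_start, p.cds_end):
                if not 1 <= coord <= self.length_bp:
                    raise ValueError(
                        f"protein {p.protein_id}: coordinate {coord} outside "
                        f"[1, {self.length_bp}]"
                    )
            if p.cds_end < p.cds_start and self.topology != "circular":
                raise ValueError(
                    f"protein {p.protein_id}: wrap-around CDS on a linear genome"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        """(G+C)/(A+C+G+T); N excluded from numerator and denominator."""
        counts = {b: self.sequence.count(b) for b in "ACGT"}
        denom = sum(counts.values())
        if denom == 0:
            return 0.0
        return (counts["G"] + counts["C"]) / denom

    def cds_nucleotides(self, protein: ProteinRecord) -> str:
        """Forward-strand-oriented coding sequence of ``protein``."""
        return self.extract(protein.cds_start, protein.cds_end, protein.strand)

    def extract(self, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end] (1-based inclusive), wrapping the origin when end < start."""
        if end >= start:
            nt = self.sequence[start - 1 : end]
        else:
            if self.topology != "circular":
                raise ValueError("wrap-around extraction on a linear genome")
            nt = self.sequence[start - 1 :] + self.sequence[:end]
        return reverse_complement(nt) if strand == "-" else nt


# ---------------------------------------------------------------------------
# translation


def _codon_map() -> dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODON_AA = _codon_map()


def translate_cds(nt: str) -> str:
    """Translate a CDS (stop codon excluded from the output).

    Codons containing N become X; an in-frame premature stop raises.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} is not a multiple of 3")
    aa = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        residue = _CODON_AA.get(codon)
        if residue is None:
            aa.append("X")
            continue
        if residue == "*":
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon at codon {i + 1}")
        aa.append(residue)
    return "".join(aa)


# ---------------------------------------------------------------------------
# GenBank IO


def _location_to_coords(loc, genome_len: int) -> tuple[int, int, str]:
    """Map a (possibly origin-joined) feature location to 1-based coordinates."""
    strand = "-" if loc.strand == -1 else "+"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) != 2:
            raise GenomeParseError(
                f"unsupported compound location with {len(parts)} parts: {loc}"
            )
        first, second = parts
        # an origin-spanning join runs ...end] + [1...
        if int(first.start) == 0 and int(second.end) == genome_len:
            return int(second.start) + 1, int(first.end), strand
        raise GenomeParseError(f"unsupported compound location (not an origin join): {loc}")
    return int(loc.start) + 1, int(loc.end), strand


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read a single-entry GenBank flat file into a :class:`GenomeRecord`.

    Every CDS feature becomes one :class:`ProteinRecord`; features lacking
    a ``/translation`` qualifier are translated from their coordinates.
    Annotated translations that disagree with their coordinates are kept
    but flagged ``inconsistent``.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenomeParseError(f"{path}: {exc}") from exc
    if len(records) != 1:
        raise GenomeParseError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    topology = rec.annotations.get("topology", "linear")
    genome = GenomeRecord(
        genome_id=rec.id or rec.name,
        sequence=str(rec.seq),
        topology=topology if topology in ("circular", "linear") else "linear",
        taxon=rec.annotations.get("organism", "") or "",
    )
    proteins: list[ProteinRecord] = []
    n_unnamed = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        start, end, strand = _location_to_coords(feat.location, genome.length_bp)
        quals = feat.qualifiers
        pid = (
            quals.get("protein_id", [None])[0]
            or quals.get("locus_tag", [None])[0]
            or quals.get("gene", [None])[0]
        )
        if pid is None:
            n_unnamed += 1
            pid = f"cds{n_unnamed:03d}"
        nt = genome.extract(start, end, strand)
        try:
            translated = translate_cds(nt)
        except ValueError:
            translated = None
        stated = quals.get("translation", [None])[0]
        if stated is not None:
            stated = stated.replace("*", "").upper()
            inconsistent = translated is not None and stated != translated
            if translated is None:
                inconsistent = True
            aa = stated
        else:
            if translated is None:
                logger.warning("%s: CDS %s cannot be translated; skipped", path, pid)
                continue
            aa = translated
            inconsistent = False
        proteins.append(
            ProteinRecord(
                protein_id=pid,
                genome_id=genome.genome_id,
                aa_sequence=aa,
                cds_start=start,
                cds_end=end,
                strand=strand,
                source="annotated",
                inconsistent=inconsistent,
            )
        )
    if not proteins:
        logger.warning("%s: genome %s has zero CDS features", path, genome.genome_id)
    genome.annotated_proteins = proteins
    return genome


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a :class:`GenomeRecord` as a GenBank flat file (round-trippable)."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id[:16],
        description=genome.taxon or genome.genome_id,
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
            "organism": genome.taxon,
        },
    )
    for p in genome.annotated_proteins:
        strand = -1 if p.strand == "-" else 1
        if p.cds_end >= p.cds_start:
            loc = FeatureLocation(p.cds_start - 1, p.cds_end, strand=strand)
        else:  # origin-spanning join
            loc = CompoundLocation(
                [
                    FeatureLocation(p.cds_start - 1, genome.length_bp, strand=strand),
                    FeatureLocation(0, p.cds_end, strand=strand),
                ]
            )
        rec.features.append(
            SeqFeature(
                loc,
                type="CDS",
                qualifiers={
                    "protein_id": [p.protein_id],
                    "translation": [p.aa_sequence],
                    "codon_start": ["1"],
                },
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def write_proteome_fasta(genomes: Iterable[GenomeRecord], path: str | Path) -> int:
    """Write all proteins as FASTA with ``genome|protein|start..end|strand`` headers."""
    n = 0
    with open(path, "w") as fh:
        for g in genomes:
            for p in g.annotated_proteins:
                fh.write(
                    f">{g.genome_id}|{p.protein_id}|{p.cds_start}..{p.cds_end}|{p.strand}\n"
                )
                fh.write(p.aa_sequence + "\n")
                n += 1
    return n


def read_fasta_genome(path: str | Path, topology: str = "circular") -> GenomeRecord:
    """Read an unannotated nucleotide FASTA (single entry) as a genome."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenomeParseError(f"{path}: expected one FASTA entry, found {len(records)}")
    rec = records[0]
    return GenomeRecord(genome_id=rec.id, sequence=str(rec.seq), topology=topology)


# ---------------------------------------------------------------------------
# summary statistics


def genome_stats(genomes: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Per-genome summary table: length, GC% (0.1% precision), gene count."""
    if not genomes:
        raise ValueError("genome_stats requires a nonempty genome list")
    rows = [
        {
            "genome_id": g.genome_id,
            "taxon": g.taxon,
            "length_bp": g.length_bp,
            "gc_percent": round(100.0 * g.gc_fraction, 1),
            "n_annotated_genes": len(g.annotated_proteins),
        }
        for g in genomes
    ]
    return pd.DataFrame(rows).sort_values("genome_id", ignore_index=True)


def taxon_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon min/median/max of length and GC content."""
    return (
        stats.groupby("taxon")
        .agg(
            n=("genome_id", "count"),
            length_min=("length_bp", "min"),
            length_median=("length_bp", "median"),
            length_max=("length_bp", "max"),
            gc_min=("gc_percent", "min"),
            gc_median=("gc_percent", "median"),
            gc_max=("gc_percent", "max"),
        )
        .reset_index()
    )


# ---------------------------------------------------------------------------
# ORF prediction


def _scan_frames(seq: str, min_aa: int):
    """Yield (start0, end0, frame) for every ATG paired with its next in-frame
    stop in ``seq`` (0-based half-open), forward orientation only."""
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == START_CODON:
                starts.append(i)
            elif codon in STOP_CODONS:
                for s in starts:
                    aa_len = (i - s) // 3
                    if aa_len >= min_aa:
                        yield s, i + 3, frame
                starts = []


def find_orfs(genome: GenomeRecord, min_aa: int = DEFAULT_MIN_AA) -> list[OrfCall]:
    """All start-to-stop ORFs with >= ``min_aa`` residues, both strands.

    Every ATG is paired with its next in-frame stop, so nested ORFs that
    share a stop codon are all reported.  Circular genomes are scanned on
    a doubled sequence so origin-spanning ORFs are found; calls longer
    than the genome are discarded and duplicates collapsed.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = genome.length_bp
    if n < 3:
        return []
    circular = genome.topology == "circular"
    fwd = genome.sequence * 2 if circular else genome.sequence
    calls: dict[tuple[int, int, str], OrfCall] = {}

    def add(start1: int, end1: int, strand: str, frame: int, aa_len: int) -> None:
        length_nt = end1 - start1 + 1 if end1 >= start1 else n - start1 + 1 + end1
        if length_nt > n:
            return
        spans = end1 < start1
        key = (start1, end1, strand)
        if key not in calls:
            calls[key] = OrfCall(start1, end1, strand, frame, aa_len, spans)

    for s0, e0, frame in _scan_frames(fwd, min_aa):
        start1 = s0 % n + 1
        end1 = (e0 - 1) % n + 1
        if not circular and e0 > n:
            continue
        add(start1, end1, "+", frame, (e0 - s0) // 3 - 1)

    rev = reverse_complement(fwd)
    m = len(fwd)
    for s0, e0, frame in _scan_frames(rev, min_aa):
        # map reverse-scan coordinates back onto the forward representation
        f_start1 = m - (e0 - 1)  # 1-based forward coord of the ORF's last nt
        f_end1 = m - s0
        start1 = (f_start1 - 1) % n + 1
        end1 = (f_end1 - 1) % n + 1
        if not circular and e0 > n:
            continue
        add(start1, end1, "-", frame, (e0 - s0) // 3 - 1)

    return sorted(calls.values(), key=lambda c: (c.start, c.strand, c.end))


def translate_orf(genome: GenomeRecord, call: OrfCall) -> ProteinRecord:
    """Translate an :class:`OrfCall` into an ``orf_predicted`` protein."""
    if call.strand == "+":
        nt = genome.extract(call.start, call.end, "+")
    else:
        nt = genome.extract(call.start, call.end, "-")
    aa = translate_cds(nt)
    if len(aa) != call.aa_length:
        raise ValueError(
            f"ORF at {call.start}..{call.end}{call.strand}: translated length "
            f"{len(aa)} != declared {call.aa_length}"
        )
    pid = f"orf_{call.start}_{call.end}_{'f' if call.strand == '+' else 'r'}"
    return ProteinRecord(
        protein_id=pid,
        genome_id=genome.genome_id,
        aa_sequence=aa,
        cds_start=call.start,
        cds_end=call.end,
        strand=call.strand,
        source="orf_predicted",
    )


def dedupe_proteome(genome: GenomeRecord) -> GenomeRecord:
    """Drop proteins sharing (start, end, strand), keeping the first."""
    seen: set[tuple[int, int, str]] = set()
    kept = []
    for p in genome.annotated_proteins:
        key = (p.cds_start, p.cds_end, p.strand)
        if key in seen:
            continue
        seen.add(key)
        kept.append(p)
    if len(kept) == len(genome.annotated_proteins):
        return genome
    return GenomeRecord(
        genome_id=genome.genome_id,
        sequence=genome.sequence,
        topology=genome.topology,
        taxon=genome.taxon,
        annotated_proteins=kept,
    )
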