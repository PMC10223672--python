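"""Synthetic genome sets with known ortholog ground truth.

The generator emulates a family of large circular dsDNA virus genomes
partitioned into genera: a shared set of single-copy core gene families,
genus-restricted families, per-genome unique genes, occasional paralog
duplications, deliberate annotation omissions (so ORF rescue has work to
do) and conserved local gene order around designated anchor families (so
synteny rescue has work to do).  Genera are star-shaped inside a
star-shaped family tree, which makes realized divergences analytically
predictable; within each genus, genomes are grouped into "species" whose
isolates differ only by a sprinkle of synonymous substitutions, giving a
true species partition for the K2P delimitation step.

Amino-acid divergence is simulated as Poisson substitution events per
branch (uniform replacement over the other 19 residues); the coding
sequence tracks each event with a random codon of the new residue, and
silent divergence is added as synonymous codon exchanges, so nucleotide
distances exceed protein distances the way real coding sequences do.
Everything is driven by one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio.Data import CodonTable

from .genomes import GenomeRecord, ProteinRecord
from .groups import GeneCatalogue

_TABLE = CodonTable.unambiguous_dna_by_id[1]
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    AA_TO_CODONS.setdefault(aa, []).append(codon)
STOP_CODONS = sorted(_TABLE.stop_codons)
AA20 = sorted(AA_TO_CODONS)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic corpus (defaults: 3 genera,
    16 genomes, 10 core families, 2 genus families per genus, ~2.5 unique
    genes per genome)."""

    n_genera: int = 3
    genomes_per_genus: tuple[int, ...] = (6, 5, 5)
    n_core_families: int = 10
    n_genus_families: int = 2  # per genus
    n_unique_per_genome: float = 2.5
    paralog_rate: float = 0.05
    annotation_omission_rate: float = 0.05
    within_genus_aa_divergence: float = 0.10
    between_genus_aa_divergence: float = 0.80
    isolates_per_species: int = 2
    within_species_nt_divergence: float = 0.004
    synonymous_factor: float = 0.5  # silent nt divergence per unit aa divergence
    kappa: float = 2.0
    mean_gene_len_aa: int = 120
    intergenic_len_nt: int = 100
    anchor_families: tuple[int, ...] = (0, 1, 2)  # indices of core families
    shuffle_gene_order: bool = False
    seed: int = 42

    def validate(self) -> None:
        for name in ("paralog_rate", "annotation_omission_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.within_genus_aa_divergence < 0 or self.between_genus_aa_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if len(self.genomes_per_genus) != self.n_genera:
            raise ValueError("genomes_per_genus must list one count per genus")
        genome_nt = (
            (self.n_core_families + self.n_genus_families + self.n_unique_per_genome)
            * (3 * self.mean_gene_len_aa + self.intergenic_len_nt)
        )
        if genome_nt > 10_000_000:
            raise ValueError("configuration would produce genomes above 10 Mb")


GENUS_NAMES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
)


@dataclass(frozen=True)
class PlantedGene:
    family_id: str  # family name, or "unique" singleton family id
    genome_id: str
    protein_id: str
    start: int
    end: int
    strand: str
    label: str  # core | genus | unique | paralog
    omitted: bool = False

    @property
    def qualified_id(self) -> str:
        return f"{self.genome_id}|{self.protein_id}"

    def gene_key(self) -> tuple[str, str, int]:
        three_prime = self.end if self.strand == "+" else self.start
        return (self.genome_id, self.strand, three_prime)


@dataclass
class GroundTruth:
    genes: list[PlantedGene]
    species: dict[str, str]  # genome_id -> species label
    gene_order: dict[str, list[str]]  # genome_id -> family ids in genomic order
    taxa: dict[str, str]  # genome_id -> genus label

    def families(self) -> dict[str, list[PlantedGene]]:
        fams: dict[str, list[PlantedGene]] = {}
        for g in self.genes:
            fams.setdefault(g.family_id, []).append(g)
        return fams

    def core_family_ids(self) -> list[str]:
        return sorted(
            {g.family_id for g in self.genes if g.label in ("core",)}
        )

    def labels(self) -> dict[tuple, str]:
        return {g.gene_key(): g.label for g in self.genes}


# ---------------------------------------------------------------------------
# sequence evolution


def _random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein; starts with M like any ATG-initiated gene product."""
    return "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length - 1))


def _reverse_translate(rng: np.random.Generator, aa: str) -> str:
    return "".join(AA_TO_CODONS[c][rng.integers(len(AA_TO_CODONS[c]))] for c in aa)


def _evolve_branch(
    rng: np.random.Generator,
    aa: str,
    cds: str,
    aa_divergence: float,
    syn_nt_divergence: float,
    indel_rate: float | None = None,
) -> tuple[str, str]:
    """Evolve (protein, CDS) along one branch.

    ``aa_divergence`` is the expected number of amino-acid substitution
    events per site (Poisson, uniform replacement); every event rewrites
    the codon.  ``syn_nt_divergence`` is the expected number of silent
    substitutions per nucleotide site, applied as synonymous codon
    exchanges at untouched positions.
    """
    aa_list = list(aa)
    codons = [cds[3 * i : 3 * i + 3] for i in range(len(aa_list))]
    n_events = rng.poisson(aa_divergence * len(aa_list))
    touched = set()
    for _ in range(n_events):
        # position 0 is the start codon, conserved by purifying selection
        i = int(rng.integers(1, len(aa_list)))
        current = aa_list[i]
        choices = [c for c in AA20 if c != current]
        new = choices[int(rng.integers(len(choices)))]
        aa_list[i] = new
        codons[i] = AA_TO_CODONS[new][int(rng.integers(len(AA_TO_CODONS[new])))]
        touched.add(i)
    # silent changes: expected syn_nt_divergence per nt site -> per codon * 3
    p_codon = min(1.0, syn_nt_divergence * 3.0)
    if p_codon > 0:
        flips = rng.random(len(codons)) < p_codon
        for i in np.nonzero(flips)[0]:
            if i in touched:
                continue
            syns = AA_TO_CODONS[aa_list[i]]
            if len(syns) > 1:
                current = codons[i]
                alts = [c for c in syns if c != current]
                codons[i] = alts[int(rng.integers(len(alts)))]
    # occasional small in-frame indels (1-2 codons), never at the start
    if indel_rate is None:
        indel_rate = 0.03 * aa_divergence
    n_indels = rng.poisson(indel_rate * len(aa_list)) if indel_rate > 0 else 0
    for _ in range(n_indels):
        if len(aa_list) < 30:
            break
        pos = int(rng.integers(1, len(aa_list)))
        size = int(rng.integers(1, 3))
        if rng.random() < 0.5 and len(aa_list) - size >= 30:
            del aa_list[pos : pos + size]
            del codons[pos : pos + size]
        else:
            for k in range(size):
                new = AA20[int(rng.integers(len(AA20)))]
                aa_list.insert(pos + k, new)
                codons.insert(
                    pos + k, AA_TO_CODONS[new][int(rng.integers(len(AA_TO_CODONS[new])))]
                )
    return "".join(aa_list), "".join(codons)


# ---------------------------------------------------------------------------
# dataset assembly


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[list[GenomeRecord], GroundTruth]:
    """Generate a genome corpus with complete planted ground truth."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    genera = [GENUS_NAMES[i] for i in range(config.n_genera)]
    within = config.within_genus_aa_divergence
    between = config.between_genus_aa_divergence
    genus_branch = max(0.0, (between - within) / 2.0)
    species_branch = within / 2.0
    isolate_syn = config.within_species_nt_divergence / 2.0
    syn = config.synonymous_factor

    # family roots
    core_ids = [f"core{i:02d}" for i in range(config.n_core_families)]
    genus_fam_ids = {
        genus: [f"{genus}_fam{i:02d}" for i in range(config.n_genus_families)]
        for genus in genera
    }
    roots: dict[str, tuple[str, str]] = {}
    strands: dict[str, str] = {}
    for fam in core_ids + [f for fams in genus_fam_ids.values() for f in fams]:
        length = max(50, int(rng.normal(config.mean_gene_len_aa, config.mean_gene_len_aa / 4)))
        aa = _random_protein(rng, length)
        roots[fam] = (aa, _reverse_translate(rng, aa))
        strands[fam] = "+" if rng.random() < 0.7 else "-"

    # genus-level ancestors of core families
    genus_core: dict[tuple[str, str], tuple[str, str]] = {}
    for genus in genera:
        for fam in core_ids:
            aa, cds = roots[fam]
            genus_core[(genus, fam)] = _evolve_branch(
                rng, aa, cds, genus_branch, syn * genus_branch
            )

    # genome roster: species of `isolates_per_species` isolates per genus
    genomes_meta = []  # (genome_id, genus, species_label)
    for genus, n_genomes in zip(genera, config.genomes_per_genus):
        s = 0
        remaining = n_genomes
        while remaining > 0:
            take = min(config.isolates_per_species, remaining)
            s += 1
            species_label = f"{genus}_sp{s}"
            for k in range(take):
                genome_id = f"{species_label}_i{k + 1}"
                genomes_meta.append((genome_id, genus, species_label))
            remaining -= take

    # species-level ancestors for every family carried by that species
    species_seen: dict[str, dict[str, tuple[str, str]]] = {}
    for genome_id, genus, species in genomes_meta:
        if species in species_seen:
            continue
        fams: dict[str, tuple[str, str]] = {}
        for fam in core_ids:
            aa, cds = genus_core[(genus, fam)]
            fams[fam] = _evolve_branch(rng, aa, cds, species_branch, syn * species_branch)
        for fam in genus_fam_ids[genus]:
            aa, cds = roots[fam]
            fams[fam] = _evolve_branch(rng, aa, cds, species_branch, syn * species_branch)
        species_seen[species] = fams

    # per-genome gene complements
    planted: list[PlantedGene] = []
    genomes: list[GenomeRecord] = []
    gene_order: dict[str, list[str]] = {}
    taxa: dict[str, str] = {}
    species_of: dict[str, str] = {}

    n_total = len(genomes_meta)
    total_unique = int(round(config.n_unique_per_genome * n_total))
    base_unique = total_unique // n_total
    extra_unique = total_unique - base_unique * n_total

    unique_counter = 0
    for idx, (genome_id, genus, species) in enumerate(genomes_meta):
        taxa[genome_id] = genus
        species_of[genome_id] = species
        fam_seqs = species_seen[species]
        carried = core_ids + genus_fam_ids[genus]

        genes: list[dict] = []  # family, aa, cds, strand, label, omitted
        for fam in carried:
            aa, cds = fam_seqs[fam]
            aa, cds = _evolve_branch(rng, aa, cds, 0.0, isolate_syn)
            label = "core" if fam in core_ids else "genus"
            omitted = (
                rng.random() < config.annotation_omission_rate
            )
            genes.append(
                dict(family=fam, aa=aa, cds=cds, strand=strands[fam], label=label,
                     omitted=omitted)
            )
            if rng.random() < config.paralog_rate:
                p_aa, p_cds = _evolve_branch(rng, aa, cds, 0.05, 0.02)
                genes.append(
                    dict(family=fam, aa=p_aa, cds=p_cds, strand=strands[fam],
                         label="paralog", omitted=False)
                )
        n_unique = base_unique + (1 if idx < extra_unique else 0)
        for _ in range(n_unique):
            unique_counter += 1
            length = max(50, int(rng.normal(config.mean_gene_len_aa, config.mean_gene_len_aa / 4)))
            aa = _random_protein(rng, length)
            genes.append(
                dict(family=f"unique{unique_counter:04d}", aa=aa,
                     cds=_reverse_translate(rng, aa),
                     strand="+" if rng.random() < 0.5 else "-",
                     label="unique", omitted=False)
            )

        # gene order: anchors and family genes keep canonical order; unique
        # genes are interleaved at random positions; optional full shuffle
        family_genes = [g for g in genes if g["label"] in ("core", "genus", "paralog")]
        unique_genes = [g for g in genes if g["label"] == "unique"]
        if config.shuffle_gene_order:
            order = list(rng.permutation(len(family_genes)))
            family_genes = [family_genes[i] for i in order]
        ordered = list(family_genes)
        for g in unique_genes:
            pos = int(rng.integers(len(ordered) + 1))
            ordered.insert(pos, g)
        rotation = int(rng.integers(len(ordered)))
        ordered = ordered[rotation:] + ordered[:rotation]

        # assemble the circular genome
        seq_parts: list[str] = []
        pos = 0
        proteins: list[ProteinRecord] = []
        order_names: list[str] = []
        counter = 0
        for g in ordered:
            spacer_len = max(20, int(rng.poisson(config.intergenic_len_nt)))
            spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
            seq_parts.append(spacer)
            pos += spacer_len
            counter += 1
            stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
            cds_full = g["cds"] + stop
            insert = cds_full if g["strand"] == "+" else _revcomp(cds_full)
            start = pos + 1
            end = pos + len(insert)
            seq_parts.append(insert)
            pos = end
            pid = f"g{counter:03d}_{g['family']}"
            planted.append(
                PlantedGene(
                    family_id=g["family"],
                    genome_id=genome_id,
                    protein_id=pid,
                    start=start,
                    end=end,
                    strand=g["strand"],
                    label=g["label"],
                    omitted=g["omitted"],
                )
            )
            order_names.append(g["family"])
            if not g["omitted"]:
                proteins.append(
                    ProteinRecord(
                        protein_id=pid,
                        genome_id=genome_id,
                        aa_sequence=g["aa"],
                        cds_start=start,
                        cds_end=end,
                        strand=g["strand"],
                        source="annotated",
                    )
                )
        genome = GenomeRecord(
            genome_id=genome_id,
            sequence="".join(seq_parts),
            topology="circular",
            taxon=genus,
            annotated_proteins=proteins,
        )
        genomes.append(genome)
        gene_order[genome_id] = order_names

    truth = GroundTruth(
        genes=planted, species=species_of, gene_order=gene_order, taxa=taxa
    )
    return genomes, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# scoring a result against the planted truth


def co_clustering_pairs(clusters: Mapping[str, set]) -> set[frozenset]:
    pairs = set()
    for members in clusters.values():
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(frozenset((members[i], members[j])))
    return pairs


@dataclass(frozen=True)
class PlantedMetrics:
    precision: float
    recall: float
    core_count_error: int
    species_ari: float


def planted_metrics(
    result: GeneCatalogue,
    truth: GroundTruth,
    protein_index: Mapping[str, ProteinRecord],
    species_assignment: Mapping[str, int] | None = None,
) -> PlantedMetrics:
    """Score a recovered catalogue against the planted truth.

    Genes are matched by (genome, strand, 3'-end) so ORF-rescued members
    with re-predicted start codons still count.  Precision/recall are
    pair-level over co-clustered gene pairs; the species score is the
    adjusted Rand index of the recovered vs planted isolate partitions
    (1.0 when no partition is supplied but the truth is trivial).
    """
    from sklearn.metrics import adjusted_rand_score

    truth_clusters: dict[str, set] = {}
    for gene in truth.genes:
        if gene.label == "unique":
            continue
        truth_clusters.setdefault(gene.family_id, set()).add(gene.gene_key())
    truth_pairs = co_clustering_pairs(truth_clusters)

    result_clusters: dict[str, set] = {}
    for grp in result.groups:
        keys = set()
        for pid in grp.protein_ids:
            rec = protein_index.get(pid)
            if rec is not None:
                keys.add(rec.gene_key())
        result_clusters[grp.group_id] = keys
    result_pairs = co_clustering_pairs(result_clusters)

    tp = len(truth_pairs & result_pairs)
    precision = tp / len(result_pairs) if result_pairs else 0.0
    recall = tp / len(truth_pairs) if truth_pairs else 1.0

    n_core_truth = len(truth.core_family_ids())
    core_count_error = abs(len(result.core_groups) - n_core_truth)

    if species_assignment is None:
        species_ari = 1.0 if len(set(truth.species.values())) == len(truth.species) else 0.0
    else:
        isolates = sorted(truth.species)
        true_labels = [truth.species[i] for i in isolates]
        pred_labels = [species_assignment[i] for i in isolates]
        species_ari = float(adjusted_rand_score(true_labels, pred_labels))
    return PlantedMetrics(
        precision=precision,
        recall=recall,
        core_count_error=core_count_error,
        species_ari=species_ari,
    )


def write_truth_tsv(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tgenome_id\tprotein_id\tstart\tend\tstrand\tlabel\tomitted\tspecies\n")
        for g in truth.genes:
            fh.write(
                f"{g.family_id}\t{g.genome_id}\t{g.protein_id}\t{g.start}\t{g.end}\t"
                f"{g.strand}\t{g.label}\t{int(g.omitted)}\t{truth.species[g.genome_id]}\n"
            )
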