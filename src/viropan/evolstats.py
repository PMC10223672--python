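"""Homology and divergence statistics.

Three quantitative tools sit downstream of the ortholog catalogue:

* pairwise identity/similarity percentages from global alignments
  (Needle-style scoring: BLOSUM62, gap open 10, extend 0.5, free end gaps);
* a shuffle-null Z-score for remote homology: the natural-pair global
  alignment score is compared with the score distribution obtained
  against composition-preserving shuffles of the partner,
  z = (S_nat - mean(S_shuffled)) / sd(S_shuffled);
* Kimura 2-parameter (K2P) nucleotide distances on codon alignments of
  concatenated core genes, d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q), which
  drive the species delimitation step (single-linkage at a conspecific
  threshold, with a distinct-species threshold above it and a flagged
  borderline band between).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genomes import GenomeRecord
from .groups import GeneCatalogue
from .profiles import build_msa

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
PURINES = {"A", "G"}

DEFAULT_N_SHUFFLES = 297
DEFAULT_SPECIES_LOW = 0.015
DEFAULT_SPECIES_HIGH = 0.050

UNDEFINED = float("nan")


def make_global_aligner(
    gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    """Needle-style global aligner: BLOSUM62, affine gaps, free end gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    try:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    except AttributeError:  # older attribute spelling
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0
    return aligner


_GLOBAL = make_global_aligner()
_BLOSUM = substitution_matrices.load("BLOSUM62")


def _global_alignment_rows(a: str, b: str) -> tuple[str, str]:
    aln = _GLOBAL.align(a, b)[0]
    a_segs, b_segs = aln.aligned
    a_out, b_out = [], []
    prev_a = prev_b = 0
    for (a0, a1), (b0, b1) in zip(a_segs, b_segs):
        if a0 > prev_a:
            a_out.append(a[prev_a:a0])
            b_out.append("-" * (a0 - prev_a))
        if b0 > prev_b:
            a_out.append("-" * (b0 - prev_b))
            b_out.append(b[prev_b:b0])
        a_out.append(a[a0:a1])
        b_out.append(b[b0:b1])
        prev_a, prev_b = a1, b1
    if prev_a < len(a):
        a_out.append(a[prev_a:])
        b_out.append("-" * (len(a) - prev_a))
    if prev_b < len(b):
        a_out.append("-" * (len(b) - prev_b))
        b_out.append(b[prev_b:])
    return "".join(a_out), "".join(b_out)


def identity_similarity(a: str, b: str) -> tuple[float, float]:
    """Percent identity and percent similarity from a global alignment.

    Identity counts identical columns; similarity additionally counts
    substitutions with a positive BLOSUM62 score.  Both are percentages
    of the full alignment length (gap columns included), so
    similarity >= identity always.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    row_a, row_b = _global_alignment_rows(a, b)
    n_cols = len(row_a)
    ident = similar = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        elif float(_BLOSUM[x, y]) > 0:
            similar += 1
    return 100.0 * ident / n_cols, 100.0 * (ident + similar) / n_cols


def shuffle_protein(seq: str, seed: int) -> str:
    """Uniform random permutation of the residues (composition preserved)."""
    chars = list(seq)
    random.Random(seed).shuffle(chars)
    return "".join(chars)


@dataclass(frozen=True)
class ZScoreResult:
    S_natS: float
    A_shfS_natS: float
    s: float
    z: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.z)


def zscore_from_stats(s_nat: float, decoy_mean: float, decoy_sd: float) -> float:
    """z = (S_nat - mean) / sd; the defining identity of the statistic."""
    if decoy_sd <= 0:
        return UNDEFINED
    return (s_nat - decoy_mean) / decoy_sd


def zscore(
    nat_a: str,
    nat_b: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    aligner: Align.PairwiseAligner | None = None,
) -> ZScoreResult:
    """Shuffle-null Z-score of the global alignment of two proteins.

    ``nat_a`` is aligned against ``n_shuffles`` composition-preserving
    shuffles of ``nat_b``; shuffles are reproducible per seed.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    aligner = aligner or _GLOBAL
    s_nat = float(aligner.score(nat_a, nat_b))
    rng = random.Random(seed)
    decoy_scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        decoy = shuffle_protein(nat_b, rng.randrange(2**31))
        decoy_scores[i] = aligner.score(nat_a, decoy)
    mean = float(np.mean(decoy_scores))
    sd = float(np.std(decoy_scores, ddof=1))
    z = zscore_from_stats(s_nat, mean, sd)
    return ZScoreResult(S_natS=s_nat, A_shfS_natS=mean, s=sd, z=z)


# ---------------------------------------------------------------------------
# Kimura 2-parameter distances


@dataclass(frozen=True)
class K2PDistance:
    P: float
    Q: float
    d: float
    n_sites: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.d)


def k2p(a: str, b: str) -> K2PDistance:
    """K2P distance between two aligned nucleotide sequences.

    Sites with a gap or a non-ACGT symbol in either sequence are excluded
    (pairwise deletion).  Returns an undefined sentinel (d = NaN) when a
    logarithm argument is non-positive or no sites remain.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    a = a.upper()
    b = b.upper()
    n = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        return K2PDistance(P=0.0, Q=0.0, d=UNDEFINED, n_sites=0)
    P = transitions / n
    Q = transversions / n
    one = 1.0 - 2.0 * P - Q
    two = 1.0 - 2.0 * Q
    if one <= 0 or two <= 0:
        return K2PDistance(P=P, Q=Q, d=UNDEFINED, n_sites=n)
    d = -0.5 * math.log(one) - 0.25 * math.log(two)
    return K2PDistance(P=P, Q=Q, d=d, n_sites=n)


def evolve_k2p(seq: str, d: float, kappa: float, rng: np.random.Generator) -> str:
    """Evolve a nucleotide sequence along a branch of K2P length ``d``.

    Uses the exact K2P substitution probabilities with
    transition/transversion rate ratio ``kappa``; expected number of
    substitutions per site equals ``d``.
    """
    if d < 0 or kappa <= 0:
        raise ValueError("d must be >= 0 and kappa > 0")
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_transition = (
        0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    )
    p_transversion_each = 0.25 - 0.25 * math.exp(-4.0 * beta_t)
    ts_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_partners = {
        "A": ("C", "T"),
        "G": ("C", "T"),
        "C": ("A", "G"),
        "T": ("A", "G"),
    }
    u = rng.random(len(seq))
    pick = rng.random(len(seq))
    out = []
    for i, base in enumerate(seq):
        if base not in "ACGT":
            out.append(base)
            continue
        if u[i] < p_transition:
            out.append(ts_partner[base])
        elif u[i] < p_transition + 2 * p_transversion_each:
            out.append(tv_partners[base][0 if pick[i] < 0.5 else 1])
        else:
            out.append(base)
    return "".join(out)


@dataclass
class K2PMatrix:
    ids: list[str]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    n_sites: np.ndarray

    def pair(self, i: str, j: str) -> float:
        return float(self.d[self.ids.index(i), self.ids.index(j)])

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.d[i])
                fh.write(f"{name:<12s} {row}\n")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    def taxon_summary(self, taxa: Mapping[str, str]):
        """Within/between-taxon distance summaries (median, min, max)."""
        import pandas as pd

        rows = []
        buckets: dict[tuple[str, str], list[float]] = {}
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                ta = taxa.get(self.ids[i], "?")
                tb = taxa.get(self.ids[j], "?")
                key = tuple(sorted((ta, tb)))
                buckets.setdefault(key, []).append(float(self.d[i, j]))
        for (ta, tb), vals in sorted(buckets.items()):
            arr = np.array(vals)
            rows.append(
                {
                    "taxon_a": ta,
                    "taxon_b": tb,
                    "kind": "within" if ta == tb else "between",
                    "n_pairs": len(vals),
                    "median": float(np.nanmedian(arr)),
                    "min": float(np.nanmin(arr)),
                    "max": float(np.nanmax(arr)),
                }
            )
        return pd.DataFrame(rows)

    def neighbor_joining_newick(self) -> str:
        """Neighbor-joining tree on the distance matrix (plumbing only)."""
        from skbio import DistanceMatrix
        from skbio.tree import nj

        dm = DistanceMatrix(np.nan_to_num(self.d, nan=np.nanmax(self.d[np.isfinite(self.d)]) * 2 if np.isfinite(self.d).any() else 1.0), ids=self.ids)
        return str(nj(dm)).strip()


def codon_backthread(protein_row: str, cds: str) -> str:
    """Thread a gapped protein row back onto its coding sequence.

    Each residue consumes one codon; protein gaps become gap triplets.
    The stop codon (and any trailing nucleotides) are dropped.
    """
    out = []
    pos = 0
    for c in protein_row:
        if c == "-":
            out.append("---")
        else:
            out.append(cds[pos : pos + 3])
            pos += 3
    return "".join(out)


def core_concat_alignment(
    catalogue: GeneCatalogue,
    genomes: Sequence[GenomeRecord],
    core_ids: Sequence[str] | None = None,
) -> dict[str, str]:
    """Codon alignment of the concatenated core genes, one row per genome.

    For each core group (canonical order: ascending group_id) the protein
    MSA is built and back-threaded onto the nucleotide ORFs; the per-group
    codon alignments are concatenated.
    """
    by_genome = {g.genome_id: g for g in genomes}
    proteins = {
        p.qualified_id: (g, p) for g in genomes for p in g.annotated_proteins
    }
    # rescued ORF-predicted members live in the catalogue, not the annotation
    for pid, rec in getattr(catalogue, "proteins", {}).items():
        if pid not in proteins and rec.genome_id in by_genome:
            proteins[pid] = (by_genome[rec.genome_id], rec)
    groups = {g.group_id: g for g in catalogue.groups}
    if core_ids is None:
        core_ids = sorted(g.group_id for g in catalogue.core_groups)
    concat: dict[str, list[str]] = {gid: [] for gid in by_genome}
    for group_id in sorted(core_ids):
        group = groups[group_id]
        missing = set(by_genome) - set(group.members)
        if missing:
            raise ValueError(
                f"group {group_id} missing from genome(s) {sorted(missing)}"
            )
        seqs = {}
        cds = {}
        for genome_id, pid in group.members.items():
            genome, prot = proteins[pid]
            seqs[pid] = prot.aa_sequence
            cds[pid] = genome.cds_nucleotides(prot)
        msa = build_msa(seqs)
        for sid, row in zip(msa.ids, msa.rows):
            genome_id = sid.split("|", 1)[0]
            concat[genome_id].append(codon_backthread(row, cds[sid]))
    return {gid: "".join(parts) for gid, parts in sorted(concat.items())}


def core_concat_distances(
    catalogue: GeneCatalogue,
    genomes: Sequence[GenomeRecord],
    core_ids: Sequence[str] | None = None,
) -> K2PMatrix:
    """Pairwise K2P distances on the concatenated core-gene codon alignment."""
    rows = core_concat_alignment(catalogue, genomes, core_ids)
    ids = sorted(rows)
    n = len(ids)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p(rows[ids[i]], rows[ids[j]])
            d[i, j] = d[j, i] = res.d
            P[i, j] = P[j, i] = res.P
            Q[i, j] = Q[j, i] = res.Q
            sites[i, j] = sites[j, i] = res.n_sites
    return K2PMatrix(ids=ids, d=d, P=P, Q=Q, n_sites=sites)


# ---------------------------------------------------------------------------
# species delimitation


@dataclass
class SpeciesPartition:
    assignment: dict[str, int]
    borderline: list[tuple[str, str]]
    low: float
    high: float
    linkage: str = "single"

    @property
    def n_species(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for k, v in self.assignment.items():
            out.setdefault(v, []).append(k)
        return [sorted(members) for _, members in sorted(out.items())]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("isolate\tspecies_cluster\n")
            for iso in sorted(self.assignment):
                fh.write(f"{iso}\t{self.assignment[iso]}\n")


def delimit_species(
    matrix: K2PMatrix,
    low: float = DEFAULT_SPECIES_LOW,
    high: float = DEFAULT_SPECIES_HIGH,
) -> SpeciesPartition:
    """Single-linkage species clusters from a K2P distance matrix.

    Pairs with d < ``low`` are conspecific; pairs with d > ``high`` are
    distinct; pairs in between follow the linkage closure and are flagged
    borderline when the closure leaves them in different species.
    Undefined distances are treated as larger than ``high``.
    """
    if not 0 <= low <= high:
        raise ValueError("need 0 <= low <= high")
    graph = nx.Graph()
    graph.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            dij = matrix.d[i, j]
            if not math.isnan(dij) and dij < low:
                graph.add_edge(matrix.ids[i], matrix.ids[j])
    assignment: dict[str, int] = {}
    for k, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    ):
        for node in comp:
            assignment[node] = k
    borderline = []
    for i in range(n):
        for j in range(i + 1, n):
            dij = matrix.d[i, j]
            if math.isnan(dij):
                continue
            if low <= dij <= high and assignment[matrix.ids[i]] != assignment[matrix.ids[j]]:
                borderline.append((matrix.ids[i], matrix.ids[j]))
    return SpeciesPartition(
        assignment=assignment, borderline=sorted(borderline), low=low, high=high
    )
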