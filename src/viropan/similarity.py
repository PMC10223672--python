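"""All-vs-all protein similarity and reciprocal-hit graph clustering.

This is the first stage of the ortholog pipeline: every protein of every
genome is compared with every protein of every other genome by optimal
local alignment (BLOSUM62, affine gaps 11/1), raw scores are converted to
bit scores and e-values with Karlin-Altschul statistics, and the
reciprocal-hit graph is cut into candidate ortholog groups.  Components
whose algebraic connectivity (the second-smallest eigenvalue of the graph
Laplacian) falls below a minimum are split recursively along the Fiedler
vector, so loosely bridged families do not collapse into one group.

The alignment engine is pluggable; the default backend is Biopython's
C pairwise aligner, which computes the exact Smith-Waterman optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genomes import VALID_AA, GenomeRecord
from .groups import OrthoGroup

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1
# (the standard values used for gapped protein search statistics).
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_EVALUE_MAX = 1e-7
DEFAULT_MIN_CONNECTIVITY = 0.3


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    aln_coverage_query: float = 1.0
    aln_coverage_subject: float = 1.0


class AlignmentScorer:
    """Optimal local protein alignment under BLOSUM62 with affine gaps.

    ``pairwise_align`` returns the exact optimal score together with one
    optimal aligned pair; tie-breaking among co-optimal alignments is the
    backend's fixed deterministic order.
    """

    def __init__(
        self,
        matrix: str = "BLOSUM62",
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
    ) -> None:
        self.matrix_name = matrix
        self.matrix = substitution_matrices.load(matrix)
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = self.matrix
        self._aligner.open_gap_score = -gap_open
        self._aligner.extend_gap_score = -gap_extend

    @staticmethod
    def _check(seq: str, label: str) -> None:
        if not seq:
            raise ValueError(f"{label}: empty sequence")
        bad = set(seq) - VALID_AA
        if bad:
            raise ValueError(f"{label}: non-amino-acid symbols {sorted(bad)}")

    def score(self, a: str, b: str) -> float:
        self._check(a, "query")
        self._check(b, "subject")
        return float(self._aligner.score(a, b))

    def pairwise_align(self, a: str, b: str) -> tuple[float, tuple[str, str]]:
        self._check(a, "query")
        self._check(b, "subject")
        aln = self._aligner.align(a, b)[0]
        a_aln, b_aln = _format_alignment(aln, a, b)
        return float(aln.score), (a_aln, b_aln)

    def bitscore(self, raw: float) -> float:
        return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)

    def evalue(self, raw: float, query_len: int, db_residues: int) -> float:
        return query_len * db_residues * 2.0 ** (-self.bitscore(raw))


def _format_alignment(aln, a: str, b: str) -> tuple[str, str]:
    """Render one optimal local alignment as a gapped string pair."""
    (a_segs, b_segs) = aln.aligned
    a_out, b_out = [], []
    prev_a, prev_b = a_segs[0][0], b_segs[0][0]
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
    return "".join(a_out), "".join(b_out)


def pairwise_align(
    a: str,
    b: str,
    scorer: AlignmentScorer | None = None,
) -> tuple[float, tuple[str, str]]:
    """Module-level convenience over :class:`AlignmentScorer.pairwise_align`."""
    return (scorer or AlignmentScorer()).pairwise_align(a, b)


# ---------------------------------------------------------------------------
# all-vs-all search


@dataclass
class SearchResult:
    """Cross-genome hits plus within-genome hits (kept for paralog calls)
    and per-protein self-alignment bit scores (used as edge-weight
    normalizers)."""

    cross: list[SimilarityHit]
    within: list[SimilarityHit]
    self_bitscores: dict[str, float]


def all_vs_all(
    genomes: Sequence[GenomeRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    scorer: AlignmentScorer | None = None,
) -> SearchResult:
    """Exhaustive pairwise similarity search over all proteomes.

    Hits are symmetric: whenever (q, s) passes the e-value cut, (s, q) is
    reported too.  Within-genome (including self) comparisons are kept in
    a separate list for later paralog analysis.
    """
    if len(genomes) < 2:
        raise ValueError("all_vs_all requires at least two genomes")
    scorer = scorer or AlignmentScorer()
    proteins: list[tuple[str, str, str]] = []  # (qualified_id, genome_id, seq)
    for g in genomes:
        if not g.annotated_proteins:
            logger.warning("genome %s has an empty proteome; skipped", g.genome_id)
            continue
        for p in g.annotated_proteins:
            proteins.append((p.qualified_id, g.genome_id, p.aa_sequence))
    proteins.sort(key=lambda t: t[0])
    db_residues = sum(len(seq) for _, _, seq in proteins)

    self_bit = {
        pid: scorer.bitscore(scorer.score(seq, seq)) for pid, _, seq in proteins
    }

    cross: list[SimilarityHit] = []
    within: list[SimilarityHit] = []
    n = len(proteins)
    for i in range(n):
        pid_i, gen_i, seq_i = proteins[i]
        for j in range(i, n):
            pid_j, gen_j, seq_j = proteins[j]
            same_genome = gen_i == gen_j
            raw = scorer.score(seq_i, seq_j)
            bit = scorer.bitscore(raw)
            ev_fwd = len(seq_i) * db_residues * 2.0 ** (-bit)
            ev_rev = len(seq_j) * db_residues * 2.0 ** (-bit)
            if same_genome:
                if ev_fwd <= evalue_max:
                    within.append(SimilarityHit(pid_i, pid_j, bit, ev_fwd))
                if i != j and ev_rev <= evalue_max:
                    within.append(SimilarityHit(pid_j, pid_i, bit, ev_rev))
            else:
                if ev_fwd <= evalue_max:
                    cross.append(SimilarityHit(pid_i, pid_j, bit, ev_fwd))
                if ev_rev <= evalue_max:
                    cross.append(SimilarityHit(pid_j, pid_i, bit, ev_rev))
    return SearchResult(cross=cross, within=within, self_bitscores=self_bit)


# ---------------------------------------------------------------------------
# spectral clustering of the reciprocal-hit graph


def algebraic_connectivity(
    graph: nx.Graph,
    normalized: bool = True,
) -> float:
    """Second-smallest Laplacian eigenvalue of ``graph``.

    Zero (within numerical tolerance) iff the graph is disconnected; a
    single-node graph is trivially connected and returns +inf.
    """
    n = graph.number_of_nodes()
    if n < 1:
        raise ValueError("empty graph")
    if n == 1:
        return math.inf
    nodes = sorted(graph.nodes)
    if normalized:
        lap = nx.normalized_laplacian_matrix(graph, nodelist=nodes, weight="weight")
    else:
        lap = nx.laplacian_matrix(graph, nodelist=nodes, weight="weight")
    vals = np.linalg.eigvalsh(np.asarray(lap.todense(), dtype=float))
    lam2 = float(np.sort(vals)[1])
    return max(lam2, 0.0) if lam2 > -1e-9 else lam2


def fiedler_partition(graph: nx.Graph, normalized: bool = True) -> tuple[set, set]:
    """Split a graph by the sign pattern of its Fiedler vector.

    Zero entries (|v| < 1e-12) are assigned to the smaller side for
    determinism.
    """
    nodes = sorted(graph.nodes)
    if normalized:
        lap = nx.normalized_laplacian_matrix(graph, nodelist=nodes, weight="weight")
    else:
        lap = nx.laplacian_matrix(graph, nodelist=nodes, weight="weight")
    vals, vecs = np.linalg.eigh(np.asarray(lap.todense(), dtype=float))
    fiedler = vecs[:, np.argsort(vals)[1]]
    # fix the global sign for determinism
    for v in fiedler:
        if abs(v) > 1e-12:
            if v < 0:
                fiedler = -fiedler
            break
    pos = {n for n, v in zip(nodes, fiedler) if v > 1e-12}
    neg = {n for n, v in zip(nodes, fiedler) if v < -1e-12}
    zeros = [n for n, v in zip(nodes, fiedler) if abs(v) <= 1e-12]
    small, large = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    small |= set(zeros)
    return small, large


def build_reciprocal_graph(
    hits: Iterable[SimilarityHit],
    self_bitscores: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Undirected graph whose edges are reciprocal hit pairs.

    Edge weight is the hit bit score normalized by the smaller of the two
    self-alignment bit scores (clamped to 1), so a perfect reciprocal
    match weighs 1.0.
    """
    directed: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        directed[key] = max(directed.get(key, -math.inf), h.bitscore)
    graph = nx.Graph()
    for (q, s), bit in directed.items():
        if (s, q) not in directed:
            continue
        if graph.has_edge(q, s):
            continue
        best = max(bit, directed[(s, q)])
        if self_bitscores:
            denom = min(
                self_bitscores.get(q, math.inf), self_bitscores.get(s, math.inf)
            )
            weight = min(best / denom, 1.0) if math.isfinite(denom) and denom > 0 else 1.0
        else:
            weight = 1.0
        graph.add_edge(q, s, weight=weight)
    return graph


def _split_until_connected(
    graph: nx.Graph, min_connectivity: float, normalized: bool
) -> list[set]:
    clusters: list[set] = []
    stack = [set(c) for c in nx.connected_components(graph)]
    while stack:
        nodes = stack.pop()
        if len(nodes) <= 2:
            clusters.append(nodes)
            continue
        sub = graph.subgraph(nodes)
        lam2 = algebraic_connectivity(sub, normalized=normalized)
        if lam2 >= min_connectivity:
            clusters.append(nodes)
            continue
        side_a, side_b = fiedler_partition(sub, normalized=normalized)
        if not side_a or not side_b:
            clusters.append(nodes)  # degenerate eigenvector; accept as-is
            continue
        for side in (side_a, side_b):
            sub_side = graph.subgraph(side)
            stack.extend(set(c) for c in nx.connected_components(sub_side))
    return clusters


def cluster_pr1(
    hits: Iterable[SimilarityHit],
    genome_of: Mapping[str, str],
    min_connectivity: float = DEFAULT_MIN_CONNECTIVITY,
    self_bitscores: Mapping[str, float] | None = None,
    normalized: bool = True,
) -> list[OrthoGroup]:
    """Extract stage-1 ortholog groups from the reciprocal-hit graph.

    Connected components are split recursively wherever their algebraic
    connectivity is below ``min_connectivity``; surviving clusters of
    size >= 2 spanning >= 2 genomes become groups tagged PR1.  When a
    cluster carries several proteins of one genome, the lexicographically
    first becomes the representative member and the rest are
    paralog-flagged.
    """
    graph = build_reciprocal_graph(hits, self_bitscores)
    clusters = _split_until_connected(graph, min_connectivity, normalized)
    clusters = [c for c in clusters if len(c) >= 2]
    clusters = [
        c for c in clusters if len({genome_of[p] for p in c}) >= 2
    ]
    clusters.sort(key=lambda c: sorted(c))
    groups = []
    for i, cluster in enumerate(clusters, start=1):
        grp = OrthoGroup(group_id=f"OG{i:04d}")
        for pid in sorted(cluster):
            gen = genome_of[pid]
            if gen in grp.members:
                grp.paralog_flags.add(pid)
            else:
                grp.members[gen] = pid
        grp.tag("PR1", "spectral cluster")
        groups.append(grp)
    return groups


# ---------------------------------------------------------------------------
# BLAST-tabular IO


def write_hits_tsv(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in BLAST tabular (outfmt-6-like) TSV."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t.\t.\t.\t.\t.\t.\t.\t.\t"
                f"{h.evalue:.3g}\t{h.bitscore:.2f}\n"
            )


def read_hits_tsv(path: str | Path) -> list[SimilarityHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            hits.append(
                SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            )
    return hits
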