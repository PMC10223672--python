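"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def smith_waterman_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Quadratic-space affine-gap Smith-Waterman, written independently of
    the package's aligner (three explicit DP matrices, no vectorization)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open)
            diag = H[i - 1][j - 1] + float(_BLOSUM[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def six_frame_orfs_bruteforce(sequence: str, circular: bool, min_aa: int):
    """Enumerate every (start codon, next in-frame stop) pair by scanning
    each of the six frames position by position."""
    stops = {"TAA", "TAG", "TGA"}
    comp = str.maketrans("ACGTN", "TGCAN")
    n = len(sequence)
    found = set()

    def scan(seq: str, strand: str):
        length = len(seq)
        for start in range(length - 2):
            if seq[start : start + 3] != "ATG":
                continue
            j = start
            while j + 3 <= length:
                codon = seq[j : j + 3]
                if j > start and codon in stops:
                    aa_len = (j - start) // 3
                    if aa_len >= min_aa and (j + 3 - start) <= n:
                        if strand == "+":
                            s1 = start % n + 1
                            e1 = (j + 2) % n + 1
                        else:
                            # map from reverse-scan coords to forward 1-based
                            f_start = len(seq) - (j + 3) + 1
                            f_end = len(seq) - start
                            s1 = (f_start - 1) % n + 1
                            e1 = (f_end - 1) % n + 1
                        found.add((s1, e1, strand))
                    break
                j += 3

    fwd = sequence * 2 if circular else sequence
    scan(fwd, "+")
    scan(fwd.translate(comp)[::-1], "-")
    return found


def dense_lambda2(nodes, weighted_edges, normalized: bool) -> float:
    """Second-smallest Laplacian eigenvalue from an explicitly constructed
    dense matrix and a full eigendecomposition."""
    idx = {n: i for i, n in enumerate(sorted(nodes))}
    k = len(idx)
    W = np.zeros((k, k))
    for u, v, w in weighted_edges:
        W[idx[u], idx[v]] = w
        W[idx[v], idx[u]] = w
    deg = W.sum(axis=1)
    L = np.diag(deg) - W
    if normalized:
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
        L = dinv[:, None] * L * dinv[None, :]
        for i in range(k):
            if deg[i] == 0:
                L[i, i] = 0.0
    vals = np.sort(np.linalg.eigvalsh(L))
    return float(vals[1])


def transitive_closure_groups(groups: list[set]) -> list[set]:
    """Brute-force closure of the share-an-element relation."""
    merged = [set(g) for g in groups]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if merged[i] and merged[j] and merged[i] & merged[j]:
                    merged[i] |= merged[j]
                    merged[j] = set()
                    changed = True
    return [g for g in merged if g]
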