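"""Multiple sequence alignments and position-specific profile models.

An ortholog group is summarized by a profile: per-column log-odds scores
over the 20 residues, built from the group's MSA with position-based
sequence weighting and substitution-matrix pseudocounts.  Profiles are
searched against proteome databases by optimal local profile-to-sequence
alignment (affine gaps), with e-values calibrated on a fixed-seed set of
composition-preserving shuffled decoys, and compared pairwise by local
column-to-column alignment (a co-emission log-odds score), which drives
the group-merging stage of the pipeline.

These are affine-gap position-specific scoring models, not full
profile HMMs; the contract (build from an MSA, search with an e-value,
compare pairwise) is what the pipeline's decisions consume, and a true
profile-HMM engine can be substituted behind the same interface.
"""

from __future__ import annotations

import json
import math
import random
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
N_AA = 20

#: background residue frequencies (BLOSUM62 marginals), summing to 1
BACKGROUND = np.array(
    [
        0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
        0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

DEFAULT_GAP_OPEN = 6.0  # bits
DEFAULT_GAP_EXTEND = 0.6
DEFAULT_PSEUDOCOUNT = 5.0
DEFAULT_CALIBRATION_SEED = 1091
DEFAULT_N_DECOYS = 200
MATCH_GAP_FRACTION = 0.5

_EULER_GAMMA = 0.5772156649015329


def _substitution_conditional() -> np.ndarray:
    """q[a, b] = P(a | b) implied by BLOSUM62 (half-bit log-odds)."""
    blosum = substitution_matrices.load("BLOSUM62")
    joint = np.zeros((N_AA, N_AA))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            joint[i, j] = BACKGROUND[i] * BACKGROUND[j] * 2.0 ** (blosum[a, b] / 2.0)
    joint /= joint.sum()
    cond = joint / joint.sum(axis=0, keepdims=True)
    return cond


_COND = _substitution_conditional()


# ---------------------------------------------------------------------------
# MSA


@dataclass
class Msa:
    """A protein multiple sequence alignment (rows share one length)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("MSA rows have unequal lengths")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self) -> dict[str, str]:
        return {i: r.replace("-", "") for i, r in zip(self.ids, self.rows)}

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")

    def to_stockholm(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for i, r in zip(self.ids, self.rows):
                fh.write(f"{i.replace(' ', '_')} {r}\n")
            fh.write("//\n")

    @classmethod
    def from_file(cls, path: str | Path, fmt: str = "fasta") -> "Msa":
        aln = AlignIO.read(str(path), fmt)
        return cls(ids=[r.id for r in aln], rows=[str(r.seq).upper() for r in aln])


def sum_of_pairs_score(msa: Msa, gap_penalty: float = 4.0) -> float:
    """Sum-of-pairs BLOSUM62 score of an alignment (gap columns cost
    ``gap_penalty`` per residue-gap pair; gap-gap pairs are free)."""
    blosum = substitution_matrices.load("BLOSUM62")
    total = 0.0
    for j in range(msa.n_cols):
        col = msa.column(j)
        for x in range(len(col)):
            for y in range(x + 1, len(col)):
                a, b = col[x], col[y]
                if a == "-" and b == "-":
                    continue
                if a == "-" or b == "-":
                    total -= gap_penalty
                else:
                    total += float(blosum[a, b])
    return total


def build_msa(sequences: Mapping[str, str]) -> Msa:
    """Progressive multiple alignment of a group's sequences.

    Inputs are canonically sorted by id so the result is deterministic
    regardless of supply order; degapping the rows recovers the inputs.
    A single sequence yields a trivial one-row MSA.  The alignment is
    delegated to MAFFT (progressive FFT-NS strategy).
    """
    if not sequences:
        raise ValueError("cannot align an empty group")
    items = sorted(sequences.items())
    if len(items) == 1:
        (sid, seq), = items
        return Msa(ids=[sid], rows=[seq])
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fa"
        with open(fasta, "w") as fh:
            for i, (sid, seq) in enumerate(items):
                fh.write(f">s{i}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--retree", "2", "--amino", "--anysymbol", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
    records = list(SeqIO.parse(_as_handle(proc.stdout), "fasta"))
    by_key = {r.id: str(r.seq).upper() for r in records}
    rows = [by_key[f"s{i}"] for i in range(len(items))]
    return Msa(ids=[sid for sid, _ in items], rows=rows)


def _as_handle(text: str):
    import io

    return io.StringIO(text)


# ---------------------------------------------------------------------------
# profile model


@dataclass
class ProfileModel:
    """Per-column log2-odds scores over the 20 residues, with affine gaps."""

    group_id: str
    scores: np.ndarray  # (n_columns, 20) bits
    probs: np.ndarray  # (n_columns, 20) mixture frequencies
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    n_seqs: int = 0
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in np.argmax(self.probs, axis=1))

    def to_json(self) -> str:
        return json.dumps(
            {
                "group_id": self.group_id,
                "gap_open": self.gap_open,
                "gap_extend": self.gap_extend,
                "n_seqs": self.n_seqs,
                "alphabet": AA_ORDER,
                "probs": self.probs.round(9).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProfileModel":
        data = json.loads(text)
        probs = np.asarray(data["probs"], dtype=float)
        scores = np.log2(probs / BACKGROUND)
        return cls(
            group_id=data["group_id"],
            scores=scores,
            probs=probs,
            gap_open=data["gap_open"],
            gap_extend=data["gap_extend"],
            n_seqs=data["n_seqs"],
        )


@dataclass(frozen=True)
class ProfileHit:
    group_id: str
    protein_id: str
    score: float
    evalue: float


def position_based_weights(msa: Msa) -> np.ndarray:
    """Henikoff position-based sequence weights, normalized to sum to n_seqs."""
    n = msa.n_seqs
    w = np.zeros(n)
    any_col = False
    for j in range(msa.n_cols):
        col = msa.column(j)
        residues = [c for c in col if c in AA_INDEX]
        if not residues:
            continue
        any_col = True
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            if c in AA_INDEX:
                w[i] += 1.0 / (r * counts[c])
    if not any_col or w.sum() == 0:
        return np.full(n, 1.0)
    return w * (n / w.sum())


def build_profile(
    msa: Msa,
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    group_id: str = "",
    position_weights: bool = True,
) -> ProfileModel:
    """Estimate a profile from an MSA.

    Match columns are those with at most 50% gaps.  Column frequencies
    mix weighted observed counts with substitution-matrix pseudocounts:
    p_a = (c * f_a + w * g_a) / (c + w), where c is the effective
    observation count, f the weighted observed frequencies and
    g_a = sum_b f_b P(a|b) the matrix-implied expectation.  Sequences
    are weighted by the position-based scheme unless ``position_weights``
    is disabled (uniform weights).
    """
    if msa.n_seqs == 0:
        raise ValueError("empty MSA")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be > 0")
    weights = (
        position_based_weights(msa) if position_weights else np.ones(msa.n_seqs)
    )
    cols = []
    for j in range(msa.n_cols):
        col = msa.column(j)
        gap_frac = col.count("-") / len(col)
        if gap_frac > MATCH_GAP_FRACTION:
            continue
        counts = np.zeros(N_AA)
        for i, c in enumerate(col):
            if c in AA_INDEX:
                counts[AA_INDEX[c]] += weights[i]
        total = counts.sum()
        if total == 0:
            continue
        f_obs = counts / total
        g = _COND @ f_obs
        p = (total * f_obs + pseudocount_weight * g) / (total + pseudocount_weight)
        cols.append(p)
    if not cols:
        raise ValueError("MSA has no match columns")
    probs = np.vstack(cols)
    scores = np.log2(probs / BACKGROUND)
    return ProfileModel(
        group_id=group_id,
        scores=scores,
        probs=probs,
        gap_open=gap_open,
        gap_extend=gap_extend,
        n_seqs=msa.n_seqs,
    )


# ---------------------------------------------------------------------------
# batched local profile-to-sequence alignment


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco


@_njit(cache=True)
def _dp_scores_kernel(
    cols: np.ndarray,
    idx: np.ndarray,
    lengths: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> np.ndarray:  # pragma: no cover - exercised via profile_search
    n, width = idx.shape
    n_cols = cols.shape[0]
    out = np.zeros(n)
    for s in range(n):
        ln = min(lengths[s], width)
        best = 0.0
        H = np.zeros(ln)
        F = np.full(ln, -1e30)
        for i in range(n_cols):
            diag_prev = 0.0
            E = -1e30
            prev_h = 0.0
            for j in range(ln):
                sc = cols[i, idx[s, j]]
                d = diag_prev + sc
                fj = F[j] - gap_extend
                hj = H[j] - gap_open
                if hj > fj:
                    fj = hj
                F[j] = fj
                e = E - gap_extend
                po = prev_h - gap_open
                if po > e:
                    e = po
                E = e
                h = d
                if fj > h:
                    h = fj
                if e > h:
                    h = e
                if h < 0.0:
                    h = 0.0
                diag_prev = H[j]
                H[j] = h
                prev_h = h
                if h > best:
                    best = h
        out[s] = best
    return out


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Pack sequences into a padded index matrix (X and padding -> 20)."""
    width = max(len(s) for s in seqs)
    mat = np.full((len(seqs), width), N_AA, dtype=np.int8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = [AA_INDEX.get(c, N_AA) for c in s]
    return mat


def _batch_local_scores(
    col_scores: np.ndarray,
    idx: np.ndarray,
    gap_open: float,
    gap_extend: float,
    lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Optimal local alignment score of a profile against many sequences.

    Affine gaps on both sides; X and padding score 0 and a large negative
    respectively so padding can never contribute.  Returns one score per
    sequence (bits).
    """
    n, width = idx.shape
    if _HAVE_NUMBA and lengths is not None:
        ext = np.hstack([col_scores, np.zeros((col_scores.shape[0], 1))])
        return _dp_scores_kernel(
            np.ascontiguousarray(ext),
            np.ascontiguousarray(idx),
            np.asarray(lengths, dtype=np.int64),
            float(gap_open),
            float(gap_extend),
        )
    # column 20 = X/padding; X scores 0, padding handled below
    ext_scores = np.hstack([col_scores, np.zeros((col_scores.shape[0], 1))])
    pad_mask = None
    if lengths is not None:
        # true padding (beyond each sequence's length) must never align
        pos = np.arange(width)[None, :]
        pad_mask = pos >= lengths[:, None]
    j_ext = np.arange(width) * gap_extend
    H = np.zeros((n, width))
    F = np.full((n, width), -np.inf)
    best = np.zeros(n)
    neg = -1e4
    for i in range(col_scores.shape[0]):
        s = ext_scores[i][idx]
        if pad_mask is not None:
            s = np.where(pad_mask, neg, s)
        diag = np.empty_like(H)
        diag[:, 0] = s[:, 0]
        diag[:, 1:] = H[:, :-1] + s[:, 1:]
        F = np.maximum(F - gap_extend, H - gap_open)
        H0 = np.maximum(np.maximum(diag, F), 0.0)
        C = H0 + j_ext
        run = np.maximum.accumulate(C, axis=1)
        E = np.full((n, width), -np.inf)
        E[:, 1:] = run[:, :-1] - gap_open - j_ext[1:] + gap_extend
        H = np.maximum(H0, E)
        np.maximum(best, H.max(axis=1), out=best)
    return best


def shuffled_decoys(
    seqs: Sequence[str],
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int = DEFAULT_CALIBRATION_SEED,
) -> list[str]:
    """Composition-preserving shuffles of database sequences (fixed seed)."""
    rng = random.Random(seed)
    pool = sorted(seqs, key=len)
    decoys = []
    for k in range(n_decoys):
        src = pool[k % len(pool)]
        chars = list(src)
        rng.shuffle(chars)
        decoys.append("".join(chars))
    return decoys


@dataclass
class EvalueCalibration:
    """Gumbel (EVD) calibration of profile search scores on decoys."""

    mu: float
    lam: float
    n_db: int

    def evalue(self, score: float) -> float:
        x = self.lam * (score - self.mu)
        if x > 30:
            p = math.exp(-x)
        else:
            p = 1.0 - math.exp(-math.exp(-x))
        return self.n_db * p

    @classmethod
    def fit(cls, decoy_scores: np.ndarray, n_db: int) -> "EvalueCalibration":
        std = float(np.std(decoy_scores))
        if std < 1e-9:
            std = 1e-9
        lam = math.pi / (std * math.sqrt(6.0))
        mu = float(np.mean(decoy_scores)) - _EULER_GAMMA / lam
        return cls(mu=mu, lam=lam, n_db=n_db)


class ProteinDatabase:
    """A searchable, encoded protein database with cached decoy scores."""

    def __init__(
        self,
        sequences: Mapping[str, str],
        n_decoys: int = DEFAULT_N_DECOYS,
        calibration_seed: int = DEFAULT_CALIBRATION_SEED,
    ) -> None:
        self.ids = sorted(sequences)
        self.seqs = [sequences[i] for i in self.ids]
        if not self.ids:
            raise ValueError("empty protein database")
        self.idx = encode_sequences(self.seqs)
        self.lengths = np.array([len(s) for s in self.seqs])
        decoys = shuffled_decoys(self.seqs, n_decoys, calibration_seed)
        self.decoy_idx = encode_sequences(decoys)
        self.decoy_lengths = np.array([len(s) for s in decoys])
        self._calibrations: dict[bytes, EvalueCalibration] = {}

    def __len__(self) -> int:
        return len(self.ids)

    def calibration(self, profile: "ProfileModel") -> EvalueCalibration:
        """Gumbel calibration of this database's decoys for one profile
        (memoized on the profile's score matrix and gap penalties)."""
        key = profile.scores.tobytes() + bytes(
            f"{profile.gap_open}:{profile.gap_extend}", "ascii"
        )
        calib = self._calibrations.get(key)
        if calib is None:
            decoy_scores = _batch_local_scores(
                profile.scores,
                self.decoy_idx,
                profile.gap_open,
                profile.gap_extend,
                self.decoy_lengths,
            )
            calib = EvalueCalibration.fit(decoy_scores, len(self))
            self._calibrations[key] = calib
        return calib


def profile_search(
    profile: ProfileModel,
    db: ProteinDatabase | Mapping[str, str],
    evalue_max: float = 0.01,
) -> list[ProfileHit]:
    """Score every database protein against ``profile``; keep e-value hits.

    Hits are sorted by descending score, ties broken by protein id.
    """
    if profile.n_columns == 0:
        raise ValueError("profile has zero match columns")
    if not isinstance(db, ProteinDatabase):
        db = ProteinDatabase(db)
    scores = _batch_local_scores(
        profile.scores, db.idx, profile.gap_open, profile.gap_extend, db.lengths
    )
    calib = db.calibration(profile)
    hits = [
        ProfileHit(profile.group_id, pid, float(s), calib.evalue(float(s)))
        for pid, s in zip(db.ids, scores)
        if calib.evalue(float(s)) <= evalue_max
    ]
    hits.sort(key=lambda h: (-h.score, h.protein_id))
    return hits


def _single_dp_best_end(
    col_scores: np.ndarray, seq_idx: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[float, int, int]:
    """Best local score and its (profile_column, seq_position) end cell."""
    width = seq_idx.shape[0]
    ext_scores = np.hstack([col_scores, np.zeros((col_scores.shape[0], 1))])
    j_ext = np.arange(width) * gap_extend
    H = np.zeros(width)
    F = np.full(width, -np.inf)
    best, best_i, best_j = 0.0, -1, -1
    for i in range(col_scores.shape[0]):
        s = ext_scores[i][seq_idx]
        diag = np.empty(width)
        diag[0] = s[0]
        diag[1:] = H[:-1] + s[1:]
        F = np.maximum(F - gap_extend, H - gap_open)
        H0 = np.maximum(np.maximum(diag, F), 0.0)
        C = H0 + j_ext
        run = np.maximum.accumulate(C)
        E = np.full(width, -np.inf)
        E[1:] = run[:-1] - gap_open - j_ext[1:] + gap_extend
        H = np.maximum(H0, E)
        j = int(np.argmax(H))
        if H[j] > best:
            best, best_i, best_j = float(H[j]), i, j
    return best, best_i, best_j


def profile_alignment_coverage(profile: ProfileModel, seq: str) -> float:
    """Fraction of profile columns spanned by the optimal local alignment.

    The end column comes from the forward pass; the start column from the
    same pass on the reversed profile and sequence (the local-alignment
    reversal identity).  Used to vet remote-homolog adoptions: genuine
    remote members align along most of the model, spurious hits only over
    short segments.
    """
    idx = np.array([AA_INDEX.get(c, N_AA) for c in seq], dtype=np.int8)
    if idx.size == 0:
        return 0.0
    _, i_end, _ = _single_dp_best_end(
        profile.scores, idx, profile.gap_open, profile.gap_extend
    )
    if i_end < 0:
        return 0.0
    _, i_end_rev, _ = _single_dp_best_end(
        profile.scores[::-1], idx[::-1], profile.gap_open, profile.gap_extend
    )
    i_start = profile.n_columns - 1 - i_end_rev
    return max(0, i_end - i_start + 1) / profile.n_columns


# ---------------------------------------------------------------------------
# profile-profile comparison


#: scale applied to the raw co-emission bit score so that the conventional
#: group-merge threshold of 20 separates related from unrelated profile
#: pairs.  Calibrated once on planted families (see docs/methods.md):
#: half-family self-comparisons score >= ~54 in these units while
#: unrelated-pair scores stay below ~12.
PVP_SCALE = 0.5


def profile_vs_profile(p1: ProfileModel, p2: ProfileModel) -> float:
    """Local column-to-column alignment score between two profiles.

    The column-pair score is the co-emission log-odds
    log2(sum_a p1_a p2_a / bg_a); gap penalties are the pairwise maxima
    of the two profiles' penalties, so the score is symmetric.  The raw
    bit score is multiplied by :data:`PVP_SCALE` to put it on the scale
    expected by the merge threshold.
    """
    if p1.n_columns == 0 or p2.n_columns == 0:
        raise ValueError("cannot compare empty profiles")
    S = np.log2(np.clip(p1.probs @ (p2.probs / BACKGROUND).T, 1e-30, None))
    gap_open = max(p1.gap_open, p2.gap_open)
    gap_extend = max(p1.gap_extend, p2.gap_extend)
    return PVP_SCALE * _local_dp_matrix(S, gap_open, gap_extend)


def _local_dp_matrix(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Local affine-gap DP over an explicit score matrix (rows x cols)."""
    n_rows, n_cols = S.shape
    j_ext = np.arange(n_cols) * gap_extend
    H = np.zeros(n_cols)
    F = np.full(n_cols, -np.inf)
    best = 0.0
    for i in range(n_rows):
        diag = np.empty(n_cols)
        diag[0] = S[i, 0]
        diag[1:] = H[:-1] + S[i, 1:]
        F = np.maximum(F - gap_extend, H - gap_open)
        H0 = np.maximum(np.maximum(diag, F), 0.0)
        C = H0 + j_ext
        run = np.maximum.accumulate(C)
        E = np.full(n_cols, -np.inf)
        E[1:] = run[:-1] - gap_open - j_ext[1:] + gap_extend
        H = np.maximum(H0, E)
        best = max(best, float(H.max()))
    return best


def write_hits_tsv(hits: Iterable[ProfileHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tprotein_id\tscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.group_id}\t{h.protein_id}\t{h.score:.3f}\t{h.evalue:.3g}\n")
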