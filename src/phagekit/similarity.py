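"""Ungapped local alignment with Karlin-Altschul significance, and the
fragmented whole-genome translated-similarity matrix.

The engine is seed-and-extend: exact word seeds (7-mers for nucleotide
comparisons, protein 3-mers for translated comparisons across all 6x6 frame
pairs) mark candidate diagonals, and each seeded diagonal is scored by the
exact maximum-sum segment along it (ungapped extension run to the diagonal
optimum). Significance uses the Karlin-Altschul formula
E = K * m * n * exp(-lambda * S) with published ungapped parameters, and
P = 1 - exp(-E).

Whole-genome similarity follows the fragmented-comparison idea: a genome is
cut into overlapping fixed-size fragments, each fragment is scored against
the other genome in translated mode, and the similarity of A against B is
the summed best fragment scores normalized by the fragments' self-scores.
The matrix is asymmetric for genomes with different variable content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .records import GenomeRecord

# --- scoring parameters (ungapped Karlin-Altschul, published values) -------
NT_MATCH, NT_MISMATCH = 1, -2
NT_LAMBDA, NT_K = 1.28, 0.46
PROT_LAMBDA, PROT_K = 0.3176, 0.134
DEFAULT_WORD_SIZE = 7  # nucleotide seed length
PROT_WORD_SIZE = 3

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i
    _NT_CODE[_b + 32] = _i  # lowercase

PROT_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(PROT_ALPHABET)}
_X = _AA_INDEX["X"]


def _build_blosum62() -> np.ndarray:
    b62 = substitution_matrices.load("BLOSUM62")
    m = np.full((21, 21), -1, dtype=np.int8)  # X (and stop, mapped to X) = -1
    for i, a in enumerate(PROT_ALPHABET[:20]):
        for j, b in enumerate(PROT_ALPHABET[:20]):
            m[i, j] = int(b62[a][b])
    return m


BLOSUM62_21 = _build_blosum62()


def _build_codon_table() -> np.ndarray:
    table = np.full(64, _X, dtype=np.uint8)
    for codon, aa in standard_dna_table.forward_table.items():
        idx = "ACGT".index(codon[0]) * 16 + "ACGT".index(codon[1]) * 4 + "ACGT".index(codon[2])
        table[idx] = _AA_INDEX.get(aa, _X)
    # stop codons stay X: translated fragments are genomic, not ORF-guided
    return table


_CODON_AA = _build_codon_table()
_REVCOMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_nt(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _translate_frames(enc: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """All six reading frames as encoded protein arrays, labelled +1..+3/-1..-3."""
    frames = []
    rc = _REVCOMP[enc][::-1]
    for label, arr in ((1, enc), (-1, rc)):
        for f in range(3):
            sub = arr[f:]
            n = len(sub) // 3
            if n == 0:
                frames.append((label * (f + 1), np.empty(0, dtype=np.uint8)))
                continue
            c = sub[: 3 * n].reshape(n, 3).astype(np.int32)
            bad = (c >= 4).any(axis=1)
            idx = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
            aa = _CODON_AA[np.where(bad, 0, idx)]
            aa[bad] = _X
            frames.append((label * (f + 1), aa))
    return frames


@dataclass
class Hsp:
    """A high-scoring segment pair from an ungapped local comparison.

    Coordinates are 1-based inclusive. For nucleotide mode they refer to the
    original (forward) sequences with ``strand`` giving the query strand; for
    translated mode they are amino-acid positions within the stated frames.
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    raw_score: int
    bit_score: float
    e_value: float
    p_value: float
    strand: str = "+"
    query_frame: int = 0
    target_frame: int = 0


def _ka_stats(score: int, m: int, n: int, lam: float, k: float) -> tuple[float, float, float]:
    e = k * m * n * np.exp(-lam * score)
    p = float(-np.expm1(-e))
    bits = (lam * score - np.log(k)) / np.log(2)
    return float(e), p, float(bits)


def _min_score(m: int, n: int, e_ceiling: float, lam: float, k: float) -> int:
    if e_ceiling <= 0:
        raise ValueError("e_ceiling must be positive")
    return int(np.ceil(np.log(k * m * n / e_ceiling) / lam))


def _diag_best(scores: np.ndarray) -> tuple[int, int, int]:
    """Maximum-sum contiguous segment of a score array.

    Returns (score, start, end) with inclusive 0-based indices; the exact
    optimum of ungapped extension on this diagonal.
    """
    p = np.concatenate([[0], np.cumsum(scores)])
    mins = np.minimum.accumulate(p[:-1])
    vals = p[1:] - mins
    j = int(np.argmax(vals))
    best = int(vals[j])
    i = int(np.argmin(p[: j + 1]))
    return best, i, j


def _seed_diagonals(q_codes: np.ndarray, t_index: dict) -> np.ndarray:
    """Unique diagonals (t_pos - q_pos) carrying at least one exact word match."""
    diags = []
    order = np.argsort(q_codes, kind="stable")
    sorted_codes = q_codes[order]
    uniq, starts = np.unique(sorted_codes, return_index=True)
    for u, s in zip(uniq, starts):
        if int(u) < 0:
            continue
        tpos = t_index.get(int(u))
        if tpos is None:
            continue
        e = s + np.searchsorted(sorted_codes[s:], u, side="right")
        qpos = order[s:e]
        diags.append((tpos[None, :] - qpos[:, None]).ravel())
    if not diags:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(diags))


def _word_codes(enc: np.ndarray, w: int, alphabet: int) -> np.ndarray:
    """Rolling word codes; positions containing an ambiguous letter get -1."""
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    x = enc.astype(np.int64)
    for k in range(w):
        codes = codes * alphabet + x[k : k + n]
        valid &= x[k : k + n] < alphabet
    codes[~valid] = -1
    return codes


def _index_words(enc: np.ndarray, w: int, alphabet: int) -> dict:
    codes = _word_codes(enc, w, alphabet)
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    uniq, starts = np.unique(sc, return_index=True)
    out = {}
    bounds = np.append(starts[1:], len(sc))
    for u, s, e in zip(uniq, starts, bounds):
        if int(u) >= 0:
            out[int(u)] = order[s:e]
    return out


def _ambiguity_fraction(enc: np.ndarray, alphabet: int = 4) -> float:
    return float(np.mean(enc >= alphabet)) if len(enc) else 1.0


def _nt_scores(q: np.ndarray, t: np.ndarray) -> np.ndarray:
    match = (q == t) & (q < 4)
    return np.where(match, NT_MATCH, NT_MISMATCH)


def local_hsps(
    query: str,
    target: str,
    mode: str = "nucleotide",
    word_size: int = DEFAULT_WORD_SIZE,
    e_ceiling: float = 10.0,
) -> list[Hsp]:
    """Significant ungapped local HSPs between two nucleotide sequences.

    Nucleotide mode seeds on exact ``word_size``-mers (both query strands) and
    scores +1/-2; translated mode seeds on exact protein 3-mers across all
    6x6 frame pairs and scores with BLOSUM62 (stops as X, -1 vs all). Each
    seeded diagonal contributes its optimal segment; HSPs with
    E > ``e_ceiling`` are discarded. Results are sorted by decreasing score.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    qe = encode_nt(query)
    te = encode_nt(target)
    if _ambiguity_fraction(qe) > 0.5 or _ambiguity_fraction(te) > 0.5:
        raise ValueError("sequence has >50% ambiguity codes")

    hsps: list[Hsp] = []
    if mode == "nucleotide":
        m, n = len(query), len(target)
        smin = max(_min_score(m, n, e_ceiling, NT_LAMBDA, NT_K), word_size * NT_MATCH)
        t_index = _index_words(te, word_size, 4)
        for strand, q in (("+", qe), ("-", _REVCOMP[qe][::-1])):
            q_codes = _word_codes(q, word_size, 4)
            for d in _seed_diagonals(q_codes, t_index):
                qi0 = max(0, -int(d))
                qi1 = min(len(q), len(te) - int(d))
                score, i, j = _diag_best(_nt_scores(q[qi0:qi1], te[qi0 + d : qi1 + d]))
                if score < smin:
                    continue
                qs, qend = qi0 + i, qi0 + j
                if strand == "-":  # map back to forward query coordinates
                    qs, qend = len(q) - 1 - qend, len(q) - 1 - qs
                ev, p, bits = _ka_stats(score, m, n, NT_LAMBDA, NT_K)
                hsps.append(
                    Hsp(
                        query_start=qs + 1,
                        query_end=qend + 1,
                        target_start=qi0 + int(d) + i + 1,
                        target_end=qi0 + int(d) + j + 1,
                        raw_score=score,
                        bit_score=bits,
                        e_value=ev,
                        p_value=p,
                        strand=strand,
                    )
                )
    elif mode == "translated":
        q_frames = _translate_frames(qe)
        t_frames = _translate_frames(te)
        m = max(1, len(query) // 3)
        n = max(1, 2 * len(target))  # total residues across six frames
        smin = _min_score(m, n, e_ceiling, PROT_LAMBDA, PROT_K)
        t_indices = {tf: _index_words(arr, PROT_WORD_SIZE, 21) for tf, arr in t_frames}
        for qf, qarr in q_frames:
            if len(qarr) < PROT_WORD_SIZE:
                continue
            q_codes = _word_codes(qarr, PROT_WORD_SIZE, 21)
            for tf, tarr in t_frames:
                if len(tarr) < PROT_WORD_SIZE:
                    continue
                for d in _seed_diagonals(q_codes, t_indices[tf]):
                    qi0 = max(0, -int(d))
                    qi1 = min(len(qarr), len(tarr) - int(d))
                    seg = BLOSUM62_21[qarr[qi0:qi1], tarr[qi0 + d : qi1 + d]]
                    score, i, j = _diag_best(seg)
                    if score < smin:
                        continue
                    ev, p, bits = _ka_stats(score, m, n, PROT_LAMBDA, PROT_K)
                    hsps.append(
                        Hsp(
                            query_start=qi0 + i + 1,
                            query_end=qi0 + j + 1,
                            target_start=qi0 + int(d) + i + 1,
                            target_end=qi0 + int(d) + j + 1,
                            raw_score=score,
                            bit_score=bits,
                            e_value=ev,
                            p_value=p,
                            query_frame=qf,
                            target_frame=tf,
                        )
                    )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    hsps.sort(key=lambda h: (-h.raw_score, h.e_value, h.query_start))
    return hsps


def best_hsp(query: str, target: str, **kwargs) -> Hsp | None:
    hits = local_hsps(query, target, **kwargs)
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# fragmented whole-genome translated similarity


@dataclass
class SimilarityMatrix:
    """Asymmetric percent similarity; values[i][j] is the similarity of
    genome i evaluated against genome j (fraction of i's fragments)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if np.isnan(self.values).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


class _TranslatedIndex:
    """Six-frame translation of a genome plus per-frame protein 3-mer indexes."""

    def __init__(self, sequence: str):
        enc = encode_nt(sequence)
        self.frames = _translate_frames(enc)
        self.indexes = {
            tf: _index_words(arr, PROT_WORD_SIZE, 21) for tf, arr in self.frames
        }
        self.frame_arrays = dict(self.frames)
        self.n_residues = max(1, sum(len(a) for _, a in self.frames))


def _kadane_list(vals: list[int]) -> int:
    best = 0
    run = 0
    for v in vals:
        run = run + v if run > 0 else v
        if run > best:
            best = run
    return best


class _Fragment:
    __slots__ = ("frames", "codes", "self_score", "n_aa")

    def __init__(self, sequence: str):
        enc = encode_nt(sequence)
        self.frames = [(f, a) for f, a in _translate_frames(enc) if len(a) >= PROT_WORD_SIZE]
        self.codes = {f: _word_codes(a, PROT_WORD_SIZE, 21) for f, a in self.frames}
        self.n_aa = max(1, len(sequence) // 3)
        self.self_score = max(
            (_kadane_list(BLOSUM62_21[a, a].tolist()) for _, a in self.frames),
            default=0,
        )


def _fragment_best_score(frag: _Fragment, tindex: _TranslatedIndex, smin: int) -> int:
    best = 0
    for qf, qarr in frag.frames:
        q_codes = frag.codes[qf]
        valid = np.flatnonzero(q_codes >= 0)
        for tf, tarr in tindex.frames:
            t_idx = tindex.indexes[tf]
            seen: set[int] = set()
            for qpos in valid:
                tpos = t_idx.get(int(q_codes[qpos]))
                if tpos is None:
                    continue
                for tp in tpos:
                    d = int(tp) - int(qpos)
                    if d in seen:
                        continue
                    seen.add(d)
                    qi0 = max(0, -d)
                    qi1 = min(len(qarr), len(tarr) - d)
                    seg = BLOSUM62_21[qarr[qi0:qi1], tarr[qi0 + d : qi1 + d]]
                    score = _kadane_list(seg.tolist())
                    if score > best:
                        best = score
    return best if best >= smin else 0


def fragmented_similarity(
    genomes: list[GenomeRecord],
    fragment_size: int = 50,
    step: int = 25,
    e_ceiling: float = 1e-3,
) -> SimilarityMatrix:
    """Fragmented translated all-against-all genome comparison.

    Each genome is tiled into overlapping ``fragment_size``-bp fragments every
    ``step`` bp (a final short fragment is kept when the length is not a
    multiple of the step; fragments shorter than one codon triplet of 9 bp
    are skipped). Each fragment's best translated HSP score against the other
    genome, capped at the fragment's self-score and zeroed when its E-value
    exceeds ``e_ceiling``, is summed and normalized by the summed self-scores:

        values[A][B] = 100 * sum_i min(best_i(B), self_i) / sum_i self_i
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    if fragment_size < step:
        raise ValueError("fragment_size must be >= step")
    labels = [g.id for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("genome ids must be unique")

    frag_sets: list[list[_Fragment]] = []
    for g in genomes:
        frags = []
        for s in range(0, max(1, len(g.sequence)), step):
            sub = g.sequence[s : s + fragment_size]
            if len(sub) < 9:
                continue
            frags.append(_Fragment(sub))
            if s + fragment_size >= len(g.sequence):
                break
        frag_sets.append(frags)
    indexes = [_TranslatedIndex(g.sequence) for g in genomes]

    n = len(genomes)
    values = np.full((n, n), 100.0)
    for i in range(n):
        total_self = sum(f.self_score for f in frag_sets[i])
        if total_self == 0:
            continue
        for j in range(n):
            if i == j:
                continue
            total = 0
            for frag in frag_sets[i]:
                smin = _min_score(
                    frag.n_aa, indexes[j].n_residues, e_ceiling, PROT_LAMBDA, PROT_K
                )
                sc = _fragment_best_score(frag, indexes[j], smin)
                total += min(sc, frag.self_score)
            values[i, j] = 100.0 * total / total_self
    return SimilarityMatrix(labels=labels, values=values)


def to_distance(matrix: SimilarityMatrix) -> DistanceMatrix:
    """d(A,B) = 100 - (sim[A][B] + sim[B][A]) / 2, diagonal forced to zero."""
    v = matrix.values
    d = 100.0 - (v + v.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(labels=list(matrix.labels), values=d)
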