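"""Dynamic-programming alignment of localized label maps to reference motif maps.

A query map (sub-pixel label positions along one imaged molecule) is converted
to basepairs through the optical scale factor s (bp per pixel) and aligned to
a reference map (motif-site basepair positions of a reference sequence) by the
recurrence

    S[i, j] = 1 + max over (g, h), i-delta <= g < i, j-delta <= h < j, of
              { S[g, h] - (1/alpha) * | |r_i - r_g| - |q_j - q_h| |
                        - (1/beta)  * ((i - g - 1) + (j - h - 1)) }

with S[i, j] = 1 when no admissible predecessor improves the score (every
matched pair may start a new local alignment).  Each matched pair rewards 1;
alpha penalizes stretch mismatch between consecutive matched intervals and
beta penalizes labels skipped in either map.  The alignment is traced back
from the maximal score cell.  Defaults: delta = 5, alpha = 500 bp,
beta = 10, s = 335 bp/px.

Molecules enter nanochannels in either direction, so both orientations are
scored and the higher-scoring one kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "QueryMap",
    "ReferenceMap",
    "AlignmentParams",
    "Alignment",
    "ScoreMatrix",
    "pixels_to_bp",
    "compute_score_matrix",
    "traceback",
    "align",
    "align_to_genome",
    "brute_force_align",
    "evaluate_pairs_score",
]


@dataclass(frozen=True)
class QueryMap:
    """Ordered sub-pixel label positions of one imaged molecule."""

    positions_px: np.ndarray
    molecule_id: str = "mol"
    molecule_length_px: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.positions_px, dtype=np.float64)
        object.__setattr__(self, "positions_px", p)
        if p.size and np.any(np.diff(p) <= 0):
            raise ValueError("query positions must be strictly increasing")
        length = self.molecule_length_px or (float(p[-1]) if p.size else 0.0)
        object.__setattr__(self, "molecule_length_px", length)
        if p.size and (p[0] < 0 or p[-1] > length):
            raise ValueError("query positions must lie within [0, molecule_length_px]")

    def reversed(self) -> "QueryMap":
        """Mirror the molecule end-to-end (positions reflected about its length)."""
        return QueryMap(
            positions_px=np.sort(self.molecule_length_px - self.positions_px),
            molecule_id=self.molecule_id,
            molecule_length_px=self.molecule_length_px,
        )


@dataclass(frozen=True)
class ReferenceMap:
    """Ordered motif-site basepair positions of one reference sequence."""

    positions_bp: np.ndarray
    sequence_id: str = "ref"
    sequence_length_bp: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.positions_bp, dtype=np.float64)
        object.__setattr__(self, "positions_bp", p)
        if p.size and np.any(np.diff(p) <= 0):
            raise ValueError("reference positions must be strictly increasing")
        length = self.sequence_length_bp or (int(p[-1]) + 1 if p.size else 0)
        object.__setattr__(self, "sequence_length_bp", length)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring constants of the recurrence (see module docstring)."""

    delta: int = 5
    alpha: float = 500.0
    beta: float = 10.0
    scale_bp_per_px: float = 335.0

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if min(self.alpha, self.beta, self.scale_bp_per_px) <= 0:
            raise ValueError("alpha, beta and scale must be strictly positive")


@dataclass(frozen=True)
class ScoreMatrix:
    """Filled score matrix S (reference x query) with traceback pointers."""

    S: np.ndarray
    back_g: np.ndarray
    back_h: np.ndarray
    reference_bp: np.ndarray
    query_bp: np.ndarray
    params: AlignmentParams


@dataclass(frozen=True)
class Alignment:
    """A monotone set of (reference index, query index) matched pairs."""

    pairs: tuple[tuple[int, int], ...]
    score: float
    orientation: str = "forward"
    sequence_id: str = "ref"
    ref_interval_bp: tuple[float, float] = (0.0, 0.0)
    molecule_id: str = "mol"


def pixels_to_bp(x, params: AlignmentParams):
    """Convert pixel coordinates to basepairs: ``q = s * x``."""
    return np.asarray(x, dtype=np.float64) * params.scale_bp_per_px


@njit(cache=True)
def _fill_matrix(r, q, delta, inv_alpha, inv_beta):  # pragma: no cover - numba
    n, m = len(r), len(q)
    S = np.ones((n, m))
    back_g = np.full((n, m), -1, np.int64)
    back_h = np.full((n, m), -1, np.int64)
    for i in range(n):
        for j in range(m):
            best = 0.0
            bg = -1
            bh = -1
            best_gap = 1 << 30
            for g in range(max(0, i - delta), i):
                for h in range(max(0, j - delta), j):
                    stretch = abs(abs(r[i] - r[g]) - abs(q[j] - q[h]))
                    v = S[g, h] - inv_alpha * stretch - inv_beta * ((i - g - 1) + (j - h - 1))
                    if v <= 0.0:
                        continue
                    gap = (i - g) + (j - h)
                    if v > best or (v == best and gap < best_gap):
                        best = v
                        bg, bh, best_gap = g, h, gap
            S[i, j] = 1.0 + best
            back_g[i, j] = bg
            back_h[i, j] = bh
    return S, back_g, back_h


def compute_score_matrix(
    reference: ReferenceMap | np.ndarray, query_bp: np.ndarray, params: AlignmentParams
) -> ScoreMatrix:
    """Fill the full score matrix for a basepair-converted query.

    Ties among equal-score predecessors resolve to the smallest index gap,
    making the traceback deterministic.
    """
    r = reference.positions_bp if isinstance(reference, ReferenceMap) else np.asarray(reference, float)
    q = np.asarray(query_bp, dtype=np.float64)
    if q.size == 0:
        raise ValueError("query map is empty")
    if r.size == 0:
        raise ValueError("reference map is empty")
    S, bg, bh = _fill_matrix(r, q, params.delta, 1.0 / params.alpha, 1.0 / params.beta)
    return ScoreMatrix(S, bg, bh, r, q, params)


def traceback(matrix: ScoreMatrix) -> Alignment:
    """Trace the top-scoring alignment back from the maximal matrix cell.

    Among equal global maxima the smallest (i, j) cell wins (row-major first
    occurrence), so repeated runs give identical alignments.
    """
    S = matrix.S
    flat = int(np.argmax(S))
    i, j = divmod(flat, S.shape[1])
    score = float(S[i, j])
    pairs = []
    while i >= 0:
        pairs.append((i, j))
        i, j = int(matrix.back_g[i, j]), int(matrix.back_h[i, j])
    pairs.reverse()
    return Alignment(pairs=tuple(pairs), score=score)


def evaluate_pairs_score(
    r: np.ndarray, q: np.ndarray, pairs, params: AlignmentParams
) -> float:
    """Re-evaluate the scoring objective over an explicit pair sequence."""
    score = 0.0
    prev = None
    for i, j in pairs:
        score += 1.0
        if prev is not None:
            g, h = prev
            stretch = abs(abs(r[i] - r[g]) - abs(q[j] - q[h]))
            score -= stretch / params.alpha + ((i - g - 1) + (j - h - 1)) / params.beta
        prev = (i, j)
    return score


def _implied_interval(
    reference: ReferenceMap, query: QueryMap, pairs, params: AlignmentParams
) -> tuple[float, float]:
    """Genomic interval spanned by the molecule: outermost matched sites
    extended by the unaligned molecule overhangs at the optical scale."""
    r = reference.positions_bp
    q_px = query.positions_px
    (i0, j0), (i1, j1) = pairs[0], pairs[-1]
    s = params.scale_bp_per_px
    start = r[i0] - s * q_px[j0]
    end = r[i1] + s * (query.molecule_length_px - q_px[j1])
    return (float(start), float(end))


def _align_oriented(
    query: QueryMap, reference: ReferenceMap, params: AlignmentParams, orientation: str
) -> Alignment:
    oriented = query if orientation == "forward" else query.reversed()
    q_bp = pixels_to_bp(oriented.positions_px, params)
    matrix = compute_score_matrix(reference, q_bp, params)
    aln = traceback(matrix)
    interval = _implied_interval(reference, oriented, aln.pairs, params)
    return Alignment(
        pairs=aln.pairs,
        score=aln.score,
        orientation=orientation,
        sequence_id=reference.sequence_id,
        ref_interval_bp=interval,
        molecule_id=query.molecule_id,
    )


def align(query: QueryMap, reference: ReferenceMap, params: AlignmentParams | None = None) -> Alignment:
    """Best alignment of one molecule to one reference, either orientation."""
    params = params or AlignmentParams()
    fwd = _align_oriented(query, reference, params, "forward")
    rev = _align_oriented(query, reference, params, "reverse")
    return fwd if fwd.score >= rev.score else rev


def align_to_genome(
    query: QueryMap, references: list[ReferenceMap], params: AlignmentParams | None = None
) -> tuple[Alignment, float]:
    """Best placement across all reference sequences and orientations.

    Returns the top-scoring alignment and the runner-up score over every
    other (sequence, orientation) candidate, usable as a confidence margin.
    """
    if not references:
        raise ValueError("at least one reference sequence is required")
    params = params or AlignmentParams()
    candidates = [
        _align_oriented(query, ref, params, orientation)
        for ref in references
        for orientation in ("forward", "reverse")
    ]
    candidates.sort(key=lambda a: a.score, reverse=True)
    best = candidates[0]
    runner_up = candidates[1].score if len(candidates) > 1 else float("-inf")
    return best, runner_up


def brute_force_align(
    reference_bp, query_bp, params: AlignmentParams
) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Exhaustive oracle: enumerate every monotone pairing with gaps <= delta.

    Intended for tiny instances only (<= 10 reference, <= 8 query labels);
    evaluates the scoring objective on each admissible pair sequence and
    returns the maximum.  Exercised in tests as an independent check of the
    dynamic program.
    """
    r = np.asarray(reference_bp, dtype=np.float64)
    q = np.asarray(query_bp, dtype=np.float64)
    if len(r) > 10 or len(q) > 8:
        raise ValueError("instance too large for exhaustive enumeration")
    if len(r) == 0 or len(q) == 0:
        raise ValueError("empty map")
    best_score = -np.inf
    best_pairs: tuple[tuple[int, int], ...] = ()

    def extend(pairs: list[tuple[int, int]], score: float) -> None:
        nonlocal best_score, best_pairs
        if score > best_score:
            best_score = score
            best_pairs = tuple(pairs)
        gi, hj = pairs[-1]
        for i in range(gi + 1, min(gi + params.delta, len(r) - 1) + 1):
            for j in range(hj + 1, min(hj + params.delta, len(q) - 1) + 1):
                stretch = abs(abs(r[i] - r[gi]) - abs(q[j] - q[hj]))
                step = 1.0 - stretch / params.alpha - ((i - gi - 1) + (j - hj - 1)) / params.beta
                pairs.append((i, j))
                extend(pairs, score + step)
                pairs.pop()

    for i in range(len(r)):
        for j in range(len(q)):
            extend([(i, j)], 1.0)
    return float(best_score), best_pairs
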