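"""Average amino-acid identity (AAI) from reciprocal best hits.

Orthologs between two proteomes are defined operationally as reciprocal
best hits (RBH): protein pairs that are each other's highest-scoring match
under Smith–Waterman local alignment with BLOSUM62 and affine gaps
(open −11 / extend −1).  AAI is 100 × the mean alignment identity over RBH
pairs, with identity counted as matching columns over all alignment
columns (gap columns included in the denominator).

Candidate hits are filtered by raw score and coverage of the shorter
sequence rather than by an E-value — a deliberate, configurable substitute
that preserves RBH semantics without Karlin–Altschul statistics.  Ties on
score break to the lexicographically smallest subject id, so results are
deterministic and independent of record order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .proteome import Proteome, sanitize

__all__ = [
    "AlignmentHit", "AAIResult", "make_aligner", "align_pair",
    "best_hits", "rbbh", "aai_pair", "aai_matrix",
    "DEFAULT_MIN_SCORE", "DEFAULT_MIN_COVERAGE",
]

DEFAULT_MIN_SCORE = 50.0
DEFAULT_MIN_COVERAGE = 0.5


@lru_cache(maxsize=None)
def make_aligner(matrix: str = "BLOSUM62", open_gap: float = -11.0,
                 extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    identity: float
    query_coverage: float
    subject_coverage: float


def align_pair(seq_a: str, seq_b: str, query_id: str = "a", subject_id: str = "b",
               aligner: Align.PairwiseAligner | None = None) -> AlignmentHit:
    """Best local alignment of two protein sequences.

    Identity = matching columns / total alignment columns (gaps count in
    the denominator); coverage = aligned residues / sequence length.
    """
    seq_a, seq_b = sanitize(seq_a), sanitize(seq_b)
    if not seq_a or not seq_b:
        raise ValueError("empty sequence in align_pair")
    aligner = aligner or make_aligner()
    alignments = aligner.align(seq_a, seq_b)
    try:
        alignment = alignments[0]
    except IndexError:
        # no positive-scoring local alignment exists
        return AlignmentHit(query_id, subject_id, 0.0, 0.0, 0.0, 0.0)
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    aligned_a = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)  # gap columns
        seg_a = seq_a[a0:a1]
        seg_b = seq_b[b0:b1]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
        aligned_a += a1 - a0
        columns += a1 - a0
        prev_a_end, prev_b_end = a1, b1
    aligned_b = sum(b1 - b0 for b0, b1 in blocks_b)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(alignment.score),
        identity=matches / columns if columns else 0.0,
        query_coverage=aligned_a / len(seq_a),
        subject_coverage=aligned_b / len(seq_b),
    )


def best_hits(proteome_a: Proteome, proteome_b: Proteome,
              min_score: float = DEFAULT_MIN_SCORE,
              min_coverage: float = DEFAULT_MIN_COVERAGE,
              aligner: Align.PairwiseAligner | None = None) -> dict[str, str]:
    """Best subject per query by score, after score and coverage filters.

    Scores are computed without traceback for speed; the traceback (needed
    only for coverage) runs on candidates in descending score order until
    one passes.  Queries with no passing hit are absent from the map.
    """
    if len(proteome_a) == 0 or len(proteome_b) == 0:
        raise ValueError("empty proteome in best_hits")
    aligner = aligner or make_aligner()
    subjects = sorted(proteome_b.records)  # lexicographic id order
    out: dict[str, str] = {}
    for query_id, query_seq in proteome_a:
        qs = sanitize(query_seq)
        scores = np.array([aligner.score(qs, sanitize(s)) for _, s in subjects])
        shorter = np.array([min(len(qs), len(sanitize(s))) for _, s in subjects])
        order = np.argsort(-scores, kind="stable")  # ties keep lexicographic order
        for idx in order:
            if scores[idx] < min_score:
                break
            sid, sseq = subjects[idx]
            hit = align_pair(qs, sseq, query_id, sid, aligner)
            cov_shorter = (hit.query_coverage if len(qs) <= len(sanitize(sseq))
                           else hit.subject_coverage)
            if cov_shorter >= min_coverage:
                out[query_id] = sid
                break
    return out


def rbbh(proteome_a: Proteome, proteome_b: Proteome,
         min_score: float = DEFAULT_MIN_SCORE,
         min_coverage: float = DEFAULT_MIN_COVERAGE) -> list[tuple[str, str]]:
    """Reciprocal best hit pairs (a_id, b_id), sorted by a_id."""
    fwd = best_hits(proteome_a, proteome_b, min_score, min_coverage)
    rev = best_hits(proteome_b, proteome_a, min_score, min_coverage)
    pairs = [(q, s) for q, s in fwd.items() if rev.get(s) == q]
    return sorted(pairs)


@dataclass
class AAIResult:
    genome_a: str
    genome_b: str
    aai: float  # percent; NaN when no orthologs pass the filters
    n_orthologs: int


def aai_pair(proteome_a: Proteome, proteome_b: Proteome,
             min_score: float = DEFAULT_MIN_SCORE,
             min_coverage: float = DEFAULT_MIN_COVERAGE) -> AAIResult:
    """AAI between two proteomes: 100 × mean RBH alignment identity."""
    pairs = rbbh(proteome_a, proteome_b, min_score, min_coverage)
    if not pairs:
        warnings.warn(
            f"no reciprocal best hits between {proteome_a.genome_id} and "
            f"{proteome_b.genome_id}; AAI undefined"
        )
        return AAIResult(proteome_a.genome_id, proteome_b.genome_id,
                         float("nan"), 0)
    seq_a = dict(proteome_a.records)
    seq_b = dict(proteome_b.records)
    identities = [
        align_pair(seq_a[qa], seq_b[qb], qa, qb).identity for qa, qb in pairs
    ]
    return AAIResult(proteome_a.genome_id, proteome_b.genome_id,
                     100.0 * float(np.mean(identities)), len(pairs))


def aai_matrix(proteomes: list[Proteome],
               min_score: float = DEFAULT_MIN_SCORE,
               min_coverage: float = DEFAULT_MIN_COVERAGE
               ) -> tuple[pd.DataFrame, list[AAIResult]]:
    """Symmetric all-vs-all AAI matrix (diagonal 100), one pair at a time."""
    ids = [p.genome_id for p in proteomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids in aai_matrix")
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    mat = pd.DataFrame(np.full((len(ids), len(ids)), 100.0),
                       index=ids, columns=ids)
    results: list[AAIResult] = []
    for i in range(len(proteomes)):
        for j in range(i + 1, len(proteomes)):
            res = aai_pair(proteomes[i], proteomes[j], min_score, min_coverage)
            results.append(res)
            mat.iloc[i, j] = mat.iloc[j, i] = res.aai
    return mat, results
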