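"""Local-alignment homology search with E-value statistics.

The pipeline's candidate generation is a BLASTP-style search: rank local
alignments of a query set against a database by E-value and keep hits below
a cutoff.  Two interchangeable backends satisfy that contract:

* :class:`BuiltinSearchBackend` — Smith–Waterman local alignment under
  affine gap penalties (a gap of length *g* costs
  ``gap_open + (g - 1) * gap_extend``) with Karlin–Altschul E-values
  ``E = K * m * n * exp(-lambda * S)``, where *m* is the query length and
  *n* the total residue count of the database.  Scoring defaults to
  BLOSUM62 with gap open 11 / extend 1.  Absolute E-values differ from
  BLAST+'s (no finite-size or composition corrections), but the pipeline
  only needs a calibrated, monotone E-value with the same cutoff interface.
* :class:`PrecomputedSearchBackend` — replays hits parsed from BLAST+
   12-column tabular files, restoring bit-compatibility with real BLAST+
  runs for users who have them.

The Karlin–Altschul parameters default to the published gapped
BLOSUM62/11/1 constants (lambda = 0.267, K = 0.041) rather than being
re-derived per run, which keeps runs deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ALPHABET, Proteome

__all__ = [
    "ScoringScheme",
    "Calibration",
    "SearchHit",
    "smith_waterman",
    "evalue_of",
    "search",
    "SearchBackend",
    "BuiltinSearchBackend",
    "PrecomputedSearchBackend",
    "STAGE_TIER1",
    "STAGE_TIER2",
    "STAGE_REVERSE",
]

# Published gapped Karlin-Altschul constants for BLOSUM62, open 11 / extend 1.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041

# Search stages, used by backends that hold per-stage precomputed hits.
STAGE_TIER1 = "tier1"
STAGE_TIER2 = "tier2"
STAGE_REVERSE = "reverse"


def _blosum62_with_worst_case_x() -> substitution_matrices.Array:
    """BLOSUM62 restricted to the 20 standard residues plus X.

    X is scored as the worst-case substitution (the matrix minimum over the
    standard residues), so ambiguous positions can never create alignment
    signal.
    """
    full = substitution_matrices.load("BLOSUM62")
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    core = ALPHABET[:-1]  # the 20 standard residues
    worst = min(full[a, b] for a in core for b in core)
    for a in ALPHABET:
        for b in ALPHABET:
            if a == "X" or b == "X":
                mat[a, b] = worst
            else:
                mat[a, b] = full[a, b]
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    Defaults mirror BLASTP's: BLOSUM62, gap open 11, gap extend 1.
    Penalties are positive integers; the aligner subtracts them.
    """

    matrix: substitution_matrices.Array = field(
        default_factory=_blosum62_with_worst_case_x
    )
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError(
                f"require gap_open >= gap_extend >= 1, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )
        arr = np.asarray(self.matrix)
        if not np.array_equal(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner(mode="local")
        aligner.substitution_matrix = self.matrix
        # Biopython charges open_gap_score for the first gapped position and
        # extend_gap_score for each further one: a gap of length g costs
        # gap_open + (g-1)*gap_extend, the convention used throughout.
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner


@dataclass(frozen=True)
class Calibration:
    """Karlin–Altschul parameters for one query/database combination.

    ``lambda_`` and ``k`` are the statistical parameters of the score
    distribution; ``query_length`` (m) and ``effective_db_length`` (n) are
    the search-space dimensions.
    """

    lambda_: float = BLOSUM62_GAPPED_LAMBDA
    k: float = BLOSUM62_GAPPED_K
    query_length: int = 0
    effective_db_length: int = 0

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class SearchHit:
    """One query→subject homology hit.

    Spans are 1-based inclusive residue intervals; they are ``None`` for the
    degenerate empty alignment (score 0).
    """

    query_id: str
    subject_id: str
    raw_score: int
    evalue: float
    query_span: Optional[tuple[int, int]] = None
    subject_span: Optional[tuple[int, int]] = None
    identity_fraction: float = 0.0


def smith_waterman(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[int, Optional[tuple[int, int]], Optional[tuple[int, int]], float]:
    """Optimal local alignment of two sequences under affine gaps.

    Returns ``(raw_score, query_span, subject_span, identity_fraction)``.
    The score is never negative; when no positive-scoring alignment exists
    the alignment is empty (score 0, spans ``None``).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme()
    aligner = scheme.make_aligner()
    return _align_one(aligner, a, b)


def _align_one(
    aligner: Align.PairwiseAligner, a: str, b: str
) -> tuple[int, Optional[tuple[int, int]], Optional[tuple[int, int]], float]:
    score = aligner.score(a, b)
    if score <= 0:
        return 0, None, None, 0.0
    aln = aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    a_span = (int(a_blocks[0][0]) + 1, int(a_blocks[-1][1]))
    b_span = (int(b_blocks[0][0]) + 1, int(b_blocks[-1][1]))
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    return int(score), a_span, b_span, identity


def evalue_of(score: float, cal: Calibration) -> float:
    """Karlin–Altschul expect value ``E = K * m * n * exp(-lambda * S)``.

    Strictly decreasing in the score and linear in both search-space
    dimensions.
    """
    return cal.k * cal.query_length * cal.effective_db_length * math.exp(
        -cal.lambda_ * score
    )


def search(
    queries: Proteome,
    database: Proteome,
    cutoff: float,
    scheme: ScoringScheme | None = None,
    lambda_: float = BLOSUM62_GAPPED_LAMBDA,
    k: float = BLOSUM62_GAPPED_K,
) -> list[SearchHit]:
    """All-vs-all local-alignment search reported at ``evalue <= cutoff``.

    At most one hit per (query, subject) pair — the optimal alignment.  The
    effective database length is the total residue count of ``database``.
    Hits are ordered by (query_id, evalue, subject_id) for determinism.
    """
    if len(queries) == 0:
        raise ValueError("empty query set")
    if len(database) == 0:
        raise ValueError("empty database")
    scheme = scheme or ScoringScheme()
    aligner = scheme.make_aligner()
    n = database.total_residues
    hits: list[SearchHit] = []
    for q in queries:
        cal = Calibration(
            lambda_=lambda_, k=k, query_length=len(q), effective_db_length=n
        )
        for s in database:
            score = aligner.score(q.sequence, s.sequence)
            if score <= 0:
                continue
            ev = evalue_of(score, cal)
            if ev > cutoff:
                continue
            _, q_span, s_span, identity = _align_one(
                aligner, q.sequence, s.sequence
            )
            hits.append(
                SearchHit(
                    query_id=q.id,
                    subject_id=s.id,
                    raw_score=int(score),
                    evalue=ev,
                    query_span=q_span,
                    subject_span=s_span,
                    identity_fraction=identity,
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id))
    return hits


class SearchBackend:
    """Contract both backends satisfy.

    ``search_stage`` must honor the post-conditions of :func:`search`: best
    hit per pair, ``evalue <= cutoff``, deterministic order.  Pipeline
    results depend only on the returned hits, never on which backend
    produced them.
    """

    def search_stage(
        self, queries: Proteome, database: Proteome, cutoff: float, stage: str
    ) -> list[SearchHit]:
        raise NotImplementedError


class BuiltinSearchBackend(SearchBackend):
    """Smith–Waterman engine with Karlin–Altschul E-values."""

    def __init__(self, scheme: ScoringScheme | None = None) -> None:
        self.scheme = scheme or ScoringScheme()

    def search_stage(
        self, queries: Proteome, database: Proteome, cutoff: float, stage: str
    ) -> list[SearchHit]:
        return search(queries, database, cutoff, self.scheme)


class PrecomputedSearchBackend(SearchBackend):
    """Replays externally computed hits (e.g. parsed BLAST+ tabular files).

    Holds one hit collection per search stage.  At construction every id in
    every hit must belong to the known sequence universe; at query time hits
    are restricted to the requested query/database subsets and cutoff.
    """

    def __init__(
        self,
        tier1_hits: Sequence[SearchHit],
        tier2_hits: Sequence[SearchHit],
        reverse_hits: Sequence[SearchHit],
        known_ids: Iterable[str],
    ) -> None:
        known = set(known_ids)
        self._by_stage: dict[str, list[SearchHit]] = {
            STAGE_TIER1: list(tier1_hits),
            STAGE_TIER2: list(tier2_hits),
            STAGE_REVERSE: list(reverse_hits),
        }
        unknown = sorted(
            {h.query_id for hits in self._by_stage.values() for h in hits}
            .union(
                h.subject_id for hits in self._by_stage.values() for h in hits
            )
            - known
        )
        if unknown:
            raise ValueError(
                f"precomputed hits reference unknown sequence ids: {unknown}"
            )

    def search_stage(
        self, queries: Proteome, database: Proteome, cutoff: float, stage: str
    ) -> list[SearchHit]:
        if stage not in self._by_stage:
            raise ValueError(f"unknown search stage {stage!r}")
        selected = [
            h
            for h in self._by_stage[stage]
            if h.evalue <= cutoff
            and h.query_id in queries
            and h.subject_id in database
        ]
        selected.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id))
        return selected
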