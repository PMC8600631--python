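"""Local-alignment engine, percent-identity arithmetic and Karlin-Altschul
E-values.

Percent identity over a V-segment alignment is the clinical quantity in this
package: ``100 * matches / alignment_length`` where the alignment length
counts matched, mismatched and gapped columns alike, so e.g. a gap-free
296-column alignment with 280 matches gives 100 * 280 / 296 = 96.4%, and the
mutation percentage is its complement.

Alignments are optimal affine-gap Smith-Waterman, computed by Biopython's
``PairwiseAligner`` (C implementation, no heuristics). Gap cost convention:
a gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the opening
column pays ``gap_open``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores (blastn-like defaults)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass(frozen=True)
class EvalueParams:
    """Karlin-Altschul parameters for E = K * m * n * exp(-lambda * S).

    Defaults approximate ungapped blastn values for the default scoring
    scheme; they are configuration, not constants, because the screening
    threshold (E <= 20) is permissive and insensitive to small changes.
    """

    lam: float = 1.28
    K: float = 0.46
    search_space_m: int = 1
    search_space_n: int = 1

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment summarised as column counts plus coordinates.

    Coordinates are half-open and 0-based. ``matches + mismatches +
    gap_columns == alignment_length`` always holds. ``mismatch_list`` gives
    (1-based subject position, subject base, query base) for each substituted
    column; ``max_match_run`` is the longest run of consecutive identical
    columns (used as D-segment evidence). For ``strand == '-'`` results the
    query coordinates refer to the original (un-reversed) query.
    """

    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    matches: int
    mismatches: int
    gap_columns: int
    alignment_length: int
    strand: str = "+"
    mismatch_list: tuple[tuple[int, str, str], ...] = ()
    max_match_run: int = 0

    def __post_init__(self) -> None:
        if self.matches + self.mismatches + self.gap_columns != self.alignment_length:
            raise ValueError(
                "matches + mismatches + gap_columns must equal alignment_length"
            )
        if min(self.matches, self.mismatches, self.gap_columns) < 0:
            raise ValueError("column counts must be non-negative")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @classmethod
    def gapless(
        cls,
        matches: int,
        alignment_length: int,
        *,
        score: Optional[float] = None,
        query_start: int = 0,
        subject_start: int = 0,
    ) -> "AlignmentResult":
        """Build a gap-free result from matches and alignment length; the
        mismatch count is implied (alignment_length - matches)."""
        mism = alignment_length - matches
        if mism < 0:
            raise ValueError("matches exceeds alignment_length")
        return cls(
            score=float(matches) if score is None else score,
            query_start=query_start,
            query_end=query_start + alignment_length,
            subject_start=subject_start,
            subject_end=subject_start + alignment_length,
            matches=matches,
            mismatches=mism,
            gap_columns=0,
            alignment_length=alignment_length,
        )


def percent_identity(result: AlignmentResult) -> float:
    """100 * matches / alignment_length, at full precision.

    User-facing output rounds to one decimal; internal computation keeps
    full precision.
    """
    if result.alignment_length <= 0:
        raise ValueError("alignment_length must be positive")
    return 100.0 * result.matches / result.alignment_length


def evalue(score: float, params: EvalueParams) -> float:
    """Expected number of chance local alignments scoring >= ``score``."""
    if score < 0:
        raise ValueError("score must be non-negative")
    return (
        params.K
        * params.search_space_m
        * params.search_space_n
        * math.exp(-params.lam * score)
    )


_EMPTY = AlignmentResult(
    score=0.0,
    query_start=0,
    query_end=0,
    subject_start=0,
    subject_end=0,
    matches=0,
    mismatches=0,
    gap_columns=0,
    alignment_length=0,
)


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _align_single(query: str, subject: str, scheme: ScoringScheme) -> AlignmentResult:
    """Optimal local alignment of ``query`` (+ strand) against ``subject``."""
    aligner = _make_aligner(scheme)
    alns = aligner.align(query, subject)
    try:
        best = alns[0]
    except IndexError:
        return _EMPTY
    if best.score <= 0:
        return _EMPTY
    q_blocks, s_blocks = best.aligned
    matches = mismatches = gaps = 0
    mismatch_list: list[tuple[int, str, str]] = []
    max_run = run = 0
    prev_q_end = prev_s_end = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            gap_here = (qs - prev_q_end) + (ss - prev_s_end)
            gaps += gap_here
            if gap_here:
                run = 0
        for i in range(qe - qs):
            qc, sc = query[qs + i], subject[ss + i]
            if qc == sc:
                matches += 1
                run += 1
                if run > max_run:
                    max_run = run
            else:
                mismatches += 1
                mismatch_list.append((ss + i + 1, sc, qc))
                run = 0
        prev_q_end, prev_s_end = qe, se
    return AlignmentResult(
        score=float(best.score),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        subject_start=int(s_blocks[0][0]),
        subject_end=int(s_blocks[-1][1]),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        alignment_length=matches + mismatches + gaps,
        strand="+",
        mismatch_list=tuple(mismatch_list),
        max_match_run=max_run,
    )


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme = ScoringScheme(),
    both_strands: bool = True,
) -> AlignmentResult:
    """Best local alignment of ``query`` against ``subject``.

    Both strands of the query are tried when ``both_strands`` is set; the
    better score wins and exact score ties resolve to the plus strand. For a
    minus-strand result, query coordinates are mapped back onto the original
    query but ``mismatch_list`` query bases come from the reversed query
    (i.e. they read in subject orientation, which is what SHM reporting
    needs).
    """
    query = query.upper()
    subject = subject.upper()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    fwd = _align_single(query, subject, scheme)
    if not both_strands:
        return fwd
    rev = _align_single(revcomp(query), subject, scheme)
    if rev.score > fwd.score:
        n = len(query)
        return AlignmentResult(
            score=rev.score,
            query_start=n - rev.query_end,
            query_end=n - rev.query_start,
            subject_start=rev.subject_start,
            subject_end=rev.subject_end,
            matches=rev.matches,
            mismatches=rev.mismatches,
            gap_columns=rev.gap_columns,
            alignment_length=rev.alignment_length,
            strand="-",
            mismatch_list=rev.mismatch_list,
            max_match_run=rev.max_match_run,
        )
    return fwd
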