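"""Internal pairwise-alignment helpers shared by anib, pangenome and signature.

Thin wrappers around Bio.Align.PairwiseAligner plus exact k-mer seeding for
fragment-vs-genome searches. Identity is always computed over alignment
columns *including* gap columns (BLAST-style semantics), and ambiguous
residues (N and friends) never count as identical.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import UNAMBIGUOUS_BASES

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PairwiseResult:
    """Coordinates and column counts of one pairwise alignment."""

    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    identities: int
    columns: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.columns if self.columns else 0.0


def _nucleotide_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner(mode=mode)
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    if mode == "global":
        # free end gaps: semi-global, so length differences are not penalized
        aligner.end_gap_score = 0.0
    return aligner


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _summarize(alignment, query: str, subject: str, ambiguous: frozenset[str]) -> PairwiseResult:
    """Count identities and columns (gap columns included) of an alignment."""
    # PairwiseAligner.align(a, b): a is "target", b is "query"; we always call
    # align(subject, query), so aligned[0] indexes the subject.
    blocks_sub, blocks_q = alignment.aligned
    identities = 0
    columns = 0
    prev_s = prev_q = None
    for (s0, s1), (q0, q1) in zip(blocks_sub, blocks_q):
        if prev_s is not None:
            columns += (s0 - prev_s) + (q0 - prev_q)
        columns += s1 - s0
        sub_block = subject[s0:s1]
        q_block = query[q0:q1]
        for a, b in zip(sub_block, q_block):
            if a == b and a not in ambiguous:
                identities += 1
        prev_s, prev_q = s1, q1
    if len(blocks_q):
        q_start, q_end = blocks_q[0][0], blocks_q[-1][1]
        s_start, s_end = blocks_sub[0][0], blocks_sub[-1][1]
    else:
        q_start = q_end = s_start = s_end = 0
    return PairwiseResult(float(alignment.score), int(q_start), int(q_end),
                          int(s_start), int(s_end), identities, columns)


_NUC_AMBIGUOUS = frozenset("NRYSWKMBDHVU-")
_PROT_AMBIGUOUS = frozenset("X-")


def local_align_nucleotide(query: str, subject: str) -> PairwiseResult | None:
    """Best local (Smith–Waterman) alignment; None if nothing scores > 0."""
    aligner = _nucleotide_aligner("local")
    alignments = aligner.align(subject, query)
    try:
        best = alignments[0]
    except (IndexError, ValueError):
        return None
    if best.score <= 0:
        return None
    return _summarize(best, query, subject, _NUC_AMBIGUOUS)


def global_align_nucleotide(query: str, subject: str) -> PairwiseResult:
    """Semi-global alignment (end gaps free) of two nucleotide sequences."""
    aligner = _nucleotide_aligner("global")
    best = aligner.align(subject, query)[0]
    return _summarize(best, query, subject, _NUC_AMBIGUOUS)


def local_align_protein(query: str, subject: str) -> PairwiseResult | None:
    """Best local BLOSUM62 alignment of two protein sequences."""
    aligner = _protein_aligner()
    try:
        best = aligner.align(subject.replace("*", "X"), query.replace("*", "X"))[0]
    except (IndexError, ValueError):
        return None
    if best.score <= 0:
        return None
    return _summarize(best, query, subject, _PROT_AMBIGUOUS)


def aligned_pairs(query: str, reference: str) -> list[tuple[int | None, int | None]]:
    """Column-by-column (reference_index, query_index) pairs of a semi-global
    alignment; ``None`` marks a gap. Indices are 0-based."""
    aligner = _nucleotide_aligner("global")
    best = aligner.align(reference, query)
    best = best[0]
    blocks_ref, blocks_q = best.aligned
    pairs: list[tuple[int | None, int | None]] = []
    prev_r = prev_q = None
    for (r0, r1), (q0, q1) in zip(blocks_ref, blocks_q):
        if prev_r is not None:
            for r in range(prev_r, r0):
                pairs.append((r, None))
            for q in range(prev_q, q0):
                pairs.append((None, q))
        for r, q in zip(range(r0, r1), range(q0, q1)):
            pairs.append((r, q))
        prev_r, prev_q = r1, q1
    return pairs


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Exact k-mer → positions index; k-mers containing ambiguity are skipped."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) <= UNAMBIGUOUS_BASES:
            index.setdefault(kmer, []).append(i)
    return index


def seed_window(fragment: str, index: dict[str, list[int]], subject_len: int,
                k: int, margin: int = 60, diag_tolerance: int = 40) -> tuple[int, int] | None:
    """Locate the subject window most consistent with the fragment.

    Collects exact k-mer seed matches, clusters their diagonals (subject
    position − fragment position) within ``diag_tolerance``, and returns the
    subject interval implied by the best-supported diagonal cluster, padded by
    ``margin``. Returns None when the fragment shares no seed with the subject.
    """
    diagonals: list[int] = []
    step = max(1, k // 2)
    for i in range(0, len(fragment) - k + 1, step):
        kmer = fragment[i:i + k]
        for pos in index.get(kmer, ()):
            diagonals.append(pos - i)
    if not diagonals:
        return None
    diagonals.sort()
    # best cluster = densest run of diagonals within the tolerance
    best_lo = best_hi = 0
    best_count = 0
    lo = 0
    for hi in range(len(diagonals)):
        while diagonals[hi] - diagonals[lo] > diag_tolerance:
            lo += 1
        if hi - lo + 1 > best_count:
            best_count = hi - lo + 1
            best_lo, best_hi = lo, hi
    d_min, d_max = diagonals[best_lo], diagonals[best_hi]
    start = max(0, d_min - margin)
    end = min(subject_len, d_max + len(fragment) + margin)
    if end <= start:
        return None
    return start, end
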