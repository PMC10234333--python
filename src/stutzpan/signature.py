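"""16S rRNA signature-nucleotide evaluation and two-step screening.

A species' signature profile is an ordered list of reference-numbered 16S
positions with their expected bases. The screening classifier decides, for a
public 16S record, whether it belongs to the profiled species:

* step 1 — align the query to the reference screening region (default
  positions 50-650) and require identity >= 99.6% and coverage of the region
  >= 90%;
* step 2 — map every profile position onto the query through a pairwise
  alignment and require each one to be covered and to carry the expected
  base. Any covered mismatch rejects the query; an uncovered position (with
  all covered ones matching) leaves it unclassifiable rather than guessed —
  the strategy is deliberately strict, preferring missed strains over false
  positives.

Ambiguity codes (R, Y, N, ...) at a signature position count as uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _align
from .genome_io import UNAMBIGUOUS_BASES, SequenceRecord


@dataclass(frozen=True)
class SignatureProfile:
    """Reference-numbered signature positions and their expected bases.

    ``positions`` holds (reference_position, expected_base) pairs; positions
    are 1-based in the coordinate system of the reference record (the profile
    header documents the numbering scheme in use).
    """

    reference_id: str
    positions: tuple[tuple[int, str], ...]
    numbering_scheme: str = "reference coordinates (1-based)"

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.positions]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("profile positions must be strictly increasing")
        for p, base in self.positions:
            if p < 1:
                raise ValueError(f"position {p} is not 1-based")
            if base not in UNAMBIGUOUS_BASES:
                raise ValueError(f"expected base {base!r} at {p} is not A/C/G/T")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ScreeningThresholds:
    min_identity_pct: float = 99.6
    min_query_coverage: float = 0.90
    query_region: tuple[int, int] = (50, 650)  # 1-based inclusive, reference coords
    min_query_length: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct out of range")
        if not (0 < self.min_query_coverage <= 1):
            raise ValueError("min_query_coverage out of range")
        if self.query_region[0] >= self.query_region[1]:
            raise ValueError("empty query region")


@dataclass
class PositionMap:
    """reference position (1-based) -> query position (1-based) or None."""

    mapping: dict[int, int | None]

    def query_position(self, reference_position: int) -> int | None:
        return self.mapping.get(reference_position)


@dataclass
class ScreeningVerdict:
    sequence_id: str
    step1: str  # pass | fail_identity | fail_coverage | fail_length
    identity_pct: float
    coverage: float
    positions_covered: int
    positions_matched: int
    verdict: str  # member | non_member | not_classifiable
    detail: dict[int, str] = field(default_factory=dict)  # pos -> match|mismatch|uncovered


def map_reference_positions(query: SequenceRecord, reference: SequenceRecord,
                            profile: SignatureProfile) -> PositionMap:
    """Map profile positions onto the query via a global pairwise alignment.

    A profile position maps to the query base aligned with that reference
    base; positions falling in query gaps or beyond the query ends are
    uncovered (None).
    """
    pairs = _align.aligned_pairs(query.sequence, reference.sequence)
    if not any(q is not None and r is not None for r, q in pairs):
        raise ValueError(f"no alignment overlap between {query.id!r} and reference")
    by_ref = {r: q for r, q in pairs if r is not None}
    mapping: dict[int, int | None] = {}
    for pos, _ in profile.positions:
        q = by_ref.get(pos - 1)
        mapping[pos] = None if q is None else q + 1
    return PositionMap(mapping)


def _region_stats(query: SequenceRecord, reference: SequenceRecord,
                  region: tuple[int, int]) -> tuple[float, float]:
    """(identity_pct, coverage) of the query against the reference region.

    Identity is computed over local-alignment columns, gap columns included;
    coverage is the fraction of the region's reference positions aligned to a
    query base.
    """
    start, end = region
    region_seq = reference.sequence[start - 1:end]
    res = _align.local_align_nucleotide(query.sequence, region_seq)
    if res is None:
        return 0.0, 0.0
    coverage = (res.subject_end - res.subject_start) / len(region_seq)
    return res.identity_pct, coverage


def screen_sequence(query: SequenceRecord, reference: SequenceRecord,
                    profile: SignatureProfile,
                    thresholds: ScreeningThresholds = ScreeningThresholds()
                    ) -> ScreeningVerdict:
    """Two-step screening classifier (identity/coverage, then signatures)."""
    if len(query) < thresholds.min_query_length:
        return ScreeningVerdict(query.id, "fail_length", 0.0, 0.0, 0, 0,
                                "not_classifiable")
    identity, coverage = _region_stats(query, reference, thresholds.query_region)
    if coverage < thresholds.min_query_coverage:
        return ScreeningVerdict(query.id, "fail_coverage", identity, coverage,
                                0, 0, "not_classifiable")
    if identity < thresholds.min_identity_pct:
        return ScreeningVerdict(query.id, "fail_identity", identity, coverage,
                                0, 0, "non_member")
    pmap = map_reference_positions(query, reference, profile)
    detail: dict[int, str] = {}
    covered = matched = 0
    for pos, expected in profile.positions:
        qpos = pmap.query_position(pos)
        base = query.sequence[qpos - 1] if qpos is not None else None
        if base is None or base not in UNAMBIGUOUS_BASES:
            detail[pos] = "uncovered"
            continue
        covered += 1
        if base == expected:
            matched += 1
            detail[pos] = "match"
        else:
            detail[pos] = "mismatch"
    if covered > matched:
        verdict = "non_member"
    elif covered == len(profile):
        verdict = "member"
    else:
        verdict = "not_classifiable"
    return ScreeningVerdict(query.id, "pass", identity, coverage,
                            covered, matched, verdict, detail)


def evaluate_signature_set(ingroup: list[SequenceRecord],
                           outgroup: list[SequenceRecord],
                           reference: SequenceRecord,
                           profile: SignatureProfile) -> pd.DataFrame:
    """Conservation and exclusivity report for each profile position.

    For every position: ``conserved`` — every in-group sequence carries the
    expected base; ``exclusive`` — no out-group sequence carries it. The
    frame's ``attrs['combination_exclusive']`` records whether any single
    out-group sequence carries all positions at once (False means the full
    combination remains species-specific even when no single position is).
    """
    if not ingroup or not outgroup:
        raise ValueError("both panels must be non-empty")

    def states(seq: SequenceRecord) -> dict[int, str | None]:
        pmap = map_reference_positions(seq, reference, profile)
        out: dict[int, str | None] = {}
        for pos, _ in profile.positions:
            qpos = pmap.query_position(pos)
            base = seq.sequence[qpos - 1] if qpos is not None else None
            out[pos] = base if base in UNAMBIGUOUS_BASES else None
        return out

    in_states = [states(s) for s in ingroup]
    out_states = [states(s) for s in outgroup]
    rows = []
    for pos, expected in profile.positions:
        conserved = all(st[pos] == expected for st in in_states)
        exclusive = all(st[pos] != expected for st in out_states)
        rows.append({"position": pos, "expected_base": expected,
                     "conserved_in_ingroup": conserved, "exclusive": exclusive})
    report = pd.DataFrame(rows)
    combination_carried = any(
        all(st[pos] == expected for pos, expected in profile.positions)
        for st in out_states
    )
    report.attrs["combination_exclusive"] = not combination_carried
    return report


def pairwise_identity_matrix(seqs: list[SequenceRecord]) -> pd.DataFrame:
    """Global-alignment identity matrix (percent), diagonal 100.

    Identity = identical columns / columns with at least one residue.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    for s in seqs:
        if not s.sequence:
            raise ValueError(f"empty sequence {s.id!r}")
    n = len(seqs)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = _align.global_align_nucleotide(seqs[i].sequence, seqs[j].sequence)
            m[i, j] = m[j, i] = res.identity_pct
    ids = [s.id for s in seqs]
    return pd.DataFrame(m, index=ids, columns=ids)


def read_profile(path: str | Path) -> SignatureProfile:
    """Read a profile TSV (# key: value header lines, then position<TAB>base)."""
    meta = {"reference_id": "", "numbering_scheme": "reference coordinates (1-based)"}
    positions: list[tuple[int, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, value = line.lstrip("# ").split(":", 1)
                meta[key.strip()] = value.strip()
            continue
        if line.lower().startswith("reference_position"):
            continue
        pos, base = line.split("\t")
        positions.append((int(pos), base.strip().upper()))
    return SignatureProfile(meta["reference_id"], tuple(positions),
                            meta["numbering_scheme"])


def write_profile(profile: SignatureProfile, path: str | Path) -> None:
    lines = [f"# reference_id: {profile.reference_id}",
             f"# numbering_scheme: {profile.numbering_scheme}",
             "reference_position\texpected_base"]
    lines += [f"{p}\t{b}" for p, b in profile.positions]
    Path(path).write_text("\n".join(lines) + "\n")


def verdicts_table(verdicts: list[ScreeningVerdict]) -> pd.DataFrame:
    return pd.DataFrame([
        {"sequence_id": v.sequence_id, "step1": v.step1,
         "identity_pct": round(v.identity_pct, 3), "coverage": round(v.coverage, 3),
         "positions_covered": v.positions_covered,
         "positions_matched": v.positions_matched, "verdict": v.verdict}
        for v in verdicts
    ])
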