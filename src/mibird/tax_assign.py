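"""Taxonomic assignment of dereplicated amplicon units from alignment hits.

Hits come either from a standard 12-column tabular similarity-search file
(the "outfmt 6" dialect) or from the built-in local aligner, and are turned
into species calls by thresholding (>= 97% identity, E-value <= 1e-5 by
default), ranking, and two confidence metrics:

* the reliability score L/(m+1): alignment length over mismatches plus one
  (one is added to the denominator to avoid zero division);
* the ratio score: reliability of the top-hit species divided by the
  reliability of the best hit to any other species, a comparable indicator
  of how cleanly the top species wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "AlignmentHit",
    "Assignment",
    "AssignParams",
    "ScoringParams",
    "parse_hit_table",
    "align_local",
    "reliability_score",
    "assign",
    "assign_all",
    "assign_units",
    "assignments_tsv",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One similarity-search hit (12-column tabular semantics)."""

    query_id: str
    subject_accession: str
    subject_species: Optional[str]
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.mismatches < 0 or self.e_value < 0:
            raise ValueError("mismatches and e_value must be non-negative")


@dataclass(frozen=True)
class Assignment:
    """A species call for one query with its confidence metrics."""

    query_id: str
    status: str  # "assigned" | "ambiguous" | "unassigned"
    species: Optional[str] = None
    top_reliability: Optional[float] = None
    second_species: Optional[str] = None
    second_reliability: Optional[float] = None
    ratio_score: Optional[float] = None
    hit: Optional[AlignmentHit] = None
    candidates: Tuple[str, ...] = ()
    reason: Optional[str] = None


@dataclass(frozen=True)
class AssignParams:
    """Assignment thresholds (defaults: identity >= 97%, E <= 1e-5)."""

    min_identity: float = 97.0
    max_evalue: float = 1e-5
    min_ratio_score: Optional[float] = None  # optional sanity threshold, off by default

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 100.0:
            raise ValueError("min_identity must lie in (0, 100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


def reliability_score(hit: AlignmentHit) -> float:
    """Alignment length over (mismatches + 1): the assignment confidence metric."""
    return hit.alignment_length / (hit.mismatches + 1)


# --- hit-table parsing ----------------------------------------------------

_NUMERIC_FIELDS = (
    ("percent_identity", 2, float),
    ("alignment_length", 3, int),
    ("mismatches", 4, int),
    ("gap_opens", 5, int),
    ("e_value", 10, float),
    ("bit_score", 11, float),
)


def parse_hit_table(
    lines: Iterable[str], taxonomy: Optional[Mapping[str, str]] = None
) -> List[AlignmentHit]:
    """Parse 12-column tabular hit lines into AlignmentHits, preserving order.

    Column order: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  ``taxonomy`` maps subject
    accession to species; without it the accession doubles as the species
    label.  Malformed lines raise with the 1-based line number.
    """
    hits = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(cols)}"
            )
        values = {}
        for name, idx, cast in _NUMERIC_FIELDS:
            try:
                values[name] = cast(cols[idx])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: cannot parse field {name!r} from {cols[idx]!r}"
                ) from None
        acc = cols[1]
        if taxonomy is not None:
            if acc not in taxonomy:
                raise KeyError(f"line {lineno}: accession {acc!r} not in taxonomy")
            species = taxonomy[acc]
        else:
            species = acc
        hits.append(AlignmentHit(query_id=cols[0], subject_accession=acc,
                                 subject_species=species, **values))
    return hits


# --- built-in local aligner ----------------------------------------------

@dataclass(frozen=True)
class ScoringParams:
    """Scoring for the built-in local aligner and its E-value statistics.

    Karlin-Altschul lambda is solved from the substitution scores at
    uniform base composition; K defaults to 0.41 and is configurable (the
    E-values are desk-scale estimates for a single-subject search, adequate
    for thresholding at 1e-5, not database-calibrated statistics).
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    ka_k: float = 0.41

    @property
    def ka_lambda(self) -> float:
        return _solve_lambda(self.match, self.mismatch)


@lru_cache(maxsize=None)
def _solve_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda s_ij) = 1 at uniform base frequencies."""
    from scipy.optimize import brentq

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


def _alignment_stats(alignment) -> Tuple[int, int, int, int]:
    """(columns, identities, mismatches, gap_opens) from a PairwiseAligner alignment."""
    counts = alignment.counts()
    length = alignment.length
    gap_opens = 0
    for seqs in (alignment.aligned[0], alignment.aligned[1]):
        # each gap between consecutive aligned blocks of one sequence is one opening
        gap_opens += max(len(seqs) - 1, 0)
    return length, counts.identities, counts.mismatches, gap_opens


def align_local(
    query: str,
    subject,
    scoring: Optional[ScoringParams] = None,
) -> AlignmentHit:
    """Best local alignment of a query against one reference, both strands.

    A desk-scale exact Smith-Waterman (via dynamic programming) over the
    forward and reverse-complement strands; identity, alignment length,
    mismatches and gap openings are derived from the traceback, and the
    E-value from the Karlin-Altschul formula E = K m n exp(-lambda S) with
    the configured parameters.  ``subject`` is a ReferenceRecord or any
    object with ``accession``, ``species`` and ``sequence`` attributes.
    """
    from Bio import Align

    from .primer_eval import reverse_complement

    scoring = scoring or ScoringParams()
    if not query or not subject.sequence:
        raise ValueError("query and subject must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend

    best = None
    for strand_seq in (subject.sequence, reverse_complement(subject.sequence)):
        aln = aligner.align(query, strand_seq)
        score = aln.score
        if best is None or score > best[0]:
            best = (score, aln[0])
    score, alignment = best
    length, identities, mismatches, gap_opens = _alignment_stats(alignment)
    lam, k = scoring.ka_lambda, scoring.ka_k
    evalue = k * len(query) * len(subject.sequence) * math.exp(-lam * score)
    bit_score = (lam * score - math.log(k)) / math.log(2.0)
    return AlignmentHit(
        query_id="query",
        subject_accession=subject.accession,
        subject_species=subject.species,
        percent_identity=100.0 * identities / length,
        alignment_length=length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        e_value=evalue,
        bit_score=bit_score,
    )


# --- assignment -----------------------------------------------------------

def _rank_key(hit: AlignmentHit) -> Tuple[float, float, str]:
    return (-hit.bit_score, -reliability_score(hit), hit.subject_accession)


def assign(hits: Sequence[AlignmentHit], params: Optional[AssignParams] = None) -> Assignment:
    """Call a species for one query from its hit list.

    Hits are collapsed to the best hit per species, ranked by bit score
    (ties: reliability score, then accession).  The top hit must clear both
    the identity and E-value thresholds or the query is unassigned.  The
    ratio score compares the top species' reliability against the best hit
    to a *different* species; equal-best hits to different species (same
    bit score and reliability) yield an ambiguous call listing candidates.
    """
    params = params or AssignParams()
    if not hits:
        return Assignment(query_id="", status="unassigned", reason="no hits")
    query_ids = {h.query_id for h in hits}
    if len(query_ids) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(query_ids)}")
    qid = hits[0].query_id

    best_per_species: Dict[str, AlignmentHit] = {}
    for h in hits:
        sp = h.subject_species or h.subject_accession
        if sp not in best_per_species or _rank_key(h) < _rank_key(best_per_species[sp]):
            best_per_species[sp] = h
    ranked = sorted(best_per_species.values(), key=_rank_key)
    top = ranked[0]
    if top.percent_identity < params.min_identity or top.e_value > params.max_evalue:
        return Assignment(query_id=qid, status="unassigned", reason="below threshold")

    top_rel = reliability_score(top)
    ties = [
        h for h in ranked[1:]
        if h.bit_score == top.bit_score and reliability_score(h) == top_rel
    ]
    if ties:
        candidates = tuple(h.subject_species for h in [top] + ties)
        return Assignment(
            query_id=qid, status="ambiguous", candidates=candidates,
            top_reliability=top_rel, reason="tied top hits",
        )
    second = ranked[1] if len(ranked) > 1 else None
    second_rel = reliability_score(second) if second else None
    ratio = top_rel / second_rel if second_rel else None
    if params.min_ratio_score is not None and ratio is not None and ratio < params.min_ratio_score:
        return Assignment(
            query_id=qid, status="unassigned", reason="ratio score below threshold",
            top_reliability=top_rel, second_reliability=second_rel, ratio_score=ratio,
        )
    return Assignment(
        query_id=qid, status="assigned", species=top.subject_species,
        top_reliability=top_rel,
        second_species=second.subject_species if second else None,
        second_reliability=second_rel, ratio_score=ratio, hit=top,
    )


def assign_all(
    hits: Sequence[AlignmentHit], params: Optional[AssignParams] = None
) -> List[Assignment]:
    """Group hits by query (preserving first-seen order) and assign each."""
    by_query: Dict[str, List[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return [assign(qhits, params) for qhits in by_query.values()]


def assign_units(
    units: Sequence[Tuple[str, str]],
    panel: Sequence,
    params: Optional[AssignParams] = None,
    scoring: Optional[ScoringParams] = None,
) -> List[Assignment]:
    """Assign (unit_id, sequence) pairs against a reference panel with the
    built-in aligner (desk-scale substitute for an external search)."""
    out = []
    for uid, seq in units:
        hits = []
        for rec in panel:
            h = align_local(seq, rec, scoring)
            hits.append(
                AlignmentHit(
                    query_id=uid, subject_accession=h.subject_accession,
                    subject_species=h.subject_species,
                    percent_identity=h.percent_identity,
                    alignment_length=h.alignment_length, mismatches=h.mismatches,
                    gap_opens=h.gap_opens, e_value=h.e_value, bit_score=h.bit_score,
                )
            )
        out.append(assign(hits, params))
    return out


def assignments_tsv(
    assignments: Sequence[Assignment],
    read_counts: Optional[Mapping[str, int]] = None,
) -> str:
    """Render assignments as TSV."""
    cols = (
        "query\tstatus\tspecies\tidentity\tlength\tmismatches\tevalue"
        "\treliability\tsecond_species\tratio_score\tread_count"
    )
    lines = [cols]
    for a in assignments:
        h = a.hit
        rc = read_counts.get(a.query_id, "") if read_counts else ""
        lines.append("\t".join(str(x) if x is not None else "" for x in (
            a.query_id, a.status, a.species,
            f"{h.percent_identity:.3f}" if h else None,
            h.alignment_length if h else None,
            h.mismatches if h else None,
            f"{h.e_value:.3g}" if h else None,
            f"{a.top_reliability:.3f}" if a.top_reliability is not None else None,
            a.second_species,
            f"{a.ratio_score:.3f}" if a.ratio_score is not None else None,
            rc,
        )))
    return "\n".join(lines) + "\n"
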