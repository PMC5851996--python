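"""Amplicon read processing: trim, merge, filter, primer removal, dereplication.

Implements the pre-assignment pipeline for paired-end amplicon surveys:

1. quality tail trimming at a Phred cutoff (default Q10),
2. overlap-based pair merging (minimum overlap 10 bp, quality-aware
   consensus),
3. removal of merged reads with ambiguous bases or unusual lengths,
4. anchored primer removal allowing up to three mismatches per primer,
5. two-tier dereplication: exact duplicates are counted, sequences seen at
   least 10 times become representatives, and rarer sequences are absorbed
   into a representative at >= 99% identity (one or two differences on a
   ~171 bp insert) or discarded with accounting.

Read counts are conserved at every stage: input = output + removed, by
reason.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .insert_resolution import edit_distance
from .primer_eval import Primer, reverse_complement

__all__ = [
    "ReadRecord",
    "MergedRead",
    "DereplicatedUnit",
    "ProcessingParams",
    "quality_trim",
    "merge_pair",
    "filter_merged",
    "trim_primers",
    "TrimResult",
    "dereplicate",
    "process_pairs",
    "read_fastq",
    "read_fastq_pairs",
    "write_units_fasta",
    "parse_units_fasta",
    "accounting_tsv",
]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: bases (may contain N) plus per-base Phred scores."""

    id: str
    bases: str
    quals: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")
        if self.quals and not all(0 <= q <= 60 for q in self.quals):
            raise ValueError(f"read {self.id}: Phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MergedRead:
    """A merged read pair with overlap accounting."""

    id: str
    bases: str
    quals: Tuple[int, ...]
    overlap_length: int
    overlap_mismatches: int

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class DereplicatedUnit:
    """A count-weighted representative sequence after dereplication.

    ``members`` lists (variant sequence, count, identity to representative),
    including the representative itself at identity 1.0; ``read_count`` is
    the total over members.
    """

    representative: str
    read_count: int
    members: Tuple[Tuple[str, int, float], ...]


@dataclass(frozen=True)
class ProcessingParams:
    """Tunable thresholds of the read pipeline (defaults follow the protocol)."""

    phred_cutoff: int = 10
    min_overlap: int = 10
    max_mismatch_fraction: float = 0.25
    length_window: Optional[Tuple[int, int]] = None
    max_primer_mismatch: int = 3
    min_reads_representative: int = 10
    rescue_identity: float = 0.99
    leading_bases: int = 0  # random-base spacer allowance before the fwd primer
    hamming_rescue: bool = False  # substitution-only identity for equal lengths

    def __post_init__(self) -> None:
        if min(
            self.phred_cutoff,
            self.min_overlap,
            self.max_primer_mismatch,
            self.min_reads_representative,
            self.leading_bases,
        ) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.length_window is not None and self.length_window[0] > self.length_window[1]:
            raise ValueError("length_window min must be <= max")

    @staticmethod
    def default_length_window(
        fwd: Primer, rev: Primer, insert_length: int = 171, tolerance: float = 0.2
    ) -> Tuple[int, int]:
        """Expected merged-amplicon length window: (primers+insert) +/- 20%."""
        expected = len(fwd.core) + len(rev.core) + insert_length
        return (round(expected * (1 - tolerance)), round(expected * (1 + tolerance)))


def quality_trim(read: ReadRecord, cutoff: int = 10) -> ReadRecord:
    """Keep the longest contiguous segment with every base at Phred >= cutoff.

    Ties go to the leftmost such segment; the result may be empty.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    best_start = best_len = 0
    start = None
    for i, q in enumerate(read.quals):
        if q >= cutoff:
            if start is None:
                start = i
        elif start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if start is not None and len(read.quals) - start > best_len:
        best_start, best_len = start, len(read.quals) - start
    end = best_start + best_len
    return ReadRecord(read.id, read.bases[best_start:end], read.quals[best_start:end])


def merge_pair(
    fwd: ReadRecord, rev: ReadRecord, params: Optional[ProcessingParams] = None
) -> Optional[MergedRead]:
    """Overlap-merge a read pair; ``None`` when no acceptable overlap exists.

    The reverse read is reverse-complemented and slid along the forward
    read (standard innie geometry).  Among offsets whose overlap is at
    least ``min_overlap``, the one with the lowest overlap mismatch
    fraction wins (ties -> longest overlap); the merge succeeds when that
    fraction is at most ``max_mismatch_fraction``.  At each overlap
    position the consensus takes the higher-quality base on disagreement
    and retains the per-position maximum quality.
    """
    params = params or ProcessingParams()
    if len(fwd) == 0 or len(rev) == 0:
        return None
    f = np.frombuffer(fwd.bases.encode("ascii"), dtype=np.uint8)
    fq = np.asarray(fwd.quals, dtype=np.int16)
    r = np.frombuffer(reverse_complement(rev.bases).encode("ascii"), dtype=np.uint8)
    rq = np.asarray(rev.quals, dtype=np.int16)[::-1]

    best = None  # (frac, -overlap, offset, mismatches)
    for offset in range(len(f)):
        ov = min(len(f) - offset, len(r))
        if ov < params.min_overlap:
            break  # overlap only shrinks as the offset grows
        mm = int(np.count_nonzero(f[offset : offset + ov] != r[:ov]))
        cand = (mm / ov, -ov, offset, mm)
        if best is None or cand < best:
            best = cand
    if best is None or best[0] > params.max_mismatch_fraction:
        return None
    frac, _, offset, mismatches = best
    ov = min(len(f) - offset, len(r))

    fo, ro = f[offset : offset + ov], r[:ov]
    fqo, rqo = fq[offset : offset + ov], rq[:ov]
    take_f = fqo >= rqo  # fwd wins quality ties
    consensus = np.where(take_f, fo, ro)
    cons_q = np.maximum(fqo, rqo)
    bases = fwd.bases[:offset] + consensus.tobytes().decode("ascii")
    quals = list(fwd.quals[:offset]) + [int(q) for q in cons_q]
    if ov < len(r):  # reverse read extends past the forward read
        bases += reverse_complement(rev.bases)[ov:]
        quals += [int(q) for q in rq[ov:]]
    return MergedRead(
        id=fwd.id,
        bases=bases,
        quals=tuple(quals),
        overlap_length=ov,
        overlap_mismatches=mismatches,
    )


def filter_merged(
    reads: Sequence[MergedRead], params: ProcessingParams
) -> Tuple[List[MergedRead], List[Tuple[MergedRead, str]]]:
    """Drop merged reads with ambiguous bases or out-of-window lengths.

    Returns (kept, removed) where every removed read carries a reason code
    ("ambiguous" or "length"); kept + removed partition the input.
    """
    if params.length_window is None:
        raise ValueError(
            "length_window must be configured (see ProcessingParams.default_length_window)"
        )
    lo, hi = params.length_window
    kept, removed = [], []
    for read in reads:
        if "N" in read.bases:
            removed.append((read, "ambiguous"))
        elif not lo <= len(read) <= hi:
            removed.append((read, "length"))
        else:
            kept.append(read)
    return kept, removed


@dataclass(frozen=True)
class TrimResult:
    """Outcome of primer removal on one merged read."""

    id: str
    status: str  # "ok" | "rejected"
    insert: Optional[str] = None
    quals: Optional[Tuple[int, ...]] = None
    reason: Optional[str] = None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_primers(
    merged: MergedRead, fwd: Primer, rev: Primer, params: Optional[ProcessingParams] = None
) -> TrimResult:
    """Remove anchored primer sequences from both ends of a merged read.

    The forward core must match (substitutions only) at the 5' end within
    ``max_primer_mismatch``, optionally after up to ``leading_bases`` spacer
    bases (the random-base spacer of tailed library constructs); the
    reverse-complemented reverse core must match symmetrically at the 3'
    end.  Both primer regions and any spacer are removed; failure on either
    end rejects the read with a reason.
    """
    params = params or ProcessingParams()
    k_f, k_r = len(fwd.core), len(rev.core)
    rc_rev = reverse_complement(rev.core)

    def best_anchor(offsets, target, seq_at):
        best = None
        for off in offsets:
            mm = _hamming(seq_at(off), target)
            if mm <= params.max_primer_mismatch and (best is None or mm < best[1]):
                best = (off, mm)
        return best

    max_shift = params.leading_bases
    if len(merged) < k_f + k_r:
        return TrimResult(merged.id, "rejected", reason="too_short")
    f_hit = best_anchor(
        range(0, max_shift + 1),
        fwd.core,
        lambda off: merged.bases[off : off + k_f],
    )
    if f_hit is None or f_hit[0] + k_f + k_r > len(merged):
        return TrimResult(merged.id, "rejected", reason="fwd_primer")
    r_hit = best_anchor(
        range(0, max_shift + 1),
        rc_rev,
        lambda off: merged.bases[len(merged) - off - k_r : len(merged) - off],
    )
    if r_hit is None:
        return TrimResult(merged.id, "rejected", reason="rev_primer")
    start = f_hit[0] + k_f
    end = len(merged) - r_hit[0] - k_r
    if end < start:
        return TrimResult(merged.id, "rejected", reason="too_short")
    return TrimResult(
        merged.id, "ok", insert=merged.bases[start:end], quals=merged.quals[start:end]
    )


def _identity(a: str, b: str, hamming: bool) -> float:
    if hamming and len(a) == len(b):
        d = _hamming(a, b)
    else:
        d = edit_distance(a, b)
    return 1.0 - d / max(len(a), len(b))


def dereplicate(
    reads: Iterable[str], params: Optional[ProcessingParams] = None
) -> Tuple[List[DereplicatedUnit], List[Tuple[str, int]]]:
    """Two-tier dereplication of insert sequences.

    Exact duplicates are collapsed first.  Sequences whose exact count
    reaches ``min_reads_representative`` become representatives; every
    under-represented sequence is compared to all representatives and
    absorbed into the best one (highest identity, ties -> highest
    representative count, then lexicographically smallest representative)
    when its identity reaches ``rescue_identity``.  Unabsorbed rare
    sequences are discarded but returned with their counts, so
    sum(unit read_counts) + sum(discarded counts) == number of input reads.
    The result is independent of input order.
    """
    params = params or ProcessingParams()
    counts = Counter(reads)
    for seq in counts:
        if not seq:
            raise ValueError("empty sequence cannot be dereplicated")
    reps = sorted(
        (s for s, c in counts.items() if c >= params.min_reads_representative),
        key=lambda s: (-counts[s], s),
    )
    members: Dict[str, List[Tuple[str, int, float]]] = {
        s: [(s, counts[s], 1.0)] for s in reps
    }
    discarded: List[Tuple[str, int]] = []
    for seq in sorted(s for s, c in counts.items() if c < params.min_reads_representative):
        best = None  # (-identity, -rep_count, rep)
        for rep in reps:
            ident = _identity(seq, rep, params.hamming_rescue)
            cand = (-ident, -counts[rep], rep)
            if best is None or cand < best:
                best = cand
        if best is not None and -best[0] >= params.rescue_identity:
            members[best[2]].append((seq, counts[seq], -best[0]))
        else:
            discarded.append((seq, counts[seq]))
    units = [
        DereplicatedUnit(
            representative=rep,
            read_count=sum(c for _, c, _ in members[rep]),
            members=tuple(members[rep]),
        )
        for rep in reps
    ]
    units.sort(key=lambda u: (-u.read_count, u.representative))
    return units, discarded


# --- end-to-end convenience ----------------------------------------------

def process_pairs(
    pairs: Iterable[Tuple[ReadRecord, ReadRecord]],
    fwd: Primer,
    rev: Primer,
    params: Optional[ProcessingParams] = None,
) -> Tuple[List[DereplicatedUnit], Dict[str, int]]:
    """Run the whole pipeline on read pairs; returns units and stage accounting.

    Accounting keys: input_pairs, merged, unmerged, filter_removed_ambiguous,
    filter_removed_length, primer_rejected, trimmed, units, reads_in_units,
    discarded_rare_reads.
    """
    params = params or ProcessingParams()
    if params.length_window is None:
        params = replace(
            params, length_window=ProcessingParams.default_length_window(fwd, rev)
        )
    acct = Counter()
    merged_reads: List[MergedRead] = []
    for f, r in pairs:
        acct["input_pairs"] += 1
        m = merge_pair(quality_trim(f, params.phred_cutoff),
                       quality_trim(r, params.phred_cutoff), params)
        if m is None:
            acct["unmerged"] += 1
        else:
            merged_reads.append(m)
    acct["merged"] = len(merged_reads)
    kept, removed = filter_merged(merged_reads, params)
    for _, reason in removed:
        acct[f"filter_removed_{reason}"] += 1
    inserts = []
    for m in kept:
        t = trim_primers(m, fwd, rev, params)
        if t.status == "ok":
            inserts.append(t.insert)
        else:
            acct["primer_rejected"] += 1
    acct["trimmed"] = len(inserts)
    units, discarded = dereplicate(inserts, params)
    acct["units"] = len(units)
    acct["reads_in_units"] = sum(u.read_count for u in units)
    acct["discarded_rare_reads"] = sum(c for _, c in discarded)
    return units, dict(acct)


# --- I/O ------------------------------------------------------------------

def read_fastq(path) -> List[ReadRecord]:
    """Read a FASTQ file (Phred+33) into ReadRecords."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            ReadRecord(
                id=rec.id,
                bases=str(rec.seq).upper(),
                quals=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def read_fastq_pairs(fwd_path, rev_path) -> List[Tuple[ReadRecord, ReadRecord]]:
    """Read two parallel FASTQ files into (forward, reverse) pairs."""
    fwd, rev = read_fastq(fwd_path), read_fastq(rev_path)
    if len(fwd) != len(rev):
        raise ValueError(
            f"paired FASTQ length mismatch: {len(fwd)} forward vs {len(rev)} reverse"
        )
    return list(zip(fwd, rev))


def write_units_fasta(units: Sequence[DereplicatedUnit], path) -> None:
    """Write representatives as FASTA with ``>unitN;size=COUNT`` headers."""
    with open(path, "w") as fh:
        for i, u in enumerate(units, start=1):
            fh.write(f">unit{i};size={u.read_count}\n{u.representative}\n")


def parse_units_fasta(path) -> List[Tuple[str, int, str]]:
    """Read a ``;size=`` dereplicated FASTA back into (id, count, sequence)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, size = rec.id.partition(";size=")
        if not size:
            raise ValueError(f"header {rec.id!r} lacks ';size=' annotation")
        out.append((name, int(size), str(rec.seq).upper()))
    return out


def accounting_tsv(acct: Dict[str, int]) -> str:
    """Stage-accounting log as TSV (stage, count)."""
    lines = ["stage\tcount"]
    lines += [f"{k}\t{v}" for k, v in acct.items()]
    return "\n".join(lines) + "\n"
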