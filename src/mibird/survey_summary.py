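"""Per-sample detection matrices, %-target computation and control screening.

Aggregates assignments (weighted by dereplicated-unit read counts) into a
sample x species read-count matrix, computes the percentage of each
sample's reads assigned to the species expected there (the "% target"
column of a survey detection table), and screens negative-control samples
for contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .tax_assign import Assignment

__all__ = [
    "SampleManifest",
    "DetectionTable",
    "detection_table",
    "target_percentages",
    "control_check",
    "load_manifest",
    "manifest_tsv",
    "summary_tsv",
]

NON_TARGET = "non_target"  # column holding unassigned/ambiguous reads


@dataclass(frozen=True)
class SampleManifest:
    """One sample's expectations: which species live there, control status."""

    sample_id: str
    expected_species: Tuple[str, ...] = ()
    is_control: bool = False


@dataclass
class DetectionTable:
    """Read counts per (sample, species) plus an unassigned bucket.

    ``counts`` is a samples x species DataFrame of assigned reads;
    ``unassigned`` holds per-sample reads whose units were unassigned or
    ambiguous.  Every assigned-but-unexpected species keeps its own column
    and additionally counts toward the non-target fraction when percentages
    are computed.
    """

    counts: pd.DataFrame
    unassigned: pd.Series

    def total(self) -> pd.Series:
        """Per-sample total reads (assigned + unassigned)."""
        return self.counts.sum(axis=1) + self.unassigned

    def to_tsv(self) -> str:
        wide = self.counts.copy()
        wide[NON_TARGET] = self.unassigned
        wide["total"] = self.total()
        return wide.to_csv(sep="\t", index_label="sample_id")


def detection_table(
    assignments_by_sample: Mapping[str, Sequence[Tuple[Assignment, int]]],
    manifest: Optional[Sequence[SampleManifest]] = None,
) -> DetectionTable:
    """Accumulate (assignment, read_count) pairs into a detection matrix.

    Assigned reads go to their species cell; unassigned and ambiguous reads
    go to the per-sample unassigned bucket.  When a manifest is given,
    samples not listed in it are an error and manifest samples with no
    assignments appear as all-zero rows.
    """
    known = None
    if manifest is not None:
        ids = [m.sample_id for m in manifest]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in manifest")
        known = set(ids)
        for sid in assignments_by_sample:
            if sid not in known:
                raise KeyError(f"unknown sample_id {sid!r} not in manifest")
    samples = list(assignments_by_sample)
    if manifest is not None:
        samples = [m.sample_id for m in manifest]

    cells: Dict[str, Dict[str, int]] = {s: {} for s in samples}
    unassigned = {s: 0 for s in samples}
    for sid, pairs in assignments_by_sample.items():
        for a, n in pairs:
            if n < 0:
                raise ValueError("read counts must be non-negative")
            if a.status == "assigned":
                cells[sid][a.species] = cells[sid].get(a.species, 0) + n
            else:
                unassigned[sid] += n
    species = sorted({sp for row in cells.values() for sp in row})
    counts = pd.DataFrame(0, index=samples, columns=species, dtype=int)
    for sid, row in cells.items():
        for sp, n in row.items():
            counts.loc[sid, sp] = n
    return DetectionTable(counts=counts, unassigned=pd.Series(unassigned, dtype=int))


def target_percentages(
    table: DetectionTable, manifest: Sequence[SampleManifest]
) -> pd.Series:
    """Percent of each non-control sample's reads assigned to expected species.

    percent_target = 100 * (reads of expected species) / (total reads); the
    raw (unrounded) value is returned — reports round to one decimal.
    Samples with zero total reads yield NaN (percentage undefined).
    """
    totals = table.total()
    out = {}
    for m in manifest:
        if m.is_control:
            continue
        if m.sample_id not in table.counts.index:
            raise KeyError(f"sample {m.sample_id!r} not in detection table")
        expected = [sp for sp in m.expected_species if sp in table.counts.columns]
        target_reads = int(table.counts.loc[m.sample_id, expected].sum()) if expected else 0
        total = int(totals.loc[m.sample_id])
        out[m.sample_id] = 100.0 * target_reads / total if total > 0 else float("nan")
    return pd.Series(out, dtype=float)


def control_check(
    table: DetectionTable, manifest: Sequence[SampleManifest]
) -> Dict[str, List[Tuple[str, int]]]:
    """List species detected (nonzero reads) in each negative control.

    Returns {control sample_id: [(species, count), ...]}; an empty list
    means the control is clean.  Non-control samples never appear.
    """
    controls = [m for m in manifest if m.is_control]
    if not controls:
        raise ValueError("manifest contains no control samples")
    report = {}
    for m in controls:
        if m.sample_id not in table.counts.index:
            raise KeyError(f"control {m.sample_id!r} not in detection table")
        row = table.counts.loc[m.sample_id]
        report[m.sample_id] = [(sp, int(n)) for sp, n in row.items() if n > 0]
    return report


# --- I/O ------------------------------------------------------------------

def load_manifest(path) -> List[SampleManifest]:
    """Read a sample manifest TSV (sample_id, expected_species ;-list, is_control)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"sample_id", "expected_species", "is_control"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        expected = tuple(s.strip() for s in row["expected_species"].split(";") if s.strip())
        out.append(
            SampleManifest(
                sample_id=row["sample_id"],
                expected_species=expected,
                is_control=str(row["is_control"]).strip().lower() in ("1", "true", "yes"),
            )
        )
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in manifest")
    return out


def manifest_tsv(manifest: Sequence[SampleManifest]) -> str:
    lines = ["sample_id\texpected_species\tis_control"]
    for m in manifest:
        lines.append(
            f"{m.sample_id}\t{';'.join(m.expected_species)}\t{'true' if m.is_control else 'false'}"
        )
    return "\n".join(lines) + "\n"


def summary_tsv(table: DetectionTable, manifest: Sequence[SampleManifest]) -> str:
    """Per-sample summary TSV: total, target, non_target, percent_target.

    Percentages are rounded to one decimal in this report; control samples
    show an empty percentage.
    """
    by_id = {m.sample_id: m for m in manifest}
    totals = table.total()
    pct = target_percentages(table, manifest)
    lines = ["sample_id\ttotal\ttarget\tnon_target\tpercent_target"]
    for sid in table.counts.index:
        m = by_id.get(sid)
        expected = [
            sp for sp in (m.expected_species if m else ()) if sp in table.counts.columns
        ]
        target = int(table.counts.loc[sid, expected].sum()) if expected else 0
        total = int(totals.loc[sid])
        if m is not None and not m.is_control and sid in pct.index and pct.loc[sid] == pct.loc[sid]:
            p = f"{pct.loc[sid]:.1f}"
        else:
            p = ""
        lines.append(f"{sid}\t{total}\t{target}\t{total - target}\t{p}")
    return "\n".join(lines) + "\n"
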