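"""In-silico PCR and amplicon taxonomic resolution.

Locates primer binding sites in reference sequences by exhaustive window
scan, extracts the amplified insert (the region strictly between the two
primer sites), and quantifies taxonomic resolution of the insert via
pairwise Levenshtein edit-distance distributions at species and genus level.

References carrying a deletion of either primer region yield no qualifying
window and are excluded from the insert panel with an explicit reason,
mirroring how reference species lacking intact primer sites are dropped
from barcode-gap analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .primer_eval import (
    HISTOGRAM_BINS,
    IUPAC,
    Primer,
    _WOBBLE_SENSE,
    reverse_complement,
)

__all__ = [
    "ReferenceRecord",
    "PrimerSite",
    "AmpliconExtract",
    "ExtractionResult",
    "DistanceTable",
    "locate_primer_site",
    "extract_insert",
    "extract_panel",
    "edit_distance",
    "distance_distributions",
    "load_panel",
    "write_panel",
    "extraction_report_tsv",
    "distance_tables_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence with its taxonomy (the unit of a panel)."""

    accession: str
    species: str
    genus: str
    family: str
    order: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.accession}: empty sequence")


@dataclass(frozen=True)
class PrimerSite:
    """A located binding site: 0-based half-open interval on the sense strand."""

    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class AmpliconExtract:
    """The insert amplified from one reference (primer regions excluded)."""

    accession: str
    insert: str
    fwd_site: Tuple[int, int]
    rev_site: Tuple[int, int]
    fwd_mismatches: int
    rev_mismatches: int


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of in-silico PCR on one reference: an extract or an exclusion."""

    accession: str
    status: str  # "ok" | "excluded"
    extract: Optional[AmpliconExtract] = None
    reason: Optional[str] = None


# --- window scan ----------------------------------------------------------

# 256-entry boolean lookup tables: _MATCH_LUT[base][byte] is True when the
# observed site byte (possibly an IUPAC code) is compatible with the
# expected base; _WOBBLE_LUT adds the sense-frame G/T wobble tolerance.
def _build_luts():
    match_lut = {}
    wobble_lut = {}
    for base in "ACGT":
        m = np.zeros(256, dtype=bool)
        w = np.zeros(256, dtype=bool)
        for code, expansion in IUPAC.items():
            if base in expansion:
                m[ord(code)] = True
            partner = _WOBBLE_SENSE.get(base)
            if partner is not None and partner in expansion:
                w[ord(code)] = True
        match_lut[base] = m
        wobble_lut[base] = w
    return match_lut, wobble_lut


_MATCH_LUT, _WOBBLE_LUT = _build_luts()


def _window_mismatch_counts(seq: str, core: str, wobble: bool) -> np.ndarray:
    """Mismatch count of ``core`` against every window of ``seq`` (sense frame)."""
    obs = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    k = len(core)
    windows = sliding_window_view(obs, k)
    mm = np.zeros(windows.shape[0], dtype=np.int32)
    for i, base in enumerate(core):
        ok = _MATCH_LUT[base][windows[:, i]]
        if wobble:
            ok = ok | _WOBBLE_LUT[base][windows[:, i]]
        mm += ~ok
    return mm


def locate_primer_site(
    reference: ReferenceRecord,
    primer: Primer,
    max_mismatch: int = 5,
    wobble: bool = True,
) -> Optional[PrimerSite]:
    """Find the best substitution-only binding window for a primer.

    Scans every window of primer-core length on the strand appropriate to
    the primer's orientation (sense for a forward primer; the reverse
    complement for a reverse primer), scores mismatches with the G/T wobble
    rule when enabled, and returns the window with the fewest mismatches
    (ties broken by the leftmost window on the scanned strand) provided it
    is within ``max_mismatch``.  Returns ``None`` when no window qualifies
    or the primer is longer than the reference.  Indels within the site are
    not modelled: a site disrupted by indels simply fails to qualify.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = reference.sequence.upper()
    k = len(primer.core)
    if k > len(seq):
        return None
    scanned = seq if primer.orientation == "forward" else reverse_complement(seq)
    mm = _window_mismatch_counts(scanned, primer.core, wobble)
    best = int(np.argmin(mm))  # argmin returns the leftmost minimum
    n_mm = int(mm[best])
    if n_mm > max_mismatch:
        return None
    if primer.orientation == "forward":
        return PrimerSite(start=best, end=best + k, mismatches=n_mm)
    L = len(seq)
    return PrimerSite(start=L - best - k, end=L - best, mismatches=n_mm)


def extract_insert(
    reference: ReferenceRecord,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 5,
    wobble: bool = True,
) -> ExtractionResult:
    """In-silico PCR on one reference: locate both sites, take the insert.

    The insert is the sense-strand subsequence strictly between the forward
    and reverse primer sites (primers excluded).  References missing either
    site, or with the reverse site upstream of the forward site, are marked
    ``excluded`` with a reason.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("extract_insert needs a forward and a reverse primer")
    fsite = locate_primer_site(reference, fwd, max_mismatch, wobble)
    if fsite is None:
        return ExtractionResult(reference.accession, "excluded", reason="fwd_site_absent")
    rsite = locate_primer_site(reference, rev, max_mismatch, wobble)
    if rsite is None:
        return ExtractionResult(reference.accession, "excluded", reason="rev_site_absent")
    if rsite.start < fsite.end:
        return ExtractionResult(reference.accession, "excluded", reason="inverted_sites")
    insert = reference.sequence[fsite.end : rsite.start]
    extract = AmpliconExtract(
        accession=reference.accession,
        insert=insert,
        fwd_site=(fsite.start, fsite.end),
        rev_site=(rsite.start, rsite.end),
        fwd_mismatches=fsite.mismatches,
        rev_mismatches=rsite.mismatches,
    )
    return ExtractionResult(reference.accession, "ok", extract=extract)


def extract_panel(
    panel: Sequence[ReferenceRecord],
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 5,
    wobble: bool = True,
) -> Tuple[List[AmpliconExtract], List[ExtractionResult]]:
    """Run :func:`extract_insert` over a panel; return (extracts, exclusions)."""
    extracts, excluded = [], []
    for rec in panel:
        res = extract_insert(rec, fwd, rev, max_mismatch, wobble)
        if res.status == "ok":
            extracts.append(res.extract)
        else:
            excluded.append(res)
    return extracts, excluded


# --- edit distances -------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance: minimum substitutions+insertions+deletions."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass(frozen=True)
class DistanceTable:
    """Edit-distance frequency distribution binned at 0,1,2,3,4,>=5."""

    category: str
    bins: Mapping[str, int]
    n_pairs: int


def _bin_distances(distances: Iterable[int], category: str) -> DistanceTable:
    bins = {b: 0 for b in HISTOGRAM_BINS}
    n = 0
    for d in distances:
        bins[str(d) if d < 5 else "ge5"] += 1
        n += 1
    return DistanceTable(category=category, bins=bins, n_pairs=n)


def distance_distributions(
    extracts: Sequence[AmpliconExtract],
    taxonomy: Mapping[str, Tuple[str, str]],
    genus_mode: str = "different_genus",
) -> Tuple[DistanceTable, DistanceTable]:
    """Pairwise insert edit-distance distributions at species and genus level.

    ``taxonomy`` maps accession to ``(species, genus)``.  Duplicate species
    are collapsed to their first occurrence (with a warning) so that every
    pair compares two distinct species.  The inter-species table covers all
    C(n,2) unordered pairs of the n species.  The genus-level table depends
    on ``genus_mode``:

    * ``"different_genus"`` (default): pairs of species belonging to
      different genera, binned directly;
    * ``"within_genus"``: congeneric species pairs;
    * ``"genus_pair_min"``: the minimum inter-species distance for each
      unordered pair of distinct genera (one entry per genus pair).
    """
    if genus_mode not in ("different_genus", "within_genus", "genus_pair_min"):
        raise ValueError(f"unknown genus_mode {genus_mode!r}")
    seen_species = set()
    kept = []
    for ex in extracts:
        if ex.accession not in taxonomy:
            raise KeyError(f"no taxonomy for accession {ex.accession!r}")
        species, genus = taxonomy[ex.accession]
        if species in seen_species:
            logger.warning("duplicate species %r collapsed to first occurrence", species)
            continue
        seen_species.add(species)
        kept.append((ex, species, genus))

    species_dists: List[int] = []
    genus_dists: List[int] = []
    genus_pair_min: dict = {}
    for (ea, _, ga), (eb, _, gb) in combinations(kept, 2):
        d = edit_distance(ea.insert, eb.insert)
        species_dists.append(d)
        if ga != gb:
            if genus_mode == "different_genus":
                genus_dists.append(d)
            elif genus_mode == "genus_pair_min":
                key = (ga, gb) if ga < gb else (gb, ga)
                prev = genus_pair_min.get(key)
                if prev is None or d < prev:
                    genus_pair_min[key] = d
        elif genus_mode == "within_genus":
            genus_dists.append(d)
    if genus_mode == "genus_pair_min":
        genus_dists = list(genus_pair_min.values())
    return (
        _bin_distances(species_dists, "inter-species"),
        _bin_distances(genus_dists, "inter-genus"),
    )


# --- I/O ------------------------------------------------------------------

_TAX_FIELDS = ("accession", "species", "genus", "family", "order")


def load_panel(fasta_path, taxonomy_tsv=None) -> List[ReferenceRecord]:
    """Read a reference panel from FASTA.

    Taxonomy is taken from pipe-delimited headers
    (``accession|species|genus|family|order``) or, when ``taxonomy_tsv`` is
    given, from a sidecar TSV with those columns keyed by accession (FASTA
    headers then need only the accession).
    """
    from Bio import SeqIO

    sidecar = None
    if taxonomy_tsv is not None:
        import pandas as pd

        df = pd.read_csv(taxonomy_tsv, sep="\t", dtype=str)
        missing = set(_TAX_FIELDS) - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy TSV missing column(s) {sorted(missing)}")
        sidecar = df.set_index("accession")

    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = rec.description
        if sidecar is not None:
            acc = header.split()[0].split("|")[0]
            if acc not in sidecar.index:
                raise KeyError(f"accession {acc!r} not in taxonomy TSV")
            row = sidecar.loc[acc]
            fields = (acc, row["species"], row["genus"], row["family"], row["order"])
        else:
            parts = header.split("|")
            if len(parts) != 5:
                raise ValueError(
                    f"header {header!r}: expected accession|species|genus|family|order"
                )
            fields = tuple(p.strip() for p in parts)
        records.append(ReferenceRecord(*fields, sequence=str(rec.seq).upper()))
    accs = [r.accession for r in records]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accessions in panel")
    return records


def write_panel(records: Sequence[ReferenceRecord], fasta_path) -> None:
    """Write a panel as FASTA with pipe-delimited taxonomy headers."""
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.accession}|{r.species}|{r.genus}|{r.family}|{r.order}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def extraction_report_tsv(
    extracts: Sequence[AmpliconExtract], excluded: Sequence[ExtractionResult]
) -> str:
    """Per-reference extraction report (accession, status, lengths, mismatches)."""
    lines = ["accession\tstatus\tinsert_length\tfwd_mismatches\trev_mismatches\treason"]
    for ex in extracts:
        lines.append(
            f"{ex.accession}\tok\t{len(ex.insert)}\t{ex.fwd_mismatches}\t{ex.rev_mismatches}\t"
        )
    for res in excluded:
        lines.append(f"{res.accession}\texcluded\t\t\t\t{res.reason}")
    return "\n".join(lines) + "\n"


def distance_tables_tsv(tables: Iterable[DistanceTable]) -> str:
    """Render distance tables as TSV (category, d0..d4, dge5, total)."""
    lines = ["category\td0\td1\td2\td3\td4\tdge5\ttotal"]
    for t in tables:
        vals = "\t".join(str(t.bins[b]) for b in HISTOGRAM_BINS)
        lines.append(f"{t.category}\t{vals}\t{t.n_pairs}")
    return "\n".join(lines) + "\n"
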