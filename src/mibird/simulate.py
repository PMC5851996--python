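"""Deterministic synthetic fixtures: reference panels and amplicon surveys.

Generates mitogenome-like reference records — random padding, a conserved
forward primer site, a ~171 bp variable insert, the reverse primer site and
more padding — with *planted* primer-site mismatches (wobble-compatible or
not) and optional primer-region deletions, plus multi-sample paired-end
read surveys (2 x 150 bp) with known species composition, substitution
errors, a quality profile with low-quality tails, and empty negative
controls.  Every generated panel ships with a truth sidecar (planted
mismatch counts, deletions, verified pairwise insert distances) and every
survey with a truth manifest of per-sample species read counts, so each
pipeline stage can be tested against known ground truth.

All randomness flows through ``numpy.random.default_rng`` seeded from the
config (integer seeds only), so identical configs give byte-identical
output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .insert_resolution import (
    ReferenceRecord,
    edit_distance,
    locate_primer_site,
)
from .primer_eval import MIBIRD_U_F, MIBIRD_U_R, Primer, reverse_complement
from .read_processing import ReadRecord
from .survey_summary import SampleManifest

__all__ = [
    "SitePlan",
    "SampleSpec",
    "SimulationConfig",
    "PanelTruth",
    "simulate_panel",
    "simulate_survey",
    "mismatch_plan_from_distribution",
    "load_config",
    "write_survey_fastq",
    "truth_sidecar_tsv",
    "truth_manifest_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Sense-frame wobble tolerance maps used when planting site variants:
# expected sense base -> observed base that the primer still accepts via a
# G/T pair.  Forward primers anneal to the antisense strand (primer base ==
# expected sense base); reverse primers anneal to the sense strand itself
# (primer base == complement of the expected sense base), which flips the map.
_WOBBLE_FWD = {"G": "A", "T": "C"}
_WOBBLE_REV = {"C": "T", "A": "G"}


@dataclass(frozen=True)
class SitePlan:
    """Planted primer-site variation for one reference record."""

    fwd_mismatches: int = 0
    rev_mismatches: int = 0
    wobble_compatible: bool = False
    delete_fwd: bool = False
    delete_rev: bool = False


@dataclass(frozen=True)
class SampleSpec:
    """One survey sample: read-pair abundance per species (name), control flag."""

    sample_id: str
    abundance: Mapping[str, int] = field(default_factory=dict)
    is_control: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for panel and survey generation.

    Defaults emulate the survey design this toolkit targets: a 410-record
    reference panel, ~171 bp inserts at least 6 edits apart between
    species, 2 x 150 bp paired-end reads, a low per-base substitution
    error rate, and a quality profile whose last few bases dip below the
    Q10 trimming cutoff.
    """

    seed: int = 0
    n_species: int = 410
    species_per_genus: int = 2
    insert_length: int = 171
    min_insert_distance: int = 6
    pad_length: int = 120
    site_plans: Mapping[int, SitePlan] = field(default_factory=dict)
    samples: Tuple[SampleSpec, ...] = ()
    read_length: int = 150
    error_rate: float = 0.001
    mean_quality: int = 35
    tail_length: int = 5
    tail_quality: int = 6
    multinomial: bool = False

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        for spec in self.samples:
            if any(n < 0 for n in spec.abundance.values()):
                raise ValueError(f"sample {spec.sample_id}: negative abundance")


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth for a simulated panel."""

    plans: Mapping[str, SitePlan]  # accession -> planted plan
    inserts: Mapping[str, str]  # accession -> planted insert
    species: Mapping[str, str]  # accession -> species name
    genus: Mapping[str, str]  # accession -> genus name
    pairwise_distances: Mapping[Tuple[str, str], int]  # verified insert distances

    def effective_mismatches(self, accession: str, wobble: bool) -> Tuple[int, int]:
        """Expected located-site mismatch counts (fwd, rev) for one record."""
        plan = self.plans[accession]
        if wobble and plan.wobble_compatible:
            return (0, 0)
        return (plan.fwd_mismatches, plan.rev_mismatches)


def mismatch_plan_from_distribution(
    distribution: Mapping[int, float],
    n_species: int,
    wobble_compatible: bool = False,
    which: str = "fwd",
) -> Dict[int, SitePlan]:
    """Turn a mismatch-count distribution into exact per-species plans.

    ``distribution`` maps mismatch count to a proportion (summing to ~1);
    counts are realised exactly by largest remainder and assigned to
    species indices in order, so the planted histogram is deterministic.
    """
    if which not in ("fwd", "rev"):
        raise ValueError("which must be 'fwd' or 'rev'")
    fracs = sorted(distribution.items())
    floors = {m: int(np.floor(f * n_species)) for m, f in fracs}
    remainder = n_species - sum(floors.values())
    by_frac = sorted(fracs, key=lambda kv: -(kv[1] * n_species - floors[kv[0]]))
    for m, _ in by_frac[:remainder]:
        floors[m] += 1
    plans: Dict[int, SitePlan] = {}
    idx = 0
    for m, _ in fracs:
        for _ in range(floors[m]):
            if which == "fwd":
                plans[idx] = SitePlan(fwd_mismatches=m, wobble_compatible=wobble_compatible)
            else:
                plans[idx] = SitePlan(rev_mismatches=m, wobble_compatible=wobble_compatible)
            idx += 1
    return plans


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _plant_site(
    expected: str,
    n_mismatches: int,
    wobble_compatible: bool,
    wobble_map: Mapping[str, str],
    rng: np.random.Generator,
) -> str:
    """Plant ``n_mismatches`` substitutions into an expected sense-frame site."""
    if n_mismatches == 0:
        return expected
    if wobble_compatible:
        eligible = [i for i, b in enumerate(expected) if b in wobble_map]
        if len(eligible) < n_mismatches:
            raise ValueError(
                f"cannot plant {n_mismatches} wobble-compatible variants: "
                f"only {len(eligible)} eligible positions"
            )
        positions = rng.choice(eligible, size=n_mismatches, replace=False)
        site = list(expected)
        for i in positions:
            site[i] = wobble_map[expected[i]]
        return "".join(site)
    if n_mismatches > len(expected):
        raise ValueError("more mismatches than site positions")
    positions = rng.choice(len(expected), size=n_mismatches, replace=False)
    site = list(expected)
    for i in positions:
        forbidden = {expected[i], wobble_map.get(expected[i])}
        choices = [b for b in "ACGT" if b not in forbidden]
        site[i] = choices[rng.integers(len(choices))]
    return "".join(site)


def _generate_inserts(
    rng: np.random.Generator, n: int, length: int, min_distance: int
) -> List[str]:
    """Random inserts whose pairwise edit distances all reach ``min_distance``.

    Each candidate is verified against every accepted insert with the same
    edit-distance routine the analysis uses; offenders are redrawn.
    """
    if min_distance > length:
        raise ValueError(
            f"min_insert_distance {min_distance} infeasible for insert length {length}"
        )
    inserts: List[str] = []
    for _ in range(n):
        for attempt in range(200):
            cand = _random_seq(rng, length)
            if all(edit_distance(cand, prev) >= min_distance for prev in inserts):
                inserts.append(cand)
                break
        else:
            raise RuntimeError("could not satisfy the pairwise-distance plan")
    return inserts


def _taxonomy(i: int, species_per_genus: int) -> Tuple[str, str, str, str]:
    g = i // species_per_genus
    genus = f"Genus{g:03d}"
    species = f"{genus} sp{i:04d}"
    family = f"Family{g // 5:03d}"
    order = f"Order{g // 20:03d}"
    return species, genus, family, order


def simulate_panel(
    config: SimulationConfig,
    fwd: Primer = MIBIRD_U_F,
    rev: Primer = MIBIRD_U_R,
    max_mismatch: int = 5,
) -> Tuple[List[ReferenceRecord], PanelTruth]:
    """Generate a reference panel with planted primer-site variation.

    Each record is ``pad + fwd site + insert + rev site + pad`` on the
    sense strand, with per-record site plans applied (mismatches, wobble
    variants, deletions).  Before emission every record is checked against
    the locator: planted sites must be found at the planted interval with
    the planted mismatch count (under ``max_mismatch``), and deleted sites
    must come back absent; offending random padding or inserts are redrawn.
    Identical configs yield identical panels.
    """
    rng = np.random.default_rng(config.seed)
    inserts = _generate_inserts(
        rng, config.n_species, config.insert_length, config.min_insert_distance
    )
    fwd_expected = fwd.core
    rev_expected = reverse_complement(rev.core)

    records: List[ReferenceRecord] = []
    plans: Dict[str, SitePlan] = {}
    truth_inserts: Dict[str, str] = {}
    species_map: Dict[str, str] = {}
    genus_map: Dict[str, str] = {}
    for i in range(config.n_species):
        plan = config.site_plans.get(i, SitePlan())
        acc = f"SYN{i:04d}"
        species, genus, family, order = _taxonomy(i, config.species_per_genus)
        insert = inserts[i]
        for attempt in range(60):
            if attempt > 0 and attempt % 10 == 0:
                # persistent spurious sites: redraw the insert itself
                for _ in range(200):
                    cand = _random_seq(rng, config.insert_length)
                    others = inserts[:i] + inserts[i + 1 :]
                    if all(
                        edit_distance(cand, o) >= config.min_insert_distance
                        for o in others
                    ):
                        insert = cand
                        inserts[i] = cand
                        break
            fsite = (
                ""
                if plan.delete_fwd
                else _plant_site(
                    fwd_expected, plan.fwd_mismatches, plan.wobble_compatible,
                    _WOBBLE_FWD, rng,
                )
            )
            rsite = (
                ""
                if plan.delete_rev
                else _plant_site(
                    rev_expected, plan.rev_mismatches, plan.wobble_compatible,
                    _WOBBLE_REV, rng,
                )
            )
            pad5 = _random_seq(rng, config.pad_length)
            pad3 = _random_seq(rng, config.pad_length)
            seq = pad5 + fsite + insert + rsite + pad3
            rec = ReferenceRecord(acc, species, genus, family, order, seq)
            if _validate_record(rec, plan, fwd, rev, config, max_mismatch):
                break
        else:
            raise RuntimeError(f"could not realise site plan for record {acc}")
        records.append(rec)
        plans[acc] = plan
        truth_inserts[acc] = insert
        species_map[acc] = species
        genus_map[acc] = genus

    distances = {}
    accs = [r.accession for r in records]
    for a_idx in range(len(accs)):
        for b_idx in range(a_idx + 1, len(accs)):
            a, b = accs[a_idx], accs[b_idx]
            distances[(a, b)] = edit_distance(truth_inserts[a], truth_inserts[b])
    truth = PanelTruth(
        plans=plans, inserts=truth_inserts, species=species_map,
        genus=genus_map, pairwise_distances=distances,
    )
    return records, truth


def _validate_record(
    rec: ReferenceRecord,
    plan: SitePlan,
    fwd: Primer,
    rev: Primer,
    config: SimulationConfig,
    max_mismatch: int,
) -> bool:
    """Check that the locator sees exactly what was planted."""
    pad, k_f, k_r = config.pad_length, len(fwd.core), len(rev.core)
    fsite = locate_primer_site(rec, fwd, max_mismatch=max_mismatch, wobble=True)
    if plan.delete_fwd:
        if fsite is not None:
            return False
    else:
        want_mm = 0 if plan.wobble_compatible else plan.fwd_mismatches
        if want_mm > max_mismatch:
            pass  # site intentionally beyond the locator's reach
        elif fsite is None or (fsite.start, fsite.end) != (pad, pad + k_f):
            return False
        elif fsite.mismatches != want_mm:
            return False
    rstart = pad + (0 if plan.delete_fwd else k_f) + config.insert_length
    rsite = locate_primer_site(rec, rev, max_mismatch=max_mismatch, wobble=True)
    if plan.delete_rev:
        if rsite is not None:
            return False
    else:
        want_mm = 0 if plan.wobble_compatible else plan.rev_mismatches
        if want_mm > max_mismatch:
            pass
        elif rsite is None or (rsite.start, rsite.end) != (rstart, rstart + k_r):
            return False
        elif rsite.mismatches != want_mm:
            return False
    return True


# --- surveys --------------------------------------------------------------

def simulate_survey(
    config: SimulationConfig,
    panel: Sequence[ReferenceRecord],
    truth: PanelTruth,
    fwd: Primer = MIBIRD_U_F,
    rev: Primer = MIBIRD_U_R,
) -> Tuple[
    Dict[str, Tuple[List[ReadRecord], List[ReadRecord]]],
    List[SampleManifest],
    Dict[str, Dict[str, int]],
]:
    """Generate paired 150 bp reads per sample from known compositions.

    Reads are the two ends of the full amplicon (primer cores + insert)
    with seeded substitution errors and the configured quality profile;
    negative controls receive no biological reads.  Returns per-sample
    (forward reads, reverse reads), the derived sample manifest, and the
    truth manifest of per-sample species read-pair counts.
    """
    rng = np.random.default_rng([config.seed, 1])
    species_to_acc = {sp: acc for acc, sp in truth.species.items()}
    reads: Dict[str, Tuple[List[ReadRecord], List[ReadRecord]]] = {}
    manifest: List[SampleManifest] = []
    truth_counts: Dict[str, Dict[str, int]] = {}

    for spec in config.samples:
        fwd_reads: List[ReadRecord] = []
        rev_reads: List[ReadRecord] = []
        counts: Dict[str, int] = {}
        if not spec.is_control:
            for species, n_pairs in spec.abundance.items():
                if species not in species_to_acc:
                    raise KeyError(f"species {species!r} absent from panel")
                if n_pairs == 0:
                    continue
                acc = species_to_acc[species]
                amplicon = fwd.core + truth.inserts[acc] + reverse_complement(rev.core)
                n_real = (
                    int(rng.poisson(n_pairs)) if config.multinomial else n_pairs
                )
                for j in range(n_real):
                    rid = f"{spec.sample_id}:{acc}:{j:05d}"
                    fwd_reads.append(
                        _make_read(rid + "/1", amplicon, config, rng, reverse=False)
                    )
                    rev_reads.append(
                        _make_read(rid + "/2", amplicon, config, rng, reverse=True)
                    )
                counts[species] = counts.get(species, 0) + n_real
        reads[spec.sample_id] = (fwd_reads, rev_reads)
        manifest.append(
            SampleManifest(
                sample_id=spec.sample_id,
                expected_species=tuple(sp for sp, n in spec.abundance.items() if n > 0),
                is_control=spec.is_control,
            )
        )
        truth_counts[spec.sample_id] = counts
    return reads, manifest, truth_counts


def _make_read(
    rid: str,
    amplicon: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    reverse: bool,
) -> ReadRecord:
    template = reverse_complement(amplicon) if reverse else amplicon
    bases = np.frombuffer(
        template[: config.read_length].encode("ascii"), dtype=np.uint8
    ).copy()
    if config.error_rate > 0:
        errs = np.flatnonzero(rng.random(bases.shape[0]) < config.error_rate)
        for i in errs:
            alternatives = _BASES[_BASES != bases[i]]
            bases[i] = alternatives[rng.integers(len(alternatives))]
    n = bases.shape[0]
    quals = [config.mean_quality] * n
    tail = min(config.tail_length, n)
    for i in range(n - tail, n):
        quals[i] = config.tail_quality
    return ReadRecord(id=rid, bases=bases.tobytes().decode("ascii"), quals=tuple(quals))


# --- I/O ------------------------------------------------------------------

def load_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file.

    Top-level keys mirror the dataclass fields; ``site_plans`` maps species
    index to SitePlan fields, or the shorthand
    ``mismatch_distribution: {0: 0.9, 1: 0.1}`` plants an exact-count plan;
    ``samples`` is a list of {sample_id, abundance: {species: pairs},
    is_control}.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    plans: Dict[int, SitePlan] = {}
    if "mismatch_distribution" in raw:
        dist = {int(k): float(v) for k, v in raw.pop("mismatch_distribution").items()}
        plans = mismatch_plan_from_distribution(
            dist, int(raw.get("n_species", SimulationConfig.n_species))
        )
    for key, fields in (raw.pop("site_plans", None) or {}).items():
        plans[int(key)] = SitePlan(**fields)
    samples = tuple(
        SampleSpec(
            sample_id=s["sample_id"],
            abundance={k: int(v) for k, v in (s.get("abundance") or {}).items()},
            is_control=bool(s.get("is_control", False)),
        )
        for s in raw.pop("samples", None) or []
    )
    return SimulationConfig(site_plans=plans, samples=samples, **raw)


def write_survey_fastq(
    reads: Mapping[str, Tuple[Sequence[ReadRecord], Sequence[ReadRecord]]], outdir
) -> None:
    """Write per-sample paired FASTQ files (``<sample>_R1.fastq`` / ``_R2.fastq``)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for sid, (fwd_reads, rev_reads) in reads.items():
        for suffix, rr in (("R1", fwd_reads), ("R2", rev_reads)):
            with open(os.path.join(outdir, f"{sid}_{suffix}.fastq"), "w") as fh:
                for r in rr:
                    fh.write(
                        f"@{r.id}\n{r.bases}\n+\n"
                        + "".join(chr(q + 33) for q in r.quals)
                        + "\n"
                    )


def truth_sidecar_tsv(truth: PanelTruth) -> str:
    """Panel truth as TSV: per-record plan plus effective mismatch counts."""
    lines = [
        "accession\tspecies\tgenus\tfwd_mismatches\trev_mismatches"
        "\twobble_compatible\tdelete_fwd\tdelete_rev"
    ]
    for acc, plan in truth.plans.items():
        lines.append(
            f"{acc}\t{truth.species[acc]}\t{truth.genus[acc]}\t{plan.fwd_mismatches}"
            f"\t{plan.rev_mismatches}\t{plan.wobble_compatible}"
            f"\t{plan.delete_fwd}\t{plan.delete_rev}"
        )
    return "\n".join(lines) + "\n"


def truth_manifest_tsv(truth_counts: Mapping[str, Mapping[str, int]]) -> str:
    """Survey truth as TSV: sample, species, read pairs."""
    lines = ["sample_id\tspecies\tread_pairs"]
    for sid, counts in truth_counts.items():
        for sp, n in counts.items():
            lines.append(f"{sid}\t{sp}\t{n}")
    return "\n".join(lines) + "\n"
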