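"""Primer evaluation against binding-site panels.

This module scores how well a PCR primer anneals to candidate binding sites:
per-position match/wobble/mismatch calls (with optional G/T wobble
acceptance), mismatch histograms over a reference panel, positional base
composition profiles, GC content, and nearest-neighbour melting temperature.

Strand conventions
------------------
All comparisons are made in *primer orientation*: the site string is the
reference subsequence read in the same direction as the primer, so a perfect
Watson-Crick duplex corresponds to ``site == primer.core``.  In this "sense"
frame the G/T wobble rule reads:

* primer ``G`` tolerates site ``A`` (the annealing-template base opposite a
  site ``A`` is ``T``, giving a G:T pair);
* primer ``T`` tolerates site ``C`` (template ``G``, giving a T:G pair).

The equivalent "template" frame (site given as the annealing-template strand,
match = Watson-Crick complement, wobble = primer G vs template T / primer T
vs template G) is available via ``frame="template"``; the two are related by
complementation.  :func:`annealing_template_site` converts between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Primer",
    "BindingSiteAlignment",
    "MismatchHistogram",
    "PositionalBaseProfile",
    "ThermoParams",
    "MIBIRD_U_F",
    "MIBIRD_U_R",
    "evaluate_binding",
    "mismatch_histogram",
    "positional_base_profile",
    "gc_content",
    "melting_temperature",
    "reverse_complement",
    "annealing_template_site",
    "load_primers",
    "histogram_to_tsv",
    "profile_to_tsv",
]

HISTOGRAM_BINS = ("0", "1", "2", "3", "4", "ge5")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC nucleotide codes expanded to the set of bases they may represent.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

# Wobble tolerance in sense-frame coordinates: primer base -> tolerated
# site base (primer G pairs with template T, i.e. site A; primer T with
# template G, i.e. site C).
_WOBBLE_SENSE = {"G": "A", "T": "C"}
# Template-frame equivalent: primer base -> tolerated template base.
_WOBBLE_TEMPLATE = {"G": "T", "T": "G"}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def annealing_template_site(sense_site: str) -> str:
    """Convert a sense-frame site to the annealing-template frame.

    The template the primer hybridises to is the complement of the sense
    site, read position-by-position against the primer (i.e. complemented
    but *not* reversed, so ``template[i]`` pairs with ``primer.core[i]``).
    """
    return sense_site.translate(_COMPLEMENT)


@dataclass(frozen=True)
class Primer:
    """A PCR primer: core oligo plus orientation and adapter decoration.

    ``core`` is the annealing portion, 5'->3', uppercase ACGT only (no
    degenerate bases).  ``adapter`` is an optional 5' tail (e.g. sequencing
    adapter) and ``n_random_bases`` the number of random spacer bases placed
    between adapter and core in library constructs.
    """

    name: str
    core: str
    orientation: str
    adapter: Optional[str] = None
    n_random_bases: int = 0

    def __post_init__(self) -> None:
        if not self.core:
            raise ValueError("primer core must be non-empty")
        bad = set(self.core) - set("ACGT")
        if bad:
            raise ValueError(
                f"primer core must be uppercase ACGT only; found {sorted(bad)!r}"
            )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"orientation must be 'forward' or 'reverse', got {self.orientation!r}"
            )
        if self.n_random_bases < 0:
            raise ValueError("n_random_bases must be non-negative")

    def __len__(self) -> int:
        return len(self.core)


#: Universal avian 12S forward primer (MiBird-U-F) with MiSeq tail.
MIBIRD_U_F = Primer(
    name="MiBird-U-F",
    core="GGGTTGGTAAATCTTGTGCCAGC",
    orientation="forward",
    adapter="ACACTCTTTCCCTACACGACGCTCTTCCGATCT",
    n_random_bases=6,
)

#: Universal avian 12S reverse primer (MiBird-U-R) with MiSeq tail.
MIBIRD_U_R = Primer(
    name="MiBird-U-R",
    core="CATAGTGGGGTATCTAATCCCAGTTTG",
    orientation="reverse",
    adapter="GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT",
    n_random_bases=6,
)


@dataclass(frozen=True)
class BindingSiteAlignment:
    """Position-wise comparison of a primer against one binding site."""

    per_position: tuple  # of (primer_base, site_base, status)
    total_mismatches: int
    three_prime_terminal_mismatch: bool
    wobble_enabled: bool

    @property
    def statuses(self) -> tuple:
        return tuple(s for _, _, s in self.per_position)


def evaluate_binding(
    primer: Primer,
    site: str,
    wobble: bool = True,
    *,
    frame: str = "sense",
    strict_iupac: bool = False,
    terminal_window: int = 1,
) -> BindingSiteAlignment:
    """Score a primer against a located binding site, position by position.

    Parameters
    ----------
    primer
        The primer; only its ``core`` is compared.
    site
        Binding site, same length as the core, in primer orientation.
        ``frame="sense"`` (default): the site is the reference subsequence
        read in primer orientation; a match is base equality.
        ``frame="template"``: the site is the annealing-template strand
        aligned against the primer; a match is Watson-Crick complementarity.
    wobble
        Accept G/T wobble pairs (primer G vs template T and primer T vs
        template G) as ``wobble_match`` rather than ``mismatch``.
    strict_iupac
        When False (default), an ambiguity code in the site counts as a
        match if the required base is within its expansion (N matches
        everything); when True only exact base identity matches.
    terminal_window
        Number of 3'-terminal primer positions inspected for the
        ``three_prime_terminal_mismatch`` flag (default: the last base).
    """
    core = primer.core
    if len(site) != len(core):
        raise ValueError(
            f"site length {len(site)} incompatible with primer core length {len(core)}"
        )
    if frame not in ("sense", "template"):
        raise ValueError(f"frame must be 'sense' or 'template', got {frame!r}")
    site = site.upper()
    wob = _WOBBLE_SENSE if frame == "sense" else _WOBBLE_TEMPLATE

    per_position = []
    n_mismatch = 0
    for p, s in zip(core, site):
        if s not in IUPAC:
            raise ValueError(f"non-nucleotide character {s!r} in binding site")
        required = p if frame == "sense" else annealing_template_site(p)
        if s == required or (not strict_iupac and required in IUPAC[s]):
            status = "match"
        elif wobble and p in wob and (
            s == wob[p] or (not strict_iupac and wob[p] in IUPAC[s])
        ):
            status = "wobble_match"
        else:
            status = "mismatch"
            n_mismatch += 1
        per_position.append((p, s, status))

    tail = per_position[-max(terminal_window, 1):]
    terminal_mm = any(st == "mismatch" for _, _, st in tail)
    return BindingSiteAlignment(
        per_position=tuple(per_position),
        total_mismatches=n_mismatch,
        three_prime_terminal_mismatch=terminal_mm,
        wobble_enabled=wobble,
    )


@dataclass(frozen=True)
class MismatchHistogram:
    """Counts of panel members by primer/site mismatch number (0..4, >=5)."""

    bins: Mapping[str, int]
    n_total: int
    n_no_site: int = 0

    @property
    def proportions(self) -> dict:
        return {k: v / self.n_total for k, v in self.bins.items()}


def mismatch_histogram(
    primer: Primer,
    panel_sites: Sequence[Optional[str]],
    wobble: bool = True,
    *,
    absent_in_ge5: bool = False,
    **eval_kwargs,
) -> MismatchHistogram:
    """Bin per-site mismatch counts over a panel into 0,1,2,3,4,>=5.

    ``panel_sites`` entries may be ``None`` for panel members without a
    locatable binding site; by default those are reported separately in
    ``n_no_site`` rather than silently dropped (set ``absent_in_ge5`` to
    count them in the >=5 bin instead).
    """
    if not panel_sites:
        raise ValueError("panel of binding sites is empty")
    bins = {b: 0 for b in HISTOGRAM_BINS}
    n_no_site = 0
    n_total = 0
    for site in panel_sites:
        if site is None:
            if absent_in_ge5:
                bins["ge5"] += 1
                n_total += 1
            else:
                n_no_site += 1
            continue
        m = evaluate_binding(primer, site, wobble, **eval_kwargs).total_mismatches
        bins[str(m) if m < 5 else "ge5"] += 1
        n_total += 1
    if n_total == 0:
        raise ValueError("no panel member has a located binding site")
    return MismatchHistogram(bins=bins, n_total=n_total, n_no_site=n_no_site)


@dataclass(frozen=True)
class PositionalBaseProfile:
    """Per-primer-position base composition of a panel of binding sites.

    ``counts[i]`` maps each observed base at primer position ``i`` to its
    count over the panel; ``match_count[i]`` is the number of panel members
    whose base equals the primer base there (the bold diagonal of a primer
    base-composition table).
    """

    primer: Primer
    counts: tuple  # of dicts base -> count
    match_count: tuple
    n_sites: int


def positional_base_profile(
    panel_sites: Sequence[str], primer: Primer
) -> PositionalBaseProfile:
    """Tally A/C/G/T composition at every primer position across a panel."""
    k = len(primer.core)
    sites = [s.upper() for s in panel_sites if s is not None]
    for s in sites:
        if len(s) != k:
            raise ValueError(
                f"ragged panel: site length {len(s)} != primer core length {k}"
            )
    counts = []
    match_count = []
    for i, p in enumerate(primer.core):
        col: dict = {"A": 0, "C": 0, "G": 0, "T": 0}
        for s in sites:
            col[s[i]] = col.get(s[i], 0) + 1
        counts.append(col)
        match_count.append(col.get(p, 0))
    return PositionalBaseProfile(
        primer=primer,
        counts=tuple(counts),
        match_count=tuple(match_count),
        n_sites=len(sites),
    )


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in a non-empty ACGT sequence."""
    if not seq:
        raise ValueError("cannot compute GC content of an empty sequence")
    bad = set(seq.upper()) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT character(s) {sorted(bad)!r} in sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


# --- Nearest-neighbour melting temperature --------------------------------

# Unified nearest-neighbour parameters (SantaLucia 1998): per-stack duplex
# formation enthalpy (kcal/mol) and entropy (cal/mol/K), keyed by the
# 5'->3' top-strand dinucleotide.
NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
# Duplex initiation terms by terminal base pair.
INIT_DH = {"G": 0.1, "C": 0.1, "A": 2.3, "T": 2.3}
INIT_DS = {"G": -2.8, "C": -2.8, "A": 4.1, "T": 4.1}

_R_GAS = 1.9872  # cal/(mol K)


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbour thermodynamic parameter set for Tm prediction.

    Defaults are the unified duplex parameters with 50 mM monovalent salt
    and 0.5 uM total oligo; both the stack tables and the conditions are
    injectable so alternative parameterisations can be swapped in.
    """

    nn_dh: Mapping[str, float] = field(default_factory=lambda: dict(NN_DH))
    nn_ds: Mapping[str, float] = field(default_factory=lambda: dict(NN_DS))
    init_dh: Mapping[str, float] = field(default_factory=lambda: dict(INIT_DH))
    init_ds: Mapping[str, float] = field(default_factory=lambda: dict(INIT_DS))
    monovalent_salt: float = 0.050  # mol/L
    oligo_conc: float = 0.5e-6  # mol/L total strand concentration

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0 or self.oligo_conc <= 0:
            raise ValueError("salt and oligo concentrations must be positive")


def melting_temperature(seq: str, params: Optional[ThermoParams] = None) -> float:
    """Nearest-neighbour duplex melting temperature in degrees Celsius.

    Sums stack enthalpies/entropies with terminal initiation terms, applies
    the salt correction dS += 0.368 (N-1) ln[Na+], and evaluates
    Tm = 1000 dH / (dS + R ln(C_T/4)) - 273.15 for a non-self-complementary
    oligo at total strand concentration C_T.
    """
    params = params or ThermoParams()
    s = seq.upper()
    if len(s) < 8:
        raise ValueError("sequence too short for nearest-neighbour Tm (need >= 8 nt)")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguity code(s) {sorted(bad)!r} not allowed in Tm input")
    dh = params.init_dh[s[0]] + params.init_dh[s[-1]]
    ds = params.init_ds[s[0]] + params.init_ds[s[-1]]
    for i in range(len(s) - 1):
        stack = s[i : i + 2]
        dh += params.nn_dh[stack]
        ds += params.nn_ds[stack]
    ds += 0.368 * (len(s) - 1) * math.log(params.monovalent_salt)
    return 1000.0 * dh / (ds + _R_GAS * math.log(params.oligo_conc / 4.0)) - 273.15


# --- Interfaces -----------------------------------------------------------

def load_primers(path) -> dict:
    """Read primer definitions from an INI-style config file.

    Each section defines one primer::

        [MiBird-U-F]
        core = GGGTTGGTAAATCTTGTGCCAGC
        orientation = forward
        adapter = ACACTCTTTCCCTACACGACGCTCTTCCGATCT
        random_bases = 6

    Returns a dict mapping primer name to :class:`Primer`.
    """
    import configparser

    cfg = configparser.ConfigParser()
    with open(path) as fh:
        cfg.read_file(fh)
    primers = {}
    for name in cfg.sections():
        sec = cfg[name]
        primers[name] = Primer(
            name=name,
            core=sec["core"].strip().upper(),
            orientation=sec["orientation"].strip().lower(),
            adapter=sec.get("adapter", fallback=None),
            n_random_bases=sec.getint("random_bases", fallback=0),
        )
    return primers


def histogram_to_tsv(hist: MismatchHistogram) -> str:
    """Render a mismatch histogram as TSV (mismatches, n, proportion)."""
    lines = ["mismatches\tn\tproportion"]
    for b in HISTOGRAM_BINS:
        lines.append(f"{b}\t{hist.bins[b]}\t{hist.bins[b] / hist.n_total:.6f}")
    lines.append(f"no_site\t{hist.n_no_site}\t")
    return "\n".join(lines) + "\n"


def profile_to_tsv(profile: PositionalBaseProfile) -> str:
    """Render a positional base profile as TSV."""
    lines = ["position\tprimer_base\tA\tC\tG\tT\tmatch_count"]
    for i, (col, mc) in enumerate(zip(profile.counts, profile.match_count), start=1):
        p = profile.primer.core[i - 1]
        lines.append(
            f"{i}\t{p}\t{col.get('A', 0)}\t{col.get('C', 0)}"
            f"\t{col.get('G', 0)}\t{col.get('T', 0)}\t{mc}"
        )
    return "\n".join(lines) + "\n"
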