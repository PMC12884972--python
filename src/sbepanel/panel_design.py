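"""Diagnostic-SNP discovery and multiplex SBE panel assembly.

A panel assay interrogates one alignment column that is diagnostic for a
species: a tagged PCR primer pair amplifies a short (80-200 bp) fragment
around the site, and an extension probe whose 3' end abuts the site is
extended by exactly one terminator, so the added base reports the allele.
Assays are pooled into wells such that every unextended-probe and
extension-product mass in a well is separated from every other assay's
masses by at least the spectrometer's resolving gap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .oligo_chem import (
    InvalidSequenceError,
    MassModel,
    ThermoParams,
    average_mass,
    complement_base,
    melting_temperature,
    reverse_complement,
)

__all__ = [
    "SpeciesAlignment",
    "DiagnosticSNP",
    "DesignConstraints",
    "PrimerPair",
    "ProbeCandidate",
    "AssayDesign",
    "Panel",
    "ValidationItem",
    "ValidationReport",
    "UnknownLabelError",
    "find_diagnostic_snps",
    "design_pcr_primers",
    "design_extension_probe",
    "probe_within_amplicon",
    "expected_peak_masses",
    "assign_wells",
    "assign_concentrations",
    "validate_panel",
]

#: Universal 10-mer 5' tag grafted onto every PCR primer so that leftover
#: primers fly well above the probe/product mass window.
DEFAULT_PRIMER_TAG = "ACGTTGGATG"


class UnknownLabelError(KeyError):
    """Raised when a species label is absent from an alignment."""


@dataclass(frozen=True)
class SpeciesAlignment:
    """A multi-species alignment of one locus (columns are 1-based)."""

    locus: str
    rows: Mapping[str, str]  # species label -> aligned sequence

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")
        allowed = set("ACGTN-")
        for label, seq in self.rows.items():
            bad = set(seq.upper()) - allowed
            if bad:
                raise InvalidSequenceError(
                    f"row {label!r} contains invalid characters {sorted(bad)!r}"
                )
        object.__setattr__(
            self, "rows", {k: v.upper() for k, v in self.rows.items()}
        )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, col: int) -> dict[str, str]:
        """Bases at a 1-based column, keyed by species."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return {sp: seq[col - 1] for sp, seq in self.rows.items()}


@dataclass(frozen=True, order=True)
class DiagnosticSNP:
    """An alignment column whose allele is unique to one species."""

    species: str
    locus: str
    column: int  # 1-based alignment coordinate
    allele: str

    def __str__(self) -> str:  # the field's c.<pos><base> shorthand
        return f"{self.locus}:c.{self.column}{self.allele}"


@dataclass(frozen=True)
class DesignConstraints:
    """Physical and spectrometric constraints on a panel design.

    Amplicon bounds are tag-inclusive (both 10-mer tags counted).  The
    minimum tagged-primer mass keeps residual primers clear of the
    analyte window; ``min_peak_gap`` is the smallest tolerable spacing
    between any two different assays' peaks sharing a well.
    """

    amplicon_bp: tuple[int, int] = (80, 200)
    primer_tm_target_c: float = 60.0
    primer_tm_tol_c: float = 6.0
    tag: str = DEFAULT_PRIMER_TAG
    min_tagged_primer_mass_da: float = 8500.0
    probe_len: tuple[int, int] = (17, 28)
    probe_tm_c: tuple[float, float] = (45.0, 90.0)
    min_peak_gap_da: float = 25.0

    def __post_init__(self) -> None:
        for lo, hi in (self.amplicon_bp, self.probe_len, self.probe_tm_c):
            if lo > hi:
                raise ValueError("constraint bounds must be ordered")
        if not self.tag:
            raise ValueError("tag must be non-empty")
        if self.min_peak_gap_da <= 0:
            raise ValueError("min_peak_gap_da must be positive")

    def to_dict(self) -> dict:
        return {
            "amplicon_bp": list(self.amplicon_bp),
            "primer_tm_target_c": self.primer_tm_target_c,
            "primer_tm_tol_c": self.primer_tm_tol_c,
            "tag": self.tag,
            "min_tagged_primer_mass_da": self.min_tagged_primer_mass_da,
            "probe_len": list(self.probe_len),
            "probe_tm_c": list(self.probe_tm_c),
            "min_peak_gap_da": self.min_peak_gap_da,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignConstraints":
        return cls(
            amplicon_bp=tuple(d["amplicon_bp"]),
            primer_tm_target_c=float(d["primer_tm_target_c"]),
            primer_tm_tol_c=float(d["primer_tm_tol_c"]),
            tag=str(d["tag"]),
            min_tagged_primer_mass_da=float(d["min_tagged_primer_mass_da"]),
            probe_len=tuple(d["probe_len"]),
            probe_tm_c=tuple(d["probe_tm_c"]),
            min_peak_gap_da=float(d["min_peak_gap_da"]),
        )


@dataclass(frozen=True)
class PrimerPair:
    """A tagged primer pair candidate around a SNP."""

    forward: str  # tag + template-binding core
    reverse: str
    forward_core: str
    reverse_core: str
    tm_forward_c: float
    tm_reverse_c: float
    amplicon_bp: int  # tag-inclusive
    span: tuple[int, int]  # 1-based template coordinates of the core span


@dataclass(frozen=True)
class ProbeCandidate:
    """An extension-probe candidate abutting a SNP."""

    sequence: str
    strand: str  # '+' or '-'
    tm_c: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssayDesign:
    """One SBE assay: primer pair, probe, allele map and peak masses.

    ``alleles`` maps species to the base observed at the query position in
    reference orientation; for a minus-strand probe the incorporated
    terminator is the complement of that base.  ``ep_masses`` is keyed by
    the reference-orientation allele.
    """

    name: str
    locus: str
    primer_f: str
    primer_r: str
    probe: str
    strand: str
    alleles: Mapping[str, str]  # species -> reference-orientation base
    uep_mass: float
    ep_masses: Mapping[str, float]  # allele -> Da
    conc_uM: float | None = None
    amplicon_bp: int | None = None
    primer_f_mass: float | None = None
    primer_r_mass: float | None = None
    designed_allele: str | None = None
    snps: tuple[DiagnosticSNP, ...] = ()
    tag: str = DEFAULT_PRIMER_TAG

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for sp, base in self.alleles.items():
            if base not in "ACGT":
                raise ValueError(f"allele for {sp!r} must be one of ACGT")

    def core_f(self) -> str:
        return self.primer_f[len(self.tag):] if self.primer_f.startswith(self.tag) else self.primer_f

    def core_r(self) -> str:
        return self.primer_r[len(self.tag):] if self.primer_r.startswith(self.tag) else self.primer_r

    def added_base(self, allele: str) -> str:
        """Terminator base incorporated when the template shows ``allele``."""
        return allele if self.strand == "+" else complement_base(allele)

    def reported_allele(self, added: str) -> str:
        """Reference-orientation allele implied by an incorporated base."""
        return added if self.strand == "+" else complement_base(added)

    def peak_masses(self) -> set[float]:
        return expected_peak_masses(self)

    @classmethod
    def from_sequences(
        cls,
        name: str,
        locus: str,
        primers: PrimerPair,
        probe: ProbeCandidate,
        alleles: Mapping[str, str],
        model: MassModel | None = None,
        tag: str = DEFAULT_PRIMER_TAG,
        **extra,
    ) -> "AssayDesign":
        """Build an assay with masses computed from its sequences."""
        model = model or MassModel.default()
        uep = average_mass(probe.sequence, model, "probe")
        ep = {}
        for allele in sorted(set(alleles.values())):
            added = allele if probe.strand == "+" else complement_base(allele)
            ep[allele] = uep + model.terminator_mass[added]
        return cls(
            name=name,
            locus=locus,
            primer_f=primers.forward,
            primer_r=primers.reverse,
            probe=probe.sequence,
            strand=probe.strand,
            alleles=dict(alleles),
            uep_mass=uep,
            ep_masses=ep,
            amplicon_bp=primers.amplicon_bp,
            primer_f_mass=average_mass(primers.forward, model, "primer"),
            primer_r_mass=average_mass(primers.reverse, model, "primer"),
            tag=tag,
            **extra,
        )


@dataclass
class Panel:
    """Assays partitioned into wells under a recorded separation constraint."""

    wells: dict[str, list[AssayDesign]]
    constraints: DesignConstraints = field(default_factory=DesignConstraints)

    def __post_init__(self) -> None:
        names = [a.name for a in self.assays()]
        if len(names) != len(set(names)):
            raise ValueError("assay names must be unique across wells")

    def assays(self) -> list[AssayDesign]:
        return [a for well in self.wells.values() for a in well]

    def assay(self, name: str) -> AssayDesign:
        for a in self.assays():
            if a.name == name:
                return a
        raise KeyError(name)

    def well_of(self, name: str) -> str:
        for wid, assays in self.wells.items():
            if any(a.name == name for a in assays):
                return wid
        raise KeyError(name)

    def loci(self) -> list[str]:
        return sorted({a.locus for a in self.assays()})


# ---------------------------------------------------------------------------
# Diagnostic SNP discovery
# ---------------------------------------------------------------------------

def find_diagnostic_snps(
    aln: SpeciesAlignment, target: str = "all"
) -> list[DiagnosticSNP]:
    """Scan alignment columns for species-unique alleles.

    A column is diagnostic for a species when that species carries a real
    base there which appears in no other row.  Columns where any row holds
    a gap or N are disqualified: missing data cannot support a claim of
    uniqueness.  Results are sorted by (species, column).
    """
    if target != "all" and target not in aln.rows:
        raise UnknownLabelError(f"species {target!r} not in alignment")
    targets = list(aln.rows) if target == "all" else [target]
    out: list[DiagnosticSNP] = []
    seqs = aln.rows
    for col in range(1, aln.length + 1):
        bases = {sp: seq[col - 1] for sp, seq in seqs.items()}
        if any(b not in "ACGT" for b in bases.values()):
            continue
        for sp in targets:
            b = bases[sp]
            if all(other == sp or ob != b for other, ob in bases.items()):
                out.append(DiagnosticSNP(sp, aln.locus, col, b))
    return sorted(out)


# ---------------------------------------------------------------------------
# Primer and probe design
# ---------------------------------------------------------------------------

_CORE_LEN_RANGE = range(18, 25)


def _candidate_cores(
    template: str,
    region: range,
    constraints: DesignConstraints,
    thermo: ThermoParams,
    model: MassModel,
    reverse: bool,
) -> list[tuple[int, int, str, float]]:
    """Enumerate primer cores (start0, end0 inclusive) passing Tm and mass."""
    lo_tm = constraints.primer_tm_target_c - constraints.primer_tm_tol_c
    hi_tm = constraints.primer_tm_target_c + constraints.primer_tm_tol_c
    out = []
    for start in region:
        for length in _CORE_LEN_RANGE:
            end = start + length - 1
            if end >= len(template) or end not in region:
                continue
            core = template[start : end + 1]
            primer_core = reverse_complement(core) if reverse else core
            try:
                tm = melting_temperature(primer_core, thermo)
            except InvalidSequenceError:
                continue
            if not lo_tm <= tm <= hi_tm:
                continue
            tagged = constraints.tag + primer_core
            if average_mass(tagged, model, "primer") < constraints.min_tagged_primer_mass_da:
                continue
            out.append((start, end, primer_core, tm))
    return out


def design_pcr_primers(
    template: str,
    snp_pos: int,
    constraints: DesignConstraints | None = None,
    thermo: ThermoParams | None = None,
    model: MassModel | None = None,
    max_candidates: int = 20,
) -> list[PrimerPair]:
    """Enumerate tagged primer pairs whose amplicon spans a SNP.

    The template is an ungapped reference sequence with 1-based
    coordinates.  Cores must sit strictly outside the SNP, satisfy the Tm
    window, and clear the tagged-mass floor; pairs are ranked by combined
    Tm deviation from target, then amplicon length.  Returns an empty list
    when the geometry is infeasible.
    """
    constraints = constraints or DesignConstraints()
    thermo = thermo or ThermoParams()
    model = model or MassModel.default()
    seq = template.upper()
    if not 1 <= snp_pos <= len(seq):
        raise IndexError(f"snp_pos {snp_pos} outside template")
    if "-" in seq:
        raise InvalidSequenceError("template must be ungapped")
    p = snp_pos - 1
    tag2 = 2 * len(constraints.tag)
    max_core_span = constraints.amplicon_bp[1] - tag2
    lo = max(0, p - max_core_span)
    hi = min(len(seq) - 1, p + max_core_span)
    fwd = _candidate_cores(seq, range(lo, p), constraints, thermo, model, reverse=False)
    rev = _candidate_cores(seq, range(p + 1, hi + 1), constraints, thermo, model, reverse=True)
    pairs: list[tuple[float, int, PrimerPair]] = []
    for fs, fe, fcore, ftm in fwd:
        if fe >= p:
            continue
        for rs, re_, rcore, rtm in rev:
            if rs <= p:
                continue
            amp = (re_ - fs + 1) + tag2
            if not constraints.amplicon_bp[0] <= amp <= constraints.amplicon_bp[1]:
                continue
            dev = abs(ftm - constraints.primer_tm_target_c) + abs(
                rtm - constraints.primer_tm_target_c
            )
            pairs.append(
                (
                    dev,
                    amp,
                    PrimerPair(
                        forward=constraints.tag + fcore,
                        reverse=constraints.tag + rcore,
                        forward_core=fcore,
                        reverse_core=rcore,
                        tm_forward_c=ftm,
                        tm_reverse_c=rtm,
                        amplicon_bp=amp,
                        span=(fs + 1, re_ + 1),
                    ),
                )
            )
    pairs.sort(key=lambda t: (t[0], t[1], t[2].forward, t[2].reverse))
    return [p for _, _, p in pairs[:max_candidates]]


def design_extension_probe(
    template: str,
    snp_pos: int,
    strand: str = "both",
    constraints: DesignConstraints | None = None,
    thermo: ThermoParams | None = None,
) -> list[ProbeCandidate]:
    """Enumerate extension probes whose 3' end abuts the SNP.

    A plus-strand probe copies template positions ``snp_pos-L .. snp_pos-1``;
    a minus-strand probe is the reverse complement of positions
    ``snp_pos+1 .. snp_pos+L``.  Either way the first extended base reads
    the SNP.  Candidates must satisfy the length and hybridization-Tm
    windows; ranked by Tm proximity to the window midpoint.
    """
    constraints = constraints or DesignConstraints()
    thermo = thermo or ThermoParams()
    seq = template.upper()
    if not 1 <= snp_pos <= len(seq):
        raise IndexError(f"snp_pos {snp_pos} outside template")
    if strand not in ("+", "-", "both"):
        raise ValueError("strand must be '+', '-' or 'both'")
    p = snp_pos - 1
    lo_len, hi_len = constraints.probe_len
    lo_tm, hi_tm = constraints.probe_tm_c
    mid_tm = (lo_tm + hi_tm) / 2
    out: list[tuple[float, ProbeCandidate]] = []
    strands = ["+", "-"] if strand == "both" else [strand]
    for st in strands:
        for length in range(lo_len, hi_len + 1):
            if st == "+":
                start = p - length
                if start < 0:
                    continue
                probe = seq[start:p]
            else:
                end = p + 1 + length
                if end > len(seq):
                    continue
                probe = reverse_complement(seq[p + 1 : end])
            try:
                tm = melting_temperature(probe, thermo)
            except InvalidSequenceError:
                continue
            if lo_tm <= tm <= hi_tm:
                out.append((abs(tm - mid_tm), ProbeCandidate(probe, st, tm)))
    out.sort(key=lambda t: (t[0], t[1].strand, t[1].sequence))
    return [c for _, c in out]


def probe_within_amplicon(
    probe: ProbeCandidate, snp_pos: int, span: tuple[int, int]
) -> bool:
    """True when a probe's template footprint lies inside a primer span.

    Primer pairs and probes are designed independently; an assay is only
    coherent when the probe (and the queried base) sit within the
    amplicon, so composers filter candidates through this predicate.
    """
    if probe.strand == "+":
        lo, hi = snp_pos - probe.length, snp_pos
    else:
        lo, hi = snp_pos, snp_pos + probe.length
    return span[0] <= lo and hi <= span[1]


# ---------------------------------------------------------------------------
# Peak masses, well partitioning, concentrations, validation
# ---------------------------------------------------------------------------

def expected_peak_masses(assay: AssayDesign) -> set[float]:
    """All masses an assay can contribute: its UEP plus one EP per allele."""
    return {float(assay.uep_mass)} | {float(m) for m in assay.ep_masses.values()}


def _conflict_graph(assays: Sequence[AssayDesign], min_gap: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.name for a in assays)
    for a, b in itertools.combinations(assays, 2):
        if any(
            abs(ma - mb) < min_gap
            for ma in expected_peak_masses(a)
            for mb in expected_peak_masses(b)
        ):
            g.add_edge(a.name, b.name)
    return g


def _exact_coloring(g: nx.Graph) -> dict[str, int]:
    """Minimum proper coloring by iterative-deepening backtracking."""
    nodes = sorted(g.nodes, key=lambda n: (-g.degree(n), n))
    for k in range(1, len(nodes) + 1):
        colors: dict[str, int] = {}

        def place(i: int) -> bool:
            if i == len(nodes):
                return True
            n = nodes[i]
            used = {colors[m] for m in g[n] if m in colors}
            # symmetry breaking: a node may open at most one fresh color
            ceiling = min(k, max(colors.values(), default=-1) + 2)
            for c in range(ceiling):
                if c in used:
                    continue
                colors[n] = c
                if place(i + 1):
                    return True
                del colors[n]
            return False

        if place(0):
            return colors
    raise AssertionError("unreachable: n colors always suffice")


def _greedy_coloring(g: nx.Graph) -> dict[str, int]:
    """Deterministic largest-degree-first greedy coloring (ties by name)."""
    colors: dict[str, int] = {}
    for n in sorted(g.nodes, key=lambda n: (-g.degree(n), n)):
        used = {colors[m] for m in g[n] if m in colors}
        colors[n] = next(c for c in itertools.count() if c not in used)
    return colors


def assign_wells(
    assays: Sequence[AssayDesign],
    min_gap: float = 25.0,
    constraints: DesignConstraints | None = None,
    exact_limit: int = 16,
) -> Panel:
    """Partition assays into the fewest wells respecting peak separation.

    Two assays conflict when any pair of their expected peak masses lies
    closer than ``min_gap``; wells are a proper coloring of the conflict
    graph.  Up to ``exact_limit`` assays the coloring is provably minimal
    (exhaustive backtracking); beyond that a deterministic
    largest-degree-first greedy order is used, with ties broken
    lexicographically by assay name.
    """
    if not assays:
        raise ValueError("need at least one assay")
    if min_gap <= 0:
        raise ValueError("min_gap must be positive")
    constraints = constraints or DesignConstraints()
    constraints = replace(constraints, min_peak_gap_da=min_gap)
    g = _conflict_graph(assays, min_gap)
    colors = _exact_coloring(g) if len(assays) <= exact_limit else _greedy_coloring(g)
    by_name = {a.name: a for a in assays}
    wells: dict[str, list[AssayDesign]] = {}
    for color in sorted(set(colors.values())):
        wid = str(color + 1)
        wells[wid] = [by_name[n] for n in sorted(colors) if colors[n] == color]
    return Panel(wells=wells, constraints=constraints)


def assign_concentrations(
    assays: Sequence[AssayDesign],
    low: tuple[float, float],
    high: tuple[float, float],
) -> dict[str, float]:
    """Probe concentration (uM) linear in UEP mass between two anchors.

    Heavier probes desorb less efficiently, so their spotting concentration
    is ramped up linearly; outside the anchor masses the concentration is
    clipped to the anchor values, keeping the map monotone non-decreasing.
    """
    (m_lo, c_lo), (m_hi, c_hi) = low, high
    if m_lo == m_hi or c_lo > c_hi:
        raise ValueError("anchors must have distinct masses and ordered concentrations")
    if m_lo > m_hi:
        m_lo, c_lo, m_hi, c_hi = m_hi, c_hi, m_lo, c_lo
    slope = (c_hi - c_lo) / (m_hi - m_lo)
    out = {}
    for a in assays:
        m = min(max(a.uep_mass, m_lo), m_hi)
        out[a.name] = c_lo + slope * (m - m_lo)
    return out


@dataclass(frozen=True)
class ValidationItem:
    scope: str  # 'assay' or 'well'
    name: str
    check: str
    ok: bool
    message: str = ""


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    items: tuple[ValidationItem, ...]
    warnings: tuple[str, ...] = ()

    def failures(self) -> list[ValidationItem]:
        return [i for i in self.items if not i.ok]


def validate_panel(
    panel: Panel, constraints: DesignConstraints | None = None
) -> ValidationReport:
    """Itemized constraint audit of a panel; never mutates it.

    Per assay: probe length window and tagged-primer mass floor (when
    primer masses are recorded).  Per well: every cross-assay pair of
    expected peak masses must be separated by at least the minimum gap.
    An empty panel passes vacuously with a warning.
    """
    constraints = constraints or panel.constraints
    items: list[ValidationItem] = []
    warnings: list[str] = []
    assays = panel.assays()
    if not assays:
        return ValidationReport(
            ok=True, items=(), warnings=("panel is empty; nothing to validate",)
        )
    lo_len, hi_len = constraints.probe_len
    for a in assays:
        ok = lo_len <= len(a.probe) <= hi_len
        items.append(
            ValidationItem(
                "assay",
                a.name,
                "probe_length",
                ok,
                f"probe length {len(a.probe)} nt (window {lo_len}-{hi_len})",
            )
        )
        for side, mass in (("forward", a.primer_f_mass), ("reverse", a.primer_r_mass)):
            if mass is None:
                continue
            ok = mass >= constraints.min_tagged_primer_mass_da
            items.append(
                ValidationItem(
                    "assay",
                    a.name,
                    f"primer_mass_{side}",
                    ok,
                    f"{mass:.1f} Da >= {constraints.min_tagged_primer_mass_da:.0f} Da floor",
                )
            )
    for wid, well in panel.wells.items():
        for a, b in itertools.combinations(well, 2):
            worst = min(
                (
                    (abs(ma - mb), ma, mb)
                    for ma in expected_peak_masses(a)
                    for mb in expected_peak_masses(b)
                ),
                default=None,
            )
            gap, ma, mb = worst
            ok = gap >= constraints.min_peak_gap_da
            items.append(
                ValidationItem(
                    "well",
                    wid,
                    f"separation:{a.name}/{b.name}",
                    ok,
                    f"closest pair {ma:.1f}/{mb:.1f} Da, gap {gap:.1f} "
                    f"(min {constraints.min_peak_gap_da:.1f})",
                )
            )
    return ValidationReport(
        ok=all(i.ok for i in items), items=tuple(items), warnings=tuple(warnings)
    )
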