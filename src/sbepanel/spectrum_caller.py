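"""Peak-list interpretation: tolerance-windowed matching and allele calls.

Matching assigns each observed peak to the nearest expected mass within a
tolerance; the tolerance must sit safely below half the well's guaranteed
cross-assay peak separation, otherwise assignments are not trustworthy.
By default the expected-mass registry holds each assay's UEP plus the EPs
of its design allele map (the envelope the panel's separation constraint
actually guarantees); ``alleles="any"`` widens it to all four possible
terminators, which recovers off-design alleles from non-target species at
the cost of that guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .insilico_assay import PeakList
from .oligo_chem import MassModel
from .panel_design import AssayDesign, expected_peak_masses

__all__ = [
    "ExpectedPeak",
    "Assignment",
    "AlleleCall",
    "UnsafeToleranceError",
    "match_peaks",
    "call_alleles",
    "call_well",
]


class UnsafeToleranceError(ValueError):
    """Raised when the match tolerance is too large for the well's spacing."""


@dataclass(frozen=True)
class ExpectedPeak:
    assay: str
    kind: str  # 'uep' or 'ep'
    allele: str | None  # reference-orientation allele for EPs
    mass: float


@dataclass(frozen=True)
class Assignment:
    """Result of matching one peak list against a well's expected masses."""

    expected: tuple[ExpectedPeak, ...]
    matches: Mapping[int, int]  # expected index -> peak index
    unassigned_peaks: tuple[int, ...]
    ambiguous_peaks: tuple[int, ...]
    peaks: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class AlleleCall:
    """Per-assay verdict: detected alleles with relative EP intensities."""

    assay: str
    alleles: Mapping[str, float]  # allele -> fraction of assay EP intensity
    status: str  # uep_only | single | multi | no_signal | ambiguous
    uep_detected: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("uep_only", "single", "multi", "no_signal", "ambiguous"):
            raise ValueError(f"unknown status {self.status!r}")
        total = sum(self.alleles.values())
        if total > 1.0 + 1e-9 or any(f <= 0 for f in self.alleles.values()):
            raise ValueError("allele fractions must lie in (0, 1] and sum <= 1")
        n = len(self.alleles)
        expect = {0: ("uep_only", "no_signal", "ambiguous"), 1: ("single",)}
        if n in expect and self.status not in expect[n]:
            raise ValueError(f"status {self.status!r} inconsistent with {n} alleles")
        if n >= 2 and self.status != "multi":
            raise ValueError("two or more alleles require status 'multi'")


def _expected_registry(
    well: Sequence[AssayDesign], alleles: str, model: MassModel
) -> list[ExpectedPeak]:
    out: list[ExpectedPeak] = []
    for a in sorted(well, key=lambda a: a.name):
        out.append(ExpectedPeak(a.name, "uep", None, float(a.uep_mass)))
        if alleles == "panel":
            for al, m in sorted(a.ep_masses.items()):
                out.append(ExpectedPeak(a.name, "ep", al, float(m)))
        elif alleles == "any":
            for added in "ACGT":
                out.append(
                    ExpectedPeak(
                        a.name,
                        "ep",
                        a.reported_allele(added),
                        float(a.uep_mass) + model.terminator_mass[added],
                    )
                )
        else:
            raise ValueError("alleles must be 'panel' or 'any'")
    return out


def _design_min_separation(well: Sequence[AssayDesign]) -> float:
    masses = [(a.name, m) for a in well for m in expected_peak_masses(a)]
    gaps = [
        abs(ma - mb)
        for i, (na, ma) in enumerate(masses)
        for nb, mb in masses[i + 1 :]
        if na != nb
    ]
    return min(gaps) if gaps else float("inf")


def match_peaks(
    peaks: PeakList,
    well: Sequence[AssayDesign],
    tol: float = 5.0,
    alleles: str = "panel",
    model: MassModel | None = None,
    tie_eps: float = 1e-6,
) -> Assignment:
    """Assign observed peaks to the nearest expected mass within ``tol``.

    Each expected mass receives at most one peak (the nearest; a displaced
    rival becomes unassigned).  A peak equidistant between two expected
    masses is flagged ambiguous and left unassigned.  ``tol`` must be
    below half the minimum cross-assay separation of the well's design
    masses.
    """
    model = model or MassModel.default()
    if tol <= 0:
        raise ValueError("tol must be positive")
    half_sep = _design_min_separation(well) / 2.0
    if tol >= half_sep:
        raise UnsafeToleranceError(
            f"tolerance {tol} Da >= half the well's minimum design separation "
            f"({half_sep:.1f} Da); calls would be unreliable"
        )
    expected = _expected_registry(well, alleles, model)
    matches: dict[int, int] = {}
    unassigned: list[int] = []
    ambiguous: list[int] = []
    for pi, (mz, _inten) in enumerate(peaks.peaks):
        dists = sorted(
            (abs(mz - e.mass), ei) for ei, e in enumerate(expected)
        )
        in_tol = [(d, ei) for d, ei in dists if d <= tol]
        if not in_tol:
            unassigned.append(pi)
            continue
        if len(in_tol) >= 2 and abs(in_tol[0][0] - in_tol[1][0]) <= tie_eps:
            ambiguous.append(pi)
            continue
        d, ei = in_tol[0]
        if ei in matches:
            prev_pi = matches[ei]
            prev_d = abs(peaks.peaks[prev_pi][0] - expected[ei].mass)
            if d < prev_d:
                matches[ei] = pi
                unassigned.append(prev_pi)
            else:
                unassigned.append(pi)
        else:
            matches[ei] = pi
    return Assignment(
        expected=tuple(expected),
        matches=dict(matches),
        unassigned_peaks=tuple(unassigned),
        ambiguous_peaks=tuple(ambiguous),
        peaks=peaks.peaks,
    )


def call_alleles(
    assignment: Assignment,
    well: Sequence[AssayDesign],
    min_allele_fraction: float = 0.05,
) -> list[AlleleCall]:
    """Reduce a peak assignment to one allele call per assay.

    EP peaks below ``min_allele_fraction`` of the assay's total EP
    intensity are suppressed as noise.  Calls are invariant to uniform
    intensity rescaling, and raising the threshold can only remove
    alleles.
    """
    if not 0 < min_allele_fraction < 1:
        raise ValueError("min_allele_fraction must lie in (0, 1)")
    by_assay: dict[str, dict] = {
        a.name: {"uep": False, "ep": {}} for a in well
    }
    for ei, pi in assignment.matches.items():
        e = assignment.expected[ei]
        inten = assignment.peaks[pi][1]
        if e.kind == "uep":
            by_assay[e.assay]["uep"] = True
        else:
            ep = by_assay[e.assay]["ep"]
            ep[e.allele] = ep.get(e.allele, 0.0) + inten
    out: list[AlleleCall] = []
    for a in sorted(well, key=lambda a: a.name):
        slot = by_assay[a.name]
        ep: dict[str, float] = slot["ep"]
        total = sum(ep.values())
        fractions = (
            {al: v / total for al, v in ep.items() if v / total >= min_allele_fraction}
            if total > 0
            else {}
        )
        # renormalize over surviving alleles so fractions describe the call
        surv = sum(fractions.values())
        fractions = {al: f / surv for al, f in fractions.items()} if surv else {}
        if fractions:
            status = "single" if len(fractions) == 1 else "multi"
        elif slot["uep"]:
            status = "uep_only"
        else:
            status = "no_signal"
        out.append(
            AlleleCall(
                assay=a.name,
                alleles=fractions,
                status=status,
                uep_detected=bool(slot["uep"]),
            )
        )
    return out


def call_well(
    peaks: PeakList,
    well: Sequence[AssayDesign],
    tol: float = 5.0,
    min_allele_fraction: float = 0.05,
    alleles: str = "panel",
    model: MassModel | None = None,
) -> list[AlleleCall]:
    """Convenience pipeline: match then call one well."""
    assignment = match_peaks(peaks, well, tol=tol, alleles=alleles, model=model)
    return call_alleles(assignment, well, min_allele_fraction=min_allele_fraction)
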