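"""Species verdicts from per-assay allele calls.

Authentication rests on a composite genotypic profile: a species is
claimed only when its full diagnostic conjunction of (assay, allele)
pairs is observed, while the remaining assays' alleles corroborate or
contradict the claim.  Multi-allele calls may satisfy several species'
conjunctions at once, which is how DNA mixtures are detected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .spectrum_caller import AlleleCall

__all__ = [
    "SpeciesProfile",
    "RuleSet",
    "ProfileScore",
    "SpeciesCall",
    "UnknownAssayError",
    "builtin_profiles",
    "score_profile",
    "identify_species",
]


class UnknownAssayError(KeyError):
    """Raised when calls reference assays outside the known panel."""


@dataclass(frozen=True)
class SpeciesProfile:
    """Expected reference-orientation allele per assay for one species.

    Assays without a site in the species are simply absent.
    """

    species: str
    alleles: Mapping[str, str]  # assay -> base

    def __post_init__(self) -> None:
        for assay, base in self.alleles.items():
            if base not in "ACGT":
                raise ValueError(f"{self.species}/{assay}: allele must be ACGT")


@dataclass(frozen=True)
class RuleSet:
    """Per species, the diagnostic (assay, allele) conjunction required."""

    rules: Mapping[str, Mapping[str, str]]  # species -> {assay: base}

    def species(self) -> list[str]:
        return sorted(self.rules)


@dataclass(frozen=True)
class ProfileScore:
    species: str
    matched: int
    mismatched: int
    missing: int
    score: float


@dataclass(frozen=True)
class SpeciesCall:
    """Identification verdict with per-species evidence."""

    verdict: str  # identified | mixture | inconclusive | non_target
    species: tuple[str, ...]
    evidence: Mapping[str, ProfileScore]

    def __str__(self) -> str:
        if self.verdict == "identified":
            return f"identified: {self.species[0]}"
        if self.verdict == "mixture":
            return "mixture: " + " + ".join(self.species)
        if self.verdict == "inconclusive":
            best = ", ".join(self.species) or "none"
            return f"inconclusive (best match: {best})"
        return "non-target material"


def builtin_profiles() -> tuple[list[SpeciesProfile], RuleSet]:
    """Bundled reference profiles and diagnostic rules for the eight
    *Cistanche* species covered by the built-in panel.

    The two pharmacopeial species carry full composite profiles observed
    on authenticated genomic DNA; the six adulterants carry their
    designed diagnostic alleles only.
    """
    text = (
        resources.files("sbepanel").joinpath("data/cistanche_profiles.json").read_text()
    )
    doc = json.loads(text)
    profiles = [
        SpeciesProfile(species=sp, alleles=dict(alleles))
        for sp, alleles in sorted(doc["profiles"].items())
    ]
    rules = RuleSet(rules={sp: dict(r) for sp, r in doc["rules"].items()})
    # internal consistency: every rule allele equals the profile allele
    by_name = {p.species: p for p in profiles}
    for sp, rule in rules.rules.items():
        prof = by_name[sp].alleles
        for assay, base in rule.items():
            if prof.get(assay) != base:
                raise ValueError(
                    f"builtin rule {sp}/{assay}={base} contradicts profile"
                )
    return profiles, rules


def score_profile(
    calls: Sequence[AlleleCall], profile: SpeciesProfile
) -> ProfileScore:
    """Compare calls against one species profile.

    An assay with a called allele set matches when the profile's allele is
    among the called alleles; profile assays without a call are missing.
    Assays absent from the profile are ignored.  The score is
    matched/(matched+mismatched), or 0 when nothing was comparable.
    """
    called = {c.assay: set(c.alleles) for c in calls}
    matched = mismatched = missing = 0
    for assay, base in profile.alleles.items():
        alleles = called.get(assay)
        if not alleles:
            missing += 1
        elif base in alleles:
            matched += 1
        else:
            mismatched += 1
    denom = matched + mismatched
    return ProfileScore(
        species=profile.species,
        matched=matched,
        mismatched=mismatched,
        missing=missing,
        score=matched / denom if denom else 0.0,
    )


def _conjunction_satisfied(
    called: Mapping[str, set], rule: Mapping[str, str]
) -> bool:
    return all(base in called.get(assay, set()) for assay, base in rule.items())


def _clean_call(
    called: Mapping[str, set], rule: Mapping[str, str]
) -> bool:
    """True when every rule assay called exactly the diagnostic allele."""
    return all(called.get(assay) == {base} for assay, base in rule.items())


def identify_species(
    calls: Sequence[AlleleCall],
    profiles: Sequence[SpeciesProfile],
    rules: RuleSet,
    min_score: float = 0.8,
    known_assays: Iterable[str] | None = None,
) -> SpeciesCall:
    """Map allele calls to a species verdict.

    Species whose full diagnostic conjunction is satisfied are candidates:
    exactly one clean candidate is ``identified``; several candidates mean
    a ``mixture`` (multi-allele calls may satisfy multiple conjunctions);
    no candidate but a composite score at or above ``min_score`` is
    ``inconclusive`` with best-guess evidence; otherwise ``non_target``.
    A single candidate with extra alleles at its own diagnostic assays is
    demoted to inconclusive rather than identified.

    When ``known_assays`` is given, calls naming other assays raise
    :class:`UnknownAssayError`.
    """
    if not 0 < min_score <= 1:
        raise ValueError("min_score must lie in (0, 1]")
    if known_assays is not None:
        known = set(known_assays)
        unknown = sorted({c.assay for c in calls} - known)
        if unknown:
            raise UnknownAssayError(f"calls reference unknown assays: {unknown}")
    called = {c.assay: set(c.alleles) for c in calls}
    by_name = {p.species: p for p in profiles}
    evidence: dict[str, ProfileScore] = {}
    for sp in rules.species():
        profile = by_name.get(sp, SpeciesProfile(sp, dict(rules.rules[sp])))
        evidence[sp] = score_profile(calls, profile)
    candidates = [
        sp for sp in rules.species() if _conjunction_satisfied(called, rules.rules[sp])
    ]
    order = lambda sp: (-evidence[sp].score, sp)
    if len(candidates) == 1:
        sp = candidates[0]
        if _clean_call(called, rules.rules[sp]):
            return SpeciesCall("identified", (sp,), evidence)
        return SpeciesCall("inconclusive", (sp,), evidence)
    if len(candidates) >= 2:
        return SpeciesCall("mixture", tuple(sorted(candidates, key=order)), evidence)
    scored = [sp for sp in rules.species() if evidence[sp].score >= min_score
              and evidence[sp].matched > 0]
    if scored:
        best = sorted(scored, key=order)
        return SpeciesCall("inconclusive", tuple(best[:1]), evidence)
    return SpeciesCall("non_target", (), evidence)
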