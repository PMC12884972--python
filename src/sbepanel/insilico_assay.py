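"""In-silico PCR, single-base extension and peak-list simulation.

The simulator mirrors the wet workflow at the level the spectrometer sees:
primer cores are located on each template of a mixture, the shortest
convergent amplicon is taken, the extension probe is annealed inside it,
and one terminator is added opposite the base 3' of the probe's terminus.
Peak intensities follow template mass fractions with no amplification-bias
model; residual unextended probe carries the remaining intensity.  A small
noise model (m/z jitter, intensity scatter, spurious peaks, detection
floor) perturbs the ideal peak list; all randomness flows from one seed.

The module also houses the synthetic-fixture generators: reference-like
templates embedding a panel's primer and probe sites with chosen alleles,
and multi-species alignments with planted species-unique substitutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .oligo_chem import MassModel, complement_base, reverse_complement
from .panel_design import AssayDesign, DiagnosticSNP, Panel, SpeciesAlignment

__all__ = [
    "MixComponent",
    "TemplateMix",
    "NoiseModel",
    "PeakList",
    "AmbiguousSiteError",
    "InfeasibleProfileError",
    "simulate_pcr",
    "simulate_extension",
    "simulate_spectrum",
    "generate_synthetic_templates",
    "generate_synthetic_alignment",
    "dna_mixture",
]


class AmbiguousSiteError(ValueError):
    """Raised when a probe anneals at more than one site in an amplicon."""


class InfeasibleProfileError(ValueError):
    """Raised when a species profile cannot be embedded in one template."""


@dataclass(frozen=True)
class MixComponent:
    species: str
    templates: Mapping[str, str]  # locus -> template sequence
    fraction: float


@dataclass(frozen=True)
class TemplateMix:
    """A DNA mixture: labelled templates with mass fractions summing to 1.

    An empty component list models a no-template (blank) control.
    """

    components: tuple[MixComponent, ...] = ()

    def __post_init__(self) -> None:
        labels = [c.species for c in self.components]
        if len(labels) != len(set(labels)):
            raise ValueError("component labels must be unique")
        if self.components:
            if any(c.fraction <= 0 for c in self.components):
                raise ValueError("fractions must be positive")
            total = sum(c.fraction for c in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions must sum to 1, got {total}")


def dna_mixture(
    parts: Sequence[tuple[str, Mapping[str, str], float]]
) -> TemplateMix:
    """Build a :class:`TemplateMix` from (species, templates, DNA amount).

    Amounts are arbitrary but positive (e.g. ng/uL of each stock combined
    at equal volumes); they are normalized to mass fractions.
    """
    total = sum(a for _, _, a in parts)
    if total <= 0:
        raise ValueError("total DNA amount must be positive")
    return TemplateMix(
        components=tuple(
            MixComponent(sp, dict(tpl), amount / total) for sp, tpl, amount in parts
        )
    )


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic distortions applied to an ideal peak list.

    detection_floor is on the relative-intensity scale of a single assay
    (ideal peak intensities are fractions of that assay's probe pool).
    """

    mz_sd_da: float = 0.0
    intensity_cv: float = 0.0
    spurious_rate: float = 0.0  # expected spurious peaks per spectrum
    detection_floor: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mz_sd_da, self.intensity_cv, self.spurious_rate, self.detection_floor) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class PeakList:
    """Observed or simulated peaks of one well, sorted by m/z."""

    well: str
    peaks: tuple[tuple[float, float], ...]  # (m/z Da, intensity >= 0)

    def __post_init__(self) -> None:
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(
            self, "peaks", tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        )

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)


# ---------------------------------------------------------------------------
# PCR and extension
# ---------------------------------------------------------------------------

def _find_sites(template: str, query: str, max_mismatch: int) -> list[int]:
    """Start indices where query matches template within max_mismatch."""
    if max_mismatch == 0:
        out, i = [], template.find(query)
        while i != -1:
            out.append(i)
            i = template.find(query, i + 1)
        return out
    n, m = len(template), len(query)
    out = []
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(template[i : i + m], query):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            out.append(i)
    return out


def simulate_pcr(
    mix: TemplateMix, assay: AssayDesign, max_mismatch: int = 0
) -> list[tuple[str, str]]:
    """Amplify each mixture component with an assay's primer cores.

    Only the template-binding cores participate (the 5' tag is
    non-templated).  For each component and locus the shortest amplicon
    with the two cores in convergent orientation is retained; alternative
    longer amplicons trigger an ambiguity warning.  Components lacking a
    site pair yield nothing.  Returns (species, amplicon) pairs with the
    amplicon written on the forward-core strand.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    core_f, core_r = assay.core_f(), assay.core_r()
    out: list[tuple[str, str]] = []
    for comp in mix.components:
        candidates: list[str] = []
        for tpl in comp.templates.values():
            tpl = tpl.upper()
            for strand_seq in (tpl, reverse_complement(tpl)):
                f_sites = _find_sites(strand_seq, core_f, max_mismatch)
                r_sites = [
                    j + len(core_r) - 1
                    for j in _find_sites(
                        strand_seq, reverse_complement(core_r), max_mismatch
                    )
                ]
                for i in f_sites:
                    ends = [j for j in r_sites if j > i + len(core_f) - 1]
                    if ends:
                        j = min(ends)
                        candidates.append(strand_seq[i : j + 1])
        if not candidates:
            continue
        candidates.sort(key=len)
        if len(candidates) > 1:
            warnings.warn(
                f"assay {assay.name}: {len(candidates)} alternative amplicons for "
                f"component {comp.species!r}; shortest retained",
                stacklevel=2,
            )
        out.append((comp.species, candidates[0]))
    return out


def simulate_extension(
    amplicons: Iterable[tuple[str, str]], assay: AssayDesign
) -> dict[str, str]:
    """Anneal the probe in each amplicon and read the incorporated base.

    The probe must match exactly on one strand; the added base is the
    complement of the template base immediately 3' of the probe's annealed
    terminus.  Components without a probe site extend nothing; more than
    one site in a single amplicon is an error.
    """
    probe = assay.probe
    probe_rc = reverse_complement(probe)
    out: dict[str, str] = {}
    for species, amp in amplicons:
        amp = amp.upper()
        added: list[str] = []
        # probe annealed to the bottom strand: probe appears on the
        # amplicon's written strand, extension reads the next base.
        for i in _find_sites(amp, probe, 0):
            if i + len(probe) < len(amp):
                added.append(amp[i + len(probe)])
        # probe annealed to the written strand: its reverse complement
        # appears; extension reads leftward.
        for i in _find_sites(amp, probe_rc, 0):
            if i > 0:
                added.append(complement_base(amp[i - 1]))
        if len(added) > 1:
            raise AmbiguousSiteError(
                f"assay {assay.name}: probe site found {len(added)} times in "
                f"the {species!r} amplicon"
            )
        if added:
            out[species] = added[0]
    return out


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------

def simulate_spectrum(
    panel: Panel,
    mix: TemplateMix,
    noise: NoiseModel | None = None,
    model: MassModel | None = None,
    max_mismatch: int = 0,
) -> list[PeakList]:
    """Simulate one peak list per panel well for a template mixture.

    Per assay, each distinct incorporated base yields an EP peak whose
    intensity is the summed mass fraction of the components templating it;
    the UEP peak carries the unextended remainder.  Noise (jitter,
    intensity scatter, spurious peaks, detection floor) is applied last
    and is deterministic under the noise model's seed.
    """
    noise = noise or NoiseModel()
    model = model or MassModel.default()
    rng = np.random.default_rng(noise.seed)
    out: list[PeakList] = []
    for wid in sorted(panel.wells):
        ideal: list[tuple[float, float]] = []
        for assay in sorted(panel.wells[wid], key=lambda a: a.name):
            amps = simulate_pcr(mix, assay, max_mismatch)
            added = simulate_extension(amps, assay)
            frac_by_comp = {c.species: c.fraction for c in mix.components}
            by_base: dict[str, float] = {}
            for species, base in added.items():
                by_base[base] = by_base.get(base, 0.0) + frac_by_comp[species]
            extended = sum(by_base.values())
            if 1.0 - extended > 1e-12:
                ideal.append((assay.uep_mass, 1.0 - extended))
            for base in sorted(by_base):
                ideal.append(
                    (assay.uep_mass + model.terminator_mass[base], by_base[base])
                )
        peaks: list[tuple[float, float]] = []
        for mz, inten in ideal:
            if noise.mz_sd_da > 0:
                mz += rng.normal(0.0, noise.mz_sd_da)
            if noise.intensity_cv > 0:
                inten *= max(0.0, 1.0 + rng.normal(0.0, noise.intensity_cv))
            peaks.append((mz, inten))
        if noise.spurious_rate > 0 and ideal:
            lo = min(m for m, _ in ideal) - 100.0
            hi = max(m for m, _ in ideal) + 100.0
            for _ in range(rng.poisson(noise.spurious_rate)):
                peaks.append((rng.uniform(lo, hi), rng.uniform(0.0, 0.1)))
        peaks = [(m, i) for m, i in peaks if i >= noise.detection_floor]
        out.append(PeakList(well=wid, peaks=tuple(peaks)))
    return out


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _cassette(assay: AssayDesign, allele: str, rng: np.random.Generator) -> str:
    """Forward-strand amplicon interior carrying ``allele`` at the query site."""
    if allele not in "ACGT":
        raise InfeasibleProfileError(
            f"assay {assay.name}: allele must be one of ACGT, got {allele!r}"
        )
    if assay.strand == "+":
        site = assay.probe + allele
    else:
        site = allele + reverse_complement(assay.probe)
    return (
        assay.core_f()
        + _random_bases(rng, int(rng.integers(8, 16)))
        + site
        + _random_bases(rng, int(rng.integers(8, 16)))
        + reverse_complement(assay.core_r())
    )


def generate_synthetic_templates(
    panel: Panel,
    profile: Mapping[str, str],
    seed: int,
    species: str = "synthetic",
) -> list[tuple[str, str]]:
    """Emit one synthetic reference template per locus for a species profile.

    ``profile`` maps assay names to the reference-orientation allele the
    species carries at that assay's query position; assays absent from the
    profile have no site in the species and are left out.  Each covered
    assay contributes a primer-core/probe-site cassette, concatenated with
    seeded random padding, so the template is regenerable bit-exactly from
    the seed.  Raises when the profile covers no assay or an embedded site
    is not unique in its template.
    """
    rng = np.random.default_rng(seed)
    assays = {a.name: a for a in panel.assays()}
    unknown = sorted(set(profile) - set(assays))
    if unknown:
        raise InfeasibleProfileError(f"profile names unknown assays: {unknown}")
    if not profile:
        raise InfeasibleProfileError("profile covers no assay")
    records: list[tuple[str, str]] = []
    for locus in panel.loci():
        covered = [
            assays[name]
            for name in sorted(profile)
            if assays[name].locus == locus
        ]
        if not covered:
            continue
        for _attempt in range(10):
            parts = [_random_bases(rng, 25)]
            for assay in covered:
                parts.append(_cassette(assay, profile[assay.name], rng))
                parts.append(_random_bases(rng, 25))
            tpl = "".join(parts)
            ok = all(
                tpl.count(a.probe) + tpl.count(reverse_complement(a.probe)) == 1
                and tpl.count(a.core_f()) == 1
                for a in covered
            )
            if ok:
                break
        else:
            raise InfeasibleProfileError(
                f"could not embed a unique site for every assay at locus {locus}"
            )
        records.append((f"{species}|{locus}", tpl))
    return records


def generate_synthetic_alignment(
    n_species: int,
    length: int,
    planted: Sequence[DiagnosticSNP],
    seed: int,
    locus: str = "synthetic_locus",
) -> SpeciesAlignment:
    """Random shared background with planted species-unique substitutions.

    All rows are identical except at the planted columns, where exactly
    the target species carries the planted allele and every other row
    shares a different background base.  Planted columns must be distinct
    and in range.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    cols = [s.column for s in planted]
    if len(cols) != len(set(cols)):
        raise ValueError("planted SNP columns must be distinct")
    if any(not 1 <= c <= length for c in cols):
        raise ValueError("planted SNP column outside alignment")
    rng = np.random.default_rng(seed)
    labels = sorted({s.species for s in planted})
    if len(labels) > n_species:
        raise ValueError("more planted species than rows requested")
    labels += [f"species_{i}" for i in range(1, n_species - len(labels) + 1)]
    labels = sorted(labels)
    background = list(_random_bases(rng, length))
    rows = {sp: list(background) for sp in labels}
    for snp in planted:
        others = [b for b in "ACGT" if b != snp.allele]
        shared = others[int(rng.integers(0, len(others)))]
        for sp in labels:
            rows[sp][snp.column - 1] = snp.allele if sp == snp.species else shared
    return SpeciesAlignment(
        locus=locus, rows={sp: "".join(seq) for sp, seq in rows.items()}
    )
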