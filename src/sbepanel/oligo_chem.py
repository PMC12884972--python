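"""Sequence utilities and the average-mass model for SBE/MALDI-TOF oligos.

Everything downstream of panel design rests on simple average-mass
arithmetic: a DNA oligo's mass is the sum of its internal nucleotide
residue masses plus a constant end-group correction, and a single-base
extension product (EP) is the unextended probe (UEP) plus the mass of one
chain-terminating, mass-modified ddNTP.  The residue masses are the
textbook average values for DNA residues; the end-group offsets and the
four terminator increments are calibrated against a published assay table
rather than assumed, because vendors do not disclose their terminator
chemistry.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "InvalidSequenceError",
    "CalibrationError",
    "DerivationError",
    "UnsupportedLengthError",
    "MassModel",
    "ThermoParams",
    "CalibrationResult",
    "TerminatorFit",
    "DNA_RESIDUE_AVG_DA",
    "TERMINATOR_AVG_DA",
    "reverse_complement",
    "complement_base",
    "gc_percent",
    "average_mass",
    "calibrate_end_offsets",
    "extension_product_mass",
    "derive_terminator_masses",
    "melting_temperature",
]


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or non-nucleotide characters."""


class CalibrationError(ValueError):
    """Raised when too few records are available to fit an end offset."""


class DerivationError(ValueError):
    """Raised when no consistent terminator assignment exists."""


class UnsupportedLengthError(ValueError):
    """Raised for oligo lengths outside the supported Tm range."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Average masses of internal DNA nucleotide residues (Da).
DNA_RESIDUE_AVG_DA = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.2}

#: Mass-modified ddNTP terminator increments (Da), reverse-engineered from
#: published UEP/EP mass pairs (see :func:`derive_terminator_masses`).
TERMINATOR_AVG_DA = {"C": 247.2, "T": 271.2, "G": 287.2, "A": 327.1}

#: End-group corrections (Da) calibrated by least squares against printed
#: oligo-mass columns.  Primers and extension probes are reported under
#: conventions differing by ~0.9 Da, so each class carries its own offset.
END_OFFSET_PRIMER_DA = -61.95
END_OFFSET_PROBE_DA = -61.02


def _check_seq(seq: str, *, what: str = "sequence", extra: str = "") -> str:
    if not isinstance(seq, str) or not seq:
        raise InvalidSequenceError(f"empty or non-string {what}")
    up = seq.upper()
    allowed = set("ACGT") | set(extra)
    bad = set(up) - allowed
    if bad:
        raise InvalidSequenceError(
            f"{what} contains non-nucleotide characters: {sorted(bad)!r}"
        )
    return up


def complement_base(base: str) -> str:
    """Watson-Crick complement of a single base."""
    b = _check_seq(base, what="base")
    if len(b) != 1:
        raise InvalidSequenceError("complement_base expects a single base")
    return b.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (A/C/G/T/N)."""
    up = _check_seq(seq, extra="N")
    return up.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """G+C content as a percentage of sequence length.

    Reported at full precision; round to one decimal to compare against
    published primer tables.
    """
    up = _check_seq(seq)
    return 100.0 * (up.count("G") + up.count("C")) / len(up)


@dataclass(frozen=True)
class MassModel:
    """Constants for average-mass arithmetic on DNA oligos.

    Parameters
    ----------
    residue_mass
        Average mass of each internal nucleotide residue (Da).
    end_offset_primer, end_offset_probe
        Constant end-group corrections (Da) added to the residue sum for
        PCR primers and for extension probes/products respectively.
    terminator_mass
        Mass increment of each mass-modified ddNTP terminator (Da), keyed
        by the incorporated base.
    """

    residue_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(DNA_RESIDUE_AVG_DA)
    )
    end_offset_primer: float = END_OFFSET_PRIMER_DA
    end_offset_probe: float = END_OFFSET_PROBE_DA
    terminator_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(TERMINATOR_AVG_DA)
    )

    def __post_init__(self) -> None:
        if set(self.residue_mass) != set("ACGT"):
            raise ValueError("residue_mass must cover exactly A, C, G, T")
        if any(m <= 280.0 for m in self.residue_mass.values()):
            raise ValueError("residue masses must exceed 280 Da")
        if set(self.terminator_mass) != set("ACGT"):
            raise ValueError("terminator_mass must cover exactly A, C, G, T")
        terms = sorted(self.terminator_mass.values())
        if any(b - a < 15.0 for a, b in zip(terms, terms[1:])):
            raise ValueError("terminator masses must be pairwise >= 15 Da apart")
        for off in (self.end_offset_primer, self.end_offset_probe):
            if not -80.0 <= off <= 0.0:
                raise ValueError("end offsets must lie in [-80, 0] Da")

    def end_offset(self, oligo_class: str) -> float:
        try:
            return {"primer": self.end_offset_primer, "probe": self.end_offset_probe}[
                oligo_class
            ]
        except KeyError:
            raise ValueError(f"unknown oligo class {oligo_class!r}") from None

    @classmethod
    def default(cls) -> "MassModel":
        return cls()

    def to_dict(self) -> dict:
        return {
            "residue_mass": dict(self.residue_mass),
            "end_offset": {
                "primer": self.end_offset_primer,
                "probe": self.end_offset_probe,
            },
            "terminator_mass": dict(self.terminator_mass),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MassModel":
        return cls(
            residue_mass=dict(d["residue_mass"]),
            end_offset_primer=float(d["end_offset"]["primer"]),
            end_offset_probe=float(d["end_offset"]["probe"]),
            terminator_mass=dict(d["terminator_mass"]),
        )


@dataclass(frozen=True)
class ThermoParams:
    """Conditions for nearest-neighbor duplex melting temperatures.

    Defaults describe a high-salt hybridization mix (200 mM monovalent,
    2 mM Mg2+, 1 uM oligo) under the unified Allawi-SantaLucia 1997
    parameter set with the Owczarzy salt correction.
    """

    nn_set: str = "allawi1997"
    monovalent_mM: float = 200.0
    divalent_mM: float = 2.0
    oligo_nM: float = 1000.0

    def __post_init__(self) -> None:
        if self.nn_set not in ("allawi1997", "sugimoto1996", "breslauer1986"):
            raise ValueError(f"unknown nearest-neighbor set {self.nn_set!r}")
        if min(self.monovalent_mM, self.divalent_mM, self.oligo_nM) < 0:
            raise ValueError("concentrations must be non-negative")


_NN_TABLES = {
    "allawi1997": _mt.DNA_NN3,
    "sugimoto1996": _mt.DNA_NN2,
    "breslauer1986": _mt.DNA_NN1,
}


def average_mass(seq: str, model: MassModel | None = None, oligo_class: str = "primer") -> float:
    """Average molecular mass (Da) of a DNA oligo.

    Sum of internal residue masses plus the class end-group offset, so the
    additive identity ``mass(a + b) == mass(a) + mass(b) - offset`` holds
    for any split of the sequence within one class.
    """
    model = model or MassModel.default()
    up = _check_seq(seq)
    return sum(model.residue_mass[b] for b in up) + model.end_offset(oligo_class)


@dataclass(frozen=True)
class CalibrationResult:
    """End-offset fit: the resulting model and per-record residuals."""

    model: MassModel
    residuals: Mapping[str, tuple[float, ...]]  # oligo_class -> residuals (Da)

    def max_abs_residual(self, oligo_class: str | None = None) -> float:
        classes = [oligo_class] if oligo_class else list(self.residuals)
        return max(
            (abs(r) for c in classes for r in self.residuals[c]), default=0.0
        )


def calibrate_end_offsets(
    records: Iterable[tuple[str, float, str]],
    residue_mass: Mapping[str, float] | None = None,
    min_records: int = 3,
) -> CalibrationResult:
    """Fit per-class end-group offsets from (sequence, printed mass, class).

    With the residue masses held fixed, the least-squares offset for a
    class is the mean of ``printed - residue_sum`` over its records.
    Residuals are reported per record in input order.
    """
    residue_mass = dict(residue_mass or DNA_RESIDUE_AVG_DA)
    by_class: dict[str, list[float]] = {}
    for seq, printed, oligo_class in records:
        if oligo_class not in ("primer", "probe"):
            raise ValueError(f"unknown oligo class {oligo_class!r}")
        up = _check_seq(seq)
        by_class.setdefault(oligo_class, []).append(
            float(printed) - sum(residue_mass[b] for b in up)
        )
    for cls_name, deltas in by_class.items():
        if len(deltas) < min_records:
            raise CalibrationError(
                f"need >= {min_records} records to calibrate the {cls_name} offset, "
                f"got {len(deltas)}"
            )
    offsets = {c: statistics.fmean(d) for c, d in by_class.items()}
    model = MassModel(
        residue_mass=residue_mass,
        end_offset_primer=offsets.get("primer", END_OFFSET_PRIMER_DA),
        end_offset_probe=offsets.get("probe", END_OFFSET_PROBE_DA),
    )
    residuals = {
        c: tuple(d - offsets[c] for d in deltas) for c, deltas in by_class.items()
    }
    return CalibrationResult(model=model, residuals=residuals)


def extension_product_mass(
    uep_mass: float, added_base: str, model: MassModel | None = None
) -> float:
    """Mass of an extension product: UEP mass plus one terminator."""
    model = model or MassModel.default()
    base = _check_seq(added_base, what="base")
    if len(base) != 1:
        raise InvalidSequenceError("added_base must be a single base")
    return float(uep_mass) + model.terminator_mass[base]


@dataclass(frozen=True)
class TerminatorFit:
    """Result of reverse-engineering terminator increments from a table."""

    terminator_mass: Mapping[str, float]
    anomalies: tuple[int, ...]  # indices of rows inconsistent with the fit


def derive_terminator_masses(
    rows: Sequence[tuple[float, float, str, str]],
    tol: float = 0.15,
) -> TerminatorFit:
    """Recover the four terminator increments from (uep, ep, snp, strand) rows.

    The incorporated base is the reported SNP allele for a plus-strand
    probe and its Watson-Crick complement for a minus-strand probe.  The
    observed increments ``ep - uep`` are clustered, and every bijection
    between the four bases and four cluster centers is scored by the
    number of rows it explains within ``tol``; the unique best assignment
    wins and unexplained rows are returned as anomalies.  The search is
    order-independent: permuting the input rows permutes only the anomaly
    indices.
    """
    if not rows:
        raise DerivationError("no rows supplied")
    added: list[str] = []
    deltas: list[float] = []
    for uep, ep, snp, strand in rows:
        base = _check_seq(snp, what="SNP allele")
        if len(base) != 1:
            raise InvalidSequenceError("SNP allele must be a single base")
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        added.append(base if strand == "+" else complement_base(base))
        deltas.append(float(ep) - float(uep))

    # Cluster the observed increments (single-linkage with a 2*tol gap).
    clusters: list[list[float]] = []
    for d in sorted(deltas):
        if clusters and d - clusters[-1][-1] <= 2 * tol:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    centers = [statistics.median(c) for c in clusters]
    if len(centers) < 4:
        raise DerivationError(
            f"only {len(centers)} distinct increments observed; need 4"
        )

    bases = "ACGT"
    best: tuple[int, dict[str, float]] | None = None
    tie = False
    for combo in itertools.combinations(sorted(centers), 4):
        for perm in itertools.permutations(combo):
            mapping = dict(zip(bases, perm))
            score = sum(
                1 for b, d in zip(added, deltas) if abs(d - mapping[b]) <= tol
            )
            if best is None or score > best[0]:
                best, tie = (score, mapping), False
            elif score == best[0] and mapping != best[1]:
                tie = True
    assert best is not None
    score, mapping = best
    if score < 4 or tie:
        raise DerivationError("no unique consistent terminator assignment")
    consistent_bases = {
        b for b, d in zip(added, deltas) if abs(d - mapping[b]) <= tol
    }
    if consistent_bases != set(bases):
        raise DerivationError(
            "consistent rows do not cover all four terminator increments"
        )
    anomalies = tuple(
        i for i, (b, d) in enumerate(zip(added, deltas)) if abs(d - mapping[b]) > tol
    )
    rounded = {b: round(m, 1) for b, m in mapping.items()}
    return TerminatorFit(terminator_mass=rounded, anomalies=anomalies)


def melting_temperature(seq: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature (degrees C).

    Computed for the oligo against its perfect complement under the
    configured parameter set and salt correction (Owczarzy Mg2+-adjusted
    monovalent correction).  Deterministic in sequence and conditions.
    """
    params = params or ThermoParams()
    up = _check_seq(seq)
    if not 10 <= len(up) <= 60:
        raise UnsupportedLengthError(
            f"supported oligo length is 10-60 nt, got {len(up)}"
        )
    return float(
        _mt.Tm_NN(
            up,
            nn_table=_NN_TABLES[params.nn_set],
            Na=params.monovalent_mM,
            Mg=params.divalent_mM,
            dnac1=params.oligo_nM,
            dnac2=0,
            saltcorr=7,
        )
    )
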