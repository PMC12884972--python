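"""Diagnostic-SNP discovery, primer/probe design and well partitioning."""

import itertools

import numpy as np
import pytest

from sbepanel.insilico_assay import generate_synthetic_alignment
from sbepanel.oligo_chem import MassModel, average_mass
from sbepanel.panel_design import (
    AssayDesign,
    DesignConstraints,
    DiagnosticSNP,
    Panel,
    SpeciesAlignment,
    UnknownLabelError,
    assign_concentrations,
    assign_wells,
    design_extension_probe,
    design_pcr_primers,
    expected_peak_masses,
    find_diagnostic_snps,
    validate_panel,
)


def brute_force_snps(aln: SpeciesAlignment) -> set:
    """Independent per-column oracle for species-unique alleles."""
    out = set()
    for col in range(1, aln.length + 1):
        bases = aln.column(col)
        if any(b not in "ACGT" for b in bases.values()):
            continue
        for sp, b in bases.items():
            if all(ob != b for o, ob in bases.items() if o != sp):
                out.add((sp, col, b))
    return out


class TestFindDiagnosticSnps:
    def test_identical_rows_yield_nothing(self):
        aln = SpeciesAlignment("loc", {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
        assert find_diagnostic_snps(aln) == []

    def test_planted_substitutions_recovered_exactly(self):
        planted = [
            DiagnosticSNP("sp_a", "loc", 11, "A"),
            DiagnosticSNP("sp_a", "loc", 40, "C"),
            DiagnosticSNP("sp_b", "loc", 77, "G"),
            DiagnosticSNP("sp_c", "loc", 150, "T"),
        ]
        aln = generate_synthetic_alignment(6, 200, planted, seed=5, locus="loc")
        found = find_diagnostic_snps(aln)
        assert {(s.species, s.column, s.allele) for s in found} == {
            (s.species, s.column, s.allele) for s in planted
        }

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n, length = int(rng.integers(2, 9)), int(rng.integers(20, 300))
            rows = {
                f"s{i}": "".join(rng.choice(list("ACGT"), size=length))
                for i in range(n)
            }
            aln = SpeciesAlignment("loc", rows)
            found = {(s.species, s.column, s.allele) for s in find_diagnostic_snps(aln)}
            assert found == brute_force_snps(aln)

    def test_gap_or_n_disqualifies_column(self):
        aln = SpeciesAlignment(
            "loc", {"a": "ACGTA", "b": "A-GTA", "c": "ANGTA"}
        )
        assert find_diagnostic_snps(aln) == []

    def test_target_filter_and_unknown_label(self):
        planted = [DiagnosticSNP("sp_a", "loc", 10, "A"),
                   DiagnosticSNP("sp_b", "loc", 20, "C")]
        aln = generate_synthetic_alignment(4, 50, planted, seed=1, locus="loc")
        only_a = find_diagnostic_snps(aln, "sp_a")
        assert {s.species for s in only_a} == {"sp_a"}
        with pytest.raises(UnknownLabelError):
            find_diagnostic_snps(aln, "nope")

    def test_sorted_output(self):
        planted = [DiagnosticSNP("sp_b", "loc", 90, "G"),
                   DiagnosticSNP("sp_a", "loc", 30, "T"),
                   DiagnosticSNP("sp_a", "loc", 10, "A")]
        aln = generate_synthetic_alignment(5, 120, planted, seed=2, locus="loc")
        found = find_diagnostic_snps(aln)
        assert found == sorted(found)


@pytest.fixture(scope="module")
def random_template():
    rng = np.random.default_rng(42)
    return "".join(rng.choice(list("ACGT"), size=500))


class TestDesignPcrPrimers:
    def test_infeasible_geometry_returns_empty(self, random_template):
        assert design_pcr_primers(random_template, 5) == []

    def test_candidates_satisfy_all_constraints(self, random_template):
        constraints = DesignConstraints()
        model = MassModel.default()
        pairs = design_pcr_primers(random_template, 250, constraints)
        assert pairs, "expected at least one candidate on a 500 bp template"
        from sbepanel.oligo_chem import melting_temperature

        for p in pairs:
            assert p.forward.startswith(constraints.tag)
            assert p.reverse.startswith(constraints.tag)
            lo, hi = constraints.amplicon_bp
            assert lo <= p.amplicon_bp <= hi
            assert p.span[0] <= 250 <= p.span[1]
            for primer in (p.forward, p.reverse):
                assert (
                    average_mass(primer, model, "primer")
                    >= constraints.min_tagged_primer_mass_da
                )
            for tm in (p.tm_forward_c, p.tm_reverse_c):
                assert (
                    abs(tm - constraints.primer_tm_target_c)
                    <= constraints.primer_tm_tol_c
                )

    def test_ranking_prefers_tm_closeness(self, random_template):
        constraints = DesignConstraints()
        pairs = design_pcr_primers(random_template, 250, constraints)
        devs = [
            abs(p.tm_forward_c - 60.0) + abs(p.tm_reverse_c - 60.0) for p in pairs
        ]
        assert devs == sorted(devs)


class TestDesignExtensionProbe:
    def test_plus_strand_probe_abuts_snp(self, random_template):
        for cand in design_extension_probe(random_template, 250, "+"):
            assert cand.sequence == random_template[250 - 1 - cand.length : 250 - 1]

    def test_minus_strand_probe_abuts_snp(self, random_template):
        from sbepanel.oligo_chem import reverse_complement

        for cand in design_extension_probe(random_template, 250, "-"):
            assert cand.sequence == reverse_complement(
                random_template[250 : 250 + cand.length]
            )

    def test_bundled_probes_pass_the_filter_on_their_own_templates(
        self, panel, species_templates, profiles_rules
    ):
        """Re-derive every bundled probe from a template containing it."""
        profiles, _ = profiles_rules
        by_species = {p.species: dict(p.alleles) for p in profiles}
        checked = 0
        for assay in panel.assays():
            species = next(
                (sp for sp, alleles in by_species.items() if assay.name in alleles),
                None,
            )
            if species is None:
                continue
            tpl = species_templates[species][assay.locus]
            if assay.strand == "+":
                pos = tpl.index(assay.probe) + len(assay.probe) + 1
            else:
                from sbepanel.oligo_chem import reverse_complement

                pos = tpl.index(reverse_complement(assay.probe))
            cands = design_extension_probe(tpl, pos, assay.strand)
            assert assay.probe in [c.sequence for c in cands], assay.name
            checked += 1
        assert checked == len(panel.assays())


class TestExpectedPeakMasses:
    def test_bundled_assay_contains_printed_pair(self, panel):
        masses = expected_peak_masses(panel.assay("Cd-2"))
        assert 5213.4 in masses and 5540.5 in masses

    def test_single_allele_map_gives_two_masses(self, panel):
        assert len(expected_peak_masses(panel.assay("Cd-2"))) == 2

    def test_three_alleles_give_four_masses(self, panel, model):
        base = panel.assay("Cd-2")
        assay = AssayDesign(
            name="x", locus="l", primer_f=base.primer_f, primer_r=base.primer_r,
            probe=base.probe, strand="+",
            alleles={"s1": "A", "s2": "C", "s3": "G"},
            uep_mass=5213.4,
            ep_masses={
                al: 5213.4 + model.terminator_mass[al] for al in "ACG"
            },
        )
        assert len(expected_peak_masses(assay)) == 4


def _toy_assay(name: str, uep: float, model: MassModel) -> AssayDesign:
    return AssayDesign(
        name=name, locus="l", primer_f="ACGTTGGATG" + "A" * 18,
        primer_r="ACGTTGGATG" + "C" * 18, probe="ACGT" * 5, strand="+",
        alleles={name: "A"}, uep_mass=uep,
        ep_masses={"A": uep + model.terminator_mass["A"]},
    )


def brute_force_chromatic_number(assays, min_gap):
    """Exhaustive well-count oracle for small instances."""
    def conflict(a, b):
        return any(
            abs(x - y) < min_gap
            for x in expected_peak_masses(a)
            for y in expected_peak_masses(b)
        )

    n = len(assays)
    for k in range(1, n + 1):
        for assignment in itertools.product(range(k), repeat=n):
            if all(
                assignment[i] != assignment[j]
                for i in range(n)
                for j in range(i + 1, n)
                if conflict(assays[i], assays[j])
            ):
                return k
    return n


class TestAssignWells:
    def test_single_assay_one_well(self, model):
        panel = assign_wells([_toy_assay("a", 5000.0, model)], min_gap=25.0)
        assert len(panel.wells) == 1

    def test_bundled_panel_two_wells(self, panel):
        repacked = assign_wells(panel.assays(), min_gap=25.0)
        assert len(repacked.wells) == 2
        assert brute_force_chromatic_number(panel.assays(), 25.0) == 2

    def test_published_partition_is_feasible(self, panel):
        assert validate_panel(panel).ok

    def test_random_instances_match_exhaustive_oracle(self, model):
        rng = np.random.default_rng(3)
        for _ in range(15):
            assays = [
                _toy_assay(f"a{i}", float(rng.uniform(5000, 5400)), model)
                for i in range(6)
            ]
            got = len(assign_wells(assays, min_gap=40.0).wells)
            assert got == brute_force_chromatic_number(assays, 40.0)

    def test_well_count_monotone_in_gap(self, panel):
        counts = [
            len(assign_wells(panel.assays(), min_gap=g).wells)
            for g in (60.0, 35.0, 25.0, 10.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_output_always_validates(self, model):
        rng = np.random.default_rng(9)
        for _ in range(10):
            assays = [
                _toy_assay(f"a{i}", float(rng.uniform(5000, 5600)), model)
                for i in range(7)
            ]
            p = assign_wells(assays, min_gap=30.0)
            assert validate_panel(p).ok


class TestAssignConcentrations:
    def test_tube2_interior_rows_reproduced(self, panel):
        tube2 = panel.wells["2"]
        by_mass = sorted(tube2, key=lambda a: a.uep_mass)
        low = (by_mass[0].uep_mass, by_mass[0].conc_uM)
        high = (by_mass[-1].uep_mass, by_mass[-1].conc_uM)
        conc = assign_concentrations(tube2, low, high)
        for a in tube2:
            assert conc[a.name] == pytest.approx(a.conc_uM, abs=0.05)

    def test_anchor_and_equal_mass_behavior(self, model):
        a = _toy_assay("a", 5000.0, model)
        b = _toy_assay("b", 5000.0, model)
        c = _toy_assay("c", 9000.0, model)
        conc = assign_concentrations([a, b, c], (5000.0, 7.0), (8000.0, 11.0))
        assert conc["a"] == pytest.approx(7.0)
        assert conc["a"] == conc["b"]
        assert conc["c"] == pytest.approx(11.0)  # clipped at the high anchor

    def test_degenerate_anchors_rejected(self, model):
        with pytest.raises(ValueError):
            assign_concentrations([_toy_assay("a", 5000.0, model)],
                                  (5000.0, 7.0), (5000.0, 9.0))


class TestValidatePanel:
    def test_bundled_panel_passes_at_25(self, panel):
        report = validate_panel(panel)
        assert report.ok
        assert not report.failures()

    def test_collapsed_panel_fails_citing_known_collision(self, panel):
        one_well = Panel(
            wells={"1": panel.assays()}, constraints=panel.constraints
        )
        report = validate_panel(one_well)
        assert not report.ok
        cited = {f.check for f in report.failures()}
        assert any("Cd-2" in c and "Csi-2" in c for c in cited)

    def test_empty_panel_passes_vacuously_with_warning(self):
        report = validate_panel(Panel(wells={}))
        assert report.ok
        assert report.warnings


class TestDesignSimulationConsistency:
    def test_designed_assay_reports_intended_allele(self):
        """A freshly designed assay, re-simulated against its own template,
        reads back the base the template carries at the query position."""
        from sbepanel.insilico_assay import (
            MixComponent,
            TemplateMix,
            simulate_extension,
            simulate_pcr,
        )

        rng = np.random.default_rng(31)
        designed = 0
        for trial in range(8):
            template = "".join(rng.choice(list("ACGT"), size=400))
            pos = 200
            pairs = design_pcr_primers(template, pos)
            probes = design_extension_probe(template, pos, "both")
            from sbepanel.panel_design import probe_within_amplicon

            combo = next(
                (
                    (pp, pc)
                    for pp in pairs
                    for pc in probes
                    if probe_within_amplicon(pc, pos, pp.span)
                ),
                None,
            )
            if combo is None:
                continue
            truth = template[pos - 1]
            assay = AssayDesign.from_sequences(
                f"t{trial}", "loc", combo[0], combo[1], alleles={"sp": truth}
            )
            mix = TemplateMix((MixComponent("sp", {"loc": template}, 1.0),))
            amps = simulate_pcr(mix, assay)
            assert amps, "designed primers must amplify their own template"
            added = simulate_extension(amps, assay)
            assert assay.reported_allele(added["sp"]) == truth
            designed += 1
        assert designed >= 5
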