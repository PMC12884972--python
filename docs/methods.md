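# Methods

## Scope

`sbepanel` models the dry half of a MassARRAY-style authentication
workflow: panel design (diagnostic SNP discovery, primer/probe design,
well pooling), the physics-free arithmetic connecting oligo sequences to
peak masses, an in-silico simulator of the PCR → single-base extension →
MALDI-TOF readout, and the interpretation path from peak lists to species
verdicts. Wet-lab steps (extraction, cycling, chip spotting) and raw
spectrum processing (baseline correction, peak picking) are out of scope;
the toolkit consumes and produces peak *lists*.

## Mass model

Average (not monoisotopic) masses are used throughout, matching how
oligo vendors and MALDI genotyping software report them.

* **Residues.** Internal nucleotide residues carry the textbook average
  masses dA 313.21, dC 289.18, dG 329.21, dT 304.2 Da. These are fixed,
  never fitted.
* **End offsets.** A single constant per oligo class absorbs the
  end-group chemistry (5′-OH/3′-OH termini, loss of one phosphate
  relative to the residue sum). The offsets are calibrated by least
  squares against the bundled panel's printed mass columns — with fixed
  residues this reduces to the mean of (printed − residue sum). The fits
  give −61.95 Da for PCR primers (28 records, max residual 0.046 Da) and
  −61.02 Da for extension probes (14 records, max residual 0.061 Da).
  The two classes differ systematically by ≈0.93 Da; whether the probe
  column reports neutral or protonated ([M+H]+) species cannot be
  decided from the table and is deliberately left open — the constant
  soaks it up either way.
* **Terminators.** The four mass-modified ddNTP increments are not
  published by the vendor, so they are reverse-engineered from the
  panel's UEP/EP pairs: the observed increments are clustered, and every
  bijection of {A,C,G,T} onto four cluster centers is scored by how many
  rows it explains within 0.15 Da, taking the incorporated base as the
  designed allele for plus-strand probes and its complement for
  minus-strand probes. The unique best assignment is {C 247.2, T 271.2,
  G 287.2, A 327.1} Da, explaining 13 of 14 rows. The CpITS row
  (Δ = 541.2 Da) is inconsistent with any single-base increment and is
  flagged as an anomaly; the package treats its printed EP mass as a
  transcription artifact, warns about it at panel load, and uses the
  model-consistent product mass in simulation.
* **Probe strands.** The fixture's probe strand annotations are exactly
  the assignment that makes the terminator table Watson–Crick-consistent
  (minus-strand probes: Csi-2, Csa-1, Csi-1, Cd-1, Ct-1). Alleles are
  always reported in reference orientation; the incorporated base is
  complemented for minus-strand probes at the simulation and calling
  boundaries.

## Melting temperatures

`melting_temperature` computes nearest-neighbor duplex Tm via Biopython's
`Tm_NN` under the unified Allawi–SantaLucia 1997 parameters with the
Owczarzy salt correction. Default conditions: 200 mM monovalent cations,
2 mM Mg²⁺, 1 µM oligo — a high-salt hybridization mix under which the
bundled probes span ≈49–77 °C, inside the 45–90 °C probe window used for
design filtering. The vendor formula behind the published primer-Tm
column is unknown (its values run ~10 °C above any standard NN set), so
Tm participates in candidate filtering only and is never used as a
correctness criterion.

## Panel design

* **Diagnostic SNPs.** A column is diagnostic for a species when that
  species' base occurs in no other row. Columns where any row holds a
  gap or N are disqualified: missing data cannot support uniqueness.
  Coordinates are 1-based throughout, matching the c.482T notation used
  in the field.
* **Primers.** Every primer is a universal 10-mer tag (ACGTTGGATG) plus
  a template-binding core of 18–24 nt. Constraints: core Tm within
  60 ± 6 °C, tagged mass ≥ 8500 Da (keeps residual primers above the
  analyte window), tag-inclusive amplicon length 80–200 bp. Candidates
  are ranked by combined Tm deviation, then amplicon length, with
  lexicographic tie-breaks so design output is reproducible without
  seeds. Amplicon lengths are counted tag-inclusive; this is the only
  reading under which the bundled panel's printed sizes can coexist with
  the stated bounds, and since the original templates are not bundled,
  amplicon-size reproduction is not a test target.
* **Probes.** 17–28 nt, 3′ end immediately adjacent to the SNP on either
  strand, hybridization Tm within 45–90 °C. Primer pairs and probes are
  designed independently; `probe_within_amplicon` is the predicate
  composers use to keep the probe footprint inside the amplicon.
* **Well pooling.** Two assays conflict when any pair of their expected
  peak masses (UEP plus one EP per allele in the design allele map) lies
  closer than `min_peak_gap` (default 25 Da, just below the bundled
  panel's tightest within-well spacing of 28.2 Da). Wells are a proper
  coloring of the conflict graph: provably minimal by backtracking up to
  16 assays, deterministic largest-degree-first greedy (ties by name)
  beyond. The separation guarantee covers *designed* alleles only: the
  published panel itself contains off-design products (e.g. the Ct-2 +G
  product at 5415.5 Da, 9.0 Da from the CpITS probe) that no two-well
  partition could separate.
* **Probe concentrations.** Heavier probes desorb less efficiently, so
  spotting concentration ramps linearly in UEP mass between two anchor
  points and clips outside them. A linear fit through the bundled
  panel's extreme rows reproduces its interior values to ±0.05 µM.

## Simulator

* **PCR.** Exact matching of template-binding cores (the tag is
  non-templated), both template strands, convergent orientation, shortest
  product retained; `max_mismatch` relaxes matching when degraded or
  divergent templates are modeled. No efficiency or bias model.
* **Extension.** The probe must match its amplicon exactly; the added
  base is the complement of the template base 3′ of the probe terminus.
  Multiple probe sites in one amplicon are an error, not a guess.
* **Intensities.** EP intensity equals the summed mass fraction of mix
  components templating that base; the UEP peak carries the unextended
  remainder (zero for a fully extending assay). This makes per-assay EP
  intensities sum exactly to the extended template fraction, so a
  detection floor of 0.0005 relative intensity cleanly separates a
  0.0007 trace fraction (detected) from the same trace under a 0.001
  floor (dropped). What this deliberately does not capture: PCR
  saturation, which in the real platform compresses the dynamic range and
  makes trace alleles appear at far higher relative intensity than their
  template fraction. Consequently, at a 0.07 % trace mix, assays whose
  locus exists only in the trace species still call cleanly, but a trace
  minor allele at a shared locus falls below the default 5 % allele
  fraction — the simulator understates the wet platform's mixture
  sensitivity by design, and passing round-trip tests certify the
  interpretation logic, not instrument-level limits of detection.
* **Noise.** Gaussian m/z jitter, multiplicative intensity scatter,
  Poisson spurious peaks, and the detection floor, applied in that
  order. All randomness flows from a single integer seed; identical
  seeds give bit-identical output.
* **Synthetic fixtures.** Reference templates are built per locus by
  concatenating one cassette per assay (forward core, padding, probe
  site carrying the profile's allele, padding, reverse-core complement)
  with seeded random spacers, then checked for site uniqueness. These
  templates emulate only what the assays touch: real loci share
  homologous backbones, carry indels, and can harbor unexpected primer
  or probe sites, so passing tests demonstrate correctness of the
  pipeline logic, not robustness to genomic cross-reactivity. Synthetic
  alignments plant species-unique substitutions on a shared random
  background; with only two rows every variant column is trivially
  unique to both species, so planted-recovery properties use three or
  more rows.

## Calling and identification

* **Matching.** Each observed peak goes to the nearest expected mass
  within a tolerance (default 5 Da); each expected mass keeps only its
  nearest peak, exact ties are flagged ambiguous, and the tolerance must
  stay below half the well's minimum design separation or matching
  refuses to run. Two registries exist: `panel` (design allele map — the
  envelope the separation constraint guarantees) and `any` (all four
  terminators per probe), which recovers off-design alleles from
  non-target species — this is how the composite profile that
  distinguishes the two pharmacopeial species is read — at the cost of
  occasional sub-tolerance collisions that the nearest-peak rule then
  arbitrates.
* **Allele calls.** EP peaks below 5 % of an assay's total EP intensity
  are suppressed as noise; calls are invariant to uniform intensity
  rescaling, and raising the threshold can only remove alleles.
* **Verdicts.** A species is `identified` only when its full diagnostic
  conjunction is matched exactly (no extra allele at any of its
  diagnostic assays); several satisfied conjunctions yield `mixture`;
  a composite score (matched/(matched+mismatched) over a species'
  profile) of at least 0.8 without a complete conjunction yields
  `inconclusive`; otherwise `non_target`. Missing (uncalled) diagnostic
  assays block identification but not the inconclusive band, mirroring
  how partial profiles present in degraded field material.

## Bundled reference data

The package ships the 14-assay *Cistanche* panel (two wells: nine assays
in well 1, five in well 2) as a plain TSV with a JSON constraints
sidecar, full composite profiles for *C. deserticola* and *C. tubulosa*
observed on authenticated genomic DNA, and designed-allele conjunctions
for the six adulterants (*C. salsa*, *C. sinensis*, *C. phelypaea*,
*C. ambigua*, *C. rosea*, *C. ridgewayana*). Masses are recomputed on
every load and drift beyond 0.2 Da raises a warning — the CpITS EP
anomaly surfaces this way rather than being silently corrected.

## Numerical choices and degenerate inputs

Masses are stored at full precision and rounded to 0.1 Da only at the
file boundary, matching the tables' precision. Empty sequences and
non-ACGT characters are rejected at every mass/GC/Tm entry point.
Empty panels validate vacuously with a warning. Blank (no-template)
controls are a first-class `TemplateMix` with no components and produce
pure-UEP spectra. Calibration demands at least three records per oligo
class; terminator derivation demands four distinct increments covering
all four bases and fails loudly on ties.

## Problem sizes used in the test suite

Property tests run at sizes a laptop handles in seconds: 100 random
alignments (≤ 8 species × ≤ 1000 columns) against a per-column oracle,
1000 jittered well spectra for assignment accuracy, 200 random
panel/profile round trips at zero noise, 20 random 6-assay pooling
instances against exhaustive search, and exhaustive 2-coloring
confirmation for the bundled 14-assay panel. The published wet-lab
performance figures (0.07 % DNA sensitivity as an instrument outcome,
field-sample concordance with Sanger sequencing) are experimental
results outside what a simulator can certify; the round-trip and
threshold properties above are their desk-scale stand-ins.
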