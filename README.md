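# sbepanel

Design, simulation and interpretation of multiplex **single-base-extension
(SBE) SNP panels** read out by MALDI-TOF mass spectrometry, built for plant
species authentication. The package ships a complete reference panel for
*Cistanche* Herba (Rou Cong Rong): 14 assays over the nuclear ITS and
chloroplast *rpl16* loci that distinguish the pharmacopeial species
*C. deserticola* and *C. tubulosa* from six adulterant congeners.

## Who this is for

Labs and regulators running (or evaluating) MassARRAY-style genotyping for
herbal authentication, and method developers who need to design new panels:
pick species-diagnostic SNPs from an alignment, wrap each in a tagged PCR
primer pair and an extension probe, pool assays into wells without peak
collisions, and interpret the resulting peak lists as species verdicts.

## The model in brief

Each assay interrogates one diagnostic SNP. A probe anneals with its 3′
end immediately adjacent to the site and is extended by exactly one
mass-modified terminator, so the product mass encodes the allele:

```
m(oligo)      = Σ residue masses + end-group offset        (average masses)
m(EP, allele) = m(UEP) + Δm(terminator of incorporated base)
```

with residues dA 313.21, dC 289.18, dG 329.21, dT 304.2 Da; end offsets
−61.95 Da (primers) and −61.02 Da (probes), calibrated by least squares
against the reference panel's printed mass columns (max residual
< 0.07 Da); and terminator increments Δm = {C 247.2, T 271.2, G 287.2,
A 327.1} Da, reverse-engineered from the panel's UEP/EP mass pairs under
Watson–Crick consistency across probe strands. Assays are pooled by
graph coloring: two assays conflict when any pair of their expected peak
masses lies closer than the spectrometer's resolving gap (25 Da by
default); the bundled panel needs exactly two wells. Identification uses
a composite genotypic profile: a species is claimed only when its full
diagnostic conjunction of (assay, allele) pairs is observed, and
multi-allele calls let mixtures satisfy several conjunctions at once.

## Worked example

Simulate pure *C. deserticola* genomic DNA through the bundled panel,
call alleles, and identify the species:

```
$ sbepanel simulate --profile Cd --seed 1 --out cd_peaks.csv
peak lists for 2 wells -> cd_peaks.csv
$ sbepanel call --peaks cd_peaks.csv --out cd_calls.tsv
14 assay calls -> cd_calls.tsv
$ sbepanel identify --calls cd_calls.tsv
identified: C. deserticola
  C. ambigua: matched=0 mismatched=0 missing=1 score=0.00
  C. deserticola: matched=10 mismatched=0 missing=0 score=1.00
  C. phelypaea: matched=0 mismatched=0 missing=1 score=0.00
  C. ridgewayana: matched=0 mismatched=0 missing=1 score=0.00
  C. rosea: matched=0 mismatched=0 missing=1 score=0.00
  C. salsa: matched=0 mismatched=2 missing=0 score=0.00
  C. sinensis: matched=0 mismatched=2 missing=0 score=0.00
  C. tubulosa: matched=4 mismatched=3 missing=2 score=0.57
```

The verdict rests on the full composite profile, not a single marker: the
four *C. deserticola* diagnostics (Cd-1 [A], Cd-2 [A], CdITS-1 [T],
CdITS-2 [C]) are all present, while the "wrong" alleles at the other
species' assays (e.g. Ct-2 [G] rather than the *C. tubulosa*-diagnostic
[A], visible in `cd_calls.tsv`) corroborate the claim and rule the
substitute out — its score reaches only 0.57 with 3 mismatches. A 50/50
two-species mix instead satisfies both species' conjunctions and is
reported as `mixture: C. deserticola + C. tubulosa`.

Other entry points: `sbepanel design` (diagnostic-SNP discovery and panel
assembly from an aligned FASTA), `sbepanel validate` (constraint audit of
a panel TSV), `sbepanel fixtures` (write the bundled panel, profiles and
synthetic reference templates), `sbepanel simulate --blank` (no-template
control). All are thin wrappers over the `sbepanel` library modules
(`oligo_chem`, `panel_design`, `insilico_assay`, `spectrum_caller`,
`species_id`, `cli_io`).

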