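# actinovar

Comparative variability analytics for pore-forming toxin families.

Actinoporins — the α-pore-forming hemolysins of sea anemones, such as the
fragaceatoxin isoforms of *Actinia fragacea* — are highly similar in sequence
and fold yet differ markedly in activity and stability. A recurring question
for such families is *where* the variability sits: do substitutions
accumulate at functional sites (the lipid-binding region, the
protomer–protomer interface of the oligomeric pore) or at non-interacting,
solvent-exposed positions under weaker purifying selection?

`actinovar` is a Python library for answering that question quantitatively,
together with the biophysical analytics used to characterize the isoforms
themselves. It is aimed at structural bioinformaticians and protein
biochemists working with small protein families that have an alignment, a
reference structure, and functional assay data.

## What it computes

**Residue classification.** Each reference position is classified along three
axes and cross-tabulated:

- *Conservation*: per-column Clustal categories — identical (`*`), strongly
  conserved (`:`), weakly conserved (`.`), non-conserved (space) — using the
  canonical ClustalX residue groups, mapped to ungapped reference numbering.
- *Accessibility*: side-chain accessible surface area from an in-repo
  Shrake–Rupley engine, expressed as the GETAREA-style ratio
  ASA(side chain in structure) / ASA(side chain in an extended Gly-X-Gly
  random-coil reference), classified low (<20 %), partial (20–50 %),
  high (>50 %).
- *Interaction role*: lipid-binding, protein–protein interface, or
  non-interacting, supplied as an annotation table.

From the joined records it reports the 4×3 conservation × accessibility count
matrices per role scope, per-role identity fractions, and the share of
varying positions attributable to non-interacting residues.

**Biophysical analytics.**

- Hemolysis traces (turbidity A700 vs time): lag time by the
  steepest-tangent/baseline intersection, maximum lysis velocity
  υ_max = max −d(A/A₀)/dt.
- Power law lag = τ·c⁻ˣ across toxin concentrations (log–log least squares).
- Percent hemolysis (A₄₁₂ − A_fin)/(A_max − A_fin) × 100 and Hill
  dose–response fits for HC50.
- Thermal melts: Tm as the maximum of the first derivative of the
  percent-change signal after 10-point group reduction.

**Sequence utilities.** FASTA I/O, cDNA translation, splicing of an
Edman-degradation N-terminal prefix onto a cDNA-translated body, theoretical
average mass, pairwise identity (pre-aligned or Needleman–Wunsch/BLOSUM62),
region-restricted difference counts, and Kabsch superposition RMSD.

**Synthetic data.** Every stage has a seeded generator with known ground
truth: families under role-dependent purifying pressure, toy structures with
controlled burial, sigmoidal lysis traces, dose–response tables, two-state
melts.

## Worked example

```bash
python examples/hemolysis_kinetics.py
```

prints

```
lag time 13.0 s, v_max 0.050 1/s (truth: 13 s, 0.05 1/s)
power law: tau 800, reaction order x 1.00
endpoint midway between controls -> 50% hemolysis
Hill fit: HC50 1.59 nM, n 2.00 (truth: 1.6 nM, 2.0)
```

The first line analyzes a synthetic turbidity trace generated with a 13 s
lag: the recovered lag and maximum velocity match the generator truth. The
power-law line fits lag = τ·c⁻ˣ to a noise-free concentration series
(τ = 800, x = 1 recovered exactly), and the Hill fit recovers the HC50 of a
noisy dose–response table within a few percent. The other scripts in
`examples/` demonstrate conservation profiling, ASA classification,
melting-temperature extraction, sequence comparison, and the full pipeline.

A thin CLI mirrors the stages (`actinovar simulate|conserve|asa|kinetics|melt|run`),
e.g.:

```bash
actinovar simulate --kind melt --seed 3 --out melt.csv
actinovar melt melt.csv
```

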