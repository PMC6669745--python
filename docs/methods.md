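# Methods

This note documents the models and procedures implemented in `actinovar`,
the parameters that matter, the numerical choices behind them, and what the
synthetic generators do and do not emulate.

## Conservation categories

Columns of a multiple alignment are classified with the four Clustal symbol
categories using the canonical ClustalX residue groups
(strong: STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW;
weak: CSA, ATV, SAG, STNK, STPA, SGND, SNDEQK, NDEQHK, NEQHRK, FVLIM, HFY).
Precedence is identical > strong > weak > non-conserved, and any gap in a
column makes it non-conserved — the conservative convention matching typical
Clustal symbol output. Categories are mapped to 1-based ungapped positions of
a chosen reference row; columns where the reference is gapped are skipped.
A Shannon column entropy (bits, over non-gap symbols) is provided as a simple
continuous variability score; it is plumbing, not a substitute for
likelihood-based rate estimation.

Because published summaries often leave open whether weakly conserved
columns count as "conserved", the cross-tab summary reports both binnings
(non-conserved = `none` only, and = `{weak, none}`).

## Accessible surface area and burial classes

The ASA engine is a Shrake–Rupley implementation: each atom's
solvent-expanded sphere (radius r + probe, probe 1.4 Å by default) is
sampled with a deterministic Fibonacci lattice (960 points by default) and
the unoccluded fraction scaled by the sphere area. Radii: C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, Se 1.90 Å; hydrogens are ignored, as crystal
structures generally lack them. At 960 points an isolated atom reproduces
the analytic sphere area to machine precision and two-sphere configurations
match the closed-form cap area to well under 1 %; the fixed lab-frame
lattice makes totals orientation-dependent at the ~0.3 % level at 960
points, shrinking as 1/√n.

Per-residue side-chain ASA (for glycine, Cα stands in for the side chain) is
expressed as a ratio to the same side chain in a random-coil reference: an
extended Gly-X-Gly tripeptide built from ideal CCD residue templates chained
at the extended Cα–Cα spacing (3.8 Å) with alternating pleat, evaluated with
the same engine and parameters. Computing the reference internally keeps the
ratio self-consistent under any probe radius, point count or radii set,
instead of tying it to an external constant table. Burial classes follow the
GETAREA-style defaults — low < 20 %, partial 20–50 %, high > 50 % of the
coil reference — and both thresholds are arguments throughout, since
published residue counts are sensitive to them.

Superposition uses the Kabsch algorithm (SVD of the covariance with a
determinant correction, so the rotation is always proper). Collinear or
too-small point sets are rejected rather than silently producing an
ill-conditioned rotation.

## Cross-tabulation

Per-residue records join the conservation category, the ASA class and an
interaction-role annotation (lipid-binding / protein–protein interface /
non-interacting) on reference numbering. Roles are always an explicit input
table — interface annotations are figure- or literature-borne and should not
be inferred. The join is inner on structure coverage; positions missing from
the structure are returned in a gap report, never silently dropped, and a
position lacking a role annotation is an error. Outputs: 4×3 count matrices
under role scopes (all / per-role / interacting), per-role strict-identity
fractions, and the attribution statistic
100 × (varying non-interacting) / (varying total), rounded to an integer.

## Hemolysis kinetics

Traces are lightly smoothed (5-point moving average with
linear-extrapolation edge padding, which keeps the slope at the trace
boundaries unbiased), normalized to the initial level A₀, and
differentiated. υ_max is the maximum descent rate of A/A₀ (units s⁻¹ under
this normalization — note that published υ_max magnitudes depend on an
unstated scaling, so only relative comparisons are meaningful across
sources). The lag time is where the tangent at the steepest descent meets
the baseline; the baseline is the mean of the leading run of points still
within 2 % of the initial level, so a trace already descending at t = 0
keeps its first sample as baseline and yields lag 0. Traces with less than a
5 % total drop are reported as non-lysing rather than raising.

The lag-vs-concentration power law lag = τ·c⁻ˣ is fitted by least squares on
log(lag) vs log(c): deterministic, and weighting relative errors, which is
the natural scale for a quantity spanning decades. Percent hemolysis is the
literal two-control formula and is deliberately not clipped to [0, 100]
(noise can exceed the controls); values outside [−5, 105] raise a warning.
The Hill fit H(c) = plateau·cⁿ/(HC50ⁿ + cⁿ) uses bounded nonlinear least
squares with HC50 initialized at the concentration nearest 50 % response and
n₀ = 1; the plateau is fixed at 100 % by default because the controls define
full lysis, and can be freed. Data that never cross 50 % still fit but are
flagged as extrapolated.

## Thermal melting

The melt pipeline is percent-change normalization (baselines = means of the
first/last 10 % of points, orientation auto-detected) → group reduction
(block averages of 10 consecutive points, trailing partial block averaged
as-is) → central-difference derivative → three-point parabolic refinement of
the derivative maximum, which de-quantizes the reduced grid. A derivative
peak that does not exceed 3× the median absolute derivative (e.g. a bare
linear baseline) is reported as "no transition" instead of a spurious Tm.
With a 0.1 °C sampling step (a 1 °C/min scan read once per 6 s) the reduced
grid is ~1 °C and noise-free two-state curves are recovered to better than
0.2 °C.

## Synthetic generators

The generators define the study conditions under which the pipeline is
validated.

- **Family**: star phylogeny; a uniform-random ancestor of length 175 and 17
  descendants, each site mutating independently with a probability set by
  its class — interface 0.078, lipid-binding 0.034, buried non-interacting
  0.02, exposed non-interacting 0.15 — and substitutions uniform over the 19
  alternatives. Role fractions are 13 % lipid, 14 % interface, 73 %
  non-interacting (40 % of those buried), mirroring a ~175-residue
  actinoporin with ~127 non-interacting positions. The per-class
  probabilities were chosen so that the expected strict-identity fractions
  across 17 sequences ((1−p)¹⁷ ≈ 56 % for lipid sites, ≈ 25 % for interface
  sites) match the regime of interest; with only ~20–25 sites per role the
  per-seed fractions scatter by ±11 points. The star tree and uniform
  substitution target are deliberate simplifications: conservation
  *categories* are what is under test, not phylogenetic or exchangeability
  realism, so passing tests say nothing about tree inference or about
  rate-matrix effects in real families.
- **Toy structures**: ideal-geometry residues from CCD templates; burial via
  two concentric dummy-atom shells (radii 4.5/6.5 Å) that leave no
  probe-sized gap; the Gly-X-Gly extended tripeptide doubles as the coil
  reference.
- **Traces**: a compact-support sigmoid (cubic smoothstep) rather than a
  logistic — the logistic's infinite tail would contradict a flat pre-lag
  phase and bias tangent-based lag recovery at short lags. Turbidity is
  exactly `initial` before onset, the maximum descent rate of A/A₀ equals
  the spec rate, and the steepest tangent meets the initial level exactly
  `lag` seconds after time zero. Defaults (A₀ 0.6 → 0.05, 0.5 s sampling,
  120 s) mirror a red-cell suspension assay at saturating toxin.
- **Melts**: two-state van 't Hoff equilibrium, K = exp[(ΔH/R)(1/Tm − 1/T)]
  with kelvin internally, linear folded/unfolded baselines (defaults −20 and
  −4 signal units at 0 °C, i.e. ~16-unit separation), ΔH 300 kJ/mol, 10–90 °C
  at 0.1 °C. Noise levels in the validation suite are quoted as fractions of
  the baseline separation.

All generators take a seed and are bit-reproducible.

## Validation problem sizes

The acceptance checks use desk-scale problems: 200 random alignments
(≤10×30) against a brute-force symbol oracle, 100 random rigid motions for
superposition, 100 seeded replicates for power-law and Hill recovery, 50 for
Tm under 2 % noise and 50 families for enrichment recovery. These sizes give
stable medians while keeping the whole suite to a couple of minutes on one
core.

## Known limitations

- ASA ratios depend on the coil-reference conformation; values are
  self-consistent within the package but not numerically identical to
  GETAREA's published table.
- The conservation scheme is symbol-based; it does not weight by
  evolutionary distance or estimate site-specific rates.
- υ_max normalization is a package convention (slope of A/A₀); absolute
  magnitudes are not comparable to instrument-specific conventions.
- mmCIF structures, alignment construction and phylogenetic inference are
  out of scope; alignments and role annotations are inputs.
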