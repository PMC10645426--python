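# Methods

## Model

Spec-seq treats binding as a two-state equilibrium, P + Sᵢ ⇌ P·Sᵢ, for a
library of sequence variants competing for one protein pool. With Kₐ(Sᵢ) the
association constant, the ratio of a variant's concentration in the bound
and unbound gel fractions is [P·Sᵢ]/[Sᵢ] = [P]·Kₐ(Sᵢ). Sequencing counts are
proportional to concentrations within a fraction, so the odds ratio between
a variant and the reference cancels both [P] and the per-fraction sequencing
depths:

    Kₐ(Sx)/Kₐ(S_ref) ≈ (N_B(x)/N_U(x)) / (N_B(ref)/N_U(ref))

The relative binding energy is the negative log of this affinity ratio,
which we report as

    ΔΔG(x) = ln(odds_ref) − ln(odds_x)   [kT]

so the reference (consensus) is exactly 0 and weaker binders are positive.
A natural-log affinity ratio is dimensionless and therefore an energy in
units of kT; a kcal/mol view is a constant rescaling (×0.593 at 25 °C,
`KCAL_PER_KT`), exposed as an output option and never the internal unit.

Assumptions: dilute protein, independent sites, no cooperativity or
dimeric binding, equilibrium reached before the gel run, and counts large
enough that multinomial sampling noise dominates (no PCR-bias model).

## Estimator choices

* **Pseudocount** α = 1 (default) is added to all four counts in each odds
  ratio so zero-count variants stay finite; α = 0 is permitted when all
  counts are positive and is used where exactness to machine precision is
  asserted.
* **min_reads** = 10 per fraction (default): log-ratios from single-digit
  counts are unstable, so such variants are reported *missing* (NaN), never
  zero. The reference must pass the floor — otherwise there is no anchor
  and the estimator raises.
* **Sign convention**: consensus 0, weaker binders positive. This matches
  non-negative energy axes in typical replicate scatter plots.

## Energy-PWM regression

The additive model ΔΔG(x) = Σ_p β[p, base_p(x)] is fit by least squares on
variants within `max_mismatch = 2` of the reference (37 of 64 variants for a
three-position randomized core). Encoding is reference-baseline one-hot with
**no intercept**: the reference base coefficient is fixed at 0 per position,
tying the model to the anchor exactly rather than re-centering post hoc.
Consequences: the fitted model predicts exactly 0 at the reference, and a
noiseless additive input reproduces β exactly (residual SD 0). R² is
uncentered (1 − SSR/Σy²), the natural definition for a through-origin
model; residual SD uses n − k degrees of freedom. A base never observed in
the neighborhood yields a NaN coefficient — flagged, not extrapolated — and
any prediction touching it is NaN.

Logo matrices mean-center each variable column (columns then sum to 0
within 1e−9 kT) and the display is the negation, preferred bases up; fixed
library positions carry no information and are flagged, not fitted. With a
missing coefficient the column is centered on the observed entries.

## Replicate / genotype comparison

For the variants measured in both tables (≥3 required): Pearson r, RMS
difference, and `noise_level = sd(a−b)/√2` — the per-experiment noise if
the two experiments contribute equal independent noise; this definition is
recorded in the report metadata because "noise level" has no unique
convention. The best-fit line is OLS of table b on table a; total least
squares is available behind a flag since both axes carry error.

## Simulator

Occupancy θᵢ = A·e^(−Eᵢ)/(1 + A·e^(−Eᵢ)) with activity A = [P]·Kₐ(ref); the
bound pool is multinomial over abundanceᵢ·θᵢ, the unbound over
abundanceᵢ·(1−θᵢ), at the configured depths. Because the estimator uses
odds ratios, estimates are invariant to A — exactly so in `expected` mode,
which emits **un-rounded** expected counts (floats flow through the same
`FractionCounts` container) so that the plug-in estimate equals truth to
~1e−15 kT. Reads are `flank5 + core + flank3` with i.i.d. substitutions at
`error_rate` (a substituted base is always a *different* base), constant
quality, names encoding fraction and serial. One root seed feeds named
crc32-derived child streams, so all outputs are bit-reproducible across
processes.

Default study conditions: 64-variant `TAANNN` library, uniform abundance,
A = 1, truth penalties i.i.d. Uniform(0, 1) kT per non-consensus base (so
variant energies span ~[0, 3] kT), 10⁶ reads/fraction for recovery checks
and 2×10⁵ in the analysis drivers, error_rate 0.01 where sequencing error
is exercised.

What the simulator does **not** emulate: PCR amplification bias, gel
mobility artifacts, dye effects, ligand depletion/competition between
sites, position-dependent error profiles, and indels. Passing tests
therefore demonstrate correctness of the estimator and plumbing under the
stated equilibrium model, not robustness to those real-data artifacts.

The targetome generator plants class labels whose effect sizes are
truncated-normal draws strictly inside the classification thresholds (ChIP
log₂FC upper-truncated at −1.1 against a −1 cut; RNA at ∓0.7 against ∓0.6;
FDR bands separated from 5e−2 and 1e−5 by orders of magnitude), so exact
label recovery is guaranteed by construction and any mismatch indicates a
pipeline defect, not sampling noise. Each classed gene carries one lost
peak 1–90 kb from its TSS on a synthetic chromosome with TSSs 1 Mb apart;
"unassigned" genes have either no peak or a retained (non-lost) peak; decoy
lost peaks sit 150–350 kb from the nearest TSS to exercise the 100 kb rule.
The developmental matrix gives activated genes geometric growth (factor
1.6–3 per pseudo-age) under 5% lognormal noise — monotone in practice —
and flat noisy profiles otherwise.

## Targetome classification

Thresholds are applied exactly as printed, all strict: lost peaks at
log₂FC < −1 and FDR < 5×10⁻²; classes at log₂FC < −0.6 / > 0.6 with
FDR < 10⁻⁵; DEGs at |log₂FC| > 1, FDR < 10⁻², with an **inclusive** ≥5 cpm
expression floor. Peak position is the interval midpoint, TSS a single base,
BED 0-based half-open; distance ties break to the lexicographically smallest
gene id (recorded in provenance). "Not significantly affected" is
operationalized as the complement of the two significant classes
(FDR ≥ 10⁻⁵ or |log₂FC| ≤ 0.6). The classification universe is the RNA
table's genes plus lost-peak-associated genes: genes without an assigned
lost peak are `unassigned`, lost-peak genes absent from the RNA table are
`missing_expression`, and the labels always partition the universe.
Differential statistics (log₂FC, FDR) are inputs, not computed here — they
come from standard differential-analysis tooling upstream, or from the
simulator in tests.

Developmental correlation uses log₂(cpm+1) by default (raw and per-gene
z-score available); the transform and gene intersection size are recorded
with the output.

## Numerical and degenerate-input behavior

* Degenerate simulation pools (all occupancies 0 or 1 after weighting)
  raise, naming the offending fraction.
* `compare_energy_tables` returns NaN r for zero-variance inputs rather
  than dividing by zero.
* Energy tables always contain every library variant; missingness is NaN,
  and exports carry a boolean `measured` column.
* Problem sizes in the shipped drivers and acceptance script (2×10⁵–10⁶
  reads/fraction, 250–300 genes) were chosen as the smallest scales at
  which sampling noise is clearly sub-tolerance for the recovery claims.

## Known limitations

Monomeric sites only (no spaced/dimeric motifs); IUPAC degeneracy limited
to N; no epistatic (dinucleotide) energy terms; no Bayesian uncertainty on
per-variant energies; flank matching is exact and positional (no indel
alignment), standing in for upstream adapter/quality trimming; the
classification reproduces the stated nearest-TSS rule directly rather than
any particular annotation tool's internals.
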