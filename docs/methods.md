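# Methods

## Scope and data model

The package operates downstream of acquisition and deconvolution: its
inputs are per-injection feature lists (retention time in minutes, peak
area, centroided EI spectrum), a reference spectral library in NIST MSP
text format, an n-alkane ladder (carbon number → retention time), compound
annotation tables (Union-list membership with SML, Cramer class), and
internal-standard definitions. Peak integration, retention-time alignment
and background subtraction are assumed done upstream.

Exact masses come from an embedded table of principal-isotope masses
(CODATA/AME values) rather than an external dependency, so that 2 ppm mass
gating cannot drift with dependency versions; the test suite cross-checks
the table against pyteomics. EI produces odd-electron molecular ions
(M⁺•) and even-electron fragment cations, so every theoretical m/z —
molecular ion and fragment subformulas alike — subtracts one electron
mass (5.48580 × 10⁻⁴ Da). At m/z 200 the electron is ≈ 2.7 ppm, larger
than the 2 ppm gate, so the correction is not optional. The formula
grammar accepts whitespace-separated or compact element tokens, plus `D`
and bracketed isotopes (`[13C]6`) for the labelled internal standards.

## Spectral scoring

**Search index (SI).** The vendor search-index formula is unpublished; we
implement the published Stein–Scott composite, the de-facto standard for
EI library search. Peaks are paired one-to-one within ±0.005 Th (HRMS
centroid scale; ppm tolerances govern annotation, not pairing), greedily
by ascending |Δm/z|. With weight vectors w = I^0.6 · (m/z)^3:

- dot term: F_dot = (Σ_pairs w_q w_l)² / (Σ_q w_q² · Σ_l w_l²) — a squared
  cosine in which unpaired peaks count only in the norms;
- ratio term: over paired peaks in m/z order,
  r_i = (Q_i/Q_{i−1})·(L_{i−1}/L_i), F_ratio = mean of min(r_i, 1/r_i);
- composite: (N_q·F_dot + N_pairs·F_ratio)/(N_q + N_pairs), ×100.

Identical spectra score exactly 100; spectra sharing no peak score 0; the
score is invariant under uniform intensity scaling. The weighted dot term
is cross-checked in tests against matchms's CosineGreedy with the same
powers (an independent implementation; ours remains the one used).

**High-resolution filtering (HRF).** The fraction of total intensity
(peaks ≥ 0.1% of the base peak) carried by peaks that have at least one
subformula of the candidate molecular formula within 2 ppm, ×100. The
subformula enumerator is an exact depth-first search over per-element
counts, heaviest element first, pruned by the attainable mass window; it
is verified exhaustively against a nested-loop oracle for parents up to
60 atoms and is capped at 120 atoms (the worst case is combinatorial).
Candidates without a molecular formula have no HRF; their Total degrades
to SI with an `si_only` flag, and they can never satisfy the fragment
criterion, hence never be identified — exact-mass annotation is
constitutive of identification here.

**Total score.** A weighted arithmetic mean, default 0.5/0.5 and
configurable, because the vendor's mixture is unpublished; only the
"> 90" gate is calibrated against the reference dataset. Fragment
annotation assigns each of the top-10 most intense peaks the |ppm|-best
subformula (ties: fewer heteroatoms, then formula string; runners-up kept
in a diagnostics field).

## Retention index

The linear (van den Dool–Kratz) convention: between bracketing alkanes n
and m, RI = 100n + 100(m−n)(rt−rt_n)/(rt_m−rt_n). It is the standard
choice for temperature-programmed runs; the isothermal logarithmic Kovats
form is out of scope. Outside the ladder the terminal segment is
extrapolated and the value flagged, but extrapolated RIs still pass
through the gate. Above C20 the even-only ladder spans 200 RI units per
segment; no special casing. A missing library RI makes the ΔRI criterion
vacuous and the top-ranked candidate by the deterministic tie rule (total
desc, fragments desc, |ΔRI| asc, name) is taken.

## Identification gate

All printed criteria are strict inequalities: Total > 90, < 2 ppm for ≥ 3
fragments (or ≥ 2 plus molecular ion when observed), |ΔRI| < 50. A
candidate sitting exactly at 90 or 50 is rejected; property tests assert
the gate is monotone (tightening thresholds never enlarges the identified
set). Replicate handling: the study design is triplicate injection; a
compound is reported when identified in ≥ 2 of 3 replicates (configurable),
keeping the best-scoring instance — the reported Total is a maximum, not a
mean. Mass-list corroboration (formula match plus observed molecular ion
against a local formula list) annotates confidence but is not a gate
criterion. When the top two Totals differ by < 1 point and both pass, the
identification is marked ambiguous rather than silently choosing.

## Quantification

Semi-quantification deliberately ignores compound-specific response: the
average response factor is the mean over standards and replicates of
area/spiked-concentration (per-replicate ratios averaged; with balanced
replicates this equals the pooled mean), and unknown concentration =
area / RF. Results carry `method="response_factor"` so they are never
confused with calibrated values. Migration (mg/kg food) = concentration
(mg/mL) × extract volume (mL) / film area (dm²) × 6 dm²/kg — the unique
dimensionally consistent chain through the default geometry (0.25 dm²
film, 1 mL final extract, conventional 6 dm²/kg contact ratio); geometry
is configuration, not hard-coded. Calibration is unweighted OLS of area
ratio on concentration with inverse prediction; samples outside the
fitted response range are flagged extrapolated. System suitability
reports the sample RSD% of area and retention time and the mean signed
ppm error of each internal standard's monitored ion, passed at
|ΔMass| ≤ 2 ppm.

## Risk screen

TDI per Cramer class: I 1.80, II 0.54, III 0.09 mg person⁻¹ day⁻¹;
EDI = migration × 1 kg/day (the European default consumption assumption).
The consideration cut-off ("over 0.00015 mg/kg") is strict: exactly
0.00015 is excluded. The functional-barrier comparison is inclusive at
printed precision — a substance reported at 0.010 mg/kg counts as
reaching the 0.01 mg/kg level — implemented as migration ≥ 0.01 within
1e-12 rather than decimal rounding, which would misclassify 0.009.
NIAS verdicts compare EDI to TDI; a considered NIAS without a Cramer
class is a hard error naming the compound (classes come from an external
structural classification consumed as an annotation table; the Cramer
decision tree itself is out of scope). IAS are judged against their SML
only; authorized substances without a listed SML pass with an explicit
note. Whether an IAS exceeding its SML should additionally be
TTC-screened is left open by the source dataset; we report the SML
exceedance only.

## Synthetic study generator

The generator emulates the study design, not the chemistry: fragments are
random atom subsets of the parent formula placed at their exact cation
masses (no bond-aware fragmentation), intensities log-normal, the
molecular ion included when it falls inside the 40–500 m/z acquisition
window. Retention comes from a piecewise-linear RI→RT model through the
alkane anchors, so the RI calculation inverts it exactly and RI tests are
closed-loop. Decoys draw their m/z values from the pooled library and
shift each by 30–80 ppm — realistic peak statistics, wrong exact-mass
structure for every candidate formula. Defaults mirror the emulated
study: triplicate injections, 200 ng/mL internal standards, 20 planted
compounds + 20 decoys, 1 ppm m/z and 5% intensity perturbations. Both
perturbations are *bounded* (uniform), matching how instrument mass
accuracy is specified; noise is not Gaussian-tailed, so passing recovery
tests demonstrates behaviour within the stated accuracy envelope, not
robustness to outlier mass errors, drifting calibration, co-elution or
matrix effects — real-data performance claims need real data. Planted
formulas are drawn from the packaged reference identification table, so
the mass distribution matches plastic-related compounds. Everything is
driven by one integer seed and is byte-deterministic.

Problem sizes used by the default test suite and the acceptance script —
20 planted + 20 decoys in triplicate for recovery, 5 compounds for the
noiseless quantification loop, 20 random parents for the enumeration
oracle — were chosen as the smallest sizes at which the checked
properties are meaningful.

## Packaged reference dataset

Two CSV transcriptions of a published screening study of post-consumer
recycled LDPE ship with the package: 83 tentatively identified substances
(12 on the Union list of authorized substances) and the 45-substance
migration/risk table. SHA-256 checksums guard against silent edits. Two
rows of the identification table (ΔRI printed as 50; one Total score of
86.2) would fail the strict gate as printed in the source; the
transcription is verbatim and is treated as data — the gate is exercised
on synthetic inputs, not by re-gating the reference table.

## Known limitations

- The SI and Total formulas are faithful to the published composite, not
  to any vendor's proprietary variant; rank behaviour is close but scores
  are not numerically interchangeable.
- HRF explains intensity by subformula existence only; it does not score
  isotope clusters or fragment plausibility.
- Semi-quantified migrations inherit the single-response-factor
  approximation and can be off by the compound's true response ratio.
- The risk screen covers single-substance thresholds; mixture effects and
  the unidentified-feature fraction are outside its scope.
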