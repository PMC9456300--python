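# Methods

## Molecular model

Oligonucleotides are modelled as ordered residue lists with explicit linkage
and terminal chemistry.  The four residues (mU = 5-methyluridine,
mC = 5-methylcytidine, A = adenosine, G = guanosine, all with
2'-O-methoxyethyl (MOE) sugars) are registry data: the free-base formula is
stored (`data/residues.tsv`) and the nucleoside formula is derived as
base + ribose (C5H10O5) + MOE substitution (C3H6O) − H2O.  Composition is
additive:

| unit | net contribution |
|---|---|
| MOE nucleoside | registry formula (e.g. MOE-G = C13H19N5O6) |
| phosphorothioate bridge | +P +S +O −H  (H3PO3S − 2 H2O) |
| phosphodiester bridge | +P +2O −H  (H3PO4 − 2 H2O) |
| terminal thiophosphate | +H +P +2O +S  (H3PO3S − H2O) |
| hydroxyl terminus | nothing |
| base loss (abasic MoeR) | −base +H2O |

Neutral free-acid species only: the drug is formulated as a sodium salt, but
sodium/potassium adduct chemistry is deliberately out of scope (see
*Limitations*).  Masses come from a CIAAW/NIST isotope table shipped as
package data; monoisotopic = most-abundant-isotope masses, average =
abundance-weighted means, nominal = integer mass numbers.  The proton mass
used for charge conversion is 1.007276 Da.

The stored sequence keeps the written left-to-right order of the drug
substance (left end labelled 3'); end labels are metadata only and no
composition or mass result depends on orientation.  Truncation labels
(`5'N-a+3'N-b`) follow a fixed package convention — a residues removed from
the left/3' end, b from the right/5' end — and are always reported alongside
explicit spans, because published shortmer labels for this drug are not used
consistently enough to infer a convention from them.

## Candidate space

Exonuclease degradation products are the contiguous sub-sequences of the
parent.  The default identification space is: lengths 2-4 (the observed
metabolite length range), all four hydroxyl/thiophosphate terminal
combinations (hydrolysis can leave the bridging thiophosphate on either
product; published metabolite notations show both leading and trailing `*`),
and at most one base loss.  For the 18-mer this is 760 candidates.
Candidates are deduplicated only by (span, terminals, losses); isobars —
different spans with identical formulas, or symmetric base losses — are all
retained and grouped by formula solely for reporting, since short repetitive
sequences make many assignments genuinely ambiguous.

## Spectral processing

*Isotope patterns* are computed by exact elemental convolution: the
per-element multinomial distribution (binary-exponentiation convolution of the
single-atom distribution) is convolved across elements and aggregated on a
nominal-mass grid, with probability-weighted centroid masses per bin.  The
nominal grid merges fine structure within an isotopologue, which matches
unit-resolution Q-TOF envelopes of 600-1700 m/z ions; peaks below the prune
threshold (default 1e-4) are removed and the rest renormalized.  The
implementation is verified against brute-force isotopologue enumeration
(max deviation < 1e-9 for formulas up to 12 atoms).

*Charge states* come from isotope spacing: z = round(1/median spacing),
accepted only if every spacing is within ±0.02 of 1/z and z ≤ 4; anything
else is reported indeterminate rather than guessed.

*Deconvolution and pairing*: each negative ion gives a neutral-mass estimate
M = |z|(m/z) + |z|·1.007276.  Ions are grouped greedily in descending
intensity order (ties: lower m/z) with complete linkage: an ion joins a
species only if it agrees with every member within the pairing tolerances
(defaults 0.2 Da, 0.1 min).  Complete linkage guarantees the documented
invariant that no species contains two estimates further apart than the mass
tolerance, and the intensity ordering makes the grouping deterministic and
permutation-invariant.  The consensus mass is the unweighted mean of per-ion
estimates (reference deconvoluted values sit between the −1 and −2 estimates,
consistent with an unweighted mean); the consensus rt is intensity-weighted.
Single-ion species are kept and flagged unconfirmed.

*Matching* compares candidate masses (monoisotopic by default; average
selectable, both deltas reported) to the consensus mass at a deliberately
loose default tolerance of 2.5 Da — the scale of the discrepancies between
reported predicted and deconvoluted masses on trustworthy rows — and is meant
to be tightened to ppm scale for well-calibrated data.  Status semantics:
*unidentified* (no candidate), *unconfirmed* (single supporting ion),
*ambiguous* (≥ 2 isobaric formula groups in tolerance), *identified*
(one formula group, confirmed pair).  Enlarging the tolerance can only grow
candidate sets and never demotes a species to unidentified.

## Quantification

EIC areas are trapezoidal integrals with boundary interpolation, making the
integral additive over disjoint windows and exact for piecewise-linear
signals.  Extraction recovery is 100·mean(method)/mean(reference) with
dispersion 100·sd(method)/mean(reference) (sample sd across replicates,
reported at the reference scale, the "91 ± 2 %" convention).  Dose-course
tables pivot per-ion areas over the eight before/after dose labels
(BID..AIVD), render undetected cells as "-" and add after/before ratio
columns; the default detection threshold is 0 (any positive area counts as
detected) because the reference data carry no numeric LOD and the package
does not invent one.

## Synthetic samples

The generator emulates the statistical structure the analysis relies on, not
the instrument physics.  Defaults are the reference study conditions: 20
planted metabolites drawn uniformly without replacement from the default
candidate space; retention times uniform over 8.5-11.0 min with a minimum
spacing of 0.12 min (enforced by construction — ordered uniform offsets on an
evenly spaced backbone — so that distinct metabolites never fall inside one
co-elution window); Gaussian chromatographic peaks of σ = 0.05 min; both
charge states −1/−2 emitted with full isotope envelopes (pruned at 1%);
additive Gaussian m/z error of sd 0.01 Da and multiplicative log-normal
intensity noise (cv 0.1); intensities log-uniform over two decades;
30 matrix peaks confined to 0.5-4 min with random m/z and *no* charge-pair
structure, so they must be rejected by the pairing logic rather than an
intensity gate.  Every emitted peak is recorded in a manifest attributing it
to exactly one metabolite or the matrix process.

What passing synthetic tests shows: the pipeline recovers planted fragments
(recall ≥ 0.95 at the default noise) and never merges ions across
metabolites under the spacing the generator guarantees.  What it does not
show: robustness to co-eluting isobars closer than the pairing tolerances,
ion suppression, drift, or real centroiding artefacts — none of which are
simulated.

## Numerical and degenerate-input choices

Report masses are rounded half-away-from-zero to two decimals.  Empty peak
lists give empty tables; an empty formula has mass 0 and a single-peak
envelope; integration windows that miss the rt grid return 0 with a warning;
unknown residue tokens, elements, dose labels and malformed peak-list rows
raise errors naming the offending token and file:line.  All randomness flows
through a mandatory integer seed; identical inputs and configuration produce
byte-identical outputs.

## Limitations and known discrepancies

* The bundled reference ion table is internally inconsistent.  Its
  deconvoluted masses reproduce from the printed ions to ±0.02 Da except for
  two rows (flagged `deconv_erratum`), but its *predicted* masses cannot all
  be reproduced from any single chemistry consistent with the notation: rows
  whose sequences carry terminal `*` marks or abasic `MoeR` units lie ~5.7 Da
  (one terminal mark) to ~25 Da (abasic unit) below every formula this model
  can produce, while unmarked rows (e.g. mU*mU*mU, predicted 1104 vs computed
  1104.25) agree.  Consequently only 8 of the 16 identified reference species
  receive a candidate at the 2.5 Da tolerance.  Several of the unmatched
  consensus masses are consistent with Na+/K+ adducts of in-space candidates
  (e.g. 1544.60 ≈ {mU,G,mC,mU} + Na − H within 0.3 Da), which supports the
  free-acid model being right and the reference assignments being
  adduct-contaminated — but adduct chemistry is out of scope here, so those
  species are reported unidentified rather than speculatively assigned.
* The advertised molecular mass of the drug substance (7110 g/mol) is not
  reproduced by the stated free-acid chemistry (computed monoisotopic
  7122.3 Da, average 7127.2 Da); the value is not used anywhere.
* MS/MS fragment ions are not modelled: oligonucleotide fragmentation is not
  sequence-specific at this scale and adds no identification power.
* Endonuclease (internal-cut) products beyond contiguous spans, oxidative
  metabolites, and absolute concentration calibration are out of scope.
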