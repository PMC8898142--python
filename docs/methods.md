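# Methods

`gardenia_qc` implements the computational core of a quality-evaluation (QE)
workflow for Gardeniae Fructus (GF) decoction pieces: annotate the
constituents behind an HPLC fingerprint's common peaks from accurate-mass
MS/MS data, score batch-to-batch fingerprint similarity, and quantify the
marker components against external-standard calibration. This note records
the models, conventions and numerical choices, and what the synthetic data
do and do not establish.

## Exact-mass calculus

Monoisotopic atomic masses are hard-coded (H 1.00782503, C 12 exact,
O 15.99491462, N 14.00307401, S 31.97207117, Cl 34.96885268 Da; electron
0.00054858; proton 1.00727646) so annotation never depends on an external
periodic-table service. Anion m/z is **electron-inclusive**:

    m/z([M-H]-)  = M - m(H) + m(e-) = M - 1.00727646
    m/z([M+Cl]-) = M + m(35Cl) + m(e-)

The electron term matters at the fourth decimal; this, and only this,
convention reproduces reference chloride-adduct values such as geniposide
[M+Cl]- = 423.1063. A corollary used throughout: for any formula,
m/z([M+Cl]-) - m/z([M-H]-) = 35.97668 Da (HCl plus two-electron
bookkeeping). ppm errors are signed, measured minus theoretical. Display
rounding is 4 decimals for m/z and 1 for ppm; all internal computation is
full precision.

Formula enumeration over bounded CHO(NS) grids (defaults C 0–60, H 0–100,
O 0–30; N/S off because every fingerprint constituent here is CHO) keeps
candidates with RDBE ≥ 0 and integer (even-electron neutrals), ranked by
|ppm|, with ties broken by |RDBE − 7| (the typical RDBE of these compound
classes) and then lexicographically — arbitrary but deterministic. The
implementation is vectorised but is verified in the test suite against an
independent triple-loop oracle on random targets.

## Neutral-loss cascades

Fragments are explained as the precursor anion minus a sequence of neutral
losses from a fixed library (H2O, CO2, HCl, anhydroglucose C6H10O5,
sinapoyl C11H10O4, caffeoyl, coumaroyl, anhydrogentiobiose C12H20O10,
anhydrorutinose C12H20O9; extensible). Because the cumulative composition
is order-invariant, the search enumerates loss *multisets* to depth 5 and
reports a canonical ordering: the HCl normalisation first (available only
to [M+Cl]- precursors, at most once — chloride adducts collapse to the
deprotonated series before further fragmentation), then losses by
descending mass, which is the order such cascades are conventionally
written. A fragment receives the shortest matching path; equal-depth ties
resolve by library order. Equal-mass compositions are genuinely ambiguous —
one gentiobiose loss is exactly two glucose losses — and the shortest-path
rule settles them deterministically.

Tolerances: 15 ppm for fragments, 5 ppm for precursors. Product-scan
fragments scatter more than survey-scan precursors; 15 ppm accommodates the
~10 ppm deviations real fragment lists show. One wrinkle: the
precursor-survival fragment re-observes the *measured* precursor species,
which can sit >15 ppm from theory while sitting ~10 ppm from the recorded
precursor m/z. The zero-loss path is therefore matched against both the
theoretical anion m/z and the spectrum's own precursor m/z.

Library matching gates on precursor ppm (≤5), retention time (±0.5 min — a
working default; reference RTs in the packaged library are minutes apart,
so the result is insensitive to this choice within a factor of a few) and
on ≥2 diagnostic fragments (the precursor anion plus cascade
intermediates). A record flagged as a reference substance yields a
`reference-confirmed` identification, otherwise `literature`. When nothing
passes, skeleton inference enumerates the precursor formula from its
accurate mass, annotates the cascade, and looks for a library compound's
cascade as the *tail* of a fragment's loss path — an acyl/glycosyl
derivative fragments down to its core's own pathway. Such hits are
`putative`. Intensities are preserved for reporting but never scored; the
fragment lists are identity evidence, not spectra to correlate.

The packaged 28-record library stores names, formulas, classes and
fragment lists exactly as published, including two published name
collisions (peaks 1/5 both "Gardenoside"; peaks 25/28 both "Crocin II" with
different formulas), which are flagged rather than resolved. Reference
cascades are stated in the source only for shanzhiside and the peak-16
derivative; for the other reference substances they were derived here from
the printed fragment lists by mass arithmetic (e.g. geniposide
423.1095 → 387.1288 → 225.0760 is HCl then anhydroglucose within fragment
tolerance).

## Fingerprint statistics

All fingerprint work runs at 254 nm on common-peak tables (RT, area) — no
raw-trace processing. Relative retention time and relative peak area are
taken against the anchor peak 11 (genipin gentiobioside); RSDs use the
n−1 denominator.

Common-peak assignment first locates the anchor as the absolute-RT nearest
neighbour (within the RRT window; otherwise the sample is invalid), then
aligns remaining template peaks to sample peaks one-to-one under a relative
RRT deviation ≤ 0.005. The alignment is an elution-order-preserving dynamic
programme that maximises the number of matches and then minimises total
deviation. Plain closest-first greedy matching was rejected: with adjacent
template peaks 0.45% apart and a 0.5% window, greedy assignment lets a
close pair swap identities under jitter, silently poisoning downstream
quantitation; order preservation makes that impossible whenever the data
preserve elution order. The 0.5% window itself is justified by replicate
RRT scatter around 0.2%.

Similarity is the congruence (cosine) coefficient on common-peak area
vectors, with Pearson as an option. The proprietary software used for such
evaluations does not publish its statistic; the cosine on common-peak
vectors is this package's reimplementation decision, and whether the
original operates on full digitised profiles is unknown. Unmatched common
peaks enter as zero area but are reported separately. The designated
reference defaults to the first sample, with a per-peak median mode for
general use.

## Quantitation

Calibration is unweighted OLS of area on ng on-column (a weighted 1/x
option exists but is off by default, matching the unweighted convention of
the published lines); the linear range is the span of the fitted points.
LOD = 3·noise/slope and LOQ = 10·noise/slope from S/N 3:1 and 10:1. This
formula fixes LOQ/LOD = 10/3; published LOD/LOQ pairs that deviate from
that ratio imply noise re-measured per dilution level, which an area-scale
formula cannot reproduce — the operation documents rather than hides this.

Content conversion follows the preparation 0.1 g powder → 50 mL extract →
30 µL injected, i.e. 60 ng on-column per mg/g, inverted as
content = X·(V·1000/v)/m/10⁶. Channels are enforced: iridoids, rutin and
jasminoside B quantify at 254 nm, chlorogenic acid at 324 nm, crocins at
430 nm; `quantify` refuses an area whose channel disagrees with the
curve's. Negative back-calculated amounts report 0, flagged out-of-range.
Contents display at 3 decimals; aggregates (min/max/mean per analyte, group
totals such as the 7-iridoid sum) compute at full precision, with the mean
using the population denominator as aggregate rows conventionally do.

## Synthetic data

The generator emulates the published study population: 40 batches whose
true contents are truncated-normal draws with the content table's empirical
means and SDs (truncation at zero; negligible bias at these means), areas
produced through the published calibration lines after the dilution chain
with 2% multiplicative lognormal noise, RTs at the published common-peak
positions with 0.1% jitter, 0–5 spurious peaks per run, and 2 ppm mass
noise on spectra. The 16 common peaks without calibration lines carry
fixed, arbitrary-but-realistic areas.

Two constructions make downstream behaviour deterministic rather than
merely probable: spurious peaks are rejection-sampled away from every
template RRT window, and per-peak RT jitter is truncated at ±2 SD and at
45% of the relative gap to the nearest template neighbour, so generated
sets can neither cross elution order nor leave the matching window. The
validation-set generator applies drift (stability) and preparation noise
(repeatability) per peak, not per run: a whole-run scale factor cancels
exactly in RPA, so run-level noise would be invisible to the statistic by
construction.

All randomness flows from the single scenario seed; ground truth is stored
beside each generated set and never consumed by pipeline stages. With zero
noise every stage is an exact inverse (round-trip identities to 1e−9);
with default noise, quantified contents recover the truth with per-analyte
MAE well inside 3×cv×mean over 40 batches.

What passing on synthetic data does **not** show: robustness to baseline
drift, co-elution, detector saturation, matrix effects, or peak-integration
error — the generator produces peak tables, not traces, and its noise is
well-behaved lognormal. Published per-batch similarity values and the
LOD/LOQ, precision, stability and recovery tables cannot be reproduced at
all without the unpublished raw chromatograms and noise traces; the test
suite substitutes exact-arithmetic checks on the published tables plus
property-based checks (scale invariance, round trips, oracle agreement) at
the published noise scales.

## Known limitations

- Positive-ion adducts, charge states beyond −1 and isotope patterns are
  out of scope (negative mode carries the information here).
- De-novo structure elucidation and positional-isomer discrimination are
  not attempted; acyl-position names are conventions inherited from the
  library.
- The published content table's own aggregate row is reproducible only to
  its printed rounding (totals to ±0.002 mg/g); one published ppm value
  (chlorogenic acid [M+Cl]-, printed 0.5) is internally inconsistent with
  its own printed m/z pair, which recomputes to 0.8 ppm.
- Problem sizes in tests and examples (40 virtual batches, 6-replicate
  validation sets, 100 enumeration targets) match the study design and keep
  every check a desk-scale computation.
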