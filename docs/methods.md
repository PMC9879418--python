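# Methods

This note documents the models and procedures implemented in
`paleodraught`, the parameters that matter, the design choices made where
the published methods leave the design open, and what the synthetic
pathway does and does not demonstrate.

## Pathology scoring and the pathological index

Each first phalanx carries five features: proximal exostosis (`pex`),
distal exostosis (`dex`) and proximal lipping (`plip`) scored ordinally
1–4 with 1 meaning no pathology, plus osteoarthritis on the proximal and
distal articular surfaces recorded present/absent. The pathological index
condenses them to a unit interval. No closed form is universally printed
for this index in the applied literature, so the package implements two
variants and makes the choice explicit configuration:

- `normalised_sum` (default): PI = Σ(score − 1) / Σ(max − 1) over the
  included features, denominator 11 for all five features (3+3+3+1+1)
  and 8 for the modified index. Under the stage-1/stage-2-dominated
  pattern typical of lightly worked prehistoric herds this produces means
  in the 0.05–0.3 range, the magnitude reported for comparable
  assemblages.
- `feature_mean`: the mean of the per-feature normalised scores, which
  weights the 2-level osteoarthritis features equally with the 4-level
  ordinal features.

Osteoarthritis coding is a genuine ambiguity in the applied literature
(presence is sometimes written as score 1). Internally the package stores
an explicit absent/present state and maps absent→1, present→2 so that more
pathology always increases the index; `oa_present_is_high=False` flips the
mapping for anyone who wants the literal historical coding. Both codings
are runnable; the default keeps the index monotone.

The modified index (MPI) drops `dex` because distal exostosis correlates
with age, not workload; MPI is therefore invariant to `dex` by
construction (tested exhaustively over all 256 score combinations).

**Hindlimb bias.** Draught work demands retrorse thrust from the
hindlimb, so worked herds show posterior > anterior mean MPI. The package
reports the posterior-minus-anterior difference with a percentile
bootstrap interval (default 2000 replicates, 95%, resampling specimens
within limb, seeded and bit-reproducible). A bootstrap rather than a named
parametric test because the per-specimen index distribution is discrete,
bounded and strongly skewed; the percentile interval makes no distributional
commitment.

**Reference herds.** The comparison table ranks the query herd's mean MPI
among reference populations and flags the "intermediate, draught-like
ordering" when the query sits between the non-draught and lifetime-draught
references. The bundled reference file contains clearly labelled
*synthetic stand-ins* preserving only the qualitative ordering of the
published comparator herds (fattened bulls < semi-feral herd < draught
oxen), because the published means are shown in figures, not printed as
numbers. Users with access to the original studies should replace the
file; nothing quantitative is asserted against the bundled values.

## Metapodial traction index

e/D1 measures broadening/extension of the distal medial condyle; the rule
is **inclusive**: index ≥ 0.75 ⇒ traction-consistent. Threshold
comparisons (0.75, the Bd cut-offs, the gracility bands) are evaluated in
decimal arithmetic on the supplied values, so a measurement written
"0.75" or "63" cannot land on the wrong side of its threshold through
binary representation.

## Osteometric sexing and withers height

Two rule sets, both pure functions of the supplied measurements:

- **Bd thresholds** (metacarpal distal breadth): < 63 mm female,
  > 65 mm male, boundaries inclusive into the ambiguous overlap band
  where large cows and small bulls meet.
- **Gracility bands** (SD/GL × 100 with GL): the castrate rule
  (GL > 215 mm and gracility in 15–17.5) is evaluated *first* because its
  band overlaps the cow band (< 17) — length is what separates an ox from
  a cow; then cow, then bull (17–20); anything else is ambiguous. The
  precedence is total and deterministic, so permuting input rows never
  changes an assignment.

Withers height is GL(mm) × factor / 10 in cm. The bundled factors
(metacarpal 6.03/6.33/6.18, metatarsal 5.33/5.62/5.45 for
female/male/castrate) follow the factor set conventionally attributed to
Matolcsi (1970); they are editable configuration validated to lie in
(4, 8), and they are deliberately excluded from exact acceptance checks.
For a specimen whose sex is ambiguous no factor is imposed: the synthesis
table reports the min–max height interval across the candidate factors
instead of choosing one.

The per-specimen synthesis table composes sex (both methods), GL,
gracility, withers height and the traction verdict; quantities whose
inputs are missing stay empty — nothing is imputed.

## Mortality

Grant mandible wear stages (MWS) map to labelled age classes through an
editable scheme whose MWS ranges must be disjoint and contiguous (age
assignment is then a total function); the absolute-age labels of the older
classes may overlap, as the published class definitions do. The bundled
scheme's MWS boundaries are the package's own transcription choices and
are meant to be replaced by a user's preferred calibration. Per class,
MNI = max(left, right), with unknown-side mandibles counted only when they
outnumber that maximum (fewer unknowns could all pair with the dominant
side). The fit also reports an element-based MNI (the most demanding
element type: sided max for metapodials and mandibles, phalanx count / 8)
separately from the mandible-based figure, since the two routinely
disagree on real assemblages and reconciling them is an interpretive, not
computational, act.

## Synthetic herd generator

The generator encodes the study conditions the analyses target:

- **Demography**: default 58 individuals (an excavated-herd scale),
  sexes (cow, bull, castrate) = (0.45, 0.45, 0.10), age-at-death drawn
  from a mixture over the age classes that concentrates 74% at the
  34–43-month meat optimum with 14% kept into adulthood and the rest
  younger. `traction_fraction` = 0.3 of adult (≥ 30 months) bulls and
  castrates are worked.
- **Pathology**: each ordinal score follows a cumulative-logit
  (proportional-odds) model, P(score ≥ k) = logistic(η − θ_k), chosen
  because the scoring is ordinal and the aetiological statements in the
  literature are directional, not quantitative. Defaults:
  θ = (2.0, 3.5, 5.0) so an unworked animal is stage 1 with
  probability ≈ 0.88 (stage 1–2 dominated, as real lightly worked herds
  are); β_age = 0.3/year on the age-linked feature (`dex`);
  β_work = 1.0 and β_hind = 3.5 on the work-linked features
  (`pex`, `plip` — the proximal, load-bearing features). The large
  hindlimb coefficient encodes hindlimb-dominant loading and gives the
  generator an unambiguous built-in posterior elevation for parameter-
  recovery testing. Osteoarthritis is a Bernoulli on the same latent
  scale (threshold 2.5).
- **Measurements**: truncated normals per (element, sex) with enforced
  dimorphism (bull SD and Bd means above cow; castrate GL longest). The
  e/D1 ratio is drawn from two beta-scaled distributions —
  0.70 + 0.20·Beta(5, 2) for worked, 0.55 + 0.25·Beta(2, 4) for unworked —
  placing > 99% of each cohort on the correct side of 0.75.
- **Skeleton and wear**: each individual expands to 2 metacarpals,
  2 metatarsals, 8 first and 8 second phalanges and 1 mandible whose MWS
  is drawn uniformly inside the true age class's range, so age-class
  recovery from wear is exact by construction. Distal metapodial fusion
  flips at 27 months.
- **Taphonomy**: per-element survival (default 0.8), loss of the distal
  epiphysis record on unfused metapodials (default 0.8) and second-phalanx
  surface erosion (default 0.6). Taphonomy only removes specimens or
  blanks fields; it never alters surviving values (tested by comparing
  thinned and unthinned runs of the same seed).
- **Randomness**: one explicit seed; per-individual demography/skeleton/
  taphonomy substreams derived via `SeedSequence.spawn`, so output is
  bit-reproducible and taphonomy settings cannot perturb another
  individual's draws.

**What the synthetic pathway shows — and does not.** Passing tests
demonstrate that the implementation recovers known ground truth under the
generator's assumptions: independent specimens given the individual,
logistic latent noise, normal measurements, side-independent recovery.
Real assemblages violate several of these (inter-recorder scoring
variance, fragmentation correlated within deposits, measurement error,
herds mixing breeds or centuries), so green tests validate the *code and
the rule set*, not any claim about a particular excavated herd.

## Numerical and interface choices

- Boundary comparisons via `decimal.Decimal` on the supplied values
  (see above); everything else in float64.
- Empty inputs degrade, never crash: validation returns findings instead
  of raising; `fit()` marks missing sections unavailable with a reason;
  empty distributions and profiles are flagged rather than emitting NaN
  silently.
- One-phalanx-per-limb-per-individual selection breaks ties by
  lexicographically smallest specimen id, so runs are deterministic.
- All linear measurements are millimetres throughout; withers heights are
  the only centimetre quantity, converted at output.
- JSON output is serialised with sorted keys and no timestamps, so equal
  inputs and seeds give byte-identical summaries.

## Problem sizes

The test suite and the acceptance script use herds of 40–200 individuals
(≈ 800–4000 specimens), 2000 bootstrap replicates and 1000–10 000-draw
simulation checks; these sizes give stable statistics (binomial/multinomial
standard errors a few percent) while keeping the whole suite in seconds.

## Known limitations

- Anterior/posterior phalanx identification is an input column; the
  morphological criteria that produce it require the physical bone and are
  out of scope.
- The sexing rules are the published fixed thresholds; no mixture-model or
  clustering alternative is implemented (a possible extension).
- The gracility and length bands were calibrated on metacarpals; the
  package applies the same configured bands to metatarsals, as the source
  analyses do, and the generator's metatarsal means were chosen to be
  compatible with them.
- Bundled reference means, withers factors and the MWS→age scheme are
  editable stand-ins/transcriptions, not authoritative data.
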