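# Methods

`speechvar` measures how *variable* a speaker's speech production is from
time-aligned segment data, and runs the two-group clinical comparison that
typically accompanies such measurements (a clinical high-risk group, CHR,
against healthy controls, HC). This note documents the measures, the
statistical models, the synthetic-data generator, the numerical choices
made where the design was genuinely open, and the known limitations.

## Inputs

The package consumes the *outputs* of an audio-analysis stack, not audio:
interval tiers from forced alignment or diadochokinetic segmentation
(Praat TextGrid long format, or the equivalent flat segment CSV), with
optional per-token attributes — a voice-onset-time (VOT) for stop tokens
and first/second formants measured at 20% and 50% of a vowel's duration.
Phone labels are ARPABET-style, with vowel stress carried as a trailing
digit (`AA1` = primary stress) or an explicit stress attribute. Times are
seconds; intervals are half-open `[start, end)`. Any time not covered by a
phone must be covered by a silence segment, so phone + silence time tiles
the recording (checked to 1e-6 s).

Four tasks are distinguished:

* **AMR** (alternating motion rate): 12 trials, one CV syllable repeated
  15 times per trial (two trials each of pa/ta/ka/ba/da/ga);
* **SMR** (sequential motion rate): 20 trials, a three-syllable sequence
  (pa-ta-ka) repeated 10 times, i.e. 30 syllables per trial;
* **READ**: a read passage;
* **SPONT**: a ~2-minute spontaneous sample.

AMR/SMR samples carry explicit trial windows; incomplete samples are
permitted but flagged via `SpeechSample.complete`.

## Token selection

* **Stop tokens**: syllable-initial stop consonants (voiceless p/t/k or
  voiced b/d/g) immediately followed by a vowel. Syllable-initiality uses
  a proxy rule — a stop qualifies if it is word-initial, preceded by a
  vowel, or preceded by silence/a gap — because aligner output does not
  carry syllabification. Each token's VOT is the `vot_s` attribute when
  present (VOT-detector input) and otherwise the stop interval's own
  duration (diadochokinetic segmenters emit the consonant interval as the
  VOT proxy). Tokens with non-positive VOT (prevoiced voiced stops) are
  excluded and counted: a coefficient of variation over signed values is
  not meaningful. Voiced-stop analysis is refused for AMR/SMR, where only
  voiceless stops are analysed.
* **Vowel tokens**: vowels bearing primary stress. In AMR/SMR every vowel
  counts (the repeated CV syllables are monosyllabic).

## The measure battery

All dispersion statistics use the coefficient of variation,
CoV = sample SD (n−1 denominator) / mean, which is scale-free. Per
participant x task the battery comprises (task applicability in
parentheses):

| measure | definition | tasks |
|---|---|---|
| `vot_cov_voiceless` | CoV of voiceless-stop VOTs | all |
| `vot_cov_voiced` | CoV of voiced-stop VOTs | READ, SPONT |
| `speech_rate_cov` | CoV of per-trial (DDK) or per-phrase (READ/SPONT) syllable rates | all |
| `vowel_duration_cov` | CoV of primary-stressed vowel durations | all |
| `formant_dispersion_20` | mean Euclidean distance (Hz) of (F1,F2) points at 20% of vowel duration from their centroid | all |
| `formant_dispersion_change` | dispersion at 50% minus dispersion at 20% (signed Hz) | all |
| `vowel_overlap` | % of vowel tokens strictly closer to another vowel category's centroid than their own (ties resolve to own) | READ, SPONT |
| `syllable_cov` | CoV of syllable spans (onset consonant start to vowel end) | AMR, SMR |
| `intersyllable_cov` | CoV of within-trial gaps between consecutive syllables | AMR, SMR |
| `pause_rate` | internal silences ≥ 150 ms per second of sample duration | READ, SPONT |

Speech rate is syllables per second, with syllables counted as vowel
nuclei. For READ/SPONT it is computed per *phrase*: a maximal spoken
interval between silences of **at least** 150 ms (the threshold is
inclusive; sub-threshold silences remain inside the phrase and its rate
denominator). Leading/trailing silence belongs to no phrase. `pause_rate`
is the count of phrase-delimiting silences divided by total sample
duration, which yields the sub-1 s⁻¹ magnitudes typical of read and
spontaneous speech.

The dispersion, overlap and pause-normalisation definitions are the
package's own reconstructions of standard vowel-space statistics; other
reasonable formulations (e.g. per-category dispersion, Mahalanobis
overlap, pauses per phrase) exist and would shift absolute values.

Analyses use the natural log of each measure (durational and rate CoVs
are right-skewed with a floor at 0). Exact zeros — possible for overlap
and pause rate — are transformed as log(ε) with ε = 1e-3 on the measure's
natural scale; negative values (possible only for the signed dispersion
change) have no log and stay NaN on the log scale. A measure is reported
missing (with a reason) below a floor of **min_n = 5** tokens; this
stability floor, like ε, is configurable.

## Inference

* **Group differences**: OLS of the log measure on a CHR indicator
  (CHR = 1). For duration-derived measures (the two VOT CoVs, vowel
  duration CoV, syllable and intersyllable CoV) the participant's mean
  speech rate in the same task enters as a covariate, since faster speech
  compresses durations. Missingness is handled by listwise deletion; a
  collinear covariate is dropped with a warning; α = 0.05 two-sided with
  no multiplicity correction (the protocol's choice, preserved as such).
* **Validity**: Pearson correlations, within the CHR group only, between
  the log measure and seven validation variables (SIPS positive, negative
  and disorganized totals; SIPS item G3 "Motor Difficulties";
  finger-tapping CoV for each hand; SIPS-RC conversion-risk score).
  Gating: correlations are computed only for measures whose group model
  was significant. Finger-tapping CoV is the sample CoV of the number of
  taps in the **first three** 10-second trials per hand (in-person
  sessions ran five trials; truncation equates the protocols).
* **Modality post-hoc**: group models refit separately for in-person and
  remote participants, plus a full-sample OLS with a group x modality
  interaction term (the exact post-hoc model is not pinned by the
  protocol; the interaction model is this package's choice).
* **Confounds / classification**: per demographic factor (age, sex, race,
  first language), a regression of the factor on the log measure — OLS
  for continuous factors, logistic for categorical ones (non-binary
  factors are binarised to most-frequent-level vs. rest). Classification
  is a univariate logistic regression of group on the log measure scored
  by leave-one-out (LOO) accuracy. Note a known LOO artifact: with
  balanced groups and a signal-free feature, the held-out sample is
  always in the training minority, so accuracy falls *below* 50% under
  the null; the test suite asserts "no better than chance" accordingly.
* **Power**: Fisher-z approximation for a two-sided test of a Pearson r,
  with the small-sample correction:
  `required_n = ceil(((z_{1-α/2} + z_power)/atanh(r))² + 3)` and
  `minimal_r = tanh((z_{1-α/2} + z_power)/sqrt(n-3))`. At r = 0.37,
  α = 0.05, power = 0.80 this gives N = 56; at n = 50 the minimal
  detectable r is 0.387. This convention (power 0.80) is pinned because it
  reproduces both numbers simultaneously; other conventions are available
  through `PowerSpec`.

## The synthetic cohort generator

The generator exists so every pipeline stage can be exercised and
calibrated without clinical recordings. It emulates:

* **Task structure** exactly (trial counts, syllables per trial, phrase
  structure for READ/SPONT).
* **Variability targets**: for each controlled measure x task, a
  per-participant target is drawn from group anchors (mean,
  between-participant SD); defaults are plausible clinical/control values
  for each task (e.g. AMR voiceless-VOT CoV 0.31 (0.09) CHR vs.
  0.27 (0.10) HC). Token durations are then drawn log-normal with the σ
  that realises the target, via CoV = √(exp(σ²) − 1). Targets are floored
  at 0.02 (20 Hz for dispersion targets). The anchors describe *measured*
  per-participant CoVs, so the target-draw SD is deflated by the expected
  CoV-estimator sampling noise (≈ c²(1/(2(n−1)) + c²/n) over n tokens);
  realised between-participant SDs then match the anchors instead of
  over-dispersing — the effect is strongest for rate CoVs, which average
  over only ~9–20 phrases or trials.
* **Timelines**: DDK trial windows are set by a drawn per-trial rate;
  VOTs and vowels are drawn i.i.d. and intersyllable gaps absorb the
  remaining window time with the participant's gap-CoV spread, so windows
  tile exactly. READ/SPONT phrases are set by drawn per-phrase rates with
  equal sub-threshold slack between syllables (clamped to 4–120 ms so
  slack can never split a phrase); when a slow phrase needs more time
  than capped slack provides, segment durations stretch to absorb it, so
  the drawn rate is realised exactly. Supra-threshold pauses (≥ 155 ms)
  separate phrases. Because intersyllable gaps are rescaled within
  trials, the realised intersyllable CoV sits slightly above its nominal
  parameter; the directly controlled VOT, vowel and rate CoVs are
  unbiased, which is why calibration anchors on them.
* **A latent motor factor** m ~ N(0,1) per participant: it is expressed
  *exactly* in the participant's voiceless-VOT CoV target (z-score equal
  to m) and, with configurable correlation ρ (default 0.37), in the
  tapping CoV; SIPS scores load weakly (0.20) on m for CHR participants.
  Tapping trials are three integer counts per hand constructed to realise
  the drawn CoV (base ≈ 65 taps/10 s; CoV mean 0.07, SD 0.035 — kept well
  away from zero so integer rounding and flooring cost at most ~1% of the
  correlation). ρ is defined against the participant's CoV *value*;
  correlations measured through noisy token-level estimates are
  necessarily attenuated below ρ.
* **Demographics and modality** from realistic cohort frequencies; risk
  scores confined to 0.8–10.1% (CHR only). An optional remote-HC
  inflation factor (> 1) scales remote controls' variability targets to
  emulate noisier remote recordings; it defaults to 1.0 so that default
  cohorts realise the pooled anchors exactly.
* **Determinism**: every participant consumes an independent
  `SeedSequence` substream keyed by (seed, participant index), so cohorts
  are byte-reproducible from (config, seed) and deleting one participant
  leaves all others unchanged.

Deliberate simplifications: one participant set per cohort (no per-task
attrition by default); all voiceless stops share one VOT mean per task
(place-of-articulation differences would inflate pooled CoVs above their
targets); speech measures are conditionally independent given the latent
factor; no demographic-measure dependence. Passing calibration therefore
shows the *pipeline* is correct and well-calibrated under the assumed
generative structure — not that real recordings satisfy that structure.

## Calibration battery (`speechvar.calibration`)

Replicate counts were sized to give tight Monte-Carlo error while staying
desk-scale; each routine takes a seed and scales linearly if more
precision is wanted:

* **Type-I error**: 1000 null AMR-only cohorts (30 + 30): group-model
  rejection rate vs. the 95% binomial envelope of α = 0.05.
* **Parameter recovery**: 200 AMR cohorts at 51 + 53: across-replicate
  mean of each group's realised voiceless-VOT CoV vs. the generating
  anchors (±0.02), and the sign of the group difference.
* **Latent recovery**: 1000 CHR-only clinical cohorts (n = 50) at
  ρ = 0.37: mean Pearson r between speech-CoV values and dominant-hand
  tapping CoV (expected slightly below ρ: ≈ −0.003 small-sample bias of r̂
  at n = 50, ≈ 1% integer-rounding loss).
* **Sign pattern**: 100 default four-task cohorts: CHR > HC group means
  for voiceless-VOT CoV and rate CoV in AMR/SMR/READ (each contrast,
  per-replicate), and a non-significant spontaneous-speech VOT contrast.
* **Classification**: LOO accuracy of the univariate classifier on READ
  cohorts, landing modestly above chance at the configured subtle effects.

## Numerical choices

* Sample SD everywhere (ddof = 1).
* Interval comparisons use 1e-9 s tolerances; phone adjacency uses 1 ms.
* CSV and TextGrid writers emit shortest round-tripping decimal floats
  (`repr`), and the CSV reader parses with correctly-rounded `float()`,
  so write→read is bit-identical and golden files are byte-stable.
* Overlap ties (a token exactly equidistant between centroids) resolve to
  the token's own category.
* Report bundles contain no wall-clock state; identical (config, seed)
  runs are byte-identical.

## Limitations

* The dispersion/overlap/pause definitions are reconstructions (see
  above); absolute values are comparable within this package, not
  necessarily across toolchains.
* The syllable-initiality proxy can disagree with dictionary
  syllabification for medial clusters (e.g. it treats a post-vocalic
  medial stop as an onset even where a dictionary would not).
* CoV estimates from few tokens are noisy and slightly downward-biased;
  the min_n floor mitigates but does not remove this.
* The generator's independence and log-normality assumptions are
  conveniences, not claims about speech; see the simplifications above.
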