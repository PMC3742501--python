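# Methods

This note documents the models and procedures implemented in
`pigletcalls`, the choices made where the design was genuinely open, and
what the synthetic data does and does not establish.

## Acoustic analysis

Calls are annotated as half-open intervals `[start_s, end_s)` in seconds
from file start. Analysis uses a Hamming window of 1024 samples at
44 100 Hz (≈23 ms), 87.5 % overlap (128-sample hop), giving a 43.07 Hz
frequency grid. The entire-call spectrum is the average magnitude spectrum
over all analysis frames fully inside the call; averaging (rather than a
single long transform) keeps the frequency grid fixed across calls of any
duration. A call must span at least one analysis window.

* **q50** — cumulative energy (amplitude squared) is scanned from 0 Hz;
  q50 is the centre of the first bin at which it reaches half the total.
  First-crossing with no interpolation keeps the statistic bin-exact and
  deterministically testable. q50 is translation-equivariant: shifting all
  energy up m bins raises q50 by exactly m bins.
* **pf** — centre of the maximum-amplitude bin, ties to the lowest
  frequency.
* **ent** — Wiener entropy, geometric/arithmetic mean of the amplitude
  spectrum, 0 for one spectral component, 1 for a flat spectrum. The raw
  value grows with signal bandwidth, so the reported feature is computed
  on the spectrum truncated at 2·q50, which removes the bandwidth
  dependence using only in-call quantities; the raw full-band value is
  stored alongside. This truncation rule is this package's own
  bandwidth correction; tools differ in how they implement the
  correction, and the cut at twice the median frequency was chosen
  because it adapts per call and needs no external reference bandwidth.
  Note the raw full-band entropy of a *band-limited* noise call can fall
  below that of a harmonic stack — the corrected `ent` restores the
  expected tonal < noisy ordering.
* **Measurement windows** — 11 positions at the call start and then every
  dur/10; the first and last are discarded and the retained 9 (indexed
  1..9, symmetric about the call midpoint) are each analysed as the single
  23 ms frame centred on the position. `q50start`/`q50end`/`q50min` and
  the location of the maximum (`q50maxloc`, ties to the earliest window)
  summarise frequency modulation. For calls barely longer than one window
  the positions nearly coincide; this is logged, not an error.
* **Standardization** — per-variable z-scores with the sample SD (ddof=1);
  the transform is stored so held-out calls can be projected consistently.
* **Screening** — greedy removal: while any retained pair has |r| > 0.9,
  the later-listed variable is dropped. On the default synthetic
  repertoire this removes `q50min` (r ≈ 0.93 with `q50start`).

No filtering is applied to recordings; annotation quality control is the
annotator's responsibility.

## Repertoire clustering

k-means is implemented locally (Lloyd's algorithm) so every policy is
explicit and seed-deterministic: 50 restarts per K with initial centroids
drawn without replacement from the data; an emptied cluster is reseeded
from the point farthest from its assigned centroid; ties in assignment
break to the lowest cluster id. Each K additionally tries a warm start
that splits the best (K−1) solution at its worst-fit point, which
guarantees WSS is non-increasing in K, hence PreK ≥ 0 and EtaK monotone.
The validity indices satisfy the telescoping identity
1−EtaK(K) = Π_{j=2..K}(1−PreK(j)) exactly (to float round-off), which the
tests assert at 1e-9.

Cluster naming at K=2 is by mean q50 (LF/HF). At K=5 the two highest-q50
clusters are HF — the more frequency-modulated one (|q50end−q50start|)
HFm, the other HFs; among the LF clusters the lowest-entropy one is LFt,
the most modulated of the rest LFm, the remainder LFs. Other K get
generic names with a warning. Representative calls are the members
nearest their centroid (ties to the lowest call id).

Discriminant-function loadings of clusters come from the generalized
eigenproblem of between- vs within-cluster scatter; coefficients are
scaled by pooled within-class SDs so magnitudes are comparable across
variables.

## Classification and significance

LDA is the pooled-covariance Gaussian discriminant with priors
proportional to training class frequencies (configurable to uniform) and
deterministic ties to the earlier class. Call-type indicator predictors
have a singular covariance by construction, so a ridge of 1e-8 is added
for that input mode.

Cross-validation is the half-split holdout: a random half fits the
discriminant, the other half is scored. The split is re-drawn (up to 100
attempts) until every class has at least two calibration calls and one
validation call. Significance:

* **Call-level permutation** — labels are permuted across calls *before*
  the split and the split is re-drawn per permutation (1000 by default);
  chance level is the null mean accuracy and
  p = (1 + #{null ≥ observed}) / (n_perm + 1), which cannot be zero.
* **pDFA** — the permutation unit is the subject. Subjects must be nested
  in situations; piglets recorded in two situations are entered as two
  piglet-situation subjects, which preserves the nesting the permutation
  scheme needs. The statistic is subject-level holdout accuracy (whole
  subjects assigned to calibration or validation), and the null permutes
  the subject-to-situation assignment while keeping each situation's
  subject count. Calibration experiments (200 null datasets, 199
  permutations) show the call-level test over-rejects when subject
  effects are injected while pDFA holds its level.

MANOVA uses Wilks Λ = det(W)/det(T) with Rao's F approximation.

The multi-call simulation draws n = 1..20 calls per situation *without
replacement* (the sensible choice when a receiver hears distinct calls),
averages them (mean features, or call-type proportions), refits the
discriminant on all non-drawn calls and classifies the averaged samples;
10 inner draws per outer repetition, 20 outer repetitions, normal 95% CI
over outer means. Situations with fewer than 20 calls (surprise, n=18)
are excluded with a warning. Note the discriminant is trained on single
calls but applied to averages, exactly as in the field's practice; the
mismatch is part of the procedure being modelled.

## Situation-level statistics

Situation profiles are per-situation mean feature vectors (natural units)
or call-type proportion vectors. Dendrograms use Ward linkage on
Euclidean distances (scipy), serialized to Newick with branch lengths
from merge heights; cophenetic distances round-trip through the tree.

The call-type × situation association uses the Pearson chi-square when
all expected counts are ≥ 5, otherwise a Monte-Carlo chi-square with
2000 tables resampled with both margins fixed. Pearson residuals
(obs−exp)/√exp are flagged at the conventional evidence tiers > 2 and
> 4.

Valence is the mean expert negativity rank (1 = most negative) over a
panel of 28 simulated experts. Spearman correlations of mean acoustics
with valence use exact permutation p-values for S ≤ 8 situations and a
seeded 10 000-draw Monte-Carlo permutation p for larger S (full
enumeration at S = 11 would need ~4·10⁷ evaluations per variable; the MC
standard error ≈ 0.003 is negligible relative to the decisions taken).
Call-type proportions are regressed on valence rank with a logit-link
binomial GLM weighted by situation call totals; overdispersion is
estimated as Pearson χ²/df and the slope tested by a drop-in-deviance F
on (1, S−2) df — with 11 situations that is the F with 9 denominator df.
All-zero or all-one proportion series are flagged as separation and
reported with a warning rather than dropped. Benjamini–Hochberg step-up
FDR is applied within each analysis family (the 8 correlations; the set
of type regressions) by default.

## Synthetic data

The generator emulates the study's structure: 11 situations with the
study's call/piglet/litter counts (1513 calls, 84+ piglets, 34 litters at
the situation level), five latent call types, situation-specific type
mixtures, and additive per-piglet and per-litter Gaussian effects.

* **Primary path (feature space).** A call of type t in situation s is
  `mean_t + piglet_offset + litter_offset + noise`, with offsets scaled as
  fractions (defaults 0.3 and 0.15) of the pooled within-type SD.
  Sampled vectors are pushed back into the feasible region (frequencies
  ≥ one bin, ent in [0,1], dur ≥ 0.034 s, q50maxloc rounded into 1..9,
  q50min ≤ min(q50start, q50end)). True type labels are retained.
* **Prototypes.** The five defaults follow the qualitative repertoire
  profiles: HF types higher-pitched and longer than LF; HFm strongly
  rising; LFt the most tonal LF type; LFs lowest and least modulated.
  Their SDs are set so the default repertoire is *blurred* — clusters
  overlap, as in the real repertoire; `sd_scale` shrinks them for
  recovery experiments (0.15 gives between-type separation well beyond
  6× the within-type SD).
* **Mixtures.** `DEFAULT_MIXTURES` concentrate HF types in
  life-threatening situations, LFt around nursing and LFs/LFm in other
  social situations, with deliberate overlap between situations of the
  same category. `CONTRAST_MIXTURES` (`recovery_design()`) is the
  separable variant for method validation: each gross category owns a
  disjoint dominant-type set and situations within a category divide that
  set distinctly, so pooled-call classification has signal to find.
* **Waveform path.** For end-to-end testing of the acoustic stage, calls
  are synthesized as a harmonic stack (amplitudes 1/h, fundamental
  sweeping linearly f_start→f_end) mixed with band-limited noise at the
  prototype's tonal fraction, edge-tapered, embedded in silence, written
  as PCM-16 WAV with a matching annotation table.
* **Expert ranks.** Each simulated expert perturbs the true valence order
  by independent adjacent transpositions (probability 0.15 per adjacent
  pair, one pass); 28 experts give mean ranks that correlate with truth
  at ρ > 0.9.

**What passing tests show — and don't.** Recovery results (PreK peak at
K=5, ≥95 % label agreement, rising accuracy curves) hold on the separable
synthetic regime and demonstrate that the *methods* detect structure that
is present; they do not show that real piglet repertoires are this
separable — the default blurred regime, like the real data, yields
overlapping clusters and much flatter accuracy curves. Two structural
limits of the generator matter when reading results: situation identity
enters the features only through the type mixture and the individual
effects, so situations with similar mixtures stay confusable at any
number of pooled calls (real calls also carry within-type situational
detail); and feature vectors are Gaussian around prototypes, without the
skew and hard physical bounds of measured acoustics.

## Numerical and reproducibility choices

All randomness flows from named seeds through `numpy` `SeedSequence`
spawning; identical configurations reproduce every table bit-identically.
Tie-breaks (cluster assignment, class prediction, representative calls,
peak bins, window maxima) are deterministic toward the lowest index. The
pipeline writes a JSON run report with versions, per-stage seeds,
settings and timings. Problem sizes in the validation suite (e.g. 200
replicate null datasets with 199 permutations; 60-call null datasets;
accuracy curves on a coarse n-grid) were chosen to give stable binomial
intervals while keeping the whole suite quick on a single CPU.

## Known limitations

* The entropy bandwidth correction is a documented stand-in for
  tool-specific variants; absolute `ent` values are comparable within
  analyses run with this package, not across tools.
* pDFA here uses subject-level holdout accuracy as its statistic; other
  formulations cross-validate subject-by-subject. Level and power are
  validated by simulation in the test suite.
* The quasi-binomial F uses residual df S−2 under the 2-parameter model.
* The multi-call simulation trains on single calls and scores averages;
  its accuracy therefore has no oracle guarantee of monotonicity in n —
  monotonicity is checked empirically on separable data.
* Expert-rank confidence intervals use the normal approximation, which is
  crude for near-unanimous panels (width collapses to 0).
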