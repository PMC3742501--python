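# pigletcalls

Quantitative analysis of the pre-weaning domestic-piglet (*Sus scrofa*)
vocal repertoire: is it a set of discrete call types or a graded continuum,
and how much does a call reveal about the situation in which it was emitted?

The package implements the full analysis chain for a repertoire study of
1513 calls recorded in 11 behavioural situations (castration, crushing,
being held, fighting for a teat, before/after/missed nursing, huddling,
isolation, reunion, surprise), grouped into three gross categories
(life-threatening / nursing-related / general social), plus a synthetic-call
generator so the whole chain is testable with known ground truth. It is
aimed at bioacousticians and animal-welfare researchers who want a
reproducible, end-to-end version of this style of repertoire analysis.

## What it computes

**Acoustic description.** Each annotated call is summarised by 8 variables
from Hamming/1024-FFT/87.5 %-overlap spectrograms at 44.1 kHz: peak
frequency `pf`, median frequency `q50` (the frequency splitting spectral
energy in half), bandwidth-corrected Wiener entropy `ent`, the q50
trajectory over nine regularly spaced measurement windows (`q50start`,
`q50end`, `q50min`, `q50maxloc`) and duration `dur`. Variables are z-scored
and screened for pairwise correlation |r| > 0.9.

**Repertoire structure.** k-means for K = 1..15 with the validity indices

    EtaK = 1 - WSS_K / WSS_1,    PreK = 1 - WSS_K / WSS_{K-1},

where `WSS_K` is the within-cluster sum of squares. The repertoire is
characterised at K = 2 (low- vs high-frequency calls, LF/HF) and K = 5
(LFs, LFm, LFt, HFs, HFm), with representative calls, cluster nesting and
discriminant-function loadings.

**Situation classification.** LDA (pooled-covariance Gaussian classes)
from acoustic variables or 0/1 call-type indicators, cross-validated by
half-split holdout, judged against a 1000-fold label-permutation null and
against pDFA (permutation at the piglet level, controlling
pseudo-replication), plus a Wilks-lambda MANOVA. A leave-sample-out
simulation measures accuracy from 1..20 pooled calls per situation, for
the 11-situation and the 3-category targets.

**Situation-level statistics.** Ward/Euclidean dendrograms of situation
profiles (Newick output), call-type x situation chi-square with Pearson
residual tiers |r| > 2 and |r| > 4 (Monte-Carlo chi-square when expected
counts drop below 5), Spearman correlations of mean acoustics with expert
negativity ranks, and quasi-binomial (logit link, Pearson-dispersion
F-tests) regressions of call-type proportions on valence rank, with
Benjamini-Hochberg FDR control.

## Worked example

```python
import pigletcalls as pc

design = pc.default_design()            # 11 situations, 1513 calls (study design)
calls = pc.generate_feature_dataset(design, pc.default_prototypes(), seed=1)

retained, dropped = pc.screen_variables(calls[pc.FEATURE_NAMES])
Z, scaler = pc.standardize(calls[retained])
curve, solutions = pc.validity_curve(Z.to_numpy(), Kmax=8, n_restarts=20, seed=3)
print(curve.as_frame().round(3).head(6).to_string(index=False))

report = pc.permutation_significance(
    Z.to_numpy(), calls["situation"].to_numpy(), n_perm=199, seed=5
)
print(f"single-call accuracy {report.percent_correct:.1f}% "
      f"(chance {report.chance_percent:.1f}%, p={report.p_value:.4f})")
```

prints (for these seeds)

```
 K       wss  etaK  preK
 1 10584.000 0.000   NaN
 2  4757.005 0.551 0.551
 3  3647.596 0.655 0.233
 4  2718.193 0.743 0.255
 5  2264.888 0.786 0.167
 6  2107.563 0.801 0.069
single-call accuracy 30.8% (chance 16.4%, p=0.0050)
```

The 2-cluster partition already removes ~55 % of the within-cluster
variance (the LF/HF split); EtaK gains flatten beyond K = 5. A single
call identifies its situation far above the permutation chance level
(~31 % against ~16 % chance across 11 situations).

The full pipeline (simulate -> cluster -> classify -> accuracy curves ->
similarity -> association -> valence) runs from the command line:

```bash
pigletcalls run-all --out run1 --seed 1
pigletcalls fixture          # the 11-situation study-design table
```

and writes delimited tables, Newick dendrograms and a JSON run report with
every seed and setting; re-running a config reproduces all tables
bit-identically.

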