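# Methods

This note documents the models, numerical choices and limitations of the
package; the README gives the overview and a worked example.

## Signal model and preprocessing

A raw recording is a uniformly sampled pupil-size series in EyeLink
arbitrary units (a.u.), with `0.0` meaning the pupil was not detected.
Recorder event lines (including the recorder's own EBLINK labels) are
discarded: blinks are re-detected from the zero spans themselves, because
vendor labels can mark anything from 10 ms glitches to 30 s closures as
"blinks".

Zero spans are partitioned by duration with inclusive blink bounds:
spans < 40 ms are tracking glitches, spans of 40–400 ms are blinks
(onset = first zero sample; a span of exactly 400 ms is a blink), spans
> 400 ms are eyelid closures. 500 Hz runs are up-sampled to 1 kHz by
midpoint interpolation that never crosses a zero span, so blink onsets
and durations are preserved exactly.

**Interpolation.** Blink spans and glitches are replaced by a cubic
spline fit through 4 context samples per side at 10 ms spacing, taken
beyond a guard margin (40 ms before onset, 80 ms after offset) that
skips eyelid-edge transients; the guard region is replaced along with
the gap. Gaps without usable context (run edge, neighbouring missing
data) stay missing and are counted. Interpolated values below zero are
clipped at 0 and counted. Closures are never spline-reconstructed: they
stay flagged in a missing mask that travels with the trace. Their
*values* are, however, bridged linearly before filtering — a 0-valued
cliff of several hundred a.u. would otherwise ring through the band-pass
far beyond the masked span. All of these offsets are config-exposed.

**Filtering.** The band-pass (0.02–4 Hz) is a windowed-sinc FIR built as
the difference of two unity-DC-gain Hamming low-passes (4 Hz minus
0.02 Hz), giving exactly zero DC gain; 30001 taps at 1 kHz (the
0.02 Hz edge is then ~0.4 at the cutoff and < 1% by 0.01 Hz after
forward-backward application). It is applied forward-backward
(zero-phase) in the frequency domain — multiplication by |H|² with
odd-reflection padding of one filter length — which is mathematically
the same as `filtfilt` with this symmetric kernel but O(N log N).
Traces must be at least 3 filter lengths long (≥ ~90 s at defaults).
Decimation to 100 Hz keeps every 10th sample; the missing mask is
OR-reduced over each 10-sample block.

**Classification and run measures.** Vigilance is classified on the raw
trace from the zero-sample fraction: < 10% vigilant, 10–40% drowsy,
40–75% very drowsy, > 75% discarded (vigilant and discarded edges
strict); drowsy and very drowsy runs are merged as "all drowsy" for
analysis. Blink rate divides the blink count by eyes-open minutes:
total time minus closure time, with blink spans counted as open time (a
blink is an open-eye behaviour; switchable). Mean pupil size is computed
on raw nonzero samples — the band-passed trace has no DC, so the tonic
level must come from the raw series.

## BIPR

Epochs span −2 to +3 s around each blink onset on the 100 Hz trace (501
samples at exactly 10 ms). Baseline is the mean of non-missing samples
in [−200, 0) ms; an epoch with an entirely missing baseline is rejected,
as is any epoch with strictly more than 40% missing in (0, 3] s. Epochs
crossing run edges are dropped; overlapping epochs from rapid blink
trains are kept. The run waveform is the pointwise mean over non-missing
values; its six features are: D = maximum over (0, 0.9] s, C = minimum
over (d_time, 2.5] s (windows config-exposed; earliest sample wins
ties), their amplitudes, time difference and peak drop. A waveform with
non-positive D or non-negative C amplitude is flagged atypical rather
than erroring. Outliers in any dependent measure are masked per measure
within each vigilance state when outside Q1 − 2·IQR .. Q3 + 2·IQR
(linear-interpolation quartiles); the scope is config-exposed because
reasonable analyses differ here.

## Reliability

ICC(2,k) is computed from the two-way ANOVA mean squares,
`(MSR − MSE) / (MSR + (MSC − MSE)/n)`. Balanced matrices use the exact
decomposition (verified against an explicit sum-of-squares oracle and
against pingouin's ICC(A,k) to 1e−10). Unbalanced matrices — subjects
contributing different run counts — use unweighted subject/run means
with k the harmonic mean of per-subject counts, and the
variance-component form with negative mean-square differences truncated
at zero so the estimate stays in [0, 1] even for a handful of subjects;
this is an approximation and is documented as such. Within-subject
reliability z-scores each measure over all runs of a state (pooled —
per-subject scaling would destroy the between-run variation being
correlated), then averages the per-subject Pearson correlations over all
run pairs.

## Twin models

Phenotypic variance is decomposed into additive genetic (A), shared
environment (C) or dominance (D), and unique environment (E). MZ pairs
share A (and D) fully; DZ pairs share A at 0.5 and D at 0.25; C is
common within every pair; E is independent. The family is chosen from
observed correlations: r_MZ > 2·r_DZ → ADE, otherwise ACE (equality →
ACE); DE is never fit. Models assume a common mean across zygosities and
twin order; pairs enter as given (no double entry; switchable), complete
pairs only.

Fitting maximizes the bivariate-normal likelihood over (μ, paths); paths
are squared into components so nonnegativity holds by construction, and
|e| is floored at 1e−6 of the phenotypic SD to keep Σ nonsingular on
degenerate data (e.g. literally identical twins). The optimizer is a
deterministic multi-start (method-of-moments start, equal-split start,
seeded perturbations), BFGS followed by a Nelder–Mead polish; repeated
fits agree to 1e−10. The saturated reference model has 6 parameters
(per-zygosity common mean, variance, covariance; closed-form ML =
sample moments with ML normalization). Selection drops one path at a
time, retaining it iff the likelihood-ratio χ² is significant at 0.05;
the non-nested AE vs CE choice uses AIC = χ²(vs saturated) −
2·df(vs saturated) as printed in the source analysis (a −2LL + 2k
variant is available behind a flag). Profile-likelihood CIs constrain a
standardized component, refit the free parameters, and bracket the
−2LL rise of 3.841 by Brent's method; bounds are clipped to [0, 1] and
flagged when unbracketed. Twin-correlation p-values are one-sided
(t = r√(df/(1−r²)), df = pairs − 2).

## Synthetic data

The pupil generator emulates: a tonic level (default 800 a.u.),
Gaussian noise low-passed at 4 Hz so it survives the pipeline's
pass-band (default SD 5 a.u.), an optional sub-0.02 Hz sinusoidal drift
(used to test the high-pass), Poisson blink counts (default 15/min,
durations 100–300 ms) and closures, and an additive BIPR kernel at each
blink onset: a positive Gaussian lobe (default +30 a.u. at 500 ms, SD
150 ms) plus a negative one (−20 a.u. at 1 s, SD 250 ms). Amplitudes are
free parameters: the source recordings are in uncalibrated EyeLink
units. Zero spans are imposed *after* kernel injection, so the kernel's
first ~100–300 ms is occluded by the blink, as in real data. Events are
placed with a 1 s minimum inter-event guard by the exact constructive
sampler for a count-conditioned homogeneous Poisson process (uniform
order statistics over the slack); infeasible demand raises.

Two consequences matter for validation. First, the two lobes overlap,
so the *summed* kernel's maximum sits slightly before the D-lobe center
and its minimum slightly after the C-lobe center; recovery checks
compare against `kernel_peaks()` (extrema of the summed kernel under
the same search rule), not the lobe centers. Second, at realistic noise
the C trough is flat enough that single-run argmin jitter spans several
10 ms samples — exactly the run-to-run variability the reliability
analysis quantifies. Systematic pipeline accuracy is therefore verified
on low-noise runs (SD 0.5 a.u.), where recovered peak times match the
kernel extrema to within one 100 Hz sample (median across a 100-subject,
300 s-run cohort) and amplitudes to within 5% at sparse blink rates.

The twin generator draws component deviates with the exact correlation
structure above; sample covariances match the populations within 3
standard errors at 50,000 pairs for every family. The multi-run
generator is `y = mean + subject + run + error` with chosen variances;
its population ICC(2,k) is the closed form
`var_subject / (var_subject + (var_run + var_error)/k)`.

What the generators do not emulate: gaze-dependent pupil foreshortening,
the pupillary light reflex, slow vigilance drift within a run,
non-Gaussian sensor noise, or any coupling between blink rate and pupil
size beyond the injected kernel. Passing tests therefore show the
estimators are correct under the stated generative models, not that the
physiological claims hold in new data.

## Problem sizes

Simulation sizes were chosen so each experiment is statistically
decisive at desk scale: twin recovery uses 2,000 pairs per zygosity with
8–20 replicates (Monte-Carlo SE of the mean ≈ 0.005, against ±0.02
tolerances); correlation recovery uses 50,000 pairs (SE ≈ 0.003); ICC
recovery uses 2,000 subjects × 3 runs × 10 replicates, with the
non-subject variance split 20% run / 80% residual (the run-effect
variance is the dominant noise term in the ICC estimate, with only k−1
degrees of freedom per replicate); the end-to-end cohort is 100 subjects
× 2 runs of 300 s.

## Known limitations

- Unbalanced ICC is an approximation (see above); the exact REML
  two-way fit is out of scope.
- Complete-pair ML only; no FIML for incomplete pairs, no sex-limitation
  or multivariate twin models, no extended pedigrees.
- The state comparison is a plain one-way ANOVA on dual-state subjects,
  as in the source analysis; a repeated-measures variant exists behind a
  flag but no mixed-effects modeling.
- Whether vigilance thresholds should apply before or after edge
  trimming is unspecified upstream; classification here uses the full
  raw run.
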