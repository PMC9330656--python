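# rtquic

Analysis of seed-amplification assay (RT-QuIC) fluorescence kinetics and the
diagnostic accuracy of α-synuclein seeding tests, built around the published
protocol for olfactory-mucosa (nasal swab) and CSF testing in Parkinson's
disease.

In RT-QuIC, misfolded α-synuclein in a patient specimen templates the
conversion of recombinant substrate into amyloid fibrils; fibril formation is
read out as Thioflavin-T (ThT) fluorescence over repeated shaking/rest cycles
(readings every 45 min). A seeding-positive well shows a sigmoidal trace — a
lag phase, exponential growth, then a plateau — while a negative well stays
at baseline noise. This package implements the full decision procedure that
turns raw plate-reader traces into per-sample positivity calls, and the
statistics used to compare those calls between specimen types.

## What it computes

**Trace processing and calling** (`rtquic.kinetics`), per run:

1. *Baseline*: for each sample, the mean rfu over the contiguous 10-h window
   minimizing the mean of the replicate-averaged trace; subtracted from every
   replicate reading (negatives floored at 0).
2. *Normalization*: readings expressed as percent of the maximum
   baseline-adjusted rfu in the run (percent of each sample's own maximum is
   available for figure-style plots).
3. *Thresholds*: the 20%-of-maximum positivity line, and a noise threshold
   mean + 3 SD of all normalized readings between 15 and 17 h. The default
   effective threshold is the larger of the two.
4. *Calling*: a replicate crosses if any reading at ≤ 80 h reaches the
   threshold; its lag time is the first such reading. A sample is positive
   when ≥ 2 of its 4 replicates cross.

**Diagnostic accuracy** (`rtquic.diagnostics`): exact 95% Clopper–Pearson
CIs for sensitivity/specificity; two-sided Fisher's exact test (point
probability method) and Cramér's V
(`|ad − bc| / √(r₁r₂c₁c₂)`) for unpaired 2×2 tables; exact two-sided McNemar
(`p = min(1, 2·P(X ≤ min(b,c))), X ~ Bin(b+c, ½)`) and Cohen's
κ = (p_o − p_e)/(1 − p_e) with the Fleiss–Cohen–Everitt asymptotic SE for
paired tables; OR-rule combination of two tests per subject.

**Synthetic cohorts** (`rtquic.synthetic`): a seeded generator of logistic
seeding traces with group-level lag/plateau distributions, per-replicate
conversion probabilities back-solved from sample-level positivity targets
(84% agger-nasi PD / 45% middle-turbinate PD / 10% non-PD), flat noisy
negatives, and a ground-truth table recorded before noise is added — so the
whole pipeline is testable end to end without any external data.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1   # 288 traces, 72 samples
python analysis/02_call_positivity.py
python analysis/03_diagnostic_accuracy.py
```

Step 02 calls the simulated first-round cohort (32 AN-PD, 11 MT-PD, 29
non-PD subjects, 4 replicate wells each):

```
noise threshold: 0.522% | effective threshold: 20.0%
        n  called_positive  positivity_pct  agrees_with_truth
group
AN-PD  32               23            71.9                1.0
MT-PD  11                8            72.7                1.0
NONPD  29                2             6.9                1.0
```

`agrees_with_truth = 1.0` means every call matches the generator's
ground-truth label; the positivity percentages scatter around their
calibration targets (84/45/10%) with binomial noise at these group sizes.
Step 03 recomputes the study-level statistics from the published count
tables:

```
first round, AN vs MT in PD: Fisher p = 0.018, Cramér's V = 0.39
second round, paired AN vs MT: kappa = 0.19 (95% CI -0.10 to 0.49), exact McNemar p = 0.021
```

i.e. agger-nasi swabs detect seeding activity significantly more often than
middle-turbinate swabs (84% vs 45% positivity in PD), and the two sampling
sites agree only weakly beyond chance in paired testing. The same machinery
is available as a CLI (`rtquic simulate | call | stats | report`).

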