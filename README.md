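# froikit

Subject-specific functional-ROI analysis for task fMRI, built around the
false-belief ("Belief > Photo") localizer used to map the theory-of-mind
(ToM) network: right/left temporoparietal junction (RTPJ, LTPJ),
precuneus (PC), dorsal/middle/ventral medial prefrontal cortex (DMPFC,
MMPFC, VMPFC) and right superior temporal sulcus (RSTS).

The package is for researchers who want to compare groups — e.g.
neurotypical (NT) adults versus adults with autism spectrum disorder
(ASD) — not on voxelwise maps but on *per-subject functional ROI
parameters*: whether a region could be identified at all, its size, its
mean statistic, and its position. It implements the complete analysis
chain as tested, reusable code, together with a synthetic-cohort
generator so that every stage can be validated end-to-end without any
scanner data.

## What it computes

**Hypothesis spaces.** The cohort is split randomly into two halves
(group-balanced). A voxelwise one-sample random-effects t-map over each
half defines, per region, a "hypothesis space": the connected
suprathreshold cluster (p < 0.001) containing the region's canonical MNI
center, e.g. RTPJ at (54, −52, 23). Spaces built in one half are only
ever applied to subjects of the other half, keeping ROI definition
independent of the group map.

**Subject fROIs.** Within a hypothesis space, a subject's candidate
voxels are those significant at p < 0.001 (uncorrected, via the map's
df) lying in a connected cluster of ≥ 11 voxels. The fROI is grown from
the peak candidate: the peak plus all candidates within 9 mm that
connect to it. Five parameters are extracted (size, mean T, and the
T-weighted center of mass x/y/z), plus the binary found-flag.

**Reliability.** Each parameter's even-run/odd-run correlation across
participants is referenced to a permutation null (5,000 permutations);
a parameter is reliable when it beats 90% of the null.

**Group inference.** Per parameter, a GLM with nuisance covariates (age,
gender, group, modality, coil, stimuli per condition, words per
stimulus, task type; mean-centered, plus intercept — the nine-column
design). Continuous parameters use a Gaussian identity-link model
(t statistics); the found-flag a binomial logit model (normal-referenced
Wald statistics). Multiple comparisons use

    corrected p = 1 − (1 − p)^m,    m ∈ {6, 12, 54}

and evidence for the null is quantified with the JZS default Bayes
factor BF01 (Cauchy prior scale r = 1, effective N = n1·n2/(n1+n2)).
Collinearity is screened with Belsley condition indices and
variance-decomposition proportions; a 3-SD screen flags ASD subjects
outside the NT distribution.

**Nonparametric matched-sample tests.** In a pairwise-matched sample
(age ±5 y, IQ ±10, same gender and acquisition parameters), group mean
differences are tested per parameter with a t-test calibrated by 25,000
label permutations; all null p-values per region are pooled and the
empirical alpha is the (5/6)th percentile of the pool, so the chance of
*any* of the six parameters crossing it under the null is 5%. A variance
analogue uses the Ansari–Bradley rank test (found-flag omitted,
percentile 1%).

**Whole-brain split-half validation.** Voxelwise group-difference t-maps
at p < 0.001 in one half of the runs define clusters whose mean response
is then tested in the held-out half (p < 0.05, same direction);
independence is enforced structurally.

## Worked example

```python
import froikit as fk
from scipy import stats

# Corrected p for an IQ effect printed as t(74) = 3.35, m = 6:
p = 2 * stats.t.sf(3.35, 74)
print(round(fk.correct_p(p, m=6), 3))        # 0.008

# JZS Bayes factor for a group coefficient, t(455) = 1.030, n = 436/28:
print(round(fk.jzs_bf01(1.030, 436, 28, 455), 3))   # 4.049

# 99% CI recovered from a coefficient and its t statistic:
low, high = fk.conf_interval(0.101, 1.030, 455)
print(round(low, 3), round(high, 3))          # -0.153 0.356
```

The Bayes factor of 4.049 says the data favor "no group difference in
RTPJ mean T" four-to-one over a difference; the CI says any true group
difference in mean T is within ±0.36 T units with 99% confidence.

A full synthetic run, from cohort generation to all reports:

```bash
froikit all --out-dir out/
# or in Python
from froikit import PipelineConfig, run_pipeline
paths = run_pipeline(PipelineConfig(out_dir="out"))
```

This writes `cohort.csv`, per-subject fROI parameter tables
(`params*.csv`), `reliability.csv`, a Table-style GLM report (`glm.csv`
with beta, t, corrected p, 99% CI, group ns and BF01 per region ×
parameter), `permtest.csv`, `wholebrain.csv` and a reproducibility
manifest. Subcommands (`simulate`, `froi`, `reliability`, `permtest`,
…) run individual stages on existing files.

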