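# mixedbeam

Analysis of mixed-beam radiation experiments on human peripheral blood:
do simultaneous X-rays and alpha particles interact synergistically, or do
their biological effects simply add?

The package takes the two raw measurement tables such a study produces —
qPCR cycle-threshold (Ct) values for radiation-responsive transcripts and
per-metaphase chromosome/fragment counts — and carries them through relative
quantification, linear dose–response fitting, additivity analysis and
effect-size statistics. A synthetic-study generator with known ground truth
makes every stage testable end to end without access to donor data.

It is written for radiation biologists and biodosimetry statisticians
working with split-dose or mixed-field exposure designs.

## The model

Each collection (donor × season × week) exposes blood to X-rays, alpha
particles or a 1:1 mixed beam (MB, half the dose each) at 0, 0.5, 1 and
2 Gy. Every endpoint is fitted linearly per collection:

- **Chromosomal aberrations** (objects counted in excess of the diploid 46
  per metaphase, per 100 cells): `Y = intercept + slope·D`, free intercept,
  because each collection has its own basal fragment level.
- **Gene expression** (2^−ΔΔCt fold change vs the collection's 0 Gy
  control): `Y = 1 + slope·D`, anchored through 1 because the data are
  normalised to the control.

Under **simple effect additivity (SEA)** the expected mixed-beam (EMB)
response at total dose `D` with X-ray share `f` is the sum of the
single-beam effects at their component doses, which for linear responses
means an expected slope

    slope_EMB = f·slope_X + (1−f)·slope_α      (f = 0.5 here)

Synergy is the observed/expected ratio `slope_MB / slope_EMB`; a ratio
above 1 means the radiations interact super-additively. Relative
biological effectiveness is the slope ratio against X-rays,
`RBE = slope_test / slope_X`, the dose to reach a target effect is
`D = effect / slope`, and a mixed exposure's dose equivalent is
`H = Σ dose_i × RBE_i` (Sv). Weekly fits are the replicate unit: all
summaries (means ± sd, t-tests, Cohen's d with the
small/medium/large/very-large convention, Šídák-adjusted ANOVA contrasts)
are computed over the weekly slope or ratio values.

A second, qualitative question — does radiation quality change *which*
transcript variants a gene produces? — is answered by ratios of net
2^−ΔCt levels between two primer pairs per gene (FDXR PP1:PP2, CDKN1A
V1:V4, MDM2 315:303/304), compared across radiation groups.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_dose_response.py
python analysis/03_synergy_rbe.py
python analysis/04_alt_transcripts.py
```

The first driver generates a synthetic two-donor study with an interaction
factor of 1.4 (i.e. genuinely synergistic data); the others analyse it.
Step 03 prints, for example:

```
126 weekly MB:EMB ratios (126 defined)
pooled synergy: mean of weekly ratios 1.408, ratio of mean slopes 1.390 (generating interaction factor 1.4)
6/6 donor-seasons show a mean ratio > 1
```

Both pooled estimators recover the generating interaction factor 1.4: the
mean of the 126 weekly observed/expected ratios (1.408, slightly high
because the noisy expected slope sits in each denominator) and the
less-biased ratio of mean slopes (1.390). Step 02 prints the Table-1-style
aberration summary (pooled X-ray slope ≈ 29, alpha ≈ 83 per 100 cells/Gy,
i.e. an alpha RBE near 3), and step 04 lists which transcript-variant
ratios differ significantly between radiation qualities.

The same pipeline runs on real tables via the CLI:

```sh
mixedbeam analyze --ct-table ct.csv --metaphase-table metaphases.csv --out results
mixedbeam report --out results
```

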