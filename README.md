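# chronosurvey

Chronotype scoring, age/sex normalization and association analysis for
population sleep-timing surveys, with a solar-time module for evaluating
Standard Time (ST) vs Daylight Saving Time (DST) policy at a given latitude
and longitude.

## Who this is for

Circadian epidemiologists and survey scientists who collect sleep-timing
questionnaires (MCTQ-style items), self-assessed alertness intervals and/or
time-use diaries, and want a reproducible pipeline from raw instrument
files to population-level chronotype statistics.

## What it computes

**Chronotype from sleep timing.** From work- and free-day sleep onset
(preparation time + latency) and sleep end, the package derives sleep
durations SDw/SDf, the mid-sleep phases MSW and MSF (hours centred on
midnight), and the sleep-debt-corrected chronotype

```
SDweek = (WD·SDw + (7−WD)·SDf) / 7
MSFsc  = MSF − (SDf − SDweek)/2      if SDf > SDw,  else MSF
```

MSFsc is reported only for respondents who can sleep freely on free days
(no alarm, or waking before the work-day alarm).

**Chronotype from self-assessment.** BAmid, the midpoint of the reported
interval of highest cognitive alertness, taken along the forward arc so
intervals crossing midnight are handled.

**Chronotype from time-use diaries.** 48 half-hour slots covering
06:00→06:00; the longest run of sleep slots is the main sleep bout, bouts
truncated by the window are censored, and the bout midpoint gives a diary
MSF (free days) or MSW (work days).

**Age/sex normalization.** Population mid-sleep advances with adult age
following a one-phase exponential decay per sex,

```
MSFsc(age) = (Y0 − Plateau)·exp(−K·age) + Plateau
```

`ChronotypeDecayModel(age, msfsc).fit()` estimates (Y0, Plateau, K) by
multi-start bounded least squares and returns a results object with
standard errors, confidence intervals and `summary()`. Bundled reference
constants: men (9.62, 2.829, 0.067), women (10.69, 2.947, 0.089). Each
subject's MSFsasc — the hypothetical chronotype at age 30 — is
`msfsc − predict(sex, age) + ref30`; the lowest and highest MSFsasc
deciles are the *extremely early* / *extremely late* chronotypes.

**Association battery.** Pearson correlations (latitude, longitude,
settlement size, outdoor time, age, BMI in women), pooled-variance Student
t tests for binary factors (partner, childcare, dog ownership, smoking,
alcohol, fruit/vegetable consumption), one-way ANOVA with Tukey HSD
post-hoc contrasts, equal-count binned trend profiles with polynomial
fits, and HDL/LDL contrasts across extreme-chronotype categories.

**Solar time.** NOAA low-precision declination and equation of time;
sunrise/sunset at horizon altitude −0.833°; ST vs DST modelled as UTC+1 vs
UTC+2 local clocks; longitude gradients in sunrise time.

**Synthetic surveys.** `GeneratorConfig`/`generate` emit raw instrument
files (mctq.csv, alertness.csv, diary.csv, demographics.csv,
biomarkers.csv) from a configurable latent model — sex-specific age decay,
geographic/settlement/lifestyle effects, a correlated BAmid, and
chronotype-linked BMI/HDL in women — together with a row-aligned truth
table, so the whole pipeline is testable without survey data.

## Worked example

```python
from chronosurvey import MctqRecord, score_mctq, mctq_eligible, bamid

rec = MctqRecord(
    workdays_per_week=5,
    work_sleep_prep=22.75, work_latency=0.25, work_sleep_end=6.0,
    free_sleep_prep=23.25, free_latency=0.25, free_sleep_end=7.5,
    alarm_free=False,
)
s = score_mctq(rec)
print(f"SDw={s.sd_work:.2f} h  SDf={s.sd_free:.2f} h  SDweek={s.sd_week:.4f} h")
print(f"MSW={s.msw:.4f}  MSF={s.msf:.4f}  MSFsc={s.msfsc:.4f}  eligible={mctq_eligible(rec)}")
print(f"BAmid(9:00, 15:30) = {bamid(9.0, 15.5):.2f} h")
```

prints

```
SDw=7.00 h  SDf=8.00 h  SDweek=7.2857 h
MSW=2.5000  MSF=3.5000  MSFsc=3.1429  eligible=True
BAmid(9:00, 15:30) = 12.25 h
```

This respondent sleeps 23:00–06:00 on work days and 23:30–07:30 on free
days. Free-day mid-sleep is 03:30, but because free-day sleep is an hour
longer than work-day sleep, half the excess over the weekly average
(0.357 h) is treated as recovery from workday sleep debt, placing the
chronotype at MSFsc = 3.14 h after midnight. The alertness midpoint of a
9:00–15:30 interval is 12.25 h.

On the command line, the winter-solstice solar arithmetic for a central
European location (49°45′N 15°30′E):

```
$ chronosurvey solar --lat 49.75 --lon 15.5 --date 2016-12-21 --offset 1
sunrise 07:53  sunset 16:00  day length 8.11 h (UTC+1)
$ chronosurvey solar --lat 49.75 --lon 15.5 --date 2016-12-21 --offset 2
sunrise 08:53  sunset 17:00  day length 8.11 h (UTC+2)
```

Under yearlong Standard Time the mid-winter sun rises just before 8 a.m.
and sets at 4 p.m.; under yearlong DST both shift to 9 a.m. and 5 p.m.,
putting most of the morning commute in darkness.

Other subcommands: `simulate`, `score`, `diary`, `normalize`, `analyze`,
`run-all` (see `chronosurvey --help`).

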