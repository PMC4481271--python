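# iasfit

Personalized fitting and classification of prostate-cancer PSA dynamics
under intermittent androgen suppression (IAS).

## The problem

Intermittent androgen suppression cycles hormone therapy on and off, guided
by the PSA biomarker: treatment stops once PSA has fallen low enough for
long enough and resumes when it rises past a threshold.  Whether a given
patient benefits from cycling — relapse prevented, merely delayed, or
actually hastened compared with continuous suppression — depends on how his
tumor's androgen-dependent and castration-resistant cell populations grow,
convert and revert.  Those rates can be estimated by fitting a dynamical
model to a patient's PSA record, but a clinically useful estimate must come
from a *short* record, and a short record alone does not pin down 13
parameters.  The remedy implemented here is rapid learning: fit the whole
records of previously treated patients, summarize their fitted parameter
vectors as a multivariate-Gaussian prior, and estimate a new patient from
his first one and a half treatment cycles by maximum a posteriori (MAP)
optimization under that prior.

## The model and estimator

Three cell burdens (PSA-equivalent ng/mL) evolve by daily linear maps that
switch with the treatment flag: androgen-dependent cells x1 shrink under
therapy and leak into reversibly (x2) and irreversibly (x3) resistant
pools; off therapy, x1 regrows and x2 reverts.  Observed PSA is x1+x2+x3.
The combined parameter vector p (initial state plus ten coefficients) is
estimated by minimizing

    J(p) = 1/(2σ²) Σₖ (oₖ − ôₖ(p))²  +  ½ (p − p̄)ᵀ Σ⁻¹ (p − p̄)  +  Q(p)

— Gaussian-noise data misfit, cohort-prior quadratic form, and a penalty
Q(p) that adds 10000·(1−e) for every violated biological constraint margin
e (so any infeasibility drives the cost above 10000).  Minimization uses
seeded differential evolution with restarts.  A fitted vector is classified
by simulating intermittent and continuous futures: Type (i) if cycling
prevents relapse, Type (ii) if it delays relapse, Type (iii) otherwise.
Classifier cross-tabulations are compared with the exact conditional r×c
Fisher test (full enumeration of margin-consistent tables).

See `docs/methods.md` for model details, constraints, defaults and
limitations.

## Worked example

```python
import iasfit as F

# a synthetic patient: feasible parameters, trial-protocol schedule,
# PSA sampled every 4 weeks with 0.64 ng/mL noise
true = F.sample_params(seed=42)
obs = F.generate_patient(true, noise_sd=0.64, seed=7)

# a cohort prior (here from 60 cohort parameter vectors)
import numpy as np
rng = np.random.default_rng(0)
prior = F.build_prior([F.sample_params(rng) for _ in range(60)])

# MAP fit of the first one and a half cycles
short = F.truncate(obs, "one_and_half")
model = F.PsaTimeCourseModel(short, prior=prior)
result = model.fit(seed=1)
print(result.summary())
print("true type:", F.classify(true).type_label,
      " fitted type:", result.classify().type_label)
```

Output:

```
PSA time-course fit                          MAP (cohort prior)
==========================================================
observations:    46    schedule segments: 3
cost: 15.9345  (sse 12.1793 + prior 3.75524 + penalty 0)
feasible: True    rmse: 0.5146 ng/mL    nfev: 6885
----------------------------------------------------------
  x1(0)        7.174182
  x2(0)        0.508448
  x3(0)        0.054960
  d11_on       0.838556
  d21_on       0.044621
  d22_on       0.896093
  d31_on       0.002070
  d32_on       0.003264
  d33_on       1.004916
  d11_off      1.200000
  d12_off      0.039710
  d22_off      1.012781
  d33_off      0.997876
==========================================================
true type: ii  fitted type: ii
```

The cost decomposes into the three objective terms; `feasible: True`
(penalty 0, cost < 10000) certifies every biological constraint holds.  The
RMSE of 0.51 ng/mL is consistent with the 0.64 ng/mL observation noise, and
the patient's Type is recovered from 46 measurements spanning only the
first one and a half cycles.

The same pipeline is scriptable from the shell:

```bash
iasfit synth --n 36 --seed 0 --outdir cohort/
iasfit fit cohort/001.csv --seed 1 --out fits/001.dat
iasfit build-prior fits/*.dat --out prior.json
iasfit map-fit cohort/002.csv --prior prior.json --mode one_and_half \
    --seed 1 --out fits/map002.dat
iasfit classify --params fits/map002.dat
iasfit evaluate --counts table.json
```

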