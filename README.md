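# carkin — multiphasic CAR-T cell kinetics

`carkin` models the cellular kinetics of CAR-T cell immunotherapy in
hematological cancers. After infusion, the circulating CAR-T count follows a
characteristic multiphasic course — a brief **distribution** decline while
the infused bolus redistributes, an antigen-driven exponential **expansion**
to a peak, a steep **contraction**, and a shallow **persistence** tail that
can last years. `carkin` implements a phenotype-structured tumor–immune ODE
model of that whole course, an automated phase-slope calibration strategy,
patient-specific least-squares fitting, the kinetic outcome metrics used to
stratify therapy responses (per-phenotype AUCs, non-exhausted fraction,
peak, engraftment, theoretical relapse, CR/PR/SD/PD classification), and a
virtual-patient generator for validating the whole pipeline.

It is written for quantitative pharmacologists and mathematical oncologists
who fit cellular-kinetics models to sparse, censored clinical blood counts.

## The model

Five populations (cells), time in days:

```
dCD/dt = −(β + η)·CD
dCT/dt = η·CD + κ(t)·F(T)·CT − (ξ + ε + λ)·CT + θ·T·CM − α·T·CT
dCM/dt = ε·CT − θ·T·CM − μ·CM
dCE/dt = λ·CT − δ·CE
dT/dt  = r·T·(1 − b·T) − γ·f(CF, T)·T
```

`CD` are distributed (freshly infused) CAR-T cells, `CT` engrafted
effectors, `CM` memory, `CE` exhausted, and `T` tumor cells;
`CF = CD + CT` is the functional (cytotoxic) pool and `C = CD+CT+CM+CE` the
total CAR-T population measured in blood. The time-dependent expansion rate

```
κ(t) = r_min + p1 / (1 + (p2·t)^p3)
```

decays from `r_min + p1` to the basal rate `r_min`; antigen dependence is
`F(T) = T/(A+T)` and the cytotoxicity saturation is
`f(CF,T) = CF/(ϑ·T + a + CF)`. The expected number of engrafted cells for a
dose `D` is `EC = η/(β+η)·D`.

Each kinetic phase is dominated by one phenotype, so the log-linear slopes
of a patient's time course identify parameters directly:
`m_d ≈ −β`, `m_e ≈ r_min + p1 − ξ`, `m_c ≈ −δ`, `m_p ≈ −μ`.
These identifications seed the patient-specific fit.

## Worked example

Generate a virtual patient and calibrate the model to it:

```python
from carkin import SyntheticCohortConfig, generate_cohort, CARTKinetics

cfg = SyntheticCohortConfig(n_patients=4, seed=11)
records, truth = generate_cohort(cfg)

model = CARTKinetics(records[0])        # a durable responder (CR)
res = model.fit(seed=1, n_starts=3)
print(res.summary())
```

```
CAR-T kinetics fit
============================================================
patient: S01    disease: synthetic    dose: 1e+08 cells
observations: 11 (10 detectable)    threshold: 2.5e+06 cells
loss (sum sq log10): 0.1801    rmse: 0.134 dex    converged: True
------------------------------------------------------------
parameter       estimate    se (dex)  status
beta               0.652          --  fixed
...
p1                 2.637       0.137  free
lam               0.9074       0.423  free
mu               0.01491       0.453  free
delta             0.2248       0.137  free
...
------------------------------------------------------------
recorded outcome: CR    model at follow-up: PD
```

`beta` was fixed by the dose-anchored distribution-phase regression (the
first step of the multi-step calibration); the remaining rates were refined
by bounded multi-start least squares on the detectable observations. The
plain fit matches the kinetics (RMSE 0.134 dex against 0.2 dex measurement
noise) but, with the late dynamics unconstrained by censored data, predicts
relapse for this recorded complete responder — the mismatch is printed, not
hidden. Re-fitting with the outcome penalty
(`model.fit(..., outcome_weight=3.0)`) reproduces the recorded CR.

The kinetic outcome metrics:

```python
ks = res.kinetic_summary()
```

```
AUC 0-28 (total):        1.89e+10 cell*day
non-exhausted fraction:  0.259
peak: 2.74e+09 cells at day 7.8 (27.4x dose)
engrafted cells (EC):    1.53e+05
```

`AUC 0-28` is the total CAR-T exposure over the first 28 days; the
non-exhausted fraction is the share of that exposure carried by
distributed + effector + memory cells (jointly, these two quantities
separate response groups); the peak expanded 27-fold over the dose; of the
1e8 infused cells, about 1.5e5 engrafted.

A command-line interface mirrors the library:

```bash
carkin simulate --dose 1e8 --t-end 365 --out traj.csv
carkin phases   --input patient.csv --out phases.json
carkin fit      --patient patient.csv --meta patient.yaml --out fit.json
carkin synth    --out-dir cohort/ --seed 5
carkin pipeline --cohort-dir cohort/ --out-dir results/
```

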