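# hrubnet

Behavioral safety analysis for workplaces that monitor unsafe acts by
observation: **safety behavior sampling** (SBS) design plus a **discrete
Bayesian network** (BN) over worker and context variables, used to rank the
drivers of high-risk unsafe behavior (HRUB) — the observed acts capable of
causing immediate serious injury.

It is written for occupational-safety researchers and analysts who have (or
plan) an observation campaign and want a reproducible path from pilot counts
to a ranked list of intervention targets.

## What it computes

**Sampling design.** Work sampling treats each instantaneous observation as
a Bernoulli trial. From a pilot estimate p = N₁/N₀, the observations needed
for relative precision S at standard-normal multiplier K are

&nbsp;&nbsp;&nbsp;&nbsp;n = K²(1−p) / (S²p)

with the conventional K = 2, S = 0.05. Randomized schedules cover every
weekday and working hour.

**Network analysis.** A nine-variable BN (age, experience, marital status,
previous accident, education, weekday, daytime, safety training, HRUB)
factorizes the joint as ∏ᵢ P(Xᵢ | parents(Xᵢ)). CPTs are learned from
observation records — missing values allowed — by EM; posteriors are exact
(variable elimination). Sensitivity of the outcome to each variable X is
measured by belief updating,

&nbsp;&nbsp;&nbsp;&nbsp;V_s = 100 · [P(HRUB=yes | X=s) − P(HRUB=yes)] / P(HRUB=yes),

summarized as the mean |V_s| per variable, alongside the mutual information
I(X; HRUB); variables are ranked by the former with MI as tie-breaker.

Because real observation campaigns are rarely shareable, the package also
ships a calibrated synthetic ground-truth network (exact marginals:
24.8 % HRUB, 73.6 % married, 4.11 % major accident, 59.5 % high school;
12.3 % HRUB given heavy training) and a seeded ancestral sampler, so the
whole pipeline is testable end to end.

## Worked example

```python
import hrubnet as h

# 1. sampling design from a pilot of 200 observations with 90 HRUBs
d = h.design(200, 90)
print(d.p, d.size.raw, d.size.nearest_ten)
# 0.45 1955.6 1960  -> observe ~1960 behaviors

# 2. observations (here: simulated from the packaged ground truth)
truth = h.default_ground_truth()
data = h.sample_dataset(truth, n=1960, seed=42)

# 3. fit the network and rank the drivers of unsafe behavior
fit = h.fit_em(truth.structure, truth.scheme, data)
report = h.analyze(fit.network)
print(f"baseline P(HRUB=yes) = {report.baseline:.4f}")
print(report.to_dataframe().to_string(index=False))
```

Output:

```
baseline P(HRUB=yes) = 0.2580
        variable  state 1  state 2 state 3  abs mean of variations  mutual information  rank
        Training    31.22    -9.00  -39.52                   26.58             0.01836     1
   MaritalStatus    -7.17    19.66       -                   13.42             0.00345     2
EducationalLevel     4.68     4.17  -26.08                   11.64             0.00299     3
      Experience    15.70     4.51   -7.44                    9.22             0.00176     4
         Daytime   -10.81    11.05     0.8                    7.56             0.00206     5
             Age    10.74    -3.08   -7.76                    7.19             0.00132     6
PreviousAccident     0.67    -1.02   -8.65                    3.45             0.00010     7
         Weekday    -5.20     2.06    1.42                    2.89             0.00024     8
```

Reading it: about 25.8 % of the 1960 simulated observations were high-risk
unsafe acts. Training is by far the strongest driver — observing a worker
with five or more safety courses (state s3) lowers the HRUB probability by
~40 % relative to baseline, while one-or-two-course workers (s1) sit ~31 %
above it. Per-state cells are signed percent variations; the dash marks a
binary variable's absent third state.

The same chain is available from the shell:

```bash
hrubnet design --n0 200 --n1 90
hrubnet run --outdir results/demo --n 1960 --seed 42
```

which writes the observation CSV, the fitted network (YAML), the ranking
and conditional-probability tables (CSV), a markdown report, and an audit
log with checksums; reruns with the same seed are byte-identical.

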