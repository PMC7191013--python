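# Methods

`hrubnet` implements a two-stage workflow for behavioral safety analysis on
construction-type worksites: (1) *safety behavior sampling* (SBS), a
work-sampling design that fixes how many instantaneous behavioral
observations are needed to estimate the rate of high-risk unsafe behavior
(HRUB), and (2) a *discrete Bayesian network* (BN) over nine workplace
variables, fitted by EM and interrogated by belief updating, to rank which
factors drive HRUB.

## Sampling design

SBS treats each observation as a Bernoulli trial (HRUB yes/no) and uses the
normal approximation to the binomial. With a pilot estimate p = N1/N0, the
total sample size for *relative* precision S at standard-normal multiplier K
is

    n = K² (1 − p) / (S² p).

Defaults K = 2 (≈ z at two-sided 95 %) and S = 0.05 are the customary values
in the work-sampling literature. With the pilot 90/200 (p = 0.45) the raw
requirement is 1955.6, presented as 1960 after nearest-ten rounding; the
ceiling (1956) is the binding integer requirement. The absolute-precision
variant K²p(1−p)/S² is available behind a flag; it is *not* the formula that
reproduces the study-scale total (it gives 396), which is why the relative
form is the default.

The observation schedule is a balanced randomized design rather than an IID
draw: each (weekday × hour) grid cell is scheduled ⌊n/G⌋ times, the
remainder drawn without replacement, the order shuffled and minutes drawn
uniformly. This keeps each cell equally represented while guaranteeing —
not merely making probable — that every weekday and every working hour is
covered whenever n ≥ G. IID uniform sampling cannot give that guarantee.

## Variables and discretization

The nine variables are age, experience, marital status, previous accident,
educational level, weekday, daytime, safety-training count, and the binary
HRUB outcome; seven have three ordered states, two are binary (25 states in
total). Numeric bins are half-open and lower-inclusive — age [0,30), [30,40),
[40,∞); experience [0,1), [1,5), [5,∞); daytime [8,11), [11,14), [14,18]
with the closing hour inclusive — a deliberate convention, since verbal
state descriptions ("from 30 to 40") never specify edge handling.
Experience's top state is labeled "above 5 years" and is treated as
unbounded. The training bins are [0,3), [3,5), [5,∞) courses: the lowest
state is described as "one or two courses", but the bin starts at zero so a
worker with no recorded course falls into the lowest state rather than
erroring. Missing values are represented by absence (empty/NA CSV cells),
never by a sentinel state.

## Network and inference

The expert-elicited DAG: age → experience, age → marital status, previous
accident → training (the employer mandates courses after an accident), and
all variables except age point directly at HRUB (age acts only through its
mediators). The joint factorizes as ∏ P(Xi | parents(Xi)); posteriors are
computed exactly by variable elimination with a min-degree ordering. At nine
nodes the largest intermediate factor is a few thousand entries, so exact
inference is always cheap and no approximate engine exists. Probabilities
are kept in linear space (underflow is impossible at this scale); the
full-assignment joint has a log-space variant for dataset likelihoods.
Zero-probability evidence raises an error rather than returning NaN — it
signals a data/model mismatch. A brute-force enumeration posterior is kept
as an independent test oracle only.

CPT storage order is fixed for bit-exact serialization: one axis per parent
in declared order, child axis last; flattened C-order therefore varies the
child fastest. Networks serialize to YAML/JSON and to XMLBIF (same table
order, documented in the writer).

## EM parameter learning

The E-step computes, per unique observed pattern, the exact posterior over
each node family given the pattern's observed variables, and accumulates
expected counts (fully observed patterns short-circuit to plain counting).
The M-step renormalizes smoothed expected counts. Patterns are grouped so
cost scales with distinct patterns, not records.

Smoothing is the one place where a naive default fails visibly. The HRUB
node has 3⁶·2 = 1458 parent configurations; a sample of ~2000 records
leaves roughly a quarter of the parent-configuration probability mass
unobserved. Any *flat* prior (Laplace +1, or a flat BDeu fraction) sends
unseen rows to a uniform 0.5 and drags the fitted HRUB marginal from ~0.25
to 0.30–0.40. The default prior is therefore an empirical-Bayes Dirichlet:
total mass `ess = 1` per node, split equally across parent configurations,
with prior *mean* equal to the node's expected marginal from the first
E-step and held fixed afterwards. Unseen rows then back off to the node's
marginal, and fitted marginals track empirical frequencies. A flat per-cell
`pseudocount` override is available (with `pseudocount=0`, unseen rows get
a uniform row by documented convention, and the fit equals closed-form
frequency counting exactly on complete data).

Because the prior is fixed after the first E-step, the fit is MAP-EM with a
constant prior and its objective — log-likelihood plus log-prior — ascends
monotonically by the usual EM argument; `loglik_trace` records that
objective (the plain log-likelihood when `pseudocount=0`). Raw-likelihood
monotonicity is not a theorem under *any* smoothing, so the trace
deliberately tracks the quantity that is actually maximized. Convergence is
declared at relative objective change < 1e-6 (default), parameter
stationarity, or 500 iterations. Initialization is uniform by default
(`random` draws Dirichlet(1) rows from the seed); with uniform init and a
fixed seed the whole fit is bit-reproducible.

## Sensitivity analysis

For each predictor X and state s, the variation statistic is the signed
percent relative change of the target's adverse-state probability under
single-variable evidence:

    V_s = 100 · (P(HRUB=yes | X=s) − P(HRUB=yes)) / P(HRUB=yes),

summarized per variable by the mean of |V_s| (two-state variables simply
contribute two terms). Conditioning is observational and places evidence on
the single variable only — mediators are not clamped. Mutual information
I(X; HRUB) is computed from the exact joint, in bits by default (the base
is configurable; published MI tables from BN tools do not always state
theirs). Ranking is by descending absolute mean variation, ties broken by
descending MI, then variable name — the tie-break the published table's own
tied rows are consistent with. Since the two statistics can order variables
differently, the report carries both rankings and their Spearman
correlation rather than asserting agreement.

## Synthetic ground truth

The study's field records are unpublished, so the package ships a fully
parameterized stand-in on the study DAG, calibrated so that exactly (to
float precision):

* P(HRUB=yes) = 0.248, P(MaritalStatus=yes) = 0.736,
  P(PreviousAccident=major) = 0.0411, P(EducationalLevel=high school)
  = 0.595, and P(HRUB=yes | Training=s3) = 0.123.

Unpinned interiors are plausible documented values: age prior (0.30, 0.48,
0.22) and experience-given-age rows put most workers at 30–40 years with
experience above 5; the weekday prior (0.28, 0.48, 0.24) puts about half of
observations midweek; the daytime prior is nearly flat. The marital-status
middle row is solved linearly so the married marginal is exact. The HRUB
table is built from per-parent-state relative-risk factors (inexperience,
being unmarried, prior accidents, low education, late weekdays and
afternoons all raise risk) and calibrated in closed form: the parent joint
is computed by exact inference, and Training-state multipliers (shape 1.6 :
1.0 : solved) are solved linearly against the marginal and conditional
targets. The construction asserts every resulting probability lies strictly
inside (0, 1) and re-verifies all five targets by inference, raising if a
user-supplied configuration is infeasible.

Known divergences from the field data this generator does not emulate:
per-variable variation/MI magnitudes (they depend on the study's unpublished
fitted CPTs; only the dominance and protective direction of training are
built in); the net effect of a previous *major* accident, which in the
synthetic network is protective because the mandated-training mediation
(accident → more courses → less HRUB) outweighs the direct risk factor,
whereas the published table shows a positive net variation; real
missingness mechanisms (masking is MCAR only); and any dependence between
repeated observations of the same worker (records are exchangeable).
Passing tests therefore demonstrate the correctness of the machinery and
the recoverability of this network's parameters at the study's scale — not
field validity.

Default sample size is 1960 records, mirroring the study. At that n the
sampling standard deviation of the HRUB frequency is ≈ 1 percentage point,
which bounds how closely any fit can track the generating 24.8 %.

## Pipeline

`run_pipeline` chains simulate/ingest → EM fit → sensitivity → report and
writes a bundle (observations, fitted network, objective trace, ranking
table, per-state conditionals, markdown report, audit log). Every random
stage derives from the single configured seed; artifacts carry no
timestamps, so identical configurations produce byte-identical bundles —
the audit log records parameters and SHA-256 checksums instead. A stage
failure aborts with the stage name and removes partial outputs. Test and
demonstration problem sizes (n = 1960 for study-scale runs, 10 000 for
recovery checks, 50 000 for distributional checks) were chosen as the
smallest sizes at which the corresponding statistical bands are meaningful.
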