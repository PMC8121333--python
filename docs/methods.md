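# Methods

## Model

`pepngrn` infers a signed, directed gene regulatory network from
discretized time-series expression data.  The data model is a sequence of
network states: for `p` genes measured at `n` time points, each column
`X^t` is the vector of discrete expression levels (2-bin: off/on; 3-bin:
low/medium/high) at time `t`.  Inference rests on three assumptions:

1. regulation is first-order Markov — a target's transition between
   adjacent time points depends on the regulators' levels at the earlier
   point (a one-step regulatory lag);
2. each target has a small number of regulators;
3. expression is adequately described by 2 or 3 discrete levels.

Between two adjacent time points a target exhibits at most one of four
*evidence types*: production (rise to the top level), decay (fall to the
bottom level), sustained production (plateau at top) and sustained decay
(plateau at bottom).  In the 3-bin setting only transitions that reach the
top or bottom level count; movements into or plateaus at the middle level
carry no evidence.  For every observed event, each candidate regulator's
pre-state implies a regulation sign: a high regulator during
production-side events (or a low regulator during decay-side events) counts
toward activation, the complementary pre-states toward inhibition.  Counts
are normalised per target and evidence type,

    Pr_e(r, t, sign) = C_e(r, t, sign) / C_e(t),

so for every (regulator, target, evidence) with at least one event the two
sign probabilities sum to 1.  State pairs are taken strictly within each
time series: the junction between two independent experiments is not a
biological transition (this may make counts differ slightly from analyses
that concatenate series).

In extended-Petri-net terms, each target gene is an output place with one
synthesis and one decay transition; regulators are control places connected
to the synthesis transition by read arcs (activation) or inhibitory arcs.
`export_pepn_structure` writes this static structure as GraphML; token
animation is out of scope.

## Score aggregation

* **v1 (unweighted)** — the mean of the four evidence probabilities;
  missing evidence contributes 0.  The score is a *conditional sign
  probability* (given that the edge exists); for a fully-evidenced target
  the two signs of a pair sum to exactly 1, and in general to
  (number of evidence types present)/4.
* **v2 (count-weighted)** — summed counts over summed target totals,
  `Σ_e C_e(r,t,s) / Σ_e C_e(t)`; frequent evidence types weigh more.  The
  two signs sum to 1 whenever any evidence exists.
* **v3 (supervised)** — one logistic-regression model per regulation sign,
  trained on the four evidence probabilities of candidate edges labelled
  against a reference network, under k-fold cross-validation (default
  k = 5; whole networks are held out when several are available, otherwise
  a seeded partition of pairs).  Training folds are balanced with SMOTE
  before fitting; each held-out pair is scored by both sign models and the
  larger probability wins, carrying that model's sign.  v3 scores are
  edge-presence probabilities, which makes likelihood assessment of a
  reference network meaningful (`network_likelihood`, in both a full
  product over edges and non-edges and an edges-only product — both are
  provided because either reading of a "network likelihood" is defensible).

After scoring, sign selection keeps the higher-scoring sign per pair and
discards exact ties (tolerance 1e-12: scores are small-denominator
rationals, so genuine ties are exact and a tie means the data cannot
distinguish activation from inhibition — a hallmark of a spurious pair).
Optional post-hoc thresholds retain the top `nReg` regulators per target
(default 3) and then drop edges scoring below `th`; the filter order is
fixed.  Per-gene decay probabilities are estimated as (negative
within-series level steps) / (time points with level > 0).

## Discretization

All three methods operate per gene row over the concatenation of every
series, so one gene gets one set of thresholds:

* **EWD** — bin width `(max − min)/k`, half-open bins, the maximum clamped
  into the top bin; deterministic and monotone.
* **EFD** — stable sort, k bins whose sizes differ by at most one, the
  remainder going to the lowest bins; ties at a bin boundary follow stable
  sort order, so equal values can straddle a boundary (exact equal-
  frequency takes precedence over tie cohesion).
* **k-means** — 1-D Lloyd iterations from deterministic quantile centres
  `(2i+1)/(2k)`, centre-movement tolerance 1e-9, at most 300 iterations,
  emptied clusters reseeded at the point farthest from its centre, clusters
  relabelled by ascending centre.  The deterministic init replaces random
  restarts: in one dimension quantile seeding is near-optimal and makes
  runs reproducible.

Constant rows map to level 0 under every method.  Rule tables ship for
k ∈ {2, 3}; the discretizers themselves accept any k ≥ 2.

## Evaluation

AUROC is computed rank-based (Mann-Whitney, ties ½), which equals
trapezoidal ROC integration; AUPR is the non-interpolated step sum
(interpolation conventions change the number, so the choice is pinned).
The candidate universe is every ordered non-self pair (restricted to a TF
list when one is supplied); pairs discarded by sign-tie selection re-enter
with score 0 so rankings remain comparable across methods.  The
challenge-style overall score, −mean log10 of per-network p-values averaged
over the two metrics, takes the p-values as inputs — the null distributions
behind them are out of scope.  Published benchmark values computed with
other tooling may differ in the third decimal through tie and
interpolation conventions.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, not
its inference rules, so recovery is a genuine test rather than a
tautology.  A sparse signed network is drawn first: non-TF targets receive
1..`max_regulators_per_target` regulators uniformly from the TF pool
(when every gene is a TF, all genes become targets).  TFs are autonomous:
their levels follow independent basal-rise/decay telegraph dynamics.  This
independence is what makes regulator attribution identifiable — mutually
regulated TFs saturate and correlate, and no rank-based method can then
separate them.

Dynamics per gene per step, reading regulator levels at the previous time
point: an inhibitor at the top level actively represses (the target falls
one level); otherwise an activator at the top level drives synthesis (the
target rises one level); a target with only inhibitors is constitutively
synthesised while its repressors are off (the classic derepression
picture).  With no active regulator the gene drifts: it rises with
`basal_synthesis_prob` or falls with `decay_prob_per_step`.  Active
repression accelerating decay — rather than merely vetoing synthesis — is
deliberate: under a veto-only rule an inhibited target's decays are
uncorrelated with its repressor and inhibition edges are statistically
invisible, which would cap whole-network recovery near 0.75 regardless of
noise.

Observation model: the discrete level plus uniform jitter of half-width
0.3 (keeps adjacent levels separable under EWD — the jittered intervals
around integer levels do not overlap); flip noise ε independently replaces
a discrete observation with a uniform random level before jitter,
emulating measurement corruption.  `simulate_expression` also returns the
pre-noise generating levels for round-trip checks.

Defaults (chosen once as the study conditions): 20 genes, 5 TFs, at most
2 regulators per target (sparse, benchmark-like in-degree), 10 series of
21 time points, 2 levels, basal rise 0.1 and decay 0.3 per step (TF
on-fraction ≈ 0.25, so sustained-decay events dominate, as they do in real
expression time courses), flip noise 0.

What the generator does *not* emulate: continuous kinetics (no ODEs),
combinatorial multi-regulator logic beyond any-activator/any-inhibitor,
steady-state or knockout designs, and technical replicates.  Passing
recovery tests therefore show the inference chain is sound under the
method's own assumptions, not that it matches wet-lab performance.

Under these conditions, v1 on equal-frequency 2-bin data attains median
AUROC ≥ 0.9 noiseless and ≥ 0.7 at ε = 0.1 over 10 seeds, degrading
monotonically in ε (the acceptance suite recomputes this).  The learned v3
weights show a stable qualitative pattern: sustained decay dominates the
activation model and sustained production the inhibition model.  The
intuition is estimation precision — sustained events are far more frequent
than switches, so their probabilities are the least noisy features and the
fitted model leans on them hardest; the regulator pre-states they implicate
encode the time-shifted (and, for the complementary sign, inverted)
relationship between regulator and target.

## Numerical and interface choices

* Zero-denominator rule everywhere: a probability whose defining total is
  0 is reported as 0 (missing evidence, never-expressed genes).
* SMOTE uses 5 nearest minority neighbours (clipped to minority size − 1),
  a seeded generator, and is applied to training folds only; a minority of
  size 1 falls back to duplication with a warning.  One SMOTE seed per
  fold (not per sign) keeps the activation/inhibition roles exchangeable.
* Logistic regression uses lbfgs with weak L2 (inverse strength C = 100)
  so weights stay finite on separable data; fits are deterministic given
  inputs.
* Max-fusion in v3 assigns the winning model's sign, activation on exact
  ties.
* Ranked outputs are totally ordered: descending score, ties broken
  lexicographically by (regulator, target); floats are printed with 6
  significant digits.
* Unsigned evaluation of v1/v2 output ranks pairs by their sign-selected
  score.

## Limitations

Single-lag evidence cannot represent multi-step cascades or combinatorial
regulator logic; 3-bin middle-level dynamics are deliberately ignored;
supervised v3 needs a reference network with enough edges of each sign in
every training fold (it raises otherwise); thresholds `nReg` and `th` are
user choices with no heuristic auto-selection.
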