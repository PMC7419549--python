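# Methods

## Model

A diagnostic network is a three-layer DAG of binary nodes: risk factors
`R_i`, diseases `D_j`, symptoms `S_k`, with edges only risk → disease and
disease → symptom.  Every disease and symptom is a noisy-OR child: parent
`X_i` activates the child unless the activation independently fails
(probability λ_i), and an always-on leak parent — the stand-in for causes
outside the model — fails with probability λ₀.  As a structural causal
model each child is the deterministic function

    y = ∨_i (x_i ∧ ū_i) ∨ ū₀ ,   P(u_i = 1) = λ_i ,   P(u₀ = 1) = λ₀ ,

of its parents and exogenous noise.  Noise convention: `u = 1` means the
activation *fails*.  States are 0/1 (JSON uses booleans).

Two modelling choices the three-layer family leaves open:

* **Disease CPTs are noisy-OR over risk factors with a leak.**  The leak
  encodes baseline prevalence, so a disease with no risk parents is
  parameterised purely by its leak, `P(D=1) = 1 − λ₀`.  This subsumes the
  classic two-layer disease–symptom (BN2O) models and is the natural
  extension point if other CPT families are ever needed.
* **The leak is an explicit always-on parent in the SCM**, not folded into
  the CPT.  This is what lets the sufficient-cause intervention switch it
  off (below).

## Diagnostic measures

Evidence ℰ is a partial risk-factor assignment ℛ plus positive and negative
symptom sets 𝒮₊, 𝒮₋.  Symptoms mentioned in neither set are *unobserved*
and are marginalised — never treated as absent — because case vignettes are
non-exhaustive.  Partial risk evidence is marginalised under the priors.

* Associative score: posterior `P(D = 1 | 𝒮±, ℛ)`.
* Expected disablement: expected `|𝒮₊ ∖ 𝒮₊′|` under `do(D = 0)` — how many
  present symptoms the cure would remove.
* Expected sufficiency: expected `|𝒮₊′|` under `do(Pa(𝒮₊) ∖ D = 0)` — how
  many present symptoms D alone would sustain.  The intervention set
  includes each present symptom's leak parent (all "exogenous influences")
  but leaves the mechanisms of 𝒮₋ and of unobserved symptoms untouched;
  the counterfactual values of 𝒮₋ are re-evaluated, not frozen.
  Counterfactually activated symptoms outside the factual 𝒮₊ are not
  counted: the measure asks which present symptoms *persist*.

Both measures are computed by three mutually checking routes:

1. **Closed form** (the production path).  Inclusion–exclusion over
   `𝒵 ⊆ 𝒮₊`:

       Σ_𝒵 (−1)^{|𝒵|} P(𝒮₋=0, 𝒵=0, D_k=1 | ℛ) τ(k,𝒵) / P(𝒮± | ℛ)

   with `τ(k,𝒵) = Σ_{S∈𝒮₊∖𝒵} (1 − λ_{k,S})` for sufficiency and
   `τ(k,𝒵) = Σ_{S∈𝒵} (1 − 1/λ_{k,S})` for disablement; λ is taken as 1
   when the edge is absent.  The disablement τ divides by λ_{k,S}, but the
   joint it multiplies contains the event `{S=0, D_k=1}`, which itself
   carries a factor λ_{k,S}; the implementation divides that factor out of
   the joint analytically (`off_probability(..., excluded_edge=...)`), so
   λ = 0 (a deterministic link) is handled by cancellation, never by
   division.  Verified by agreement with the definitional route at
   λ = 10⁻⁶ and by the exact λ = 0 case.
2. **Twin network** (the definitional path).  Factual and counterfactual
   copies of every intervention-affected node share their family's
   exogenous noise; the factual half is conditioned on the evidence, the
   counterfactual half carries the intervention.  For one noisy-OR family
   the joint of the factual child and its copy given both parent vectors
   is obtained by marginalising the shared noise in closed form
   (`P(both off) = λ₀ Π_{i: either parent on} λ_i`, etc.), after which the
   twin network is an ordinary discrete BN that is summed exactly over the
   relevant nodes: unobserved risks, diseases and their copies, and the
   queried symptom pairs.  Unevidenced, unqueried symptom families are
   exactly marginalised by omission.
3. **Abduction–action–prediction** (the reference oracle).  Exhaustive
   enumeration of all exogenous noise assignments: weight by `P(u)`
   restricted to evidence-consistent worlds, re-evaluate the structural
   equations under the intervention, average.  Cost `2^{#noise terms}`;
   restricted by contract to test-size networks via a hard cap of 22
   enumerated bits (the twin evaluator carries the same cap).  Random test
   networks that exceed the cap are redrawn — a size restriction, not a
   selection on outcomes.

## Exact inference

Negative ("off") symptom evidence factorises across diseases in a noisy-OR
network, and positive evidence reduces to off-events by the quickscore
inclusion–exclusion.  For a fixed off-set, diseases are conditionally
independent given the risk layer, so each term is

    Π_S λ₀_S · Σ_r w(r) Π_j [(1 − p_j(r)) + p_j(r) m_j] ,

with `p_j(r)` the disease activation probability under risk configuration
`r` and `m_j` the product of λ's from disease j into the off-set.
Unobserved risk configurations are enumerated (vectorised); observed risks
are clamped and conditioned on, matching the `P(· | ℛ)` convention of the
closed form.  Off-set terms are memoised within a query.  Caps: 16
positive symptoms (2¹⁶ subsets), 16 unobserved risk factors; both raise
informative errors.  The contract is exactness, checked against full-joint
enumeration to 10⁻¹⁰ on randomised networks and to 10⁻¹² for joint
normalisation.

## Rankings and evaluation

Rankings are full (every modelled disease appears once), sorted by score
with ties broken by higher posterior then lexicographic id — fully
deterministic.  Rank positions are 1-based.  Two positions are recorded
per vignette: the delivered-order position (used for top-k accuracy) and a
tie-aware position where equal scores share the minimum position (used for
mean ranks and win/draw/loss counts); the distinction matters because the
counterfactual measures produce exact-zero ties for all non-causes.

Cohort statistics: top-k accuracy curves, relative error reduction
`1 − e_c/e_a`, mean true-disease rank, pairwise wins/draws/losses, rarity
strata, and matched differential evaluation where each vignette is scored
at its own differential size k.  Rarity bands are assigned by the true
disease's prior given the risk evidence, `P(D=1 | ℛ)`; the default edges
`(10⁻⁴, 10⁻³, 10⁻², 5·10⁻², 2·10⁻¹)` are explicitly non-canonical
configuration values.

## Synthetic data

The generator emulates the assumed generative process: a layered network
with configurable per-layer sizes and edge densities, uniform parameter
draws, and vignettes created by forcing the true disease on (do-style),
forward-sampling the exogenous noise, rejecting worlds where no child
symptom of the true disease presents (cap 10⁴ draws, then an error
suggesting parameter changes), and revealing evidence partially.  A
disease with no symptom children cannot present and is excluded from the
true-disease draw.  Unrevealed symptoms are dropped from the evidence
entirely (vignettes stay non-exhaustive); if the reveal hides every
positive symptom, one positive child of the true disease is force-revealed
so the vignette has a complaint.

Defaults, chosen once as a realistic desk-scale regime: 5 risks, 10
diseases, 15 symptoms; densities 0.35 (risk→disease) and 0.3
(disease→symptom); λ ∈ [0.2, 0.9]; leak failures ∈ [0.9, 0.995] (disease
baseline prevalence 0.5–10%, symptom leak activation 0.5–10%); risk priors
∈ [0.05, 0.5]; reveal probabilities 0.8 (positive symptoms and risks) and
0.2 (negative symptoms); differential sizes `k = 1 + Poisson(1.58)`, mean
2.58.  Reproducibility: one master seed; per-vignette seeds derive from
(master, index); cohort and model files are canonical JSON, byte-stable
under identical configs.

What the synthetic cohorts do *not* show: real presentations are authored
by clinicians from knowledge partly outside any network, evidence reveal
is not an independent-coin process, and real disease models have hundreds
of nodes with elicited (not uniform-random) parameters.  Passing the
cohort checks therefore demonstrates the correctness and internal
consistency of the inference and evaluation machinery, and the qualitative
advantage of causal over associative ranking *within the model family* —
not clinical accuracy.

## Problem sizes and numerical choices

Test and acceptance runs use: 200 random networks (≤ 4 nodes per layer,
≤ 3 positive symptoms) for three-route equivalence at 10⁻⁹; 60 networks
against full-joint enumeration at 10⁻¹⁰; a 500-vignette cohort on the
default 10-disease network for the evaluation pipeline.  These sizes make
the exhaustive oracles exact and the whole suite fast while exercising
every code path; the closed form itself scales to tens of diseases per the
inference caps above.  Zero-probability evidence raises a dedicated error
(`ZeroEvidenceError`) rather than returning NaN; cohort evaluation catches
it per vignette, records the failure, and continues.

## Known limitations

Binary nodes and noisy-OR mechanisms only; exactly three layers; no
learning of parameters from data; no approximate inference for very large
models; no loader for externally published disease-model formats; doctors'
differential behaviour is not simulated — matched-k evaluation consumes k
values supplied with the vignettes.
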