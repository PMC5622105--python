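# Methods

`ecmbind` turns label-free proteomic quantification of a remodeled
extracellular matrix (ECM) into predictions of integrin-receptor occupancy.
This note records the models, the defaults and the numerical choices, and
what the synthetic tests do and do not establish about real data.

## From emPAI scores to ligand pools

Shotgun proteomics of a three-step ECM extraction (0.5 M NaCl, 1% SDS,
4 M GnHCl fractions; control vs fibrotic livers) reports an exponentially
modified protein abundance index (emPAI) per protein, fraction and group.
emPAI is approximately proportional to molar abundance, so with the mass
concentration loaded per fraction (0.25 µg/µL by default) it acts as a
proteomic ruler:

    c [µM] = emPAI × loading [µg/µL ≡ g/L] / (MW [kDa] × 1000 [g/mol]) × 1e6

Fractions are pooled by *summing* emPAI per protein and group before the
conversion. The original fraction pooling happened inside a search platform
(MudPIT-style recombination of per-fraction search results); summation is
our documented approximation of it — it preserves additivity and
monotonicity of the observable peptide evidence, which is all the
downstream analysis uses, but it is not a reimplementation of
spectrum-level recombination (spectra are out of scope).

Fold changes are `log2(max(c_trt, f)/max(c_ctl, f))` with the zero floor
`f = 1e-5 µM` applied at the molar stage. Proteins with zero pooled
abundance in exactly one group are classified unique to the other group;
zero in both → excluded and logged. Several printed fold-change cells in
the reference abundance table are not reproducible from their own printed
µM cells (e.g. a sign flip for collagen IVα1 and all zero-floored rows);
the loader flags rows whose printed value deviates from the recomputed one
by more than 0.02 (chosen to tolerate last-digit rounding of the 2 d.p.
inputs, the largest benign deviation being 0.018) and the pipeline always
reports the recomputed values.

## Binding models

Both models are closed mass-action systems over nine species (nM):
free receptor I, free ligand E, singly/doubly occupied receptors Cm/Cd,
and aggregate receptor pairs Aim, Aid, Amm, Amd, Add (index = occupancy of
the two paired receptors: i empty, m single, d double).

**Divalent model.** Sequential two-site binding, I + E ⇌ Cm (Ki = k2/k1)
and Cm + E ⇌ Cd (Kc = k4/k3). All equilibrium constants here are
dissociation-type (off/on, nM); literature sometimes quotes the reciprocal
association constants, which we treat as naming aliases. Kc = 0.01·Ki by
default: the first binding event switches the receptor to a high-affinity
conformation, producing positive cooperativity of the fully occupied
fraction.

**Aggregation model.** Bound receptors (Cm or Cd) pair with an *unbound*
receptor with Ka = k6/k5 (10·Ki by default); ligand binds the empty half of
a pair with Kp = k10/k9 and fills the second site of a singly bound half
with Kx = k8/k7 (Kp = 100·Kx). Aggregation is the scheme's abstraction of
integrin clustering into focal adhesions. Kp is only constrained to exceed
Ki by the published relations; we default to Kp = 10·Ki and expose it as
configuration. Consequently the *aggregate-pair* steady-state magnitudes
(Add) are reproducible only up to this unidentified parameter, while the
single-receptor observable Cd is insensitive to it (the package's own
sensitivity analysis shows |ΔCd| < 1e-5 % under ten-fold Kp/Kx changes),
which is why value-level checks are restricted to Cd and to percent-change
ratios.

The published Amd balance carries factors of E on its k8 exchange terms
that have no counterpart in the E and Add balances and that break receptor
conservation; we implement the conservation-consistent mass-action form
`+ k8 (Add − Amd) + k7 E (Amm − Amd)` and keep the published variant behind
an off-by-default `printed_amd_form` flag for comparison (a regression test
demonstrates the violation).

**Microrate assembly.** Only ratio relations are published beyond (k1, k2).
We pin every bimolecular on-rate to the ligand's measured k_on and derive
the off-rates from the ratios, which keeps the published kinetics intact,
makes every equilibrium relation exact to 1e-12, and anchors all timescales
physically. Units are converted once at ingestion (ligand µM → nM ×1000;
k_on s⁻¹M⁻¹ → nM⁻¹s⁻¹ ×1e-9) and logged.

## Numerics

* **Integration.** `scipy.integrate.solve_ivp` with LSODA and the analytic
  Jacobian; rtol 1e-10, atol 1e-12 × receptor total (so trace aggregate
  species stay resolved even when ligand exceeds them by 16 orders of
  magnitude). Trajectories are checked for negative excursions (tolerance
  −1e-12 nM) and for conservation of the receptor- and ligand-weighted
  totals to 1e-6 relative; violations raise instead of returning bad data.
* **Steady states.** The default horizon is 1e6 s with a convergence flag
  (max relative derivative < 1e-9). That horizon is *not* sufficient for
  the slowest mode of the aggregation scheme in the collagen scenarios: the
  aggregate ladder drains only through the minor Aim/Aid pools, giving a
  terminal relaxation time of order 1e7 s during which absolute derivatives
  are already below machine noise. Steady-state values are therefore
  polished by a damped Newton solve of rhs = 0 with the two conservation
  laws substituted for the I and E balances, seeded by the ODE endpoint and
  judged on the relative Newton step (< 1e-11); the polish agrees with a
  1e10-s integration to ~1e-11 relative and removes the horizon from the
  error budget. If the polish is rejected (non-convergence or negative
  components) the horizon is extended ×100 up to three times and the flag
  reports honestly.
* **Divalent oracle.** The divalent equilibrium has a closed form up to a
  scalar root: free ligand E solves a monotone equation on [0, L], found by
  Brent bracketing to machine precision. It cross-checks the integrator in
  the tests (100 random scenarios, 1e-6 relative) and provides the fast
  path for divalent occupancy curves. No such reduction exists for the
  aggregation scheme — with Kc ≠ Kx the network is not detailed-balanced,
  so its steady state is genuinely kinetic and is always computed by
  integration + polish.
* **Sensitivity analysis.** One-at-a-time ten-fold perturbations act on the
  off-rate of the named constant only, keeping bimolecular timescales
  fixed. Perturbing Ki co-scales k4 by default so the Kc = 0.01·Ki relation
  is maintained (set `maintain_kc_relation=False` to treat Kc as an
  independently fixed constant). Everything is deterministic; identical
  inputs give bit-identical tables.
* **Hill coefficient.** Least-squares slope of log(y/(1−y)) against
  log(ligand) over points with occupancy in (0.05, 0.95), on the fully
  occupied fraction Cd/R_total. Note that this observable of a sequential
  two-site receptor has a limiting logit slope of 2 at low and 1 at high
  ligand, so its fitted value lies strictly between 1 and 2 even with equal
  stepwise constants (≈1.33 at Kc = Ki over the default 0.01–100×Ki grid);
  cooperativity *enhancement* is read as the increase above that ladder
  baseline (≈1.88 at Kc = 0.01·Ki). Only a true 1:1 curve gives 1.0.

## Synthetic data

The generator emulates the statistical structure of the fractionated
two-group experiment: per-protein emPAI log-normal (log-mean 0, log-sd 1.2,
matching the few-orders-of-magnitude spread of the fixture table), a
per-protein log2-normal treatment effect (mean 0, sd 1 by default),
molecular weights uniform on 15–300 kDa, a Dirichlet(1,1,1) split of each
group's signal across the three fractions, and *group-level* dropout
(control 7%, treatment 1% — the asymmetry behind the observed excess of
treatment-unique proteins). Dropout is modeled at the group level because
the presence classification operates per group, not per fraction.

What the generator does **not** emulate: peptide-level sampling noise,
detectability bias of emPAI at low coverage, shared peptides between
collagen chains, fraction-specific extraction chemistry, or any
between-animal variance structure. Passing recovery tests therefore show
that the quantification stage is an unbiased inverse of this generative
model, not that emPAI itself is an unbiased abundance estimate on real
spectra.

## Problem sizes used in the shipped analyses

Fixture steady states use the six published ligand:receptor pairings × two
groups; the sensitivity tables perturb five constants × two directions per
scenario; occupancy/Hill analyses use 50-point log-spaced grids spanning
0.01–100×Ki; the oracle cross-check uses 100 random scenarios with
log-uniform Ki, Kc and totals; synthetic recovery uses 2000 proteins.

## Known limitations

* Single ligand, single receptor per scenario: no competition between ECM
  species for a shared receptor pool (deliberately out of scope).
* No spatial clustering, stochasticity, receptor trafficking or downstream
  signaling; "aggregation" is a well-mixed pairing reaction.
* Aggregate-pair concentrations depend on the unidentified Kp/Kx scale and
  should be compared across conditions, not read as absolute numbers.
* Scenarios without published rate pairs (e.g. fibrinogen, α5β1 pairings)
  are accepted only through user-supplied rate configs, never as fixtures.
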