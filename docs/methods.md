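# Methods

## Model

The core object is a mass-action reaction network for active p38 acting on
two competing substrates. Binding is random-order: ATP and the protein
substrate attach independently, only the full ternary complex catalyses,
and catalysis is irreversible (product rebinding is excluded from the base
scheme). Enzyme states are enumerated as (enzyme variant, ATP bound?,
substrate slot, inhibitor bound?) and every legal single-ligand
association is emitted as one reversible reaction, so the network is
generated rather than hand-listed. Consequences of that construction:

- **Conservation.** Each species carries an integer moiety composition
  (enzyme, MK2 core, ATF2 core, adenosine, inhibitor, competitor). Every
  moiety weight vector lies in the left null space of the stoichiometry
  matrix, checked exactly in integer arithmetic at build time. Phosphoryl
  bookkeeping adds further laws (e.g. ADP − pMK2 − pATF2 is constant);
  the named moieties are not claimed to span the whole null space.
- **Detailed balance.** Because every dissociation constant is a function
  of (state, ligand) chosen to satisfy the cycle conditions, all closed
  binding cycles have unit product of equilibrium constants. This is not
  assumed: `check_thermodynamic_cycles` enumerates elementary cycles of
  the reversible-reaction graph (all cycles here have ≤ 8 edges), keeps
  the composition-balanced ones, and reports Π(k_f/k_r). The builder can
  deliberately omit the (1−f) correction (see below) to demonstrate that
  the check catches a broken network.

### Assumptions

- Only active p38 is modeled; activation kinetics, phosphatases,
  scaffolding and compartments are out of scope.
- One-hit phosphorylation in the core model (the multisite extension
  relaxes this); ADP release is folded into the catalysis step and ADP
  never rebinds.
- All forward rates are diffusion-limited; affinities therefore fix the
  off-rates (k_off = K_D·k_on).

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| K_D,ATP | ATP–p38 affinity | 67 | µM |
| K_D,ATF2 | ATF2–p38 affinity | 38 | µM |
| K_D,MK2 | MK2–p38 affinity | 20 | nM |
| k_cat,ATF2 | ATF2 turnover | 1.2 | s⁻¹ |
| k_cat,MK2 | MK2 turnover | 2.4 (in-house) / 0.17 (literature) | s⁻¹ |
| k_on (protein) | protein–protein association | 10⁶ | M⁻¹s⁻¹ |
| k_on (small) | ATP/compound association | 10⁷ | M⁻¹s⁻¹ |
| altered_factor | fold-change in mechanisms #3–5 | 10 | — |

Internal units are nM and seconds (k_on = 10⁻³ / 10⁻² nM⁻¹s⁻¹), keeping
state variables well scaled at the 0.5 nM enzyme level. Default initial
conditions are 0.5 nM p38, 50 µM ATP, 100 nM ATF2, 10 nM MK2; pMK2 is
read at 1800 s and pATF2 at 7200 s.

**The two k_cat,MK2 values.** Two measurements of the MK2 turnover rate
exist: an in-house determination of 2.4 s⁻¹ and a literature value of
0.17 s⁻¹. The package default is 2.4 s⁻¹. The inhibitor and headline
simulations use 0.17 s⁻¹, documented here as the package's own choice: at
2.4 s⁻¹ the simulated 30-min MK2 readout overshoots ~60-fold (conversion
complete within a minute), which flattens every MK2 dose-response, whereas
the assays being emulated read out in their linear range and the measured
virtual-compound IC50s sit at K_I scale — only consistent with a
near-linear readout. At 0.17 s⁻¹
the simulated readout is ~48% conversion. Structural, conservation and
equilibrium results are k_cat-independent.

## Alternate mechanisms (one per network, no stacking)

1. **Substrate inhibition** — pMK2/pATF2 rebind the enzyme (and its ATP
   form) at the unphosphorylated substrates' rates; dead-end complexes.
2. **pMK2 binds ATF2** — at the p38–ATF2 affinity, blocking ATF2.
3. **Altered ATP affinity** — MK2 turnover converts p38 → p38\*, whose
   K_D,ATP is *multiplied* by `altered_factor`.
4. **Altered ATF2 affinity** — as #3 for K_D,ATF2.
5. **Altered ATF2 catalysis** — as #3 with k_cat,ATF2 *divided* by
   `altered_factor`.

p38\* is produced only at the MK2 catalysis step, stays altered, and keeps
unaltered MK2 binding/catalysis constants. The 10-fold change is applied
in the *inhibitory* direction (affinity weakened / catalysis slowed): a
"lowered 10-fold" description of an affinity is directionally ambiguous,
and only this direction suppresses ATF2 phosphorylation as the downstream
experiments require; passing `altered_factor < 1` flips it. Note one
unavoidable coupling: in #3 the altered ATP site slows p38\* on *both*
substrates (the site is shared), so #3 retains an MK2 dose dependence
through prolonged substrate competition and shows a ~7% pMK2 deficit —
the suite discriminates #3 from #4/#5 by that deficit.

## Inhibitors

`InhibitorSpec(ki, selectivity_f, inhibitor_class, atp_mode)`:

- **classical** — affinity K_I for every enzyme form (f ≡ 0).
- **substrate_selective** — K_I for MK2-bound forms, K_I/(1−f) elsewhere.
  Stabilising the p38·MK2 complex forces the MK2 dissociation rate from
  every inhibitor-bound complex to carry a factor (1−f); that is exactly
  the detailed-balance closure of the p38 → p38·MK2 → p38·MK2·I → p38·I
  square. f = 1 is handled as the limit: the compound simply has no
  binding reactions to non-MK2 forms.
- `atp_mode="noncompetitive"` (default; the two variants behave
  near-identically here) lets ATP and compound co-bind with unchanged ATP
  affinity; `"competitive"` makes them mutually exclusive.
- Inhibitor-bound complexes never catalyse. When an inhibitor is combined
  with mechanism #1, phospho-substrate complexes follow the same affinity
  pattern as their unphosphorylated counterparts — the unique
  detailed-balance-consistent extension of "rates equal to the
  unphosphorylated interactions".

### A kinetic ceiling on single-assay selectivity

An equilibrium analysis predicts a single-assay selectivity of
~(K_I/(1−f))/K_I,app ≈ 30 for K_I = 1 nM, f = 0.99. The mass-action model
gives ≈ 7, and the gap is mechanistic, not numerical: the p38·MK2 complex
commits to catalysis (k_cat·ATP-occupancy ≈ 0.073 s⁻¹) or dissociates
(0.02 s⁻¹) faster than a nM-scale compound associates
(k_on·[I] = 10⁻²·[I] s⁻¹), so the MK2-assay IC50 has a floor near
(k_cat,eff + k_off)/k_on ≈ 10 nM regardless of K_I. Tight, slow-off
substrates are kinetically protected targets on catalytic timescales.
This ceiling is reported as a finding, not tuned away.

## Simulation

BDF with analytic Jacobian, rtol 10⁻⁸, atol 10⁻⁶ nM (rates span
0.02–670 s⁻¹); fallback to LSODA and then a 10× relaxed rtol before
raising with diagnostics. Every trajectory is checked for moiety
conservation to 10⁻⁶ relative and for negative excursions beyond 100×atol.
Halving the tolerances moves readouts by < 10⁻⁹ relative.

Assay runners build one network per configuration and re-integrate per
dose (initial conditions change, topology does not). Dose grids are 12
log-spaced points spanning [K_I/100, K_I·10⁴] plus the zero dose; the
zero-dose well of the same configuration defines the normalisation
("fraction of maximal signal"), so the noise-free normalised response at
dose 0 is exactly 1.

**Two-stage pull-down.** Stage 1: 5 nM p38 + ATP + variable MK2, 3600 s
(descriptions of the emulated protocol disagree between 1 h and 2 h;
3600 s is the default, configurable). Capture and wash then dissociate every
p38-containing complex to its free enzyme form (p38 or p38\*) — capture is
of total p38, washes remove partners — discarding all MK2, pMK2 and
nucleotide; stage 2 re-initialises with the carried enzyme, fresh 50 µM
ATP and 100 nM ATF2 for 7200 s. Sub-atol negative solver excursions are
clamped to zero at the hand-over.

**Virtual compound.** Dose d scales the p38 initial condition by
1 − d/(d + K_I) (ideal non-selective binder); the assay is re-run per
dose.

**Generic weak competitor.** A third substrate with K_D = 40 µM and
k_cat = 1 s⁻¹ (no measured value exists; configurable) and no
altered-state induction. A simple competitive treatment at 100 µM
(2.5×K_D) predicts partial pATF2 inhibition, which the corresponding
wet-lab experiment did not show; the discrepancy is left visible rather
than tuned away.

## Multisite extension

Substrates become ordered phosphoform chains S_p0 … S_pn (defaults: 2
ATF2 sites, 3 MK2 sites, per the known p38 sites); each step requires
fresh binding and catalysis with the base constants, and the product
dissociates between steps (distributive). Site-pattern combinatorics are
deliberately collapsed to ordered levels — the tested claims concern the
fully phosphorylated readout only. n = 1 reproduces the base network
reaction-for-reaction. Only sub-maximal forms bind the enzyme; a
selective compound treats every MK2 phosphoform complex as its preferred
target. The readout is the fully phosphorylated form of each substrate.

Observed behavior: the IC50 against fully phosphorylated ATF2 falls
monotonically with the number of ATF2 sites (every interruptible step
multiplies the inhibitor's leverage), for both compound classes, and the
dual-context loss of selectivity is unchanged. For the *classical*
compound this ATF2 potency is invariant (< 1%) in the number of MK2
sites; for the *selective* compound it is not (≈ 35% between 1 and 3 MK2
sites at the default k_cat): its ATF2 potency works through sequestration
into MK2-phosphoform complexes, whose lifetime scales with the number of
unphosphorylated MK2 sites. The invariance claim therefore holds only
class-wise, and the test suite reports the selective-compound deviation
honestly.

## Dose-response analysis

4PL model y = bottom + (top − bottom)/(1 + (d/IC50)^h), fitted by
least squares on log₁₀(dose) (zero dose excluded from the fit, used for
normalisation). Bottom is free with a ≥ 0 bound by default
(`constrain_bottom=True` pins it, mirroring the two conventions of
plate-fit software). Flat data (span < 0.2) or < 5 distinct positive
doses return a typed non-convergence sentinel; a fitted IC50 beyond the
largest dose is reported censored ("> max dose"). IC50 uncertainty is the
geometric (fold) standard error 10^SE(log₁₀IC50); when the bottom bound
pins the covariance, the fit is repeated with bottom frozen to recover
it. For noisy replicate data, inverse-signal weights (constant-CV
weighting, matching the multiplicative noise) are the recommended and
tested scheme: unweighted fits let the high-signal plateau dominate and
recover the IC50 within 1.5-fold in only ~92% of trials, weighted fits in
~100%.

Derived metrics: selectivity = IC50_ATF2/IC50_MK2 (reported at 2
significant figures capped at 2 decimals, which reproduces the reported
table entries derivable from reported inputs; a censored ATF2 IC50
propagates to a "> bound" selectivity); shift = IC50_single/IC50_dual
(> 1 = left-shift); copies-per-cell → µM via c = n/(N_A·V) with cell
volumes in pl.

## Synthetic data

The noise model replicates each clean observation as y·e^ε,
ε ~ N(0, ln gsd), gsd = 1.2 by default (the fold-error style of the
emulated tables; the true plate noise magnitude is unpublished, so this
is a configurable stand-in), n = 2 replicates for compound curves and 4
for time courses. Zeros stay zero; gsd = 1 degenerates to exact
replication; one integer seed makes the bundle byte-reproducible
(sha256-checksummed manifest). The generator emulates fraction-of-maximum
readouts with multiplicative error only — no plate-position effects,
washing artifacts, detection-antibody kinetics or signal saturation — so
passing statistical tests demonstrate estimator correctness under the
stated noise model, not robustness to real plate pathologies.

## Interfaces

SBML L2V4 export writes species (nM initial concentrations, compartment
size 1), reactions and MathML mass-action kinetic laws with local kf/kr
parameters, sanitising ids (`:`→`_`, `*`→`star`) while keeping the
display name; every write is re-parsed and cross-checked. The import
reconstructs a simulatable network. CSVs use a fixed column schema and
17-significant-digit floats (round-trip < 10⁻¹² relative). The CLI is a
thin layer over these calls; its YAML config rejects unknown keys and
stamps outputs with a config hash.

## Problem sizes

The shipped suites use the sizes the analyses need and nothing more:
12-dose grids per curve, 6–8-point MK2 titrations, 200 seeded trials for
the recovery study, multisite grids up to 4 ATF2 × 3 MK2 sites
(≤ ~50 species, ≤ ~800 enumerated cycles). The full test suite runs in
under a minute; the acceptance script in a few seconds.

## Known limitations

- Single-compartment, activation-free, phosphatase-free biochemistry.
- The kinetic selectivity ceiling above means simulated single-assay
  selectivity understates equilibrium expectations for tight, slow-off
  substrates.
- Mechanism #3 cannot be made MK2-dose-insensitive with a shared ATP
  site (see Alternate mechanisms); its textbook flat titration is not
  reproducible from the reported constants.
- Fitted Hill slopes on simulated curves are effective parameters;
  multi-site binding polynomials are not fitted mechanistically.
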