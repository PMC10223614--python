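# Methods

This note records the modelling choices behind `gutflux`: what is being
computed, which constants are calibration versus convention, what the
synthetic generators do and do not emulate, and where the numerics need
care.

## Community model and growth allocation

Each taxon model is a per-gDW stoichiometric network: fluxes in mmol/gDW/h,
biomass flux normalized so unit flux is a growth rate of 1/h.  Communities
couple taxa through a shared lumen: each taxon keeps a private metabolite
compartment (`<taxon>__<met>`), its exchange reactions link the private
compartment to lumen metabolites (`<met>_lu`), and the lumen row of the
stoichiometric matrix weights taxon exchange fluxes by relative abundance
`a_i` (mass-fraction coupling).  Sign convention throughout: exchange flux
> 0 exports out of the compartment, < 0 imports.  Environment exchanges are
bounded below by the diet (`lb = −max_uptake`) and unbounded above.

Abundances are filtered at a cutoff of 1e-4 **relative** abundance and
renormalized; the filter normalizes counts-like input first, which makes it
idempotent.

Growth allocation is the cooperative trade-off with `τ = 0.7`:

1. LP: `μ_c* = max Σ a_i μ_i` subject to `S v = 0, lb ≤ v ≤ ub` (HiGHS).
2. QP: `min Σ μ_i²` subject to the same constraints plus `Σ a_i μ_i ≥ τ μ_c*`.
   The environment provides no QP solver, so the stage is solved with SLSQP
   on the exact gradient, started from the stage-1 vertex; the program is
   convex, and strict convexity in `μ` makes the growth rates unique.
3. LP polish: growth rates are fixed (slack 1e-9, retried at 1e-6) and total
   environment intake is minimized.  This removes the degeneracy of
   non-growth fluxes — the paper-style reports only ever read fluxes this
   polish pins down — and restores machine-precision steady state
   (`‖S v‖∞ ~ 1e-15` in practice, checked against 1e-6 everywhere).

`minimize_intake` is the parsimonious-medium LP (import slack variables, one
per environment exchange) at a growth floor; it doubles as the polish.

## Diets

The study conditions name three diet styles with printed shares of total
dietary energy: Atkins 1.7% carbohydrate / 70% lipid / 24% protein, vegan
63.35% / 20.99% / 15.66%.  A typical-US split of 50/35/15 is used for the
western style, which has no printed values.  Shares are realized as
exchange-bound tables using Atwater factors (4 kcal/g carbohydrate and
protein, 9 kcal/g lipid) converted to kcal/mmol by molar mass; each class
distributes its energy over a small nutrient roster (glucose + starch;
oleate; four amino acids).  The printed Atkins shares sum to 95.7%, so the
generated Atkins diet carries the residual 4.3% on a miscellaneous
energy nutrient of class "other"; the lipid share of *total* energy is then
exactly 70%.  Minerals and water carry zero energy in every style.

Total diet energy is 12 kcal on the flux basis.  This constant is sized so
that the western carbohydrate supply just limits the default community
(demand ≈ 6.4 mmol glc/gDW/h against a bound of ≈ 5.8): under-supply is what
makes diet styles distinguishable downstream (vegan, with more carbohydrate,
supports faster growth and higher acetate export; Atkins starves the
fermenters), mirroring the qualitative diet ordering of gut-community
simulations.

## Synthetic taxa and the 3:1:1 calibration

Toy taxon models are uptake → conversion-chain → biomass backbones with
growth-coupled secretion: one mol carbon source yields `growth_yield`
(default 0.05 gDW, giving μ_max = 0.5/h at the default 10 mmol/gDW/h uptake
capacity) plus fixed molar yields of each product.  Because secretion and
co-substrate consumption are stoichiometrically tied to growth, the solved
community fluxes are fully determined — intentional, so tests are exact.

The 12-taxon default roster names the key genera/species of the gut SCFA
economy (three *Bacteroides*, two *Coprococcus*, *A. putredinis*,
*B. adolescentis*, *C. aerofaciens*, *S. variabile*, *P. copri*, *R. bromii*,
*D. longicatena*, *L. rhamnosus*) with producer/consumer roles matching
field consensus: *Bacteroides*/*Prevotella* as acetate/propionate sources,
butyrate producers (*C. catus*, *S. variabile*) cross-feeding on acetate,
*R. bromii* as the starch specialist and net acetate consumer,
*D. longicatena* importing tryptophan, *B. adolescentis* importing
tyrosine/phenylalanine.  Net secretion yields are calibrated once so that
the equal-abundance preset exports acetate : butyrate : propionate =
7.2 : 2.4 : 2.4 = 3 : 1 : 1 per mol carbon — the canonical healthy colonic
SCFA ratio.  This is a generator constant, not a fit: in the interior
trade-off regime growth rates are proportional to abundances, lumen export
of metabolite m is proportional to `Σ_i a_i² r_im` (r = net mol per mol
carbon over growth yield), and with equal abundances the ratio reduces to
the yield sums above.

What the generator does **not** emulate: real strain-level stoichiometry
(AGORA models have thousands of reactions; these have ≤ ~40), genome-scale
redundancy and alternate pathways, pH/thermodynamic effects, lipid
catabolism (diet lipids are deliberately unusable by the toy taxa, as most
gut fermenters use them poorly), or compositional zero-inflation.  Passing
tests therefore validate the *pipeline arithmetic* — coupling, allocation,
sensitivities, statistics — not any biological claim about real guts.

## Paired studies and planted effects

`generate_paired_study` emulates a matched-pair design: each pair shares an
age (12–25) and gender, one member per status.  Log-abundances start from a
flat profile, receive a pair-level household effect (sd 0.15, common to both
members), the configured ADHD log-fold shifts, and independent per-member
log-normal noise, then renormalize.  Matching multinomial counts at a
documented pseudo-depth (10,000 reads) accompany the proportions because
Chao1 needs singletons/doubletons, which proportions cannot supply.

**Elasticity-variance planting.**  In the interior regime the elasticity of
lumen flux m to taxon k's abundance is `ε_m = C + 2 s_mk` with `s_mk` the
taxon's quadratic share of that flux and C common across the panel, so the
variance of k's elasticities across the flux panel is 4·Var_m(s_mk).  The
generator plants a wider ADHD spread by giving the ADHD member a *strain
variant* of the designated taxon whose per-product secretion yields are
scaled by `exp(±g)`, with `g` found by bisection on this closed form until
the share variance reaches the requested inflation (default 3×).  The
default designated taxon is *S. variabile*: its producer/consumer contrast
(butyrate out, acetate in) gives the largest deterministic baseline spread,
and a single designee avoids variants diluting each other through shared
product pools.

**Noise level.**  The pair classifier compares member variances at a
relative threshold θ = 0.2.  The default log-abundance noise sd of 0.015 was
set by a Monte-Carlo power analysis on the closed-form share model: at sd
0.03/0.02/0.015 the null (no planted effect) mislabel rate is 16%/4%/0.7%,
while a 3× planted inflation is detected with power ≈ 1 throughout; 0.015
keeps the operating point (≤5% null mislabels, ≥80% planted recovery)
satisfied with margin.  This sd models residual within-pair compositional
mismatch in a deliberately low-noise regime — real inter-subject variation
is far larger, and with realistic noise this classifier at θ = 0.2 would not
be usable without many more panel fluxes.

## Elasticities

Forward one-sided difference on the log scale (a single stated step rather
than a central pair), default h = 0.1 ⇒ a native 10.5% parameter increase.
Abundance parameters are bumped before renormalization (one taxon up, then
the vector rescaled — a compositional bump); diet parameters scale the
uptake bound.  The perturbed community is re-solved with the full
cooperative trade-off.  Direction (import/export) is recorded separately;
the magnitude enters the log.  Fluxes with baseline magnitude ≤ 1e-6
mmol/gDW/h yield *undefined* records — never ±∞ — as do fluxes that vanish
under the perturbation; infeasible perturbed solves flag their records.

Pair labels: per member, the sample variance of the taxon's defined
elasticities across the flux panel (the variance is taken across the flux
panel for the taxon's abundance parameter — one of several readings of
"variance of elasticity coefficients", fixed here and used consistently);
ADHD if the ADHD-member variance exceeds the control variance by more than
θ = 0.2 relative, Control for the reverse, Same otherwise, NA when the
taxon is absent from either member or fewer than two elasticities are
defined.  θ is a tunable with this default; the source analyses never
quantify "wider range".

## Diversity

Indices operate on counts (Chao1 is undefined on proportions); pipeline
input proportions are scaled by the pseudo-depth and rounded.  Chao1 uses
the bias-corrected `S + F1(F1−1)/2` when no doubletons exist.  Evenness is
Simpson evenness `(1/D)/S`.  Weighted UniFrac is the normalized variant
(bounded in [0,1]); both variants ignore the root edge.  Mann-Whitney U uses
the exact Gaussian-binomial null distribution for tie-free problems with
`n_A·n_B ≤ 400`, explicit permutation enumeration for small tied pools, and
a tie-corrected, continuity-corrected normal approximation otherwise.  The
F test is the plain two-sided variance-ratio test.  Implementations are
first-principles (scipy supplies only distribution functions); scikit-bio
and scipy.stats serve as cross-check oracles in the tests.

## Intervention

The probiotic dose moves the renormalized composition along the straight
segment from the sample towards the pure-probiotic vertex, so the
least-squares objective is a quadratic in `u = 1/(1+m)` and unimodal in m;
golden-section search on [0, 5] (doses are small in practice; the bracket is
generous) with boundary snapping.  The "randomly selected control" of the
source design is replaced by an explicit reference-sample argument with a
seeded random default — reproducibility over fidelity to an unstated RNG.
Flux shifts are `100·(post−pre)/|pre|` with pre-fluxes below 1e-6 flagged
undefined and sign changes across that band flagged as direction flips.
Exchange fluxes below 1 mmol/gDCW/h are reported as insignificant in the
panel summary.

## Sizes, determinism, degenerate inputs

The default pipeline (10 pairs, 12 taxa, 3 diets, elasticity on all diets)
performs ~400 trade-off solves and completes in about a minute on one core;
tests use 2–3 pair configurations, and the planted-recovery checks use 50
pairs with a single designated taxon.  All randomness flows from one global
seed through SHA-256-derived per-stage seeds (< 2^31), so any stage can be
re-run in isolation and manifests are bit-reproducible.  Degenerate cases
are contracts, not crashes: empty communities, all-zero samples, zero-energy
diets, zero-variance groups and unknown taxa raise typed errors; infeasible
or unbounded solves surface in the solution status.
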