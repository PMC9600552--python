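# Methods

`microgut` simulates the first weeks of the infant-gut microbial community
as a multiscale, spatially explicit dynamic flux-balance model.  This note
documents the model, its parameters, the numerical choices, what the bundled
toy networks do and do not represent, and the problem sizes the test suite
uses.

## Model overview

The colon is a regular 225 × 8 lattice of 2 mm × 2 mm sites (0.05 mL each,
90 mL in total), proximal at column 0.  Each site holds metabolite amounts
(μmol) and at most one bacterial population of a single species, sized in
bacteria.  One timestep represents 3 minutes; one simulated day is 480
steps.

Each timestep:

1. **Feeding.**  Every 60 steps (3 h) a pulse of 211 μmol lactose is split
   equally over the sites of the six most proximal columns.  Lactose is the
   only carbon input; water is symbolic (always available, never tracked).
   Oxygen, when enabled, is placed uniformly at t = 0 or released from the
   top and bottom rows each step.
2. **Metabolism.**  Every population solves an FBA problem (below) and
   applies the resulting exchange fluxes to its site and the ATP production
   to its own size (1×10⁹ bacteria per μmol ATP).
3. **Division.**  Populations at ≥1×10¹⁰ bacteria split in half into a
   uniformly chosen empty von-Neumann neighbor.  Boxed-in populations keep
   growing to at most 2×10¹⁰ and then suspend metabolism until space frees.
4. **Death, washout, colonization.**  Each population dies with probability
   0.0075 per step; populations in the distal column are deleted; each
   empty site gains a random roster species at 5×10⁷ bacteria with
   probability 5×10⁻⁵.
5. **Mixing.**  A Kawasaki-style sweep swaps site contents (populations,
   not metabolites) with a site drawn uniformly from self + first- and
   second-order neighbors; each site swaps at most once per sweep.
6. **Transport.**  Metabolites diffuse (forward Euler, D = 4.4×10⁻⁵ cm²/s)
   and then advect one column distally per step; the distal column's
   advecting content is removed and recorded as the outflow ("fecal")
   stream.  Oxygen diffuses but does not advect.

Runs are initialized by seeding each site with probability 0.3 with a
uniformly random roster species at 5×10⁷ bacteria (≈540 populations, ≈3×10¹⁰
bacteria on the default lattice).  All randomness flows from one seeded
`numpy` generator, so a run is bit-reproducible from (config, seed).

## FBA with an enzymatic constraint

Per population and timestep, with all fluxes in μmol per timestep per
population unit (1 unit = 10¹⁰ bacteria):

    maximize   f_ATP                      (ATP-drain objective)
    s.t.       S f = 0                    (steady state)
               Σᵢ fᵢ ≤ a                  (enzymatic constraint, a = 2)
               uptake(m) ≤ amount(m)/(B/U)  per metabolite m
               0 ≤ f                       (reversible reactions split)

The objective is a mass-neutral ATP hydrolysis drain (ATP + H₂O → ADP + Pᵢ):
ATP production proxies growth, and because the drain returns every atom, the
exchange fluxes of a valid solution carry zero net C, H, O and N.  The
enzymatic constraint caps the *summed* flux — exchange and objective columns
included — representing finite enzyme capacity per cell; because fluxes are
per population unit, the cap scales with population size.  It is what makes
yield/rate trade-offs (overflow metabolism, the bifid shunt switch) appear:
at scarce substrate the LP maximizes yield per substrate, at abundant
substrate it maximizes yield per unit of flux budget.

Numerical choices:

* LP solver: HiGHS.  A persistent warm-started model per species (via the
  binding shipped inside scipy) handles the lattice inner loop;
  `scipy.optimize.linprog` is the automatic fallback and the cross-check
  path in the tests.  Feasibility tolerances are 10⁻⁹.
* Alternate optima are resolved deterministically by a secondary
  minimize-total-flux criterion: by default a composite objective
  `f_ATP − 10⁻⁶·Σf` (one solve), with an exact two-stage mode
  (`solve_step(..., exact=True)`) that the tests verify against it.
* Lattice runs memoize solutions: per-unit uptake bounds are clamped at `a`
  (a bound above the summed-flux cap can never bind) and floored onto the
  dyadic grid `a·k/128` before solving.  Cached solutions are therefore
  always feasible for the true bounds; growth is under-estimated by at most
  ~0.8 % relative.  This is purely an evaluation-speed device and is off in
  `solve_step`.
* Sites whose non-water metabolite amounts are all below 10⁻⁹ μmol skip the
  LP (the solution is zero to solver tolerance anyway).

## Environment numerics

Diffusion uses one forward-Euler step of the 5-point Laplacian per timestep
with no-flux walls; the transfer fraction is D·Δt/Δx² = 0.198 per neighbor
(stability 4·0.198 = 0.79 < 1), and a configuration that violates stability
is rejected.  Diffusion conserves mass to machine precision; advection moves
whole columns, so the whole-run ledger

    inputs − outflow − Δ(lattice) − (biomass uptake − biomass secretion) = 0

closes to float round-off (verified per metabolite in the tests).

Advection is one site per step; on the default 225-column lattice a feeding
pulse therefore exits after ≈220–225 steps ≈ 11 h, the neonatal transit
time.  Lattice rescaling by a factor *n* on the site side follows the
1/n² rules for the initialization/colonization probabilities and the number
of mixing sweeps, with fractional sweeps run over a random site subset.

## Mixing calibration

"First- and second-order neighbors" is implemented as the 4 adjacent plus 4
diagonal sites (plus self, 9 candidates).  Measured by tracer mean-squared
displacement along the long axis (MSD = 2Dt fitted through the origin over
the first 50 steps), this yields D ≈ 5.4×10⁻⁵ cm²/s, within 6 % of the
target population diffusion constant of 5.7×10⁻⁵ cm²/s and 1.2–1.3× the
metabolite diffusion.  The wider 5×5 candidate block was rejected by the
same calibration (it gives ≈1.5×10⁻⁴ cm²/s, 2.6× too fast).  The neighbor
set is a parameter of `mix` for sensitivity work.

## Toy metabolic networks

Real GEM rosters (e.g. the 15 AGORA reconstructions of the infant
consortium) can be loaded from SBML/FBC, curated with the edit table, and
simulated unchanged.  For a self-contained artifact the package bundles
three hand-written archetypes whose lumped reactions are elementally
balanced (C/H/O/N, neutral-acid convention, NADH ≡ NAD + H₂) and
thermodynamically downhill on the supplied standard transformed formation
energies (pH 7, I = 0.1 M, Alberty-style values):

* **bifid_toy** — bifid-shunt fermenter.  Lactose → hexose pool → F6PPK
  (phosphoketolase, the knockout target) → 3 acetyl + 2 pyruvate + 2 NADH +
  2 ATP per lactose; acetate kinase adds 1 ATP per acetyl.  Pyruvate goes
  to lactate (reversible LDH; low-yield, flux-cheap: 5 ATP, 2 lactate,
  3 acetate per lactose) or through pyruvate-formate lyase and the
  ethanol branch (high-yield: 6 ATP with acetate:ethanol:formate 4:1:2).
  Under the constraint the optimum switches from the 4:1:2 profile to the
  3:2 acetate:lactate profile as lactose rises — the bifid shunt switch.
* **facan_toy** — facultative anaerobe.  Mixed-acid fermentation (6 ATP per
  lactose at best) and aerobic respiration (52 ATP per lactose with
  oxygen), so oxygen availability flips the community outcome; consumes
  lactate via reversible LDH.
* **cross_toy** — lactate specialist.  Propionate fermentation
  (3 lactate → 2 propionate + acetate + CO₂, 1 ATP per lactate) split into
  activation/rearrangement/fermentation steps so its summed-flux cost
  reflects the length of the real methylmalonyl pathway; lactose yields
  only 1 ATP per hexose.  Resulting ATP per unit flux budget on abundant
  lactose: 0.263 (bifid) > 0.235 (facultative) > 0.207 (cross-feeder); on
  lactate 0.167 (cross-feeder) vs 0.071 (others).  These orderings, not the
  specific numbers, carry the community dynamics: the primary-fermenter,
  early-aerobe and secondary-consumer niches.
* **broken_toy** — negative control that fabricates acetate from water; it
  fails the atom audit and the no-substrate growth check by design.

What the toys do *not* emulate: the 700-odd minor extracellular metabolites
of real reconstructions, amino-acid/mucin metabolism, strain diversity
within genera, d-lactate (tracked but unused by the toys), and realistic
absolute enzyme counts (reaction lumping is coarse).  Passing tests
therefore demonstrate the mechanisms — metabolic switching, oxygen-driven
succession, lactate cross-feeding, mass/energy conservation — not
quantitative agreement with any particular organism beyond the bracketed
bifid-shunt yields, which are pathway stoichiometry.

## Audits

* **Atom balance**: each solution's net exchange, formula-weighted over
  C/H/O/N, must vanish to 10⁻⁸ μmol (observed ≤ ~10⁻¹⁴ on desk runs).
* **Gibbs audit**: Δ_rG = Σᵢ F_net(i)·ΔfG′(i) over exchanged metabolites
  must be ≤ 0; the sign convention reported is outputs-minus-inputs, so
  admissible solves are negative ("energy loss").  Equality is admissible
  only at negligible growth.  Missing energies mark the audit partial
  rather than failing it.
* **Model checks**: growth on lactose (or lactate for lactate specialists)
  and exactly zero growth with only water open.

## Desk-scale problem sizes

The full study scale (225×8, 21 days, 30 replicates) is supported but the
test suite runs reduced conditions, chosen once as the smallest sizes at
which establishment stochasticity does not dominate the deterministic rate
ordering (initial populations die at 0.0075/step while the lactose band
passes a site only ~10 of every 60 steps, so establishment per initial
population is a low-probability branching event; the number of independent
attempts grows with lattice size):

* anaerobic succession: 150×6 lattice, 4 days, 5 seeds;
* initial-oxygen succession (0.1 μmol/site): 100×4, 6 days, 5 seeds —
  asserted as early facultative dominance followed by its replacement by
  anaerobes (in the source system the specifically-*Bifidobacterium*
  recovery takes weeks at full scale);
* phosphoketolase knockout and lactate-uptake block: 60×4, 2 days, 5 seeds;
* feeding pulses are scaled by height/8 so per-site dosing matches the
  default geometry.

## Known limitations

* One population per site: no within-site competition; uptake contention
  is resolved only through time.
* The enzymatic constraint weighs all reactions equally (no
  reaction-specific crowding coefficients), and lumping in the toys makes
  "one flux unit" coarser than in a full reconstruction.
* Advection of bacteria, pH, mucus/HMO substrates and host oxygen
  consumption are out of scope.
* The Gibbs table ships approximate literature values; audits with real
  GEMs should supply an eQuilibrator-derived table via `--gibbs-csv`.
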