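# Methods

## The model

`defensym` is an individual-based Monte Carlo simulator of an
aphid–endosymbiont–parasitoid system. A fixed population of `n_hosts = 200`
asexual, sessile hosts occupies distinct integer cells of a 500 × 500 grid;
a proportion of them carries a facultative defensive endosymbiont
(the motivating system is *Acyrthosiphon pisum* / *Hamiltonella defensa* /
*Aphidius ervi*, but nothing in the model is specific to it). Ten parasitoid
females forage on the grid. Discrete time steps advance one generation until
every host has either died naturally or been successfully parasitised; the
progeny frequencies then seed the next generation, for `n_generations = 100`
by default.

Within one generation:

1. **Layout.** Host cells are drawn uniformly without replacement. Exactly
   `n_infected` hosts are flagged infected with a controlled aggregation
   level `a ∈ (0, 1]`: the number of patches is `round(a · n_infected)`
   (clamped to `[1, n_infected]`), patch sizes differ by at most one, each
   patch centre is uniform over the continuous grid extent, and each patch
   in turn claims its size in nearest unflagged hosts (greedy, Euclidean
   distance). `a = 0.005` puts a typical cohort in one clump, `a = 1`
   yields an effectively random infection pattern. The same procedure is
   reapplied every generation, so the aggregation level is a constant of
   the simulation.
2. **Life histories.** Longevity is Exponential and fecundity Poisson, with
   means `S_un = 150` steps and `λ_un = 60` progeny for uninfected hosts;
   infected hosts pay a constitutive cost `c`, scaling both means by
   `1 − c`. Reproduction is spread over life at a constant per-step rate
   `f / L`. Wasps draw longevity Exponential(`S_p`) and a proovigenic egg
   supply Poisson(`λ_p = 150`).
3. **Horizontal transmission.** Each step, an uninfected host at distance
   `d` from a live donor acquires the symbiont from that donor with
   probability `exp(−(1 − h) d)`; independent trials over donors combine to
   `1 − Π_i (1 − exp(−(1 − h) d_i))`. A convert immediately pays the cost
   on its remaining longevity and rate, transmits vertically to all progeny
   it produces from that step on, but — see below — does not itself become
   a horizontal donor within the same generation.
4. **Foraging.** Each live wasp (randomised order per step) picks a target
   among all live hosts with weight `exp(−κ d)`, moves straight toward it
   at a Normal(`μ = 10`, `σ = 5`) step length truncated at zero (negative
   draws redrawn), and attacks on arrival: an uninfected host is killed and
   receives one egg; an infected host escapes with probability `R`, staying
   alive, perceivable and reproducing. Dead hosts are never attacked
   (no superparasitism). Wasps die when their lifetime elapses or their
   eggs run out; they cannot discriminate infected from uninfected hosts
   and do not evolve.
5. **Turnover.** Vertical transmission is perfect, so the next generation's
   infected count is a Binomial(`n_hosts`, `p′`) draw with
   `p′ = progeny_infected / progeny_total` (deterministic rounding is
   available as a toggle). Zero total progeny is recorded as extinction.
   `p = 0` and `p = 1` are absorbing.

**Pest-control efficacy** is measured over a single generation: the same
host realisation (layout, infection pattern, life-history draws — common
random numbers, asserted by fingerprint) is run once without wasps and once
with them, and efficacy is `100 × (control − treatment) / control` percent,
averaged per-replicate. Averaging the per-replicate percent reductions was
preferred over the ratio of averaged progeny totals; with common random
numbers the two differ only slightly, and the per-replicate average comes
with a straightforward SE. Horizontal transmission stays active in the
control arm: it is part of host biology, not of parasitism.

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| `n_hosts` | hosts per generation | count | 200 |
| `n_parasitoids` | foraging wasp females | count | 10 |
| `p0` | initial infected proportion | fraction | 0.20 |
| `a` | aggregation level (patches per infected host) | fraction | 0.04 |
| `s_un` | mean uninfected host longevity | time steps | 150 |
| `lambda_un` | mean uninfected host fecundity | progeny | 60 |
| `c` | constitutive infection cost | fraction | 0.4 |
| `h` | horizontal-transmission intensity | – | 0.8 |
| `s_p` | mean wasp longevity | time steps | 100 |
| `lambda_p` | mean wasp egg supply | eggs | 150 |
| `r` | resistance of infected hosts | probability | 0.9 |
| `mu`, `sigma` | wasp step length (Normal, truncated at 0) | cells | 10, 5 |
| `kappa` | perception decay | 1/cell | `1/mu` |

The population sizes, `p0`, host means, `λ_p` and movement parameters are
the fixed study conditions. `c`, `h`, `s_p`, `r` and `a` are the
experimental axes; their defaults are the central anchor values at which
the other axes are examined (`c = 0.4`, `h = 0.8`, `S_p = 100`, `R = 0.9`,
`a = 0.04` "aggregative"). The named sweep presets in
`defensym.FIGURE_PRESETS` encode the full grids (`c ∈ {0.2…0.6}`,
`R ∈ {0, 0.1, …, 1}`, `S_p ∈ {0, 20, …, 300}`,
`h ∈ {0, .2, .4, .6, .8, .9, 1}`, `a ∈ {0.005, 0.04, 1}`, efficacy at
`p0 ∈ {0.2, 0.5, 0.8}`). The transmission-by-aggregation preset fixes
`R = 0`: with strong protection the selective advantage of infection
saturates at fixation for every aggregation level, and the
transmission-by-aggregation effect it isolates would be invisible.

`kappa` is an implementation parameter: the perception weight needs a decay
scale and `1/mu` keeps perception commensurate with locomotion, so
behaviour is stable under grid rescaling.

## Design choices in genuinely open corners

- **Step quantisation.** Longevities are continuous draws compared against
  the integer step counter: an individual completes step `t` iff
  `t + 1 ≤ L`, living `floor(L)` whole steps. The alternative — granting a
  partial step a full reproduction tick — weights a host by
  `f · ceil(L)/L`, whose expectation diverges as `L → 0` under the
  Exponential draw; tallies would be dominated by the shortest-lived hosts
  and every trajectory would random-walk to fixation or loss. With floor
  quantisation a host's lifetime contribution `rate × floor(L)` never
  exceeds its drawn fecundity; the downward bias (`E[floor(L)/L] ≈ 0.97`
  at `S_un = 150`) applies identically to both infection classes.
- **Donor competence.** Hosts converted by horizontal transmission do not
  act as horizontal donors until the next generation (their progeny are
  infected, and they are donors from birth thereafter). If converts
  transmit from the next time step, any infected clump becomes a travelling
  conversion wave: successive boundary hosts convert and immediately relay,
  so even the most aggregated layout saturates the grid within a
  generation and the aggregation level has no limiting effect on spread —
  contrary to the central role host clumping plays in these systems.
  Biologically, a freshly acquired symbiont must first establish and reach
  transmissible titres, which takes longer than one foraging time step.
  The toggle `chain_transmission=True` restores within-generation relay for
  sensitivity analysis.
- **Multiple donors** combine as independent Bernoulli trials (union of
  events). `h = 0` is implemented literally (`exp(−d)`, non-zero at short
  range); `transmission_enabled=False` provides the true
  zero-transmission control.
- **Retargeting.** A wasp re-selects its target every step, which
  automatically handles targets killed by other wasps; the nearest host
  carries the largest weight, so pursuit converges. `sticky_target=True`
  keeps the current target while it lives. A wasp may re-attack a resisting
  host (it stays a valid target, often at distance zero); attacks are
  restricted to the current target.
- **Phase order** within a step: natural deaths → transmission → parasitoid
  phase → reproduction. Reproduction last means a host attacked at step `t`
  does not reproduce at step `t`. Newly infected recipients are processed
  synchronously (one uniform per recipient, host-index order).
- **Fast-forward.** Once no wasp can ever act again *and* transmission can
  no longer fire (no live donor/recipient pair, or transmission disabled),
  each survivor's remaining reproduction `rate × (floor(L) − t)` is accrued
  in closed form — identical to continued stepping, just without the loop.
  While live donors and recipients coexist the engine keeps stepping, since
  conversions would still alter the progeny split.
- **Efficiency.** Hosts are stationary within a generation, so the pairwise
  `log(1 − exp(−(1−h)d))` matrix is computed once per generation and the
  per-recipient log-survival sum is refreshed only when the donor set
  changes. This is an exact reorganisation, not an approximation.
- **Randomness.** One `numpy` Generator drives a run; the per-step draw
  order is documented in `defensym.engine` so an independent trace can
  reproduce the engine exactly (this is tested). Replicates use
  `base_seed + i`; sweep cells derive a seed from a hash of the cell's
  parameter fingerprint, so any cell reruns bit-identically in isolation.

## What the simulator does and does not emulate

The generator *is* the study system: stochastic life histories, spatially
explicit distance-dependent transmission and foraging, and demographic
stochasticity in generation turnover. It deliberately omits: host movement
(aphids treated as sessile), superparasitism, egg maturation (wasps are
proovigenic), induced (attack-triggered) infection costs, imperfect
vertical transmission and symbiont loss, host stage structure,
density-dependent host regulation beyond the fixed 200-host reset, and any
evolution of parasitoid virulence. Passing tests therefore speak to the
dynamics of this idealised system, not to quantitative prediction for any
real aphid population; parameter units are arbitrary model units.

## Numerical notes and degenerate inputs

- Probabilities combine in log space (`log1p`/`expm1`); pairs with
  `exp(−(1−h)d) < 1e−12` cannot fire at double precision (tested).
- `c = 1` gives zero-mean (degenerate) draws: longevity, fecundity and rate
  are exactly 0. A zero-longevity host dies before its first step.
- `S_p = 0` wasps die before acting; every host then dies naturally.
- Host cell coordinates are integers; patch centres and wasp positions are
  continuous. Distances are Euclidean with hard grid edges (no torus).
  Straight-line movement between in-grid points cannot leave the grid.
- Nearest-host ties in patch assignment break by host index (stable sort);
  target-selection weight underflow (all weights 0) falls back to the
  nearest host.
- Extinct replicates (no progeny at all) are excluded from steady-state
  means and reported as a count.

## Problem sizes used by the test suite and acceptance script

The full study conditions (200 hosts, 100 generations, 100 replicates) are
the package defaults. The test suite exercises the headline contrasts at
20 replicates of 100 generations each, and the acceptance script reports
steady-state cells at 10 replicates and efficacy cells at 20 paired
replicates — sizes chosen so the whole battery runs on a laptop-class CPU
in minutes while leaving the reported contrasts many standard errors wide.
`n_replicates=100` reproduces the full-size experiments via the library or
CLI.

## Known limitations

- The `a = 1` "random" pattern is generated by the same centre-based
  procedure as every other aggregation level (one patch per infected
  host); nearest-host-to-random-centre sampling is only approximately a
  uniform choice of infected identities (Voronoi-area bias).
- Efficacy is undefined when the control generation produces no progeny;
  such replicates are excluded and counted.
- With `chain_transmission=True` the aggregation effect on spread largely
  disappears (see above); the toggle exists for sensitivity analysis, not
  as an alternative default.
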