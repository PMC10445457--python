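# Methods

## Hardware model

A droplet's lifecycle is a rigid seven-stage chain:

| stage | resource(s) | default duration |
|---|---|---|
| prep | liquid_handler | 120 s |
| transit_in | main_flowpath | 60 s |
| rinse_a | main_flowpath | 90 s |
| residence | reactor *i* | job-specific |
| transit_out | main_flowpath | 60 s |
| rinse_b | main_flowpath **and** reactor *i* | 120 s |
| analysis | hplc | 300 s |

Immediacy constraints make every offset rigid: a prepared droplet transits
to its reactor at once (room-temperature reactivity), the residence clock
starts when transit_in ends, transit to analysis follows the residence
immediately, and each transit is followed by its rinse/vent without a gap.
rinse_a cleans only the flowpath and runs concurrently with the residence;
rinse_b cleans the flowpath *and* the droplet's reactor, so the reactor is
free for a new droplet only after rinse_b ends. HPLC analysis starts at the
end of transit_out and may overlap rinse_b (disjoint hardware). A single
job's span is therefore the sum of its stage durations minus those two
permitted overlaps (540 s for a 300 s residence with all other stages at
60 s).

Intervals are half-open `[start, end)`: back-to-back occupancy of a
resource is legal, and a *collision* is any positive-measure overlap of two
**distinct** droplets on one resource. One droplet's own stages may overlap
(its rinse_a is still running when a very short residence ends); that is
physically a droplet waiting on its own rinse, not a collision, and all
three collision checkers treat it identically. The several rinse droplets
of the physical platform are folded into one aggregate duration per rinse
type; stage durations are configuration, not constants, since they depend
on the installed pumps and HPLC method.

## Scheduler

Jobs are sorted by the LPT rule — descending residence time, stable under
ties — and laid out with back-to-back preparation: job *i* preps when the
liquid handler frees from job *i*−1, and takes the reactor that frees
earliest (lowest index on ties). That layout may contain collisions.

`resolve` then scans droplets in execution order and delays each droplet's
preparation — in whole multiples of the scheduler time unit (default 1 s) —
until its rigid chain is collision-free against every droplet committed
before it. Preparations are only ever delayed, never advanced, and never
leapfrog a later droplet's preparation, so execution order is preserved;
an already-feasible schedule is a fixed point. The sweep is O(n²) with
small constants (500 jobs in about a second) and, on exhaustively
enumerable instances (≤4 jobs, ≤2 reactors, unit-scale durations), its
makespan equals the brute-force minimum over all order-preserving delay
vectors on the time grid.

Reactor assignment is fixed before shifting and not revisited — a known
limitation: a different assignment could occasionally admit a shorter
schedule. Heating and cooling are deliberately **not** scheduled; instead
`temperature_change_warnings` flags consecutive jobs on one reactor whose
setpoints differ by more than a threshold (default 20 °C), since the
control layer will pause production there.

### When LPT helps — and when it does not

In the platform's operating regime — a batch that fits the reactor bank,
with analysis faster than droplet preparation — the makespan is
max<sub>i</sub>(i·t_prep + span<sub>i</sub>), which longest-first ordering
minimizes; across 100 random instances in that regime LPT beats the
arbitrary input order in aggregate mean. When a downstream bottleneck
binds (HPLC slower than prep, or heavy reactor reuse), longest-first
ordering *synchronizes* the outbound transits — a long residence prepared
early and a short residence prepared late arrive at the flowpath and HPLC
together — and LPT can lose to an arbitrary order. The LPT default is kept
because it matches the platform's intended use; callers scheduling
bottleneck-bound batches may pass their own order to `initial_schedule`.

## Discrete-event simulator

`simulate` replays a schedule as acquire/release events under exclusive
occupancy and records every double-acquire as a conflict (it keeps running
to collect all of them), which makes it an oracle independent of the
scheduler's interval arithmetic — the two agree on feasibility across
randomized batches by test.

With `pause_for_temperature` on, droplets are admitted in scheduled prep
order; each droplet's whole chain is delayed rigidly until (a) its
reactor's simulated temperature reaches the droplet's target and (b) every
resource it needs is free (first-come-first-served per resource), so pauses
only ever delay and can never create conflicts. Reactor temperature is
piecewise linear: it holds while a droplet occupies the reactor, then ramps
toward the next droplet's setpoint from the moment the reactor is released
(end of rinse_b), at `heat_rate` (default 1.0 °C/s — cartridge heaters are
fast) or `cool_rate` (default 0.1 °C/s — cooling takes minutes). By default
each reactor starts at its first droplet's target (pre-equilibrated);
passing `initial_temp` starts the bank at ambient instead. Whether the real
control software also holds inter-stage transfers during equilibration is
unknown; only preparation is paused here.

## Kinetics

The benchmark chemistry is the SNAr reaction of 4-fluoronitrobenzene (ArF,
limiting) with 1-methylpiperazine in acetonitrile, third order overall:

    d[ArF]/dt = −k [ArF] [R₂NH]²

The amine is consumed at `amine_stoich` = 2 mol per mol ArF by default (one
equivalent as nucleophile, one scavenging HF); the generator and the fitter
share this setting, and it is configurable to 1. Initial amine
concentration defaults to 2.08 M (2.0 equivalents against the 1.04 M ArF
condition) — a typical excess for this chemistry, fixed across both ArF
levels of the campaign design.

Integration uses adaptive LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰, tight enough
that solver bias is far below measurement noise; mass balance
([ArF] + product constant) holds to 10⁻⁸ M by test against a fixed-step RK4
oracle. `fit_rate_constant` minimizes squared residuals of measured [ArF]
against the integrated model jointly across all initial-concentration
groups at one temperature, parametrising k on a log scale (positivity);
flat data are reported as k = 0 with infinite standard error rather than an
error. The standard error comes from the Gauss–Newton approximation with
the delta method for the log-parametrisation.

Eyring analysis is ordinary (unweighted) least squares of ln(k/T) on 1/T —
"linear regression" in the plain sense; ΔH‡ = −slope·R and
ΔS‡ = (intercept − ln(k_B/h))·R with CODATA constants at full precision,
and standard errors propagate linearly from the slope/intercept errors
(undefined, reported as NaN, for a two-point fit). Internally everything is
SI (M, s, K); the reporting layer prints k × 10⁴ as is conventional for
this reaction.

On the four measured rate constants (3.32, 5.00, 7.90, 10.6 × 10⁻⁴
M⁻² s⁻¹ at 60–90 °C) the regression gives ΔH‡ = 36.8 kJ/mol and
ΔS‡ = −202 J/(mol K); excluding 90 °C gives 39.5 kJ/mol and −194
J/(mol K). Both are recomputed at runtime by `scripts/acceptance.py` and
asserted in the test suite.

## Bayesian optimizer

Mixed domains are encoded as min–max-scaled continuous features plus
one-hot categorical blocks; `decode(encode(x)) == x` by property test. The
surrogate is a Gaussian process with a constant × Matérn-5/2 kernel plus a
fitted white-noise term (ARD off), `normalize_y` on, hyperparameters by
marginal-likelihood maximization at each refit. Before `n_init` = 5
observations, proposals are space-filling (seeded Latin hypercube over the
continuous block, uniform categorical levels). After that, each proposal
draws one acquisition from {UCB (β = 2), EI (ξ = 0.01), Thompson (one joint
posterior sample)} according to the current sampling weights and returns
the acquisition's maximizer over a candidate pool of ≥ 2000 seeded random
points plus Gaussian perturbations (σ = 0.05 in encoded units) of the five
best observed conditions. Acquisition maximization by pool search — rather
than a dedicated global optimizer — is deterministic given the seed and
adequate at these dimensionalities (≤ 10).

`tell` multiplies the weight of any acquisition whose proposal improved the
incumbent by 1.5, then renormalizes with a floor so every acquisition keeps
at least `0.1 / 3` sampling probability and never starves. Batch asks rely
on the acquisition-sampling diversity itself (no fantasization) — a known
limitation for large parallel batches. Everything (LHS, pool, acquisition
draw, Thompson sample, GP restarts) derives from the single campaign seed,
so identical seeds give identical trajectories.

## Virtual bench

The SNAr generator integrates the rate law with ground-truth rate constants
seeded from the measured values and applies multiplicative Gaussian noise
(measured = true·(1 + ε), ε ~ N(0, σ), clipped at 0) — reproducibility on
such platforms is quoted as a relative SD, and replicate experiments showed
about 3 % — with σ = 1 % for kinetics recovery studies (HPLC quantitation
of a single analyte is more precise than full reaction outcomes). The
campaign design is two ArF levels × five residence times (5–40 min) at
70 °C plus one level × five times at 60, 80 and 90 °C: 25 measurements.

The Buchwald–Hartwig surface is *qualitative-faithful, not data-fitted*:
response = catalyst multiplier (tBuBrettPhos Pd G3 1.0, tBuXPhos Pd G3 0.7,
XantPhos Pd G3 0.02 — a dead catalyst for campaigns that offer it) × base
multiplier (DBU 1.0, BTMG 0.8) × a temperature term rising linearly from
0.4 at 50 °C to 1.0 at 100 °C × a residence-time term varying ≤ 5 %. Its
optimum — (tBuBrettPhos Pd G3, DBU, maximum temperature), response 1.0 — is
seed-invariant; only measurements are stochastic (3 % relative SD, the
normalized objective invariant to the internal-standard scale by
construction). All quantitative optimizer claims are stated against this
bench's own optimum, never against campaign values from real chemistry,
which depend on the actual reaction system and are not reproducible in
silico.

What the bench does **not** emulate: solvent evaporation and headspace
effects, liquid-handler charge errors, chromatographic peak overlap,
response-factor drift, or any interaction terms between temperature and
catalyst. Passing tests therefore demonstrate the correctness of the
algorithms under the stated noise model, not performance on real chemistry.

## Problem sizes and determinism

The test suite runs the scheduler feasibility study at 200 random batches
(1–50 jobs, 1–10 reactors), the oracle comparison on 12 exhaustively
enumerable instances, the kinetics recovery at 100 seeds (single
temperature) plus 50 seeds (full design), and the closed-loop study at 20
seeded campaigns of 30 experiments — sizes chosen so the whole suite
completes in a few minutes on one core while keeping the Monte-Carlo
medians stable. Every stochastic component takes an explicit seed;
identical seeds reproduce identical outputs byte-for-byte (manifests
record command, seed, input hashes and package version, excluding
timestamps).

## Known limitations

* Reactor assignment is a pre-pass heuristic; no joint
  assignment-and-delay optimization.
* The scheduler ignores heating/cooling; the simulator's pause model is the
  corrective, and makespans under large temperature swings are accordingly
  larger than scheduled.
* LPT is a heuristic whose advantage inverts in bottleneck-bound regimes
  (see above).
* The GP surrogate treats one-hot dimensions as ordinary coordinates; no
  categorical-specific kernel.
* Single-objective optimization only.
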