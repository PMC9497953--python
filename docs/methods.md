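# Methods

## Model

`riskgame` simulates a finite, well-mixed population of `N = a·n`
individuals facing a recurring collective risk. Each round is a threshold
public-goods game played in `a` randomly drawn subgroups of size `n`:
members are endowed `m` units, collaborators (strategies `C`, `CP`, `PP`)
pay a contribution `u`, and the subgroup survives the risk only if its
total contribution reaches the threshold `U`. Survival leaves balances
untouched; failure sets every member's balance — collaborator and
defector alike — to exactly zero. Individual payoffs are therefore a
segmented (all-or-nothing) function of the subgroup's collaboration
level, which distinguishes the collective-risk dilemma from a linear
public-goods game.

Two sanctioning mechanisms act on defectors (`D`), both local to the
round's subgroup:

* **Central (pool) punishment.** Every `CP` member pays `w1` toward a
  sanctioning institution. If the subgroup's pooled fund `w1·n_CP`
  reaches the establishment threshold `w`, the institution forms and
  docks each defector `t1` — exactly once per round, however many `CP`s
  support it.
* **Peer punishment.** Every `PP` member punishes every defector in the
  subgroup (all-against-all): the punisher pays `w2` per act, the
  defector loses `t2` per act, with `w2 ≤ t2` enforced. A defector in a
  subgroup with several punishers is therefore docked `t2·n_PP`, and a
  punisher facing several defectors pays `w2·n_D`.

Between rounds, strategies evolve by pairwise imitation: each individual
`i` draws one model `j` uniformly from the rest of the population and
adopts `j`'s strategy with the Fermi probability
`p_ij = 1 / (1 + exp((r_i − r_j)/β))`, where `r` are the end-of-round
balances. All comparisons use the frozen end-of-round snapshot and are
applied simultaneously (synchronous update). Afterwards exactly
`round(α·N)` distinct individuals (round half to even) mutate, each to a
strategy drawn uniformly from the allowed set minus its current one.

## Parameters

| symbol | meaning | default | note |
|--------|---------|---------|------|
| `N, a, n` | population, subgroup count, subgroup size | 100, 10, 10 | `N = a·n` enforced |
| `m` | per-round endowment (units) | 10 | |
| `u` | contribution (units) | 5 | `u ≤ m` |
| `w1, w` | per-`CP` institution support; establishment threshold | 2, 4 | two supporters suffice |
| `w2` | cost per peer-punishment act | 1 | `w2 ≤ t2` |
| `t1, t2` | punishment intensities (units docked) | swept: `t1 ∈ [2, 9.5]`, `t2 ∈ [1, 6.5]`, step 0.5 | `t1 = 2·t2` makes the types cost-comparable (`t1:t2 = w1:w2`) |
| `U` | risk-resistance threshold (units) | 25; swept over {15, 25, 35} | 15/25/35 require 3/5/7 contributors |
| `β` | learning temperature | 0.1 | smaller = more deterministic copying |
| `α` | mutation rate | 0.05 | 5 mutants per round at `N = 100` |
| `rounds` | rounds per run | 3000 | see below |
| `stable_window` | trailing rounds for stable-state statistics | 500 | |
| `replicates` | default replicate count | 20 | |

## Statistics

All statistics are window averages; "stable state" is the trailing
`stable_window` rounds, "process" is every round.

* **Collaboration rate** — fraction of individuals belonging to subgroups
  that met `U`. All members of a successful subgroup count, defectors
  included (they, too, survived the risk); a collaborators-only variant
  is available via `mode="collaborators_only"`.
* **Enhancement** — collaboration rate of the full four-strategy run
  minus a matched-seed run with one punisher strategy removed
  (`{C,D,PP}` isolates central punishment, `{C,D,CP}` isolates peer
  punishment). Reduced and full runs at a grid cell share the replicate
  seed, so the subtraction is paired; because the excluded strategy makes
  its intensity inert, a reduced run is reused along that axis.
* **Cost–benefit ratio (CBR)** — resources docked per defector divided by
  cost paid per punisher of that type. Numerators and denominators are
  pooled over the window before dividing (ratio of means), which stays
  well defined in rounds without defectors or punishers; a ratio whose
  punisher type or defector pool is empty over the whole window is NaN.
  Closed forms used as cross-checks: `cbr_peer = (t2/w2)·(ΣPP/ΣD)`
  whenever defined, and `cbr_central ≤ t1/w1` with equality only if every
  defector sat under an established institution.
* **Resource wastage** — `k` = mean subgroup contribution minus `U`,
  zoned insufficient (`k<0`), none (`0≤k<3`), slight (`3≤k<6`), waste
  (`k≥6`). `k` is defined at subgroup level: the cutpoints correspond to
  fractions of one extra contributor's `u = 5`.

## Design choices at genuinely open points

* **Institution scope** is per subgroup: the fund is pooled from the
  subgroup's own `CP`s, matching every other subgroup-local mechanic.
* **`w1` is sunk**: it is paid whether or not the fund reaches `w` — the
  support payment is an upfront investment, not a refundable pledge.
* **Balances may go negative** before risk resolution (heavy punishment
  stacks linearly; no floor), keeping the cost–benefit accounting linear.
  Failure then clears negative balances to zero as well — "losing
  everything" is read literally as a reset.
* **Imitation is population-wide**: the `N` individuals form one learning
  pool; a subgroup-scoped variant is available
  (`LearningConfig(partner_scope="subgroup")`) but off by default.
* **Learning precedes mutation**, one imitation event per individual per
  round, resources compared are the single current round's balances
  (endowments are reissued each round and failure zeroes balances, which
  is only coherent per round).
* **Thresholds are inclusive** (`w1·n_CP ≥ w`, `Σu ≥ U`).

## Numerical and implementation choices

* Resources are float64; parameters are small rationals (halves), so
  threshold comparisons are exact up to a 1e−9 guard tolerance.
* The Fermi probability uses the overflow-safe logistic (`expit`),
  saturating to 0/1 for large gaps.
* The production loop is a numba-compiled kernel that consumes the
  *identical* random stream as the composed reference operations
  (partition → contributions → central → peer → risk → learning →
  mutation); a regression test asserts bit-identical time series between
  the two engines. Mutation picks distinct individuals by partial
  Fisher–Yates so both paths draw the same sequence.
* One `numpy.random.Generator` (PCG64) per run seeds every draw; sweep
  rows derive unique 31-bit seeds via SHA-256 of the parameter tuple,
  while the figure experiments share one seed per (U, replicate) to keep
  comparisons paired.

## Run length, windows and replicate counts

Runs use `T = 3000` rounds with a 500-round trailing window and 20
replicates (10 for the 6×6×3 coarse-grid enhancement surfaces). The
dynamics reach their quasi-stationary regime within a few hundred rounds
from the uniform random start; the trailing window is used instead of a
literal final round to tame single-round noise, and halving it does not
visibly move the statistics. The coarse grid (`t1` step 1.5, `t2` step
1) is the package's desk-scale default for surface extremes; the full
16×12 grid is available through the same functions.

## What the simulation does and does not capture

The generator *is* the study system — there is no external data. It
emulates a well-mixed population with uniform random initial strategies,
global imitation and re-randomized subgroups each round. It does not
model spatial or network structure, persistent group membership,
defecting punishers (`CD`/`PD`), antisocial punishment, or heterogeneous
endowments; conclusions from the test suite are claims about this model,
not about behavioural data.

A structural property worth knowing when interpreting sweeps: with
`β = 0.1` and per-round balances spanning several units, the Fermi rule
is effectively a step function of the payoff sign, so strategies that
are strictly payoff-dominated in most rounds (the punisher minorities)
are held near the mutation floor `α·N/(|S|−1)` rather than at an
interior selection equilibrium. Stable-state punisher shares — and with
them the stable-state cost–benefit ratios — are therefore driven mainly
by the mutation rate and the frequency of payoff ties (e.g. `PP` ties
with `C` exactly when its subgroup holds no defector), not by the
punishment intensities themselves; intensities act chiefly through how
hard defectors are hit while punishers are present.
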