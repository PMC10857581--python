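# Methods

## Model

One-shot threshold public goods game (collective-risk dilemma) in groups
of `N` seats. A defector in a group with `j` cooperators earns
`π_D(j) = b (1 − r + r θ(j − M))`; a cooperator earns `π_C(j) = π_D(j) − c b`.
`θ` is the unit step with `θ(0) = 1` — the convention lives in a single
function (`hybridcrd.game.heaviside`) and every threshold comparison in
the package routes through it. Payoffs may be negative (a cooperator
missing the threshold at `r = 1` nets `−c b`); no clamping is applied.

Hybrid groups contain `N − a` adaptive seats plus a block of `a` fixed
agents that cooperates **as one perfectly correlated unit** with
probability `p` per interaction: every hybrid expectation is the
two-point mixture `p f(j = i + a) + (1 − p) f(j = i)`. Modeling the
agents as `a` independent Bernoulli(p) contributors is a deliberately
excluded variant — it changes every derived surface.

The adaptive population of size `Z` evolves by the pairwise-comparison
rule: pick a focal individual uniformly; with probability `μ` flip its
strategy; otherwise pick a role model uniformly among the other `Z − 1`
(nothing happens if strategies match — no resampling) and imitate with
the Fermi probability `1 / (1 + e^{−β(f_rm − f_focal)})`. Fitness is the
exact expectation of the hybrid payoff over the multivariate
hypergeometric draw of `N − a − 1` co-players from the other `Z − 1`
individuals. The cooperator count `k` then performs a birth–death chain
with

```
T+(k) = ((Z−k)/Z) (μ + (1−μ) (k/(Z−1))      P(D→C))
T−(k) = ( k   /Z) (μ + (1−μ) ((Z−k)/(Z−1))  P(C→D))
```

### The mutation term

The bare imitation transitions (exposed as `transitions="printed"`) have
no additive mutation inflow; under them `k = 0` and `k = Z` are absorbing
and no unique stationary distribution exists. The update protocol above
— a focal individual mutates unconditionally with probability `μ` —
yields the additive `μ` term, restores ergodicity, and is the package
default (`with-mutation`). `stationary_distribution` refuses `μ = 0` and
the printed mode rather than return a degenerate or non-unique vector;
the printed transition probabilities themselves remain inspectable
through `transition_plus/minus` and `transition_matrix`.

## Stationary solver

Birth–death chains are reversible, so the stationary vector has the
closed product form `P(k) ∝ Π_{j<k} T+(j)/T−(j+1)`, accumulated in log
space (at `Z = 100` the raw products over/underflow). The default method
additionally computes the eigenvalue-1 eigenvector of the transposed
row-stochastic transition matrix with `numpy.linalg.eig`, takes the
eigenvalue closest to 1, and fails loudly if the two vectors disagree
beyond `1e−8` sup-norm (observed agreement at the default parameters is
~`1e−13`). The **returned** probabilities are the product-form values:
the eigenvector carries O(machine-eps) absolute noise that, on tail
entries of order `1e−9` (the mutation floor at `Z = 100`), amounts to
~`1e−6` relative error and would break detailed balance checks, whereas
the closed form satisfies `P(k) T+(k) = P(k+1) T−(k+1)` to ~`1e−15`
relative.

Other numerical choices:

- Binomial coefficients are exact integers (`math.comb`), routed through
  `binom_safe(n, r) = 0` outside `0 ≤ r ≤ n` so boundary states of the
  hypergeometric sums vanish instead of erroring; division by the
  normalizing coefficient happens once per sum.
- Fermi exponents are clamped to ±700 before exponentiation; at extreme
  fitness differences the probability saturates at 0/1 within double
  precision.
- `f_C(0)` and `f_D(Z)` are undefined by the model and set to 0; the
  imitation factors `k/(Z−1)` and `(Z−k)/(Z−1)` vanish exactly there, so
  the values are never consumed (asserted in tests).
- Derived probabilities are clipped to [0, 1] only against float dust
  (≤ `1e−9`); larger excursions raise.

## Observables and controls

`C̄ = Σ P(k) k/Z`; `s_G(k)` is the hypergeometric threshold-attainment
probability with the agent block realized all-or-none (marginal
semantics, mirroring the payoff expectation); `s̄_G = Σ P(k) s_G(k)`.
`s_G(k)` is non-decreasing in `k` and affine non-decreasing in `p` at
fixed `k`, but the end-to-end `s̄_G(p)` need not be monotone because
`P(k)` itself shifts with `p` — the balanced scenario (`a = 3`) at high
risk shows an interior dip in success between the compensation region
(low `p`, humans carry the goal) and the agent-driven region (`p → 1`).

Controls replace the hybrid configuration with an all-adaptive one:
substitution keeps `N` (`a → 0`); addition shrinks the group
(`a → 0, N → N − a`). `p` is zeroed together with `a` — it is formally
inert once `a = 0`, and zeroing prevents accidental use. The addition
control of the `a = 4` scenario is an `N = 2, M = 3` group that can never
reach the threshold on its own; the game type therefore permits `M > N`
(the threshold step simply never fires). Deltas are hybrid − control on
the same metric.

## Parameters

| symbol | meaning | default | notes |
|--------|---------|---------|-------|
| `N`    | group size | 6 | seats, adaptive + agents |
| `M`    | cooperator threshold | 3 | `M > N` allowed for addition controls |
| `r`    | risk probability | swept | [0, 1] |
| `b`    | endowment | 1 | currency unit |
| `c`    | contribution fraction | 0.1 | of `b` |
| `a`    | fixed agents per group | 2/3/4 | the three scenarios |
| `p`    | agent block cooperation prob. | swept | [0, 1] |
| `Z`    | adaptive population size | 100 | chain has `Z + 1` states |
| `μ`    | mutation probability | 0.01 | per update of the focal |
| `β`    | selection strength | 2 | Fermi steepness |

Sweeps default to a 51 × 51 lattice over `(r, p) ∈ [0,1]²`
(`--grid-n` densifies); delta sweeps solve each control once per `r`
since controls are `p`-independent. Acceptance and regime tests use
21 × 21 grids — at ~5 ms per stationary solve this keeps each end-to-end
check in seconds while resolving every qualitative feature of the
surfaces (the interior success dip at `a = 3, r = 0.9` is several
hundredths deep and spans a wide `p` band).

## Agent-based simulator

The simulator executes the explicit `Z`-agent protocol above. By default
fitness is the exact hypergeometric expectation, so the simulation and
the chain share transition probabilities *exactly* and their agreement
(total-variation distance of occupancies, per-state up/down frequencies
vs `T±(k)`) isolates the correctness of the update rule and the
stationary solver; a sampled-group fitness mode exists as a robustness
probe only. The agent block is realized afresh per sampled group
(marginal semantics). Runs are bit-reproducible under a fixed seed;
random draws are pre-generated in blocks of 10⁵ to keep the Python
update loop tight (~10⁶ steps/s at `Z = 20`).

What the simulator emulates is precisely the model's idealization — a
well-mixed population, one strategy revision per step, exact payoff
expectations. It does not emulate features of real hybrid-team data
(bounded group counts per generation, payoff sampling noise, human
learning beyond imitation), so agreement between the simulator and the
chain validates the mathematics, not the behavioral realism of the
model.

## Known limitations

- The cooperation level of the `a = 4` scenario sits at a
  mutation–selection floor of `C̄ ≈ 0.095` (constant over the whole
  `(r, p)` grid, since `f_C − f_D = −c b` identically there). This is the
  exact consequence of `μ = 0.01, β = 2, c b = 0.1` under the additive
  mutation term; qualitatively "no cooperation" on a 0–1 scale, but not
  numerically below 0.05.
- Only one agent block per group; no independent-Bernoulli agents; no
  repeated CRD, heterogeneous endowments, structured populations, or
  small-mutation-limit approximations.
- The CLI's YAML config mirrors flags one-to-one; flags always win.
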