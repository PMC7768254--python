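# Methods

## The process being modeled

The general geometric indel (GGI) model is a continuous-time Markov chain
on sequences. At any site, an insertion of `n` residues occurs at rate
λ·x^(n−1)(1−x) and a deletion of `n` residues at rate μ·y^(n−1)(1−y):
events are initiated at rates λ and μ per site and their lengths are
geometric with means 1/(1−x) and 1/(1−y). Inserted residues are drawn
independently from the stationary distribution ρ of a substitution rate
matrix **R**; substitutions act independently of the indel process, so an
alignment likelihood factorizes into a gap-profile (M/I/D column) term and
residue-emission terms (match emissions exp(**R**t), insert emissions ρ).
Everything below concerns the gap-profile term; the sequence-level
generator is never materialized as a matrix (its state space is infinite)
but is realized operationally by the simulator.

## The 3-state approximation

Alignments are scored by a conditionally normalized pair HMM (a
transducer) `F(t)` with one Match, one Insert, and one Delete state and
transition matrix

          M    I    D
      M [ a    b    c ]
      I [ f    g    h ]
      D [ p    q    r ]

An exact solution of this form cannot exist for general (x, y): alignment
gap lengths under the process are not geometric even though event lengths
are. The approximation instead requires that composing `F(t)` with the
infinitesimal machine `G(dt)` — a 3-state transducer whose M row starts
an insertion with probability λ·dt, a deletion with μ·dt, and whose I/D
rows extend with probability x (resp. y) — stays inside the 3-state
family: `F(t)·G(dt) ≈ F(t+dt)`.

The product machine has 9 states. Matching its expected class-transition
counts to those of `F(t+dt)` and letting dt → 0 yields ODEs for the four
primary expected counts over match-to-match excursions:

    dT̄_MM/dt = μ b f (1−y)/(1−g y) − (λ+μ) a
    dT̄_MI/dt = −μ b (1−g)/(1−g y) + λ(1−b)
    dT̄_IM/dt = λ a − μ f (1−g)(b(1−r)+c q) / ((1−g y)(f(1−r)+h p))
    dT̄_DI/dt = μ (1−g)(b(1−r−h q)+c g q) / ((1−g y)(f(1−r)+h p))

with T̄_MM(0) = 1 and all other counts 0. The remaining counts follow from
linear occupancy identities (e.g. T̄_MD = 1 − T̄_MM − T̄_MI), the insert and
delete occupancies have closed forms

    S̄_I(t) = exp(λt/(1−x)) − 1,    S̄_D(t) = exp(μt/(1−y)) − 1,

and the transition probabilities are count ratios (a = T̄_MM,
f = T̄_IM/S̄_I, …). The right-hand sides above were derived symbolically
(first-order perturbation of the expected-count calculus on the 9-state
product, via sympy) and are guarded by a test that compares them at random
parameter points against finite differences of that calculus computed
through an entirely separate code path (`machines.compose_fg` +
`machines.expected_transition_count`); agreement is required to a relative
1e−4.

With x = y = 0 (single-residue indels) the system is solved exactly by the
classical TKF91 birth-death closed form (α = e^(−μt), β, γ), which is
implemented directly and used both as a comparison model and as an
oracle: the ODE solution must match it to 1e−6 across a rate/time grid.

## Expected-count calculus

For a machine with states classed M/I/D/N (Null = reads nothing, writes
nothing), the expected number of X→Y class transitions over walks that
begin and end in Match — with null states removed from the walk before
counting — is

    E[T_XY] = [ U (J_XY ∘ (V Q)) W ]_{1,1}

where U, V, W are geometric-series sums (I − Q_sel)^(−1) over the
appropriate sub-selected transition matrices. The inverses are computed by
direct solve; convergence is checked via spectral radius < 1 − 1e−12, and
a non-terminating machine raises. By convention a selector containing
only the Null class yields 0 (no null states survive removal).

## Gap-length distribution and statistics

A gap is a maximal run of I/D columns between two M columns; every
inter-match interval contributes exactly one (S_I, S_D) observation, with
(0, 0) for adjacent matches. The model's joint distribution is computed by
a dynamic program over in-gap states with one emission per step; the mass
beyond the G×G grid is bounded by the surviving in-gap weight after G
extension steps, (b, c)·A^G·𝟙 with A = [[g, h], [q, r]] (decaying at A's
spectral radius).

Relative entropy uses the standard conventions: reference-zero cells
contribute nothing; a supported cell with zero model mass gives +∞ (no
pseudocounts, so genuinely unsupported models are visible). The truncated
variant conditions both distributions on {S_I ≤ G′, S_D ≤ G′} and
renormalizes. Empirical intervals are pooled with equal weight per
interval (not per replicate).

## The simulator

A Gillespie scheme on the descendant sequence: with m residues the total
event rate is λ(m+1) + μm. Insertions occur at junctions — immediately to
the right of each residue plus one site at the left edge (m+1 sites), the
immortal-link convention that makes the x = y = 0 limit exactly the
birth-death links model. Deletions start at a uniformly chosen residue and
extend rightward by a geometric length, truncated at the sequence end
(dropping the 1−y normalization for end-hitting lengths keeps the
per-residue deletion rate at exactly μ). The insertion-site convention
only affects end intervals, which are discarded. Residue identities are
not simulated: gap statistics are residue-blind under the model's
factorization. Events can overlap arbitrarily — inserted residues are
deletable (and then leave no alignment column), deleted ancestral residues
leave a D column; extinction is a valid outcome.

Each replicate consumes an independent RNG stream derived from the base
seed and the replicate index, so results are reproducible and pooling is
order-invariant. The production implementation tracks the alignment as a
column-code list with an index map and is checked column-for-column
against a naive per-column reference implementation consuming the same
variate stream; it is additionally validated against two exact laws:
the TKF91 gap distribution at x = y = 0, and the interval distribution of
the insertion-only process (μ = 0), whose interior intervals follow an
exactly solvable pure-growth chain with P(S_I = 0) = e^(−λt).

## Default study conditions

The simulation-based checks run at the indel-symmetric central point
λ = μ = 1, x = y = 0.5, t = 0.5 — mean indel length 2, representative of
protein structural-alignment indels — with ancestral length L = 10³,
N = 10⁴ replicates, and gap cutoff G = 10², run as 20 chunks so that
replicate-level standard errors are available for the pooled statistics.
Unit tests that only need distributional sanity use smaller L and N
(L = 80–500, N = 30–2000), sized so each test finishes in seconds while
keeping Monte-Carlo standard errors well below the effects being tested.

## Numerical choices

- ODE integration: adaptive DOP853 with rtol 1e−10, atol 1e−12, first
  step ≤ 1e−6/(λ+μ). The state vector is the four primary counts;
  occupancies come from their closed forms and all other counts from the
  linear identities at each right-hand-side evaluation.
- 0/0 ratios: when an occupancy is below 1e−12, the I/D-row probabilities
  take their t = 0 limits (f, g, h) = (1−x, x, 0), (p, q, r) = (1−y, 0, y).
- TKF91 removable singularities: β and γ are evaluated by analytic limits
  when |λ−μ| ≤ 1e−9·max(λ, μ), when λ = 0 or μ = 0, and at t = 0.
- "Within tolerance" checks default to 1e−9 absolute unless stated.
- Viterbi tie-breaking prefers Match over Delete over Insert.

## Finite sequences and alignment

The infinite-sequence machine is augmented heuristically for finite
sequences: a start state that copies the Match row (the left edge behaves
like an immortal match, so insertions may precede the first residue), and
end transitions with each state's probability of *not* inserting (1−b
from M and Start, 1−g from I, 1−q from D), the match/delete choice being
resolved by input exhaustion as usual for conditionally normalized
machines. This reading reproduces the exact TKF91 finite-sequence machine
at x = y = 0 and is properly normalized (the likelihood summed over all
descendants is 1). It remains a heuristic for x, y > 0: no ODEs are
derived for start/end transitions.

## Known limitations

- The 3-state machine is an approximation for x, y > 0: its gap lengths
  are (bivariate) geometric while the true interval law is not. The error
  grows with t, x, y, and the rates; in particular the model's
  empty-interval probability a(t) carries a small intrinsic bias (order
  1e−3 at the central point) that is resolvable by simulation at N = 10⁴,
  while the expected insertion length is exact at all parameters. The
  acceptance tests record this honestly: the mean-length and
  relative-entropy-ordering checks pass, the 3-SE empty-gap check does
  not.
- Finite-L simulations carry end effects of order 1/L in interior
  intervals near the right edge (truncated deletions) even after end-gap
  discarding.
- Rare long gaps are limited by the recorded cutoff G and by sampling; no
  parametric tail modeling is attempted.
- No parameter estimation (of λ, μ, x, y or **R**) is provided; the
  likelihood surface is exposed for external optimizers via
  `forward_likelihood`.
- Comparator approximations beyond TKF91 (fragment and trajectory-
  enumeration models) are out of scope.
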