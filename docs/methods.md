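# Methods

## Model

Each landscape instance governs one or more sequence positions, all evolving
independently under the same continuous-time Markov chain over the alphabet.
The chain is parameterized by a scaled fitness vector `F` (entries
`F_i = 2N f_i`, dimensionless, any finite reals) and a fixed relative
mutation-rate matrix `M` (all ones unless supplied).  Off-diagonal rates use
the mutation–selection fixation factor

    q_ij = M_ij (F_j − F_i) / (1 − exp(F_i − F_j)),

whose limit as `F_i → F_j` is the neutral rate `M_ij`.  To avoid
catastrophic cancellation the limit is substituted whenever
`|F_i − F_j| < 1e-9`; at `|F_i − F_j| = 1e-8` the exact expression and the
limit agree to about `5e-9`, so the threshold is far below any biologically
meaningful fitness difference.

The stationary distribution is the softmax of `F` when `M` is uniformly 1
(the chain is then reversible); otherwise `πQ = 0, Σπ = 1` is solved by
least squares on `Qᵀ` augmented with the normalization row, which is robust
for any irreducible chain.  Reducibility (some allele unreachable because of
zero mutation rates) is detected by a strong-connectivity check and reported
with the disconnected symbol groups, since the stationary distribution is
then not unique.

Scalings of `Q`:

| mode | divisor | effect |
|---|---|---|
| `normalized` (default) | `−Σ_i π_i q_ii` | one expected substitution per position per unit branch length |
| `flat_scaled` | `|A| − 1` | neutral landscapes tick at rate 1; selection slows the clock |
| `raw` | — | rates as produced by the formula |

Normalization is re-applied after **every** landscape change: each landscape
is independently normalized, so branch lengths always mean expected
substitutions per position under the *current* landscape.

## Time on the tree

The global time of a point is its distance from the root.  A point on a
branch is addressed as (child-node name, offset from the parent end) with
`0 ≤ offset < branch_length` — half-open, so an event landing exactly on a
node belongs to the branches below it, and an event scheduled within `1e-9`
of a node is snapped onto the node (guarding against a change scheduled a
float-rounding instant before a split instead of on both daughters).  A
change exactly at the root is rejected; the initial landscape governs from
time 0.  Nothing assumes ultrametric trees.  Newick input requires branch
lengths on all non-root edges; a bare number in internal-label position is
rejected (it is almost always a support value) rather than guessed at.

## Event loop

Branches are processed in breadth-first order, each child starting from its
parent's end state and landscape.  On a branch the total exit rate is
`Σ_positions (−q_aa)` plus, in the stochastic regime, the change rate λ
("an extra site").  Waiting times are exponential in the total rate; a draw
that overshoots the next deterministic change or the branch end is
discarded in favour of that event — by memorylessness the redraw under the
new landscape is statistically equivalent to adjusting the old draw, and
simpler.  Event type, substituted position and target allele are chosen by
cumulative-sum inversion of single uniforms in a fixed order (time, type,
position, allele), so a seed reproduces bit-identically across machines and
thread counts.

Landscape changes recompute `Q` and `π` lazily: the matrices are rebuilt on
first use after a change.  Runs whose observable never consults `Q` — e.g.
counting landscape changes on a zero-length sequence, which the engine
supports — skip the linear algebra entirely; since λ does not depend on `Q`
(unless the opt-in co-scaling with a raw `Q` is requested), no sampled law
is affected.

## Change timing and generation

*Stochastic*: Poisson with rate λ per unit branch length.  *Periodic*:
epochs at global times `interval, 2·interval, …` crossing every lineage
alive at that depth; the replacement is either derived once per epoch from
the previous epoch's landscape and shared by all lineages (the shared-epoch
chain makes the shared mode well-defined even after lineages have diverged),
or derived independently per lineage from that lineage's current landscape.
*Explicit*: user-listed branch coordinates, optionally with explicit
replacement vectors (allowed only with explicit times, since otherwise there
is no defined order to consume them in).

New landscapes: `resample` (fresh i.i.d. draws from the initial
distribution — hence unavailable when the initial vector was a fixed file),
`permute` (uniform permutation, identity included), `explicit`, and
`increase_current`/`decrease_current` (shift the resident allele's fitness
by ±delta).  The increase/decrease rules are restricted to single-position
landscapes ("the current allele" is otherwise undefined) and additionally to
non-shared timing, because parallel lineages carry different resident
alleles.  `delta` is additive on the scaled-fitness axis and constant per
event; its magnitude is the user's choice.  In the validation experiments
the package uses `delta = 0.1` per epoch — small against the lognormal(0,
0.5) initial values, so the fitness gain of the resident allele unfolds
gradually across the comb tree's 100 generations rather than freezing the
position immediately.

## Synthetic data and what it does (not) show

The generators emulate the study conditions of the validation panel:
initial fitness values drawn lognormal(μ = 0, σ = 0.5), landscape change by
shuffling, trees that are either hand-built (the 4-leaf tree of total
length 8), caterpillar combs (strictly binary: every inner node has two
children of which one is a leaf; a depth-100 comb has 101 leaves and total
length 200), single branches standing in for trees of a given total branch
length (valid for Poisson change counts, which depend on the total length
only), or pure-birth trees for realistic topology.  None of this emulates
real data's alignment error, rate heterogeneity beyond distinct landscapes,
indels, or selection on interactions between positions — epistasis enters
only implicitly, through landscape change.  Passing tests therefore show the
simulator realizes its own model exactly; they say nothing about how well
that model fits any particular gene.

## Problem sizes and numerical choices

Validation runs use 1000 replicates for change-count statistics (binomial /
Poisson standard errors of a fraction of a percent), 1000 positions or 1000
single-position instances for the comb experiments, and 10^5 replicates for
the transition-frequency comparison with `expm(Qt)` (scipy's
scaling-and-squaring, independent of the event loop).  The large
change-count runs (total lengths 95 and 5622.5) carry zero-length sequences,
since change counts are independent of sequence content; the smaller runs
carry real sequences through the full machinery.  Statistical assertions use
4-standard-error bands throughout; algebraic identities (zero row sums,
detailed balance under symmetric `M`, softmax vs linear solve, unit expected
rate after normalization) are checked at `1e-10`.

Multi-instance runs derive instance `i` of group `g` from the independent
random stream `(seed, g, i)`; results are assembled by index, so any thread
count produces byte-identical output.

## Known limitations

- No indels, no recombination, no individual-based population dynamics; the
  simulated events are substitutions.
- The mutation matrix is fixed for the whole run.
- Explicit replacement vectors require explicit change times.
- One timing regime per landscape; combining stochastic and deterministic
  schedules on the same landscape is rejected by construction of the
  configuration schema.
- Branch lengths are interpreted in expected substitutions per position only
  under the default normalization; under `raw` scaling the user owns the
  units (and may opt to co-scale λ with the raw expected rate).
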