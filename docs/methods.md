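# Methods

## Model

Evolution proceeds site-independently down a rooted tree. A simulation is
parameterised by a root distribution π over (A, C, G, T) and one 4×4
row-stochastic substitution matrix `P_e` per edge, rows indexing the parent
state and columns the child state. No exponential (`exp(tQ)`) structure is
assumed: any matrix of the model's shape is admissible, which is what makes
the processes nonhomogeneous (each edge its own matrix) and — for SSM and
GMM — nonstationary (composition can drift along the tree).

Branch lengths follow the log-det convention `l_e = -¼ ln det(P_e)`,
the expected number of substitutions per site for this model family. An
input edge length therefore fixes the determinant of the edge's matrix to
`D = exp(-4 l_e)`, and the simulator's central task is sampling random
matrices of each model's shape with that exact determinant.

Unrooted input trees (outermost Newick node of degree ≥ 3) are rooted at
the outermost node, the only location recoverable from the input alone, and
π is placed there. Internal node labels in the Newick text are parsed and
ignored. Zero-length branches are rejected at parse time — under the
determinant constraint `l = 0` forces `det P = 1`, which for a stochastic
matrix that is not a permutation means `P = I`; since that is a degenerate
edge (no substitutions ever), it must be requested explicitly with
`--allow-zero-length`, in which case the edge receives the identity matrix.

## Matrix samplers

**JC69** has the closed form: eigenvalues `(1, e, e, e)` with
`e = exp(-4l/3)`, diagonal `a = (1+3e)/4`, off-diagonal `b = (1-e)/4`.
`det = e³ = exp(-4l)` exactly and `a > b` for every `l > 0`, so the matrix
is always DLC. The sampler is deterministic — JC69 has a single matrix per
length.

**K81** matrices are simultaneously diagonalised by the Hadamard basis with
non-unit eigenvalues `x = a+b-c-d`, `y = a-b+c-d`, `z = a-b-c+d` and
`det = xyz`. The sampler draws `x ~ U(D, 1)`, `y ~ U(D/x, 1)`, sets
`z = D/(xy)` (so the determinant holds by construction), and rejects the
draw if any of `a, b, c, d` is negative. **K80** is the sub-family with a
double eigenvalue: `x ~ U(√D, 1)`, `y = D/x²`, entries
`a = (1+2x+y)/4`, `b = (1-y)/4`, `c = (1-2x+y)/4` (reject on `c < 0`; `b`
cannot go negative since `y ≤ 1`). Sampling the eigenvalues positive makes
the diagonal strictly dominant, so these matrices are DLC on arrival; the
price is that matrices with negative eigenvalues (still stochastic) are
outside the sampler's range — a deliberate trade of coverage for guaranteed
termination.

**SSM and GMM** have no convenient spectral parameterisation, so the
sampler works by continuation from the identity. Draw a random matrix `M`
of the model's shape — GMM: four independent flat-Dirichlet rows; SSM: two
flat-Dirichlet rows with rows 3/4 the reverses of rows 2/1. If
`det(M) ≥ D` the draw is discarded (the path below could not cross `D`).
Otherwise `P(s) = (1-s)I + sM` stays inside the shape class for all
`s ∈ [0,1]` (the identity belongs to both classes and both are convex), and
`f(s) = det P(s)` falls continuously from 1 to `det(M) < D`, so a crossing
exists. The *first* crossing is located by scanning `s = k/1000` for the
first `f(s) ≤ D` and bisecting inside that bracket; taking the first
crossing keeps `s` small, i.e. keeps the matrix close to the identity,
which favours diagonally dominant (DLC-friendly) results. `f` need not be
monotone, so later crossings may exist; they are simply never selected.

Bisection runs until the bracket width reaches ~1e-17 (about 55 halvings),
returning the endpoint whose determinant is closest to `D`. This typically
leaves `|det - D|` near 1e-16 and keeps the branch-length error
`|det - D| / (4D)` below 1e-9 even at extreme lengths (`l ≈ 3`,
`D ≈ 6e-6`), where a fixed absolute determinant tolerance would not.

## DLC conversion and the trial cap

The emitted parameters must be identifiable: for a given leaf joint
distribution there is a unique parameter set whose matrices are all DLC —
diagonal entry strictly the largest in every column. Ties are disqualifying
(they already break uniqueness), hence the strict inequality.

Each model carries the group of row permutations that map its symbolic
pattern onto itself up to relabelling, computed by brute force over all 24
permutations of (A, C, G, T). The groups come out as: JC69 — identity only;
K80 — {id, (AG)(CT)}; K81 — the Klein four-group of double transpositions;
SSM — an order-8 dihedral group (the double transpositions plus the single
swaps (CG) and (AT) and two 4-cycles, all of which preserve the reversal
structure of rows 3/4); GMM — all of S₄. The check is symbolic on labels,
not numeric on a sample matrix, to avoid accidental coincidences.

A sampled matrix that is not DLC is row-permuted by the (at most one)
group element that moves every column maximum onto the diagonal. An odd
permutation flips the determinant's sign — the permuted matrix would no
longer carry the requested branch length — so results with non-positive
determinant are rejected; only even permutations can ever produce an
emitted matrix. Any failure (shape rejection, no DLC permutation,
determinant-sign flip) consumes one trial; after 1000 trials on a single
edge the run aborts and asks for a re-start with a different seed. In
practice JC69/K80/K81 succeed on the first trials and the mixture models
within a handful.

## Simulation and reproducibility

A run consumes randomness in a fixed order: root distribution, then one
matrix per edge in pre-order (children in Newick order), then the root
sequence (L i.i.d. draws from π), then pre-order propagation where each
site's child state is drawn from the row of the edge matrix indexed by the
parent state (states processed in A, C, G, T order). Identical seeds
therefore reproduce alignments and parameter files byte for byte. Internal
sequences are discarded after their children are generated unless
`keep_internal` retains them for debugging.

Outputs: a FASTA alignment (60-column wrap, records in leaf appearance
order) and a plain-text parameter file with the model, seed, tree, root
distribution, and one block per edge — terminal edges first by leaf
appearance, then internal edges breadth-first from the root — each block
holding the edge label, branch length, and the matrix at 17 significant
digits, which round-trips doubles exactly. The format is this package's
own; it is line-oriented and re-parseable (`read_params`).

## Diagnostics as test oracles

The `diagnostics` module implements the estimators the test suite uses to
close the loop: the empirical pairwise joint `J[i,j]` (site counts), the
paralinear distance

    d(u,v) = -¼ [ ln |det F| - ½ ln( Π_i f_i · Π_j g_j ) ],

with `F = J/L` and `f, g` its marginals, and the per-matrix log-det length.
The paralinear distance is additive along paths; when all marginals are
uniform (JC69/K80/K81 with the uniform root) it equals the sum of the
per-edge log-det lengths, which is what the recovery tests assert — exactly
on the analytic joint `F = P₁ᵀ diag(π) P₂`, and within sampling error on
simulated data, with the standard error obtained by the multinomial delta
method. Under SSM/GMM the marginal terms do not cancel and path additivity
of the per-edge lengths is not asserted. The absolute value in `ln |det F|`
guards against tiny negative determinants at short alignments.

Independent numerical oracles in the tests: a cofactor-expansion 4×4
determinant (no linear-algebra library involved) validates every emitted
matrix's determinant contract, and the permutation groups are re-derived in
the acceptance suite from the cell-partition definition.

## Scales and defaults

Defaults mirror the documented workflow: the worked example is the 5-taxon
tree with branch lengths (0.01, 0.2, 0.3, 0.4, 0.5, 0.7) at 10,000 sites.
Property tests use 200 matrices per model per length for the
shape/DLC/determinant contracts; conditional-frequency and
distance-recovery checks run at 500,000 sites, where binomial standard
errors (~1e-3) are small enough to detect real biases while keeping the
whole suite in the tens of seconds on one CPU; the convergence check
contrasts 20 replicates at 20,000 vs 80,000 sites.

## What the tests do and do not show

The synthetic data exercised here is exactly what the tool produces, so the
tests validate the generator's own contracts (determinant, shape, DLC,
reproducibility, marginal and conditional distributions) — they do not
claim that any real alignment evolves by these models. Known limitations:
the K80/K81 samplers exclude negative-eigenvalue matrices; the mixture
sampler covers only matrices reachable as the first identity-mixture
crossing from a flat-Dirichlet draw (a dense but not exhaustive subset of
each class); and the sampling law over the constraint surface is a design
choice of this package — only the determinant constraint itself, not any
particular distribution over matrices, is guaranteed.
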