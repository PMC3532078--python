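# dtphylosim

Simulation of DNA multiple sequence alignments under **discrete-time Markov
models** on phylogenetic trees — directly from substitution matrices, with no
rate-matrix (continuous-time) structure imposed.

## The problem

Most sequence simulators (Seq-Gen, INDELible, Evolver, …) work with
continuous-time models: every edge matrix has the form `exp(tQ)` for a rate
matrix `Q`, which in practice restricts simulation to stationary,
time-reversible processes. Researchers who study the behaviour of
reconstruction and model-selection methods under *nonhomogeneous* (different
process on each lineage) or *nonstationary* (drifting base composition) data
need alignments generated from arbitrary row-stochastic matrices instead.

`dtphylosim` simulates on a given tree `T` with branch lengths measured in
expected substitutions per site. The parameters of the process are a root
distribution π and one 4×4 row-stochastic matrix `P_e` per edge `e`, where
`P_e[y, x]` is the probability that parent state `y` is substituted by child
state `x`. The branch-length convention is the log-det one:

```
l_e = -¼ · ln det(P_e)
```

so a requested edge length pins the determinant of the edge matrix to
`D = exp(-4 l_e)`. The core of the package is a family of samplers that draw
random matrices of a model's shape satisfying this constraint *exactly*
(to ~1e-12 in the determinant, ~1e-9 in the length):

| model | shape | free params/edge | sampler |
|-------|-------|-----------------|---------|
| `jc69` | diagonal `a`, off-diagonal `b` | 1 | closed form: eigenvalues (1, e, e, e), `e = exp(-4l/3)` |
| `k80` | Kimura 2-parameter | 2 | eigenvalue draw: eigenvalues (x, x, y), `x²y = D` |
| `k81` | Kimura 3-parameter | 3 | eigenvalue draw: eigenvalues (x, y, z), `xyz = D` |
| `ssm` | strand symmetric (row 3 = reversed row 2, row 4 = reversed row 1) | 6 | identity-mixture: first `s` with `det((1-s)I + sM) = D` |
| `gmm` | general Markov (all 16 entries free up to row sums) | 12 | identity-mixture |

Every emitted matrix is converted to **DLC** (diagonal largest in column,
strictly) form by an allowable row permutation — a permutation that maps the
model's pattern onto itself — so the emitted parameter set is identifiable:
it is the unique DLC parameter set producing the simulated leaf distribution.
If no permutation yields a DLC matrix the draw is repeated, up to 1000 trials
before the run aborts with a re-start error.

JC69/K80/K81 are doubly stochastic and run with the uniform root
distribution; SSM draws a strand-symmetric root (π_A = π_T, π_C = π_G) and
GMM a flat-Dirichlet root, so both can generate genuinely nonstationary data.

## Worked example

With `tree.txt` containing a 5-taxon tree:

```
((species1:0.01,species2:0.2,species3:0.3):0.5,species4:0.4,species5:0.7);
```

```bash
dtphylosim tree.txt data.fa 10000 k81 --seed 20
```

simulates a 10,000-site alignment under the discrete-time K81 model and
prints:

```
dtphylosim: model=K81 leaves=5 edges=6 length=10000 seed=20
dtphylosim: sampling trials per edge: total=21 max=7
dtphylosim: wrote data.fa and data.fa.params.txt
```

`data.fa` holds the five leaf sequences; `data.fa.params.txt` lists every
parameter used: the model, the seed, the input tree, the root distribution
and one matrix block per edge — terminal edges first in the order the leaves
appear in the Newick text, then internal edges top-down from the root. The
first block of this run:

```
edge: species1
length: 0.01
matrix:
0.9900862539065749 0.001111917470788315 0.00039098993446817776 0.0084108386881684982
0.001111917470788315 0.9900862539065749 0.0084108386881684982 0.00039098993446817776
0.00039098993446817776 0.0084108386881684982 0.9900862539065749 0.001111917470788315
0.0084108386881684982 0.00039098993446817776 0.001111917470788315 0.9900862539065749
```

The matrix has the K81 shape (four parameters `a b c d` arranged in the
Kimura 3-parameter symmetry), its diagonal is the strict maximum of every
column, and `-¼ ln det = 0.01`, the requested branch length. Runs repeat
byte-identically under the same `--seed`.

From Python:

```python
import numpy as np, dtphylosim as dps

tree = dps.parse_newick("(A:0.2,B:0.3);")
aln, rec = dps.simulate_alignment(tree, dps.get_model("k81"), 500_000,
                                  np.random.default_rng(31))
d = dps.paralinear_distance(dps.empirical_joint(aln, "A", "B"))
print(round(d, 4))   # 0.5006 — the paralinear distance between the leaves
                     # estimates the 0.2 + 0.3 path length
```

## Scope

No indels, no among-site rate variation, no amino-acid or codon alphabets,
and no continuous-time (`exp(tQ)`) matrices — the discrete-time matrix *is*
the parameter. Parameter inference and tree reconstruction are out of scope;
the `diagnostics` module provides only the estimators (pairwise joints,
paralinear distance) used to validate the simulator's own output.
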