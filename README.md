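# mranet

Network inference from systematic perturbation screens by **modular response
analysis (MRA)**, scaled to medium and large biological systems (hundreds to
~1,000 genes), with a CLR-style pruning heuristic, mutual-information
baseline algorithms, a ground-truth steady-state simulator, and a
benchmarking harness.

## Who this is for

You have a perturbation screen: the expression (or activity) of *n* genes
measured at steady state, once unperturbed and once under the knockdown or
knockout of each single gene — shRNA panels, CRISPR/Cas9 KO collections, or
simulated equivalents. You want the *direct*, signed, directed regulatory
network among those genes, not the blur of downstream effects that simple
co-expression methods report.

## The model

Let `x ∈ R^n` be the steady-state activities of `n` modules (genes) governed
by an unknown smooth dynamical system `ẋ = f(x, p)` with one perturbable
parameter `p_k` per module. From the observed **global responses**

    R[i,k] = 2 (x_i(p⁰+Δp_k) − x_i(p⁰)) / (x_i(p⁰+Δp_k) + x_i(p⁰)),

the bounded, numerically stable relative change of module *i* under the
elementary perturbation of module *k* (an absolute-value denominator variant
handles signed z-score data), MRA recovers the **local response matrix**
`r`, where `r[i,j]` is the direct interaction strength of gene *j* on gene
*i* (positive = activation, negative = inhibition) with the normalization
`r[i,i] = −1`. The two are linked by

    r R = −P,        P = diag(P_11, …, P_nn),

with `P` the perturbation-sensitivity diagonal. Two solvers are provided:

- the closed form `r = −[diag(R⁻¹)]⁻¹ R⁻¹`, and
- a **blockwise** formulation: for each row *i* the homogeneous relations
  `R[i,k] = Σ_{j≠i} r[i,j] R[j,k]` (k ≠ i) form an independent
  (n−1)-dimensional system solved by LU factorization with partial
  pivoting — n embarrassingly parallel systems, bit-identical results for
  any worker count.

Because a large system's `r` is dense, a **CLR-adapted heuristic** z-scores
every entry against its row and column background and combines the two as
`Z[i,j] = sign(r[i,j]) √(z_row² + z_col²)` before edge selection (the
MRA+CLR algorithm). MI baselines (relevance-network CLR, MRNET, ARACNE with
data-processing-inequality pruning) and a confusion-matrix /
hypergeometric-test harness support head-to-head benchmarking under a
uniform top-x% selection protocol.

## Worked example

```python
import mranet as m

# simulate a ground-truth screen: 50 regulators, 50 targets, 5% knockdowns
net = m.generate_topology(n_tf=50, n_ta=50, mean_degree=2.0, seed=1)
config = m.SimulationConfig(mode="linear", perturbation_strength=0.05, seed=1)
data = m.generate_perturbation_dataset(net, config)

model = m.ModularResponseAnalysis(data)
results = model.fit(method="blockwise", workers=4)
print(results.summary())
```

```
Modular Response Analysis Results
=============================================
modules                                   100
solver                              blockwise
off-diagonal |r| median                     0
off-diagonal |r| max                     1.48
sensitivity |P| min                   0.02596
sensitivity |P| max                    0.1667
condition estimate (1-norm)             25.08
pivot warnings                              0
max subsystem residual              2.082e-17
=============================================
```

The fit is well conditioned (condition estimate 25, residuals at machine
precision); the median off-diagonal coupling is 0 (a sparse true network
leaves most pairs unconnected) with real interactions up to |r| ≈ 1.5.
Score the pruned network against the generating topology:

```python
ref = m.ReferenceNetwork(
    {tuple(sorted((e.regulator, e.target))): 1.0 for e in net.edge_frame().itertuples()},
    list(net.module_ids),
)
table = results.evaluate(ref, fraction=0.10)   # top 10% of the 4950 pairs
print(table.TP, table.FP, f"{table.precision:.3f}", f"{table.pvalue:.3e}")
```

```
200 295 0.404 2.160e-219
```

All 200 true regulatory pairs sit inside the top-10% selection
(hypergeometric p ≈ 2e−219); precision 0.40 reflects that 495 pairs were
selected while only 200 exist. The same pipeline is scriptable from the
shell (`mranet simulate`, `response`, `infer`, `prune`, `baselines`,
`evaluate`, `compare` — see `mranet --help`).

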