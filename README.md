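# regcn — community detection by refined centers and expanded pseudo-labels

`regcn` partitions an undirected network — a protein-interaction map,
a social graph, a citation network — into K communities without any
labeled training data, using both the topology and optional node
attributes. It is aimed at the module-detection setting where
communities are assortative (denser inside than between) and
attributes are homophilous (similar nodes tend to connect).

## Method

The pipeline self-trains a two-layer graph convolutional network (GCN)
from automatically chosen seed nodes:

1. **Seed.** Compute each node's local density ρ_i (nodes within d_c
   hops), relative distance δ_i (hops to the nearest denser node) and
   structural centrality φ_i = ρ_i·δ_i; the K largest-φ density peaks
   become structure centers, one pseudo-label each.
2. **Refine.** Alternate until stable: train a GCN
   `Z = softmax(Â ReLU(Â X W⁰) W¹)` on the current centers and
   partition by argmax; then, inside each community's induced
   subgraph, move the center to the node with the largest weighted
   count of simple paths of lengths 1–3 to its neighbors
   (α₁, α₂, α₃ = 0.6, 0.35, 0.05). This rescues runs whose initial
   centers fell into the same community.
3. **Expand.** Grow each community's supervision to the τ nodes whose
   affiliation strength z_{x,k} is closest to the center's, with
   τ ≈ N/(K·d̄²) so that the 2-hop neighborhoods of the supervised
   nodes can cover the graph.
4. **Classify.** Train a fresh GCN on the expanded pseudo-labeled set;
   its argmax is the final partition, scored by ACC/NMI/ARI when
   ground truth is available.

See `docs/methods.md` for the full model, conventions and limitations.

## Worked example

Generate a planted-partition benchmark (three blocks of 50 nodes,
within-block edge probability 0.25, between 0.02, block-correlated
binary attributes), then detect and score:

```bash
regcn synth --blocks 50,50,50 --pin 0.25 --pout 0.02 \
    --attr-dim 60 --seed 7 --out bench
regcn detect --edges bench.edges.tsv --attrs bench.attrs.tsv \
    --k 3 --truth bench.truth.tsv --seed 1 --out membership.tsv
```

which prints

```
{"acc": 100.0, "nmi": 100.0, "ari": 100.0}
```

— the partition in `membership.tsv` matches the planted blocks
exactly: best-mapping accuracy, normalized mutual information and
adjusted Rand index all at 100 percent. On harder inputs these
diverge; e.g. NMI near zero means the partition carries essentially no
information about the ground truth. The same run from Python:

```python
from regcn import generate_sbm, easy_sbm_spec, run_regcn, RunConfig

net = generate_sbm(easy_sbm_spec(seed=7))
partition, trace, report = run_regcn(net, RunConfig(k=3, seed=1))
print(report["metrics"])        # {'acc': 100.0, 'nmi': 100.0, 'ari': 100.0}
print(report["initial_centers"], "->", report["refined_centers"])
```

Other subcommands: `regcn score` (ACC/NMI/ARI between two membership
files), `regcn ablate` (the four model variants — refinement and/or
expansion disabled — on matched seeded benchmarks) and
`regcn tausweep` (both expansion strategies across a τ grid).

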