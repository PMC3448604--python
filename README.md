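# segproof

Uncertainty-guided proofreading of superpixel segmentations.

An automatic segmentation is represented as a **probabilistic segmentation
graph**: a region adjacency graph (RAG) over watershed superpixels whose
edges carry the probability that the two regions belong to the same object.
From this graph the package computes a ground-truth-free certainty score —
the normalized expected self-agreement of the graph (a probabilistic
generalization of the adjusted Rand index, here called GPR) — and uses it to

1. rank candidate edges for manual yes/no inspection by their expected
   impact on the score,
2. simulate proofreading sessions against a ground-truth oracle, and
3. terminate proofreading once the score passes a cutoff,

so that only a small fraction of edges needs human attention while the
resulting agglomerated segmentation stays close to ground truth.

## Layout

| module | role |
| --- | --- |
| `segproof.graph_core` | labelings, partitions, RAG construction, graph JSON |
| `segproof.edge_model` | 8 edge features, ground-truth edge labels, random-forest edge classifier |
| `segproof.connectivity` | max-product best-path connection strengths (pruned Dijkstra variant), incremental table updates, optional multi-path refinement |
| `segproof.metrics` | Rand index, adjusted Rand index, U-GPR/GPR, GPR vs a concrete segmentation |
| `segproof.priority` | expected-impact edge ranking, probability-band filtering, strategy orders |
| `segproof.proofread_loop` | oracle decisions, graph/table updates, cutoff-terminated sessions |
| `segproof.agglomeration` | mean-boundary and edge-probability threshold merging, quality sweeps |
| `segproof.synthdata` | synthetic scenes: Voronoi ground truth, nested superpixels, noisy boundary maps, calibration-controlled probabilities |
| `segproof.cli`, `segproof.report`, `segproof.io` | command line, summary tables, file formats |

## CLI

```sh
segproof synth --seed 1 --out scene.h5            # synthetic scene bundle
segproof train-edges --bundle scene.h5 --out model.joblib
segproof classify-edges --bundle test.h5 --model model.joblib --out graph.json
segproof gpr --graph graph.json                   # certainty report
segproof rank --graph graph.json --out rank.csv   # impact ranking
segproof proofread --graph graph.json --bundle test.h5 \
    --strategy gpr --cutoff 0.9 --out session.json
segproof sweep --graph graph.json --bundle test.h5 --out sweep.csv
segproof report session_*.json --out table.csv
```

Every command logs its seed, version and config hash to stderr; outputs are
reproducible from the config and seed alone.

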