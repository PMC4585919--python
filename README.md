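# sigdistill

Cohesiveness-guided distillation of gene-expression signatures for tumor
subtyping.

## The problem

Panels of genes differentially expressed among immunohistochemistry-defined
breast-tumor subtypes ([ER+|PR+]HER2−, [ER+|PR+]HER2+, [ER−|PR−]HER2+,
[ER−|PR−]HER2−, or a 2-class ER± scheme) often contain hundreds to thousands
of genes.  Many of them are redundant — co-expressed members of the same
transcriptional program — and the redundancy both inflates assay cost and
buries the discriminating signal in noise.  `sigdistill` reduces such a
"diff-gene" panel to a minimal *signature* that clusters tumor samples into
their subtypes at least as accurately as the full panel.

## The method

For each class of candidate genes *C_r* (one class per subtype, or one
pooled class), define the **cohesiveness**

    Co(C_r) = 1 / d̄(C_r),      d̄ = (2 / m(m−1)) Σ_{i<j} d_ij

where *d_ij* is the Euclidean distance between the expression vectors of
genes *i* and *j* over the samples and *m* = |C_r|.  The number of
representatives a class needs under a **cohesive strength** *K* > 0 is

    N(C_r) = clamp( round(K · d̄(C_r)), 1, m )

so diverse classes get more representatives and every class keeps at least
one.  Each class is then split into *N(C_r)* subclasses by average-linkage
(UPGMA) hierarchical clustering of its gene vectors, and from each subclass
the gene nearest (Euclidean) to the subclass's mean vector — the
*nearest-to-center* principle — is kept.  The shared strength *K* is chosen
by sweeping a log-spaced grid and maximizing the external clustering
**F-value** of the candidate signature: samples are re-clustered (UPGMA on
per-gene z-scored expression restricted to the signature, cut at the number
of subtypes) and compared against the known labels; the **Rand index** is
reported alongside.  Ties between K values prefer the smaller signature.

A synthetic-data module generates labeled expression layers with planted,
block-correlated informative genes so that the whole analysis runs and can
be validated without any external downloads.

## Worked example

```python
from sigdistill import (SimulationConfig, simulate_layer, truth_panels,
                        pooled_panel, select_signature, evaluate_panel)

config = SimulationConfig(seed=1)   # 4 subtypes x 15 samples, 2 blocks x 8
expr, labels, truth = simulate_layer(config)  # genes per subtype, 300 noise
result = select_signature(expr, labels, truth_panels(truth), mode="pooled")
print(len(result.signature), result.chosen_K, result.score.f_value, result.score.rand)
diff = evaluate_panel(expr, labels, pooled_panel(truth))
print(len(pooled_panel(truth)), diff.f_value, diff.rand)
```

prints

```
5 0.1868807587585218 1.0 1.0
64 1.0 1.0
```

i.e. the 64-gene candidate panel is distilled to a 5-gene signature (at
cohesive strength K ≈ 0.187) that still clusters all 60 samples into their
four subtypes perfectly (F-value 1.0, Rand index 1.0).

The same analysis is available from a shell:

```sh
sigdistill simulate --seed 1 --out-dir scratch/sim
sigdistill run --config examples/demo_config.json --out-dir scratch/demo
```

`run` writes the signature gene lists, selection JSON, K-sweep traces, a
panel-comparison report (candidate panels vs. signatures, identical
clustering settings per row) and the overlap between pooled-mode and
per-subtype-mode signatures.

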