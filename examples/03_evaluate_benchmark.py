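"""Score an inferred network against its gold standard.

Runs the full simulate -> infer -> evaluate loop and prints the standard
confusion metrics plus AUC.  TPR is the fraction of true edges recovered,
FPR the fraction of non-edges wrongly predicted, PPV the precision of the
predicted edge list, MCC a balanced single-number summary in [-1, 1], and
AUC the area under the ROC curve obtained by ranking all gene pairs by
their score.
"""

from cmi2ni import (
    InferenceConfig,
    confusion,
    edge_ranking,
    infer_network,
    metrics,
    random_dag,
    roc_auc,
    simulate_expression,
)

dag = random_dag(n=10, edge_density=0.25, seed=3)
expr = simulate_expression(dag, m=500, seed=4)
net = infer_network(expr, InferenceConfig(theta=0.05))

counts = confusion(net, dag.skeleton)
ms = metrics(counts)
auc_ms, _ = roc_auc(edge_ranking(net), dag.skeleton)

print(f"counts: TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn}")
for name, value in ms.as_dict().items():
    if name != "auc":
        print(f"{name}: {'undefined' if value is None else f'{value:.3f}'}")
print(f"auc: {auc_ms.auc:.3f}")
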