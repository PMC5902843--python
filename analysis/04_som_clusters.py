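"""Train the hexagonal SOM on the SE-gene enrichment matrix, group nodes
into six clusters, assign cell types to their most enriched cluster, and
test per-cluster SE vs non-SE enrichment by permutation."""

import json

import pandas as pd

from common import RUN_DIR, ensure_stages

ensure_stages("simulate", "psi", "enrich", "som")

clusters = pd.read_csv(RUN_DIR / "celltype_clusters.tsv", sep="\t")
stats = pd.read_csv(RUN_DIR / "cluster_stats.tsv", sep="\t")
truth = json.loads((RUN_DIR / "ground_truth.json").read_text())["celltype_cluster"]

print("cell-type assignment (planted cluster in parentheses):")
for r in clusters.itertuples():
    print(f"  {r.celltype} -> cluster {r.cluster} (planted {truth[r.celltype]})")
print("per-cluster SE vs non-SE enrichment:")
print(stats.to_string(index=False))
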