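"""Compare expression of SE-associated vs non-AS genes (null by
construction) and test toy splicing-factor motif enrichment in synthetic
skip-site flanks."""

import json

import pandas as pd

from common import RUN_DIR, ensure_stages

ensure_stages("simulate", "psi", "enrich", "som", "downstream")

expr = json.loads((RUN_DIR / "expression_comparison.json").read_text())
motifs = pd.read_csv(RUN_DIR / "motif_enrichment.tsv", sep="\t")

print(
    "expression SE vs non-SE genes: "
    f"median log2 {expr['median_log2_se']:.2f} vs {expr['median_log2_non_se']:.2f}, "
    f"Mann-Whitney p = {expr['p_value']:.3f} "
    f"({'no ' if expr['p_value'] >= 0.05 else ''}significant difference)"
)
print("motif enrichment in skip flanks vs controls:")
print(motifs[["motif_id", "odds_ratio", "p_value", "q_value"]].to_string(index=False))
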