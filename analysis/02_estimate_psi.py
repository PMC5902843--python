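"""Estimate psi per event and cell type from junction reads and call the
predominant isoform with the type-specific cutoffs (<=0.2 for SE/A3SS,
>=0.8 for RI/A5SS, either tail for MXE)."""

import pandas as pd

from common import RUN_DIR, ensure_stages

ensure_stages("simulate", "psi")

calls = pd.read_csv(RUN_DIR / "psi_calls.tsv", sep="\t")
counts = pd.read_csv(RUN_DIR / "type_counts.tsv", sep="\t")

n_passed = int(calls["passed_filter"].sum())
print(f"{n_passed}/{len(calls)} estimates pass the CI-width/depth filter")
print(f"{int(calls['called'].sum())} predominant-isoform calls")
print("called events per type x cell type (totals row last):")
print(counts.to_string(index=False))
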