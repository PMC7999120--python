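#!/usr/bin/env python
"""Transcript-protein concordance of the two differential layers.

Thresholds the transcriptome table at fold change > 1.5 / FDR < 0.05 and
the proteome at fold change > 1.2 / p < 0.05, intersects the called
sets on the shared measured universe, and scores direction agreement.
"""

import argparse
import json
from pathlib import Path

from pairedlfq import io
from pairedlfq.integration import concordance, threshold_deg

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

deg = io.read_deg_table(args.data_dir / "deg.tsv")
results = io.read_table(args.out_dir / "differential.tsv")
deg_calls = threshold_deg(deg)
dep_calls = results[results["significant"]]
report = concordance(
    deg_calls, dep_calls,
    deg_universe=set(deg["gene"].astype(str)),
    dep_universe=set(results["feature_id"].astype(str)),
)
io.write_table(report.as_frame(), args.out_dir / "concordance.tsv", f"seed={args.seed}")
(args.out_dir / "venn.jsonl").write_text(json.dumps({
    "deg_only": report.n_deg - report.n_common,
    "dep_only": report.n_dep - report.n_common,
    "common": report.n_common,
}) + "\n", encoding="utf-8")

print(f"{report.n_deg} DEGs, {report.n_dep} DEPs, {report.n_common} in common "
      f"on a {report.universe_size}-feature shared universe")
print(f"{report.n_concordant}/{report.n_common} common calls agree in direction "
      f"(quadrants {report.quadrants}); overlap p = {report.overlap_p:.3g}")
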