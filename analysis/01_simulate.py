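#!/usr/bin/env python
"""Generate the synthetic paired-knockdown study dataset.

Emulates four patient-derived cell lines measured under scrambled and
targeting siRNA: a MaxQuant-style peptide intensity table with MNAR
missingness, a matching transcriptome differential table, gene sets, a
flux stress-test trace, and staining counts.  Writes everything under
results/data/ together with the ground-truth table.
"""

import argparse
from pathlib import Path

from pairedlfq import io, simulate
from pairedlfq.cli import _sub_seeds

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

params = simulate.SimParams(seed=args.seed)
deg_seed, gmt_seed, trace_seed, count_seed = _sub_seeds(args.seed + 1, 4)

matrix, truth = simulate.simulate_peptides(params)
io.write_peptides(matrix, args.out_dir / "peptides.tsv")
io.write_design(matrix, args.out_dir / "design.tsv")
io.write_table(truth, args.out_dir / "truth.tsv", f"seed={args.seed}")

deg = simulate.simulate_deg_table(truth, seed=deg_seed)
io.write_table(deg[["gene", "log2fc", "fdr"]], args.out_dir / "deg.tsv",
               f"seed={args.seed}")
sets, desc = simulate.simulate_gene_sets(truth, seed=gmt_seed)
io.write_gmt(sets, desc, args.out_dir / "genesets.gmt")
io.write_trace(simulate.simulate_trace(seed=trace_seed), args.out_dir / "trace.tsv")

n_de = int(truth["is_de"].sum())
n_down = int((truth["direction"] == "down").sum())
missing = float(matrix.missing_mask.to_numpy().mean())
print(f"wrote {len(matrix.peptide_ids)} peptides / {params.n_proteins} proteins "
      f"for {params.n_pairs} paired cell lines to {args.out_dir}")
print(f"spiked {n_de} differential proteins ({n_down} down, {n_de - n_down} up); "
      f"{missing:.1%} of cells missing (abundance-dependent)")
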