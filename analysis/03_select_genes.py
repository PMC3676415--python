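#!/usr/bin/env python
"""Score genes with the improved volcano plot and select the candidates.

Each probe gets a Welch t-test p-value (control vs salt) and a MergeValue
from 20 class-stratified bootstrap rounds of linear SVM-RFE; probes with
p <= 0.05 and MergeValue >= 0.5 are selected. Reports recall of the planted
informative probes and writes the score table plus the volcano figure.
"""

import argparse
from pathlib import Path

import pandas as pd

from saltgenes.preprocess import ExpressionMatrix
from saltgenes.selection import (
    RfeConfig,
    SelectionThresholds,
    improved_volcano_select,
    save_volcano_plot,
    score_genes,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--bootstraps", type=int, default=20)
parser.add_argument("--in-dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

matrix = ExpressionMatrix.from_tsv(
    args.in_dir / "expression_normalized.tsv", args.in_dir / "labels.tsv"
)
scores = score_genes(matrix, RfeConfig(n_bootstraps=args.bootstraps, seed=args.seed + 3))
thresholds = SelectionThresholds()
selected, table = improved_volcano_select(scores, thresholds)

out = args.out_dir
out.mkdir(parents=True, exist_ok=True)
report = scores.join(table[["selected", "stratum", "neg_log10_p"]]).rename_axis("probe_id")
report.to_csv(out / "selection.tsv", sep="\t")
save_volcano_plot(table, str(out / "volcano.png"), thresholds)
pd.Series(sorted(selected)).to_csv(out / "selected_probes.txt", index=False, header=False)

truth_path = Path("results/analysis/inputs/truth_informative.tsv")
msg = ""
if truth_path.exists():
    truth = pd.read_csv(truth_path, sep="\t", index_col=0)
    planted = set(truth.index[truth["informative"]])
    recall = len(selected & planted) / len(planted)
    msg = f"; recall of planted informative probes {100 * recall:.1f}%"
print(f"{len(selected)} of {matrix.n_probes} probes selected at "
      f"p <= {thresholds.p_max}, MergeValue >= {thresholds.merge_min}{msg}")
print(f"score table -> {out / 'selection.tsv'}, volcano figure -> {out / 'volcano.png'}")
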