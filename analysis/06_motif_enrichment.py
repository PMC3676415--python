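#!/usr/bin/env python
"""Test promoter-motif enrichment and match the motif against a reference.

Scans the CT-rich consensus TCTCTCTCT over the target and background
promoter sets, chi-square tests presence, and compares the detected motif
against the CTRMCAMV35S reference under the identity rule (score > 4 and
> 80% matched positions).
"""

import argparse
from pathlib import Path

import pandas as pd

from saltgenes.motifs import MotifConsensus, chi_square_presence, compare_motifs, presence_table, scan_motif
from saltgenes.simulate import read_fasta

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)  # accepted so every step takes the same flags
parser.add_argument("--in-dir", type=Path, default=Path("results/analysis/inputs"))
parser.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

motif = MotifConsensus("CT-rich", "TCTCTCTCT")
target = read_fasta(args.in_dir / "promoters_target.fasta")
background = read_fasta(args.in_dir / "promoters_background.fasta")
tab = presence_table(scan_motif(target, motif), scan_motif(background, motif))
chi2, p, low_expected = chi_square_presence(tab)

reference = MotifConsensus("CTRMCAMV35S", "TCTCTCTCT")
score, pct, identical = compare_motifs(motif, reference)

args.out_dir.mkdir(parents=True, exist_ok=True)
pd.DataFrame([{
    "motif": motif.iupac,
    "target_present": tab.target_present, "target_total": len(target),
    "background_present": tab.background_present, "background_total": len(background),
    "chi2": chi2, "p_value": p, "low_expected_warning": low_expected,
    "reference": reference.name, "match_score": score, "match_pct": pct,
    "identical_to_reference": identical,
}]).to_csv(args.out_dir / "motif_enrichment.tsv", sep="\t", index=False)

print(f"{motif.iupac}: present in {tab.target_present}/{len(target)} target vs "
      f"{tab.background_present}/{len(background)} background promoters")
print(f"chi-square = {chi2:.2f}, p = {p:.3g}" + (" (low expected counts)" if low_expected else ""))
print(f"vs {reference.name}: score {score}, {pct:.0f}% matched -> "
      f"{'identical' if identical else 'distinct'}")
print(f"report -> {args.out_dir / 'motif_enrichment.tsv'}")
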