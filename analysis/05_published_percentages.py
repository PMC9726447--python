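#!/usr/bin/env python
"""Recompute the per-strain and strain-averaged source-population percentages
from the published per-population assigned bp totals for the Saaz (CBS 1538)
and Frohberg (W34/70) lager strains.

Writes results/published_percentages.tsv.
"""

from pathlib import Path

from lagerpaint.painter import AncestrySummary, percentages_from_bp, summarize_across_strains

CBS1538_BP = {"Tibet": 6_233_324, "Ireland": 4_188_309, "NorthCarolina": 690_505}
W3470_BP = {"Tibet": 5_558_609, "Ireland": 4_525_481, "NorthCarolina": 619_169}
GENOME_BP = 12_050_494

outdir = Path("results")
outdir.mkdir(exist_ok=True)
rows = []
for strain, bp in (("CBS 1538", CBS1538_BP), ("W34/70", W3470_BP)):
    pct = percentages_from_bp(bp)
    for label in ("Ireland", "Tibet", "NorthCarolina"):
        rows.append((strain, label, bp[label], round(pct[label], 2)))

summaries = [
    AncestrySummary(bp, GENOME_BP - sum(bp.values()), GENOME_BP)
    for bp in (CBS1538_BP, W3470_BP)
]
means = summarize_across_strains(summaries)
for label in ("Ireland", "Tibet", "NorthCarolina"):
    rows.append(("mean", label, "", round(means[label], 2)))

with open(outdir / "published_percentages.tsv", "w") as fh:
    fh.write("strain\tpopulation\tassigned_bp\tpercent_of_assigned\n")
    for r in rows:
        fh.write("\t".join(str(x) for x in r) + "\n")

for strain, label, bp, pct in rows:
    bp_s = f"{bp:,}" if bp != "" else "-"
    print(f"{strain:10s} {label:15s} {bp_s:>11s} {pct:>7.2f}%")
print(f"\nstrain-averaged (rounded): Tibet {round(means['Tibet'])}%, "
      f"Ireland {round(means['Ireland'])}%, "
      f"North Carolina {round(means['NorthCarolina'])}%")
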