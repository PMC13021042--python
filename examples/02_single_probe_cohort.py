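"""Simulate a single-probe comparison cohort and analyze the memory bias.

Generates 16 integrating observers through the single-probe design (12
blocks of 12 baseline + 36 comparison trials; probes 16-105 deg from the
target with a similar/dissimilar judgment), then runs the offset pipeline:
high-confidence filtering, bias split by judgment, and the
ambivalent-probe analysis that equates physical probe distance across
judgment types.
"""

from wmbias import ObserverSpec, exp1_design, generate_dataset
from wmbias.pipeline import analyze_table

table = generate_dataset(exp1_design(), [ObserverSpec()] * 16, seed=7)
report = analyze_table(table, seed=7)

print(f"{len(table)} trials; mean high-confidence retention "
      f"{report.retention['fraction'].mean():.0%}\n")

for _, row in report.judgment_bias.group.iterrows():
    print(f"bias after {row['condition']:>10} judgments: "
          f"{row['mean']:5.2f} deg, t({row['df']})={row['t']:.2f}, "
          f"p={row['p']:.2g}, d={row['cohens_d']:.2f}")

amb = report.ambivalent_test
print(f"\nambivalent-distance difference (similar - dissimilar): "
      f"{amb['mean']:.2f} deg, t({amb['df']})={amb['t']:.2f}, p={amb['p']:.2g}")

# Reports are pulled several degrees toward probes judged similar, but
# barely toward probes judged dissimilar — and the difference survives at
# matched physical distances (the ambivalent analysis), so it reflects
# subjective, not merely physical, similarity.
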