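"""Contrast the two forces that can shape codon usage: GC3 mutational bias
versus translational selection.

Generates two 250-gene genomes — one with mutational bias only, one with
codon optimality coupled to expression — and runs the headline association
report on each. Under bias alone, usage Axis 1 tracks GC3 and not
expression; under selection, the expression correlation appears.
"""

import pandas as pd

import codonvol as cv
from codonvol.association import association_report, build_metric_table

for label, strength in (("mutational bias only", 0.0), ("translational selection", 2.0)):
    genome = cv.generate_genome(cv.SyntheticGenomeSpec(
        n_genes=250, max_codons=300, gc3_bias=0.7, selection_strength=strength, seed=5))
    vol = cv.genome_scan(genome.sequences, seed=6)
    per_gene, _, _ = cv.usage_axes(genome.sequences)
    gmt = build_metric_table(volatility=vol, usage=per_gene, expression=genome.expression)
    report = association_report(gmt)
    print(f"== {label} (selection_strength = {strength})")
    frame = report.to_frame()
    cols = ["comparison", "n", "r_squared", "spearman_rho", "spearman_p"]
    print(frame[frame.comparison.isin(["axis1~gc3", "axis1~expression"])][cols]
          .round(4).to_string(index=False))
    print()

print("Axis 1 ~ GC3 is strong in both regimes; Axis 1 ~ expression is flat under")
print("pure mutational bias and emerges only when optimal-codon preference is")
print("coupled to expression — the contrast the association stage quantifies.")
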