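"""Correspondence analysis of synonymous codon usage (RSCU space).

Generates a genome with heterogeneous GC3, summarizes every gene by its
59-dimensional RSCU vector, and decomposes the gene x codon table into
orthogonal axes ranked by inertia. Axis 1 should track GC3: under a pure
mutational-bias regime, third-position composition is the dominant source
of codon-usage variation.
"""

from scipy import stats

import codonvol as cv

genome = cv.generate_genome(cv.SyntheticGenomeSpec(n_genes=300, max_codons=400, seed=7))
per_gene, inertia, excluded = cv.usage_axes(genome.sequences, min_length_bp=100)

print(per_gene.head(6).round(4).to_string())
print()
print("Axis inertia shares (axes above the 5% cutoff are 'significant'):")
print(inertia.head(4).round(4).to_string(index=False))

r = stats.pearsonr(per_gene["axis1"], per_gene["gc3"])
print()
print(f"Pearson r(Axis 1, GC3) = {r.statistic:.3f} (p = {r.pvalue:.2g})")
print("ENC near 61 means nearly uniform synonymous usage; GC3 is the G+C")
print("fraction at third positions of the 59 synonymously degenerate codons.")
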