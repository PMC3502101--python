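"""Scan a synthetic genome for genes with elevated codon volatility.

Builds a 150-gene synthetic genome, scores every gene's summed codon
volatility (kappa = 4.1), and assigns each a P-value against the
synonymous re-encoding null: small P means the gene's codon choices are
more volatile than expected under genome-average codon usage.
"""

import codonvol as cv

genome = cv.generate_genome(cv.SyntheticGenomeSpec(n_genes=150, max_codons=300, seed=42))
scan = cv.genome_scan(genome.sequences, model=cv.MutationModel(4.1), threshold=1e-6, seed=0)

print(scan.sort_values("p_value").head(8).to_string(index=False))
print()
print(f"{int(scan.elevated_flag.sum())} of {len(scan)} genes elevated at P < 1e-6.")
print("v_sum is the summed per-codon volatility; null_mean/null_var are the exact")
print("moments of v_sum when each site is re-encoded with a synonymous codon drawn")
print("from genome-wide usage. A mutational-bias-only genome (as simulated here)")
print("should flag nothing: volatility deviations are noise around the null.")
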