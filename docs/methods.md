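# Methods

This note documents the statistical models, numerical conventions and design
choices behind `codonvol`, and what the synthetic-data experiments do and do
not establish.

## Codon volatility

For a sense codon `c` under the standard nuclear code (NCBI table 1), the
volatility is

    nu(c) = sum_{n in N*(c), nonsyn} w(c,n)  /  sum_{n in N*(c)} w(c,n)

where `N*(c)` is the set of single-point-mutation neighbors that are not
stop codons, and `w` is `kappa` for transitions (A<->G, C<->T) and 1 for
transversions. Stop codons are excluded both as inputs and as neighbors:
they contribute to neither numerator nor denominator. `kappa = 1` recovers
plain neighbor counting (AGA: 6/8 = 0.75); the genome-scan default is
`kappa = 4.1`, a transition:transversion ratio appropriate to a plant
nuclear genome. Volatility is 1 exactly for the single-codon families ATG
(Met) and TGG (Trp). Codons containing ambiguity characters are rejected at
this layer; higher layers decide whether to skip or fail.

A gene's score is `v_sum`, the sum of its codons' volatilities (`v_mean` =
`v_sum`/n is also reported).

## The significance null

The package assigns each gene P = Pr(V >= v_sum) under **independent
per-site synonymous re-encoding**: each residue is re-encoded with a codon
drawn from that amino acid's genome-wide synonymous frequency vector,
estimated from the scanned CDS collection itself (an external frequency
table may be supplied instead). This null conditions on the protein, so
amino-acid composition cannot drive significance — only a gene's synonymous
codon choices can. Small P means elevated volatility; the default selection
threshold is 1e-6.

Because sites are independent, the null mean and variance of `v_sum` are
exact sums of per-site moments (`exact_normal` mode applies a normal
approximation to that sum, without continuity correction). `monte_carlo`
mode draws re-encodings and uses the estimator (1 + #{samples >= obs}) /
(1 + n_samples), which can never report zero and is authoritative in the
extreme tail; the two agree to |dP| <= 0.01 in the mid-range at 300 codons.
Degenerate nulls (e.g. an all-Met/Trp gene) give P = 1 by the >=
convention. P-values are invariant to codon order within a gene.

## Codon usage statistics

**RSCU.** For codon `c` in a family of size `k` with family total `N_aa`,
RSCU = `k n_c / N_aa`; families absent from a gene are flagged missing
(NaN), distinct from an unused codon in a present family (0). Only the 59
codons with a synonymous alternative are analysed.

**GC3** is the G+C fraction at third positions of degenerate codons only
(ATG/TGG excluded); missing if a gene has none.

**ENC.** Wright's estimator Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with
per-family homozygosity F = (n sum p^2 - 1)/(n - 1), class means over the
2-, 3- (Ile), 4- and 6-fold families. Families with n <= 1, or with F <= 0
(uninformative at small counts), are excluded from their class mean; a class
with no estimable family is imputed from the family-count-weighted mean
reciprocal of the estimable classes; the result is clipped to [20, 61].
Note the bias-corrected F drifts at O(1/n) under count doubling — the
self-concatenation invariance is asymptotic and is tested at a count scale
(~1000 observations per family) where the drift is below 0.1 Nc units.

**Correspondence analysis.** The genes x 59 RSCU table (NaN -> 0) is
treated as a contingency-style array: with grand total N, P = X/N, row
masses r, column masses c, the standardized residuals
S = (P - r c^T)/sqrt(r c^T) are decomposed by SVD. Total inertia equals
sum(sigma^2) = chi^2/N; axes are reported in decreasing inertia order and
axes above a 5% inertia share are marked significant. Axes receive a
deterministic orientation (the dominant column loading of each axis is made
positive) so signs are comparable across runs; row coordinates are principal
(mass-standardized and scaled by sigma). Genes shorter than 100 bp are
excluded from the usage pipeline and logged.

## Pairwise dN/dS

Inputs are CDS pairs; gene-model extraction from genomic reads is a
precondition, not a feature. Proteins are aligned with affine-gap dynamic
programming (BLOSUM62, gap open 11 / extend 1; local by default, mirroring
partial orthologs; global optional), the alignment is back-translated so
each residue column becomes its source codon and each protein gap a
whole-codon gap, and gapped columns are dropped before estimation
(pairwise deletion). Coverage is reported as ungapped aligned codons over
the reference codon count.

**NG86.** Synonymous site counts per codon use the fraction of non-stop
single-base changes that are synonymous at each position, averaged over the
two sequences; multi-hit codon pairs are averaged over all minimal
mutational pathways that avoid stops (if every pathway is blocked, all
pathways are used with stop steps counted nonsynonymous and the estimate
flagged). Jukes–Cantor correction d = -3/4 ln(1 - 4p/3) is applied to pS
and pN; p >= 3/4 leaves the distance undefined and flags the estimate.
The estimator is symmetric in sequence order. Note that very short
alignments saturate easily: a single synonymous difference in one Phe codon
already gives pS = 3.

**M0 likelihood fit.** The one-ratio 61-state codon model has rates
q_ij ∝ pi_j * kappa^[transition] * omega^[nonsynonymous] for single-base
changes, zero otherwise, normalized to one expected substitution per codon
per unit t. Codon frequencies come from the alignment (F3x4 default, F61
optional). The pair likelihood sum_xy n_xy log(pi_x P_xy(t)) (counts
symmetrized — the pair is unrooted) is maximized over log(t, kappa, omega)
by bounded L-BFGS-B from three omega starts {0.1, 0.5, 2.0}; transition
probabilities use the symmetric eigendecomposition available for reversible
generators. dN and dS are derived codeml-style: substitution flow is split
into synonymous and nonsynonymous parts and divided by site fractions
computed from the same mutational process at omega = 1, so reported dN/dS
equals the fitted omega. Estimates below 50 ungapped codons, saturated
alignments, and non-convergent fits are flagged, not hidden.

## Synthetic genomes

The generator produces the study conditions for every test: `n_genes` = 600
genes, lengths uniform on 34–800 codons (mean ~420, the scale of real plant
CDSs; 34 codons is the 100-bp analysis floor), amino acids drawn from an
average-proteome-like composition, expression Normal(6.44, 2.02) on the
log2 scale (an RMA-like law).

**Mutational bias.** Each gene draws a G+C target `g` from a Beta law with
mean `gc3_bias` (default 0.7) and spread `gc3_sd` (default 0.15, a
plant-genome-like between-gene GC3 spread); within each synonymous family a
codon's weight is the product over its three bases of `g` (G/C) or `1-g`
(A/T) — the neutral mutational-equilibrium form. For 2- and 4-fold families
this reduces to a third-position G/C preference; in the 6-fold families it
also biases the sub-family split (AGR vs CGN arginine, TTR vs CTN leucine,
AGY vs TCN serine). That sub-family channel matters: it is the only route
by which a protein-conditioned volatility P-value can couple to GC3 at all.
Even through it the attainable coupling is modest — the per-gene volatility
z-score moves by only ~0.9 per unit of GC3 target, so with a 0.15 spread
the volatility~GC3 rank correlation is ~0.15–0.25, significant and
sign-stable but far weaker than the near-total axis1~GC3 correlation. Usage
statistics are simply more sensitive to compositional bias than the
conditioned volatility statistic.

**Translational selection.** With `selection_strength` s > 0, a gene with
standardized expression z > 0 mixes a point mass on one designated optimal
codon per amino acid (a fixed C-then-G-ending table, configurable) into its
family distribution with weight s*z/(1 + s*z). s = 0 makes expression
independent of every usage metric by construction — the negative control
that lets the association stage demonstrate *absence* of an expression
effect as a detectable outcome rather than a vacuous one.

**Ortholog simulation.** `evolve_pair` evolves each site of a CDS for time
t by sampling the descendant codon from the exact finite-time transition
distribution exp(Qt) of the M0 process (equivalent in distribution to
simulating the continuous-time chain), with pi taken from the ancestral
sequence (F3x4 default). `truncate_to_fragment` keeps a contiguous window
of ceil(fraction*n) codons at a seeded offset, emulating ~30%-coverage
partial orthologs. `sample_stationary_cds` provides equilibrium ancestors
for unbiased parameter-recovery experiments.

**What the generator does not emulate:** introns/UTRs, indel evolution,
assembly artifacts, context-dependent (e.g. CpG) mutation, amino-acid
composition responding to GC pressure, or genes sharing evolutionary
history. Passing tests therefore show the statistics behave correctly under
a clean two-force model, not that real genomes contain no further
structure.

## Pipeline and reproducibility

The end-to-end run chains simulate -> validate -> volatility -> usage ->
dnds -> associate. Validation strips trailing stops silently and rejects
(never repairs) sequences with internal stops, non-multiple-of-3 length, or
ambiguity codons, logging a typed reason per rejection. A dnds-stage
failure degrades the run (the association report skips the omega
comparison) rather than aborting it. Every run writes its resolved flat-key
config, per-stage TSVs, and a JSON manifest with derived seeds, attrition
counts and output checksums; identical config + seed reproduces identical
bytes. Defaults encode the analysis constants: kappa 4.1, elevation
threshold 1e-6, 100-bp length filter, 5% axis-inertia cutoff,
high-expression quantile 0.167. No multiple-testing correction is applied
across the four headline comparisons, and the overlay stage reports a
rank-based (Mann–Whitney) location test alongside subset/complement
moments.

## Problem sizes

Test and acceptance experiments use desk-scale sizes chosen to give each
check clear resolution: 500 null genes of 200 codons for P-value
calibration (Monte-Carlo, 2000 samples per gene), 5000-codon pairs for M0
parameter recovery (omega recovered within ±0.05 at 0.3, ±0.1 at 1.0,
kappa within ±0.5 of 4.1; the acceptance script averages three independent
pairs per level), and 600-gene genomes for the headline correlation
pattern.

## Known limitations

- The exact_normal P-value is a normal approximation; for genes of a few
  dozen codons its extreme tail is unreliable — monte_carlo is
  authoritative there (and its minimum reportable P is 1/(n_samples+1)).
- NG86 with kappa-blind counting underestimates omega when transitions are
  strongly favoured; it is kept as the fast, assumption-light cross-check,
  with M0 as the model-based estimate.
- The M0 fit assumes stationarity and reversibility; pairs whose
  compositions differ strongly violate F3x4 stationarity and will absorb
  the mismatch into t and kappa.
- Correspondence analysis treats missing families as zero counts; genes
  dominated by rare amino acids therefore shrink toward the origin rather
  than being imputed.
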