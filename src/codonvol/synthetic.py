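"""Synthetic genomes, expression tables and diverged ortholog pairs.

The generator embodies the two competing forces the analysis contrasts:

* **GC3 mutational bias** — each gene draws a G+C target from a Beta law
  centred on ``gc3_bias``; within every synonymous family each codon is
  weighted by that probability at every base (neutral mutational-equilibrium
  form).  For 2- and 4-fold families this reduces to a third-position G/C
  preference; in the 6-fold families it also biases the sub-family choice,
  the channel that couples composition to volatility.  This is a
  codon-choice-level stand-in for an explicit mutation-accumulation process.
* **Translational selection** — with ``selection_strength > 0``, genes with
  above-average expression mix in a point mass on one designated optimal
  codon per amino acid, coupling codon usage to expression.

Ortholog pairs are produced by evolving a CDS under the 61-state codon
substitution process for a chosen (omega, kappa, t); fragments emulate
partial shotgun-derived orthologs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import codon_model
from .genetic_code import GeneticCode, standard_code
from .volatility import CodingSequence

# Average-proteome-like amino-acid composition (UniProt/Swiss-Prot style
# frequencies, renormalized over the 20 standard residues).
AA_COMPOSITION: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0966, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

DEFAULT_EXPRESSION_MEAN = 6.44
DEFAULT_EXPRESSION_SD = 2.02


def default_optimal_codons(code: GeneticCode | None = None) -> dict[str, str]:
    """One designated optimal codon per amino acid.

    Convention: the alphabetically first codon with C at the third position,
    else G, else the first codon of the family — a fixed, configurable table
    emulating a C/G-ending optimal set as seen in translationally selected
    plant genomes.
    """
    code = code or standard_code()
    out = {}
    for aa, codons in code.families().items():
        for third in "CG":
            cands = [c for c in codons if c[2] == third]
            if cands:
                out[aa] = cands[0]
                break
        else:
            out[aa] = codons[0]
    return out


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic CDS collection.

    ``gc3_bias`` is the mean third-position G+C probability of the mutational
    regime; each gene's own target is Beta-distributed around it with spread
    ``gc3_sd``, emulating between-gene compositional heterogeneity.
    ``selection_strength`` scales how strongly genes with above-average
    expression prefer the optimal codon (0 = pure mutational regime).
    Expression is Normal on the log2 scale, default mean 6.44 / SD 2.02
    (an RMA-normalized microarray-like law).
    """

    n_genes: int = 600
    min_codons: int = 34
    max_codons: int = 800
    length_distribution: str = "uniform"  # or "lognormal"
    gc3_bias: float = 0.7
    gc3_sd: float = 0.15
    selection_strength: float = 0.0
    expression_mean: float = DEFAULT_EXPRESSION_MEAN
    expression_sd: float = DEFAULT_EXPRESSION_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.min_codons > self.max_codons:
            raise ValueError(f"min_codons {self.min_codons} > max_codons {self.max_codons}")
        if self.min_codons < 34:
            raise ValueError("min_codons must be >= 34 (the 100-bp analysis floor)")
        if not 0 < self.gc3_bias < 1:
            raise ValueError("gc3_bias must lie in (0, 1)")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")


@dataclass
class SyntheticGenome:
    sequences: list[CodingSequence]
    expression: pd.Series  # gene_id -> log2 expression
    truth: pd.DataFrame    # per-gene generator ground truth
    spec: SyntheticGenomeSpec


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    # Clamp sd below the Bernoulli bound so alpha, beta stay positive.
    max_sd = np.sqrt(mean * (1 - mean)) * 0.95
    sd = min(sd, max_sd)
    if sd <= 0:
        return mean * 1e6, (1 - mean) * 1e6
    nu = mean * (1 - mean) / sd**2 - 1
    return mean * nu, (1 - mean) * nu


def _gene_lengths(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.length_distribution == "uniform":
        return rng.integers(spec.min_codons, spec.max_codons + 1, size=spec.n_genes)
    if spec.length_distribution == "lognormal":
        mid = np.sqrt(spec.min_codons * spec.max_codons)
        raw = rng.lognormal(mean=np.log(mid), sigma=0.5, size=spec.n_genes)
        return np.clip(raw.astype(int), spec.min_codons, spec.max_codons)
    raise ValueError(f"unknown length distribution {spec.length_distribution!r}")


def generate_genome(
    spec: SyntheticGenomeSpec,
    code: GeneticCode | None = None,
    aa_composition: dict[str, float] | None = None,
    optimal_codons: dict[str, str] | None = None,
) -> SyntheticGenome:
    """Generate a synthetic CDS collection with expression and ground truth.

    Per gene: a protein is drawn from the amino-acid composition; each
    residue's codon is drawn from a mixture of the gene's GC3-biased family
    distribution (weight 1) and a point mass on the optimal codon (weight
    ``selection_strength`` x standardized expression, floored at 0).
    Byte-reproducible from the spec's seed.
    """
    code = code or standard_code()
    comp = aa_composition or AA_COMPOSITION
    optimal = optimal_codons or default_optimal_codons(code)
    rng = np.random.default_rng(spec.seed)
    aas = sorted(comp)
    aa_probs = np.array([comp[a] for a in aas], dtype=float)
    aa_probs = aa_probs / aa_probs.sum()
    families = code.families()

    lengths = _gene_lengths(spec, rng)
    expression = rng.normal(spec.expression_mean, spec.expression_sd, size=spec.n_genes)
    a, b = _beta_params(spec.gc3_bias, spec.gc3_sd)
    gc3_targets = np.clip(rng.beta(a, b, size=spec.n_genes), 0.02, 0.98)
    z = (expression - spec.expression_mean) / spec.expression_sd

    sequences: list[CodingSequence] = []
    truth_rows = []
    width = len(str(spec.n_genes))
    for g in range(spec.n_genes):
        gene_id = f"SYN{g + 1:0{width}d}"
        n = int(lengths[g])
        target = float(gc3_targets[g])
        sel_w = spec.selection_strength * max(float(z[g]), 0.0)
        protein_idx = rng.choice(len(aas), size=n, p=aa_probs)
        codons: list[str] = []
        fam_dist: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
        for ai in protein_idx:
            aa = aas[ai]
            if aa not in fam_dist:
                fam = families[aa]
                # GC bias weights every base of the codon; within 2- and
                # 4-fold families positions 1-2 are constant and cancel, so
                # this reduces to the third-position rule there, while in the
                # 6-fold families (Leu, Ser, Arg) it also biases the
                # sub-family choice — the channel that couples composition to
                # volatility.
                base = np.array(
                    [np.prod([target if b in "GC" else 1 - target for b in c]) for c in fam]
                )
                base = base / base.sum()
                if sel_w > 0:
                    opt = np.array([1.0 if c == optimal[aa] else 0.0 for c in fam])
                    base = (base + sel_w * opt) / (1 + sel_w)
                fam_dist[aa] = (fam, np.cumsum(base))
            fam, cum = fam_dist[aa]
            codons.append(fam[int(np.searchsorted(cum, rng.random(), side="left"))])
        sequences.append(CodingSequence(gene_id=gene_id, codons=tuple(codons),
                                        source_note="synthetic"))
        truth_rows.append(
            {"gene_id": gene_id, "n_codons": n, "gc3_target": target,
             "selection_weight": sel_w, "log2_expression": float(expression[g])}
        )
    expr = pd.Series(expression, index=[r["gene_id"] for r in truth_rows], name="log2_expr")
    expr.index.name = "gene_id"
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return SyntheticGenome(sequences=sequences, expression=expr, truth=truth, spec=spec)


@dataclass(frozen=True)
class OrthologSimSpec:
    """Divergence parameters for simulating an ortholog pair."""

    omega: float
    kappa: float = 4.1
    t: float = 0.5  # expected substitutions per codon site
    frequency_model: str = "F3x4"  # or "F61", "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0 or self.kappa <= 0 or self.t < 0:
            raise ValueError("omega, kappa must be positive and t non-negative")


def _sim_pi(cds: CodingSequence, spec: OrthologSimSpec, code: GeneticCode) -> np.ndarray:
    if spec.frequency_model == "F3x4":
        return codon_model.f3x4_frequencies([cds.codons], code)
    if spec.frequency_model == "F61":
        return codon_model.f61_frequencies([cds.codons], code)
    if spec.frequency_model == "uniform":
        n = len(codon_model.model_structure(code).codons)
        return np.full(n, 1.0 / n)
    raise ValueError(f"unknown frequency model {spec.frequency_model!r}")


def evolve_pair(
    cds: CodingSequence, spec: OrthologSimSpec, code: GeneticCode | None = None
) -> tuple[CodingSequence, CodingSequence]:
    """(ancestral copy, diverged copy) under the 61-state codon process.

    Each site evolves independently for time ``t``: the descendant codon is
    drawn from the exact finite-time transition distribution exp(Qt) row of
    the ancestral codon, which is equivalent in distribution to simulating
    the continuous-time chain.  Stop codons are unreachable by construction.
    """
    code = code or standard_code()
    struct = codon_model.model_structure(code)
    rng = np.random.default_rng(spec.seed)
    if spec.t == 0:
        return cds, replace(cds, gene_id=cds.gene_id + "_div")
    pi = _sim_pi(cds, spec, code)
    Q = codon_model.rate_matrix(pi, spec.kappa, spec.omega, code)
    P = codon_model.transition_probabilities(Q, pi, spec.t)
    cum = np.cumsum(P, axis=1)
    anc_idx = np.array([struct.index[c] for c in cds.codons])
    u = rng.random(len(anc_idx))
    rows = cum[anc_idx]
    desc_idx = (rows < u[:, None]).sum(axis=1)
    desc_idx = np.minimum(desc_idx, len(struct.codons) - 1)
    descendant = tuple(struct.codons[i] for i in desc_idx)
    return cds, CodingSequence(
        gene_id=cds.gene_id + "_div", codons=descendant,
        source_note=f"evolved omega={spec.omega} kappa={spec.kappa} t={spec.t}",
    )


def sample_stationary_cds(
    n_codons: int, pi: np.ndarray, seed: int, gene_id: str = "ANC",
    code: GeneticCode | None = None,
) -> CodingSequence:
    """A CDS with codons drawn iid from a stationary codon distribution."""
    code = code or standard_code()
    struct = codon_model.model_structure(code)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(struct.codons), size=n_codons, p=pi / pi.sum())
    return CodingSequence(gene_id=gene_id, codons=tuple(struct.codons[i] for i in idx),
                          source_note="stationary sample")


def truncate_to_fragment(cds: CodingSequence, fraction: float, seed: int) -> CodingSequence:
    """A contiguous codon window of ceil(fraction * n) codons at a seeded offset."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = int(np.ceil(fraction * cds.n_codons))
    if n < 1:
        raise ValueError("fragment would be empty")
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, cds.n_codons - n + 1))
    return CodingSequence(
        gene_id=cds.gene_id, codons=cds.codons[offset : offset + n],
        source_note=f"fragment {offset}:{offset + n} of {cds.n_codons}",
    )
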