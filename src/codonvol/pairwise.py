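"""Protein-guided pairwise codon alignment and dN/dS estimation.

Ortholog pairs are aligned at the protein level (Smith-Waterman local by
default, mirroring partial-gene orthologs; Needleman-Wunsch global
optional), the protein alignment is back-translated to a codon alignment,
and dN/dS is estimated either by Nei-Gojobori (1986) counting with pathway
averaging and Jukes-Cantor correction, or by maximum likelihood under the
one-ratio (M0) codon substitution model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import minimize

from . import codon_model
from .genetic_code import BASES, GeneticCode, standard_code
from .volatility import CodingSequence

logger = logging.getLogger(__name__)

GAP_CODON = "---"


@dataclass(frozen=True)
class ProteinAlignment:
    """Two gapped amino-acid strings of equal length plus their ungapped offsets."""

    seq1: str
    seq2: str
    score: float
    mode: str
    start1: int = 0  # offset of the aligned span within the ungapped proteins
    start2: int = 0

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise ValueError("gapped protein strings differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.seq1, self.seq2)):
            raise ValueError("alignment contains a double-gap column")


def align_proteins(
    p1: str,
    p2: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    mode: str = "local",
) -> ProteinAlignment:
    """Optimal pairwise protein alignment with affine gap penalties.

    Deterministic: of equally scoring alignments the aligner's first
    (highest-road) traceback is taken.
    """
    if not p1 or not p2:
        raise ValueError("empty protein sequence")
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be local or global, got {mode!r}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    aln = aligner.align(p1, p2)[0]
    coords = aln.coordinates
    g1, g2 = [], []
    for k in range(coords.shape[1] - 1):
        a0, a1 = int(coords[0, k]), int(coords[0, k + 1])
        b0, b1 = int(coords[1, k]), int(coords[1, k + 1])
        if a1 > a0 and b1 > b0:
            g1.append(p1[a0:a1])
            g2.append(p2[b0:b1])
        elif a1 > a0:
            g1.append(p1[a0:a1])
            g2.append("-" * (a1 - a0))
        else:
            g1.append("-" * (b1 - b0))
            g2.append(p2[b0:b1])
    return ProteinAlignment(
        seq1="".join(g1),
        seq2="".join(g2),
        score=float(aln.score),
        mode=mode,
        start1=int(coords[0, 0]),
        start2=int(coords[1, 0]),
    )


@dataclass(frozen=True)
class CodonAlignment:
    """Gapped codon lists mirroring a guiding protein alignment."""

    codons1: tuple[str, ...]
    codons2: tuple[str, ...]
    id1: str = "seq1"
    id2: str = "seq2"

    def __post_init__(self) -> None:
        if len(self.codons1) != len(self.codons2):
            raise ValueError("codon alignment rows differ in length")

    def ungapped_pairs(self) -> list[tuple[str, str]]:
        return [
            (a, b) for a, b in zip(self.codons1, self.codons2)
            if a != GAP_CODON and b != GAP_CODON
        ]


def backtranslate_alignment(
    pa: ProteinAlignment,
    cds1: CodingSequence,
    cds2: CodingSequence,
    code: GeneticCode | None = None,
) -> CodonAlignment:
    """Thread the codons of two CDS through their guiding protein alignment.

    Each residue column becomes the corresponding codon; a protein gap
    becomes one whole-codon gap.  The CDS must translate to the aligned
    residues over the aligned span; a mismatch raises with the offending
    residue position.
    """
    code = code or standard_code()
    rows = []
    for gapped, cds, start, label in (
        (pa.seq1, cds1, pa.start1, "seq1"),
        (pa.seq2, cds2, pa.start2, "seq2"),
    ):
        out: list[str] = []
        pos = start
        for col, aa in enumerate(gapped):
            if aa == "-":
                out.append(GAP_CODON)
                continue
            if pos >= cds.n_codons:
                raise ValueError(f"{label} ({cds.gene_id}): alignment runs past the CDS end")
            codon = cds.codons[pos]
            translated = code.translate(codon)
            if translated != aa:
                raise ValueError(
                    f"{label} ({cds.gene_id}): residue {pos + 1} translates to "
                    f"{translated!r} but the alignment has {aa!r}"
                )
            out.append(codon)
            pos += 1
        rows.append(tuple(out))
    return CodonAlignment(codons1=rows[0], codons2=rows[1], id1=cds1.gene_id, id2=cds2.gene_id)


@dataclass(frozen=True)
class DnDsEstimate:
    dN: float
    dS: float
    omega: float  # NaN when dS = 0 (undefined)
    method: str
    kappa_hat: float | None = None
    t_hat: float | None = None
    lnL: float | None = None
    coverage_pct: float | None = None
    flags: tuple[str, ...] = ()


def alignment_coverage(ca: CodonAlignment, reference_codon_count: int) -> float:
    """Percentage of the reference CDS covered by ungapped aligned codons."""
    if reference_codon_count <= 0:
        raise ValueError("reference length must be positive")
    return 100.0 * len(ca.ungapped_pairs()) / reference_codon_count


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) counting with pathway averaging
# ---------------------------------------------------------------------------

def _ng86_site_count(codon: str, code: GeneticCode) -> float:
    """Synonymous site count of one codon (stop-creating changes excluded)."""
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(nb):
                continue
            tot += 1
            if code.translate(nb) == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s


def _pathway_diffs(c1: str, c2: str, code: GeneticCode) -> tuple[float, float, bool]:
    """(syn diffs, nonsyn diffs, stop_blocked) averaged over minimal pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked (possible only for 2-3 substitution codons), all pathways are
    used with stop transitions counted as nonsynonymous, and the pair is
    flagged.
    """
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0, False
    valid, fallback = [], []
    for order in itertools.permutations(positions):
        current = c1
        syn = nonsyn = 0
        blocked = False
        for p in order:
            nxt = current[:p] + c2[p] + current[p + 1 :]
            if code.is_stop(nxt) or code.is_stop(current):
                blocked = True
            if (not code.is_stop(nxt) and not code.is_stop(current)
                    and code.translate(nxt) == code.translate(current)):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        (fallback if blocked else valid).append((syn, nonsyn))
    paths = valid if valid else fallback
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd, not valid


def ng86_dnds(ca: CodonAlignment, code: GeneticCode | None = None) -> DnDsEstimate:
    """Nei-Gojobori counting estimate with Jukes-Cantor multiple-hit correction.

    Gapped columns are dropped (pairwise deletion); synonymous site counts
    are averaged over the two sequences; multi-hit codon pairs are averaged
    over all minimal stop-free mutational pathways.  Symmetric in sequence
    order.  pS or pN >= 3/4 leaves the corresponding distance undefined and
    flags the estimate.
    """
    code = code or standard_code()
    pairs = ca.ungapped_pairs()
    if not pairs:
        raise ValueError("no ungapped codon pairs to compare")
    site_cache: dict[str, float] = {}

    def sites(c: str) -> float:
        if c not in site_cache:
            site_cache[c] = _ng86_site_count(c, code)
        return site_cache[c]

    S1 = sum(sites(a) for a, _ in pairs)
    S2 = sum(sites(b) for _, b in pairs)
    S = (S1 + S2) / 2
    N = 3 * len(pairs) - S
    Sd = Nd = 0.0
    flags: list[str] = []
    for a, b in pairs:
        sd, nd, blocked = _pathway_diffs(a, b, code)
        Sd += sd
        Nd += nd
        if blocked:
            flags.append("stop_blocked_pathway")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0

    def jc(p: float) -> float:
        if p >= 0.75:
            return float("nan")
        return float(abs(-0.75 * np.log(1 - 4 * p / 3)))

    dS, dN = jc(pS), jc(pN)
    if np.isnan(dS) or np.isnan(dN):
        flags.append("saturated_jc_undefined")
    omega = dN / dS if dS and dS > 0 else float("nan")
    return DnDsEstimate(
        dN=dN, dS=dS, omega=omega, method="NG86", flags=tuple(sorted(set(flags))),
    )


# ---------------------------------------------------------------------------
# One-ratio (M0) maximum-likelihood fit
# ---------------------------------------------------------------------------

DEFAULT_OMEGA_STARTS = (0.1, 0.5, 2.0)


def _pair_counts(ca: CodonAlignment, code: GeneticCode) -> np.ndarray:
    struct = codon_model.model_structure(code)
    n = len(struct.codons)
    counts = np.zeros((n, n))
    for a, b in ca.ungapped_pairs():
        counts[struct.index[a], struct.index[b]] += 1
    # Symmetrize: the pair is unrooted, the likelihood should not depend on
    # which sequence is labelled ancestral.
    return (counts + counts.T) / 2


def m0_fit(
    ca: CodonAlignment,
    code: GeneticCode | None = None,
    frequency_model: str = "F3x4",
    omega_starts: tuple[float, ...] = DEFAULT_OMEGA_STARTS,
    lnl_tol: float = 1e-8,
) -> DnDsEstimate:
    """Maximum-likelihood (t, kappa, omega) under the one-ratio codon model.

    Codon frequencies come from the alignment itself (F3x4 by default, F61
    optional).  The likelihood is optimized over log-parameters by bounded
    quasi-Newton from multiple omega starts.  dN and dS are derived from the
    fitted process codeml-style: substitution flow split into synonymous and
    nonsynonymous parts, per sites counted from the same mutational process
    at omega = 1, so the reported dN/dS equals the fitted omega.
    """
    code = code or standard_code()
    pairs = ca.ungapped_pairs()
    n_pairs = len(pairs)
    if n_pairs == 0:
        raise ValueError("no ungapped codon pairs to fit")
    flags: list[str] = []
    if n_pairs < 50:
        flags.append("short_alignment")
        logger.warning("m0_fit: only %d ungapped codon pairs (recommend >= 50)", n_pairs)
    codon_lists = [tuple(a for a, _ in pairs), tuple(b for _, b in pairs)]
    if frequency_model == "F3x4":
        pi = codon_model.f3x4_frequencies(codon_lists, code)
    elif frequency_model == "F61":
        pi = codon_model.f61_frequencies(codon_lists, code)
    else:
        raise ValueError(f"unknown frequency model {frequency_model!r}")
    counts = _pair_counts(ca, code)
    p_diff = float(np.mean([a != b for a, b in pairs]))
    t0 = max(0.05, 1.2 * p_diff)

    def neg_lnl(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        return -codon_model.pair_log_likelihood(counts, pi, t, kappa, omega, code)

    bounds = [(np.log(1e-6), np.log(50.0)), (np.log(0.01), np.log(100.0)),
              (np.log(1e-4), np.log(50.0))]
    best = None
    converged = False
    for w0 in omega_starts:
        x0 = np.log([t0, 2.0, w0])
        res = minimize(neg_lnl, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500})
        if best is None or res.fun < best.fun - lnl_tol:
            best = res
        converged = converged or res.success
    assert best is not None
    if not converged:
        flags.append("non_convergence")
    t_hat, kappa_hat, omega_hat = (float(v) for v in np.exp(best.x))
    rho_s, rho_n = codon_model.flow_fractions(pi, kappa_hat, omega_hat, code)
    rho_s1, rho_n1 = codon_model.flow_fractions(pi, kappa_hat, 1.0, code)
    # sites per codon: 3*rho_1 of each class; substitutions per codon: t*rho
    dS = t_hat * rho_s / (3 * rho_s1) if rho_s1 > 0 else float("nan")
    dN = t_hat * rho_n / (3 * rho_n1) if rho_n1 > 0 else float("nan")
    if p_diff > 0.85:
        flags.append("saturated")
    omega = dN / dS if dS and dS > 0 else float("nan")
    return DnDsEstimate(
        dN=dN, dS=dS, omega=omega, method="M0",
        kappa_hat=kappa_hat, t_hat=t_hat, lnL=-float(best.fun),
        flags=tuple(sorted(set(flags))),
    )
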