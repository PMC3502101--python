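"""Muse/Goldman-Yang-style 61-state codon substitution model.

Shared machinery for pairwise maximum-likelihood dN/dS estimation and for
simulating diverged ortholog pairs.  Instantaneous rates between sense
codons differing at a single nucleotide are

    q_ij  propto  pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-nucleotide changes and for changes into stop codons.  Q is
scaled so that one unit of time t corresponds to one expected substitution
per codon; the process is reversible with stationary distribution pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_code import GeneticCode, mutation_class, standard_code, TRANSITION


@dataclass(frozen=True)
class CodonModelStructure:
    """Precomputed sparsity structure of the 61-state model for one genetic code."""

    codons: tuple[str, ...]
    index: dict[str, int]
    pairs: np.ndarray        # (n_pairs, 2) int indices i, j with a single-nt difference
    is_transition: np.ndarray
    is_nonsynonymous: np.ndarray


_STRUCT_CACHE: dict[int, CodonModelStructure] = {}


def model_structure(code: GeneticCode | None = None) -> CodonModelStructure:
    code = code or standard_code()
    key = id(code)
    if key in _STRUCT_CACHE:
        return _STRUCT_CACHE[key]
    codons = code.sense_codons
    index = {c: i for i, c in enumerate(codons)}
    pairs, ts, nonsyn = [], [], []
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            pairs.append((i, j))
            ts.append(mutation_class(ci[p], cj[p]) == TRANSITION)
            nonsyn.append(code.translate(ci) != code.translate(cj))
    struct = CodonModelStructure(
        codons=codons,
        index=index,
        pairs=np.array(pairs, dtype=int),
        is_transition=np.array(ts, dtype=bool),
        is_nonsynonymous=np.array(nonsyn, dtype=bool),
    )
    _STRUCT_CACHE[key] = struct
    return struct


def f3x4_frequencies(codon_lists: list[tuple[str, ...]], code: GeneticCode | None = None) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from position-specific base composition."""
    struct = model_structure(code)
    pos_counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for codons in codon_lists:
        for c in codons:
            for p in range(3):
                pos_counts[p, base_idx[c[p]]] += 1
    pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [pos_freq[0, base_idx[c[0]]] * pos_freq[1, base_idx[c[1]]] * pos_freq[2, base_idx[c[2]]]
         for c in struct.codons]
    )
    return pi / pi.sum()


def f61_frequencies(
    codon_lists: list[tuple[str, ...]], code: GeneticCode | None = None, pseudocount: float = 0.5
) -> np.ndarray:
    """Empirical sense-codon frequencies with a small pseudocount."""
    struct = model_structure(code)
    counts = np.full(len(struct.codons), pseudocount)
    for codons in codon_lists:
        for c in codons:
            counts[struct.index[c]] += 1
    return counts / counts.sum()


def rate_matrix(
    pi: np.ndarray, kappa: float, omega: float, code: GeneticCode | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Build the (optionally rate-1-normalized) 61x61 generator Q."""
    struct = model_structure(code)
    n = len(struct.codons)
    Q = np.zeros((n, n))
    i, j = struct.pairs[:, 0], struct.pairs[:, 1]
    rates = pi[j] * np.where(struct.is_transition, kappa, 1.0)
    rates = rates * np.where(struct.is_nonsynonymous, omega, 1.0)
    Q[i, j] = rates
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    if normalize:
        mu = -float(pi @ np.diag(Q))
        if mu > 0:
            Q = Q / mu
    return Q


def transition_probabilities(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition (Q is pi-reversible)."""
    d = np.sqrt(pi)
    B = (Q * d[None, :]) / d[:, None]
    B = (B + B.T) / 2  # symmetrize away rounding noise
    w, V = np.linalg.eigh(B)
    P = (V * np.exp(w * t)) @ V.T
    P = P / d[None, :] * d[:, None]
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def flow_fractions(
    pi: np.ndarray, kappa: float, omega: float, code: GeneticCode | None = None
) -> tuple[float, float]:
    """(rho_S, rho_N): fractions of substitution flow that are synonymous/nonsynonymous."""
    struct = model_structure(code)
    i, j = struct.pairs[:, 0], struct.pairs[:, 1]
    rates = pi[i] * pi[j] * np.where(struct.is_transition, kappa, 1.0)
    rates = rates * np.where(struct.is_nonsynonymous, omega, 1.0)
    total = rates.sum()
    rho_n = float(rates[struct.is_nonsynonymous].sum() / total)
    return 1.0 - rho_n, rho_n


def pair_log_likelihood(
    counts: np.ndarray, pi: np.ndarray, t: float, kappa: float, omega: float,
    code: GeneticCode | None = None,
) -> float:
    """Log-likelihood of a 61x61 codon-pair count matrix under the model.

    L = sum_xy n_xy * log(pi_x * P_xy(t)); the ancestral state is integrated
    out by reversibility (stationary start).
    """
    Q = rate_matrix(pi, kappa, omega, code)
    P = transition_probabilities(Q, pi, t)
    like = pi[:, None] * P
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(np.maximum(like[mask], 1e-300))))
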