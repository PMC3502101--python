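"""Synonymous codon usage statistics: RSCU, Wright's ENC, GC3, and
correspondence analysis of the 59-dimensional RSCU space.

Only the 59 codons with a synonymous alternative enter the multivariate
analysis; ATG, TGG and the three stops carry no synonymous-choice
information.  Correspondence analysis decomposes the genes x codons RSCU
table under the chi-square metric into orthogonal axes ranked by their share
of the total inertia.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, standard_code
from .volatility import CodingSequence

logger = logging.getLogger(__name__)

ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product("ACGT", repeat=3))
_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}

DEFAULT_MIN_LENGTH_BP = 100
DEFAULT_AXIS_INERTIA_CUTOFF = 0.05


def count_codons(cds: CodingSequence) -> np.ndarray:
    """64-vector of codon counts in ALL_CODONS (alphabetical) order."""
    counts = np.zeros(64, dtype=int)
    for c in cds.codons:
        counts[_CODON_INDEX[c]] += 1
    return counts


def rscu(counts: np.ndarray, code: GeneticCode | None = None) -> pd.Series:
    """Relative synonymous codon usage over the 59 degenerate codons.

    RSCU_c = k * n_c / N_aa for codon c in a family of size k with total
    family count N_aa.  Families with zero total are returned as NaN
    (missing), distinct from a genuinely unused codon in a used family (0.0).
    """
    code = code or standard_code()
    out = {}
    for aa, codons in code.families().items():
        if len(codons) < 2:
            continue
        family_counts = np.array([counts[_CODON_INDEX[c]] for c in codons], dtype=float)
        total = family_counts.sum()
        k = len(codons)
        for c, n_c in zip(codons, family_counts):
            out[c] = k * n_c / total if total > 0 else np.nan
    return pd.Series(out).sort_index()


def gc3(cds: CodingSequence, code: GeneticCode | None = None) -> float:
    """Fraction of G or C at third positions of synonymously degenerate codons.

    ATG and TGG third positions carry no synonymous freedom and are excluded.
    NaN when the gene contains no degenerate codon.
    """
    code = code or standard_code()
    degenerate = set(code.degenerate_codons)
    thirds = [c[2] for c in cds.codons if c in degenerate]
    if not thirds:
        return float("nan")
    return sum(b in "GC" for b in thirds) / len(thirds)


def _degeneracy_classes(code: GeneticCode) -> dict[int, list[tuple[str, ...]]]:
    classes: dict[int, list[tuple[str, ...]]] = {}
    for aa, codons in code.families().items():
        if len(codons) > 1:
            classes.setdefault(len(codons), []).append(codons)
    return classes


def enc(counts: np.ndarray, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons (Nc), clipped to [20, 61].

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with class-mean homozygosities
    F = (n * sum(p_hat^2) - 1) / (n - 1).  Families with n <= 1 codon
    observations, or with F <= 0 (uninformative at small n), are excluded
    from their class mean.  A class with no estimable family is imputed from
    the family-count-weighted mean of the estimable classes' reciprocal
    homozygosities; NaN if no class is estimable at all.
    """
    code = code or standard_code()
    classes = _degeneracy_classes(code)
    class_F: dict[int, float] = {}
    for k, families in classes.items():
        fs = []
        for codons in families:
            fam = np.array([counts[_CODON_INDEX[c]] for c in codons], dtype=float)
            n = fam.sum()
            if n <= 1:
                continue
            p = fam / n
            f = (n * np.sum(p**2) - 1) / (n - 1)
            if f > 0:
                fs.append(f)
        if fs:
            class_F[k] = float(np.mean(fs))
    if not class_F:
        return float("nan")
    # family-count-weighted mean reciprocal over estimable classes
    weights = {k: len(classes[k]) for k in class_F}
    recip = sum(weights[k] / class_F[k] for k in class_F) / sum(weights.values())
    nc = 2.0
    for k in sorted(classes):
        n_fam = len(classes[k])
        f_k = class_F.get(k, 1.0 / recip)
        nc += n_fam / f_k
    return float(np.clip(nc, 20.0, 61.0))


@dataclass(frozen=True)
class CodonUsageProfile:
    gene_id: str
    counts: np.ndarray
    rscu: pd.Series
    enc: float
    gc3: float
    n_degenerate_codons: int


def codon_usage_profile(cds: CodingSequence, code: GeneticCode | None = None) -> CodonUsageProfile:
    code = code or standard_code()
    counts = count_codons(cds)
    degenerate = set(code.degenerate_codons)
    return CodonUsageProfile(
        gene_id=cds.gene_id,
        counts=counts,
        rscu=rscu(counts, code),
        enc=enc(counts, code),
        gc3=gc3(cds, code),
        n_degenerate_codons=sum(1 for c in cds.codons if c in degenerate),
    )


@dataclass
class CorrespondenceResult:
    """Row (gene) and column (codon) principal coordinates with inertia shares."""

    row_coordinates: pd.DataFrame
    column_coordinates: pd.DataFrame
    inertia_fraction: np.ndarray
    total_inertia: float


def correspondence_analysis(matrix: pd.DataFrame, tol: float = 1e-12) -> CorrespondenceResult:
    """Correspondence analysis of a nonnegative genes x codons table.

    The table is treated as a contingency-style array: with grand total N,
    correspondence matrix P = X/N, row masses r and column masses c, the
    standardized residuals S = (P - r c^T) / sqrt(r c^T) are decomposed by
    SVD.  Principal row coordinates are diag(1/sqrt(r)) U Sigma; total
    inertia is sum(sigma^2) = chi^2/N.  NaN cells (absent families) are
    treated as zero counts.  All-identical rows give zero inertia and zero
    retained axes.
    """
    if matrix.shape[0] < 3:
        raise ValueError("correspondence analysis needs >= 3 rows")
    X = matrix.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    if (X < 0).any():
        raise ValueError("negative cells in CA input")
    keep_cols = X.sum(axis=0) > 0
    keep_rows = X.sum(axis=1) > 0
    Xk = X[np.ix_(keep_rows, keep_cols)]
    total = Xk.sum()
    P = Xk / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv**2 > tol
    sv, U, Vt = sv[keep], U[:, keep], Vt[keep, :]
    # Deterministic axis orientation: the dominant column loading of each
    # axis is made positive, so signs are stable across inputs and runs.
    for k in range(len(sv)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total_inertia = float(np.sum(sv**2))
    frac = sv**2 / total_inertia if total_inertia > 0 else np.zeros(0)
    if total_inertia == 0:
        sv = sv[:0]
        U = U[:, :0]
        Vt = Vt[:0, :]
    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sv) / np.sqrt(c)[:, None]
    axes = [f"axis{i + 1}" for i in range(len(sv))]
    row_df = pd.DataFrame(
        np.full((matrix.shape[0], len(sv)), np.nan), index=matrix.index, columns=axes
    )
    row_df.iloc[np.flatnonzero(keep_rows)] = row_coords
    col_df = pd.DataFrame(
        np.full((matrix.shape[1], len(sv)), np.nan), index=matrix.columns, columns=axes
    )
    col_df.iloc[np.flatnonzero(keep_cols)] = col_coords
    return CorrespondenceResult(
        row_coordinates=row_df,
        column_coordinates=col_df,
        inertia_fraction=frac if total_inertia > 0 else np.zeros(len(sv)),
        total_inertia=total_inertia,
    )


def usage_axes(
    sequences: list[CodingSequence],
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
    axis_inertia_cutoff: float = DEFAULT_AXIS_INERTIA_CUTOFF,
    code: GeneticCode | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-gene usage table with Axis 1/2 coordinates, plus an inertia report.

    Genes shorter than ``min_length_bp`` nucleotides are excluded and listed.
    Returns (per-gene DataFrame indexed by gene_id with columns n_codons,
    enc, gc3, axis1, axis2; inertia DataFrame with per-axis fraction and a
    significance flag at the cutoff; excluded gene ids).
    """
    code = code or standard_code()
    kept, excluded = [], []
    for cds in sequences:
        if 3 * cds.n_codons >= min_length_bp:
            kept.append(cds)
        else:
            excluded.append(cds.gene_id)
    if excluded:
        logger.info("usage_axes: excluded %d genes shorter than %d bp", len(excluded), min_length_bp)
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} genes pass the {min_length_bp} bp filter; need >= 3")
    profiles = [codon_usage_profile(cds, code) for cds in kept]
    rscu_mat = pd.DataFrame([p.rscu for p in profiles], index=[p.gene_id for p in profiles])
    ca = correspondence_analysis(rscu_mat)
    n_axes = ca.row_coordinates.shape[1]
    per_gene = pd.DataFrame(
        {
            "n_codons": [c.n_codons for c in kept],
            "enc": [p.enc for p in profiles],
            "gc3": [p.gc3 for p in profiles],
            "axis1": ca.row_coordinates["axis1"] if n_axes >= 1 else np.nan,
            "axis2": ca.row_coordinates["axis2"] if n_axes >= 2 else np.nan,
        },
        index=pd.Index([p.gene_id for p in profiles], name="gene_id"),
    )
    inertia = pd.DataFrame(
        {
            "axis": [f"axis{i + 1}" for i in range(len(ca.inertia_fraction))],
            "inertia_fraction": ca.inertia_fraction,
        }
    )
    inertia["significant"] = inertia["inertia_fraction"] > axis_inertia_cutoff
    return per_gene, inertia, excluded
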