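"""Protein-guided codon alignment, NG86 counting and M0 likelihood fits."""

import itertools

import numpy as np
import pytest

import codonvol as cv
from codonvol import codon_model
from codonvol.pairwise import (
    CodonAlignment,
    GAP_CODON,
    align_proteins,
    alignment_coverage,
    backtranslate_alignment,
    m0_fit,
    ng86_dnds,
)
from codonvol.synthetic import OrthologSimSpec, evolve_pair, sample_stationary_cds
from codonvol.volatility import CodingSequence, validate_cds


# --- protein alignment -----------------------------------------------------

def test_identity_alignment_score(code):
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    pa = align_proteins("MKV", "MKV", mode="global")
    assert pa.seq1 == pa.seq2 == "MKV"
    assert pa.score == pytest.approx(sum(blosum[a, a] for a in "MKV"))


def brute_force_best_score(p1, p2, blosum, gap_open=11, gap_extend=1):
    """Enumerate all gapped alignments of length <= 6 for 3-residue inputs."""
    best = -np.inf
    n, m = len(p1), len(p2)

    def rec(i, j, cols):
        nonlocal best
        if i == n and j == m:
            score = 0.0
            run = None
            for a, b in cols:
                if a == "-" or b == "-":
                    side = 0 if a == "-" else 1
                    score -= gap_open if run != side else gap_extend
                    run = side
                else:
                    score += blosum[a, b]
                    run = None
            best = max(best, score)
            return
        if i < n and j < m:
            rec(i + 1, j + 1, cols + [(p1[i], p2[j])])
        if i < n:
            rec(i + 1, j, cols + [(p1[i], "-")])
        if j < m:
            rec(i, j + 1, cols + [("-", p2[j])])

    rec(0, 0, [])
    return best


def test_global_alignment_matches_bruteforce():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    pa = align_proteins("MKV", "MRV", mode="global")
    assert pa.score == pytest.approx(brute_force_best_score("MKV", "MRV", blosum))
    assert len(pa.seq1) == len(pa.seq2)


def test_local_alignment_extracts_block():
    pa = align_proteins("AAAMKVAAA", "MKV", mode="local")
    assert pa.seq1 == "MKV" and pa.seq2 == "MKV"
    assert pa.start1 == 3 and pa.start2 == 0


def test_empty_protein_error():
    with pytest.raises(ValueError):
        align_proteins("", "MKV")


# --- back-translation ------------------------------------------------------

def test_backtranslate_gapless():
    a = validate_cds("ATGAAAGTT", "a")
    b = validate_cds("ATGCGTGTT", "b")
    pa = align_proteins(a.protein(), b.protein(), mode="global")
    ca = backtranslate_alignment(pa, a, b)
    assert ca.codons1 == ("ATG", "AAA", "GTT")
    assert ca.codons2 == ("ATG", "CGT", "GTT")


def test_backtranslate_gap_becomes_codon_gap():
    a = validate_cds("ATGAAACGTGTT", "a")   # MKRV
    b = validate_cds("ATGAAAGTT", "b")      # MKV
    pa = align_proteins(a.protein(), b.protein(), mode="global")
    ca = backtranslate_alignment(pa, a, b)
    assert GAP_CODON in ca.codons2
    assert len(ca.codons1) == len(ca.codons2) == 4


def test_backtranslate_translation_mismatch_error():
    a = validate_cds("ATGAAAGTT", "a")
    b = validate_cds("ATGCGTGTT", "b")
    pa = align_proteins(a.protein(), b.protein(), mode="global")
    corrupted = CodingSequence("b", ("ATG", "GGT", "GTT"))  # R -> G at residue 2
    with pytest.raises(ValueError, match="residue 2"):
        backtranslate_alignment(pa, a, corrupted)


def test_alignment_coverage():
    ca = CodonAlignment(("ATG", "AAA", "GTT"), ("ATG", "AAA", "GTT"))
    assert alignment_coverage(ca, 3) == pytest.approx(100.0)
    assert alignment_coverage(ca, 6) == pytest.approx(50.0)


# --- NG86 ------------------------------------------------------------------

def hand_pathway_oracle(c1, c2, code):
    """Independent pathway averaging for a codon pair (stops excluded)."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    paths = []
    for order in itertools.permutations(diff):
        cur, steps, ok = c1, [], True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if code.codon_to_aa[nxt] == "*":
                ok = False
                break
            steps.append(code.codon_to_aa[nxt] == code.codon_to_aa[cur])
            cur = nxt
        if ok:
            paths.append(steps)
    sd = np.mean([sum(s) for s in paths])
    nd = np.mean([len(s) - sum(s) for s in paths])
    return sd, nd


def test_ng86_identical_sequences():
    ca = CodonAlignment(("TTT", "AAA"), ("TTT", "AAA"))
    est = ng86_dnds(ca)
    assert est.dN == 0.0 and est.dS == 0.0
    assert np.isnan(est.omega)


def test_ng86_single_synonymous_codon_saturates():
    """One Phe codon has only 1/3 synonymous site, so a synonymous difference
    saturates the Jukes-Cantor correction (pS = 3)."""
    est = ng86_dnds(CodonAlignment(("TTT",), ("TTC",)))
    assert est.dN == 0.0
    assert np.isnan(est.dS)
    assert "saturated_jc_undefined" in est.flags


def test_ng86_matches_hand_enumerated_pathways(code):
    """Two-codon toy with a double-substitution codon vs independent oracle."""
    from codonvol.pairwise import _ng86_site_count, _pathway_diffs

    c1, c2 = "TTT", "GTA"  # differs at positions 1 and 3
    sd, nd = hand_pathway_oracle(c1, c2, code)
    got_sd, got_nd, blocked = _pathway_diffs(c1, c2, code)
    assert not blocked
    assert got_sd == pytest.approx(sd, abs=1e-10)
    assert got_nd == pytest.approx(nd, abs=1e-10)
    # full estimate on the two-codon alignment against a hand recomputation
    ca = CodonAlignment(("TTT", "AAA"), ("GTA", "AAA"))
    S = (_ng86_site_count("TTT", code) + _ng86_site_count("AAA", code)
         + _ng86_site_count("GTA", code) + _ng86_site_count("AAA", code)) / 2
    N = 6 - S
    pS, pN = sd / S, nd / N
    est = ng86_dnds(ca)
    assert est.dS == pytest.approx(abs(-0.75 * np.log(1 - 4 * pS / 3)), abs=1e-10)
    assert est.dN == pytest.approx(abs(-0.75 * np.log(1 - 4 * pN / 3)), abs=1e-10)


def test_ng86_symmetric(small_genome):
    cds = small_genome.sequences[0]
    _, div = evolve_pair(cds, OrthologSimSpec(omega=0.4, t=0.4, seed=2))
    fwd = ng86_dnds(CodonAlignment(cds.codons, div.codons))
    rev = ng86_dnds(CodonAlignment(div.codons, cds.codons))
    assert fwd.dN == pytest.approx(rev.dN, abs=1e-12)
    assert fwd.dS == pytest.approx(rev.dS, abs=1e-12)


def test_ng86_gap_columns_dropped():
    core = (("AAA", "CGT", "TTT", "GGG", "CCC", "GAA"),
            ("AAG", "CGT", "TTT", "GGA", "CCC", "GAA"))
    padded = (core[0] + (GAP_CODON, "CCC"), core[1] + ("GGG", GAP_CODON))
    a = ng86_dnds(CodonAlignment(*core))
    b = ng86_dnds(CodonAlignment(*padded))
    assert a.dN == pytest.approx(b.dN) and a.dS == pytest.approx(b.dS)


# --- M0 fit ----------------------------------------------------------------

@pytest.fixture(scope="module")
def m0_sim():
    """Stationary ancestor + diverged copies at omega 0.3 and 1.0 (t=0.5, kappa=4.1)."""
    rng_codons = np.random.default_rng(17)
    struct = codon_model.model_structure()
    pi = codon_model.f3x4_frequencies([tuple(rng_codons.choice(struct.codons, 300))])
    anc = sample_stationary_cds(3000, pi, seed=18)
    pairs = {}
    for omega, seed in ((0.3, 19), (1.0, 20)):
        _, div = evolve_pair(anc, OrthologSimSpec(omega=omega, kappa=4.1, t=0.5, seed=seed))
        pairs[omega] = CodonAlignment(anc.codons, div.codons)
    return pairs


def test_m0_identical_sequences_t_zero(small_genome):
    cds = small_genome.sequences[1]
    est = m0_fit(CodonAlignment(cds.codons, cds.codons))
    assert est.t_hat <= 1e-4
    assert est.dS == pytest.approx(0.0, abs=1e-4)


def test_m0_recovers_omega(m0_sim):
    est = m0_fit(m0_sim[0.3])
    assert abs(est.omega - 0.3) <= 0.05
    assert abs(est.kappa_hat - 4.1) <= 0.5
    est_neutral = m0_fit(m0_sim[1.0])
    assert abs(est_neutral.omega - 1.0) <= 0.1


def test_m0_lnl_at_optimum_beats_truth(m0_sim):
    """Fitted lnL >= lnL evaluated at the simulation parameters."""
    from codonvol.pairwise import _pair_counts

    ca = m0_sim[0.3]
    est = m0_fit(ca)
    counts = _pair_counts(ca, cv.standard_code())
    pi = codon_model.f3x4_frequencies([tuple(a for a, _ in ca.ungapped_pairs()),
                                       tuple(b for _, b in ca.ungapped_pairs())])
    lnl_true = codon_model.pair_log_likelihood(counts, pi, 0.5, 4.1, 0.3)
    assert est.lnL >= lnl_true - 1e-6


def test_estimators_rank_omega_consistently(m0_sim):
    """NG86 and M0 both order omega = 0.3 below omega = 1.0."""
    ng = {w: ng86_dnds(ca).omega for w, ca in m0_sim.items()}
    ml = {w: m0_fit(ca).omega for w, ca in m0_sim.items()}
    assert ng[0.3] < ng[1.0]
    assert ml[0.3] < ml[1.0]
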