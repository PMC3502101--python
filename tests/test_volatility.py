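"""Gene-level volatility, the synonymous re-encoding null, and the genome scan."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import codonvol as cv
from codonvol.genetic_code import MutationModel
from codonvol.volatility import (
    CodingSequence,
    GenomeCodonFrequencies,
    RejectionRecord,
    gene_volatility,
    genome_scan,
    null_moments,
    sample_null_vsums,
    validate_cds,
    volatility_pvalue,
)


# --- validation ------------------------------------------------------------

@pytest.mark.parametrize(
    "raw,expected_codons",
    [("ATGAAATGA", ("ATG", "AAA")),   # trailing stop stripped
     ("atg aaa\nTGA", ("ATG", "AAA")),  # whitespace/case tolerant
     ("ATGAAA", ("ATG", "AAA"))],
)
def test_validate_accepts(raw, expected_codons):
    out = validate_cds(raw, "g")
    assert isinstance(out, CodingSequence)
    assert out.codons == expected_codons


@pytest.mark.parametrize(
    "raw,reason",
    [("ATGTGAAAA", "internal_stop"),
     ("ATGAA", "length_not_multiple_of_3"),
     ("ATGANA", "ambiguous_base"),
     ("", "empty_sequence"),
     ("TGA", "empty_sequence")],
)
def test_validate_rejects(raw, reason):
    out = validate_cds(raw, "g")
    assert isinstance(out, RejectionRecord)
    assert out.reason == reason


@given(st.lists(st.sampled_from(sorted(cv.standard_code().sense_codons)), min_size=1, max_size=40))
def test_validate_roundtrip_on_sense_codons(codons):
    """Any concatenation of sense codons validates to exactly those codons."""
    out = validate_cds("".join(codons), "g")
    assert isinstance(out, CodingSequence)
    assert list(out.codons) == codons


# --- gene volatility -------------------------------------------------------

def test_gene_volatility_examples(code):
    m1 = MutationModel(1.0)
    cds = CodingSequence("g", ("ATG", "TGG"))
    assert gene_volatility(cds, m1, code) == (pytest.approx(2.0), pytest.approx(1.0))
    cds = CodingSequence("g", ("AGA", "AGA"))
    assert gene_volatility(cds, m1, code)[0] == pytest.approx(1.5)
    cds = CodingSequence("g", ("AGA",))
    assert gene_volatility(cds, MutationModel(4.1), code)[0] == pytest.approx(12.2 / 17.3)


# --- null moments ----------------------------------------------------------

def test_null_moments_no_synonymous_freedom(code, genome_freqs):
    m = MutationModel(4.1)
    mean, var = null_moments("MW", genome_freqs, m, code)
    assert var == 0.0
    assert mean == pytest.approx(gene_volatility(CodingSequence("g", ("ATG", "TGG")), m, code)[0])


def test_null_moments_uniform_arg(code):
    """Site mean under uniform frequencies equals the mean over the 6 Arg codons."""
    fams = code.families()
    uniform = GenomeCodonFrequencies({
        aa: (codons, np.full(len(codons), 1 / len(codons))) for aa, codons in fams.items()
    })
    m = MutationModel(1.0)
    mean, var = null_moments("R", uniform, m, code)
    vols = [cv.codon_volatility(c, code, m) for c in fams["R"]]
    assert mean == pytest.approx(np.mean(vols))
    assert var == pytest.approx(np.var(vols))


def test_null_moments_match_monte_carlo(code, genome_freqs):
    """Exact site-wise moments agree with 1e5 Monte-Carlo re-encodings."""
    m = MutationModel(4.1)
    protein = "MARWLSKGIRPFVQDNHTEYC" * 3
    mean, var = null_moments(protein, genome_freqs, m, code)
    rng = np.random.default_rng(7)
    samples = sample_null_vsums(protein, genome_freqs, m, 100_000, rng, code)
    se_mean = samples.std(ddof=1) / np.sqrt(len(samples))
    assert abs(samples.mean() - mean) < 3 * se_mean
    # variance of the sample variance ~ 2 var^2 / (n-1) for near-normal sums
    se_var = var * np.sqrt(2 / (len(samples) - 1))
    assert abs(samples.var(ddof=1) - var) < 5 * se_var


def test_null_moments_unknown_residue(code, genome_freqs):
    with pytest.raises(KeyError, match="B"):
        null_moments("MB", genome_freqs, MutationModel(1.0), code)


# --- P-values --------------------------------------------------------------

def test_degenerate_null_pvalue_is_one(code, genome_freqs):
    cds = CodingSequence("g", ("ATG", "TGG", "ATG"))
    for method in ("exact_normal", "monte_carlo"):
        res = volatility_pvalue(cds, genome_freqs, MutationModel(4.1), method=method,
                                n_samples=1000, seed=0, code=code)
        assert res.p_value == pytest.approx(1.0, abs=1e-3)


def test_max_volatile_recoding_has_min_p(code, genome_freqs):
    """Re-encoding every site with its most volatile synonym minimizes P."""
    m = MutationModel(4.1)
    rng = np.random.default_rng(3)
    protein = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=120))
    fams = code.families()
    vol = {c: cv.codon_volatility(c, code, m) for c in code.sense_codons}
    best = tuple(max(fams[aa], key=lambda c: vol[c]) for aa in protein)
    typical = tuple(fams[aa][0] for aa in protein)
    p_best = volatility_pvalue(CodingSequence("b", best), genome_freqs, m, code=code).p_value
    p_typ = volatility_pvalue(CodingSequence("t", typical), genome_freqs, m, code=code).p_value
    assert p_best < p_typ


def test_monte_carlo_agrees_with_exact_normal(code, genome_freqs):
    """|P_mc - P_normal| <= 0.01 for mid-range P at 300 codons."""
    m = MutationModel(4.1)
    rng = np.random.default_rng(11)
    checked = 0
    for seed in range(8):
        aas = rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=300)
        codons = []
        for aa in aas:
            fam, probs = genome_freqs.family(aa)
            codons.append(fam[rng.choice(len(fam), p=probs)])
        cds = CodingSequence(f"g{seed}", tuple(codons))
        p_exact = volatility_pvalue(cds, genome_freqs, m, code=code).p_value
        if not 0.05 < p_exact < 0.95:
            continue
        p_mc = volatility_pvalue(cds, genome_freqs, m, method="monte_carlo",
                                 n_samples=100_000, seed=seed, code=code).p_value
        assert abs(p_mc - p_exact) <= 0.01
        checked += 1
    assert checked >= 3


def test_pvalue_invariant_under_codon_permutation(code, genome_freqs):
    m = MutationModel(4.1)
    rng = np.random.default_rng(5)
    cds = CodingSequence("g", tuple(rng.choice(sorted(code.sense_codons), size=90)))
    shuffled = list(cds.codons)
    rng.shuffle(shuffled)
    p1 = volatility_pvalue(cds, genome_freqs, m, code=code).p_value
    p2 = volatility_pvalue(CodingSequence("g", tuple(shuffled)), genome_freqs, m,
                           code=code).p_value
    assert p1 == pytest.approx(p2, abs=1e-12)


# --- genome scan -----------------------------------------------------------

def test_scan_flags_forced_max_volatile_gene(code, small_genome):
    """With one shared protein, the maximally volatile encoding has the smallest P."""
    m = MutationModel(4.1)
    fams = code.families()
    vol = {c: cv.codon_volatility(c, code, m) for c in code.sense_codons}
    protein = "RLSGIKEDA" * 20
    rng = np.random.default_rng(9)
    genes = []
    for k in range(30):
        codons = tuple(fams[aa][rng.choice(len(fams[aa]))] for aa in protein)
        genes.append(CodingSequence(f"g{k}", codons))
    forced = CodingSequence("forced", tuple(max(fams[aa], key=lambda c: vol[c])
                                            for aa in protein))
    df = genome_scan(genes + [forced], model=m, seed=0)
    assert df.loc[df["p_value"].idxmin(), "gene_id"] == "forced"


def test_scan_deterministic(small_genome):
    df1 = genome_scan(small_genome.sequences[:50], seed=4, method="monte_carlo",
                      n_samples=2000)
    df2 = genome_scan(small_genome.sequences[:50], seed=4, method="monte_carlo",
                      n_samples=2000)
    assert df1.equals(df2)


def test_scan_empty_input_error():
    with pytest.raises(ValueError):
        genome_scan([])


def test_null_pvalues_uniform_small(code, genome_freqs):
    """P-values of genes drawn from the null itself look uniform (KS at alpha 1%)."""
    m = MutationModel(4.1)
    rng = np.random.default_rng(13)
    pvals = []
    for k in range(150):
        aas = rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=150)
        codons = []
        for aa in aas:
            fam, probs = genome_freqs.family(aa)
            codons.append(fam[rng.choice(len(fam), p=probs)])
        cds = CodingSequence(f"n{k}", tuple(codons))
        pvals.append(volatility_pvalue(cds, genome_freqs, m, code=code).p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
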