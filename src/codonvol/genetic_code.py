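"""Genetic code tables, point-mutation neighborhoods and per-codon volatility.

The volatility of a sense codon is the probability that a random point
mutation changes the encoded amino acid, restricted to mutations that do not
create a stop codon.  Mutations are optionally weighted by the
transition:transversion ratio kappa.  Everything else in the package is built
on the three primitives defined here: neighbor enumeration, mutation-class
assignment, and the weighted volatility quotient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple

from Bio.Data import CodonTable

BASES = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

TRANSITION = "transition"
TRANSVERSION = "transversion"

STOP = "*"


class CodonError(ValueError):
    """Raised for malformed codons, stop codons where sense codons are required."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map over the 64 DNA codons.

    ``codon_to_aa`` maps every 3-mer over ACGT to a one-letter amino-acid
    symbol, with ``"*"`` marking stop codons.  The standard nuclear code
    (NCBI translation table 1) is the only table shipped; the class is a
    plain value so tests can inject toy codes.
    """

    codon_to_aa: dict[str, str]
    name: str = "standard"

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must map all 64 codons, got {len(self.codon_to_aa)}")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP))

    @property
    def degenerate_codons(self) -> tuple[str, ...]:
        """Sense codons with at least one synonymous alternative (59 in the standard code)."""
        fams = self.families()
        return tuple(sorted(c for aa, cods in fams.items() for c in cods if len(cods) > 1))

    def families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> sorted tuple of its codons (stops excluded)."""
        out: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            if aa != STOP:
                out.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(v)) for aa, v in out.items()}

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(codon_to_aa=mapping, name="standard")


@dataclass(frozen=True)
class MutationModel:
    """Transition:transversion weighting of point mutations.

    ``kappa`` multiplies transition mutations; transversions carry weight 1.
    ``kappa = 1`` recovers unweighted neighbor counting; the genome-scan
    default elsewhere in the package is 4.1.
    """

    kappa: float = 1.0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")

    def weight(self, base_from: str, base_to: str) -> float:
        return self.kappa if mutation_class(base_from, base_to) == TRANSITION else 1.0


class Neighbor(NamedTuple):
    codon: str
    position: int  # 1-based position of the substituted base
    mutation: str  # TRANSITION or TRANSVERSION
    synonymous: bool


def _check_codon(codon: str, code: GeneticCode) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise CodonError(f"malformed codon {codon!r}: expected 3 letters over ACGT")
    if code.is_stop(codon):
        raise CodonError(f"stop codon {codon!r} has no defined volatility")


def mutation_class(base_from: str, base_to: str) -> str:
    """Classify a base substitution as transition or transversion."""
    for b in (base_from, base_to):
        if b not in BASES:
            raise CodonError(f"invalid nucleotide {b!r}")
    if base_from == base_to:
        raise CodonError(f"identical bases {base_from!r}: not a mutation")
    same_class = ({base_from, base_to} <= _PURINES) or ({base_from, base_to} <= _PYRIMIDINES)
    return TRANSITION if same_class else TRANSVERSION


def point_mutation_neighbors(codon: str, code: GeneticCode | None = None) -> list[Neighbor]:
    """All single-point-mutation neighbors of a sense codon, stops excluded.

    Returns at most 9 entries (3 positions x 3 alternative bases), each
    differing from ``codon`` at exactly one position and never encoding a
    stop.  AGA, for example, has 8: TGA is removed as a stop.
    """
    code = code or standard_code()
    _check_codon(codon, code)
    aa = code.translate(codon)
    out: list[Neighbor] = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(neighbor):
                continue
            out.append(
                Neighbor(
                    codon=neighbor,
                    position=pos + 1,
                    mutation=mutation_class(codon[pos], base),
                    synonymous=code.translate(neighbor) == aa,
                )
            )
    return out


def codon_volatility(
    codon: str, code: GeneticCode | None = None, model: MutationModel | None = None
) -> float:
    """Weighted fraction of non-stop point-mutation neighbors that are nonsynonymous.

    With the default unweighted model this is the classic quotient — for AGA,
    6 of its 8 non-stop neighbors change the amino acid, so the volatility is
    6/8 = 0.75.  With kappa != 1 each neighbor contributes kappa (transition)
    or 1 (transversion) to both sums.
    """
    code = code or standard_code()
    model = model or MutationModel(1.0)
    neighbors = point_mutation_neighbors(codon, code)
    # Every sense codon in the standard code has at least one non-stop neighbor.
    assert neighbors, f"codon {codon!r} has no non-stop neighbors"
    total = 0.0
    nonsyn = 0.0
    for nb in neighbors:
        w = model.kappa if nb.mutation == TRANSITION else 1.0
        total += w
        if not nb.synonymous:
            nonsyn += w
    return nonsyn / total
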