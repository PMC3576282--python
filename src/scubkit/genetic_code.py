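"""The 59-codon synonymous-codon universe.

Synonymous codon usage statistics are computed over the 59 codons of the
standard nuclear genetic code that belong to an amino acid with at least two
codons and are neither a start nor a stop signal: the three stop codons
(TAA, TGA, TAG) and the two single-codon amino acids Met (ATG) and Trp (TGG)
are excluded, leaving 18 amino acids with synonymous codons (SCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

NUCLEOTIDES = ("A", "C", "G", "T")

#: Codons never counted as synonymous codons: stops plus the two
#: single-codon amino acids.
EXCLUDED_CODONS = frozenset({"TAA", "TGA", "TAG", "ATG", "TGG"})

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TGA", "TAG"})

#: Third-position class labels in the conventional reporting order.
THIRD_CLASSES = ("NNA", "NNT", "NNC", "NNG")


@dataclass(frozen=True)
class GeneticCode:
    """Standard nuclear genetic code restricted to the synonymous-codon set.

    Attributes
    ----------
    codon_to_aa
        Every one of the 64 DNA triplets mapped to its one-letter amino-acid
        symbol, or ``*`` for a stop codon.
    sc_set
        The 59 synonymous codons, lexicographically ordered (bit-stable
        output ordering).
    aa_groups
        Amino acid -> tuple of its synonymous codons (18 groups, each of
        size >= 2, lexicographic within group).
    third_class
        Synonymous codon -> third-position class (``NNA``/``NNT``/``NNC``/
        ``NNG``).
    """

    codon_to_aa: dict[str, str]
    sc_set: tuple[str, ...]
    aa_groups: dict[str, tuple[str, ...]]
    third_class: dict[str, str]
    sc_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sc_index", {c: i for i, c in enumerate(self.sc_set)}
        )

    def is_sc(self, codon: str) -> bool:
        return codon in self.sc_index

    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def build_genetic_code() -> GeneticCode:
    """Construct the 59-codon / 18-amino-acid synonymous-codon universe.

    Uses NCBI translation table 1 (standard nuclear code). Deterministic:
    ``sc_set`` is lexicographic, group members lexicographic within group.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = "*"

    sc_set = tuple(
        sorted(c for c in codon_to_aa if c not in EXCLUDED_CODONS)
    )

    aa_groups: dict[str, list[str]] = {}
    for codon in sc_set:
        aa_groups.setdefault(codon_to_aa[codon], []).append(codon)
    groups = {aa: tuple(sorted(cs)) for aa, cs in sorted(aa_groups.items())}

    third_class = {c: "NN" + c[2] for c in sc_set}

    return GeneticCode(
        codon_to_aa=codon_to_aa,
        sc_set=sc_set,
        aa_groups=groups,
        third_class=third_class,
    )


def codon_table_tsv(code: GeneticCode) -> str:
    """Render the SC universe as a TSV (codon, amino acid, third class)."""
    lines = ["codon\taa\tthird_class"]
    for codon in code.sc_set:
        lines.append(f"{codon}\t{code.codon_to_aa[codon]}\t{code.third_class[codon]}")
    return "\n".join(lines) + "\n"
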