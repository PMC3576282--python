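"""Binning genes and codons into intron-number and exon-position strata.

Two stratification schemes are supported: genes grouped by intron count
(0-9; genes with 10 or more introns are excluded and tallied) and codon
records of multi-exon genes grouped by (exon_total, exon_index) for genes
with 2-10 exons.  Within a stratum, codon counts are pooled across genes by
default before frequencies are computed; a per-gene-mean mode is available
in :mod:`scubkit.scub_stats` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codon_extraction import CodonRecord, GeneModel

MAX_INTRON_BIN = 9
MIN_EXON_TOTAL = 2
MAX_EXON_TOTAL = 10

POSITION_CLASSES = ("first", "interstitial", "last")


@dataclass(frozen=True)
class StratumKey:
    scheme: str  # "by_intron" | "by_exon_position"
    intron_bin: int | None = None
    exon_total: int | None = None
    exon_index: int | None = None

    def __post_init__(self) -> None:
        if self.scheme == "by_intron":
            if self.intron_bin is None or not 0 <= self.intron_bin <= MAX_INTRON_BIN:
                raise ValueError(f"intron_bin must be 0..{MAX_INTRON_BIN}")
        elif self.scheme == "by_exon_position":
            if self.exon_total is None or self.exon_index is None:
                raise ValueError("exon_total and exon_index required")
            if not MIN_EXON_TOTAL <= self.exon_total <= MAX_EXON_TOTAL:
                raise ValueError(
                    f"exon_total must be {MIN_EXON_TOTAL}..{MAX_EXON_TOTAL}"
                )
            if not 0 <= self.exon_index < self.exon_total:
                raise ValueError("exon_index must be < exon_total")
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")


def stratify_by_intron(
    models: list[GeneModel],
) -> tuple[dict[int, list[GeneModel]], int]:
    """Group genes by intron count 0-9; return (bins, n_excluded)."""
    bins: dict[int, list[GeneModel]] = {k: [] for k in range(MAX_INTRON_BIN + 1)}
    excluded = 0
    for m in models:
        if m.intron_count <= MAX_INTRON_BIN:
            bins[m.intron_count].append(m)
        else:
            excluded += 1
    return bins, excluded


def stratify_by_exon_position(
    models_with_records: list[tuple[GeneModel, list[CodonRecord]]],
) -> tuple[dict[tuple[int, int], list[CodonRecord]], int]:
    """Key codon records of 2-10-exon genes by (exon_total, owner_exon).

    Single-exon genes and genes with more than 10 exons are excluded and
    counted.  Every record of a retained gene lands in exactly one cell.
    """
    cells: dict[tuple[int, int], list[CodonRecord]] = {}
    excluded = 0
    for model, records in models_with_records:
        total = model.exon_count
        if not MIN_EXON_TOTAL <= total <= MAX_EXON_TOTAL:
            excluded += 1
            continue
        for r in records:
            cells.setdefault((total, r.owner_exon), []).append(r)
    return cells, excluded


def position_class(exon_total: int, exon_index: int) -> str:
    """Classify an exon as first / interstitial / last."""
    if exon_total < 2:
        raise ValueError("position_class requires exon_total >= 2")
    if not 0 <= exon_index < exon_total:
        raise ValueError("exon_index out of range")
    if exon_index == 0:
        return "first"
    if exon_index == exon_total - 1:
        return "last"
    return "interstitial"


def stratum_manifest(
    intron_bins: dict[int, list[GeneModel]] | None = None,
    exon_cells: dict[tuple[int, int], list[CodonRecord]] | None = None,
) -> str:
    """Render a TSV manifest (scheme, key, n_genes, n_codons) of strata."""
    lines = ["scheme\tkey\tn_genes\tn_codons"]
    if intron_bins is not None:
        for k in sorted(intron_bins):
            genes = intron_bins[k]
            n_codons = sum(m.n_codons for m in genes)
            lines.append(f"by_intron\t{k}\t{len(genes)}\t{n_codons}")
    if exon_cells is not None:
        for total, idx in sorted(exon_cells):
            recs = exon_cells[(total, idx)]
            lines.append(f"by_exon_position\t{total}:{idx}\t.\t{len(recs)}")
    return "\n".join(lines) + "\n"
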