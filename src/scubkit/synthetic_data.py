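"""Synthetic genomes with planted codon-usage structure.

The generator emits FASTA + GFF3 (plus a machine-readable truth table) for
multi-exon protein-coding genes whose third-position codon composition is
under explicit control, so that every pipeline stage can be validated against
known ground truth:

* a third-position class distribution (NNA/NNT/NNC/NNG probabilities) that
  is a configurable function of a gene's intron count — a linear gradient by
  default, emulating the monotone intron-number trends seen in real genomes;
* an optional exon-position effect that shifts third-position mass between
  A/T and C/G in interstitial exons only, planting cap- or cup-shaped
  exon profiles;
* an optional CpG-depletion process acting on codon junctions: a codon whose
  third nucleotide is C followed by a codon starting with G keeps its C only
  with an internally derived probability, and is otherwise synonymously
  converted to the T-ending codon of the same codon box (the deamination
  analogue, C->T).  The depletion factor ``d`` is defined so that after the
  process the junction (C,G) cell equals ``d`` times the product of the
  junction marginals.

Amino-acid content is drawn i.i.d. (uniform over the 18 SC amino acids by
default): amino-acid identity is irrelevant to every downstream statistic
except grouping, and uniform usage maximizes per-group counts at small n.
Codon boundaries are cut at arbitrary nucleotide offsets within the CDS, so
phase-1 and phase-2 split codons arise naturally; introns are neutral filler
with canonical GT...AG ends.  Half of the genes are placed on the minus
strand to exercise strand handling.  Generation is reproducible: the same
seed yields byte-identical FASTA/GFF3/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_extraction import owner_exons, reverse_complement
from .genetic_code import THIRD_CLASSES, build_genetic_code

_CODE = build_genetic_code()

#: Third-position nucleotide order used for class-probability vectors,
#: matching the NNA/NNT/NNC/NNG reporting order.
CLASS_NT = ("A", "T", "C", "G")

_AAS = tuple(sorted(_CODE.aa_groups))  # 18 amino acids
_AA_INDEX = {aa: i for i, aa in enumerate(_AAS)}

_STOPS = ("TAA", "TAG", "TGA")

# Lookup tables for vectorized codon sampling -------------------------------

_N_AA = len(_AAS)
_AVAIL = np.zeros((_N_AA, 4), dtype=bool)  # aa x class availability
_CLASS_COUNTS = np.zeros((_N_AA, 4), dtype=np.int64)
_CLASS_CODONS = np.full((_N_AA, 4, 4), -1, dtype=np.int64)  # codon ids in sc_set
for _aa, _codons in _CODE.aa_groups.items():
    _i = _AA_INDEX[_aa]
    for _c in _codons:
        _j = CLASS_NT.index(_c[2])
        _AVAIL[_i, _j] = True
        _CLASS_CODONS[_i, _j, _CLASS_COUNTS[_i, _j]] = _CODE.sc_index[_c]
        _CLASS_COUNTS[_i, _j] += 1

_SC_ARRAY = np.array(_CODE.sc_set)
#: codon id -> id of the same-box codon with third position T (C->T
#: deamination target); identity where the third position is not C.
_C_TO_T = np.arange(len(_CODE.sc_set))
for _c in _CODE.sc_set:
    if _c[2] == "C":
        _C_TO_T[_CODE.sc_index[_c]] = _CODE.sc_index[_c[:2] + "T"]
_THIRD_IS_C = np.array([c[2] == "C" for c in _CODE.sc_set])
_FIRST_IS_G = np.array([c[0] == "G" for c in _CODE.sc_set])

#: Amino acids whose codons all begin with G (the only G-initial codons).
_G_FIRST_AAS = frozenset("ADEGV")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome.

    ``n_genes`` maps intron count -> number of genes.  The third-position
    class probabilities of a gene with ``k`` introns are
    ``base + slope_sign * k * third_class_slope`` where mass moves from C and
    G to A and T as ``k`` grows (``third_class_slope`` > 0 plants the
    land-plant-like trend; 0 plants none).  ``exon_effect`` shifts
    ``exon_effect_size`` of probability mass from C/G to A/T (cap) or the
    reverse (cup) in interstitial exons of multi-exon genes.
    ``cpg_depletion`` is the junction CpG depletion factor d in [0, 1]
    (1 = no depletion).
    """

    n_genes: dict[int, int] = field(
        default_factory=lambda: {k: 20 for k in range(10)}
    )
    codons_per_exon: float = 30.0
    min_codons_per_exon: int = 5
    min_exon_nt: int = 9
    third_class_base: tuple[float, float, float, float] = (0.20, 0.20, 0.30, 0.30)
    third_class_slope: float = 0.02
    exon_effect: str = "none"  # none | cap | cup
    exon_effect_size: float = 0.10
    cpg_depletion: float = 1.0
    aa_probs: dict[str, float] | None = None
    intron_min_len: int = 20
    intron_mean_len: float = 40.0
    genes_per_contig: int = 25
    intergenic_len: int = 30

    def __post_init__(self) -> None:
        if self.exon_effect not in {"none", "cap", "cup"}:
            raise ValueError("exon_effect must be none, cap or cup")
        if not 0.0 <= self.cpg_depletion <= 1.0:
            raise ValueError("cpg_depletion must be in [0, 1]")
        if abs(sum(self.third_class_base) - 1.0) > 1e-9:
            raise ValueError("third_class_base must sum to 1")
        if self.min_codons_per_exon * 3 < self.min_exon_nt:
            raise ValueError(
                "min_codons_per_exon * 3 must be >= min_exon_nt "
                "(exon cut points could not respect the minimum exon length)"
            )
        for k in self.n_genes:
            probs = self.class_probs(k)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(
                    f"class probabilities out of [0,1] at intron count {k}"
                )
            for cell in ("first", "interstitial"):
                adj = self.cell_probs(k, 1 if cell == "interstitial" else 0, 3)
                if np.any(adj < 0) or np.any(adj > 1):
                    raise ValueError(
                        f"exon effect drives class probabilities out of [0,1] "
                        f"at intron count {k}"
                    )

    # -- planted probability structure --------------------------------------

    def aa_weights(self) -> np.ndarray:
        if self.aa_probs is None:
            return np.full(_N_AA, 1.0 / _N_AA)
        w = np.array([self.aa_probs.get(aa, 0.0) for aa in _AAS], dtype=float)
        if w.sum() <= 0:
            raise ValueError("aa_probs assigns no mass to any SC amino acid")
        return w / w.sum()

    def class_probs(self, intron_count: int) -> np.ndarray:
        """Gene-level third-position class probabilities, order (A,T,C,G)."""
        base = np.array(self.third_class_base, dtype=float)
        shift = self.third_class_slope * intron_count
        return base + np.array([shift, shift, -shift, -shift])

    def cell_probs(self, intron_count: int, exon_index: int, exon_total: int) -> np.ndarray:
        """Class probabilities for codons owned by one exon cell."""
        probs = self.class_probs(intron_count)
        interstitial = exon_total >= 3 and 0 < exon_index < exon_total - 1
        if self.exon_effect == "none" or not interstitial:
            return probs
        e = self.exon_effect_size / 2.0
        delta = np.array([e, e, -e, -e])
        return probs + (delta if self.exon_effect == "cap" else -delta)

    def p_first_g(self) -> float:
        """P(a body codon starts with G) — fixed by amino-acid composition.

        Only Ala, Asp, Glu, Gly and Val have G-initial codons, and all of
        their codons are G-initial, so this is simply their total weight.
        """
        w = self.aa_weights()
        return float(sum(w[_AA_INDEX[aa]] for aa in _G_FIRST_AAS))

    def cpg_keep_prob(self) -> float:
        """Internal keep-probability for C|G junctions implementing ``d``.

        Solving cell(C,G) = d * m3(C) * m1(G) for the post-process junction
        marginals gives keep = d (1 - pG) / (1 - d pG) with pG = P(first=G).
        """
        d = self.cpg_depletion
        pg = self.p_first_g()
        return d * (1.0 - pg) / (1.0 - d * pg)

    def expected_third_class_freq(self, intron_count: int) -> pd.Series:
        """Expected pooled NNA/NNT/NNC/NNG frequencies for one intron bin.

        Accounts for per-amino-acid renormalization over the classes each
        amino acid actually possesses, and for the C->T conversions of the
        junction CpG-depletion process.
        """
        probs = self.class_probs(intron_count)
        w = self.aa_weights()
        agg = np.zeros(4)
        for i in range(_N_AA):
            p = np.where(_AVAIL[i], probs, 0.0)
            agg += w[i] * p / p.sum()
        # CpG sweep converts a C-ending codon to T-ending with probability
        # (1 - keep) * P(next codon starts G).
        conv = (1.0 - self.cpg_keep_prob()) * self.p_first_g()
        moved = agg[2] * conv
        agg[2] -= moved
        agg[1] += moved
        return pd.Series(agg, index=list(THIRD_CLASSES))


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    gff_lines: list[str]
    truth: pd.DataFrame

    def gff_text(self) -> str:
        return "##gff-version 3\n" + "\n".join(self.gff_lines) + "\n"

    def fasta_text(self) -> str:
        out = []
        for name in self.contigs:
            out.append(f">{name}")
            seq = self.contigs[name]
            out.extend(seq[i : i + 80] for i in range(0, len(seq), 80))
        return "\n".join(out) + "\n"


def sample_codon(aa: str, class_probs, rng: np.random.Generator) -> str:
    """Draw one synonymous codon for ``aa`` given third-position class probs.

    ``class_probs`` is (pA, pT, pC, pG).  Classes the amino acid lacks get
    zero mass (renormalized over the rest); the codon is then uniform within
    the chosen (amino acid, class) cell.
    """
    i = _AA_INDEX[aa]
    p = np.where(_AVAIL[i], np.asarray(class_probs, dtype=float), 0.0)
    total = p.sum()
    if total <= 0:
        # All requested mass sits on classes this amino acid lacks:
        # degrade to uniform over the classes it does have.
        p = _AVAIL[i].astype(float)
        total = p.sum()
    cls = rng.choice(4, p=p / total)
    j = rng.integers(_CLASS_COUNTS[i, cls])
    return str(_SC_ARRAY[_CLASS_CODONS[i, cls, j]])


def _sample_codon_ids(
    aa_idx: np.ndarray, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized codon draw: class by planted probs, codon uniform in cell."""
    p = np.where(_AVAIL[aa_idx], probs, 0.0)
    p = p / p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(aa_idx))
    cls = (cum < u[:, None]).sum(axis=1)
    counts = _CLASS_COUNTS[aa_idx, cls]
    j = (rng.random(len(aa_idx)) * counts).astype(np.int64)
    return _CLASS_CODONS[aa_idx, cls, j]


def _apply_cpg_sweep(
    codon_ids: np.ndarray, keep_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Deplete C|G codon junctions by synonymous C->T third-position swaps."""
    if keep_prob >= 1.0 or len(codon_ids) < 2:
        return codon_ids
    cg = _THIRD_IS_C[codon_ids[:-1]] & _FIRST_IS_G[codon_ids[1:]]
    n_cg = int(cg.sum())
    if n_cg == 0:
        return codon_ids
    convert = rng.random(n_cg) >= keep_prob
    idx = np.flatnonzero(cg)[convert]
    out = codon_ids.copy()
    out[idx] = _C_TO_T[out[idx]]
    return out


def _make_gene_cds(
    spec: SyntheticSpec, intron_count: int, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """One CDS (start..stop) and its exon nucleotide lengths."""
    n_exons = intron_count + 1
    body_per_exon = np.maximum(
        rng.poisson(spec.codons_per_exon, n_exons), spec.min_codons_per_exon
    )
    n_codons = int(body_per_exon.sum()) + 2  # start + stop
    total_nt = 3 * n_codons

    # Exon cut points at arbitrary nucleotide offsets: minimum length per
    # exon plus a multinomial split of the remainder, so split-codon phases
    # 1 and 2 occur as often as phase 0.
    extra = total_nt - n_exons * spec.min_exon_nt
    lengths = spec.min_exon_nt + rng.multinomial(extra, np.full(n_exons, 1.0 / n_exons))
    exon_lengths = tuple(int(x) for x in lengths)

    owners = owner_exons(exon_lengths)  # per codon, incl. start and stop
    n_body = n_codons - 2
    aa_idx = rng.choice(_N_AA, size=n_body, p=spec.aa_weights())
    probs = np.empty((n_body, 4))
    for e in range(n_exons):
        mask = owners[1:-1] == e
        if mask.any():
            probs[mask] = spec.cell_probs(intron_count, e, n_exons)
    codon_ids = _sample_codon_ids(aa_idx, probs, rng)
    codon_ids = _apply_cpg_sweep(codon_ids, spec.cpg_keep_prob(), rng)
    stop = _STOPS[rng.integers(3)]
    cds = "ATG" + "".join(_SC_ARRAY[codon_ids]) + stop
    return cds, exon_lengths


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_intron(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    extra_mean = max(spec.intron_mean_len - spec.intron_min_len, 1.0)
    length = spec.intron_min_len + int(rng.geometric(1.0 / extra_mean)) - 1
    return "GT" + _random_seq(max(length - 4, 0), rng) + "AG"


def build_genome(spec: SyntheticSpec, seed: int) -> SyntheticGenome:
    """Generate contigs, GFF3 features and the truth table in memory."""
    rng = np.random.default_rng(seed)
    gff_lines: list[str] = []
    truth_rows: list[dict] = []
    contigs: dict[str, str] = {}

    gene_plan = [
        (k, i) for k in sorted(spec.n_genes) for i in range(spec.n_genes[k])
    ]
    contig_parts: list[str] = []
    contig_id = "contig1"
    offset = 0  # 0-based length of current contig so far
    n_on_contig = 0
    counter = 0

    def flush_contig() -> None:
        nonlocal contig_parts, offset, n_on_contig, contig_id
        if contig_parts:
            contigs[contig_id] = "".join(contig_parts)
        contig_parts = []
        offset = 0
        n_on_contig = 0
        contig_id = f"contig{len(contigs) + 1}"

    for intron_count, _ in gene_plan:
        counter += 1
        gene_id = f"gene{counter:05d}"
        tid = f"{gene_id}.t1"
        strand = "+" if counter % 2 == 1 else "-"

        cds, exon_lengths = _make_gene_cds(spec, intron_count, rng)
        # Slice the CDS into exon pieces and interleave introns.
        pieces, pos = [], 0
        for ln in exon_lengths:
            pieces.append(cds[pos : pos + ln])
            pos += ln
        introns = [_make_intron(spec, rng) for _ in range(len(exon_lengths) - 1)]
        gene_seq_parts = [pieces[0]]
        for intr, piece in zip(introns, pieces[1:]):
            gene_seq_parts.append(intr)
            gene_seq_parts.append(piece)
        gene_seq = "".join(gene_seq_parts)

        # Exon coordinates within the gene (0-based half-open), reading order.
        exon_spans, pos = [], 0
        for ln, part in zip(exon_lengths, gene_seq_parts[::2]):
            exon_spans.append((pos, pos + ln))
            pos += ln + (len(introns[len(exon_spans) - 1]) if len(exon_spans) - 1 < len(introns) else 0)

        spacer = _random_seq(spec.intergenic_len, rng)
        contig_parts.append(spacer)
        offset += len(spacer)
        gene_start0 = offset
        placed = gene_seq if strand == "+" else reverse_complement(gene_seq)
        contig_parts.append(placed)
        offset += len(gene_seq)

        glen = len(gene_seq)
        segments: list[tuple[int, int, str]] = []  # 1-based inclusive + phase
        cum = 0
        for s0, e0 in exon_spans:
            phase = str((3 - cum % 3) % 3)
            cum += e0 - s0
            if strand == "+":
                start, end = gene_start0 + s0 + 1, gene_start0 + e0
            else:
                start = gene_start0 + (glen - e0) + 1
                end = gene_start0 + (glen - s0)
            segments.append((start, end, phase))
        segments.sort(key=lambda t: t[0])

        gmin = min(s for s, _, _ in segments)
        gmax = max(e for _, e, _ in segments)
        gff_lines.append(
            f"{contig_id}\tscubkit_sim\tgene\t{gmin}\t{gmax}\t.\t{strand}\t.\tID={gene_id}"
        )
        gff_lines.append(
            f"{contig_id}\tscubkit_sim\tmRNA\t{gmin}\t{gmax}\t.\t{strand}\t.\tID={tid};Parent={gene_id}"
        )
        for s, e, phase in segments:
            gff_lines.append(
                f"{contig_id}\tscubkit_sim\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\tParent={tid}"
            )

        probs = spec.class_probs(intron_count)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "contig": contig_id,
                "strand": strand,
                "intron_count": intron_count,
                "exon_count": intron_count + 1,
                "n_codons": len(cds) // 3,
                "exon_lengths": ",".join(str(x) for x in exon_lengths),
                "p_nna": probs[0],
                "p_nnt": probs[1],
                "p_nnc": probs[2],
                "p_nng": probs[3],
                "exon_effect": spec.exon_effect,
                "exon_effect_size": spec.exon_effect_size,
                "cpg_depletion": spec.cpg_depletion,
            }
        )

        n_on_contig += 1
        if n_on_contig >= spec.genes_per_contig:
            contig_parts.append(_random_seq(spec.intergenic_len, rng))
            flush_contig()
    if contig_parts:
        contig_parts.append(_random_seq(spec.intergenic_len, rng))
        contigs[contig_id] = "".join(contig_parts)

    return SyntheticGenome(
        contigs=contigs,
        gff_lines=gff_lines,
        truth=pd.DataFrame(truth_rows),
    )


def generate_genome(
    spec: SyntheticSpec, outdir: str | Path, seed: int
) -> tuple[Path, Path, Path]:
    """Write genome.fasta, genes.gff3 and truth.tsv; byte-stable per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = build_genome(spec, seed)
    fasta = outdir / "genome.fasta"
    gff = outdir / "genes.gff3"
    truth = outdir / "truth.tsv"
    fasta.write_text(genome.fasta_text())
    gff.write_text(genome.gff_text())
    genome.truth.to_csv(truth, sep="\t", index=False)
    return fasta, gff, truth
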