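"""Synonymous-codon usage statistics.

All statistics are ratios of codon tallies over the 59-codon synonymous
universe within one stratum (an intron-number bin, an exon-position cell, or
a whole genome):

* per-codon SC frequency: count of a codon / count of all SCs of its amino
  acid;
* third-position class frequencies NNA/NNT/NNC/NNG: counts of SCs ending in
  a given nucleotide / total SC count (sums to 1);
* the NNA/T : NNC/G ratio per amino acid ((A+T)-ending / (C+G)-ending
  counts) and its mean over the 18 amino acids;
* four 16-cell dinucleotide context tables used to probe methylation-driven
  (CpG -> TpG/CpA) substitution: within-codon second-third (NNN) and
  first-second pairs, the codon-junction pair (third nucleotide, next
  codon's first nucleotide), and the pair (previous codon's last nucleotide,
  first nucleotide).

Undefined ratios (zero denominators) propagate as NaN, never as 0 or
infinity; means skip them and report how many were skipped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_extraction import CodonRecord
from .genetic_code import GeneticCode, NUCLEOTIDES, THIRD_CLASSES

#: Fixed ordering of dinucleotide cells (first letter major, A,C,G,T order).
PAIR_INDEX = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

_ACGT = set("ACGT")


@dataclass
class CodonCountTable:
    """Codon and neighbour-pair tallies for one stratum.

    ``boundary_counts`` tallies (third nucleotide, next codon's first
    nucleotide) over records that have a next neighbour; ``first_counts``
    tallies (previous codon's last nucleotide, first nucleotide) over records
    with a previous neighbour.  Both are therefore bounded above by the codon
    total.
    """

    counts: pd.Series
    boundary_counts: pd.Series
    first_counts: pd.Series
    label: str = ""

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_codons(
    records: list[CodonRecord], code: GeneticCode, label: str = ""
) -> CodonCountTable:
    """Tally filtered codon records into a :class:`CodonCountTable`."""
    c: Counter[str] = Counter()
    boundary: Counter[str] = Counter()
    first: Counter[str] = Counter()
    for r in records:
        c[r.codon] += 1
        if r.next_first in _ACGT:
            boundary[r.codon[2] + r.next_first] += 1
        if r.prev_last in _ACGT:
            first[r.prev_last + r.codon[0]] += 1
    counts = pd.Series(
        [c.get(codon, 0) for codon in code.sc_set],
        index=list(code.sc_set),
        dtype=np.int64,
    )
    return CodonCountTable(
        counts=counts,
        boundary_counts=pd.Series(
            [boundary.get(p, 0) for p in PAIR_INDEX], index=list(PAIR_INDEX), dtype=np.int64
        ),
        first_counts=pd.Series(
            [first.get(p, 0) for p in PAIR_INDEX], index=list(PAIR_INDEX), dtype=np.int64
        ),
        label=label,
    )


def merge_tables(tables: list[CodonCountTable], label: str = "") -> CodonCountTable:
    """Pool several count tables (counts add; used for pooled strata)."""
    if not tables:
        raise ValueError("no tables to merge")
    return CodonCountTable(
        counts=sum(t.counts for t in tables),
        boundary_counts=sum(t.boundary_counts for t in tables),
        first_counts=sum(t.first_counts for t in tables),
        label=label,
    )


def sc_frequency(table: CodonCountTable, code: GeneticCode) -> pd.Series:
    """Within-amino-acid codon frequencies over the 59-codon set.

    For each amino acid with at least one observed SC, each member codon's
    frequency is its count divided by the amino acid's total; members of
    unobserved amino acids are NaN (undefined, not zero).
    """
    freq = pd.Series(np.nan, index=table.counts.index, dtype=float)
    for aa, codons in code.aa_groups.items():
        group = table.counts.loc[list(codons)]
        total = group.sum()
        if total > 0:
            freq.loc[list(codons)] = group / total
    return freq


def third_class_frequency(table: CodonCountTable, code: GeneticCode) -> pd.Series:
    """NNA/NNT/NNC/NNG frequencies: class counts over the total SC count."""
    total = table.total
    out = pd.Series(np.nan, index=list(THIRD_CLASSES), dtype=float)
    if total == 0:
        return out
    for cls in THIRD_CLASSES:
        members = [c for c in code.sc_set if code.third_class[c] == cls]
        out[cls] = table.counts.loc[members].sum() / total
    return out


def at_gc_ratio(
    table: CodonCountTable, code: GeneticCode
) -> tuple[pd.Series, float, int]:
    """Per-amino-acid (A+T)-ending : (C+G)-ending ratio and its mean.

    Returns (per-aa ratios, mean over defined ratios, number skipped).
    Amino acids with a zero C/G-ending count have an undefined ratio (NaN)
    and are excluded from the mean.
    """
    ratios = pd.Series(np.nan, index=sorted(code.aa_groups), dtype=float)
    for aa, codons in code.aa_groups.items():
        at = sum(table.counts[c] for c in codons if c[2] in "AT")
        gc = sum(table.counts[c] for c in codons if c[2] in "CG")
        if gc > 0:
            ratios[aa] = at / gc
    n_skipped = int(ratios.isna().sum())
    mean = float(ratios.mean()) if n_skipped < len(ratios) else float("nan")
    return ratios, mean, n_skipped


def _pair_freq_from_counts(counts: pd.Series, denom: float) -> pd.Series:
    if denom <= 0:
        return pd.Series(np.nan, index=list(PAIR_INDEX), dtype=float)
    return counts / denom


def context_frequencies(
    table: CodonCountTable, denominator: str = "events"
) -> dict[str, pd.Series]:
    """The four 16-cell dinucleotide context tables as frequencies.

    ``nnn`` (second-third within codon) and ``firstsecond`` (first-second)
    are always divided by the stratum's total SC count and so sum to 1.
    For the junction tables ``boundary`` (third, next first) and
    ``first_pair`` (previous last, first), ``denominator="events"`` divides
    by the number of codons possessing the relevant neighbour, making each
    16-vector sum to 1 and comparable across strata of different sizes;
    ``denominator="total"`` divides by the full SC count instead.
    """
    if denominator not in {"events", "total"}:
        raise ValueError("denominator must be 'events' or 'total'")
    total = table.total
    nnn = Counter()
    firstsecond = Counter()
    for codon, n in table.counts.items():
        if n:
            nnn[codon[1] + codon[2]] += int(n)
            firstsecond[codon[0] + codon[1]] += int(n)
    nnn_counts = pd.Series(
        [nnn.get(p, 0) for p in PAIR_INDEX], index=list(PAIR_INDEX), dtype=float
    )
    fs_counts = pd.Series(
        [firstsecond.get(p, 0) for p in PAIR_INDEX], index=list(PAIR_INDEX), dtype=float
    )
    b_denom = table.boundary_counts.sum() if denominator == "events" else total
    f_denom = table.first_counts.sum() if denominator == "events" else total
    return {
        "nnn": _pair_freq_from_counts(nnn_counts, total),
        "boundary": _pair_freq_from_counts(table.boundary_counts.astype(float), b_denom),
        "first_pair": _pair_freq_from_counts(table.first_counts.astype(float), f_denom),
        "firstsecond": _pair_freq_from_counts(fs_counts, total),
    }


@dataclass
class ScubProfile:
    """Every SCUB statistic for one stratum, as labelled vectors."""

    label: str
    n_codons: int
    per_codon_freq: pd.Series
    third_class_freq: pd.Series
    at_gc_ratio_per_aa: pd.Series
    at_gc_ratio_mean: float
    at_gc_ratio_n_skipped: int
    nnn_freq: pd.Series
    boundary_freq: pd.Series
    first_pair_freq: pd.Series
    firstsecond_freq: pd.Series

    def to_feature_series(self, which: tuple[str, ...] = ("per_codon",)) -> pd.Series:
        """Concatenate selected statistics into one named feature vector."""
        parts = []
        if "per_codon" in which:
            parts.append(self.per_codon_freq.add_prefix("sc:"))
        if "third_class" in which:
            parts.append(self.third_class_freq.copy())
        if "at_gc_ratio" in which:
            parts.append(self.at_gc_ratio_per_aa.add_prefix("atgc:"))
            parts.append(pd.Series({"atgc_mean": self.at_gc_ratio_mean}))
        if "nnn" in which:
            parts.append(self.nnn_freq.add_prefix("nnn:"))
        if "boundary" in which:
            parts.append(self.boundary_freq.add_prefix("bnd:"))
        if not parts:
            raise ValueError("no statistics selected")
        return pd.concat(parts)


def compute_profile(
    table: CodonCountTable,
    code: GeneticCode,
    denominator: str = "events",
) -> ScubProfile:
    """Derive the full :class:`ScubProfile` from one count table."""
    ratios, mean, n_skipped = at_gc_ratio(table, code)
    ctx = context_frequencies(table, denominator=denominator)
    return ScubProfile(
        label=table.label,
        n_codons=table.total,
        per_codon_freq=sc_frequency(table, code),
        third_class_freq=third_class_frequency(table, code),
        at_gc_ratio_per_aa=ratios,
        at_gc_ratio_mean=mean,
        at_gc_ratio_n_skipped=n_skipped,
        nnn_freq=ctx["nnn"],
        boundary_freq=ctx["boundary"],
        first_pair_freq=ctx["first_pair"],
        firstsecond_freq=ctx["firstsecond"],
    )


def mean_profiles(profiles: list[ScubProfile], label: str = "") -> ScubProfile:
    """Average per-gene profiles (the per-gene-mean pooling mode).

    Each vector statistic is averaged cell-wise over the genes in which it is
    defined (NaN-skipping), weighting every gene equally regardless of its
    codon count.
    """
    if not profiles:
        raise ValueError("no profiles to average")

    def avg(attr: str) -> pd.Series:
        return pd.concat([getattr(p, attr) for p in profiles], axis=1).mean(axis=1)

    means = [p.at_gc_ratio_mean for p in profiles if np.isfinite(p.at_gc_ratio_mean)]
    return ScubProfile(
        label=label,
        n_codons=sum(p.n_codons for p in profiles),
        per_codon_freq=avg("per_codon_freq"),
        third_class_freq=avg("third_class_freq"),
        at_gc_ratio_per_aa=avg("at_gc_ratio_per_aa"),
        at_gc_ratio_mean=float(np.mean(means)) if means else float("nan"),
        at_gc_ratio_n_skipped=len(profiles) - len(means),
        nnn_freq=avg("nnn_freq"),
        boundary_freq=avg("boundary_freq"),
        first_pair_freq=avg("first_pair_freq"),
        firstsecond_freq=avg("firstsecond_freq"),
    )


def profiles_to_frame(
    profiles: dict[int, ScubProfile],
    which: tuple[str, ...] = ("third_class", "at_gc_ratio", "per_codon"),
) -> pd.DataFrame:
    """One row per stratum key, one column per named statistic."""
    rows = {k: p.to_feature_series(which=which) for k, p in profiles.items()}
    return pd.DataFrame(rows).T.sort_index()


def correlate_with_intron_number(
    profiles: dict[int, ScubProfile],
    which: tuple[str, ...] = ("third_class", "at_gc_ratio", "per_codon"),
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate each statistic against intron number across bins.

    Returns a frame indexed by statistic name with columns ``rho``,
    ``pvalue`` and ``n_bins``.  Statistics that are constant across bins (or
    defined in fewer than 3 bins) get NaN rho and are thereby flagged rather
    than silently reported as zero correlation.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError("method must be 'spearman' or 'pearson'")
    nonempty = {k: p for k, p in profiles.items() if p.n_codons > 0}
    if len(nonempty) < 3:
        raise ValueError("need >= 3 non-empty intron bins")
    frame = profiles_to_frame(nonempty, which=which)
    bins = frame.index.to_numpy(dtype=float)
    out = []
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    for col in frame.columns:
        y = frame[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.allclose(y[ok], y[ok][0]):
            out.append((col, np.nan, np.nan, int(ok.sum())))
            continue
        res = corr(bins[ok], y[ok])
        out.append((col, float(res.statistic), float(res.pvalue), int(ok.sum())))
    return pd.DataFrame(out, columns=["statistic", "rho", "pvalue", "n_bins"]).set_index(
        "statistic"
    )
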