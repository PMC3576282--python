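import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from scubkit.codon_extraction import GeneModel, assign_codons, filter_sc_records
from scubkit.scub_stats import (
    CodonCountTable,
    PAIR_INDEX,
    at_gc_ratio,
    compute_profile,
    context_frequencies,
    correlate_with_intron_number,
    count_codons,
    merge_tables,
    sc_frequency,
    third_class_frequency,
)


def records_from_cds(cds, code):
    model = GeneModel("g", "+", cds, (len(cds),))
    return filter_sc_records(assign_codons(model), code)


def table_from_counts(code, counts_dict):
    """Build a count table with given codon counts and empty junction tables."""
    counts = pd.Series(0, index=list(code.sc_set), dtype=np.int64)
    for codon, n in counts_dict.items():
        counts[codon] = n
    zeros = pd.Series(0, index=list(PAIR_INDEX), dtype=np.int64)
    return CodonCountTable(counts=counts, boundary_counts=zeros.copy(),
                           first_counts=zeros.copy())


class StringScanOracle:
    """Independent recount of every statistic by plain string scanning.

    Shares no code with the implementation: codons are read off the CDS
    string, amino acids come from Bio.Seq translation, and every ratio is
    plain dict-and-float arithmetic.
    """

    EXCLUDE = {"TAA", "TGA", "TAG", "ATG", "TGG"}

    def __init__(self, cds):
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        self.kept = []
        for i, c in enumerate(codons):
            if c in self.EXCLUDE or any(b not in "ACGT" for b in c):
                continue
            nxt = codons[i + 1][0] if i + 1 < len(codons) else None
            prv = codons[i - 1][2] if i > 0 else None
            self.kept.append((c, nxt, prv))

    def codon_counts(self):
        out = {}
        for c, _, _ in self.kept:
            out[c] = out.get(c, 0) + 1
        return out

    def sc_freq(self, codon):
        aa = str(Seq(codon).translate())
        counts = self.codon_counts()
        group_total = sum(
            n for c, n in counts.items() if str(Seq(c).translate()) == aa
        )
        return counts.get(codon, 0) / group_total if group_total else None

    def third_freq(self, nt):
        total = len(self.kept)
        return sum(1 for c, _, _ in self.kept if c[2] == nt) / total

    def at_gc_mean(self):
        by_aa = {}
        for c, _, _ in self.kept:
            aa = str(Seq(c).translate())
            at, gc = by_aa.get(aa, (0, 0))
            if c[2] in "AT":
                at += 1
            else:
                gc += 1
            by_aa[aa] = (at, gc)
        ratios = [at / gc for at, gc in by_aa.values() if gc > 0]
        return sum(ratios) / len(ratios) if ratios else None

    def nnn_freq(self, pair):
        return sum(1 for c, _, _ in self.kept if c[1:] == pair) / len(self.kept)

    def boundary_freq(self, pair):
        events = [(c[2] + n) for c, n, _ in self.kept if n is not None]
        return events.count(pair) / len(events)

    def first_pair_freq(self, pair):
        events = [(p + c[0]) for c, _, p in self.kept if p is not None]
        return events.count(pair) / len(events)


class TestCountCodons:
    def test_simple_tally(self, code):
        recs = records_from_cds("ATG" + "GCTGCTGCC" + "TAA", code)
        table = count_codons(recs, code)
        assert table.counts["GCT"] == 2 and table.counts["GCC"] == 1
        assert table.total == 3

    def test_empty_input_all_zero(self, code):
        table = count_codons([], code)
        assert table.total == 0
        assert table.boundary_counts.sum() == 0

    def test_boundary_counts_hand_walk(self, code):
        # ATG GCT GCG TAA: junction GCT|GCG gives (T,G), GCG|TAA gives (G,T).
        table = count_codons(records_from_cds("ATGGCTGCGTAA", code), code)
        assert table.counts["GCT"] == 1 and table.counts["GCG"] == 1
        assert table.boundary_counts["TG"] == 1
        assert table.boundary_counts["GT"] == 1
        assert table.boundary_counts.sum() == 2


class TestScFrequency:
    def test_alanine_arithmetic(self, code):
        table = table_from_counts(code, {"GCT": 2, "GCC": 1, "GCA": 0, "GCG": 1})
        freq = sc_frequency(table, code)
        assert freq["GCT"] == 0.5 and freq["GCC"] == 0.25
        assert freq["GCG"] == 0.25 and freq["GCA"] == 0.0

    def test_single_observed_codon_is_one(self, code):
        freq = sc_frequency(table_from_counts(code, {"TGT": 3}), code)
        assert freq["TGT"] == 1.0 and freq["TGC"] == 0.0

    def test_unobserved_group_is_nan_not_zero(self, code):
        freq = sc_frequency(table_from_counts(code, {"TGT": 1}), code)
        assert np.isnan(freq["GCT"])

    def test_group_normalization(self, code):
        rng = np.random.default_rng(0)
        table = table_from_counts(
            code, {c: int(n) for c, n in zip(code.sc_set, rng.integers(0, 30, 59))}
        )
        freq = sc_frequency(table, code)
        for aa, codons in code.aa_groups.items():
            sub = freq[list(codons)]
            if not sub.isna().any():
                assert sub.sum() == pytest.approx(1.0, abs=1e-12)


class TestThirdClassFrequency:
    def test_all_c_ending(self, code):
        f = third_class_frequency(table_from_counts(code, {"GCC": 5}), code)
        assert f.tolist() == [0.0, 0.0, 1.0, 0.0]  # NNA, NNT, NNC, NNG

    def test_even_split(self, code):
        table = table_from_counts(code, {"GCA": 2, "GCT": 2, "GCC": 2, "GCG": 2})
        assert third_class_frequency(table, code).tolist() == [0.25] * 4

    def test_zero_total_flagged_nan(self, code):
        assert third_class_frequency(table_from_counts(code, {}), code).isna().all()

    def test_sums_to_one(self, code):
        rng = np.random.default_rng(1)
        table = table_from_counts(
            code, {c: int(n) for c, n in zip(code.sc_set, rng.integers(1, 9, 59))}
        )
        assert third_class_frequency(table, code).sum() == pytest.approx(1.0, abs=1e-12)


class TestAtGcRatio:
    def test_alanine_ratio(self, code):
        table = table_from_counts(code, {"GCT": 2, "GCA": 2, "GCC": 1, "GCG": 1})
        ratios, _, _ = at_gc_ratio(table, code)
        assert ratios["A"] == 2.0

    def test_zero_denominator_excluded_from_mean(self, code):
        table = table_from_counts(
            code, {"GCT": 2, "GCA": 2, "GCC": 1, "GCG": 1, "TGT": 1, "TGC": 1}
        )
        ratios, mean, n_skipped = at_gc_ratio(table, code)
        assert np.isnan(ratios["F"])  # Phe unobserved -> undefined
        assert n_skipped == 16  # only Ala and Cys have defined ratios
        assert mean == pytest.approx((ratios["A"] + ratios["C"]) / 2)

    def test_all_gc_group_is_undefined_when_no_at(self, code):
        table = table_from_counts(code, {"GCC": 3, "GCG": 1})
        ratios, mean, _ = at_gc_ratio(table, code)
        assert ratios["A"] == 0.0  # AT count 0, GC count 4 -> ratio 0
        table2 = table_from_counts(code, {"GCT": 3})
        ratios2, _, n_skipped = at_gc_ratio(table2, code)
        assert np.isnan(ratios2["A"])  # GC denominator 0 -> undefined
        assert n_skipped == 18

    def test_isoleucine_has_no_nng(self, code):
        assert "ATG" not in code.aa_groups["I"]
        table = table_from_counts(code, {"ATT": 1, "ATA": 1, "ATC": 2})
        ratios, _, _ = at_gc_ratio(table, code)
        assert ratios["I"] == 1.0  # (1+1)/2, Ile has no G-ending codon


class TestContextFrequencies:
    def test_single_codon_nnn_cell(self, code):
        ctx = context_frequencies(table_from_counts(code, {"GCG": 3}))
        assert ctx["nnn"]["CG"] == 1.0
        assert ctx["nnn"].drop("CG").sum() == 0.0
        assert ctx["firstsecond"]["GC"] == 1.0

    def test_boundary_cell_hand_walk(self, code):
        # ATG GCG TAA: only GCG kept, next_first = T -> boundary (G,T) = 1.
        table = count_codons(records_from_cds("ATGGCGTAA", code), code)
        ctx = context_frequencies(table)
        assert ctx["boundary"]["GT"] == 1.0
        assert ctx["first_pair"]["GG"] == 1.0  # prev_last G (from ATG), first G

    def test_total_denominator_mode(self, code):
        table = count_codons(records_from_cds("ATGGCTGCGTAA", code), code)
        events = context_frequencies(table, denominator="events")
        total = context_frequencies(table, denominator="total")
        assert events["boundary"].sum() == pytest.approx(1.0, abs=1e-12)
        # Both kept codons have a next neighbour, so the modes agree here.
        assert total["boundary"].equals(events["boundary"])

    def test_invalid_denominator(self, code):
        with pytest.raises(ValueError):
            context_frequencies(table_from_counts(code, {"GCG": 1}), denominator="x")


class TestOracleEquivalence:
    """Every statistic equals an independent string-scan recount to 1e-12."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_statistics_match_oracle(self, code, seed):
        rng = np.random.default_rng(seed)
        body = rng.choice(list(code.sc_set), size=int(rng.integers(10, 48)))
        cds = "ATG" + "".join(body) + "TAA"
        table = count_codons(records_from_cds(cds, code), code)
        profile = compute_profile(table, code)
        oracle = StringScanOracle(cds)

        for codon in code.sc_set:
            expected = oracle.sc_freq(codon)
            got = profile.per_codon_freq[codon]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)
        for nt, cls in zip("ATCG", ["NNA", "NNT", "NNC", "NNG"]):
            assert profile.third_class_freq[cls] == pytest.approx(
                oracle.third_freq(nt), abs=1e-12
            )
        assert profile.at_gc_ratio_mean == pytest.approx(oracle.at_gc_mean(), abs=1e-12)
        for pair in PAIR_INDEX:
            assert profile.nnn_freq[pair] == pytest.approx(
                oracle.nnn_freq(pair), abs=1e-12
            )
            assert profile.boundary_freq[pair] == pytest.approx(
                oracle.boundary_freq(pair), abs=1e-12
            )
            assert profile.first_pair_freq[pair] == pytest.approx(
                oracle.first_pair_freq(pair), abs=1e-12
            )


class TestInvariants:
    def test_scale_invariance(self, code):
        rng = np.random.default_rng(2)
        counts = {c: int(n) for c, n in zip(code.sc_set, rng.integers(1, 9, 59))}
        t1 = table_from_counts(code, counts)
        t5 = table_from_counts(code, {c: 5 * n for c, n in counts.items()})
        p1, p5 = compute_profile(t1, code), compute_profile(t5, code)
        pd.testing.assert_series_equal(p1.per_codon_freq, p5.per_codon_freq)
        pd.testing.assert_series_equal(p1.third_class_freq, p5.third_class_freq)
        assert p1.at_gc_ratio_mean == pytest.approx(p5.at_gc_ratio_mean)

    def test_at_symmetry(self, code):
        """A<->T / C<->G exchangeable counts give NNA=NNT and NNC=NNG.

        Counts are placed only on codons whose third-position mirror (A<->T,
        C<->G) is a synonym, so the composition is exchangeable by
        construction (2-fold boxes pair T with C and A with G, so their
        mirrors change the amino acid and they are left at zero).
        """
        mirror = {"A": "T", "T": "A", "C": "G", "G": "C"}
        counts = {}
        for aa, codons in code.aa_groups.items():
            for c in codons:
                if c[:2] + mirror[c[2]] in codons:
                    counts[c] = {"A": 7, "T": 7, "C": 2, "G": 2}[c[2]]
        f = third_class_frequency(table_from_counts(code, counts), code)
        assert f["NNA"] == pytest.approx(f["NNT"], abs=1e-12)
        assert f["NNC"] == pytest.approx(f["NNG"], abs=1e-12)

    def test_merge_tables_adds(self, code):
        t = count_codons(records_from_cds("ATGGCTGCGTAA", code), code)
        merged = merge_tables([t, t])
        assert merged.total == 2 * t.total
        assert (merged.boundary_counts == 2 * t.boundary_counts).all()


class TestCorrelation:
    def _profiles(self, code, values_by_bin):
        """Profiles whose NNC frequency is planted per bin via Ala counts."""
        out = {}
        for k, nnc in values_by_bin.items():
            n = 1000
            table = table_from_counts(
                code, {"GCC": int(n * nnc), "GCA": n - int(n * nnc)}
            )
            out[k] = compute_profile(table, code)
        return out

    def test_monotone_profile_gives_rho_one(self, code):
        profiles = self._profiles(code, {k: 0.1 + 0.05 * k for k in range(10)})
        report = correlate_with_intron_number(profiles, which=("third_class",))
        assert report.loc["NNC", "rho"] == pytest.approx(1.0)
        assert report.loc["NNA", "rho"] == pytest.approx(-1.0)
        assert report.loc["NNC", "pvalue"] < 0.05

    def test_constant_profile_flagged_nan(self, code):
        profiles = self._profiles(code, {k: 0.4 for k in range(5)})
        report = correlate_with_intron_number(profiles, which=("third_class",))
        assert np.isnan(report.loc["NNC", "rho"])

    def test_requires_three_bins(self, code):
        profiles = self._profiles(code, {0: 0.1, 1: 0.2})
        with pytest.raises(ValueError, match=">= 3"):
            correlate_with_intron_number(profiles)

    def test_pearson_switch(self, code):
        profiles = self._profiles(code, {k: 0.1 + 0.05 * k for k in range(6)})
        report = correlate_with_intron_number(
            profiles, which=("third_class",), method="pearson"
        )
        assert report.loc["NNC", "rho"] == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            correlate_with_intron_number(profiles, method="kendall")
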