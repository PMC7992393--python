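"""Clustering vs single-linkage oracle, capture screen, window stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oysterkit.io_core import Feature, revcomp
from oysterkit.repeatstats import (
    capture_screen,
    chromosome_enrichment,
    conserved_end_count,
    density_correlation,
    end30,
    greedy_cluster,
    helitron_density,
    pair_identity,
    window_counts,
)
from oysterkit.simulate import ElementSpec, make_element, random_seq

AA = "ACDEFGHIKLMNPQRSTVWY"


def single_linkage_oracle(ends, threshold=0.80):
    """Connected components of the >= threshold identity graph."""
    n = len(ends)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pair_identity(ends[i], ends[j]) >= threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def _mutate_subs(seq, k, rng):
    chars = list(seq)
    for p in rng.choice(len(chars), size=k, replace=False):
        chars[p] = "ACGT"[("ACGT".index(chars[p]) + 1 + int(rng.integers(3))) % 4]
    return "".join(chars)


class TestEnd30:
    def test_suffix_of_element(self, rng):
        seq, _ = make_element(ElementSpec(), rng)
        assert end30(seq) == seq[-30:]
        assert end30(seq).endswith("CTAG")

    def test_reverse_strand_uses_own_strand(self, rng):
        seq, _ = make_element(ElementSpec(), rng)
        assert end30(revcomp(revcomp(seq))) == seq[-30:]

    def test_short_element_errors(self):
        with pytest.raises(ValueError):
            end30("TCAAACTAG")


class TestPairIdentity:
    def test_identical(self):
        s = random_seq(np.random.default_rng(0), 30, 0.4)
        assert pair_identity(s, s) == 1.0

    def test_single_substitution(self):
        s = random_seq(np.random.default_rng(1), 30, 0.4)
        t = _mutate_subs(s, 1, np.random.default_rng(2))
        assert pair_identity(s, t) == pytest.approx(29 / 30)

    def test_six_substitutions_reach_threshold(self):
        rng = np.random.default_rng(3)
        s = random_seq(rng, 30, 0.4)
        t = _mutate_subs(s, 6, rng)
        assert pair_identity(s, t) >= 0.80


class TestGreedyCluster:
    def test_all_identical_one_family(self):
        fams = greedy_cluster(["ACGT" * 7 + "AC"] * 10)
        assert len(fams) == 1 and sorted(fams[0].member_indices) == list(range(10))

    def test_two_planted_families_match_single_linkage(self):
        rng = np.random.default_rng(8)
        while True:  # seeds with low cross identity (fixture premise)
            a = random_seq(rng, 30, 0.4)
            b = random_seq(rng, 30, 0.4)
            if pair_identity(a, b) <= 0.45:
                break
        ends = []
        for seed in (a, b):
            for _ in range(25):
                ends.append(_mutate_subs(seed, int(rng.integers(0, 3)), rng))
        order = rng.permutation(len(ends))
        ends = [ends[i] for i in order]
        fams = greedy_cluster(ends)
        got = {frozenset(f.member_indices) for f in fams}
        assert got == single_linkage_oracle(ends)
        assert len(got) == 2

    def test_order_stability_under_permutation(self):
        rng = np.random.default_rng(9)
        seed = random_seq(rng, 30, 0.4)
        ends = [_mutate_subs(seed, int(rng.integers(0, 3)), rng) for _ in range(20)]
        ends += [random_seq(rng, 30, 0.4) for _ in range(5)]
        f1 = {frozenset(f.member_indices) for f in greedy_cluster(ends)}
        perm = rng.permutation(len(ends))
        shuffled = [ends[i] for i in perm]
        f2_raw = greedy_cluster(shuffled)
        f2 = {frozenset(int(perm[m]) for m in f.member_indices) for f in f2_raw}
        assert f1 == f2

    def test_conserved_end_counting_modes(self):
        rng = np.random.default_rng(10)
        seed = random_seq(rng, 30, 0.4)
        ends = [seed] * 4 + [random_seq(rng, 30, 0.4) for _ in range(3)]
        fams = greedy_cluster(ends)
        assert conserved_end_count(fams) == 4
        assert conserved_end_count(fams, count_all=True) == 7


class TestCaptureScreen:
    @staticmethod
    def _encode_protein(frag):
        from Bio.Data.CodonTable import standard_dna_table

        table = {}
        for codon, aa in standard_dna_table.forward_table.items():
            table.setdefault(aa, codon)
        return "".join(table[a] for a in frag)

    def test_planted_fragment_matched(self, rng):
        prot = "".join(AA[i] for i in np.random.default_rng(0).integers(0, 20, 150))
        dna = self._encode_protein(prot[40:100])  # 60 residues
        elem, _ = make_element(ElementSpec(), rng)
        carrier = elem[:250] + dna + elem[250:]
        matches = capture_screen([carrier, elem], {"p": prot})
        assert [m.element_index for m in matches] == [0]
        assert matches[0].aln_len > 50 and matches[0].identity >= 0.85

    def test_short_fragment_rejected_by_length_rule(self, rng):
        prot = "".join(AA[i] for i in np.random.default_rng(1).integers(0, 20, 150))
        dna = self._encode_protein(prot[40:85])  # 45 residues
        elem, _ = make_element(ElementSpec(), rng)
        assert capture_screen([elem[:250] + dna + elem[250:]], {"p": prot}) == []

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(2)
        prots = {
            f"p{i}": "".join(AA[j] for j in rng.integers(0, 20, 200)) for i in range(4)
        }
        elems = [random_seq(rng, 1000, 0.35) for _ in range(50)]
        matches = capture_screen(elems, prots)
        assert len(matches) / (len(elems) * len(prots)) < 0.01

    def test_empty_protein_set_errors(self):
        with pytest.raises(ValueError):
            capture_screen(["ACGT" * 100], {})


class TestWindowCounts:
    def test_larger_overlap_wins(self):
        f = Feature("c", 95_000, 103_000, "+", "gene")
        ws = window_counts([f], {"c": 200_000})
        assert ws[0].counts["gene"] == 1 and ws[1].counts["gene"] == 0

    def test_exact_tie_goes_to_lower_window(self):
        f = Feature("c", 98_000, 102_000, "+", "LTR")
        ws = window_counts([f], {"c": 200_000})
        assert ws[0].counts["LTR"] == 1 and ws[1].counts["LTR"] == 0

    def test_feature_beyond_chromosome_errors(self):
        with pytest.raises(ValueError):
            window_counts([Feature("c", 0, 300_000)], {"c": 200_000})

    @settings(max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 499_000), st.integers(1, 150_000)),
            min_size=1,
            max_size=40,
        )
    )
    def test_count_conservation(self, spans):
        feats = [
            Feature("c", s, min(s + l, 500_000), "+", "other") for s, l in spans
        ]
        ws = window_counts(feats, {"c": 500_000})
        assert sum(sum(w.counts.values()) for w in ws) == len(feats)


class TestDensities:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, p = density_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_closed_form_fixture(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 7.0]
        r, p = density_correlation(x, y)
        from scipy import stats

        r_ref, p_ref = stats.pearsonr(x, y)
        assert abs(r - r_ref) < 1e-12 and abs(p - p_ref) < 1e-10

    def test_null_correlation_small(self):
        big = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            r, _ = density_correlation(rng.normal(size=200), rng.normal(size=200))
            if abs(r) >= 0.2:
                big += 1
        assert big == 0

    def test_zero_variance_undefined(self):
        assert density_correlation([1.0] * 5, [1, 2, 3, 4, 5]) is None

    def test_density_arithmetic(self):
        assert helitron_density(0, 50.0) == 0.0
        assert helitron_density(100, 50.0) == 2.0
        assert helitron_density(751, 647.887097) == pytest.approx(1.159, abs=1e-3)

    def test_enrichment_rule(self):
        assert chromosome_enrichment({"a": 1.0, "b": 1.0, "c": 1.0}) == []
        dens = {f"c{i}": 1.0 for i in range(4)}
        dens["hot"] = 5.0
        assert chromosome_enrichment(dens) == ["hot"]
        ten = {f"c{i}": 2.0 for i in range(9)}
        ten["x"] = 2.0 + 2.5 * np.std(list(ten.values()) + [4.0])
        ten["x"] = 4.0
        sd = np.std(list(ten.values()))
        assert chromosome_enrichment(ten) == (["x"] if 4.0 > np.mean(list(ten.values())) + sd else [])
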