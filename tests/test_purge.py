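"""Minimizer mapping and iterative haplotig purging, with an
exact-alignment oracle built on edlib."""

import edlib
import numpy as np
import pytest

from oysterkit.io_core import SeqRecord, revcomp
from oysterkit.purge import (
    PurgeResult,
    build_minimizer_index,
    intersect_keep_lists,
    iterative_purge,
    map_contig,
)
from oysterkit.simulate import AssemblyConfig, _mutate, random_seq, simulate_assembly


def oracle_covered_frac(query: str, target: str, chunk: int = 500, max_div: float = 0.12) -> float:
    """True covered fraction by exact (edit-distance) alignment of query
    chunks against the target, both strands."""
    covered = 0
    for s in range(0, len(query), chunk):
        c = query[s : s + chunk]
        if len(c) < 50:
            continue
        d = edlib.align(c, target, mode="HW", task="distance")["editDistance"]
        drc = edlib.align(revcomp(c), target, mode="HW", task="distance")["editDistance"]
        if min(d, drc) <= max_div * len(c):
            covered += len(c)
    return covered / len(query)


def oracle_purge(contigs, min_len=10_000, min_frac=0.30) -> set[str]:
    """Same iterative schedule, removal decisions from the exact oracle."""
    lengths = {r.id: len(r.seq) for r in contigs}
    seqs = {r.id: r.seq for r in contigs}
    pool = sorted(lengths, key=lambda c: (-lengths[c], c))
    removed: set[str] = set()
    while pool:
        ref, others = pool[0], pool[1:]
        dropped = {
            o
            for o in others
            if lengths[o] > min_len
            and oracle_covered_frac(seqs[o], seqs[ref]) >= min_frac
        }
        removed |= dropped
        pool = [c for c in others if c not in dropped]
    return removed


class TestMinimizerIndex:
    def test_identical_contigs_share_all_minimizers(self, rng):
        s = random_seq(rng, 20_000, 0.33)
        idx = build_minimizer_index([SeqRecord("a", s), SeqRecord("b", s)])
        assert set(idx["a"].sorted_hashes) == set(idx["b"].sorted_hashes)

    def test_revcomp_shares_canonical_minimizers(self, rng):
        s = random_seq(rng, 20_000, 0.33)
        idx = build_minimizer_index([SeqRecord("a", s), SeqRecord("b", revcomp(s))])
        assert set(idx["a"].sorted_hashes) == set(idx["b"].sorted_hashes)

    def test_disjoint_contigs_share_almost_nothing(self, rng):
        a = random_seq(rng, 10_000, 0.33)
        b = random_seq(rng, 10_000, 0.33)
        idx = build_minimizer_index([SeqRecord("a", a), SeqRecord("b", b)])
        shared = np.intersect1d(idx["a"].sorted_hashes, idx["b"].sorted_hashes)
        assert len(shared) / len(idx["a"].sorted_hashes) < 0.01

    def test_short_contig_indexed_with_whatever_exists(self):
        idx = build_minimizer_index([SeqRecord("t", "ACGTACGTACGT")])
        assert idx["t"].length == 12  # fewer than k+w bases, possibly no minimizers


class TestMapContig:
    def test_containment_fraction(self, rng):
        target = random_seq(rng, 40_000, 0.33)
        query = target[10_000:20_000] + random_seq(rng, 10_000, 0.33)
        idx = build_minimizer_index([SeqRecord("t", target), SeqRecord("q", query)])
        hit = map_contig("q", idx, ["t"])["t"]
        assert hit.query_covered_frac == pytest.approx(0.5, abs=0.05)

    def test_divergent_copy_maps_near_fully(self, rng):
        target = random_seq(rng, 30_000, 0.33)
        query = _mutate(target, 0.03, rng)
        idx = build_minimizer_index([SeqRecord("t", target), SeqRecord("q", query)])
        assert map_contig("q", idx, ["t"])["t"].query_covered_frac >= 0.9

    def test_unrelated_query_maps_nowhere(self, rng):
        idx = build_minimizer_index(
            [SeqRecord("t", random_seq(rng, 30_000, 0.33)),
             SeqRecord("q", random_seq(rng, 30_000, 0.33))]
        )
        assert map_contig("q", idx, ["t"])["t"].query_covered_frac <= 0.05


class TestIterativePurge:
    def test_small_copy_protected_by_length_rule(self, rng):
        a = random_seq(rng, 100_000, 0.33)
        contigs = [
            SeqRecord("A", a),
            SeqRecord("B", _mutate(a[:50_000], 0.03, rng)),
            SeqRecord("C", a[60_000:65_000]),  # 5 kb copy, never removed
        ]
        res = iterative_purge(contigs)
        assert res.kept_ids == {"A", "C"}
        assert res.removed_ids == {"B"}
        assert res.removed[0].evidence.query_covered_frac >= 0.30

    def test_no_pair_above_threshold_keeps_all(self, rng):
        contigs = [SeqRecord(f"c{i}", random_seq(rng, 15_000, 0.33)) for i in range(5)]
        res = iterative_purge(contigs)
        assert res.kept_ids == {c.id for c in contigs} and res.removed == []

    def test_identical_triplet_keeps_lexicographic_first(self, rng):
        s = random_seq(rng, 20_000, 0.33)
        res = iterative_purge([SeqRecord(n, s) for n in ("b", "a", "c")])
        assert res.kept_ids == {"a"}
        assert res.removed_ids == {"b", "c"}

    def test_masked_repeats_do_not_drive_removal(self, rng):
        from oysterkit.io_core import Feature

        rep = random_seq(rng, 12_000, 0.33)
        a = random_seq(rng, 10_000, 0.33) + rep + random_seq(rng, 10_000, 0.33)
        b = random_seq(rng, 4_000, 0.33) + rep + random_seq(rng, 4_000, 0.33)
        mask = [Feature("A", 10_000, 22_000, ".", "other"),
                Feature("B", 4_000, 16_000, ".", "other")]
        unmasked = iterative_purge([SeqRecord("A", a), SeqRecord("B", b)])
        masked = iterative_purge([SeqRecord("A", a), SeqRecord("B", b)], repeat_mask=mask)
        assert unmasked.removed_ids == {"B"}  # shared repeat drives removal
        assert masked.removed_ids == set()

    def test_matches_exact_alignment_oracle(self):
        rng = np.random.default_rng(17)
        contigs: list[SeqRecord] = []
        sources = [random_seq(rng, 20_000, 0.33) for _ in range(6)]
        for i, s in enumerate(sources):
            contigs.append(SeqRecord(f"src{i}", s))
        for i in range(8):  # haplotigs of various sources
            src = sources[i % 6]
            cut = rng.integers(0, 5000)
            frag = src[cut : cut + 12_000 + int(rng.integers(0, 4000))]
            contigs.append(SeqRecord(f"hap{i}", _mutate(frag, 0.03, rng)))
        for i in range(6):  # unrelated fill
            contigs.append(SeqRecord(f"rnd{i}", random_seq(rng, 12_000, 0.33)))
        assert len(contigs) == 20
        res = iterative_purge(contigs)
        assert res.removed_ids == oracle_purge(contigs)

    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_planted_truth_recovery(self, seed):
        contigs, truth = simulate_assembly(AssemblyConfig(), np.random.default_rng(seed))
        res = iterative_purge(contigs)
        hap_ids = {h.contig_id for h in truth.haplotigs}
        removed = res.removed_ids
        assert len(removed & hap_ids) >= 0.95 * len(hap_ids)
        false_big = {
            c for c in removed - hap_ids
            if len(next(r.seq for r in contigs if r.id == c)) > 10_000
        }
        assert false_big == set()
        # idempotence at identical thresholds
        kept = [c for c in contigs if c.id in res.kept_ids]
        assert iterative_purge(kept).removed == []


class TestIntersectKeepLists:
    def test_intersection_and_reasons(self):
        res = intersect_keep_lists({"x", "y"}, {"y", "z"}, {"x", "y", "z"})
        assert res.kept_ids == {"y"}
        assert {(r.contig_id, r.reason) for r in res.removed} == {
            ("x", "external_only"), ("z", "external_only")
        }

    def test_equal_lists_keep_everything(self):
        res = intersect_keep_lists({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert res.kept_ids == {"a", "b"} and res.removed == []

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            res = intersect_keep_lists({"a"}, {"b"}, {"a", "b"})
        assert res.kept_ids == set()

    def test_unknown_id_is_hard_error(self):
        with pytest.raises(ValueError):
            intersect_keep_lists({"a", "q"}, {"a"}, {"a"})
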