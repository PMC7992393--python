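"""Generator contracts: element structure, planting, determinism, truth."""

import numpy as np
import pytest
from scipy import stats

from oysterkit.heliscan import find_3prime_candidates, ScanParams
from oysterkit.helentron import find_subtir
from oysterkit.io_core import SeqRecord, revcomp
from oysterkit.simulate import (
    AssemblyConfig,
    ElementSpec,
    diploid_haplotypes,
    make_element,
    make_family_seed,
    plant_elements,
    random_seq,
    simulate_assembly,
    simulate_depth,
    simulate_markers,
    simulate_reads,
)


class TestMakeElement:
    def test_structure_and_purity(self, rng):
        spec = ElementSpec()
        for _ in range(20):
            seq, truth = make_element(spec, rng)
            assert seq.startswith("TC") and seq.endswith("CTAG")
            assert len(seq) == truth.length >= 200
            # internal TC would hijack nearest-upstream terminus pairing
            assert seq.find("TC", 1) == -1
            hp = truth.hairpin
            span = seq[hp.start : hp.end]
            assert 16 <= len(span) <= 20
            assert span == revcomp(span)  # planted hairpins are perfect palindromes
            gap = len(seq) - 4 - hp.end
            assert 2 <= gap <= 30

    def test_detector_fires_at_planted_terminus(self, rng):
        p = ScanParams()
        for _ in range(10):
            seq, _ = make_element(ElementSpec(), rng)
            host = "G" * 60 + seq + "G" * 60
            hits = find_3prime_candidates(
                host,
                hairpin_gap=p.hairpin_gap,
                span_range=p.span_range,
                min_stem=p.min_stem,
                max_mismatch=p.max_mismatch,
                max_loop=p.max_loop,
                min_stem_gc=p.min_stem_gc,
            )
            assert 60 + len(seq) in [pos for pos, _ in hits]

    def test_length_distribution_matches_truncated_normal(self):
        rng = np.random.default_rng(7)
        spec = ElementSpec()
        lengths = [make_element(spec, rng)[1].length for _ in range(10_000)]
        se = spec.length_sd / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - spec.length_mean_truncated()) < 3 * se

    def test_no_subtir_when_disabled(self, rng):
        spec = ElementSpec(with_subtir=0.0)
        for _ in range(10):
            seq, truth = make_element(spec, rng)
            assert truth.subtir is None

    def test_inconsistent_ranges_rejected(self):
        with pytest.raises(ValueError):
            ElementSpec(hairpin_gap_to_3prime=(10, 2))
        with pytest.raises(ValueError):
            ElementSpec(p_at_site=1.5)

    def test_family_members_share_terminal_30(self, rng):
        seed = make_family_seed(rng)
        spec = ElementSpec(family_seed_3prime=seed)
        for _ in range(5):
            seq, _ = make_element(spec, rng)
            assert seq[-30:] == seed


class TestPlantElements:
    def test_degenerate_at_probability(self, rng):
        host = SeqRecord("h", random_seq(rng, 120_000, 0.33))
        _, planted = plant_elements(host, 50, ElementSpec(p_at_site=1.0), rng)
        assert len(planted) == 50
        assert all(p.at_site for p in planted)

    def test_zero_elements_leaves_host_unchanged(self, rng):
        host = SeqRecord("h", random_seq(rng, 1000, 0.33))
        out, planted = plant_elements(host, 0, ElementSpec(), rng)
        assert out.seq == host.seq and planted == []

    def test_truth_intervals_and_flanks(self, rng):
        host = SeqRecord("h", random_seq(rng, 100_000, 0.33))
        out, planted = plant_elements(host, 30, ElementSpec(), rng)
        prev_end = 0
        for p in sorted(planted, key=lambda x: x.start):
            assert prev_end <= p.start < p.end <= len(out.seq)
            prev_end = p.end
            elem = out.seq[p.start : p.end]
            if p.strand == "-":
                elem = revcomp(elem)
            assert elem.startswith("TC") and elem.endswith("CTAG")
            is_at = out.seq[p.start - 1] == "A" and out.seq[p.end] == "T"
            assert is_at == p.at_site

    def test_at_fraction_within_binomial_ci(self):
        rng = np.random.default_rng(42)
        host = SeqRecord("h", random_seq(rng, 800_000, 0.33))
        _, planted = plant_elements(
            host, 300, ElementSpec(p_at_site=0.86), rng
        )
        k = sum(p.at_site for p in planted)
        lo, hi = stats.binom.ppf([0.005, 0.995], 300, 0.86)
        assert lo <= k <= hi

    def test_overcrowded_host_errors(self, rng):
        host = SeqRecord("h", random_seq(rng, 2000, 0.33))
        with pytest.raises(ValueError):
            plant_elements(host, 1500, ElementSpec(), rng)


class TestAssembly:
    def test_same_seed_is_byte_identical(self):
        a, ta = simulate_assembly(AssemblyConfig(), np.random.default_rng(5))
        b, tb = simulate_assembly(AssemblyConfig(), np.random.default_rng(5))
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]
        assert ta.features == tb.features

    def test_haplotigs_are_divergent_subsequences(self):
        cfg = AssemblyConfig()
        contigs, truth = simulate_assembly(cfg, np.random.default_rng(6))
        by_id = {c.id: c.seq for c in contigs}
        for h in truth.haplotigs:
            src = by_id[h.source_id][h.src_start : h.src_end]
            hap = by_id[h.contig_id]
            assert len(src) == len(hap)
            mism = sum(1 for x, y in zip(src, hap) if x != y)
            assert 0 < mism / len(src) < 2.5 * cfg.haplotig_divergence

    def test_features_lie_within_chromosomes(self):
        _, truth = simulate_assembly(AssemblyConfig(), np.random.default_rng(8))
        for f in truth.features:
            assert 0 <= f.start < f.end <= truth.chrom_lengths[f.seq_id]

    def test_excess_density_rejected(self):
        with pytest.raises(ValueError):
            simulate_assembly(
                AssemblyConfig(gene_per_100kb=100.0), np.random.default_rng(1)
            )


class TestDepthReadsMarkers:
    def test_unbiased_depth_mean(self, rng):
        recs = [SeqRecord("s", random_seq(rng, 50_000, 0.33))]
        tracks = simulate_depth(recs, rng, mean_depth=30, gc_bias_slope=0.0)
        d = tracks[0].depths
        assert np.all(d >= 0)
        se = np.sqrt(30 / len(d))
        assert abs(np.mean(d) - 30) < 3 * se

    def test_junk_scaffold_depth_is_depressed(self, rng):
        recs = [
            SeqRecord("ok", random_seq(rng, 20_000, 0.33)),
            SeqRecord("junk", random_seq(rng, 20_000, 0.33)),
        ]
        tracks = simulate_depth(recs, rng, mean_depth=30, junk_ids=["junk"])
        means = {t.seq_id: np.mean(t.depths) for t in tracks}
        assert means["junk"] < 0.2 * means["ok"]

    def test_reads_deterministic_and_error_free_match_haplotypes(self):
        g = random_seq(np.random.default_rng(3), 5000, 0.33)
        h1, h2 = diploid_haplotypes(g, 0.02, np.random.default_rng(4))
        r1 = simulate_reads([h1, h2], np.random.default_rng(9), depth=5)
        r2 = simulate_reads([h1, h2], np.random.default_rng(9), depth=5)
        assert r1 == r2
        for read in r1[:50]:
            assert read in h1 or read in h2 or revcomp(read) in h1 or revcomp(read) in h2

    def test_noise_free_markers_are_monotone(self):
        markers, scaffolds = simulate_markers(
            {"chr1": 200_000}, np.random.default_rng(2), cm_noise_sd=0.0
        )
        orient = {s.scaffold_id: s.orientation for s in scaffolds}
        for s in {m.aln_seq_id for m in markers}:
            ms = sorted(
                (m for m in markers if m.aln_seq_id == s), key=lambda m: m.aln_pos
            )
            cms = [m.cm for m in ms]
            rho = stats.spearmanr(range(len(cms)), cms).statistic
            assert rho == (1.0 if orient[s] == 1 else -1.0)

    def test_min_markers_enforced(self):
        with pytest.raises(ValueError):
            simulate_markers({"c": 1000}, np.random.default_rng(1), markers_per_scaffold=1)
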