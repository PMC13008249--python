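"""Loop-TSS linking, anchor classification, pair configurations, matching."""

import numpy as np
import pytest

import chromalink as cl
from chromalink.errors import ValidationError
from chromalink.intervals import Anchor, GenomicInterval, TSSRecord, TSSTable
from chromalink.loops import TSSWindow, TSSWindows
from chromalink.simulate import LoopSpec, SimulationConfig, gen_genome_and_genes, gen_loops

from conftest import make_loopset, make_peakset, random_intervals
from oracles import brute_classify_flags, brute_link, brute_match_loopsets


def tss_table(rows):
    return TSSTable([TSSRecord(g, c, strand, t) for g, c, strand, t in rows])


class TestMakeTssWindows:
    def test_plus_strand(self):
        win = cl.make_tss_windows(tss_table([("g1", "chr1", "+", 10_000)]))
        assert win.windows[0].interval == GenomicInterval("chr1", 5_000, 11_000)

    def test_minus_strand_mirror(self):
        win = cl.make_tss_windows(tss_table([("g1", "chr1", "-", 10_000)]))
        assert win.windows[0].interval == GenomicInterval("chr1", 9_000, 15_000)

    def test_clipping_at_chrom_start(self):
        win = cl.make_tss_windows(tss_table([("g1", "chr1", "+", 2_000)]))
        assert win.windows[0].interval == GenomicInterval("chr1", 0, 3_000)

    def test_clipping_at_chrom_end_with_genome(self):
        genome = cl.Genome({"chr1": 10_500})
        win = cl.make_tss_windows(tss_table([("g1", "chr1", "-", 10_000)]), genome=genome)
        assert win.windows[0].interval == GenomicInterval("chr1", 9_000, 10_500)

    def test_strand_ignorant_mode(self):
        win = cl.make_tss_windows(tss_table([("g1", "chr1", "-", 10_000)]), strand_aware=False)
        assert win.windows[0].interval == GenomicInterval("chr1", 5_000, 11_000)

    def test_tss_outside_chromosome_errors(self):
        genome = cl.Genome({"chr1": 5_000})
        with pytest.raises(ValidationError, match="beyond"):
            cl.make_tss_windows(tss_table([("g1", "chr1", "+", 9_000)]), genome=genome)

    def test_degenerate_extents_rejected(self):
        with pytest.raises(ValidationError):
            cl.make_tss_windows(tss_table([("g1", "chr1", "+", 100)]), 0, 0)


def simple_windows(entries):
    return TSSWindows([TSSWindow(g, GenomicInterval(c, s, e)) for g, c, s, e in entries])


class TestLinkLoopsToTss:
    def test_anchor_in_window_links(self):
        loops = make_loopset([(("chr1", 5_500, 6_500), ("chr1", 100_000, 101_000))])
        windows = simple_windows([("g1", "chr1", 5_000, 11_000)])
        report = cl.link_loops_to_tss(loops, windows)
        assert report.n_loops_linked == 1
        assert report.gene_to_loops == {"g1": ["L0"]}
        assert report.loop_to_genes == {"L0": ["g1"]}

    def test_far_loop_not_retained(self):
        loops = make_loopset([(("chr1", 500_000, 501_000), ("chr1", 900_000, 901_000))])
        windows = simple_windows([("g1", "chr1", 5_000, 11_000)])
        assert cl.link_loops_to_tss(loops, windows).n_loops_linked == 0

    def test_planted_attachment_recovered_exactly(self):
        cfg = SimulationConfig(seed=3, loops=LoopSpec(n_loops=50, q_tss=0.35))
        genome, tss = gen_genome_and_genes(cfg)
        loops, _, _, truth = gen_loops(cfg, genome, tss)
        windows = cl.make_tss_windows(tss, genome=genome)
        report = cl.link_loops_to_tss(loops, windows)
        attached = {k for k, v in truth.loop_attached_gene.items() if v}
        assert {lp.loop_id for lp in report.retained_loops} == attached
        # each retained loop maps to exactly its planted gene
        for loop_id, genes in report.loop_to_genes.items():
            assert genes == [truth.loop_attached_gene[loop_id]]

    def test_equals_brute_force(self, rng):
        for _ in range(25):
            pairs = [
                (a, b)
                for a, b in zip(
                    random_intervals(rng, 40, max_pos=30_000),
                    random_intervals(rng, 40, max_pos=30_000),
                )
            ]
            win_ivs = random_intervals(rng, 15, max_pos=30_000, max_width=2_000)
            loops = make_loopset(pairs)
            windows = simple_windows(
                [(f"g{i}", c, s, e) for i, (c, s, e) in enumerate(win_ivs)]
            )
            report = cl.link_loops_to_tss(loops, windows)
            # canonicalization may reorder anchors; brute force is order-blind
            canon = [
                (
                    (l.anchor1.interval.chrom, l.anchor1.interval.start, l.anchor1.interval.end),
                    (l.anchor2.interval.chrom, l.anchor2.interval.start, l.anchor2.interval.end),
                )
                for l in loops
            ]
            want = {loops.loops[i].loop_id for i in brute_link(canon, win_ivs)}
            assert {lp.loop_id for lp in report.retained_loops} == want


class TestClassifyAnchor:
    grhl2 = make_peakset([("chr1", 100, 300)], "GRHL2")
    pr = make_peakset([("chr1", 250, 500)], "PR")
    windows = simple_windows([("g1", "chr1", 400, 900)])

    @pytest.mark.parametrize(
        "start, end, category",
        [
            (90, 120, "GRHL2"),
            (450, 460, "PR+TSS"),
            (260, 290, "GRHL2+PR"),
            (200, 600, "GRHL2+PR+TSS"),
            (10_000, 10_100, "Other"),
            (600, 700, "TSS"),
        ],
    )
    def test_categories(self, start, end, category):
        ann = cl.classify_anchor(
            Anchor(GenomicInterval("chr1", start, end), 1), self.grhl2, self.pr, self.windows
        )
        assert ann.category == category
        assert (ann.category == "Other") == (
            not (ann.has_grhl2 or ann.has_pr or ann.has_tss)
        )

    def test_agrees_with_independent_overlap_scans(self, rng):
        grhl2_ivs = random_intervals(rng, 60, max_pos=20_000)
        pr_ivs = random_intervals(rng, 60, max_pos=20_000)
        win_ivs = random_intervals(rng, 30, max_pos=20_000, max_width=2_000)
        grhl2 = make_peakset(grhl2_ivs, "GRHL2")
        pr = make_peakset(pr_ivs, "PR")
        windows = simple_windows([(f"g{i}", c, s, e) for i, (c, s, e) in enumerate(win_ivs)])
        for iv in random_intervals(rng, 150, max_pos=20_000):
            ann = cl.classify_anchor(Anchor(GenomicInterval(*iv), 1), grhl2, pr, windows)
            assert (ann.has_grhl2, ann.has_pr, ann.has_tss) == brute_classify_flags(
                iv, grhl2_ivs, pr_ivs, win_ivs
            )


class TestAnchorCategoryTable:
    def _annotated_report(self, cfg_seed=5, n_loops=60, q_tss=0.5):
        cfg = SimulationConfig(seed=cfg_seed, loops=LoopSpec(n_loops=n_loops, q_tss=q_tss))
        genome, tss = gen_genome_and_genes(cfg)
        loops, grhl2, pr, truth = gen_loops(cfg, genome, tss)
        windows = cl.make_tss_windows(tss, genome=genome)
        report = cl.annotate_anchors(cl.link_loops_to_tss(loops, windows), grhl2, pr, windows)
        return report, truth

    def test_two_anchors_per_retained_loop(self):
        report, _ = self._annotated_report()
        table = cl.anchor_category_table(report)
        assert table["n_anchors"] == 2 * report.n_loops_linked
        assert sum(table["counts"].values()) == table["n_anchors"]

    def test_empty_report(self):
        loops = make_loopset([(("chr1", 0, 100), ("chr1", 5_000, 5_100))])
        windows = simple_windows([("g1", "chr2", 0, 1_000)])
        report = cl.link_loops_to_tss(loops, windows)
        table = cl.anchor_category_table(report)
        assert table["n_anchors"] == 0 and sum(table["counts"].values()) == 0

    def test_planted_configuration_counts_exact(self):
        report, truth = self._annotated_report()
        by_loop = {}
        for ann in report.annotations:
            by_loop.setdefault(ann.loop_id, []).append(ann.pair_label)
        for loop_id, labels in by_loop.items():
            assert sorted(labels) == truth.loop_configs[loop_id]


class TestPairConfigurationTable:
    def _report(self, mixture, n_loops=120, seed=11, q_tss=1.0):
        cfg = SimulationConfig(
            seed=seed, loops=LoopSpec(n_loops=n_loops, q_tss=q_tss, config_mixture=mixture)
        )
        genome, tss = gen_genome_and_genes(cfg)
        loops, grhl2, pr, truth = gen_loops(cfg, genome, tss)
        windows = cl.make_tss_windows(tss, genome=genome)
        report = cl.annotate_anchors(cl.link_loops_to_tss(loops, windows), grhl2, pr, windows)
        return report, truth

    def test_pr_filter_and_cobound_fraction_match_plant(self):
        mixture = {
            ("GRHL2+PR", "PR"): 0.4,
            ("GRHL2", "Other"): 0.3,
            ("PR", "Other"): 0.3,
        }
        report, truth = self._report(mixture)
        result = cl.pair_configuration_table(report, require_pr_anchor=True)
        retained = {lp.loop_id for lp in report.retained_loops}
        planted_pr = {
            k
            for k in retained
            if any(lbl in ("PR", "GRHL2+PR") for lbl in truth.loop_configs[k])
        }
        assert result.n_loops == len(planted_pr)
        planted_cobound = {
            k for k in planted_pr if "GRHL2+PR" in truth.loop_configs[k]
        }
        assert result.frac_cobound_anchor == pytest.approx(
            len(planted_cobound) / len(planted_pr)
        )
        # counts per unordered pair equal the planted multinomial assignment
        from collections import Counter

        planted_counts = Counter(tuple(truth.loop_configs[k]) for k in planted_pr)
        got_counts = {c.pair_label: c.count for c in result.configurations}
        assert got_counts == dict(planted_counts)

    def test_frequencies_sum_to_one(self):
        report, _ = self._report(
            {("GRHL2+PR", "PR"): 0.5, ("GRHL2", "PR"): 0.5}, n_loops=40
        )
        result = cl.pair_configuration_table(report)
        assert sum(c.frequency for c in result.configurations) == pytest.approx(1.0)

    def test_removing_pr_filter_never_decreases_counts(self):
        report, _ = self._report(
            {("GRHL2+PR", "PR"): 0.3, ("GRHL2", "Other"): 0.4, ("Other", "Other"): 0.3}
        )
        with_filter = {
            c.pair_label: c.count
            for c in cl.pair_configuration_table(report, True).configurations
        }
        without = {
            c.pair_label: c.count
            for c in cl.pair_configuration_table(report, False).configurations
        }
        for pair, n in with_filter.items():
            assert without.get(pair, 0) >= n

    def test_all_other_mixture_is_empty_under_filter(self):
        report, _ = self._report({("Other", "Other"): 1.0}, n_loops=25)
        result = cl.pair_configuration_table(report, require_pr_anchor=True)
        assert result.n_loops == 0 and result.configurations == []


class TestMatchLoopsets:
    def test_identical_sets_fully_shared(self):
        pairs = [(("chr1", 0, 1_000), ("chr1", 50_000, 51_000))]
        m = cl.match_loopsets(make_loopset(pairs), make_loopset(pairs))
        assert m.n_a_only == 0 and m.n_b_only == 0 and m.n_shared == 1

    def test_disjoint_sets(self):
        a = make_loopset([(("chr1", 0, 1_000), ("chr1", 50_000, 51_000))])
        b = make_loopset([(("chr1", 5_000, 6_000), ("chr1", 90_000, 91_000))])
        m = cl.match_loopsets(a, b)
        assert m.n_shared == 0 and m.n_a_only == 1 and m.n_b_only == 1

    def test_one_anchor_overlap_is_not_enough(self):
        a = make_loopset([(("chr1", 0, 1_000), ("chr1", 50_000, 51_000))])
        b = make_loopset([(("chr1", 0, 1_000), ("chr1", 90_000, 91_000))])
        assert cl.match_loopsets(a, b).n_shared == 0

    def test_symmetry_and_brute_force(self, rng):
        for _ in range(25):
            def rand_pairs(n):
                out = []
                for _ in range(n):
                    c = f"chr{rng.integers(1, 3)}"
                    s1 = int(rng.integers(0, 30_000))
                    s2 = s1 + int(rng.integers(2_000, 20_000))
                    w = int(rng.integers(200, 3_000))
                    out.append(((c, s1, s1 + w), (c, s2, s2 + w)))
                return out

            a_pairs, b_pairs = rand_pairs(int(rng.integers(1, 60))), rand_pairs(int(rng.integers(1, 60)))
            a, b = make_loopset(a_pairs), make_loopset(b_pairs)
            m = cl.match_loopsets(a, b)
            canon = lambda ls: [
                (
                    (l.anchor1.interval.chrom, l.anchor1.interval.start, l.anchor1.interval.end),
                    (l.anchor2.interval.chrom, l.anchor2.interval.start, l.anchor2.interval.end),
                )
                for l in ls
            ]
            want = brute_match_loopsets(canon(a), canon(b))
            assert (m.n_a_only, m.n_b_only, m.n_shared) == want
            back = cl.match_loopsets(b, a)
            assert back.n_shared == m.n_shared
            assert (back.n_a_only, back.n_b_only) == (m.n_b_only, m.n_a_only)


class TestSpanSummary:
    def test_fifty_kb_example(self):
        loops = make_loopset([(("chr1", 1_000, 2_000), ("chr1", 51_000, 52_000))])
        summary = cl.span_summary(loops)
        assert summary.spans_bp["L0"] == 50_000
        assert summary.max_span_bp == 50_000
        assert summary.histogram["50-100"] == 1

    def test_degenerate_loop_flagged(self):
        loops = make_loopset([(("chr1", 0, 1_000), ("chr1", 0, 1_000))])
        with pytest.warns(UserWarning, match="degenerate"):
            summary = cl.span_summary(loops)
        assert summary.n_degenerate == 1

    def test_empty_set_errors(self):
        with pytest.raises(ValidationError):
            cl.span_summary(cl.LoopSet("x", []))

    def test_loguniform_sample_bounded_and_binned(self):
        cfg = SimulationConfig(seed=9, loops=LoopSpec(n_loops=300, q_tss=0.0))
        genome, tss = gen_genome_and_genes(cfg)
        loops, _, _, _ = gen_loops(cfg, genome, tss)
        summary = cl.span_summary(loops)
        spans_kb = np.array(list(summary.spans_bp.values())) / 1000
        assert summary.max_span_bp <= 500_000 and spans_kb.min() >= 20
        assert sum(summary.histogram.values()) == len(loops)
        # log-uniform on [20, 500]: expected bin mass proportional to log width
        log_width = np.log(500) - np.log(20)
        for label, lo, hi in (("20-50", 20, 50), ("50-100", 50, 100), ("100-200", 100, 200), ("200-500", 200, 500)):
            expect = len(loops) * (np.log(hi) - np.log(lo)) / log_width
            sd = np.sqrt(expect)
            assert abs(summary.histogram[label] - expect) < 4 * sd + 1
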