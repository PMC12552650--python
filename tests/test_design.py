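"""Guide enumeration, CFD scoring, filters, selection and assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirscreen.annotation import GenomicInterval, RegionMap, reverse_complement
from mirscreen import design
from mirscreen.design import (
    CfdPenaltyTable,
    CfdTableError,
    ControlGeneSet,
    GuideCandidate,
    OffTargetSite,
    apply_design_filters,
    assemble_library,
    cfd_score,
    choose_control_genes,
    design_dko_pair,
    enumerate_candidates,
    enumerate_off_targets,
    pad_non_targeting,
    select_guides_for_hairpin,
)
from mirscreen.simulate import make_cfd_table


def _cand(proto, cut=100, strand="+", region="stem5p", score=0.5, sites=(), pam="AGG"):
    return GuideCandidate(
        protospacer=proto, pam=pam, chrom="c", cut_site=cut, strand=strand,
        region_class=region, on_target_score=score, off_target_sites=tuple(sites),
    )


def _site(cfd, coding=True):
    return OffTargetSite(GenomicInterval("c", 0, 20), 1, cfd, coding)


def brute_force_pam_scan(seq, window, pam="NGG"):
    """Oracle: literal scan of both strands for 20-mer + NGG."""
    hits = []
    for i in range(len(seq) - 22):
        if seq[i + 21 : i + 23] == "GG" and set(seq[i : i + 23]) <= set("ACGT"):
            hits.append(("+", seq[i : i + 20], window.start + i + 17))
        if seq[i : i + 2] == "CC" and set(seq[i : i + 23]) <= set("ACGT"):
            hits.append(("-", reverse_complement(seq[i + 3 : i + 23]), window.start + i + 6))
    return sorted(hits)


class TestEnumerateCandidates:
    def test_single_plus_strand_pam(self):
        window = GenomicInterval("c", 50, 73)
        cands = enumerate_candidates("A" * 20 + "AGG", window)
        assert len(cands) == 1
        assert cands[0].cut_site == 50 + 17
        assert cands[0].strand == "+"

    def test_ccn_start_gives_minus_strand_candidate(self):
        rng = np.random.default_rng(3)
        seq = "CCA" + "".join(rng.choice(list("ACT"), size=20))
        window = GenomicInterval("c", 0, 23)
        cands = enumerate_candidates(seq, window)
        minus = [c for c in cands if c.strand == "-"]
        assert len(minus) == 1
        assert minus[0].protospacer == reverse_complement(seq[3:23])
        assert minus[0].cut_site == 6

    def test_no_pam_empty(self):
        assert enumerate_candidates("ACATACATACATACATACATACA", GenomicInterval("c", 0, 23)) == []

    def test_ambiguous_bases_skip_candidate(self):
        seq = "N" * 20 + "AGG"
        assert enumerate_candidates(seq, GenomicInterval("c", 0, 23)) == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=23, max_size=60))
    def test_matches_brute_force_scan(self, seq):
        window = GenomicInterval("c", 10, 10 + len(seq))
        got = sorted((c.strand, c.protospacer, c.cut_site)
                     for c in enumerate_candidates(seq, window))
        assert got == brute_force_pam_scan(seq, window)


class TestCfdScore:
    TABLE = CfdPenaltyTable(
        mismatch={(5, "A", "G"): 0.6, (12, "C", "T"): 0.5},
        pam={"AGG": 1.0, "TAG": 0.26},
    )

    def test_perfect_match_scores_one(self):
        g = "A" * 20
        assert cfd_score(g, g, "AGG", self.TABLE) == 1.0

    def test_single_mismatch_factor(self):
        g = "A" * 20
        site = g[:4] + "G" + g[5:]
        assert cfd_score(g, site, "AGG", self.TABLE) == pytest.approx(0.6)

    def test_two_mismatch_product(self):
        g = "A" * 11 + "C" + "A" * 8
        site = g[:4] + "G" + g[5:11] + "T" + g[12:]
        assert cfd_score(g, site, "AGG", self.TABLE) == pytest.approx(0.30)

    def test_pam_penalty_multiplies(self):
        g = "A" * 20
        assert cfd_score(g, g, "TAG", self.TABLE) == pytest.approx(0.26)

    def test_missing_key_raises_naming_key(self):
        g = "A" * 20
        site = "C" + g[1:]
        with pytest.raises(CfdTableError, match="position=1 guide_base=A site_base=C"):
            cfd_score(g, site, "AGG", self.TABLE)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=20), st.integers(0, 2**31 - 1))
    def test_all_single_and_double_mismatch_variants_match_oracle(self, guide, seed):
        """Exhaustive single-mismatch (and sampled double-mismatch) product oracle."""
        table = make_cfd_table(0)
        for pos in range(20):
            for b in "ACGT":
                if b == guide[pos]:
                    continue
                site = guide[:pos] + b + guide[pos + 1 :]
                expected = table.mismatch[(pos + 1, guide[pos], b)]
                assert cfd_score(guide, site, "AGG", table) == pytest.approx(expected)
        rng = np.random.default_rng(seed)
        for _ in range(10):
            p1, p2 = sorted(rng.choice(20, size=2, replace=False))
            b1 = "ACGT"[(("ACGT".index(guide[p1])) + 1) % 4]
            b2 = "ACGT"[(("ACGT".index(guide[p2])) + 1) % 4]
            site = guide[:p1] + b1 + guide[p1 + 1 : p2] + b2 + guide[p2 + 1 :]
            expected = (
                table.mismatch[(p1 + 1, guide[p1], b1)]
                * table.mismatch[(p2 + 1, guide[p2], b2)]
            )
            assert cfd_score(guide, site, "AGG", table) == pytest.approx(expected)


class TestOffTargets:
    def test_planted_exact_duplicate_found_with_cfd_one(self):
        table = make_cfd_table(0)
        proto = "ACGTACGTACGTACGTACGT"
        genome = {"c": "T" * 30 + proto + "AGG" + "T" * 30 + proto + "TGG" + "T" * 10}
        guide = GuideCandidate(protospacer=proto, pam="AGG", chrom="c",
                               cut_site=30 + 17, strand="+")
        sites = enumerate_off_targets(guide, genome, 0, table)
        assert len(sites) == 1
        assert sites[0].mismatch_count == 0 and sites[0].cfd == 1.0

    def test_two_mismatch_decoy_scores_penalty_product(self):
        table = make_cfd_table(0)
        proto = "ACGTACGTACGTACGTACGT"
        decoy = "TCGTACGTACGTACGTACGA"
        genome = {"c": "T" * 30 + proto + "AGG" + "TT" + decoy + "AGG" + "TT"}
        guide = GuideCandidate(protospacer=proto, pam="AGG", chrom="c",
                               cut_site=30 + 17, strand="+")
        sites = [s for s in enumerate_off_targets(guide, genome, 2, table)
                 if s.mismatch_count == 2]
        expected = table.mismatch[(1, "A", "T")] * table.mismatch[(20, "T", "A")]
        assert len(sites) == 1
        assert sites[0].cfd == pytest.approx(expected)

    def test_no_duplicates_no_sites_at_zero_mismatches(self):
        table = make_cfd_table(0)
        proto = "ACGTACGTACGTACGTACGT"
        genome = {"c": "T" * 30 + proto + "AGG" + "T" * 30}
        guide = GuideCandidate(protospacer=proto, pam="AGG", chrom="c",
                               cut_site=30 + 17, strand="+")
        assert enumerate_off_targets(guide, genome, 0, table) == []


class TestDesignFilters:
    def test_low_on_target_excluded(self):
        kept, excl = apply_design_filters([_cand("A" * 20, score=0.19)])
        assert kept == [] and excl[0].reason == "on_target"

    def test_bin1_over_three_excluded(self):
        sites = [_site(1.0)] * 4
        kept, excl = apply_design_filters([_cand("A" * 20, score=0.9, sites=sites)])
        assert kept == [] and excl[0].reason == "off_target"

    def test_boundaries_are_kept(self):
        sites = [_site(1.0)] * 3
        kept, excl = apply_design_filters([_cand("A" * 20, score=0.2, sites=sites)])
        assert len(kept) == 1 and excl == []

    def test_unscored_never_silently_kept(self):
        kept, excl = apply_design_filters([_cand("A" * 20, score=None)])
        assert kept == [] and excl[0].reason == "unscored"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.one_of(st.none(), st.floats(0, 1)), st.integers(0, 6)),
        max_size=20,
    ))
    def test_partition_with_single_reason(self, specs):
        cands = [
            _cand("A" * 19 + "ACGT"[i % 4], cut=i, score=s,
                  sites=[_site(1.0)] * b)
            for i, (s, b) in enumerate(specs)
        ]
        kept, excl = apply_design_filters(cands)
        assert len(kept) + len(excl) == len(cands)
        assert all(e.reason in ("unscored", "on_target", "off_target") for e in excl)


class TestSelection:
    RM = RegionMap("H", tuple(["stem5p"] * 30 + ["loop"] * 20 + ["stem3p"] * 30))

    def test_stem_guides_selected_before_loop(self):
        stems = [_cand(f"{b}AAAAAAAAAAAAAAAAAAA", region="stem5p", score=s)
                 for b, s in zip("ACG", (0.3, 0.4, 0.5))]
        loops = [_cand(f"T{b}AAAAAAAAAAAAAAAAAA", region="loop", score=s)
                 for b, s in zip("AC", (0.9, 0.8))]
        sel = select_guides_for_hairpin(stems + loops, self.RM)
        assert len(sel.guides) == 4
        assert [g.region_class for g in sel.guides[:3]] == ["stem5p"] * 3
        assert sel.guides[3].on_target_score == 0.9  # best loop guide

    def test_fewer_than_minimum_excludes_hairpin(self):
        sel = select_guides_for_hairpin(
            [_cand("A" * 20, score=0.9), _cand("C" + "A" * 19, score=0.9)], self.RM
        )
        assert sel.excluded

    def test_deterministic_top_four_of_six(self):
        cands = [_cand(b * 20, region="stem3p", score=s)
                 for b, s in zip("ACGTAC", (0.9, 0.8, 0.7, 0.6, 0.5, 0.4))]
        # duplicate protospacers differ by cut to stay distinct objects
        cands = [design.GuideCandidate(
            protospacer=c.protospacer, pam=c.pam, chrom="c", cut_site=i,
            strand="+", region_class=c.region_class, on_target_score=c.on_target_score)
            for i, c in enumerate(cands)]
        sel1 = select_guides_for_hairpin(cands, self.RM)
        sel2 = select_guides_for_hairpin(list(reversed(cands)), self.RM)
        assert [g.protospacer for g in sel1.guides] == [g.protospacer for g in sel2.guides]
        assert [g.on_target_score for g in sel1.guides] == [0.9, 0.8, 0.7, 0.6]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["stem5p", "loop", "stem3p"]),
                              st.floats(0, 1)), min_size=3, max_size=12))
    def test_never_prefers_loop_over_available_stem(self, specs):
        cands = [
            _cand("".join("ACGT"[(i >> (2 * k)) & 3] for k in range(10)) + "A" * 10,
                  cut=i, region=r, score=s)
            for i, (r, s) in enumerate(specs)
        ]
        sel = select_guides_for_hairpin(cands, self.RM)
        if not sel.excluded:
            chosen = sel.guides
            if any(g.region_class == "loop" for g in chosen):
                unchosen_stem = [c for c in cands if c not in chosen
                                 and c.region_class != "loop"]
                assert not unchosen_stem


class TestControlsAndPadding:
    def test_four_gene_example(self):
        cs = choose_control_genes([{"A": 50, "B": 10, "C": -5, "D": -40}], 1, 1)
        assert cs.essential_genes == ("A",) and cs.nonessential_genes == ("D",)

    def test_conflicting_tables_resolved_by_mean(self):
        t1 = {"A": 10, "B": 30, "C": 0, "D": -10, "E": -30, "F": 5}
        t2 = {"A": 40, "B": 0, "C": 2, "D": -30, "E": -10, "F": 5}
        cs = choose_control_genes([t1, t2], 2, 2)
        assert cs.essential_genes == ("A", "B")  # means 25, 15
        assert cs.nonessential_genes == ("D", "E")  # means -20, -20 tie -> lexicographic

    def test_tie_at_boundary_lexicographic(self):
        cs = choose_control_genes([{"A": 5, "B": 5, "C": -5, "D": -5}], 1, 1)
        assert cs.essential_genes == ("A",) and cs.nonessential_genes == ("C",)

    def test_insufficient_genes_error(self):
        with pytest.raises(ValueError):
            choose_control_genes([{"A": 1, "B": 2}], 2, 2)

    def test_padding_reproduces_published_count(self):
        pool = [f"NT{i:04d}" for i in range(200)]
        assert len(pad_non_targeting(7332, 0.01, pool, seed=0)) == 74

    def test_padding_small_library(self):
        pool = [f"NT{i:04d}" for i in range(10)]
        assert len(pad_non_targeting(99, 0.01, pool, seed=0)) == 1

    def test_zero_fraction_empty(self):
        assert pad_non_targeting(1000, 0.0, [], seed=0) == []

    def test_pool_too_small_reports_required(self):
        with pytest.raises(ValueError, match="74"):
            pad_non_targeting(7332, 0.01, ["NT1"], seed=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(50, 20000))
    def test_padding_fraction_integer_optimal(self, n_other):
        pool = [f"NT{i:05d}" for i in range(300)]
        k = len(pad_non_targeting(n_other, 0.01, pool, seed=1))
        assert abs(k - 0.01 * n_other / 0.99) <= 0.5  # closest integer count
        if n_other >= 2000:  # at library scale the fraction lands within 0.1 pp
            assert abs(k / (n_other + k) - 0.01) <= 0.001


class TestDkoPair:
    def _c(self, cut, proto):
        return GuideCandidate(protospacer=proto, pam="AGG", chrom="c",
                              cut_site=cut, strand="+")

    def test_innermost_flanking_pair(self):
        target = GenomicInterval("c", 100, 145)
        cands = [self._c(70, "A" * 20), self._c(95, "C" * 20),
                 self._c(153, "G" * 20), self._c(185, "T" * 20)]
        pair = design_dko_pair(target, cands)
        assert (pair.left_guide.cut_site, pair.right_guide.cut_site) == (95, 153)
        # exhaustive oracle: minimal excision among all flanking pairs
        best = min((r.cut_site - l.cut_site)
                   for l in cands if l.cut_site < 100
                   for r in cands if r.cut_site > 145)
        assert len(pair.excised_interval) == best

    def test_missing_side_is_error(self):
        target = GenomicInterval("c", 100, 145)
        with pytest.raises(ValueError, match="right"):
            design_dko_pair(target, [self._c(70, "A" * 20)])

    def test_excision_spans_target(self):
        target = GenomicInterval("c", 100, 145)
        pair = design_dko_pair(target, [self._c(95, "C" * 20), self._c(153, "G" * 20)])
        assert pair.excised_interval.contains(target)
        assert pair.cassette_layout == ("gRNA", "tracrRNA", "U6", "gRNA")


def _selection(hid, protos, score=0.5):
    from mirscreen.design import HairpinSelection
    return HairpinSelection(hid, [
        _cand(p, cut=i, region="stem5p", score=score) for i, p in enumerate(protos)
    ])


def _unique_protos(n, seed=0):
    from mirscreen.simulate import random_protospacers
    return random_protospacers(n, np.random.default_rng(seed))


class TestAssembleLibrary:
    def test_fixture_composition_arithmetic(self):
        protos = iter(_unique_protos(30))
        sels = [
            _selection("H1", [next(protos) for _ in range(4)]),
            _selection("H2", [next(protos) for _ in range(4)]),
            _selection("H3", [next(protos) for _ in range(3)]),
        ]
        cs = ControlGeneSet(("E1",), ("N1",))
        ctrl = {g: [_cand(next(protos), cut=i) for i in range(4)] for g in ("E1", "N1")}
        padding = pad_non_targeting(19, 0.01, [next(protos)], seed=0)
        m = assemble_library(sels, cs, ctrl, padding)
        assert m.composition["mirna"] == 11
        assert m.composition["essential_ctrl"] + m.composition["noness_ctrl"] == 8
        assert m.composition["non_targeting"] == 0

    def test_control_arm_of_200_genes_has_800_guides(self):
        protos = iter(_unique_protos(820))
        ess = tuple(f"E{i:03d}" for i in range(100))
        non = tuple(f"N{i:03d}" for i in range(100))
        ctrl = {g: [_cand(next(protos), cut=i) for i in range(4)] for g in ess + non}
        m = assemble_library([], ControlGeneSet(ess, non), ctrl, [])
        assert m.composition["essential_ctrl"] + m.composition["noness_ctrl"] == 800

    def test_duplicate_protospacer_collision_raises(self):
        p = "A" * 20
        sels = [_selection("H1", [p, "C" * 20, "G" * 20])]
        cs = ControlGeneSet(("E1",), ())
        ctrl = {"E1": [_cand(p, cut=9)]}
        with pytest.raises(ValueError, match="A" * 20):
            assemble_library(sels, cs, ctrl, [])

    def test_empty_selections_flagged(self):
        protos = iter(_unique_protos(10))
        ctrl = {"E1": [_cand(next(protos), cut=i) for i in range(4)]}
        m = assemble_library([], ControlGeneSet(("E1",), ()), ctrl, [next(protos)])
        assert m.report["zero_mirna_targets"]

    def test_byte_identical_manifest_across_reruns(self):
        protos = _unique_protos(30)
        def build():
            it = iter(protos)
            sels = [_selection("H1", [next(it) for _ in range(4)]),
                    _selection("H2", [next(it) for _ in range(3)])]
            ctrl = {"E1": [_cand(next(it), cut=i) for i in range(4)]}
            return assemble_library(sels, ControlGeneSet(("E1",), ()), ctrl,
                                    [next(it), next(it)], seed=7)
        assert build().to_tsv() == build().to_tsv()

    def test_published_totals_imply_64_three_guide_hairpins(self):
        from mirscreen.simulate import synthetic_manifest
        m = synthetic_manifest(seed=0)
        assert m.composition["mirna"] == 6532
        assert m.report["n_mirna_targets"] == 1649
        assert m.report["three_guide_targets"] == 4 * 1649 - 6532 == 64
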