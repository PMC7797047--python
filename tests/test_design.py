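"""Guide design: PAM scanning, filters, off-target rules, mutation series."""

import re
import warnings

import numpy as np
import pytest
from Bio.Seq import Seq

from titracrispr import (
    GeneTarget,
    LibrarySpec,
    apply_sequence_filters,
    compact_subset,
    make_negc,
    mutate_compounding,
    mutate_doubles,
    mutate_singles,
    scan_pam_candidates,
    screen_off_targets,
    select_parents,
)
from titracrispr.design import DOUBLE_MUT_PAIRS, SINGLE_MUT_POSITIONS, spacer_index

from conftest import GOOD_SPACER, make_parent


def _random_seq(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


class TestScanPam:
    def test_single_forced_motif(self):
        gene = GeneTarget("g", "CC" + "A" * 21)
        cands = scan_pam_candidates(gene)
        assert len(cands) == 1
        assert cands[0].pam_offset == 1
        assert cands[0].protospacer == "A" * 20
        assert cands[0].spacer == "T" * 20

    def test_no_c_means_no_candidates(self):
        gene = GeneTarget("g", "ATG" + "AGT" * 40)
        assert all("CC" not in gene.cds[i : i + 2] for i in range(len(gene.cds)))
        assert scan_pam_candidates(gene) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_count_matches_regex_scan_oracle(self, seed):
        cds = "ATG" + _random_seq(497, seed)
        gene = GeneTarget("g", cds)
        # independent oracle: overlapping CC occurrences with >=20 nt after the motif
        oracle = [m.start() + 1 for m in re.finditer("(?=CC)", cds)
                  if m.start() + 23 <= len(cds)]
        cands = scan_pam_candidates(gene)
        assert [c.pam_offset for c in cands] == oracle
        for c in cands:
            assert c.spacer == str(Seq(c.protospacer).reverse_complement())

    def test_ordered_by_offset(self):
        gene = GeneTarget("g", "CCA" * 30)
        offs = [c.pam_offset for c in scan_pam_candidates(gene)]
        assert offs == sorted(offs)


class TestSequenceFilters:
    @pytest.mark.parametrize(
        "spacer,expected",
        [
            ("G" * 20, {"gc_high"}),
            ("G" * 7 + "TTTTT" + "C" * 8, {"polyT"}),  # GC = 75%, run of 5 T
            (GOOD_SPACER, set()),  # GC = 50%, max T-run 1
            ("GC" * 9 + "AT", {"gc_high"}),  # GC = 18/20 = 90%
            ("A" * 20, {"gc_low"}),
        ],
    )
    def test_reason_codes(self, spacer, expected):
        res = apply_sequence_filters(spacer)
        assert set(res.reasons) == expected
        assert res.passed == (not expected)

    def test_boundaries_are_strict(self):
        # exactly 45% GC (9/20) and exactly 80% (16/20) both fail
        spacer_45 = "G" * 9 + "A" * 11
        spacer_80 = "G" * 16 + "A" * 4
        assert apply_sequence_filters(spacer_45).reasons == {"gc_low"}
        assert apply_sequence_filters(spacer_80).reasons == {"gc_high"}
        # 10/20 = 50% passes
        assert apply_sequence_filters("G" * 10 + "A" * 10).passed

    def test_four_t_run_allowed(self):
        spacer = "G" * 8 + "TTTT" + "C" * 6 + "AA"  # GC = 70%, run of 4 T
        assert apply_sequence_filters(spacer).passed


def _brute_force_hits(proto, background):
    """Sliding-window identity oracle over both strands."""
    rc = str(Seq(proto).reverse_complement())
    hits = []
    for seq in background:
        for s in range(len(seq) - 19):
            win = seq[s : s + 20]
            for strand, ref in (("+", proto), ("-", rc)):
                ident = sum(a == b for a, b in zip(win, ref)) / 20
                if ident > 0.75:
                    hits.append((s, strand, ident))
    return hits


# non-self-reverse-complementary spacer so strand hits are unambiguous
OT_SPACER = "GATTACACGTTCGAGGTCAA"


class TestOffTargets:
    def test_two_perfect_sites_trigger_redesign(self):
        p = make_parent(OT_SPACER)
        bg = ["AAAA" + p.protospacer + "TTTT" + p.protospacer + "GGGG"]
        v = screen_off_targets(p, bg)
        assert v.redesign and "multi_perfect" in v.rules_fired

    def test_single_perfect_site_is_the_target(self):
        p = make_parent(OT_SPACER)
        bg = ["AAAA" + p.protospacer + "GGGG"]
        assert not screen_off_targets(p, bg).redesign

    def test_95pct_with_pam_triggers_redesign(self):
        p = make_parent(OT_SPACER)
        site = list(p.protospacer)
        site[12] = {"A": "G", "C": "T", "G": "A", "T": "C"}[site[12]]  # 19/20
        bg = ["AAACCG" + "".join(site) + "AAAA"]  # CCN immediately 5'
        v = screen_off_targets(p, bg)
        assert v.redesign and "high_homology_pam" in v.rules_fired

    def test_seed_mismatch_blocks_rule_iii(self):
        p = make_parent(OT_SPACER)
        site = list(p.protospacer)
        comp = {"A": "G", "C": "T", "G": "A", "T": "C"}
        for i in (2, 10, 13, 17):  # 16/20 = 80%; position 2 is inside the seed 8-mer
            site[i] = comp[site[i]]
        bg = ["AAACCG" + "".join(site) + "AAAA"]
        v = screen_off_targets(p, bg)
        assert not v.redesign

    def test_seed_perfect_80pct_with_pam_triggers_rule_iii(self):
        p = make_parent(OT_SPACER)
        site = list(p.protospacer)
        comp = {"A": "G", "C": "T", "G": "A", "T": "C"}
        for i in (10, 13, 15, 18):  # all outside the PAM-proximal 8-mer
            site[i] = comp[site[i]]
        bg = ["AAACCG" + "".join(site) + "AAAA"]
        v = screen_off_targets(p, bg)
        assert v.redesign and "seed_match_pam" in v.rules_fired

    def test_empty_background_is_an_error(self):
        with pytest.raises(ValueError):
            screen_off_targets(make_parent(), [])

    @pytest.mark.parametrize("seed", range(5))
    def test_hit_homologies_match_brute_force(self, seed):
        p = make_parent(OT_SPACER)
        rng = np.random.default_rng(seed)
        bg = ["".join(rng.choice(list("ACGT"), size=3000))]
        v = screen_off_targets(p, bg)
        oracle = _brute_force_hits(p.protospacer, bg)
        got = [(h.start, h.strand, h.homology) for h in v.hits]
        assert sorted(got) == sorted(oracle)


class TestSelectParents:
    def _cands(self, offsets, gene="g"):
        # spacer content is irrelevant for role assignment
        return [make_parent(gene_id=gene, role=None, pam_offset=o) for o in offsets]

    def test_non_overlapping_forced_assignment(self):
        roles = select_parents(self._cands([10, 40, 210]))
        assert roles["SG1"].pam_offset == 10
        assert roles["SG2"].pam_offset == 40
        assert roles["SG3"].pam_offset == 210

    def test_overlap_skips_to_next_candidate(self):
        roles = select_parents(self._cands([10, 25, 90, 250, 205]))
        assert roles["SG1"].pam_offset == 10
        assert roles["SG2"].pam_offset == 90  # 25 overlaps SG1's window
        assert roles["SG3"].pam_offset == 205

    def test_partial_assignment(self):
        roles = select_parents(self._cands([160, 300]))
        assert "SG1" not in roles and "SG2" not in roles
        assert roles["SG3"].pam_offset == 300

    def test_order_invariance(self):
        offsets = [205, 90, 10, 250, 25]
        a = select_parents(self._cands(offsets))
        b = select_parents(self._cands(sorted(offsets, reverse=True)))
        assert {r: c.pam_offset for r, c in a.items()} == {
            r: c.pam_offset for r, c in b.items()
        }


class TestMutationSeries:
    def test_compounding_count_and_positions(self):
        variants = mutate_compounding(make_parent())
        assert len(variants) == 14
        assert variants[0].mutated_positions == frozenset({-20})
        assert variants[13].mutated_positions == frozenset(range(-20, -6))
        # positions -6..-1 untouched in the deepest variant
        parent = make_parent()
        for pos in range(-6, 0):
            i = spacer_index(pos)
            assert variants[13].spacer[i] == parent.spacer[i]

    def test_compounding_monotone_nesting(self):
        variants = mutate_compounding(make_parent())
        for a, b in zip(variants, variants[1:]):
            assert a.mutated_positions < b.mutated_positions

    def test_mutation_is_involution_and_hamming_consistent(self):
        parent = make_parent()
        comp = str.maketrans("ACGT", "TGCA")
        for v in (
            mutate_compounding(parent) + mutate_singles(parent) + mutate_doubles(parent)
        ):
            hamming = sum(a != b for a, b in zip(v.spacer, parent.spacer))
            assert hamming == v.n_mut == len(v.mutated_positions)
            # flipping the mutated bases back restores the parent
            restored = list(v.spacer)
            for p in v.mutated_positions:
                i = spacer_index(p)
                restored[i] = restored[i].translate(comp)
            assert "".join(restored) == parent.spacer

    def test_singles_positions(self):
        variants = mutate_singles(make_parent())
        assert len(variants) == 15
        positions = {next(iter(v.mutated_positions)) for v in variants}
        assert positions == set(SINGLE_MUT_POSITIONS)
        assert -3 not in positions and -9 not in positions
        minus1 = next(v for v in variants if v.mutated_positions == {-1})
        parent = make_parent()
        diffs = [i for i in range(20) if minus1.spacer[i] != parent.spacer[i]]
        assert diffs == [spacer_index(-1)]

    def test_doubles_exact_pairs(self):
        variants = mutate_doubles(make_parent())
        assert len(variants) == 5
        assert {v.mutated_positions for v in variants} == set(DOUBLE_MUT_PAIRS)
        assert all(v.n_mut == 2 for v in variants)


class TestNegC:
    def test_default_count_and_determinism(self):
        a = make_negc(seed=7)
        b = make_negc(seed=7)
        assert len(a) == 45
        assert [v.spacer for v in a] == [v.spacer for v in b]

    def test_every_control_passes_filters(self):
        for v in make_negc(n=20, seed=3):
            assert apply_sequence_filters(v.spacer).passed
            assert v.strategy == "negC" and v.n_mut == 0


class TestCompactSubset:
    def _full_gene_lib(self, gene_ids):
        variants = []
        for g in gene_ids:
            for role in ("SG1", "SG3"):
                p = make_parent(gene_id=g, role=role)
                from titracrispr import GuideVariant

                variants.append(
                    GuideVariant(
                        guide_id=f"{g}_{role}", gene_id=g, role=role,
                        strategy="parent", mutated_positions=frozenset(),
                        spacer=p.spacer, parent=p,
                    )
                )
                variants.extend(mutate_compounding(p))
        # make ids unique across genes (mutate_* reuses the gene/role stem)
        return LibrarySpec(variants=variants)

    def test_sixteen_guides_per_complete_gene(self):
        lib = self._full_gene_lib(["gA"])
        compact = compact_subset(lib)
        targeting = [v for v in compact.variants if v.strategy != "negC"]
        assert len(targeting) == 16
        assert sum(v.strategy == "parent" for v in targeting) == 2
        assert all(
            4 <= v.n_mut <= 10 for v in targeting if v.strategy == "compounding"
        )

    def test_missing_parent_warns_and_halves(self):
        p = make_parent(gene_id="gB", role="SG1")
        from titracrispr import GuideVariant

        variants = [
            GuideVariant(guide_id="gB_SG1", gene_id="gB", role="SG1",
                         strategy="parent", mutated_positions=frozenset(),
                         spacer=p.spacer, parent=p)
        ] + mutate_compounding(p)
        with pytest.warns(UserWarning, match="SG3"):
            compact = compact_subset(LibrarySpec(variants=variants))
        assert len([v for v in compact.variants if v.strategy != "negC"]) == 8

    def test_union_over_ten_genes(self):
        lib = self._full_gene_lib([f"g{i:02d}" for i in range(10)])
        compact = compact_subset(lib)
        assert len([v for v in compact.variants if v.strategy != "negC"]) == 160

    def test_designed_library_compact(self, toy_library):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            compact = compact_subset(toy_library)
        for gene_id, variants in compact.by_gene().items():
            roles = {v.role for v in variants}
            expected = 16 if roles == {"SG1", "SG3"} else 8
            assert len(variants) == expected
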