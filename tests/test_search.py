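"""VEnCode search: validity oracle, sampling, heuristics, ranking."""

import itertools

import numpy as np
import pytest

from vencodes import (
    InputError, VEnCode, heuristic2_vencodes, heuristic_vencodes, is_vencode,
    sample_vencodes, sort_by_sparseness, sparsity_filter, top_vencodes,
)
from vencodes.search import SearchReport

from conftest import (
    brute_force_vencodes, cnf_is_vencode, landscape_from_matrix,
    random_landscape,
)


class TestIsVencode:
    def test_single_target_exclusive_re(self):
        L = landscape_from_matrix([[1, 0, 0], [1, 1, 1]])
        assert is_vencode(L, ["RE001"])
        assert not is_vencode(L, ["RE002"])

    def test_pair_coactive_somewhere_fails_complementary_pair_passes(self):
        # N02 has both REs active -> the AND gate also fires there
        L = landscape_from_matrix([[1, 1, 1], [1, 0, 1]])
        assert not is_vencode(L, ["RE001", "RE002"])
        # complementary inactivity per column -> exclusive intersection
        L2 = landscape_from_matrix([[1, 1, 0], [1, 0, 1]])
        assert is_vencode(L2, ["RE001", "RE002"])

    def test_unknown_id_is_error(self):
        L = landscape_from_matrix([[1, 0]])
        with pytest.raises(InputError, match="ghost"):
            is_vencode(L, ["ghost"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_cnf_truth_oracle_on_all_triples(self, seed):
        rng = np.random.default_rng(seed)
        L = random_landscape(rng, r=12, c=8)
        for triple in itertools.combinations(L.re_ids, 3):
            assert is_vencode(L, triple) == cnf_is_vencode(L, triple)

    def test_supersets_of_valid_codes_stay_valid(self, rng):
        L = random_landscape(rng, r=10, c=6, density=0.3)
        valid2 = brute_force_vencodes(L, 2)
        for pair in valid2:
            for extra in L.re_ids:
                if extra not in pair:
                    assert is_vencode(L, tuple(pair) + (extra,))


class TestSampling:
    def test_finds_planted_triple(self, planted_landscape):
        filtered = sparsity_filter(planted_landscape, 3)
        rep = sample_vencodes(filtered, 3, n_samples=10_000, seed=5)
        assert frozenset(("RE0001", "RE0002", "RE0003")) in {
            c.as_set() for c in rep.vencodes
        }

    def test_hits_are_subset_of_brute_force(self, rng):
        for _ in range(5):
            L = random_landscape(rng, r=10, c=6, density=0.3)
            rep = sample_vencodes(L, 3, n_samples=2000, seed=7)
            brute = brute_force_vencodes(L, 3)
            assert {c.as_set() for c in rep.vencodes} <= brute

    def test_r_smaller_than_k_is_error(self):
        L = landscape_from_matrix([[1, 0], [1, 0]])
        with pytest.raises(InputError):
            sample_vencodes(L, 3, 10)

    def test_deterministic_under_seed(self, planted_landscape):
        a = sample_vencodes(planted_landscape, 3, 500, seed=9)
        b = sample_vencodes(planted_landscape, 3, 500, seed=9)
        assert [c.res for c in a.vencodes] == [c.res for c in b.vencodes]
        assert a.n_iterations == b.n_iterations

    def test_max_hits_stops_early(self, rng):
        L = random_landscape(rng, r=12, c=4, density=0.15)
        rep = sample_vencodes(L, 2, n_samples=5000, seed=1, max_hits=3)
        assert len(rep.vencodes) <= 3
        if len(rep.vencodes) == 3:
            assert rep.n_iterations < 5000

    def test_codes_are_deduplicated_sets(self, planted_landscape):
        rep = sample_vencodes(planted_landscape, 3, 5000, seed=3)
        sets = [c.as_set() for c in rep.vencodes]
        assert len(sets) == len(set(sets))


class TestHeuristic:
    def test_target_exclusive_re_padded_with_next_sparsest(self):
        # RE001 active only in target; k=4 pads with the 3 next sparsest
        arr = np.zeros((6, 6), dtype=bool)
        arr[:, 0] = True
        arr[1, 1:3] = True
        arr[2, 1:2] = True
        arr[3, 1:4] = True
        arr[4, 1:5] = True
        arr[5, 1:6] = True
        L = landscape_from_matrix(arr)
        rep = heuristic_vencodes(L, k=4, quota=1)
        assert set(rep.vencodes[0].res) == {"RE001", "RE003", "RE002", "RE004"}

    def test_forced_pair_found_at_depth_two(self):
        # no single RE is specific, one sparsest-first pair is
        L = landscape_from_matrix([
            [1, 1, 0, 0],
            [1, 0, 1, 1],
            [1, 1, 1, 1],
        ])
        rep = heuristic_vencodes(L, k=2)
        assert frozenset(("RE001", "RE002")) in {c.as_set() for c in rep.vencodes}

    def test_empty_result_is_not_an_error(self):
        L = landscape_from_matrix([[1, 1, 1], [1, 1, 1]])
        rep = heuristic_vencodes(L, k=2)
        assert rep.vencodes == []

    @pytest.mark.parametrize("seed", range(10))
    def test_hits_subset_of_brute_force_random_landscapes(self, seed):
        rng = np.random.default_rng(1000 + seed)
        r, c, k = 12, 7, 3
        L = random_landscape(rng, r=r, c=c, density=0.35)
        rep = heuristic_vencodes(L, k, quota=10_000)
        brute = brute_force_vencodes(L, k)
        assert {v.as_set() for v in rep.vencodes} <= brute

    def test_hit_rate_at_least_sampling_at_equal_budget(self):
        found_h = found_s = 0
        for seed in range(40):
            rng = np.random.default_rng(2000 + seed)
            L = random_landscape(rng, r=12, c=8, density=0.4)
            budget = 50
            rep_h = heuristic_vencodes(L, 3, quota=1)
            if rep_h.vencodes:
                found_h += 1
            rep_s = sample_vencodes(L, 3, n_samples=budget, seed=seed, max_hits=1)
            if rep_s.vencodes:
                found_s += 1
        assert found_h >= found_s

    def test_deterministic(self, planted_landscape):
        a = heuristic_vencodes(planted_landscape, 3)
        b = heuristic_vencodes(planted_landscape, 3)
        assert [c.res for c in a.vencodes] == [c.res for c in b.vencodes]


class TestHeuristic2:
    def enh_prom_pair(self):
        # enhancers: the 2 sparsest are co-active with the target in N01 only
        enh = landscape_from_matrix([
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 1, 1],
        ], ids=["e1", "e2", "e3"], re_class="enhancer")
        # one promoter inactive exactly in the problematic cell type
        prom = landscape_from_matrix([
            [1, 0, 1, 1],
            [1, 1, 1, 1],
        ], ids=["p1", "p2"], re_class="promoter")
        return enh, prom

    def test_mixed_code_resolves_problematic_cell_type(self):
        enh, prom = self.enh_prom_pair()
        rep = heuristic2_vencodes(enh, prom, k1=2, k2=1)
        assert len(rep.vencodes) >= 1
        code = rep.vencodes[0]
        assert set(code.res) == {"e1", "e2", "p1"}
        assert code.k1 == 2 and code.k2 == 1
        assert code.re_classes == ("enhancer", "enhancer", "promoter")

    def test_enhancers_alone_returned_minimal(self):
        enh = landscape_from_matrix([[1, 0, 0], [1, 1, 0]],
                                    ids=["e1", "e2"], re_class="enhancer")
        prom = landscape_from_matrix([[1, 0, 0]], ids=["p1"], re_class="promoter")
        rep = heuristic2_vencodes(enh, prom, k1=2, k2=2)
        assert [c.res for c in rep.vencodes] == [("e1", "e2")]
        assert rep.vencodes[0].k2 == 0

    def test_pad_to_full_appends_promoters(self):
        enh = landscape_from_matrix([[1, 0, 0], [1, 1, 0]],
                                    ids=["e1", "e2"], re_class="enhancer")
        prom = landscape_from_matrix([[1, 0, 0], [1, 1, 1]],
                                     ids=["p1", "p2"], re_class="promoter")
        rep = heuristic2_vencodes(enh, prom, k1=2, k2=1, pad_to_full=True)
        assert rep.vencodes[0].res == ("e1", "e2", "p1")

    def test_cell_type_universe_mismatch_is_error(self):
        enh = landscape_from_matrix([[1, 0, 0]], re_class="enhancer")
        prom = landscape_from_matrix([[1, 0]], re_class="promoter")
        with pytest.raises(InputError, match="universe"):
            heuristic2_vencodes(enh, prom, 1, 1)


class TestTopVencodes:
    def make_reports(self, target="T"):
        codes = [VEnCode(target, (f"a{i}",) * 1, "sampling") for i in range(3)]
        codes += [VEnCode(target, (f"b{i}", f"c{i}"), "heuristic") for i in range(4)]
        return [SearchReport(target, "sampling", 10, codes[:3]),
                SearchReport(target, "heuristic", 10, codes[3:])]

    def test_returns_n_highest_e(self):
        reports = self.make_reports()
        scores = {}
        all_codes = reports[0].vencodes + reports[1].vencodes
        for i, c in enumerate(all_codes):
            scores[c.as_set()] = float(i)
        top = top_vencodes(reports, 5, lambda c: scores[c.as_set()])
        got = [scores[c.as_set()] for c in top]
        assert got == sorted(scores.values(), reverse=True)[:5]

    def test_tie_on_e_prefers_smaller_k(self):
        reports = self.make_reports()
        top = top_vencodes(reports, 3, lambda c: 1.0)
        assert [c.k for c in top] == [1, 1, 1]

    def test_stable_under_report_order(self):
        reports = self.make_reports()
        scores = {c.as_set(): float(hash(c.res) % 97)
                  for r in reports for c in r.vencodes}
        a = top_vencodes(reports, 4, lambda c: scores[c.as_set()])
        b = top_vencodes(reports[::-1], 4, lambda c: scores[c.as_set()])
        assert [c.res for c in a] == [c.res for c in b]

    def test_mixed_targets_rejected(self):
        r1 = SearchReport("A", "sampling", 1, [VEnCode("A", ("x",), "sampling")])
        r2 = SearchReport("B", "sampling", 1, [VEnCode("B", ("y",), "sampling")])
        with pytest.raises(InputError):
            top_vencodes([r1, r2], 1, lambda c: 1.0)
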