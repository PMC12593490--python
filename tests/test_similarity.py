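import numpy as np
import pytest

import mnpkit as mk
from mnpkit.errors import ContractError

from conftest import make_matched_profiles, make_profile

# printed GS values and the integer match counts that invert them (N = 369)
PRINTED_GS = [(10, 2.71), (44, 11.92), (100, 27.10), (168, 45.53),
              (203, 55.01), (255, 69.11), (275, 74.53), (279, 75.61),
              (327, 88.62)]


class TestComputeGs:
    @pytest.mark.parametrize("n,expected", PRINTED_GS)
    def test_published_values_from_match_counts(self, n, expected):
        a, b = make_matched_profiles(n, 369)
        r = mk.compute_gs(a, b)
        assert (r.n, r.N) == (n, 369)
        assert r.gs == expected

    def test_identical_profiles_are_100(self):
        a, b = make_matched_profiles(369, 369)
        assert mk.compute_gs(a, b).gs == 100.00

    def test_no_matches(self):
        a, b = make_matched_profiles(0, 369)
        assert mk.compute_gs(a, b).gs == 0.00

    def test_rounding_convention_inverts_all_printed_values(self):
        # every printed value corresponds to an integer n under
        # round-half-away-from-zero at N=369
        for n, printed in PRINTED_GS:
            assert mk.round_percent(100 * n / 369) == printed

    def test_het_match_requires_exact_set_equality(self):
        a = make_profile("a", {"m1": ["AC", "GT"]})
        b = make_profile("b", {"m1": ["AC"]})
        assert mk.compute_gs(a, b).n == 0

    def test_missing_counts_against_total_mode(self):
        a = make_profile("a", {"m1": ["AC"], "m2": ["GT"]})
        b = make_profile("b", {"m1": ["AC"], "m2": None})
        total = mk.compute_gs(a, b, mode="total")
        shared = mk.compute_gs(a, b, mode="shared")
        assert (total.n, total.N, total.gs) == (1, 2, 50.00)
        assert (shared.n, shared.N, shared.gs) == (1, 1, 100.00)

    def test_symmetry_property(self):
        rng = np.random.default_rng(5)
        ids = [f"m{i}" for i in range(60)]
        profiles = [
            make_profile(f"s{j}", {
                mid: None if rng.random() < 0.1 else
                ["".join(rng.choice(list("ACGT"), 2))
                 for _ in range(int(rng.integers(1, 3)))]
                for mid in ids})
            for j in range(6)
        ]
        for i in range(6):
            for j in range(i + 1, 6):
                ab = mk.compute_gs(profiles[i], profiles[j])
                ba = mk.compute_gs(profiles[j], profiles[i])
                assert (ab.n, ab.N, ab.gs) == (ba.n, ba.N, ba.gs)

    def test_disjoint_universes_rejected(self):
        a = make_profile("a", {"m1": ["A"]})
        b = make_profile("b", {"m2": ["A"]})
        with pytest.raises(ContractError):
            mk.compute_gs(a, b)


class TestGsMatrix:
    def _db(self, profiles):
        return mk.MarkerDatabase(markers=[], profiles={p.strain: p
                                                       for p in profiles})

    def test_pair_count_for_32_strains(self):
        profiles = [make_profile(f"s{i:02d}", {"m1": ["A"]}) for i in range(32)]
        m = mk.gs_matrix(self._db(profiles))
        assert len(m.values) == 496          # C(32, 2)

    def test_matrix_symmetric_with_unit_diagonal(self):
        a = make_profile("a", {"m1": ["A"], "m2": ["C"]})
        b = make_profile("b", {"m1": ["A"], "m2": ["G"]})
        c = make_profile("c", {"m1": ["T"], "m2": ["G"]})
        frame = mk.gs_matrix(self._db([a, b, c])).to_frame()
        assert (frame.to_numpy() == frame.to_numpy().T).all()
        assert (np.diag(frame.to_numpy()) == 100.0).all()

    def test_single_strain_rejected(self):
        with pytest.raises(ContractError):
            mk.gs_matrix(self._db([make_profile("a", {"m1": ["A"]})]))


class TestClassifyPair:
    @pytest.mark.parametrize("gs,expected", [
        (99.00, "identical"), (98.99, "distinct"), (88.62, "distinct"),
        (100.0, "identical"), (0.0, "distinct"),
    ])
    def test_threshold_inclusive(self, gs, expected):
        assert mk.classify_pair(gs) == expected

    def test_out_of_range(self):
        with pytest.raises(ContractError):
            mk.classify_pair(100.5)


def _clades(tree):
    """Set of leaf-name frozensets, one per internal node."""
    k = len(tree.labels)
    Z = tree.linkage_matrix
    members = {i: frozenset([tree.labels[i]]) for i in range(k)}
    out = set()
    for row in range(Z.shape[0]):
        merged = members[int(Z[row, 0])] | members[int(Z[row, 1])]
        members[k + row] = merged
        out.add(merged)
    return out


class TestClustering:
    def test_two_blocks_split_first(self):
        ids = {"m1": ["A"], "m2": ["C"]}
        other = {"m1": ["G"], "m2": ["T"]}
        profiles = [make_profile(s, ids) for s in "ab"] + \
            [make_profile(s, other) for s in "cd"]
        m = mk.gs_matrix(mk.MarkerDatabase(markers=[], profiles={
            p.strain: p for p in profiles}))
        tree = mk.cluster_gs(m)
        assert {frozenset("ab"), frozenset("cd")} <= _clades(tree)

    def test_single_vs_average_linkage_hand_computed(self):
        # chaining matrix: single linkage chains A-B-C then D; average
        # pairs (A,B) with (C,D)
        labels = list("ABCD")
        d = np.array([
            [0.00, 0.10, 0.60, 0.70],
            [0.10, 0.00, 0.25, 0.65],
            [0.60, 0.25, 0.00, 0.30],
            [0.70, 0.65, 0.30, 0.00],
        ])
        single = mk.cluster_from_distances(d, labels, method="single")
        average = mk.cluster_from_distances(d, labels, method="average")
        assert frozenset("ABC") in _clades(single)
        assert {frozenset("AB"), frozenset("CD")} <= _clades(average)

    def test_merge_heights_non_decreasing(self, small_sim):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.2, 1.0, size=(10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = mk.cluster_from_distances(d, [f"s{i}" for i in range(10)])
        heights = tree.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        assert sorted(tree.leaf_order) == [f"s{i}" for i in range(10)]

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ContractError):
            mk.cluster_from_distances(d, ["a", "b"])


class TestSummarizeRanges:
    def test_identical_group(self):
        profiles = [make_profile(s, {"m1": ["A"]}) for s in "abc"]
        m = mk.gs_matrix(mk.MarkerDatabase(markers=[], profiles={
            p.strain: p for p in profiles}))
        df = mk.summarize_ranges(m, {s: "g" for s in "abc"})
        row = df.iloc[0]
        assert (row["min"], row["max"], row["mean"]) == (100.0, 100.0, 100.0)

    def test_hand_built_trio_range(self):
        # three-strain group engineered to pairwise GS 74.53 / 55.01 / 45.53:
        # 139 markers match in all three, 136 in x,y only, 64 in x,z only,
        # 29 in y,z only, 1 in none (sums: x-y 275, x-z 203, y-z 168 of 369)
        pattern_counts = [(("AA", "AA", "AA"), 139), (("CC", "CC", "GG"), 136),
                          (("TT", "GG", "TT"), 64), (("GT", "AC", "AC"), 29),
                          (("AA", "CC", "GG"), 1)]
        calls = {"x": {}, "y": {}, "z": {}}
        i = 0
        for (hx, hy, hz), count in pattern_counts:
            for _ in range(count):
                mid = f"m{i:04d}"
                calls["x"][mid], calls["y"][mid], calls["z"][mid] = \
                    [hx], [hy], [hz]
                i += 1
        assert i == 369
        m = mk.gs_matrix(mk.MarkerDatabase(markers=[], profiles={
            s: make_profile(s, c) for s, c in calls.items()}))
        assert m.get("x", "y").gs == 74.53
        assert m.get("x", "z").gs == 55.01
        assert m.get("y", "z").gs == 45.53
        df = mk.summarize_ranges(m, {"x": "trio", "y": "trio", "z": "trio"})
        assert df.iloc[0]["min"] == 45.53 and df.iloc[0]["max"] == 74.53

    def test_unknown_strain_rejected(self):
        profiles = [make_profile(s, {"m1": ["A"]}) for s in "ab"]
        m = mk.gs_matrix(mk.MarkerDatabase(markers=[], profiles={
            p.strain: p for p in profiles}))
        with pytest.raises(ContractError):
            mk.summarize_ranges(m, {"a": "g"})

    def test_cross_group_rows_present(self):
        a = make_profile("a", {"m1": ["A"]})
        b = make_profile("b", {"m1": ["A"]})
        c = make_profile("c", {"m1": ["C"]})
        m = mk.gs_matrix(mk.MarkerDatabase(markers=[], profiles={
            "a": a, "b": b, "c": c}))
        df = mk.summarize_ranges(m, {"a": "g1", "b": "g1", "c": "g2"})
        cross = df[(df.group_a == "g1") & (df.group_b == "g2")]
        assert cross.iloc[0]["n_pairs"] == 2 and cross.iloc[0]["max"] == 0.0


class TestParameterRecovery:
    @pytest.mark.parametrize("f", [0.0, 0.25, 0.5, 0.9, 1.0])
    def test_engineered_sharing_fraction_recovered(self, f):
        M = 400
        n = round(f * M)
        a, b = make_matched_profiles(n, M)
        assert mk.compute_gs(a, b).gs == mk.round_percent(100 * n / M)
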