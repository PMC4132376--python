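"""Subject distances, dendrograms, twin-pair linkage, permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata

from plaquetx import (
    MetadataError,
    PlaquetxError,
    SynthConfig,
    cluster,
    distance_matrix,
    pair_linkage,
    pair_table,
    permutation_null,
    simulate,
    stratify_linkage,
)


def dist_df(arr, labels):
    return pd.DataFrame(np.asarray(arr, dtype=float), index=labels, columns=labels)


def brute_force_agglomerate(dist: np.ndarray, method: str):
    """Naive O(n^3) agglomeration; returns the merge sequence as
    (frozenset, frozenset, height) with lowest-index tie-break."""
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges = []
    link = {
        "average": lambda a, b: np.mean([dist[i, j] for i in a for j in b]),
        "complete": lambda a, b: max(dist[i, j] for i in a for j in b),
        "single": lambda a, b: min(dist[i, j] for i in a for j in b),
    }[method]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = link(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] | clusters[j]
        ]
    return merges


def merge_sets_from_scipy(merge: np.ndarray, n: int):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, h, _) in enumerate(merge):
        sa, sb = members[int(a)], members[int(b)]
        out.append((sa, sb, h))
        members[n + k] = sa | sb
    return out


class TestDistance:
    def test_identical_profiles_zero_distance(self):
        mat = pd.DataFrame({"A": [1, 5, 3, 9], "B": [2, 10, 6, 18]}, index=list("wxyz"))
        d = distance_matrix(mat)
        assert d.loc["A", "B"] == pytest.approx(0.0)

    def test_reversed_ranking_distance_two(self):
        mat = pd.DataFrame({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1]}, index=list("wxyz"))
        d = distance_matrix(mat)
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(21)
        mat = pd.DataFrame(
            rng.normal(size=(12, 5)), columns=[f"S{j}" for j in range(5)]
        )
        d = distance_matrix(mat)
        for i in range(5):
            for j in range(5):
                ri = rankdata(mat.iloc[:, i])
                rj = rankdata(mat.iloc[:, j])
                expected = 1 - pearsonr(ri, rj).statistic
                assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_rejected(self):
        mat = pd.DataFrame({"A": [1, 2, 3], "B": [5, 5, 5]})
        with pytest.raises(PlaquetxError, match="constant"):
            distance_matrix(mat)

    def test_euclidean_metric(self):
        mat = pd.DataFrame({"A": [0, 0], "B": [3, 4]})
        d = distance_matrix(mat, metric="euclidean")
        assert d.loc["A", "B"] == pytest.approx(5.0)


class TestCluster:
    def test_closest_pair_merges_first(self):
        d = dist_df([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]], list("ABC"))
        tree = cluster(d)
        assert frozenset(("A", "B")) in tree.cherry_pairs()

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_ultrametric_input_is_fixed_point(self, method):
        # heights: {A,B} at 0.2, {C,D} at 0.4, root at 1.0
        d = dist_df(
            [[0, 0.2, 1, 1], [0.2, 0, 1, 1], [1, 1, 0, 0.4], [1, 1, 0.4, 0]],
            list("ABCD"),
        )
        tree = cluster(d, method=method)
        coph = squareform(cophenet(tree.merge))
        np.testing.assert_allclose(coph, d.to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_merge_order_matches_brute_force(self, method):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            raw = rng.uniform(0.1, 2.0, (n, n))
            d = np.triu(raw, 1)
            d = d + d.T
            tree = cluster(dist_df(d, [f"s{i}" for i in range(n)]), method=method)
            got = merge_sets_from_scipy(tree.merge, n)
            expected = brute_force_agglomerate(d, method)
            for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
                assert {ga, gb} == {ea, eb}
                assert gh == pytest.approx(eh, abs=1e-12)

    def test_newick_roundtrip_heights(self):
        d = dist_df([[0, 0.2, 1, 1], [0.2, 0, 1, 1], [1, 1, 0, 0.4], [1, 1, 0.4, 0]], list("ABCD"))
        nwk = cluster(d).to_newick()
        assert nwk.endswith(";")
        for leaf in "ABCD":
            assert leaf in nwk


def two_pair_profiles():
    """Four subjects forming two unambiguous twin pairs (rank-identical
    within pair, reversed ranking between pairs)."""
    base = np.array([3.0, 7.0, 1.0, 9.0, 5.0, 2.0])
    mat = pd.DataFrame(
        {"P1a": base, "P1b": 2 * base, "P2a": base[::-1], "P2b": 2 * base[::-1]},
        index=[f"t{i}" for i in range(6)],
    )
    md = pd.DataFrame(
        {
            "subject_id": ["P1a", "P1b", "P2a", "P2b"],
            "pair_id": ["P1", "P1", "P2", "P2"],
            "zygosity": ["MZ", "MZ", "DZ", "DZ"],
            "caries_status": ["CF", "CF", "CF", "CA"],
            "decayed_surfaces": [0, 0, 0, 2],
        }
    )
    return mat, md


class TestPairLinkage:
    def test_separated_pairs_fully_linked(self):
        mat, md = two_pair_profiles()
        tree = cluster(distance_matrix(mat))
        res = pair_linkage(tree, md)
        assert res.strata["overall"] == {"linked": 2, "total": 2, "fraction": 1.0}

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    def test_separation_implies_full_linkage_any_method(self, method):
        """If every within-pair distance is below every between-pair distance,
        all pairs are cherries for all three linkage methods."""
        rng = np.random.default_rng(33)
        n_pairs = 6
        labels = [f"P{p}{s}" for p in range(n_pairs) for s in "ab"]
        n = len(labels)
        d = rng.uniform(0.8, 1.2, (n, n))
        d = np.triu(d, 1)
        d = d + d.T
        for p in range(n_pairs):
            i, j = 2 * p, 2 * p + 1
            d[i, j] = d[j, i] = rng.uniform(0.01, 0.1)
        md = pd.DataFrame(
            {
                "subject_id": labels,
                "pair_id": [l[:-1] for l in labels],
                "zygosity": "DZ",
                "caries_status": "CF",
                "decayed_surfaces": 0,
            }
        )
        tree = cluster(dist_df(d, labels), method=method)
        res = pair_linkage(tree, md)
        assert res.strata["overall"]["fraction"] == 1.0

    def test_nearest_neighbor_definition(self):
        mat, md = two_pair_profiles()
        tree = cluster(distance_matrix(mat))
        res = pair_linkage(tree, md, linked_def="nearest")
        assert res.pair_flags.all()

    def test_malformed_pair_rejected(self):
        mat, md = two_pair_profiles()
        bad = pd.concat(
            [md, pd.DataFrame([{"subject_id": "P1c", "pair_id": "P1", "zygosity": "MZ",
                                "caries_status": "CF", "decayed_surfaces": 0}])],
            ignore_index=True,
        )
        tree = cluster(distance_matrix(mat))
        with pytest.raises(MetadataError, match="exactly 2"):
            pair_linkage(tree, bad)


class TestStratify:
    def make_metadata(self):
        from plaquetx import generate_cohort

        return generate_cohort(SynthConfig(seed=4))

    def test_study_like_zygosity_fractions(self):
        """Flags of 4/6 MZ and 10/13 DZ stratify to 66.7% and 76.9%."""
        md = self.make_metadata()
        pairs = pair_table(md)
        flags = pd.Series(False, index=pairs.index)
        mz = pairs.index[pairs["zygosity"] == "MZ"]
        dz = pairs.index[pairs["zygosity"] == "DZ"]
        flags[mz[:4]] = True
        flags[dz[:10]] = True
        res = stratify_linkage(flags, pairs)
        assert res.strata["MZ"]["fraction"] == pytest.approx(4 / 6)
        assert res.strata["DZ"]["fraction"] == pytest.approx(10 / 13)
        assert res.strata["overall"]["linked"] == 14

    def test_all_discordant_linked_gives_unit_fraction(self):
        md = self.make_metadata()
        pairs = pair_table(md)
        flags = pairs["concordance"] == "discordant"
        res = stratify_linkage(flags, pairs)
        assert res.strata["discordant"]["fraction"] == 1.0
        assert res.strata["concordant"]["fraction"] == 0.0

    def test_strata_partition_overall(self):
        md = self.make_metadata()
        pairs = pair_table(md)
        rng = np.random.default_rng(0)
        flags = pd.Series(rng.random(len(pairs)) < 0.5, index=pairs.index)
        res = stratify_linkage(flags, pairs)
        s = res.strata
        assert s["MZ"]["linked"] + s["DZ"]["linked"] == s["overall"]["linked"]
        assert s["concordant"]["linked"] + s["discordant"]["linked"] == s["overall"]["linked"]
        cells = sum(s[f"{z}_{c}"]["linked"] for z in ("MZ", "DZ") for c in ("concordant", "discordant"))
        assert cells == s["overall"]["linked"]


class TestPermutationNull:
    def test_two_pair_null_fraction_one_third(self):
        """A balanced 4-leaf tree has 2 cherries; over the 3 possible pairings
        of 4 subjects the expected linked count is 2/3 (fraction 1/3)."""
        mat, md = two_pair_profiles()
        res = permutation_null(mat, md, n_perm=3000, seed=5)
        assert res["observed"] == 2
        assert res["null_mean"] / 2 == pytest.approx(1 / 3, abs=0.03)
        assert res["p_value"] == pytest.approx(1 / 3, abs=0.05)

    def test_determinism(self):
        mat, md = two_pair_profiles()
        a = permutation_null(mat, md, n_perm=200, seed=9)
        b = permutation_null(mat, md, n_perm=200, seed=9)
        assert a["p_value"] == b["p_value"]
        np.testing.assert_array_equal(a["null_counts"], b["null_counts"])

    def test_odd_subject_count_rejected(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)), columns=list("ABC"))
        md = pd.DataFrame(
            {"subject_id": list("AB"), "pair_id": ["p", "p"], "zygosity": "DZ",
             "caries_status": "CF", "decayed_surfaces": 0}
        )
        with pytest.raises(PlaquetxError, match="even"):
            permutation_null(mat, md, n_perm=10, seed=0)


class TestRecoveryProperties:
    def test_mz_linked_at_least_dz_with_extra_mz_effect(self):
        """With a positive extra MZ-shared effect, MZ pairs link at least as
        often as DZ pairs on average."""
        from plaquetx import add_scaled_log2, aggregate, relative_abundance, size_factors

        mz_fracs, dz_fracs = [], []
        for r in range(25):
            cfg = SynthConfig(
                n_species=30, transcripts_per_species=3, pair_effect_sd=0.6,
                mz_extra_effect_sd=1.2, subject_noise_sd=0.6, seed=7000 + r,
            )
            md, cm, _ = simulate(cfg)
            prof = aggregate(cm, "species")
            relative_abundance(prof)
            add_scaled_log2(prof, size_factors(cm))
            res = pair_linkage(cluster(distance_matrix(prof)), md)
            mz_fracs.append(res.strata["MZ"]["fraction"])
            dz_fracs.append(res.strata["DZ"]["fraction"])
        assert np.mean(mz_fracs) >= np.mean(dz_fracs)
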