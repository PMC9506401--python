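"""Descriptive outputs: roll-ups, richness, PCA, Bray-Curtis, heatmap bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rarebiome.rarity import UncommonSet
from rarebiome.summaries import (
    bin_heatmap,
    bin_heatmap_frame,
    binary_pca,
    bray_curtis,
    bray_curtis_matrix,
    cluster_order,
    detect_plant_groupings,
    mean_richness,
    per_plant_top_otu,
    phylum_rollup,
    richness,
)

from conftest import make_grouped_abundance, make_taxonomy


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 0], [0, 3], 1.0),
            ([2, 2], [2, 0], 1 / 3),
            ([0, 0], [0, 0], 0.0),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([1, -1], [0, 1])

    def test_against_scipy_oracle(self):
        from scipy.spatial.distance import braycurtis as scipy_bc

        rng = np.random.default_rng(11)
        for _ in range(1000):
            x = rng.integers(0, 30, size=6).astype(float)
            y = rng.integers(0, 30, size=6).astype(float)
            if (x + y).sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(scipy_bc(x, y))
            assert bray_curtis(x, y) == pytest.approx(bray_curtis(y, x))
            assert 0.0 <= bray_curtis(x, y) <= 1.0


class TestHeatmapBins:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.0, 0),
            (0.05, 1),
            (0.1, 1),
            (0.100001, 2),
            (0.25, 2),
            (0.4, 3),
            (0.5, 3),
            (0.75, 4),
            (1.0, 4),
            (3.0, 5),
            (5.0, 5),
            (7.2, 6),
            (100.0, 6),
        ],
    )
    def test_bin_boundaries(self, value, expected):
        assert bin_heatmap(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_heatmap(-0.1)

    @given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
    def test_partition_of_nonnegative_reals(self, v):
        b = bin_heatmap(v)
        assert b in range(7)
        # each value falls in exactly one half-open bin
        edges = [0.0, 0.1, 0.25, 0.5, 1.0, 5.0, float("inf")]
        if v == 0:
            assert b == 0
        else:
            lo = 0.0 if b == 1 else edges[b - 1]
            assert lo < v <= edges[b]

    def test_frame_binning(self):
        groups = [("maize", "root", "soil")]
        rel = make_grouped_abundance([[0.0, 7.2]], groups, ["a", "b"])
        binned = bin_heatmap_frame(rel.values)
        assert list(binned.iloc[0]) == [0, 6]


class TestClusterOrder:
    def test_identical_samples_merge_first(self):
        frame = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]], index=["a", "b", "c"], columns=["x", "y"]
        )
        d = bray_curtis_matrix(frame)
        order, z = cluster_order(d)
        pos = {lbl: i for i, lbl in enumerate(order)}
        assert abs(pos["a"] - pos["b"]) == 1

    def test_line_metric_merges_closest(self):
        # points at 0, 1, 5 on a line: 0 and 1 merge first
        d = pd.DataFrame(
            [[0, 1, 5], [1, 0, 4], [5, 4, 0]], index=list("pqr"), columns=list("pqr"), dtype=float
        )
        order, z = cluster_order(d)
        assert int(z[0, 2] * 0 + 2) == 2  # first merge joins two singletons
        pos = {lbl: i for i, lbl in enumerate(order)}
        assert abs(pos["p"] - pos["q"]) == 1

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.random((5, 4)), index=list("edcba"), columns=list("wxyz"))
        d = bray_curtis_matrix(frame)
        order1, _ = cluster_order(d)
        perm = [3, 1, 4, 0, 2]
        d2 = d.iloc[perm, perm]
        order2, _ = cluster_order(d2)
        assert order1 == order2  # pre-sorting by label makes order canonical

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=list("ab"), columns=list("ab"), dtype=float)
        with pytest.raises(ValueError):
            cluster_order(d)


class TestPlantGroupings:
    def test_adjacent_pair_detected(self):
        order = ["maize-sand", "maize-soil", "rice-sand", "wheat-sand", "rice-soil", "wheat-soil"]
        labels = {
            lbl: (lbl.split("-")[0], lbl.split("-")[1]) for lbl in order
        }
        assert detect_plant_groupings(order, labels) == ["maize"]

    def test_substrate_blocked_order_no_groups(self):
        order = ["a-sand", "b-sand", "a-soil", "b-soil"]
        labels = {lbl: tuple(lbl.split("-")) for lbl in order}
        assert detect_plant_groupings(order, labels) == []

    def test_hosts_with_wrong_sample_count_skipped(self):
        order = ["a-sand", "a-soil", "b-sand"]
        labels = {lbl: tuple(lbl.split("-")) for lbl in order}
        assert detect_plant_groupings(order, labels) == ["a"]


class TestBinaryPca:
    def test_identical_samples_identical_scores(self):
        frame = pd.DataFrame(
            [[1, 0, 1], [1, 0, 1], [0, 1, 0], [1, 1, 0]],
            index=list("abcd"),
            columns=["o1", "o2", "o3"],
        )
        scores, ev = binary_pca(frame)
        assert np.allclose(scores.loc["a"], scores.loc["b"])
        assert (np.diff(ev) <= 1e-12).all()  # non-increasing variance

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            (rng.random((5, 8)) < 0.5).astype(int),
            index=[f"s{i}" for i in range(5)],
            columns=[f"o{j}" for j in range(8)],
        )
        scores, ev = binary_pca(frame)
        x = frame.to_numpy(float)
        xc = x - x.mean(0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(x, rowvar=False, ddof=1)))[::-1]
        assert np.allclose(ev, evals[: len(ev)], atol=1e-9)
        # score column variances equal the eigenvalues
        assert np.allclose(scores.var(axis=0, ddof=1).to_numpy(), ev, atol=1e-9)

    def test_too_few_samples_rejected(self):
        frame = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"], columns=["x", "y"])
        with pytest.raises(ValueError):
            binary_pca(frame)


class TestRichness:
    def test_counts_and_means(self):
        frame = pd.DataFrame(
            [[True, False, True], [False, False, False]], index=["s1", "s2"], columns=list("abc")
        )
        assert list(richness(frame)) == [2, 0]
        assert mean_richness(frame) == 1.0
        by = pd.Series(["g1", "g2"], index=["s1", "s2"])
        grouped = mean_richness(frame, by)
        assert grouped["g1"] == 2.0 and grouped["g2"] == 0.0


class TestPhylumRollup:
    def _setup(self):
        groups = [(h, "root", "soil") for h in ("maize", "rice")]
        rel = make_grouped_abundance(
            [[40.0, 10.0, 50.0], [20.0, 0.0, 80.0]], groups, ["a", "b", "c"]
        )
        tax = make_taxonomy(
            {
                "a": {"phylum": "Ascomycota"},
                "b": {"phylum": "Basidiomycota"},
                "c": {"phylum": "Ascomycota"},
            }
        )
        return rel, tax

    def test_counts_sum_to_uncommon_size(self):
        rel, tax = self._setup()
        unc = UncommonSet(compartment=("root", "soil"), otu_ids=frozenset(["a", "b"]))
        ps = phylum_rollup(rel, unc, tax)
        assert ps.total_uncommon == 2
        assert ps.n_otus == {"Ascomycota": 1, "Basidiomycota": 1}
        # mean over hosts of summed uncommon abundance per phylum
        assert ps.mean_read_percent["Ascomycota"] == pytest.approx((40 + 20) / 2)
        assert ps.mean_read_percent["Basidiomycota"] == pytest.approx((10 + 0) / 2)

    def test_missing_phylum_bucketed_unclassified(self):
        rel, _ = self._setup()
        tax = make_taxonomy({"a": {}, "b": {"phylum": "Basidiomycota"}, "c": {}})
        unc = UncommonSet(compartment=("root", "soil"), otu_ids=frozenset(["a"]))
        ps = phylum_rollup(rel, unc, tax)
        assert ps.n_otus == {"unclassified": 1}

    def test_empty_uncommon_set(self):
        rel, tax = self._setup()
        unc = UncommonSet(compartment=("root", "soil"), otu_ids=frozenset())
        ps = phylum_rollup(rel, unc, tax)
        assert ps.total_uncommon == 0
        assert ps.percent_uncommon_of_total == 0.0


class TestPerPlantTopOtu:
    def test_argmax_with_threshold_and_ties(self):
        groups = [(h, "shoot", "soil") for h in ("maize", "rice", "wheat")]
        rel = make_grouped_abundance(
            [[5.0, 5.0, 90.0], [0.1, 0.0, 99.9], [0.0, 0.0, 100.0]],
            groups,
            ["bb", "aa", "common"],
        )
        unc = UncommonSet(compartment=("shoot", "soil"), otu_ids=frozenset(["aa", "bb"]))
        top = per_plant_top_otu(rel, unc)
        assert top["maize"] == ("aa", 5.0)  # tie -> lexicographically smaller
        assert top["rice"] == ("bb", 0.1)
        assert "wheat" not in top  # nothing above threshold
        relaxed = per_plant_top_otu(rel, unc, threshold_percent=0.15)
        assert "rice" not in relaxed  # 0.1 <= 0.15 no longer counts

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(9)
        hosts = [f"h{i}" for i in range(6)]
        otus = [f"o{j}" for j in range(7)]
        vals = rng.random((6, 7)) * 10
        rel = make_grouped_abundance(vals, [(h, "root", "sand") for h in hosts], otus)
        unc = UncommonSet(compartment=("root", "sand"), otu_ids=frozenset(otus))
        top = per_plant_top_otu(rel, unc)
        for i, h in enumerate(hosts):
            j = int(np.argmax(vals[i]))
            assert top[h][0] == otus[j]
            assert top[h][1] == pytest.approx(vals[i, j])
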