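"""Population summaries, CV, nonparametric comparisons, affinity matrix."""

import numpy as np
import pandas as pd
import pytest

from seedshape.population import (compare_groups, cv_percent,
                                  model_affinity_matrix, summarize)


class TestSummarize:
    def test_cv_of_reported_area_cells(self):
        # sample constructed to mean 1.64, sd 0.20 -> CV = 12.2%
        df = pd.DataFrame({"pop": ["p"] * 3, "A": [1.44, 1.64, 1.84]})
        out = summarize(df, "pop", traits=["A"])
        assert out.loc["p", "A_mean"] == pytest.approx(1.64)
        assert out.loc["p", "A_sd"] == pytest.approx(0.20)
        assert round(out.loc["p", "A_cv"], 1) == 12.2
        assert round(cv_percent(1.64, 0.20), 1) == 12.2

    def test_constant_column(self):
        df = pd.DataFrame({"pop": ["p"] * 4, "A": [2.0] * 4})
        out = summarize(df, "pop", traits=["A"])
        assert out.loc["p", "A_sd"] == 0.0
        assert out.loc["p", "A_cv"] == 0.0

    def test_single_row_group(self):
        df = pd.DataFrame({"pop": ["p"], "A": [1.5]})
        out = summarize(df, "pop", traits=["A"])
        assert out.loc["p", "A_sd"] == 0.0
        assert out.loc["p", "A_min"] == out.loc["p", "A_max"] == 1.5

    def test_zero_mean_cv_missing_with_warning(self):
        df = pd.DataFrame({"pop": ["p"] * 2, "A": [-1.0, 1.0]})
        with pytest.warns(UserWarning, match="CV undefined"):
            out = summarize(df, "pop", traits=["A"])
        assert np.isnan(out.loc["p", "A_cv"])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "pop": rng.choice(["a", "b"], size=40),
            "A": rng.normal(1.0, 0.1, size=40),
        })
        shuffled = df.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(summarize(df, "pop"),
                                      summarize(shuffled, "pop"))


class TestCompareGroups:
    def test_null_rejection_rate_is_nominal(self):
        """Three samples from one distribution: p > 0.05 in >=90% of
        replicates."""
        rng = np.random.default_rng(11)
        keep = 0
        for _ in range(100):
            df = pd.DataFrame({
                "g": np.repeat(list("abc"), 50),
                "v": rng.normal(0.0, 1.0, 150),
            })
            if compare_groups(df, "v", "g").p_value > 0.05:
                keep += 1
        assert keep >= 90

    def test_separated_groups_detected_with_distinct_letters(self):
        """Location shifts of 0/1/2 SD at n=50 are detected essentially
        always, with three distinct letters."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(40):
            df = pd.DataFrame({
                "g": np.repeat(list("abc"), 50),
                "v": np.concatenate([rng.normal(d, 1.0, 50)
                                     for d in (0.0, 1.0, 2.0)]),
            })
            comp = compare_groups(df, "v", "g")
            letters = set(comp.letters.values())
            if comp.p_value < 0.05 and len(letters) == 3:
                hits += 1
        assert hits >= 38

    def test_two_group_fallback(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b"], 40),
            "v": np.concatenate([rng.normal(0, 1, 40),
                                 rng.normal(3, 1, 40)]),
        })
        comp = compare_groups(df, "v", "g")
        assert comp.p_value < 0.05
        assert sorted(comp.letters.values()) == ["a", "b"]

    def test_two_similar_groups_share_a_letter(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b"], 40),
            "v": rng.normal(0, 1, 80),
        })
        comp = compare_groups(df, "v", "g")
        assert set(comp.letters.values()) == {"a"}

    def test_every_group_gets_a_letter(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "g": np.repeat(list("abcde"), 30),
            "v": np.concatenate([rng.normal(d, 1.0, 30)
                                 for d in (0, 0.2, 1.5, 1.6, 4.0)]),
        })
        comp = compare_groups(df, "v", "g")
        assert all(len(v) >= 1 for v in comp.letters.values())
        # groups sharing a letter were not significantly different
        for a, b in [("a", "b"), ("c", "d")]:
            row = comp.pairwise_p.query(
                "group_a in @a and group_b in @b or "
                "group_a in @b and group_b in @a")
            if (row["p_holm"] >= comp.alpha).all():
                assert set(comp.letters[a]) & set(comp.letters[b])

    def test_single_group_rejected(self):
        df = pd.DataFrame({"g": ["a"] * 5, "v": range(5)})
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(df, "v", "g")


class TestAffinityMatrix:
    def test_single_cell(self):
        df = pd.DataFrame({"species": ["s"], "model": ["DM5"], "J": [91.3]})
        mat = model_affinity_matrix(df)
        assert mat.shape == (1, 1)
        assert mat.loc["s", "DM5"] == 91.3

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "species": rng.choice(["x", "y"], 30),
            "model": rng.choice(["DM5", "DM6"], 30),
            "J": rng.uniform(70, 95, 30),
        })
        a = model_affinity_matrix(df)
        b = model_affinity_matrix(df.sample(frac=1.0, random_state=9))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_cells_are_nan_and_sorted(self):
        df = pd.DataFrame({
            "species": ["y", "x", "x"],
            "model": ["DM6", "DM5", "DM6"],
            "J": [80.0, 90.0, 70.0],
        })
        mat = model_affinity_matrix(df)
        assert list(mat.index) == ["x", "y"]
        assert list(mat.columns) == ["DM5", "DM6"]
        assert np.isnan(mat.loc["y", "DM5"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            model_affinity_matrix(pd.DataFrame(columns=["species", "model",
                                                        "J"]))


class TestShapeVsSizeVariability:
    def test_shape_traits_vary_less_than_size_traits(self):
        """On synthetic populations, CV of AR/C/R stays below CV of A/P:
        shape varies less than size."""
        from seedshape.morphometry import measure_mask
        from seedshape.synthetic import SyntheticSeedConfig, \
            generate_population
        masks, _ = generate_population(
            "DM2", 15, SyntheticSeedConfig(rng_seed=19, height_px=120))
        rows = [measure_mask(m).as_dict() for m in masks]
        df = pd.DataFrame(rows)
        df["pop"] = "p"
        out = summarize(df, "pop")
        for shape_trait in ("AR", "C", "R"):
            for size_trait in ("A", "P"):
                assert (out.loc["p", f"{shape_trait}_cv"]
                        < out.loc["p", f"{size_trait}_cv"])
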