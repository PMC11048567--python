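"""Floristic metrics: relative abundance, richness, FQI, dominance,
Rényi profiles, and species accumulation (with enumeration oracles)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invgrad import (
    AbundanceVector,
    DataModelError,
    PlotSample,
    dominants_50_20,
    fqi,
    mean_native_richness,
    mean_plot_fqi,
    relative_abundance,
    renyi_profile,
    species_accumulation,
)
from conftest import INVADER, make_dataset


def plot(pid, cover, group="A", tid="T01"):
    return PlotSample(plot_id=pid, transect_id=tid, group=group, cover=cover)


class TestRelativeAbundance:
    def test_single_species(self):
        av = relative_abundance([plot("p", {"a": 38.0})])
        assert av.proportions == {"a": 1.0}

    def test_hand_example(self):
        av = relative_abundance([plot("p", {"a": 15.0, "b": 5.0})])
        assert av.proportions["a"] == pytest.approx(0.75)
        assert av.proportions["b"] == pytest.approx(0.25)

    def test_all_zero_rejected(self):
        with pytest.raises(DataModelError):
            relative_abundance([plot("p", {"a": 0.0})])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.dictionaries(
            st.sampled_from("abcdefgh"),
            st.floats(min_value=0.1, max_value=98),
            min_size=1,
        )
    )
    def test_normalization(self, cover):
        av = relative_abundance([plot("p", cover)])
        assert sum(av.proportions.values()) == pytest.approx(1.0, abs=1e-9)


class TestNativeRichness:
    def test_invader_excluded(self):
        ds = make_dataset([{g: ({"a": 3.0, "b": 3.0, "c": 3.0, INVADER: 63.0}
                                if g == "A" else {"a": 3.0}) for g in "ABCDE"}])
        assert mean_native_richness(ds.plots_in_group("A"), ds) == 3.0

    def test_mean_over_plots(self):
        groups = {
            "A": {f"s{i}": 3.0 for i in range(4)},
            "B": {f"s{i}": 3.0 for i in range(6)},
        }
        groups.update({g: {"s0": 3.0} for g in "CDE"})
        ds = make_dataset([groups])
        plots = [p for p in ds.plots if p.group in "AB"]
        assert mean_native_richness(plots, ds) == pytest.approx(5.0)

    def test_nonnatives_excluded(self):
        ds = make_dataset(
            [{g: {"exotic": 15.0, "nat": 3.0} for g in "ABCDE"}],
            natives={"exotic": False, "nat": True},
        )
        assert mean_native_richness(ds.plots, ds) == 1.0


class TestFQI:
    def test_constant_c(self):
        ds = make_dataset(
            [{g: {f"s{i}": 3.0 for i in range(4)} for g in "ABCDE"}],
            c_values={f"s{i}": 4 for i in range(4)},
        )
        assert fqi(ds.plots, ds) == pytest.approx(8.0)

    def test_single_species(self):
        ds = make_dataset([{g: {"s0": 3.0} for g in "ABCDE"}], c_values={"s0": 7})
        assert fqi(ds.plots, ds) == pytest.approx(7.0)

    def test_hand_example_nine_species(self):
        cs = {f"s{i}": c for i, c in enumerate([3, 5, 8, 2, 6, 0, 4, 7, 1])}
        ds = make_dataset([{g: {n: 3.0 for n in cs} for g in "ABCDE"}], c_values=cs)
        assert fqi(ds.plots, ds) == pytest.approx(12.0)  # mean 4 * sqrt(9)

    def test_missing_c_values_excluded(self):
        ds = make_dataset(
            [{g: {"s0": 3.0, "s1": 3.0} for g in "ABCDE"}],
            c_values={"s0": 4, "s1": None},
        )
        assert fqi(ds.plots, ds) == pytest.approx(4.0)

    def test_no_qualifying_species_is_zero(self):
        ds = make_dataset(
            [{g: {"exotic": 3.0} for g in "ABCDE"}], natives={"exotic": False}
        )
        assert fqi(ds.plots, ds) == 0.0

    def test_sqrt_s_scaling(self):
        # constant mean C: FQI grows as sqrt of richness
        vals = []
        for s in (4, 16):
            ds = make_dataset(
                [{g: {f"s{i}": 3.0 for i in range(s)} for g in "ABCDE"}],
                c_values={f"s{i}": 5 for i in range(16)},
            )
            vals.append(fqi(ds.plots, ds))
        assert vals[1] / vals[0] == pytest.approx(2.0)

    def test_mean_plot_fqi_identical_plots_match_pooled(self):
        ds = make_dataset(
            [{g: {f"s{i}": 3.0 for i in range(4)} for g in "ABCDE"}],
            c_values={f"s{i}": 4 for i in range(4)},
        )
        assert mean_plot_fqi(ds.plots, ds) == pytest.approx(fqi(ds.plots, ds))

    def test_mean_plot_fqi_below_pooled_for_turnover(self):
        # each plot holds one species (C=4): per-plot FQI 4, pooled 4*sqrt(5)
        ds = make_dataset(
            [{g: {f"s{i}": 3.0} for i, g in enumerate("ABCDE")}],
            c_values={f"s{i}": 4 for i in range(5)},
        )
        assert mean_plot_fqi(ds.plots, ds) == pytest.approx(4.0)
        assert fqi(ds.plots, ds) == pytest.approx(4.0 * math.sqrt(5))

    def test_mean_plot_fqi_empty_rejected(self):
        ds = make_dataset([{g: {"s0": 3.0} for g in "ABCDE"}], c_values={"s0": 7})
        with pytest.raises(DataModelError):
            mean_plot_fqi([], ds)


class TestDominants5020:
    def test_hand_example(self):
        av = AbundanceVector({"a": 0.40, "b": 0.25, "c": 0.20, "d": 0.15})
        assert dominants_50_20(av) == ["a", "b", "c"]

    def test_single_species(self):
        assert dominants_50_20(AbundanceVector({"a": 1.0})) == ["a"]

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=10)
    )
    def test_cumulative_at_least_half(self, raw):
        total = sum(raw)
        av = AbundanceVector({f"s{i}": v / total for i, v in enumerate(raw)})
        doms = dominants_50_20(av)
        assert doms
        assert sum(av.proportions[d] for d in doms) >= 0.5 - 1e-9

    def test_every_20pct_species_included(self):
        av = AbundanceVector({"a": 0.30, "b": 0.30, "c": 0.25, "d": 0.15})
        doms = dominants_50_20(av)
        assert set(doms) >= {s for s, p in av.proportions.items() if p >= 0.2}


class TestRenyi:
    def test_uniform_profile_flat(self):
        av = AbundanceVector({f"s{i}": 1 / 8 for i in range(8)})
        prof = renyi_profile(av)
        for v in prof.values:
            assert v == pytest.approx(math.log(8), abs=1e-12)

    def test_closed_forms(self):
        av = AbundanceVector({"a": 0.5, "b": 0.5})
        prof = renyi_profile(av, alphas=[2])
        assert prof.values[0] == pytest.approx(-math.log(0.5))
        av = AbundanceVector({"a": 0.7, "b": 0.2, "c": 0.1})
        prof = renyi_profile(av, alphas=[0, 1, 2, math.inf])
        assert prof.values[0] == pytest.approx(math.log(3))
        shannon = -sum(p * math.log(p) for p in (0.7, 0.2, 0.1))
        assert prof.values[1] == pytest.approx(shannon, abs=1e-9)
        assert prof.values[2] == pytest.approx(-math.log(0.54))
        assert prof.values[3] == pytest.approx(-math.log(0.7))

    def test_negative_alpha_rejected(self):
        with pytest.raises(DataModelError):
            renyi_profile(AbundanceVector({"a": 1.0}), alphas=[-1])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=12))
    def test_nonincreasing_in_alpha(self, raw):
        total = sum(raw)
        av = AbundanceVector({f"s{i}": v / total for i, v in enumerate(raw)})
        prof = renyi_profile(av)
        assert all(
            v1 >= v2 - 1e-9 for v1, v2 in zip(prof.values, prof.values[1:])
        )

    def test_shannon_limit_continuity(self):
        av = AbundanceVector({"a": 0.6, "b": 0.3, "c": 0.1})
        near = renyi_profile(av, alphas=[1 - 1e-7, 1, 1 + 1e-7])
        assert near.values[0] == pytest.approx(near.values[1], abs=1e-5)
        assert near.values[2] == pytest.approx(near.values[1], abs=1e-5)


def enumeration_oracle(plots):
    """Mean richness over all equally likely subsets of each size."""
    n = len(plots)
    present = [p.species_present() for p in plots]
    means = []
    for k in range(1, n + 1):
        richness = [
            len(frozenset().union(*(present[i] for i in combo)))
            for combo in itertools.combinations(range(n), k)
        ]
        means.append(float(np.mean(richness)))
    return means


class TestAccumulation:
    @pytest.fixture()
    def four_plots(self):
        # incidences a:1110, b:1000, c:0011
        covers = [
            {"a": 3.0, "b": 3.0},
            {"a": 3.0},
            {"a": 3.0, "c": 3.0},
            {"c": 3.0},
        ]
        return [plot(f"p{i}", c) for i, c in enumerate(covers)]

    def test_exact_matches_enumeration(self, four_plots):
        curve = species_accumulation(four_plots, method="exact")
        oracle = enumeration_oracle(four_plots)
        assert np.allclose(curve.expected_richness, oracle, atol=1e-12)

    def test_exact_matches_enumeration_six_plots(self, default_study):
        plots = list(default_study.plots[:6])
        curve = species_accumulation(plots, method="exact")
        oracle = enumeration_oracle(plots)
        assert np.allclose(curve.expected_richness, oracle, atol=1e-12)

    def test_terminal_value_is_total_richness(self, four_plots):
        for method in ("exact", "permutation"):
            curve = species_accumulation(four_plots, method=method, seed=0)
            assert curve.expected_richness[-1] == 3.0

    def test_first_value_is_mean_plot_richness(self, four_plots):
        curve = species_accumulation(four_plots, method="exact")
        assert curve.expected_richness[0] == pytest.approx(np.mean([2, 1, 2, 1]))

    def test_monotone_nondecreasing(self, default_study):
        plots = default_study.plots_in_group("C")
        curve = species_accumulation(plots, method="exact")
        assert all(
            a <= b + 1e-12
            for a, b in zip(curve.expected_richness, curve.expected_richness[1:])
        )

    def test_permutation_converges_to_exact(self, four_plots):
        exact = species_accumulation(four_plots, method="exact")
        perm = species_accumulation(four_plots, method="permutation", n_perm=3000, seed=1)
        mc_se = np.array(perm.spread) / math.sqrt(3000)
        diff = np.abs(np.array(perm.expected_richness) - np.array(exact.expected_richness))
        assert np.all(diff <= np.maximum(4 * mc_se, 0.05))

    def test_invalid_n_perm(self, four_plots):
        with pytest.raises(DataModelError):
            species_accumulation(four_plots, method="permutation", n_perm=0)
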