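"""Barcode-screen processing: normalisation chain, robust Z, combination calls."""

import numpy as np
import pandas as pd
import pytest

from synscreen import hiphop
from synscreen.hiphop import (
    DegenerateScaleError,
    cluster_profiles,
    combination_specific,
    linkage_to_newick,
    quantile_normalize,
    robust_z,
    saturation_correct,
    select_tag,
    sensitivity_epsilon,
    snm_normalize,
    specific_set,
)
from synscreen.synth import SCREEN_ROLES, SynthConfig, gen_combination_screens


def long_table(values_by_array, batches=None, treatments=None):
    """Build an intensity table from {array: {probe_label: value}}."""
    rows = []
    for array, probes in values_by_array.items():
        for label, value in probes.items():
            strain, tag, rep = label.rsplit("|", 2)
            rows.append(
                {
                    "strain": strain,
                    "tag": tag,
                    "replicate": int(rep),
                    "intensity": value,
                    "array": array,
                    "batch": (batches or {}).get(array, "b1"),
                    "treatment": (treatments or {}).get(array, array),
                    "essentiality": "het-essential",
                    "is_control": strain.startswith("ctrl"),
                }
            )
    return pd.DataFrame(rows)


class TestQuantileNormalize:
    def probes(self, values):
        return {f"s{i}|up|1": v for i, v in enumerate(values)}

    def test_identical_arrays_unchanged(self):
        t = long_table({"a1": self.probes([1, 2, 3]), "a2": self.probes([1, 2, 3])})
        out = quantile_normalize(t)
        assert np.allclose(out["intensity"], t["intensity"])

    def test_doubled_array_maps_to_mean_order_statistics(self):
        t = long_table({"a1": self.probes([1, 2, 3]), "a2": self.probes([2, 4, 6])})
        out = quantile_normalize(t)
        for arr in ("a1", "a2"):
            got = np.sort(out.loc[out["array"] == arr, "intensity"])
            assert np.allclose(got, [1.5, 3.0, 4.5])

    def test_sorted_vectors_identical_after_normalization(self):
        rng = np.random.default_rng(1)
        t = long_table(
            {f"a{k}": self.probes(rng.lognormal(3, 1, 50)) for k in range(4)}
        )
        out = quantile_normalize(t)
        sorted_cols = [
            np.sort(out.loc[out["array"] == f"a{k}", "intensity"]) for k in range(4)
        ]
        for col in sorted_cols[1:]:
            assert np.allclose(col, sorted_cols[0])

    def test_rank_preserved_within_array(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(3, 1, 30)
        t = long_table(
            {"a1": self.probes(vals), "a2": self.probes(rng.lognormal(3, 1, 30))}
        )
        out = quantile_normalize(t)
        before = t.loc[t["array"] == "a1", "intensity"].to_numpy()
        after = out.loc[out["array"] == "a1", "intensity"].to_numpy()
        assert (np.argsort(before) == np.argsort(after)).all()

    def test_unequal_probe_counts_rejected(self):
        t = long_table({"a1": self.probes([1, 2, 3]), "a2": self.probes([1, 2])})
        with pytest.raises(ValueError):
            quantile_normalize(t)


class TestSaturationCorrect:
    def table(self, values):
        return long_table({"a1": {f"s{i}|up|1": v for i, v in enumerate(values)}})

    def test_far_from_ceiling_nearly_identity(self):
        c = 1000.0
        t = self.table([1.0, 5.0, 9.0])
        out = saturation_correct(t, ceiling=c)
        assert np.allclose(out["intensity"], t["intensity"], rtol=0.01)

    def test_half_ceiling_maps_to_ceiling(self):
        out = saturation_correct(self.table([500.0]), ceiling=1000.0)
        assert out["intensity"].iloc[0] == pytest.approx(1000.0)

    def test_inverts_simulated_transfer_function(self):
        c = 1000.0
        x = np.linspace(10, 0.9 * c, 50)
        y = c * x / (c + x)  # simulated saturated measurement
        out = saturation_correct(self.table(list(y)), ceiling=c)
        assert np.allclose(out["intensity"], x, rtol=0.02)

    def test_near_ceiling_winsorized_and_flagged(self):
        out = saturation_correct(self.table([990.0, 100.0]), ceiling=1000.0)
        assert bool(out["saturated"].iloc[0]) is True
        assert bool(out["saturated"].iloc[1]) is False
        assert np.isfinite(out["intensity"]).all()


class TestSnmNormalize:
    def build(self, batch_effect=0.0, n_probes=12):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, n_probes)
        treat_effect = {"t1": 0.0, "t2": -1.0}
        arrays = {}
        batches, treatments = {}, {}
        for t in ("t1", "t2"):
            for b_idx, b in enumerate(("b1", "b2")):
                arr = f"{t}@{b}"
                shift = batch_effect * b_idx
                arrays[arr] = {
                    f"s{i}|up|1": base[i] + treat_effect[t] + shift
                    for i in range(n_probes)
                }
                batches[arr] = b
                treatments[arr] = t
        return long_table(arrays, batches, treatments)

    def test_no_batch_effect_is_identity(self):
        t = self.build(batch_effect=0.0)
        out = snm_normalize(t)
        assert np.allclose(out["intensity"], t["intensity"], atol=1e-9)

    def test_additive_batch_shift_removed_treatment_contrast_kept(self):
        t = self.build(batch_effect=0.5)
        out = snm_normalize(t)
        means = out.groupby(["treatment", "batch"])["intensity"].mean()
        # batch contrast gone
        assert means["t1"]["b1"] == pytest.approx(means["t1"]["b2"], abs=1e-9)
        # treatment contrast preserved within 5%
        contrast = means["t1"].mean() - means["t2"].mean()
        assert contrast == pytest.approx(1.0, rel=0.05)

    def test_single_batch_is_noop(self):
        t = self.build(batch_effect=0.0)
        t["batch"] = "b1"
        out = snm_normalize(t)
        assert np.allclose(out["intensity"], t["intensity"])

    def test_confounded_design_refused(self):
        t = self.build(batch_effect=0.5)
        # make each batch hold exactly one treatment
        t["batch"] = np.where(t["treatment"] == "t1", "b1", "b2")
        with pytest.raises(ValueError, match="confounded"):
            snm_normalize(t)


class TestSelectTag:
    def strain_rows(self, strain, tag, reps, array="a1"):
        return {f"{strain}|{tag}|{r + 1}": v for r, v in enumerate(reps)}

    def test_lower_cv_tag_wins(self):
        t = long_table(
            {
                "a1": {
                    **self.strain_rows("s1", "up", [10, 10.1, 9.9, 10, 10]),
                    **self.strain_rows("s1", "down", [10, 14, 6, 12, 8]),
                }
            }
        )
        assert select_tag(t)["s1"] == "up"
        noisy_up = long_table(
            {
                "a1": {
                    **self.strain_rows("s1", "up", [10, 14, 6, 12, 8]),
                    **self.strain_rows("s1", "down", [10, 10.1, 9.9, 10, 10]),
                }
            }
        )
        assert select_tag(noisy_up)["s1"] == "down"

    def test_tie_prefers_uptag(self):
        t = long_table(
            {
                "a1": {
                    **self.strain_rows("s1", "up", [10, 11, 9, 10, 10]),
                    **self.strain_rows("s1", "down", [10, 11, 9, 10, 10]),
                }
            }
        )
        assert select_tag(t)["s1"] == "up"

    def test_degenerate_zero_mean_tag_disqualified(self):
        t = long_table(
            {
                "a1": {
                    **self.strain_rows("s1", "up", [0, 0, 0, 0, 0]),
                    **self.strain_rows("s1", "down", [10, 11, 9, 10, 10]),
                }
            }
        )
        assert select_tag(t)["s1"] == "down"


class TestRobustZ:
    def build(self, strain_values, control_values, treatment="t"):
        probes = {}
        for strain, v in strain_values.items():
            probes[f"{strain}|up|1"] = v
        for i, v in enumerate(control_values):
            probes[f"ctrl_{i}|up|1"] = v
        return long_table({"a1": probes}, treatments={"a1": treatment})

    def test_strain_at_control_median_scores_zero(self):
        t = self.build({"s1": 3.0}, [1, 2, 3, 4, 5])
        p = robust_z(t, "t", tag_used=pd.Series({"s1": "up"}))
        assert p.z["s1"] == pytest.approx(0.0)

    def test_stated_formula_arithmetic(self):
        # controls {1..5}: median 3, MAD 1 -> scale 1.4826; x = 1.5173 -> z ~ +1
        t = self.build({"s1": 1.5174}, [1, 2, 3, 4, 5])
        p = robust_z(t, "t", tag_used=pd.Series({"s1": "up"}))
        assert p.z["s1"] == pytest.approx(1.0, abs=1e-3)

    def test_depletion_scores_positive(self):
        t = self.build({"weak": 1.0, "strong": 5.0}, [1, 2, 3, 4, 5])
        p = robust_z(t, "t", tag_used=pd.Series({"weak": "up", "strong": "up"}))
        assert p.z["weak"] > 0 > p.z["strong"]

    def test_constant_controls_degenerate(self):
        t = self.build({"s1": 1.0}, [3, 3, 3, 3])
        with pytest.raises(DegenerateScaleError):
            robust_z(t, "t", tag_used=pd.Series({"s1": "up"}))

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        strains = {f"s{i}": v for i, v in enumerate(rng.normal(10, 1, 8))}
        controls = list(rng.normal(10, 1, 9))
        tags = pd.Series({s: "up" for s in strains})
        base = robust_z(self.build(strains, controls), "t", tag_used=tags)
        shifted = robust_z(
            self.build(
                {s: 2.5 * v + 7 for s, v in strains.items()},
                [2.5 * v + 7 for v in controls],
            ),
            "t",
            tag_used=tags,
        )
        assert np.allclose(base.z.to_numpy(), shifted.z.to_numpy())


class TestCombinationSpecific:
    def test_clean_combination_hit_included(self, combo_result):
        r = combo_result(
            {"s1": 3.1}, {"s1": 0.5}, {"s1": 1.0}, {"s1": 1.9}, {"s1": 0.2}
        )
        assert specific_set(r) == {"s1"}

    def test_single_agent_hit_excluded(self, combo_result):
        r = combo_result(
            {"s1": 3.1}, {"s1": 2.5}, {"s1": 1.0}, {"s1": 0.1}, {"s1": 0.2}
        )
        assert specific_set(r) == set()

    def test_weak_combination_excluded(self, combo_result):
        r = combo_result({"s1": 1.9})
        assert specific_set(r) == set()

    def test_threshold_is_inclusive_for_combo_strict_for_singles(self, combo_result):
        r = combo_result({"s1": 2.0}, {"s1": 2.0})
        assert specific_set(r) == set()  # single at exactly 2.0 disqualifies
        r = combo_result({"s1": 2.0}, {"s1": 1.999})
        assert specific_set(r) == {"s1"}

    def test_monotone_shrinking_in_threshold(self, combo_result):
        z = {f"s{i}": v for i, v in enumerate([3.5, 2.5, 1.5, 4.5, 0.5])}
        r = combo_result(z)
        sizes = [len(specific_set(r, thr)) for thr in (1.0, 2.0, 3.0, 4.0, 99.0)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0

    def test_panels_reported_separately(self, combo_result):
        ess = {"s1": "het-essential", "s2": "hom-nonessential"}
        r = combo_result({"s1": 3.0, "s2": 3.0}, essentiality=ess)
        panels = combination_specific(r)
        assert panels == {
            "het-essential": {"s1"},
            "hom-nonessential": {"s2"},
        }


class TestSensitivityEpsilon:
    def test_product_and_sum_modes(self, combo_result):
        r = combo_result(
            {"s": 4.0}, {"s": 9.0}, {"s": 1.0}, {"s": 9.0}, {"s": 1.0}
        )  # combo-dose screens hold z_A = z_B = 1
        assert sensitivity_epsilon(r, "product")["s"] == pytest.approx(3.0)
        assert sensitivity_epsilon(r, "sum")["s"] == pytest.approx(2.0)

    def test_multiplicative_null_is_zero(self, combo_result):
        r = combo_result(
            {"s": 6.0}, {"s": 0.0}, {"s": 2.0}, {"s": 0.0}, {"s": 3.0}
        )
        assert sensitivity_epsilon(r, "product")["s"] == pytest.approx(0.0)

    def test_spiked_specific_strain_keeps_full_epsilon(self, combo_result):
        r = combo_result({"s": 5.0})
        assert sensitivity_epsilon(r, "product")["s"] == pytest.approx(5.0)
        assert sensitivity_epsilon(r, "sum")["s"] == pytest.approx(5.0)


class TestClustering:
    def test_identical_profiles_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 10)
        mat = pd.DataFrame({"a": v, "b": v, "c": rng.normal(0, 1, 10)}).T
        link, labels = cluster_profiles(mat)
        first = link[0]
        assert {labels[int(first[0])], labels[int(first[1])]} == {"a", "b"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_at_distance_two(self):
        v = np.array([1.0, -2.0, 3.0, 0.5])
        mat = pd.DataFrame({"a": v, "b": -v}).T
        link, _ = cluster_profiles(mat)
        assert link[0][2] == pytest.approx(2.0)

    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(5)
        centers = {"A": rng.normal(0, 1, 20), "B": rng.normal(0, 1, 20),
                   "C": rng.normal(0, 1, 20)}
        rows = {}
        truth = {}
        for g, center in centers.items():
            for i in range(4):
                name = f"{g}{i}"
                rows[name] = center + rng.normal(0, 0.01, 20)
                truth[name] = g
        mat = pd.DataFrame(rows).T
        link, labels = cluster_profiles(mat)
        from scipy.cluster.hierarchy import fcluster

        assign = fcluster(link, t=3, criterion="maxclust")
        groups = {}
        for lab, cl in zip(labels, assign):
            groups.setdefault(cl, set()).add(truth[lab])
        assert all(len(g) == 1 for g in groups.values())
        assert len(groups) == 3

    def test_newick_round_trip_labels(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(0, 1, (4, 6)), index=list("abcd"))
        link, labels = cluster_profiles(mat)
        nwk = linkage_to_newick(link, labels)
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")") == 3
        for lab in "abcd":
            assert lab in nwk


class TestFiveScreenPipeline:
    def test_spikes_recovered_with_high_precision_and_recall(self):
        from synscreen.cli import process_five_screens

        table, spikes = gen_combination_screens(SynthConfig(seed=1))
        result = process_five_screens(table, {r: r for r in SCREEN_ROLES})
        called = specific_set(result)
        tp = len(called & spikes)
        assert tp / len(spikes) >= 0.9
        assert tp / max(len(called), 1) >= 0.9

    def test_spike_leaked_into_single_screen_is_gated_out(self):
        from synscreen.cli import process_five_screens

        table, spikes = gen_combination_screens(
            SynthConfig(seed=2, spikes_in_single=5)
        )
        result = process_five_screens(table, {r: r for r in SCREEN_ROLES})
        called = specific_set(result)
        leaked = sorted(spikes)  # first 5 picked spikes leak into a_ic20
        table2, _ = gen_combination_screens(SynthConfig(seed=2, spikes_in_single=0))
        clean = specific_set(
            process_five_screens(table2, {r: r for r in SCREEN_ROLES})
        )
        assert len(called) <= len(clean) - 5 + 1  # leaked spikes dropped
        assert called <= spikes
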