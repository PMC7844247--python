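import numpy as np
import pandas as pd
import pytest

from riboshift import (
    FractionTable,
    abundance_max_filter,
    assign_fractions,
    call_changes,
    combine_60s_fractions,
    compositional_calls,
    generate_lfq_experiment,
    normalize_shares,
    select_shared,
    simulated_catalog,
    total_rp_summary,
    transcript_protein_association,
)
from riboshift.synthetic import ProteomeSimConfig, study_planted_proteome_changes


class TestAssignFractions:
    def test_planted_class_profiles_recover_planted_order(self):
        cfg = ProteomeSimConfig(noise_cv=0.0, seed=1)
        tables, _ = generate_lfq_experiment(cfg)
        table = FractionTable(tables[("Col-0", "20C")], cfg.catalog)
        identity = assign_fractions(table)
        assert identity.labels == {
            "F1": "30S/40S",
            "F2": "50S",
            "F3": "60S",
            "F4": "60S/80S",
            "F6": "polysome",
        }

    def test_marker_fractions_restricted_to_60s_labels(self, labeled_table):
        identity = assign_fractions(labeled_table)
        for marker in ("eIF6A", "NMD3"):
            frac = labeled_table.data.loc[marker].idxmax()
            assert identity.labels[frac] in ("60S", "60S/80S")

    def test_single_fraction_of_40s_rps_forced(self, toy_catalog):
        data = pd.DataFrame({"F1": [10.0, 8.0]}, index=["S1", "S2"])
        identity = assign_fractions(FractionTable(data, toy_catalog))
        assert identity.labels == {"F1": "30S/40S"}

    def test_no_rps_errors(self, toy_catalog):
        data = pd.DataFrame({"F1": [1.0], "F2": [2.0]}, index=["X"])
        with pytest.raises(ValueError, match="no ribosomal proteins"):
            assign_fractions(FractionTable(data, toy_catalog))


class TestTotalRPSummary:
    def test_toy_sums_match_hand_arithmetic(self, labeled_table):
        totals = total_rp_summary(labeled_table)
        assert totals["RP60S"] == pytest.approx(
            labeled_table.data.loc[["L1", "L2"]].to_numpy().sum()
        )
        assert totals["RP40S"] == pytest.approx(
            labeled_table.data.loc[["S1", "S2"]].to_numpy().sum()
        )

    def test_single_protein_single_fraction(self, toy_catalog):
        data = pd.DataFrame({"F1": [7.5]}, index=["L1"])
        assert total_rp_summary(FractionTable(data, toy_catalog))["RP60S"] == 7.5

    def test_all_zero_table(self, toy_catalog):
        data = pd.DataFrame(np.zeros((2, 2)), index=["L1", "S1"], columns=["F1", "F2"])
        assert (total_rp_summary(FractionTable(data, toy_catalog)) == 0).all()


class TestNormalizeShares:
    def test_reference_shares_sum_to_one(self, labeled_table):
        identity = assign_fractions(labeled_table)
        shares = normalize_shares(labeled_table, identity, "60S")
        classes = labeled_table.classes()
        ref = [p for p in shares.shares.index if classes[p] == "RP60S"]
        assert np.allclose(shares.shares.loc[ref].sum(axis=0), 1.0)

    def test_hand_computed_toy_shares(self, toy_catalog):
        # one 60S-labeled fraction: 60S RPs at 2 and 6, factor X at 4
        data = pd.DataFrame(
            {"F1": [0.1, 0.1, 1.0], "F2": [2.0, 6.0, 4.0]}, index=["L1", "L2", "X"]
        )
        table = FractionTable(data, toy_catalog)
        from riboshift.riboproteome import FractionIdentity

        identity = FractionIdentity(labels={"F1": "30S/40S", "F2": "60S"})
        shares = normalize_shares(table, identity, "60S").shares
        assert shares.loc["L1", "F2"] == pytest.approx(0.25)
        assert shares.loc["L2", "F2"] == pytest.approx(0.75)
        assert shares.loc["X", "F2"] == pytest.approx(0.5)

    def test_scale_invariance_per_fraction(self, labeled_table):
        identity = assign_fractions(labeled_table)
        base = normalize_shares(labeled_table, identity, "60S").shares
        scaled_data = labeled_table.data.copy()
        scaled_data["F3"] *= 13.7
        scaled = FractionTable(scaled_data, labeled_table.catalog)
        rescaled = normalize_shares(scaled, identity, "60S").shares
        pd.testing.assert_frame_equal(base, rescaled)

    def test_40s_compartment_excludes_60s_rps(self, labeled_table):
        identity = assign_fractions(labeled_table)
        shares = normalize_shares(labeled_table, identity, "40S")
        assert not {"L1", "L2"} & set(shares.shares.index)

    def test_zero_reference_sum_excluded_with_warning(self, toy_catalog):
        data = pd.DataFrame({"F1": [0.0, 0.0, 1.0]}, index=["L1", "L2", "X"])
        from riboshift.riboproteome import FractionIdentity

        identity = FractionIdentity(labels={"F1": "60S"})
        shares = normalize_shares(FractionTable(data, toy_catalog), identity, "60S")
        assert shares.excluded_fractions == ["F1"]


class TestCombine60S:
    @staticmethod
    def make_shares(df):
        from riboshift.riboproteome import NormalizedShareTable

        return NormalizedShareTable(
            shares=df, compartment="60S", reference_sums=pd.Series(1.0, index=df.columns)
        )

    def test_equal_shares_pass_through(self):
        df = pd.DataFrame({"F3": [0.3], "F4": [0.3]}, index=["X"])
        assert combine_60s_fractions(self.make_shares(df))["X"] == pytest.approx(0.3)

    def test_mean_of_two_fractions(self):
        df = pd.DataFrame({"F3": [0.2], "F4": [0.4]}, index=["X"])
        assert combine_60s_fractions(self.make_shares(df))["X"] == pytest.approx(0.3)

    def test_missing_in_one_fraction_halves(self):
        df = pd.DataFrame({"F3": [0.4], "F4": [np.nan]}, index=["X"])
        assert combine_60s_fractions(self.make_shares(df))["X"] == pytest.approx(0.2)


class TestAbundanceMaxFilter:
    def test_peak_in_50s_fraction_excluded(self, toy_catalog):
        data = pd.DataFrame(
            {"F1": [1.0, 1.0, 0.1], "F2": [1.0, 1.0, 5.0], "F3": [10.0, 10.0, 2.0]},
            index=["L1", "L2", "X"],
        )
        from riboshift.riboproteome import FractionIdentity

        identity = FractionIdentity(labels={"F1": "30S/40S", "F2": "50S", "F3": "60S"})
        table = FractionTable(data, toy_catalog)
        assert not abundance_max_filter(table, identity, "X", "60S")
        assert abundance_max_filter(table, identity, "L1", "60S")

    def test_tie_resolves_against_inclusion(self, toy_catalog):
        data = pd.DataFrame({"F2": [1.0, 5.0], "F3": [1.0, 5.0]}, index=["L1", "X"])
        from riboshift.riboproteome import FractionIdentity

        identity = FractionIdentity(labels={"F2": "50S", "F3": "60S"})
        assert not abundance_max_filter(FractionTable(data, toy_catalog), identity, "X", "60S")

    def test_absent_protein_is_false(self, labeled_table):
        identity = assign_fractions(labeled_table)
        assert not abundance_max_filter(labeled_table, identity, "GHOST", "60S")


class TestCallChanges:
    def test_presence_absence_and_numeric_calls(self):
        mut = pd.Series({"A": 0.4, "B": 0.0, "C": 0.4, "D": 0.3})
        wt = pd.Series({"A": 0.0, "B": 0.2, "C": 0.4, "D": 0.1})
        calls = call_changes(mut, wt)
        assert calls.loc["A", "status"] == "+"
        assert calls.loc["B", "status"] == "-"
        assert calls.loc["C", "log2_fc"] == 0.0
        assert calls.loc["C", "magnitude_class"] == "weak_up"
        assert calls.loc["D", "log2_fc"] == pytest.approx(np.log2(3))
        assert calls.loc["D", "magnitude_class"] == "strong_up"

    def test_magnitude_boundaries(self):
        mut = pd.Series({"A": 2.0, "B": 1.0, "C": 0.25})
        wt = pd.Series({"A": 1.0, "B": 2.0, "C": 1.0})
        calls = call_changes(mut, wt)
        assert calls.loc["A", "magnitude_class"] == "weak_up"  # fc exactly 1
        assert calls.loc["B", "magnitude_class"] == "weak_down"  # fc exactly -1
        assert calls.loc["C", "magnitude_class"] == "strong_down"

    def test_numeric_antisymmetry(self, rng):
        a = pd.Series(rng.uniform(0.1, 1.0, 6), index=list("ABCDEF"))
        b = pd.Series(rng.uniform(0.1, 1.0, 6), index=list("ABCDEF"))
        fc_ab = call_changes(a, b)["log2_fc"]
        fc_ba = call_changes(b, a)["log2_fc"]
        assert np.allclose(fc_ab, -fc_ba)


class TestSelectShared:
    @staticmethod
    def calls(rows):
        df = pd.DataFrame(rows).set_index("protein_id")
        return df

    def example_calls(self):
        return self.calls(
            [
                dict(protein_id="A", status="+", log2_fc=np.nan, magnitude_class="presence",
                     temperature="10C"),
                dict(protein_id="B", status="numeric", log2_fc=1.5, magnitude_class="strong_up",
                     temperature="10C"),
                dict(protein_id="C", status="numeric", log2_fc=-0.5, magnitude_class="weak_down",
                     temperature="10C"),
            ]
        )

    def test_identical_sets_all_shared(self):
        a = self.example_calls()
        shared = select_shared(a, a.copy())
        assert set(shared.index) == {"A", "B", "C"}
        assert shared.attrs["n_increase"] == 2 and shared.attrs["n_decrease"] == 1

    def test_symmetry_in_experiments(self):
        a = self.example_calls()
        b = a.copy()
        b.loc["C", ["log2_fc", "magnitude_class"]] = [0.7, "weak_up"]
        s_ab = select_shared(a, b)
        s_ba = select_shared(b, a)
        assert set(s_ab.index) == set(s_ba.index) == {"A", "B"}

    def test_opposite_direction_excluded(self):
        a = self.example_calls()
        b = a.copy()
        b.loc["B", ["status", "log2_fc", "magnitude_class"]] = ["numeric", -1.5, "strong_down"]
        assert "B" not in select_shared(a, b).index

    def test_categorical_and_numeric_calls_can_agree(self):
        a = self.calls(
            [dict(protein_id="A", status="+", log2_fc=np.nan, magnitude_class="presence",
                  temperature="10C")]
        )
        b = self.calls(
            [dict(protein_id="A", status="numeric", log2_fc=0.4, magnitude_class="weak_up",
                  temperature="10C")]
        )
        assert list(select_shared(a, b).index) == ["A"]

    def test_both_temperatures_mode_requires_warm_agreement(self):
        rows = [
            dict(protein_id="A", status="numeric", log2_fc=1.2, magnitude_class="strong_up",
                 temperature="10C"),
            dict(protein_id="A", status="numeric", log2_fc=0.3, magnitude_class="weak_up",
                 temperature="20C"),
            dict(protein_id="B", status="numeric", log2_fc=1.2, magnitude_class="strong_up",
                 temperature="10C"),
            dict(protein_id="B", status="numeric", log2_fc=-0.3, magnitude_class="weak_down",
                 temperature="20C"),
        ]
        a = self.calls(rows)
        shared = select_shared(a, a.copy(), mode="both_temperatures")
        assert list(shared.index) == ["A"]


class TestEndToEnd:
    def make_experiment(self, experiment, seed, noise_cv=0.0, censor=0.0, planted=None):
        mutant = "reil1-1 reil2-2"
        if planted is None:
            # plant only on non-reference classes so shares of unplanted
            # proteins are untouched and zero-noise recovery is exact
            planted = (
                ("eIF6A", mutant, "10C", 2.5),
                ("NMD3", mutant, "10C", 2.5),
                ("RLP24", mutant, "10C", 0.4),
                ("NOG1", "Col-0", "10C", "absent"),
            )
        cfg = ProteomeSimConfig(
            genotypes=("Col-0", mutant),
            planted_changes=planted,
            noise_cv=noise_cv,
            censor_threshold=censor,
            experiment=experiment,
            seed=seed,
        )
        tables, ledger = generate_lfq_experiment(cfg)
        fts = {
            key: FractionTable(df, cfg.catalog, genotype=key[0], temperature=key[1])
            for key, df in tables.items()
        }
        return fts, ledger

    def test_zero_noise_shared_report_equals_planted_ledger(self):
        fts1, ledger = self.make_experiment("DS1", seed=21)
        fts2, _ = self.make_experiment("DS2", seed=22)
        calls1 = compositional_calls(fts1, "60S")
        calls2 = compositional_calls(fts2, "60S")
        shared = select_shared(calls1, calls2, mode="cold_only")
        expected = {
            "eIF6A": "increase",
            "NMD3": "increase",
            "RLP24": "decrease",
            "NOG1": "increase",
        }
        assert dict(shared["direction"]) == expected

    def test_planted_count_matches_construction(self):
        fts1, _ = self.make_experiment("DS1", seed=31)
        fts2, _ = self.make_experiment("DS2", seed=32)
        shared = select_shared(
            compositional_calls(fts1, "60S"), compositional_calls(fts2, "60S")
        )
        assert len(shared) == 4


class TestAssociation:
    def test_join_and_concordance(self, toy_catalog):
        calls = pd.DataFrame(
            {
                "status": ["numeric", "numeric", "+"],
                "log2_fc": [-1.2, 0.8, np.nan],
                "magnitude_class": ["strong_down", "weak_up", "presence"],
            },
            index=pd.Index(["L1", "L2", "GHOST"], name="protein_id"),
        )
        transcripts = pd.DataFrame(
            {"log2_fc": [-1.0, 0.5], "p_value": [0.001, 0.2]},
            index=["AT1G00010", "AT1G00020"],
        )
        out = transcript_protein_association(calls, toy_catalog, transcripts)
        # RPL3B-style: protein down, transcript down and significant
        assert out.loc["L1", "concordant"]
        # same direction but not significant
        assert not out.loc["L2", "concordant"]
        # no transcript record: retained with null partner
        assert np.isnan(out.loc["GHOST", "transcript_log2_fc"])

    def test_join_size_matches_construction(self, toy_catalog):
        calls = call_changes(
            pd.Series({"L1": 0.5, "S1": 0.2}), pd.Series({"L1": 0.25, "S1": 0.2})
        )
        transcripts = pd.DataFrame({"log2_fc": [1.0], "p_value": [0.01]}, index=["AT1G00010"])
        out = transcript_protein_association(calls, toy_catalog, transcripts)
        assert len(out) == 2
        assert out["transcript_log2_fc"].notna().sum() == 1


class TestScaleInvarianceEndToEnd:
    def test_calls_invariant_to_per_fraction_rescaling(self):
        cfg = ProteomeSimConfig(
            genotypes=("Col-0", "reil1-1 reil2-2"),
            planted_changes=tuple(study_planted_proteome_changes("reil1-1 reil2-2")),
            noise_cv=0.0,
            seed=41,
        )
        tables, _ = generate_lfq_experiment(cfg)
        fts = {
            k: FractionTable(v, cfg.catalog, genotype=k[0], temperature=k[1])
            for k, v in tables.items()
        }
        base = compositional_calls(fts, "60S")
        scaled = {
            k: FractionTable(
                v.data * np.array([3.0, 1.0, 0.5, 2.0, 1.0, 7.0]), cfg.catalog,
                genotype=v.genotype, temperature=v.temperature,
            )
            for k, v in fts.items()
        }
        rescaled = compositional_calls(scaled, "60S")
        pd.testing.assert_frame_equal(base.sort_index(), rescaled.sort_index())
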