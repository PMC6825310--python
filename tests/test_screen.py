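"""Screen mechanics: table shape, filters, masks, determinism, deltas."""

import math

import pandas as pd
import pytest

from clonalqn.qn_core import Perturbation, QNModelError, stabilize
from clonalqn.screen import (
    MIXED_TUMOR_CLONES,
    delta_matrix,
    druggable_targets,
    effective_monotherapies,
    evaluate_condition,
    export_matrix,
    export_table,
    healthy_toxicity_filter,
    run_screen,
)


class TestEvaluateCondition:
    def test_baseline_rows_are_viable(self, in_vivo, clones):
        res = evaluate_condition(in_vivo, clones["myc_low"], ())
        assert res.apoptosis.midpoint <= 3

    def test_same_node_pair_rejected(self, in_vivo, clones):
        with pytest.raises(QNModelError, match="nonsensical"):
            evaluate_condition(in_vivo, clones["myc_low"], ("MEK", "MEK"))

    def test_treating_a_clone_fixed_node_conflicts(self, in_vivo, clones):
        with pytest.raises(QNModelError, match="already fixed"):
            evaluate_condition(in_vivo, clones["myc_high_pure"], ("Myc",))

    def test_unordered_pair_semantics(self, in_vivo, clones):
        a = evaluate_condition(in_vivo, clones["myc_low"], ("COX2", "MEK"))
        b = evaluate_condition(in_vivo, clones["myc_low"], ("MEK", "COX2"))
        assert a == b

    def test_phd2_inhibition_toxic_in_healthy(self, in_vivo, clones):
        res = evaluate_condition(in_vivo, clones["healthy"], ("PHD2",))
        assert res.apoptosis.midpoint > 3

    def test_phd2_vhl_mutual_pair_not_toxic(self, in_vivo, clones):
        res = evaluate_condition(in_vivo, clones["healthy"], ("PHD2", "VHL"))
        assert res.apoptosis.midpoint <= 3


class TestRunScreen:
    def test_row_count_mono_plus_pairs(self, druggable_screen, in_vivo, clones):
        m = len(druggable_targets(in_vivo))
        expected_per_clone = 1 + m + m * (m - 1) // 2  # baseline + monos + pairs
        counts = druggable_screen.data.groupby("clone").size()
        assert (counts == expected_per_clone).all()
        assert len(counts) == len(clones)

    def test_rerun_with_same_seed_is_identical(self, in_vivo, clones, druggable_screen, tmp_path):
        again = run_screen(in_vivo, clones, seed=1)
        export_table(druggable_screen, tmp_path / "a.csv")
        export_table(again, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_provenance_records_model_hash_and_seed(self, druggable_screen):
        prov = druggable_screen.provenance
        assert prov["seed"] == 1
        assert len(prov["model_hash"]) == 16

    def test_inhibiting_an_already_zero_node_changes_nothing(self, in_vivo, clones):
        """In the pure Myc-high clone Wnt1 is already driven to 0, so
        inhibiting it leaves the phenotype summaries unchanged."""
        c = clones["myc_high_pure"]
        _, s, _ = stabilize(in_vivo, c.perturbation_list(), seed=0)
        assert (s["Wnt1"].min, s["Wnt1"].max) == (0, 0)
        base = evaluate_condition(in_vivo, c, ())
        treated = evaluate_condition(in_vivo, c, ("Wnt1",))
        assert base.proliferation == treated.proliferation
        assert base.apoptosis == treated.apoptosis


class TestToxicityFilter:
    def test_strict_threshold_boundary(self, druggable_screen):
        mask = healthy_toxicity_filter(druggable_screen, threshold=3.0)
        tab = druggable_screen.data
        healthy = tab[(tab["clone"] == "healthy") & (tab["n_inhibitors"] > 0)]
        for _, row in healthy.iterrows():
            assert mask[row["treatment"]] == (row["apoptosis_mid"] > 3.0)

    def test_phd2_and_vhl_toxic_except_with_each_other(self, druggable_screen):
        mask = healthy_toxicity_filter(druggable_screen)
        assert mask["PHD2"] and mask["VHL"]
        assert not mask["PHD2+VHL"]
        for t, toxic in mask.items():
            parts = set(t.split("+"))
            if parts & {"PHD2", "VHL"} and parts != {"PHD2", "VHL"}:
                assert toxic, t

    def test_missing_healthy_rows_is_an_error(self, in_vivo, clones):
        tab = run_screen(
            in_vivo, [clones["myc_low"]], targets=["MEK"], seed=0
        )
        with pytest.raises(QNModelError, match="healthy"):
            healthy_toxicity_filter(tab)

    def test_masking_is_monotone_in_threshold(self, druggable_screen):
        loose = healthy_toxicity_filter(druggable_screen, threshold=3.5)
        tight = healthy_toxicity_filter(druggable_screen, threshold=2.5)
        assert all(tight[t] or not loose[t] for t in loose)


class TestEffectiveMonotherapies:
    def test_mek_is_effective_for_apoptosis(self, druggable_screen):
        assert "MEK" in effective_monotherapies(druggable_screen, "apoptosis")

    def test_no_change_targets_are_not_effective(self, druggable_screen):
        eff = effective_monotherapies(druggable_screen, "apoptosis")
        assert "VEGF" not in eff  # VEGF feeds angiogenesis, not apoptosis
        assert "GSK3b" not in eff  # GSK3b inhibition is pro-survival

    def test_epsilon_drops_marginal_targets(self, druggable_screen):
        strict = set(effective_monotherapies(druggable_screen, "apoptosis", eps=0.0))
        demanding = set(effective_monotherapies(druggable_screen, "apoptosis", eps=2.0))
        assert demanding <= strict


class TestDeltaMatrix:
    def test_delta_is_pair_minus_mono_averaged_over_clones(self, druggable_screen):
        dm = delta_matrix(druggable_screen, "apoptosis")
        want = sum(
            druggable_screen.midpoint(c, ("COX2", "MEK"), "apoptosis")
            - druggable_screen.midpoint(c, ("COX2",), "apoptosis")
            for c in MIXED_TUMOR_CLONES
        ) / 2
        assert dm.values.loc["COX2", "MEK"] == pytest.approx(want)

    def test_diagonal_masked_as_same_node(self, druggable_screen):
        dm = delta_matrix(druggable_screen, "apoptosis")
        for t in dm.values.index:
            assert dm.mask.loc[t, t] == "same_node"

    def test_toxic_cells_masked_with_reason(self, druggable_screen):
        dm = delta_matrix(druggable_screen, "apoptosis")
        assert "healthy_toxicity" in dm.mask.loc["COX2", "PHD2"]
        assert dm.mask.loc["PHD2", "VHL"] == ""  # the exempt mutual pair

    def test_drop_phd2_vhl_is_presentation_only(self, druggable_screen):
        dm = delta_matrix(druggable_screen, "apoptosis", drop_phd2_vhl=True)
        assert "phd2_vhl" in dm.mask.loc["PHD2", "MEK"]
        assert dm.mask.loc["PHD2", "VHL"] == ""  # mutual pair still shown
        # underlying values untouched
        base = delta_matrix(druggable_screen, "apoptosis")
        pd.testing.assert_frame_equal(dm.values, base.values)

    def test_mek_cox2_tops_the_apoptosis_matrix(self, druggable_screen):
        a, b, v = delta_matrix(druggable_screen, "apoptosis").argmax()
        assert {a, b} == {"COX2", "MEK"}
        assert v > 0

    def test_clone_selectivity_of_mek(self, druggable_screen):
        """Apoptosis gain from MEK inhibition is larger in the Myc-high
        mixed clone than the Myc-low mixed clone."""
        def gain(clone):
            return druggable_screen.midpoint(clone, ("MEK",), "apoptosis") - \
                druggable_screen.midpoint(clone, (), "apoptosis")
        assert gain("myc_high_mixed") > gain("myc_low_mixed")

    def test_combination_beats_both_monotherapies_in_myc_low(self, druggable_screen):
        combo = druggable_screen.midpoint("myc_low_mixed", ("COX2", "MEK"), "apoptosis")
        assert combo > druggable_screen.midpoint("myc_low_mixed", ("MEK",), "apoptosis")
        assert combo > druggable_screen.midpoint("myc_low_mixed", ("COX2",), "apoptosis")


class TestResilience:
    def test_mixed_clones_resist_therapy_better_than_pure(self, druggable_screen):
        """Across inhibitor treatments, each mixed clone keeps at least the
        proliferation and at most the apoptosis of its pure counterpart;
        at least 90% of treatments must satisfy both."""
        tab = druggable_screen
        pairs = [("myc_high_mixed", "myc_high_pure"), ("myc_low_mixed", "myc_low")]
        treatments = sorted(
            set(tab.data.loc[tab.data["n_inhibitors"] > 0, "treatment"])
        )
        ok = 0
        for tr in treatments:
            tt = tuple(tr.split("+"))
            if all(
                tab.midpoint(mixed, tt, "proliferation") >= tab.midpoint(pure, tt, "proliferation")
                and tab.midpoint(mixed, tt, "apoptosis") <= tab.midpoint(pure, tt, "apoptosis")
                for mixed, pure in pairs
            ):
                ok += 1
        assert ok / len(treatments) >= 0.9


class TestExport:
    def test_table_csv_shape(self, druggable_screen, tmp_path):
        path = tmp_path / "table.csv"
        export_table(druggable_screen, path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(druggable_screen.data) + 1  # header
        assert (tmp_path / "table.csv.provenance.json").exists()

    def test_masked_cells_serialized_empty_with_reasons(self, druggable_screen, tmp_path):
        dm = delta_matrix(druggable_screen, "apoptosis")
        export_matrix(dm, csv_path=tmp_path / "dm.csv")
        df = pd.read_csv(tmp_path / "dm.csv", index_col=0)
        reasons = pd.read_csv(tmp_path / "dm.csv.mask.csv", index_col=0).fillna("")
        for a in df.index:
            for b in df.columns:
                if reasons.loc[a, b]:
                    assert math.isnan(df.loc[a, b]), (a, b)

    def test_heatmap_written(self, druggable_screen, in_vivo, tmp_path):
        dm = delta_matrix(druggable_screen, "apoptosis")
        export_matrix(dm, figure_path=tmp_path / "dm.png", model=in_vivo)
        assert (tmp_path / "dm.png").stat().st_size > 0
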