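"""Effect summaries and the command-line workflow."""

import numpy as np
import pytest
from click.testing import CliRunner

from phylofabric.priors import f_upsilon_cutpoints
from phylofabric.summaries import (accumulation_curves,
                                   directional_change_variance,
                                   effect_summary, fold_change,
                                   path_effect_counts)
from phylofabric.trees import read_newick


@pytest.fixture
def balanced4():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


class TestFoldChange:
    @pytest.mark.parametrize("x,expected", [(0.73, 5.37), (2.0, 100.0),
                                            (0.0, 1.0)])
    def test_examples(self, x, expected):
        assert fold_change(x) == pytest.approx(expected, rel=1e-2)

    def test_log_additivity(self, rng):
        a, b = rng.normal(size=2)
        assert fold_change(a + b) == pytest.approx(
            fold_change(a) * fold_change(b), rel=1e-12)


class TestPathCounts:
    def test_no_effects_all_zero(self, balanced4):
        df = path_effect_counts(balanced4, {}, {})
        assert (df[["n_beta_pos", "n_beta_neg", "n_upsilon_gt1",
                    "n_upsilon_lt1"]].values == 0).all()

    def test_single_positive_beta_on_left_child(self, balanced4):
        # node 1 is the ancestor of {A,B}; its branch carries the effect
        df = path_effect_counts(balanced4, {1: 0.5}, {}).set_index("tip")
        assert df.loc["A", "n_beta_pos"] == 1
        assert df.loc["B", "n_beta_pos"] == 1
        assert df.loc["C", "n_beta_pos"] == 0
        assert (df["n_beta_neg"] == 0).all()

    def test_nested_beta_and_small_upsilon(self, balanced4):
        df = path_effect_counts(balanced4, {1: 0.5},
                                {1: 0.5}).set_index("tip")
        row = df.loc["A"]
        assert (row["n_beta_pos"], row["n_beta_neg"],
                row["n_upsilon_gt1"], row["n_upsilon_lt1"]) == (1, 0, 0, 1)
        assert df.loc["C"].sum() == 0


class TestAccumulation:
    def test_no_effects_flat(self, balanced4):
        df, slope = accumulation_curves(balanced4, {}, {})
        assert len(df) == 0 and slope == 0.0

    def test_single_effect_steps_at_midpoint(self, balanced4):
        df, _ = accumulation_curves(balanced4, {1: 0.5}, {})
        assert len(df) == 1
        assert df.loc[0, "time"] == pytest.approx(0.5)  # midpoint of stem
        assert df.loc[0, "cumulative_count"] == 1
        assert df.loc[0, "lineages"] == 2

    def test_effects_everywhere_give_increasing_curve(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        beta = {int(b): 0.1 for b in tree.branches()}
        df, slope = accumulation_curves(tree, beta, {})
        assert len(df) == len(beta)
        assert df["cumulative_count"].is_monotonic_increasing
        assert slope > 0


class TestChangeVariance:
    def test_zero_shift(self):
        assert directional_change_variance(0.0, 2.0) == 0.0

    def test_default_formula(self):
        # beta*t = 1 over t = 4
        assert directional_change_variance(0.25, 4.0) == pytest.approx(0.25)

    def test_halving_time_doubles_variance(self):
        v1 = directional_change_variance(1.0, 2.0)   # x = 2 over t = 2
        v2 = directional_change_variance(2.0, 1.0)   # x = 2 over t = 1
        assert v2 == pytest.approx(2 * v1)

    def test_pluggable_formula(self):
        assert directional_change_variance(
            1.0, 2.0, formula=lambda b, t: b) == 1.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            directional_change_variance(1.0, 0.0)


class TestEffectSummary:
    def test_envelope_consistency(self, balanced4):
        df = effect_summary(balanced4, {2: 1.0}, {1: 3.0})
        urow = df[df.kind == "upsilon"].iloc[0]
        lo, hi = f_upsilon_cutpoints(int(urow.clade_tips))
        assert (urow.value > hi) == (urow.value > urow.cut_high)
        brow = df[df.kind == "beta"].iloc[0]
        assert brow.fold_change == pytest.approx(10 ** brow.beta_t)


class TestCliWorkflow:
    def test_simulate_fit_select_summarize_roundtrip(self, tmp_path):
        from phylofabric.cli import main
        runner = CliRunner()
        out = tmp_path / "out"
        r = runner.invoke(main, ["--seed", "3", "--out-dir", str(out),
                                 "simulate", "--scenario", "null_bm",
                                 "--n-tips", "20"])
        assert r.exit_code == 0, r.output
        tree_file = out / "null_bm.nwk"
        trait_file = out / "null_bm.csv"
        assert tree_file.exists() and trait_file.exists()

        r = runner.invoke(main, ["--seed", "3", "--out-dir", str(out),
                                 "select", str(tree_file), str(trait_file),
                                 "--variant", "combined",
                                 "--iterations", "4000", "--runs", "2"])
        assert r.exit_code == 0, r.output
        assert (out / "selection.csv").exists()
        ann = out / "annotated.nwk"
        assert ann.exists()

        r = runner.invoke(main, ["--seed", "3", "--out-dir", str(out),
                                 "summarize", str(tree_file), str(ann)])
        assert r.exit_code == 0, r.output
        assert (out / "effects.csv").exists()
        assert (out / "path_counts.csv").exists()

    def test_fit_writes_sample_log(self, tmp_path):
        from phylofabric.cli import main
        runner = CliRunner()
        out = tmp_path / "out"
        runner.invoke(main, ["--seed", "5", "--out-dir", str(out),
                             "simulate", "--scenario", "single_beta",
                             "--n-tips", "20"])
        tree_file = out / "single_beta_2.0.nwk"
        r = runner.invoke(main, ["--seed", "5", "--out-dir", str(out),
                                 "fit", str(tree_file),
                                 str(out / "single_beta_2.0.csv"),
                                 "--variant", "directional",
                                 "--iterations", "3000"])
        assert r.exit_code == 0, r.output
        assert (out / "samples_run0.csv").exists()
        assert (out / "inclusion_run0.csv").exists()

    def test_input_error_exit_code(self, tmp_path):
        from phylofabric.cli import main
        bad = tmp_path / "bad.nwk"
        bad.write_text("((A:1,B:1")
        traits = tmp_path / "t.csv"
        traits.write_text("A,1\nB,2\n")
        runner = CliRunner()
        r = runner.invoke(main, ["--out-dir", str(tmp_path / "o"), "fit",
                                 str(bad), str(traits)])
        assert r.exit_code != 0

    def test_validate_passes(self, tmp_path):
        from phylofabric.cli import main
        runner = CliRunner()
        r = runner.invoke(main, ["--seed", "1",
                                 "--out-dir", str(tmp_path), "validate"])
        assert r.exit_code == 0, r.output
        assert "all checks passed" in r.output
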