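"""Unit and property tests for preprocessing and the four-step screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trzmir.errors import ConfigError, DesignError, FormatError, MetadataError
from trzmir.screen import (
    FoldChangeRecord,
    ScreenCriteria,
    exclude_negative_responders,
    filter_expressed,
    fold_changes,
    hierarchical_cluster,
    load_expression_matrix,
    mean_rfc,
    preprocess,
    quantile_normalize,
    relative_fold_change,
    screen,
)
from trzmir.simulate import ArraySimConfig, simulate_array

from conftest import make_normalized


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_hand_computed_rank_means(self):
        X = np.array([[2.0, 16.0], [4.0, 32.0], [8.0, 64.0]])
        out = quantile_normalize(X)
        expected = np.array([[9.0, 9.0], [18.0, 18.0], [36.0, 36.0]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        X = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize(X), X)

    def test_single_column_is_identity(self):
        X = np.array([[3.0], [1.0], [2.0]])
        np.testing.assert_allclose(quantile_normalize(X), X)

    def test_ties_get_mean_of_tied_target_values(self):
        X = np.array([[1.0, 10.0], [1.0, 20.0], [2.0, 30.0]])
        # target = mean of sorted columns = (5.5, 10.5, 16); tie in col 0
        # spans ranks 0-1 -> both get (5.5 + 10.5) / 2 = 8
        out = quantile_normalize(X)
        np.testing.assert_allclose(out[:, 0], [8.0, 8.0, 16.0])
        np.testing.assert_allclose(out[:, 1], [5.5, 10.5, 16.0])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sorted_columns_identical_after_normalization(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(2.0, 1.0, size=(17, 5))
        out = quantile_normalize(X)
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_column_permutation_commutes(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(2.0, 1.0, size=(11, 4))
        perm = rng.permutation(4)
        np.testing.assert_allclose(
            quantile_normalize(X[:, perm]), quantile_normalize(X)[:, perm]
        )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConfigError):
            quantile_normalize(np.empty((0, 0)))


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def _write_dataset(tmp_path, matrix_text, samples_text):
    mpath = tmp_path / "m.tsv"
    spath = tmp_path / "s.csv"
    mpath.write_text(matrix_text)
    spath.write_text(samples_text)
    return mpath, spath


SAMPLES_2 = (
    "sample_id,cell_line,her2_status,treatment,dose_ug_ml,hours\n"
    "SKBR3_treated,SKBR3,positive,treated,4,144\n"
    "SKBR3_control,SKBR3,positive,control,0,144\n"
)


class TestLoadExpressionMatrix:
    def test_wellformed_dimensions(self, tmp_path):
        m, s = _write_dataset(
            tmp_path,
            "mirna_id\tSKBR3_treated\tSKBR3_control\na\t2\t3\nb\t4\t5\nc\t6\t7\n",
            SAMPLES_2,
        )
        mat = load_expression_matrix(m, s)
        assert mat.values.shape == (3, 2)
        assert mat.n_clipped == 0

    def test_negative_value_clipped_to_eps(self, tmp_path):
        m, s = _write_dataset(
            tmp_path,
            "mirna_id\tSKBR3_treated\tSKBR3_control\na\t-5\t3\n",
            SAMPLES_2,
        )
        mat = load_expression_matrix(m, s)
        assert mat.values.loc["a", "SKBR3_treated"] == 1.0
        assert mat.n_clipped == 1

    def test_duplicate_mirna_ids_rejected(self, tmp_path):
        m, s = _write_dataset(
            tmp_path,
            "mirna_id\tSKBR3_treated\tSKBR3_control\na\t2\t3\na\t4\t5\n",
            SAMPLES_2,
        )
        with pytest.raises(FormatError):
            load_expression_matrix(m, s)

    def test_sample_sheet_mismatch_rejected(self, tmp_path):
        m, s = _write_dataset(
            tmp_path,
            "mirna_id\tSKBR3_treated\tSKBR3_control\tExtra\na\t2\t3\t4\n",
            SAMPLES_2,
        )
        with pytest.raises(MetadataError):
            load_expression_matrix(m, s)


# ---------------------------------------------------------------------------
# screen steps
# ---------------------------------------------------------------------------

def _norm_four_lines(values_by_mirna: dict[str, dict[str, float]]):
    """values_by_mirna: mirna -> {column -> log2 value} over the 8 columns."""
    cols = [
        f"{line}_{cond}"
        for line in ("SKBR3", "BT474", "MCF7", "MDA-MB-231")
        for cond in ("treated", "control")
    ]
    df = pd.DataFrame(
        {c: {m: v[c] for m, v in values_by_mirna.items()} for c in cols}
    )
    return make_normalized(df)


class TestFilterExpressed:
    def test_either_condition_keeps_one_sided_expression(self):
        norm = _norm_four_lines({"a": {c: (6.5 if c.endswith("treated") else 5.0)
                                       for c in [f"{l}_{t}" for l in
                                                 ("SKBR3", "BT474", "MCF7", "MDA-MB-231")
                                                 for t in ("treated", "control")]}})
        assert filter_expressed(norm) == ["a"]

    def test_one_dim_line_removes_mirna(self):
        vals = {}
        for line in ("SKBR3", "BT474", "MCF7", "MDA-MB-231"):
            level = 5.9 if line == "MCF7" else 7.5
            vals[f"{line}_treated"] = level
            vals[f"{line}_control"] = level
        norm = _norm_four_lines({"a": vals})
        assert filter_expressed(norm) == []

    def test_all_zero_matrix_retains_nothing(self):
        vals = {f"{l}_{t}": 0.0 for l in ("SKBR3", "BT474", "MCF7", "MDA-MB-231")
                for t in ("treated", "control")}
        norm = _norm_four_lines({"a": vals, "b": vals})
        assert filter_expressed(norm) == []

    def test_both_conditions_rule_is_stricter(self):
        vals = {f"{l}_{t}": (6.5 if t == "treated" else 5.0)
                for l in ("SKBR3", "BT474", "MCF7", "MDA-MB-231")
                for t in ("treated", "control")}
        norm = _norm_four_lines({"a": vals})
        crit = ScreenCriteria(expression_rule="both_conditions")
        assert filter_expressed(norm, crit) == []


class TestFoldChanges:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [(7.0, 6.0, 2.0), (5.0, 6.0, 0.5), (6.3, 6.3, 1.0)],
    )
    def test_definition(self, treated, control, expected):
        vals = {f"{l}_{t}": 6.0 for l in ("SKBR3", "BT474", "MCF7", "MDA-MB-231")
                for t in ("treated", "control")}
        vals["SKBR3_treated"], vals["SKBR3_control"] = treated, control
        norm = _norm_four_lines({"a": vals})
        recs = fold_changes(norm, "SKBR3")
        assert recs[0].fc_linear == pytest.approx(expected)

    def test_missing_condition_is_design_error(self):
        norm = make_normalized(pd.DataFrame({"SKBR3_treated": {"a": 6.0}}),
                               lines=(("SKBR3", "positive"),))
        with pytest.raises(DesignError):
            fold_changes(norm, "SKBR3")


class TestExcludeNegativeResponders:
    @pytest.mark.parametrize(
        "fcs,kept",
        [((1.4, 0.8), True), ((1.6, 1.0), False), ((1.5, 1.0), True),
         ((1.0, 0.5), False), ((1.0, 1.0 / 1.5), True)],
    )
    def test_rule_and_strict_boundaries(self, fcs, kept):
        fc_neg = {
            line: [FoldChangeRecord("a", line, float(np.log2(fc)))]
            for line, fc in zip(("MCF7", "MDA-MB-231"), fcs)
        }
        out = exclude_negative_responders(fc_neg)
        assert ("a" in out) is kept

    def test_no_negative_lines_is_design_error(self):
        with pytest.raises(DesignError):
            exclude_negative_responders({})


class TestRelativeFoldChange:
    @pytest.mark.parametrize(
        "pos,negs,expected",
        [(1.5, (1.5, 1.5), 1.0), (3.0, (1.0, 4.0), 1.5), (0.5, (1.0, 1.0), 0.5)],
    )
    def test_geometric_mean_ratio(self, pos, negs, expected):
        fc_pos = FoldChangeRecord("a", "SKBR3", float(np.log2(pos)))
        fc_negs = [FoldChangeRecord("a", l, float(np.log2(f)))
                   for l, f in zip(("MCF7", "MDA-MB-231"), negs)]
        assert relative_fold_change(fc_pos, fc_negs).rfc_linear == pytest.approx(expected)

    def test_empty_negative_list_rejected(self):
        with pytest.raises(DesignError):
            relative_fold_change(FoldChangeRecord("a", "SKBR3", 0.0), [])

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_self_cancellation(self, pos_fc, other):
        # RFC is 1 whenever the positive-line FC equals the geometric mean of
        # the negative-line FCs
        log2_pos = float(np.log2(pos_fc))
        log2_other = float(np.log2(other))
        negs = [FoldChangeRecord("a", "MCF7", log2_other),
                FoldChangeRecord("a", "MDA-MB-231", 2 * log2_pos - log2_other)]
        rfc = relative_fold_change(FoldChangeRecord("a", "SKBR3", log2_pos), negs)
        assert rfc.rfc_linear == pytest.approx(1.0, abs=1e-9)


class TestMeanRfc:
    @pytest.mark.parametrize(
        "pair,expected",
        [((2.4300, 3.5825), 2.9505), ((1.5730, 1.6897), 1.6303)],
    )
    def test_published_cross_line_aggregates(self, pair, expected):
        assert round(mean_rfc(pair), 4) == expected

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_on_equal_inputs(self, x):
        assert mean_rfc((x, x)) == pytest.approx(x, rel=1e-9)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ConfigError):
            mean_rfc((1.0, -2.0))


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

class TestScreen:
    def test_zero_noise_recovers_planted_responder(self):
        cfg = ArraySimConfig(
            n_mirnas=200, noise_log2_sd=0.0,
            planted={"miR-sim-0001": {"SKBR3": 1.2, "BT474": 1.2}}, rng_seed=1,
        )
        matrix, _ = simulate_array(cfg)
        report = screen(preprocess(matrix))
        assert report.up_set() == {"miR-sim-0001"}
        assert report.down_set() == set()
        # ideal RFC is 2^1.2 = 2.2974; quantile normalization compresses the
        # planted shift slightly because treated columns are forced onto the
        # pooled distribution
        for line in ("SKBR3", "BT474"):
            (rec,) = report.per_line_up[line]
            assert rec.rfc_linear == pytest.approx(2.0 ** 1.2, abs=0.08)

    def test_nothing_passes_floor_gives_empty_report(self):
        cfg = ArraySimConfig(n_mirnas=20, noise_log2_sd=0.0,
                             low_expression_fraction=1.0, rng_seed=3)
        matrix, _ = simulate_array(cfg)
        report = screen(preprocess(matrix))
        assert report.n_expressed == 0
        assert report.n_after_exclusion == 0
        assert report.mean_up == [] and report.mean_down == []

    def test_raising_threshold_never_adds_to_up_lists(self):
        # low noise keeps negative-line fold changes inside both exclusion
        # windows, isolating the monotonicity of the up-listing rule itself
        cfg = ArraySimConfig(
            n_mirnas=100, noise_log2_sd=0.05,
            planted={f"miR-sim-{i:04d}": {"SKBR3": 0.3 + 0.3 * i, "BT474": 0.3 + 0.3 * i}
                     for i in range(5)},
            rng_seed=7,
        )
        matrix, _ = simulate_array(cfg)
        norm = preprocess(matrix)
        loose = screen(norm, ScreenCriteria(fc_threshold=1.3, down_threshold=1 / 1.3))
        tight = screen(norm, ScreenCriteria(fc_threshold=1.8, down_threshold=1 / 1.8))
        assert tight.up_set() <= loose.up_set()
        for line in ("SKBR3", "BT474"):
            assert {r.mirna_id for r in tight.per_line_up[line]} <= {
                r.mirna_id for r in loose.per_line_up[line]
            }

    def test_report_lists_are_sorted_by_response_strength(self):
        cfg = ArraySimConfig(
            n_mirnas=150, noise_log2_sd=0.1,
            planted={f"miR-sim-{i:04d}": {"SKBR3": 0.8 + 0.2 * i, "BT474": 0.8 + 0.2 * i}
                     for i in range(4)},
            rng_seed=11,
        )
        matrix, _ = simulate_array(cfg)
        report = screen(preprocess(matrix))
        for recs in (*report.per_line_up.values(), report.mean_up):
            mags = [abs(r.log2_rfc) for r in recs]
            assert mags == sorted(mags, reverse=True)

    def test_missing_negative_line_is_design_error(self):
        vals = {f"{l}_{t}": 7.0 for l in ("SKBR3", "BT474") for t in ("treated", "control")}
        norm = make_normalized(pd.DataFrame({c: {"a": v} for c, v in vals.items()}),
                               lines=(("SKBR3", "positive"), ("BT474", "positive")))
        with pytest.raises(DesignError):
            screen(norm)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestHierarchicalCluster:
    def test_identical_columns_merge_at_height_zero(self, rng):
        col = rng.normal(size=30)
        df = pd.DataFrame({"a": col, "b": col, "c": rng.normal(size=30)})
        result = hierarchical_cluster(df)
        assert result.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_distance_two(self, rng):
        col = rng.normal(size=30)
        df = pd.DataFrame({"a": col, "b": -col})
        result = hierarchical_cluster(df)
        assert result.linkage_matrix[0, 2] == pytest.approx(2.0)

    def test_same_line_pairs_merge_before_cross_line(self, rng):
        # line effect sd 1.0 dominates treatment effect sd 0.2, so each
        # line's treated/control pair should merge first
        for _ in range(5):
            base = rng.normal(0, 1, size=(60, 1))
            cols = {}
            for line in ("L1", "L2", "L3"):
                line_effect = rng.normal(0, 1.0, size=60)
                for cond in ("treated", "control"):
                    cols[f"{line}_{cond}"] = (
                        base[:, 0] + line_effect + rng.normal(0, 0.2, size=60)
                    )
            df = pd.DataFrame(cols)
            result = hierarchical_cluster(df)
            labels = result.labels
            n = len(labels)
            # the first three merges must each join a same-line pair
            for merge in result.linkage_matrix[:3]:
                i, j = int(merge[0]), int(merge[1])
                assert i < n and j < n
                assert labels[i].split("_")[0] == labels[j].split("_")[0]

    def test_zero_variance_column_gets_unit_distance(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        result = hierarchical_cluster(df)
        assert result.linkage_matrix[0, 2] == pytest.approx(1.0)

    def test_single_column_rejected(self):
        with pytest.raises(DesignError):
            hierarchical_cluster(pd.DataFrame({"a": [1.0, 2.0]}))
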