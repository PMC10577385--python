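"""Trial table I/O, survival filtering, and descriptive summaries."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hdtrial import (SimConfig, SiteConfig, TrialTable, anova_tukey,
                     filter_blocks, generate_trial, read_trial, summarize,
                     write_trial)
from hdtrial.trial_data import EmptyTrialWarning, SchemaError, ValidationError

CSV3 = """site,provenance,block,tree,dbh_cm,height_m,alive
S1,A,B1,t1,10.0,9.5,1
S1,A,B1,t2,12.0,11.0,1
S1,B,B1,t3,8.0,7.5,1
"""


def test_read_well_formed_csv():
    table = read_trial(io.StringIO(CSV3), planned_per_block=3)
    assert len(table) == 3
    assert list(table.data["tree"]) == ["t1", "t2", "t3"]  # order preserved


def test_read_missing_column_is_schema_error():
    broken = CSV3.replace("height_m", "height")
    with pytest.raises(SchemaError, match="height_m"):
        read_trial(io.StringIO(broken))


def test_read_invalid_measurement_names_row():
    bad = CSV3.replace("12.0,11.0,1", "12.0,-1.0,1")
    with pytest.raises(ValidationError, match="row 1"):
        read_trial(io.StringIO(bad))


def test_writer_reader_round_trip(tmp_path):
    cfg = SimConfig(
        sites=[SiteConfig(label="S", n_blocks=4, dbh_mean=15.0,
                          trees_per_plot=2)],
        provenances=list("ABCDEFGHIJKLMNOPQRSTUVWXY"),
        provenance_offsets={"S": {}}, phi0=20.0, phi1=1.2, phi2=0.03,
        sigma=0.8, gamma=0.3, survival_prob=0.8, reference_site="S", seed=9,
    )
    table = generate_trial(cfg)
    assert len(table) == 200
    # quantize to the writer's precision first so the round trip is exact
    table.data["dbh_cm"] = table.data["dbh_cm"].round(1)
    table.data["height_m"] = table.data["height_m"].round(1)
    path = tmp_path / "trial.csv"
    write_trial(table, path)
    back = read_trial(path, planned_per_block=table.planned_per_block)
    assert back == table


class TestFilterBlocks:
    def _table(self, alive_per_block, planned=10):
        rows = []
        for b, n_alive in alive_per_block.items():
            for i in range(planned):
                a = 1 if i < n_alive else 0
                rows.append(("S", "A", b, f"{b}-{i}",
                             10.0 if a else np.nan, 9.0 if a else np.nan, a))
        df = pd.DataFrame(rows, columns=["site", "provenance", "block", "tree",
                                         "dbh_cm", "height_m", "alive"])
        return TrialTable(df, planned_per_block=planned)

    def test_threshold_is_inclusive(self):
        table = self._table({"B1": 5, "B2": 8})
        kept = filter_blocks(table, 0.60)
        assert set(kept.data["block"]) == {"B2"}

    def test_full_survival_is_identity(self):
        table = self._table({"B1": 10, "B2": 10})
        assert filter_blocks(table) == table

    def test_idempotent(self):
        table = self._table({"B1": 5, "B2": 8, "B3": 7})
        once = filter_blocks(table)
        assert filter_blocks(once) == once

    def test_all_discarded_warns(self):
        table = self._table({"B1": 2, "B2": 3})
        with pytest.warns(EmptyTrialWarning):
            out = filter_blocks(table)
        assert len(out) == 0

    def test_against_brute_force_recount(self):
        # 20 blocks of 25 positions at 65% survival: the retained set must
        # equal the blocks whose alive count reaches ceil(0.6*25) = 15
        cfg = SimConfig(
            sites=[SiteConfig(label="S", n_blocks=20, dbh_mean=15.0)],
            provenances=list("ABCDEFGHIJKLMNOPQRSTUVWXY"),
            provenance_offsets={"S": {}}, phi0=20.0, phi1=1.2, phi2=0.03,
            sigma=0.5, survival_prob=0.65, reference_site="S", seed=13,
        )
        table = generate_trial(cfg)
        expected = set()
        for block in sorted(set(table.data["block"])):
            sub = table.data[table.data["block"] == block]
            assert len(sub) == 25
            if sum(sub["alive"]) / 25 >= 0.60:
                expected.add(block)
        kept = filter_blocks(table, 0.60)
        assert set(kept.data["block"]) == expected


class TestSummarize:
    def test_hand_arithmetic(self):
        df = pd.DataFrame({
            "site": "S", "provenance": "A", "block": "B1",
            "tree": ["t1", "t2"], "dbh_cm": [10.0, 20.0],
            "height_m": [9.0, 15.0], "alive": 1,
        })
        out = summarize(TrialTable(df), include_site_totals=False)
        assert out.loc[0, "mean_dbh"] == pytest.approx(15.0)
        assert out.loc[0, "se_dbh"] == pytest.approx(5.0)

    def test_constant_trait_has_zero_se(self):
        df = pd.DataFrame({
            "site": "S", "provenance": "A", "block": "B1",
            "tree": ["t1", "t2", "t3"], "dbh_cm": 10.0,
            "height_m": 9.0, "alive": 1,
        })
        out = summarize(TrialTable(df), include_site_totals=False)
        assert out.loc[0, "se_dbh"] == 0.0
        assert out.loc[0, "se_height"] == 0.0

    def test_counts_conserved_and_means_bounded(self, small_table):
        out = summarize(small_table)
        for site in ("S1", "S2"):
            sub = out[out["site"] == site]
            total = sub[sub["provenance"] == "(all)"]
            parts = sub[sub["provenance"] != "(all)"]
            assert parts["n"].sum() == int(total["n"].iloc[0])
            live = small_table.alive()
            live = live[live["site"] == site]
            assert live["dbh_cm"].min() <= total["mean_dbh"].iloc[0] \
                <= live["dbh_cm"].max()

    def test_empty_table_rejected(self):
        df = pd.DataFrame(columns=["site", "provenance", "block", "tree",
                                   "dbh_cm", "height_m", "alive"])
        with pytest.raises(ValueError):
            summarize(TrialTable(df))


class TestAnovaTukey:
    def _table(self, groups):
        rows = []
        for site, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((site, "A", "B1", f"{site}-{i}", v, v / 2, 1))
        df = pd.DataFrame(rows, columns=["site", "provenance", "block", "tree",
                                         "dbh_cm", "height_m", "alive"])
        return TrialTable(df)

    def test_identical_groups_give_zero_f(self):
        res = anova_tukey(self._table({"S1": [10, 12, 14], "S2": [10, 12, 14]}))
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        a, b = [10.0, 12, 13, 15], [11.0, 14, 16, 18]
        res = anova_tukey(self._table({"S1": a, "S2": b}))
        t, _ = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2)

    def test_matches_hand_sum_of_squares(self):
        rng = np.random.default_rng(3)
        groups = {f"S{i}": list(rng.normal(10 + i, 2, 10)) for i in range(3)}
        res = anova_tukey(self._table(groups))
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2)
                  for v in groups.values())
        f_hand = (ssb / 2) / (ssw / (30 - 3))
        assert res.f_statistic == pytest.approx(f_hand)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey(self._table({"S1": [10, 12], "S2": [11]}))

    def test_tukey_p_dominates_unadjusted(self):
        rng = np.random.default_rng(8)
        groups = {f"S{i}": list(rng.normal(10 + 0.5 * i, 2, 12))
                  for i in range(4)}
        res = anova_tukey(self._table(groups))
        for _, row in res.tukey.iterrows():
            _, p_raw = stats.ttest_ind(groups[row["group1"]],
                                       groups[row["group2"]])
            assert row["p_adj"] >= p_raw - 1e-10
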