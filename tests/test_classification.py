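"""Cascade rules vs independently coded brute-force oracles, and boundaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_feature_fixture
from reefexo.classify import (CascadeConfig, classify_exudate_subtypes,
                              classify_features, class_peak_area_summary,
                              flag_background, flag_transient,
                              split_ambient_exudate,
                              treatment_association_categories)
from reefexo.classify import test_exometabolites as exometabolite_test
from reefexo.io import DIELS, PRODUCERS, FeatureTable


# ----------------------------------------------------------------------
# independent brute-force oracles (plain python loops, no shared code path)
# ----------------------------------------------------------------------

def oracle_background(table, meta):
    blanks = meta[meta["role"] == "blank"]["sample_id"]
    samp = meta[meta["role"] == "experimental"]["sample_id"]
    out = []
    for f in table.data.index:
        mean = sum(table.data.loc[f, s] for s in samp) / len(samp)
        mx = max(table.data.loc[f, b] for b in blanks)
        if mean < 2.0 * mx:
            out.append(f)
    return out


def oracle_transient(table, meta, thr=2e5):
    samp = meta[meta["role"] == "experimental"]["sample_id"]
    out = []
    for f in table.data.index:
        count = sum(1 for s in samp if table.data.loc[f, s] >= thr)
        if count < 3:
            out.append(f)
    return out


def oracle_split(table, meta, floor=1e5):
    exp = meta[meta["role"] == "experimental"]
    amb = exp[exp["treatment"] == "Ambient"]["sample_id"]
    end = exp[exp["timepoint"] == "end"]
    exudate = []
    for f in table.data.index:
        amb_mean = max(np.mean([table.data.loc[f, s] for s in amb]), floor)
        best = -np.inf
        for trt in ("Control",) + PRODUCERS:
            for diel in DIELS:
                cell = end[(end["treatment"] == trt) & (end["diel"] == diel)]["sample_id"]
                m = max(np.mean([table.data.loc[f, s] for s in cell]), floor)
                best = max(best, np.log2(m / amb_mean))
        if best > 1.0:
            exudate.append(f)
    return exudate


def oracle_subtypes(table, meta, exudate, floor=1e5):
    exp = meta[meta["role"] == "experimental"]
    amb = exp[exp["treatment"] == "Ambient"]["sample_id"]
    end = exp[exp["timepoint"] == "end"]

    def doubled(f, trt, diel):
        cell = end[(end["treatment"] == trt) & (end["diel"] == diel)]["sample_id"]
        amb_mean = max(np.mean([table.data.loc[f, s] for s in amb]), floor)
        m = max(np.mean([table.data.loc[f, s] for s in cell]), floor)
        return np.log2(m / amb_mean) > 1.0

    out = {}
    for f in exudate:
        cd, cn = doubled(f, "Control", "Day"), doubled(f, "Control", "Night")
        prod = any(doubled(f, t, d) for t in PRODUCERS for d in DIELS)
        if cd and cn:
            out[f] = "incubation_artifact"
        elif prod:
            out[f] = "benthic_exudate"
        elif cd or cn:
            out[f] = "planktonic_exudate"
        else:
            out[f] = "benthic_exudate"
    return out


@pytest.mark.parametrize("seed", range(8))
def test_filters_match_brute_force_oracles(seed):
    """Each rule-based flag equals an independently coded evaluation."""
    rng = np.random.default_rng(seed)
    table, meta = random_feature_fixture(rng)
    assert set(flag_background(table, meta)) == set(oracle_background(table, meta))
    assert set(flag_transient(table, meta)) == set(oracle_transient(table, meta))
    _, exudate, ratios = split_ambient_exudate(table, meta)
    assert set(exudate) == set(oracle_split(table, meta))
    got = classify_exudate_subtypes(ratios, exudate, set())
    assert got.to_dict() == oracle_subtypes(table, meta, exudate)


# ----------------------------------------------------------------------
# boundary behaviour of individual rules
# ----------------------------------------------------------------------

def _mini_table(meta, fill=0.0):
    cols = meta["sample_id"].tolist()
    return pd.DataFrame(fill, index=["F"], columns=cols)


class TestBackgroundRule:
    def test_mean_below_twice_blank_max(self, default_sim):
        meta = default_sim.metadata
        data = _mini_table(meta, 100.0)
        data.loc["F", meta[meta["role"] == "blank"]["sample_id"]] = 60.0
        flagged = flag_background(FeatureTable(data), meta)
        assert flagged == ["F"]          # 100 < 2 * 60

    def test_absent_from_blanks_never_background(self, default_sim):
        meta = default_sim.metadata
        data = _mini_table(meta, 5.0)
        data.loc["F", meta[meta["role"] == "blank"]["sample_id"]] = 0.0
        assert flag_background(FeatureTable(data), meta) == []

    def test_no_blanks_raises(self, default_sim):
        meta = default_sim.metadata
        exp = meta[meta["role"] == "experimental"]
        data = _mini_table(exp, 5.0)
        with pytest.raises(ValueError):
            flag_background(FeatureTable(data), exp)


class TestTransientRule:
    @pytest.mark.parametrize("n_above,flagged", [(2, True), (3, False)])
    def test_less_than_three_boundary(self, default_sim, n_above, flagged):
        meta = default_sim.metadata
        exp_ids = meta[meta["role"] == "experimental"]["sample_id"].tolist()
        data = _mini_table(meta, 1e4)
        data.loc["F", exp_ids[:n_above]] = 2e5      # exactly at threshold counts
        got = flag_transient(FeatureTable(data), meta)
        assert (got == ["F"]) == flagged


class TestAmbientExudateSplit:
    def _with_cells(self, meta, amb_value, end_value, trt="Turf", diel="Day"):
        data = _mini_table(meta, 0.0)
        exp = meta[meta["role"] == "experimental"]
        data.loc["F", exp[exp["treatment"] == "Ambient"]["sample_id"]] = amb_value
        cell = exp[(exp["treatment"] == trt) & (exp["diel"] == diel)
                   & (exp["timepoint"] == "end")]["sample_id"]
        data.loc["F", cell] = end_value
        return FeatureTable(data)

    def test_ratio_above_two_is_exudate(self, default_sim):
        meta = default_sim.metadata
        ft = self._with_cells(meta, 1e6, 2.5e6)
        _, exu, _ = split_ambient_exudate(ft, meta)
        assert exu == ["F"]

    def test_ratio_exactly_two_is_ambient(self, default_sim):
        meta = default_sim.metadata
        ft = self._with_cells(meta, 1e6, 2e6)
        ambient, _, _ = split_ambient_exudate(ft, meta)
        assert ambient == ["F"]

    def test_zero_ambient_mean_floored(self, default_sim):
        """Empty baseline: floor at 1e5 gives log2(8e5/1e5) = 3 -> exudate."""
        meta = default_sim.metadata
        ft = self._with_cells(meta, 0.0, 8e5)
        _, exu, ratios = split_ambient_exudate(ft, meta)
        assert exu == ["F"]
        assert ratios.loc["F", "Turf|Day"] == pytest.approx(3.0)

    def test_no_ambient_samples_raises(self, default_sim):
        meta = default_sim.metadata
        sub = meta[meta["treatment"] != "Ambient"]
        ft = FeatureTable(_mini_table(sub, 1.0))
        with pytest.raises(ValueError):
            split_ambient_exudate(ft, sub)

    def test_raising_threshold_shrinks_exudate_set(self):
        rng = np.random.default_rng(11)
        table, meta = random_feature_fixture(rng)
        sets = []
        for thr in (0.5, 1.0, 2.0):
            _, exu, _ = split_ambient_exudate(table, meta, log2_threshold=thr)
            sets.append(set(exu))
        assert sets[2] <= sets[1] <= sets[0]


class TestExometaboliteTest:
    def test_identical_means_not_significant(self, default_sim):
        meta = default_sim.metadata
        rng = np.random.default_rng(0)
        cols = meta["sample_id"].tolist()
        base = rng.uniform(1e5, 2e5, (30, len(cols)))
        data = pd.DataFrame(base, index=[f"F{i}" for i in range(30)], columns=cols)
        exo, tests, _ = exometabolite_test(FeatureTable(data), meta,
                                           list(data.index))
        assert exo == []

    def test_lowering_alpha_shrinks_set(self, default_sim):
        table, meta = default_sim.feature_table, default_sim.metadata
        _, exu, _ = split_ambient_exudate(table, meta)
        sets = {}
        for alpha in (0.05, 0.01):
            exo, _, _ = exometabolite_test(table, meta, exu, alpha)
            sets[alpha] = set(exo)
        assert sets[0.01] <= sets[0.05]

    def test_fdr_adjusted_not_below_raw(self, default_cascade):
        t = default_cascade.tests
        assert (t["p_fdr"] >= t["p_dunnett"] - 1e-12).all()

    def test_short_replicate_group_raises(self, default_sim):
        meta = default_sim.metadata.copy()
        keep = ~((meta["treatment"] == "Turf") & (meta["diel"] == "Day")
                 & (meta["replicate"] > 1))
        meta2 = meta[keep]
        table = default_sim.feature_table.subset_samples(meta2["sample_id"])
        with pytest.raises(ValueError, match="Turf"):
            exometabolite_test(table, meta2, table.feature_ids[:5])


class TestSubtypePrecedence:
    def _ratios(self, **cells):
        cols = [f"{t}|{d}" for t in ("Control",) + PRODUCERS for d in DIELS]
        df = pd.DataFrame(0.0, index=["F"], columns=cols)
        for k, v in cells.items():
            df.loc["F", k.replace("_", "|", 1)] = v
        return df

    def test_doubled_in_both_controls_is_artifact(self):
        r = self._ratios(Control_Day=2.0, Control_Night=1.5, Turf_Day=3.0)
        got = classify_exudate_subtypes(r, ["F"], set())
        assert got["F"] == "incubation_artifact"

    def test_doubled_in_turf_only_is_benthic(self):
        r = self._ratios(Turf_Day=1.5)
        assert classify_exudate_subtypes(r, ["F"], set())["F"] == "benthic_exudate"

    def test_doubled_in_one_control_only_is_planktonic(self):
        r = self._ratios(Control_Day=1.5)
        assert classify_exudate_subtypes(r, ["F"], set())["F"] == "planktonic_exudate"

    def test_benthic_beats_planktonic(self):
        r = self._ratios(Control_Day=1.5, Turf_Night=1.5)
        assert classify_exudate_subtypes(r, ["F"], set())["F"] == "benthic_exudate"


class TestSummaries:
    def test_class_share_hand_example(self, default_sim):
        meta = default_sim.metadata
        cols = meta["sample_id"].tolist()
        data = pd.DataFrame(0.0, index=["a", "b", "c"], columns=cols)
        data.loc["a"] = 2.0
        data.loc["b"] = 2.0
        data.loc["c"] = 6.0
        labels = pd.Series({"a": "exometabolite", "b": "exometabolite",
                            "c": "ambient"})
        shares = class_peak_area_summary(FeatureTable(data), labels, meta)
        assert np.allclose(shares["exometabolite"], 0.4)
        assert np.allclose(shares["ambient"], 0.6)

    def test_association_categories(self):
        cells = {"f1": {("Pocillopora", "Day")},
                 "f2": {(p, "Day") for p in PRODUCERS} | {(p, "Night") for p in PRODUCERS},
                 "f3": {("Turf", "Day"), ("Turf", "Night")}}
        cats = treatment_association_categories(cells, ["f1", "f2", "f3"]).set_index("feature_id")
        assert cats.loc["f1", "category"] == "Pocillopora//day-only"
        assert bool(cats.loc["f1", "unique"])
        assert bool(cats.loc["f2", "all_producers"])
        assert cats.loc["f3", "diel_activity"] == "both"


class TestCascadeInvariants:
    def test_counts_conserved(self, default_sim, default_cascade):
        counts = default_cascade.counts()
        assert sum(counts.values()) == len(default_sim.feature_table.data)
        n_exudate = (counts["exometabolite"] + counts["benthic_exudate"]
                     + counts["planktonic_exudate"] + counts["incubation_artifact"])
        assert (counts["background"] + counts["transient"] + counts["ambient"]
                + n_exudate) == len(default_sim.feature_table.data)

    def test_labels_mutually_exclusive(self, default_cascade):
        assert (default_cascade.labels != "").all()

    def test_alpha_zero_yields_no_exometabolites(self, default_sim):
        cfg = CascadeConfig(alpha=0.0)
        res = classify_features(default_sim.feature_table, default_sim.metadata, cfg)
        assert (res.labels == "exometabolite").sum() == 0
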