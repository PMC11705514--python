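"""Canonical-sum normalization, fold changes and the regression models."""

import numpy as np
import pandas as pd
import pytest

from trnamod.quant import (
    CANONICAL,
    fold_change,
    interaction_model,
    interaction_screen,
    microarray_fold_change,
    normalize,
    per_nucleoside_model,
)
from trnamod.simulate import make_microarray, make_peak_area_table


def toy_table():
    rows = []
    for t, mq in [("NBF", 10.0), ("12H", 20.0)]:
        for rep in (1, 2, 3):
            sample = f"{t}-{rep}"
            for nuc, area in [("A", 25.0), ("G", 5.0), ("C", 5.0), ("U", 5.0),
                              ("manQ", mq)]:
                rows.append({"sample": sample, "time": t, "nucleoside": nuc,
                             "area": area})
    return pd.DataFrame(rows)


class TestNormalize:
    def test_arithmetic(self):
        out = normalize(toy_table())
        manq = out[(out["nucleoside"] == "manQ") & (out["time"] == "NBF")]
        assert (manq["normalized"] == 0.25).all()

    def test_canonical_sum_is_one_per_sample(self):
        out = normalize(toy_table())
        sums = out[out["nucleoside"].isin(CANONICAL)].groupby("sample")["normalized"].sum()
        assert (sums == 1.0).all()

    def test_scaling_invariance(self):
        table = toy_table()
        scaled = table.copy()
        factors = {s: f for s, f in zip(scaled["sample"].unique(), (2.0, 0.5, 7.0, 1.3, 9.9, 0.1))}
        scaled["area"] = scaled["area"] * scaled["sample"].map(factors)
        a = normalize(table)["normalized"].to_numpy()
        b = normalize(scaled)["normalized"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_missing_canonical_errors(self):
        bad = toy_table()
        bad = bad[~((bad["sample"] == "NBF-1") & (bad["nucleoside"] == "G"))]
        with pytest.raises(ValueError, match="NBF-1"):
            normalize(bad)

    def test_zero_canonical_errors(self):
        bad = toy_table()
        bad.loc[bad["nucleoside"] == "A", "area"] = 0.0
        with pytest.raises(ValueError):
            normalize(bad)

    def test_generator_roundtrip_exact_at_zero_cv(self):
        table, truth = make_peak_area_table(
            {"manQ": {"12H": 2.0}}, n_replicates=2, cv=0.0,
            time_points=("NBF", "12H"), seed=0,
        )
        out = normalize(table)
        manq = out[out["nucleoside"] == "manQ"].set_index("sample")
        expected = truth.set_index("time")["true_abundance"].iloc[0]
        nbf = manq[manq["time"] == "NBF"]["normalized"]
        assert nbf.to_numpy() == pytest.approx(expected, rel=1e-12)


class TestFoldChange:
    def test_reference_is_identity(self):
        fc = fold_change(normalize(toy_table()))
        nbf = fc[fc["time"] == "NBF"]
        assert (nbf["fold_change"] == 1.0).all()

    def test_two_fold(self):
        fc = fold_change(normalize(toy_table()))
        row = fc[(fc["nucleoside"] == "manQ") & (fc["time"] == "12H")]
        assert row["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_missing_reference_errors(self):
        table = normalize(toy_table())
        with pytest.raises(ValueError):
            fold_change(table[table["time"] != "NBF"])

    def test_zero_reference_flagged(self):
        table = normalize(toy_table())
        table.loc[(table["nucleoside"] == "manQ") & (table["time"] == "NBF"),
                  "normalized"] = 0.0
        fc = fold_change(table)
        row = fc[(fc["nucleoside"] == "manQ") & (fc["time"] == "12H")]
        assert row["undefined"].iloc[0]
        assert np.isnan(row["fold_change"].iloc[0])

    def test_monte_carlo_recovery(self):
        # true FC 0.5 at CV 10%, n=3: estimate within [0.4, 0.6] almost always
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            table, _ = make_peak_area_table(
                {"manQ": {"12H": 0.5}}, n_replicates=3, cv=0.10,
                time_points=("NBF", "12H"), seed=seed,
            )
            fc = fold_change(normalize(table))
            est = fc[(fc["nucleoside"] == "manQ") & (fc["time"] == "12H")][
                "fold_change"].iloc[0]
            hits += 0.4 <= est <= 0.6
        assert hits / n_sims >= 0.95


class TestPerNucleosideModel:
    def test_flat_data_gives_p_one(self):
        table = toy_table()
        table.loc[table["nucleoside"] == "manQ", "area"] = 10.0
        out = per_nucleoside_model(normalize(table))
        row = out[out["nucleoside"] == "manQ"].iloc[0]
        assert row["F"] == 0.0 and row["p"] == 1.0

    def test_matches_textbook_anova(self):
        # 2 groups x 3 replicates, F computed by closed form
        values = {"NBF": [1.0, 2.0, 3.0], "12H": [5.0, 6.0, 7.0]}
        rows = [{"sample": f"{t}-{i}", "time": t, "nucleoside": "x", "normalized": v}
                for t, vs in values.items() for i, v in enumerate(vs)]
        table = pd.DataFrame(rows)
        grand = np.mean([v for vs in values.values() for v in vs])
        ss_between = sum(3 * (np.mean(vs) - grand) ** 2 for vs in values.values())
        ss_within = sum((v - np.mean(vs)) ** 2 for vs in values.values() for v in vs)
        f_hand = (ss_between / 1) / (ss_within / 4)
        out = per_nucleoside_model(table)
        assert out["F"].iloc[0] == pytest.approx(f_hand, rel=1e-10)

    def test_power_on_strong_effect(self):
        # group separation of 10 SD at n=3 is essentially always detected
        detected = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rows = []
            for t, mu in [("NBF", 0.0), ("12H", 10.0)]:
                for i in range(3):
                    rows.append({"sample": f"{t}-{i}", "time": t, "nucleoside": "x",
                                 "normalized": mu + rng.normal(0, 1)})
            out = per_nucleoside_model(pd.DataFrame(rows))
            detected += bool(out["significant"].iloc[0])
        assert detected >= 49

    def test_replicate_requirement(self):
        rows = [{"sample": "a", "time": "NBF", "nucleoside": "x", "normalized": 1.0},
                {"sample": "b", "time": "12H", "nucleoside": "x", "normalized": 2.0}]
        with pytest.raises(ValueError, match="time"):
            per_nucleoside_model(pd.DataFrame(rows))

    def test_bh_adjustment_column(self):
        out = per_nucleoside_model(normalize(toy_table()), adjust=True)
        assert "p_adj" in out.columns
        assert (out["p_adj"] >= out["p"] - 1e-15).all()


class TestInteractionModel:
    def test_planted_effect_detected_null_not(self):
        rng = np.random.default_rng(42)
        n = 12
        treatment = np.repeat(["NBF", "PBF"], n // 2)
        expr = rng.normal(10, 1, n)
        linked = 0.8 * expr + (treatment == "PBF") * 3.0 + rng.normal(0, 0.3, n)
        null = rng.normal(5, 0.3, n)
        res_link = interaction_model(linked, expr, treatment)
        res_null = interaction_model(null, expr, treatment)
        assert res_link.terms.loc["expression", "p"] < 0.05
        assert res_link.terms.loc["treatment", "p"] < 0.05
        assert res_null.terms.loc["expression", "p"] > 0.05

    def test_constant_expression_reduces_to_anova(self):
        rng = np.random.default_rng(1)
        treatment = np.repeat(["NBF", "12H"], 3)
        values = np.where(treatment == "12H", 5.0, 1.0) + rng.normal(0, 0.5, 6)
        res = interaction_model(values, np.ones(6), treatment)
        table = pd.DataFrame({
            "sample": [f"s{i}" for i in range(6)], "time": treatment,
            "nucleoside": "x", "normalized": values,
        })
        anova = per_nucleoside_model(table)
        assert res.terms.loc["treatment", "F"] == pytest.approx(
            anova["F"].iloc[0], rel=1e-10
        )

    def test_unmatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            interaction_model([1.0, 2.0], [1.0], ["a", "b"])

    def test_screen_layout_one_row_per_pair_term(self):
        table, _ = make_peak_area_table(
            {"Q": {"12H": 0.5}, "m1G": {"12H": 2.0}},
            n_replicates=3, cv=0.05, time_points=("NBF", "12H"), seed=3,
        )
        mod = normalize(table)
        mod["treatment"] = np.where(mod["time"] == "NBF", "NBF", "PBF")
        rng = np.random.default_rng(4)
        expr = pd.DataFrame([
            {"sample": s, "gene": g, "value": float(rng.normal(10, 1))}
            for s in mod["sample"].unique() for g in ("QTRT1", "TRMT10C")
        ])
        out = interaction_screen(mod, expr)
        assert set(zip(out["modification"], out["enzyme"])) == {
            ("Q", "QTRT1"), ("Q", "TRMT10C"), ("m1G", "QTRT1"), ("m1G", "TRMT10C")
        }
        assert set(out["term"]) <= {"expression", "treatment", "time"}


class TestMicroarray:
    def test_probe_averaging_and_fc(self):
        expr = pd.DataFrame([
            {"probe": "p1", "sample": "NBF-1", "time": "NBF", "value": 4.0},
            {"probe": "p2", "sample": "NBF-1", "time": "NBF", "value": 6.0},
            {"probe": "p1", "sample": "NBF-2", "time": "NBF", "value": 4.0},
            {"probe": "p2", "sample": "NBF-2", "time": "NBF", "value": 6.0},
            {"probe": "p1", "sample": "12H-1", "time": "12H", "value": 8.0},
            {"probe": "p2", "sample": "12H-1", "time": "12H", "value": 12.0},
            {"probe": "p1", "sample": "12H-2", "time": "12H", "value": 8.0},
            {"probe": "p2", "sample": "12H-2", "time": "12H", "value": 12.0},
        ])
        pmap = pd.DataFrame([{"probe": "p1", "gene": "g"}, {"probe": "p2", "gene": "g"}])
        out = microarray_fold_change(expr, pmap)
        assert out[out["time"] == "NBF"]["fold_change"].iloc[0] == 1.0
        assert out[out["time"] == "12H"]["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_gene_without_probes_errors(self):
        expr = pd.DataFrame([{"probe": "p1", "sample": "s", "time": "NBF", "value": 1.0}])
        pmap = pd.DataFrame([{"probe": "p1", "gene": "g1"}, {"probe": "px", "gene": "g2"}])
        with pytest.raises(ValueError, match="g2"):
            microarray_fold_change(expr, pmap)

    def test_simulation_detection_rates(self):
        sens, fps = [], []
        for seed in range(20):
            expr, pmap, truth = make_microarray(seed=seed)
            out = microarray_fold_change(expr, pmap)
            calls = out.drop_duplicates("gene").set_index("gene")["significant"]
            truth = truth.set_index("gene")
            tp = int((calls & truth["affected"]).sum())
            fp = int((calls & ~truth["affected"]).sum())
            sens.append(tp)
            fps.append(fp)
        assert np.median(sens) >= 14
        assert np.median(fps) <= 2
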