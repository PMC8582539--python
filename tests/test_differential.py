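"""Cohort-level contrast engines: clinical tables, differential SNV/CNA,
integration filter, burden contrast."""

import numpy as np
import pandas as pd
import pytest

from chromarm import differential, stats
from chromarm.model import CnaCallMatrix


def make_groups(n_lost, n_pres):
    g = {f"L{i}": "lost" for i in range(n_lost)}
    g.update({f"P{i}": "preserved" for i in range(n_pres)})
    return g


class TestClinicalAssociation:
    def _cohort(self, var, values_by_sample):
        return pd.DataFrame({"sample": list(values_by_sample),
                             var: list(values_by_sample.values())})

    def test_sex_table_reproduces_fisher(self):
        # counts: lost 69 F / 224 M, preserved 40 F / 42 M
        samples, groups, sexes = [], {}, []
        spec = [("lost", "female", 69), ("lost", "male", 224),
                ("preserved", "female", 40), ("preserved", "male", 42)]
        k = 0
        for grp, sex, cnt in spec:
            for _ in range(cnt):
                samples.append(f"S{k}")
                groups[f"S{k}"] = grp
                sexes.append(sex)
                k += 1
        cohort = pd.DataFrame({"sample": samples, "sex": sexes})
        res, tables = differential.clinical_association_table(
            cohort, groups, variables={"sex": "categorical"})
        assert res.loc[0, "test"] == "fisher_exact"
        assert res.loc[0, "p"] <= 1e-4
        assert tables["sex"].loc["male", "lost"] == 224

    def test_multilevel_variable_uses_chi_square_under_auto_policy(self):
        rng = np.random.default_rng(0)
        groups = make_groups(60, 60)
        cohort = pd.DataFrame({
            "sample": list(groups),
            "smoking": rng.choice(["non-smoker", "light", "heavy"], 120)})
        res, _ = differential.clinical_association_table(
            cohort, groups, variables={"smoking": "categorical"})
        assert res.loc[0, "test"].startswith("chi_square")

    def test_continuous_variable_uses_mann_whitney(self):
        groups = make_groups(20, 20)
        rng = np.random.default_rng(1)
        cohort = pd.DataFrame({"sample": list(groups),
                               "age": rng.normal(60, 10, 40)})
        res, _ = differential.clinical_association_table(
            cohort, groups, variables={"age": "continuous"})
        assert res.loc[0, "test"].startswith("mann_whitney")

    def test_single_level_variable_recorded_untestable(self):
        groups = make_groups(5, 5)
        cohort = pd.DataFrame({"sample": list(groups), "sex": ["male"] * 10})
        res, _ = differential.clinical_association_table(
            cohort, groups, variables={"sex": "categorical"})
        assert res.loc[0, "test"] == "untestable"

    def test_missing_values_dropped_pairwise(self):
        groups = make_groups(4, 4)
        cohort = pd.DataFrame({
            "sample": list(groups),
            "sex": ["male", "female", np.nan, "male"] * 2,
            "adjuvant_rt": ["yes"] * 4 + ["no"] * 4})
        res, tables = differential.clinical_association_table(cohort, groups)
        assert tables["sex"].loc[:, ["lost", "preserved"]].to_numpy().sum() == 6
        assert tables["adjuvant_rt"].to_numpy()[:, :2].sum() == 8


class TestDifferentialSnv:
    def _snvs(self, rows):
        df = pd.DataFrame(rows, columns=["sample", "gene", "classification"])
        df["synonymous"] = df["classification"] == "Silent"
        return df

    def test_patient_counted_once_per_gene(self):
        groups = make_groups(15, 15)
        rows = [("L0", "KRAS", "Missense_Mutation")] * 5  # 5 hits, 1 patient
        rows += [(f"L{i}", "KRAS", "Missense_Mutation") for i in range(1, 12)]
        res = differential.differential_snv(self._snvs(rows), groups,
                                            min_patients=10)
        assert res.loc[0, "n_lost_mut"] == 12

    def test_min_patient_filter_excludes_nine(self):
        groups = make_groups(20, 20)
        rows = [(f"L{i}", "G9", "Missense_Mutation") for i in range(9)]
        rows += [(f"L{i}", "G10", "Missense_Mutation") for i in range(10)]
        res = differential.differential_snv(self._snvs(rows), groups)
        assert set(res["gene"]) == {"G10"}

    def test_ttn_and_synonymous_excluded(self):
        groups = make_groups(15, 15)
        rows = [(f"L{i}", "TTN", "Missense_Mutation") for i in range(15)]
        rows += [(f"L{i}", "SILG", "Silent") for i in range(15)]
        rows += [(f"L{i}", "REAL", "Missense_Mutation") for i in range(12)]
        res = differential.differential_snv(self._snvs(rows), groups)
        assert set(res["gene"]) == {"REAL"}

    def test_p_matches_direct_fisher_and_q_recomputable(self):
        groups = make_groups(50, 50)
        rows = [(f"L{i}", "A", "Missense_Mutation") for i in range(30)]
        rows += [(f"P{i}", "A", "Missense_Mutation") for i in range(10)]
        rows += [(f"L{i}", "B", "Missense_Mutation") for i in range(12)]
        rows += [(f"P{i}", "B", "Missense_Mutation") for i in range(11)]
        res = differential.differential_snv(self._snvs(rows), groups)
        a = res.set_index("gene")
        expected = stats.fisher_exact_2x2([[30, 10], [20, 40]]).p
        assert a.loc["A", "p"] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(res["q"], stats.bh_adjust(res["p"].to_numpy()))

    def test_invariant_to_record_order(self):
        groups = make_groups(20, 20)
        rows = [(f"L{i}", g, "Missense_Mutation")
                for g in ("A", "B") for i in range(12)]
        df = self._snvs(rows)
        res1 = differential.differential_snv(df, groups)
        res2 = differential.differential_snv(
            df.sample(frac=1, random_state=0).reset_index(drop=True), groups)
        pd.testing.assert_frame_equal(res1, res2)


class TestDifferentialCna:
    def _matrix(self, lost_calls, pres_calls, gene="G"):
        n1, n2 = len(lost_calls), len(pres_calls)
        cols = {f"L{i}": [v] for i, v in enumerate(lost_calls)}
        cols.update({f"P{i}": [v] for i, v in enumerate(pres_calls)})
        return CnaCallMatrix(pd.DataFrame(cols, index=pd.Index([gene],
                                                               name="gene")))

    def test_identical_carrier_counts_null(self):
        m = self._matrix([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        res = differential.differential_cna(m, make_groups(10, 10))
        gain = res[res["event_class"] == "gain"].iloc[0]
        assert gain["p"] == 1.0 and gain["q"] == 1.0

    def test_delegation_identity_with_fisher(self):
        lost = [1] * 50 + [0] * 50
        pres = [1] * 10 + [0] * 90
        m = self._matrix(lost, pres)
        res = differential.differential_cna(m, make_groups(100, 100))
        gain = res[res["event_class"] == "gain"].iloc[0]
        expected = stats.fisher_exact_2x2([[50, 10], [50, 90]]).p
        assert gain["p"] == pytest.approx(expected, abs=1e-12)

    def test_event_classes_are_separate_bh_families(self):
        m = self._matrix([2, -2, 1, -1, 0], [0, 0, 0, 0, 0])
        res = differential.differential_cna(m, make_groups(5, 5))
        for cls, sub in res.groupby("event_class"):
            assert np.allclose(sub["q"], stats.bh_adjust(sub["p"].to_numpy()))

    def test_planted_3q_gain_dominates_significant_gains(self, small_bundle):
        b = small_bundle
        groups = dict(zip(b.truth["sample"], b.truth["true_status"]))
        groups = {s: g for s, g in groups.items()
                  if g in ("lost", "preserved")
                  and b.truth.set_index("sample").loc[s, "hpv_status"] == "negative"}
        res = differential.differential_cna(b.cna, groups)
        gains = res[(res["event_class"] == "gain") & (res["q"] < 0.1)]
        sig_genes = set(gains["gene"])
        on_3q = [g for g in sig_genes if g.startswith("3q") or g == "PIK3CA"]
        assert len(sig_genes) > 0
        assert len(on_3q) / len(sig_genes) > 0.8


class TestIntegration:
    def _cna(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "event_class", "q"])
        df["p"] = df["q"] / 2
        return df

    def _de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "q"])

    def test_passing_gain_is_concordant_up(self):
        out, _ = differential.integrate_cna_mrna(
            self._cna([("A", "gain", 0.05)]), self._de([("A", 1.5, 0.005)]))
        assert out.loc[0, "concordant"] and out.loc[0, "cn_type"] == "gain"

    def test_subthreshold_fold_change_filtered(self):
        out, _ = differential.integrate_cna_mrna(
            self._cna([("A", "gain", 0.05)]), self._de([("A", 0.9, 0.005)]))
        assert out.empty

    def test_dual_significance_assigned_to_lower_q_class(self):
        cna = self._cna([("A", "shallow_deletion", 0.02),
                         ("A", "amplification", 0.08)])
        out, _ = differential.integrate_cna_mrna(cna,
                                                 self._de([("A", -2.0, 1e-4)]))
        assert out.loc[0, "cn_type"] == "deletion"
        assert out.loc[0, "concordant"]

    def test_missing_de_entry_dropped_and_counted(self):
        out, n_missing = differential.integrate_cna_mrna(
            self._cna([("A", "gain", 0.01)]), self._de([("B", 2.0, 0.001)]))
        assert out.empty and n_missing == 1


class TestBurdenContrast:
    def test_identical_distributions_null(self):
        groups = make_groups(5, 5)
        burdens = pd.DataFrame({"sample": list(groups),
                                "pga": [0.1, 0.2, 0.3, 0.4, 0.5] * 2})
        res = differential.burden_contrast(burdens, groups)
        assert res.p == pytest.approx(1.0)

    def test_delegates_to_mann_whitney(self):
        groups = make_groups(6, 6)
        rng = np.random.default_rng(4)
        vals = rng.random(12)
        burdens = pd.DataFrame({"sample": list(groups), "pga": vals})
        res = differential.burden_contrast(burdens, groups)
        direct = stats.mann_whitney_u(vals[:6], vals[6:])
        assert res.p == pytest.approx(direct.p)
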