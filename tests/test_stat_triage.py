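"""QC prefilter, volcano selection, PCA and reporting."""

import numpy as np
import pytest

from metid.feature_matching import FeatureRecord, MatchResult, SampleMetadata
from metid.spectral_synthesis import Peak
from metid.stat_triage import (
    PrefilterThresholds,
    crossref_and_report,
    mode_venn,
    pca_overview,
    qc_prefilter,
    volcano_select,
)


def meta(n_treated=3, n_control=3, n_qc=4):
    out = []
    out += [SampleMetadata(f"T{i}", "treated") for i in range(1, n_treated + 1)]
    out += [SampleMetadata(f"C{i}", "control") for i in range(1, n_control + 1)]
    out += [SampleMetadata(f"QC{i}", "QC") for i in range(1, n_qc + 1)]
    return out


def feature(fid, treated, control, qc):
    areas = {}
    areas.update({f"T{i+1}": a for i, a in enumerate(treated)})
    areas.update({f"C{i+1}": a for i, a in enumerate(control)})
    areas.update({f"QC{i+1}": a for i, a in enumerate(qc)})
    return FeatureRecord(fid, 300.0, 5.0, (), "DDA+", areas)


class TestPrefilter:
    def test_constant_qc_areas_have_zero_rsd(self):
        f = feature("F1", [1, 1, 1], [1, 1, 1], [100, 100, 100, 100])
        st = qc_prefilter([f], meta())["F1"]
        assert st.qc_rsd == 0.0

    def test_sample_sd_rsd_value(self):
        f = feature("F1", [1, 1, 1], [1, 1, 1], [90, 100, 110, 100])
        st = qc_prefilter([f], meta())["F1"]
        assert st.qc_rsd == pytest.approx(8.1650, abs=1e-3)
        assert st.passes_prefilter

    def test_zero_qc_mean_fails_rsd_criterion(self):
        f = feature("F1", [1, 1, 1], [1, 1, 1], [0, 0, 0, 0])
        st = qc_prefilter([f], meta())["F1"]
        assert not st.passes_prefilter

    def test_needs_two_qc_samples(self):
        with pytest.raises(ValueError, match="QC"):
            qc_prefilter([], meta(n_qc=1))

    @pytest.mark.parametrize(
        "rsd_target, should_pass", [(29.9, True), (30.1, False)]
    )
    def test_rsd_threshold_is_strict(self, rsd_target, should_pass):
        # two QC values with mean 100 and sample sd chosen to hit the target RSD
        half_spread = rsd_target / 100.0 * 100.0 / np.sqrt(2)
        qc = [100 - half_spread, 100 + half_spread]
        f = feature("F1", [1, 1, 1], [1, 1, 1], qc)
        st = qc_prefilter([f], meta(n_qc=2))["F1"]
        assert st.qc_rsd == pytest.approx(rsd_target, abs=1e-6)
        assert st.passes_prefilter is should_pass

    @pytest.mark.parametrize("n_present, should_pass", [(7, False), (8, True)])
    def test_group_presence_is_strict_at_70_percent(self, n_present, should_pass):
        # 10 samples per group; 7/10 = 0.7 is NOT > 0.7
        treated = [100.0] * n_present + [0.0] * (10 - n_present)
        f = feature("F1", treated, [0.0] * 10, [100.0] * 4)
        st = qc_prefilter([f], meta(n_treated=10, n_control=10))["F1"]
        assert st.group_presence["treated"] == pytest.approx(n_present / 10)
        assert st.passes_prefilter is should_pass

    @pytest.mark.parametrize("n_qc_present, should_pass", [(2, False), (3, True)])
    def test_qc_presence_is_strict_at_50_percent(self, n_qc_present, should_pass):
        qc = [100.0] * n_qc_present + [0.0] * (4 - n_qc_present)
        f = feature("F1", [100.0] * 3, [100.0] * 3, qc)
        st = qc_prefilter([f], meta())["F1"]
        # 2/4 = 0.5 is NOT > 0.5; RSD over sparse QCs can also fail, so force
        # the comparison on the presence criterion alone
        lax = PrefilterThresholds(max_qc_rsd=1e9)
        st2 = qc_prefilter([f], meta(), lax)["F1"]
        assert st2.passes_prefilter is should_pass


class TestVolcano:
    def test_tenfold_feature_selected(self):
        f = feature("F1", [1000, 1100, 900], [100, 110, 90], [500] * 4)
        stats = volcano_select([f], meta())
        st = stats["F1"]
        assert st.fold_change == pytest.approx(10.0, rel=1e-9)
        assert st.p_value < 0.05
        assert st.significant

    def test_flat_feature_not_selected(self):
        f = feature("F1", [100, 100, 100], [100, 100, 100], [100] * 4)
        st = volcano_select([f], meta())["F1"]
        assert st.fold_change == pytest.approx(1.0)
        assert not st.significant

    def test_control_elevated_feature_excluded_despite_small_p(self):
        f = feature("F1", [100, 110, 90], [1000, 1100, 900], [500] * 4)
        st = volcano_select([f], meta())["F1"]
        assert st.fold_change == pytest.approx(0.1, rel=1e-9)
        assert st.p_value < 0.05
        assert not st.significant

    def test_missing_group_is_an_error(self):
        f = feature("F1", [1, 1, 1], [1, 1, 1], [1] * 4)
        with pytest.raises(ValueError, match="control"):
            volcano_select([f], [m for m in meta() if m.role != "control"])

    def test_funnel_monotonicity(self):
        rng = np.random.default_rng(3)
        feats = []
        for i in range(50):
            fc = rng.choice([1.0, 10.0])
            base = 10 ** rng.uniform(3, 5)
            feats.append(
                feature(
                    f"F{i}",
                    base * fc * rng.lognormal(0, 0.2, 3),
                    base * rng.lognormal(0, 0.2, 3),
                    base * rng.lognormal(0, rng.choice([0.05, 0.5]), 4),
                )
            )
        stats = qc_prefilter(feats, meta())
        stats = volcano_select(feats, meta(), stats=stats)
        for st in stats.values():
            if st.significant:
                assert st.passes_prefilter

    def test_type_one_error_calibrated_under_null(self):
        """No group effect: ~5% of features reach p < 0.05."""
        rng = np.random.default_rng(1)
        n = 200
        feats = [
            feature(
                f"F{i}",
                1000 * rng.lognormal(0, 0.3, 6),
                1000 * rng.lognormal(0, 0.3, 6),
                [1000] * 4,
            )
            for i in range(n)
        ]
        stats = volcano_select(feats, meta(n_treated=6, n_control=6))
        frac = np.mean([st.p_value < 0.05 for st in stats.values()])
        assert 0.03 <= frac <= 0.07

    def test_strong_spikes_recovered_in_at_least_95_percent_of_replicates(self):
        """True FC 10 at 20% CV and n=3 is selected almost always."""
        rng = np.random.default_rng(5)
        sigma = np.sqrt(np.log1p(0.2**2))
        hits = 0
        reps = 100
        for _ in range(reps):
            f = feature(
                "S",
                1000 * 10 * rng.lognormal(0, sigma, 3),
                1000 * rng.lognormal(0, sigma, 3),
                [5000] * 4,
            )
            if volcano_select([f], meta())["S"].significant:
                hits += 1
        assert hits >= 0.95 * reps


class TestPca:
    def test_rank_one_structure_dominates_pc1(self):
        m = meta(n_treated=4, n_control=4, n_qc=2)
        feats = [
            feature("F1", [1e5] * 4, [1e3] * 4, [1e4] * 2),
            feature("F2", [2e5] * 4, [2e3] * 4, [2e4] * 2),
        ]
        scores, explained = pca_overview(feats, m)
        assert explained[0] > 0.99
        t = scores.loc[scores.role == "treated", "PC1"]
        c = scores.loc[scores.role == "control", "PC1"]
        assert t.min() > c.max() or c.min() > t.max()

    def test_explained_variance_sums_below_one(self):
        rng = np.random.default_rng(2)
        m = meta()
        feats = [
            feature(f"F{i}", rng.uniform(1, 100, 3), rng.uniform(1, 100, 3),
                    rng.uniform(1, 100, 4))
            for i in range(10)
        ]
        _, explained = pca_overview(feats, m, n_components=3)
        assert np.sum(explained) <= 1.0 + 1e-12

    def test_scores_deterministic_with_fixed_sign_rule(self):
        rng = np.random.default_rng(4)
        m = meta()
        feats = [
            feature(f"F{i}", rng.uniform(1, 100, 3), rng.uniform(1, 100, 3),
                    rng.uniform(1, 100, 4))
            for i in range(8)
        ]
        s1, _ = pca_overview(feats, m)
        s2, _ = pca_overview(feats, m)
        assert s1.equals(s2)

    def test_qc_replicates_cluster_tighter_than_biology(self):
        rng = np.random.default_rng(6)
        m = meta(n_treated=5, n_control=5, n_qc=5)
        feats = []
        for i in range(40):
            base = 10 ** rng.uniform(3, 5)
            feats.append(
                feature(
                    f"F{i}",
                    base * rng.lognormal(0, 0.5, 5),
                    base * rng.lognormal(0, 0.5, 5),
                    base * rng.lognormal(0, 0.05, 5),
                )
            )
        scores, _ = pca_overview(feats, m)

        def mean_pairwise(df):
            pts = df[["PC1", "PC2"]].to_numpy()
            d = [np.linalg.norm(a - b) for i, a in enumerate(pts) for b in pts[i + 1:]]
            return np.mean(d)

        qc = mean_pairwise(scores[scores.role == "QC"])
        bio = mean_pairwise(scores[scores.role != "QC"])
        assert qc < bio


def match(fid, cid, mode="DDA+", level=3, tentative=True):
    return MatchResult(fid, cid, 0.0005, 3, 0.95, level,
                       acquisition_mode=mode, tentative=tentative)


class TestCrossrefAndVenn:
    def _stats(self, feats, m, significant_ids):
        stats = qc_prefilter(feats, m)
        stats = volcano_select(feats, m, stats=stats)
        for fid, st in stats.items():
            st.significant = fid in significant_ids
        return stats

    def test_significant_and_matched_feature_reported(self):
        m = meta()
        f = feature("F1", [1000] * 3, [100] * 3, [500] * 4)
        stats = self._stats([f], m, {"F1"})
        report = crossref_and_report(stats, [match("F1", "Ketoprofen-R63")], m, [f])
        assert len(report) == 1
        assert report.iloc[0]["compound"] == "Ketoprofen-R63"
        assert report.iloc[0]["confidence_level"] == 3

    def test_significant_but_unmatched_feature_absent(self):
        m = meta()
        f = feature("F1", [1000] * 3, [100] * 3, [500] * 4)
        stats = self._stats([f], m, {"F1"})
        assert len(crossref_and_report(stats, [], m, [f])) == 0

    def test_matched_but_not_significant_feature_absent(self):
        m = meta()
        f = feature("F1", [100] * 3, [100] * 3, [100] * 4)
        stats = self._stats([f], m, set())
        report = crossref_and_report(stats, [match("F1", "Ketoprofen-R63")], m, [f])
        assert len(report) == 0

    def test_single_shared_metabolite_lands_in_intersection(self):
        venn = mode_venn([match("F1", "X", "DDA+"), match("F2", "X", "DIA+")])
        assert venn["elements"] == 1
        assert venn["DDA+&DIA+"] == 1
        assert venn["DDA+"] == 0  # exclusive region is empty

    def test_empty_report_all_zero(self):
        venn = mode_venn([])
        assert venn == {"elements": 0}

    def test_five_element_toy_matches_brute_force(self):
        matches = [
            match("F1", "A", "DDA+"), match("F2", "A", "DDA-"),
            match("F3", "B", "DDA+"),
            match("F4", "C", "DIA+"), match("F5", "C", "DDA+"), match("F6", "C", "DDA-"),
            match("F7", "D", "DIA+"),
            match("F8", "E", "DDA-"),
        ]
        venn = mode_venn(matches)
        memberships = {
            "A": {"DDA+", "DDA-"}, "B": {"DDA+"}, "C": {"DDA+", "DDA-", "DIA+"},
            "D": {"DIA+"}, "E": {"DDA-"},
        }
        assert venn["elements"] == 5
        assert venn["DDA+"] == sum(1 for s in memberships.values() if s == {"DDA+"})
        assert venn["DDA+&DDA-"] == 1
        assert venn["DDA+&DDA-&DIA+"] == 1
        assert venn["total:DDA+"] == sum(1 for s in memberships.values() if "DDA+" in s)
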