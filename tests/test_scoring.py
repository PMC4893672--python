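import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pqselect.core_io import FragmentAnnotation, PSM
from pqselect.scoring import (HuberSettings, build_peptide_metrics,
                              differential_scores, huber_estimate,
                              ion_coverage, ion_coverage_summed,
                              matched_intensity_per_psm, protein_scales)


def reference_huber(values, k=1.2, tol=1e-7, max_iter=2000):
    """Brute-force fixed-point oracle: winsorized-mean iteration from the
    median at 10x tighter tolerance."""
    x = np.asarray(values, float)
    med = np.median(x)
    scale = 1.4826 * np.median(np.abs(x - med))
    if scale == 0:
        return med, 0.0
    mu = med
    for _ in range(max_iter):
        mu1 = np.mean(np.clip(x, mu - k * scale, mu + k * scale))
        if abs(mu1 - mu) < tol * scale:
            return mu1, scale
        mu = mu1
    return mu, scale


class TestHuberEstimate:
    def test_symmetric_data(self):
        result = huber_estimate([1, 2, 3])
        assert result.location == pytest.approx(2.0)
        assert result.scale == pytest.approx(1.4826)

    def test_one_outlier_winsorized(self):
        result = huber_estimate([10, 12, 14, 16, 30])
        assert result.location == pytest.approx(14.0)
        assert result.scale == pytest.approx(2.9652)

    def test_constant_data_degenerate(self):
        result = huber_estimate([5, 5, 5, 5])
        assert result.location == 5 and result.scale == 0
        assert result.degenerate

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            huber_estimate([1.0])

    def test_matches_fixed_point_oracle_on_random_samples(self):
        """Both routes converge to the same winsorized-mean fixed point; the
        estimator runs at a tight tolerance, the oracle 10x tighter."""
        rng = np.random.default_rng(20240917)
        tight = HuberSettings(tolerance=1e-10, max_iterations=500)
        for _ in range(500):
            n = int(rng.integers(3, 40))
            x = rng.lognormal(mean=rng.normal(0, 1),
                              sigma=rng.uniform(0.2, 1.5), size=n)
            mine = huber_estimate(x, tight)
            loc, scale = reference_huber(x, tol=1e-11, max_iter=5000)
            assert mine.scale == pytest.approx(scale, abs=1e-12)
            assert abs(mine.location - loc) < 1e-8

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30),
           st.floats(-1e5, 1e5))
    def test_shift_covariance(self, values, shift):
        base = huber_estimate(values)
        shifted = huber_estimate([v + shift for v in values])
        tol = 1e-6 * max(1.0, abs(base.location), abs(shift))
        assert shifted.location == pytest.approx(base.location + shift, abs=tol)
        assert shifted.scale == pytest.approx(base.scale, abs=tol)

    def test_outlier_free_data_location_is_plain_mean(self):
        """When every point already lies inside the winsorization band, the
        clamp is the identity and the location is the plain mean after one
        step."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            x = 10 + rng.normal(0, 0.1, size=9)
            med = np.median(x)
            band = 1.2 * 1.4826 * np.median(np.abs(x - med))
            if (np.all(np.abs(x - med) <= band)
                    and np.all(np.abs(x - x.mean()) <= band)):
                checked += 1
                assert huber_estimate(x).location == pytest.approx(
                    x.mean(), rel=1e-9)
        assert checked > 0

    def test_matches_mass_huber_reference(self):
        """Cross-check against the R MASS implementation this estimator
        mirrors."""
        datasets = [
            [10, 12, 14, 16, 30],
            [1.5, 2.5, 2.7, 3.1, 9.9, 2.2, 2.4],
            [100, 110, 118, 121, 130, 145, 400, 90],
        ]
        rcode = "library(MASS);" + ";".join(
            "r<-huber(c({}),k=1.2);cat(r$mu,r$s,'\\n')".format(
                ",".join(map(str, data))) for data in datasets)
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True).stdout.split()
        for i, data in enumerate(datasets):
            mu, s = float(out[2 * i]), float(out[2 * i + 1])
            mine = huber_estimate(data)
            assert mine.location == pytest.approx(mu, rel=1e-4)
            assert mine.scale == pytest.approx(s, rel=1e-6)


class TestMatchedIntensity:
    def test_sums_annotation_intensities(self, psm_factory):
        assert matched_intensity_per_psm(
            psm_factory("TESTR", [100, 200, 50])) == 350

    def test_empty_annotations_give_zero(self, psm_factory):
        assert matched_intensity_per_psm(psm_factory("TESTR", [])) == 0.0

    def test_single_fragment(self):
        psm = PSM("S1", "TESTR", ("P1",), "e1",
                  (FragmentAnnotation("y", 1, 1, 7.5),))
        assert matched_intensity_per_psm(psm) == 7.5


def _protein_psms(factory, protein, peptides, experiment="exp1"):
    """One PSM per (peptide, intensity) pair for a protein."""
    psms = []
    for pep, sums in peptides.items():
        for i, total in enumerate(sums):
            psms.append(factory(pep, [total], spectrum_id=f"{pep}.{i}",
                                experiment_id=experiment,
                                accessions=(protein,)))
    return psms


class TestBuildPeptideMetrics:
    def test_average_and_spectral_count(self, psm_factory):
        psms = _protein_psms(psm_factory, "P1", {
            "AAAAAAAAK": [300, 500], "CCCCCCCCK": [100], "DDDDDDDDK": [200]})
        result = build_peptide_metrics(psms)
        by_pep = {m.peptide_sequence: m for m in result.metrics}
        assert by_pep["AAAAAAAAK"].avg_matched_intensity == 400
        assert by_pep["AAAAAAAAK"].spectral_count == 2

    def test_ambiguous_peptides_dropped_and_counted(self, psm_factory):
        psms = _protein_psms(psm_factory, "P1", {
            "AAAAAAAAK": [1], "CCCCCCCCK": [2], "DDDDDDDDK": [3]})
        psms.append(psm_factory("EEEEEEEEK", [5], accessions=("P1", "P2")))
        result = build_peptide_metrics(psms)
        assert "EEEEEEEEK" not in {m.peptide_sequence for m in result.metrics}
        assert result.n_ambiguous_peptides == 1

    def test_protein_floor_applied_per_experiment(self, psm_factory):
        psms = _protein_psms(psm_factory, "P1", {
            "AAAAAAAAK": [1], "CCCCCCCCK": [2], "DDDDDDDDK": [3]}, "exp1")
        psms += _protein_psms(psm_factory, "P1", {
            "AAAAAAAAK": [1], "CCCCCCCCK": [2]}, "exp2")
        result = build_peptide_metrics(psms)
        experiments = {m.experiment_id for m in result.metrics}
        assert experiments == {"exp1"}
        assert result.n_dropped_protein_floor == 2


class TestDifferentialScores:
    def _metrics(self, psm_factory, values, experiment="exp1"):
        peptides = {f"PE{'ACDEFGHILNSTVW'[i]}AAAAK": [v]
                    for i, v in enumerate(values)}
        return build_peptide_metrics(
            _protein_psms(psm_factory, "P1", peptides, experiment)).metrics

    def test_outlier_peptide_score(self, psm_factory):
        metrics = self._metrics(psm_factory, [10, 12, 14, 16, 30])
        scores = {s.peptide_sequence: s.scores["exp1"]
                  for s in differential_scores(metrics)}
        top = max(scores.values())
        assert top == pytest.approx((30 - 14) / 2.9652, abs=1e-3)

    def test_peptide_at_location_scores_zero(self, psm_factory):
        metrics = self._metrics(psm_factory, [10, 12, 14, 16, 30])
        scores = {s.peptide_sequence: s.scores["exp1"]
                  for s in differential_scores(metrics)}
        assert sorted(scores.values())[2] == pytest.approx(0.0, abs=1e-9)

    def test_mean_of_identical_experiments_is_the_per_experiment_score(
            self, psm_factory):
        metrics = []
        for exp in ("exp1", "exp2", "exp3"):
            metrics += self._metrics(psm_factory, [10, 12, 14, 16, 30], exp)
        for s in differential_scores(metrics):
            assert s.mean_score == pytest.approx(s.scores["exp1"])

    def test_degenerate_protein_scores_undefined(self, psm_factory):
        metrics = self._metrics(psm_factory, [5, 5, 5, 5])
        for s in differential_scores(metrics):
            assert s.scores["exp1"] is None
            assert "exp1" in s.degenerate_experiments
            assert s.mean_score is None

    def test_scale_invariance_of_scores(self, psm_factory):
        rng = np.random.default_rng(11)
        for _ in range(20):
            values = rng.lognormal(8, 1, size=6)
            for c in (10.0, 0.001, 37.5):
                base = differential_scores(self._metrics(psm_factory, values))
                scaled = differential_scores(
                    self._metrics(psm_factory, values * c))
                a = {s.peptide_sequence: s.scores["exp1"] for s in base}
                b = {s.peptide_sequence: s.scores["exp1"] for s in scaled}
                for pep in a:
                    assert b[pep] == pytest.approx(a[pep], rel=1e-9, abs=1e-9)

    def test_protein_scales_keyed_per_experiment(self, psm_factory):
        metrics = (self._metrics(psm_factory, [10, 12, 14], "exp1")
                   + self._metrics(psm_factory, [100, 120, 140], "exp2"))
        scales = protein_scales(metrics)
        assert scales[("P1", "exp1")].location != scales[("P1", "exp2")].location
        assert scales[("P1", "exp1")].n_peptides == 3


class TestIonCoverage:
    def test_per_spectrum_then_across_experiments(self, psm_factory):
        psms = [psm_factory("AAAAAAAAK", [1] * 12, "S1", "exp1"),
                psm_factory("AAAAAAAAK", [1] * 18, "S2", "exp1"),
                psm_factory("AAAAAAAAK", [1] * 15, "S3", "exp2")]
        metrics = [m for m in build_peptide_metrics(
            psms, min_peptides_per_protein=1).metrics]
        assert ion_coverage(metrics)["AAAAAAAAK"] == pytest.approx(15.0)

    def test_single_psm_per_experiment(self, psm_factory):
        psms = [psm_factory("AAAAAAAAK", [1] * 31, f"S{i}", f"exp{i}")
                for i in range(3)]
        metrics = build_peptide_metrics(psms, min_peptides_per_protein=1).metrics
        assert ion_coverage(metrics)["AAAAAAAAK"] == 31

    def test_no_annotations_give_zero(self, psm_factory):
        psms = [psm_factory("AAAAAAAAK", [], "S1", "exp1")]
        metrics = build_peptide_metrics(psms, min_peptides_per_protein=1).metrics
        assert ion_coverage(metrics)["AAAAAAAAK"] == 0

    def test_summed_convention_differs(self, psm_factory):
        psms = [psm_factory("AAAAAAAAK", [1] * 12, "S1", "exp1"),
                psm_factory("AAAAAAAAK", [1] * 18, "S2", "exp1")]
        metrics = build_peptide_metrics(psms, min_peptides_per_protein=1).metrics
        assert ion_coverage_summed(metrics)["AAAAAAAAK"] == pytest.approx(30.0)
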