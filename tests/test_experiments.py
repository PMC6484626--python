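"""End-to-end experiment drivers and the report bundle."""

import numpy as np
import pandas as pd
import pytest

import histocv as h

NOISELESS = h.SimConfig(n_patients=20, patches_per_core=8,
                        patient_effect_sd=0, core_effect_sd=0, noise_sd=0, seed=1)


@pytest.fixture(scope="module")
def noiseless_cohort():
    return h.simulate_cohort(NOISELESS)


@pytest.mark.parametrize("level,k", [("patient", 5), ("core", 5), ("patch", 2)])
def test_separable_classes_give_perfect_accuracy_everywhere(noiseless_cohort, level, k):
    truth = noiseless_cohort.true_labels
    table = h.run_cv_experiment(noiseless_cohort, truth, h.FoldSpec(k, level, seed=2),
                                classifier_kind="nearest_centroid")
    y_true = truth.loc[table["patch_id"]].to_numpy()
    t, p, mask = h.binarize(y_true, table["predicted"].to_numpy(), h.DETECTION)
    summary = h.fold_metrics(t[mask], p[mask], table["fold"].to_numpy()[mask])
    assert summary.mean["accuracy"] == pytest.approx(100.0)
    assert (summary.per_fold["accuracy"] == 100.0).all()


def test_every_included_patch_predicted_exactly_once(small_cohort):
    truth = small_cohort.true_labels
    table = h.run_cv_experiment(small_cohort, truth, h.FoldSpec(5, "patient", 3))
    assert len(table) == len(truth)
    assert not table["patch_id"].duplicated().any()
    assert set(table["patch_id"]) == set(truth.index)


def test_patches_without_truth_are_excluded(small_cohort):
    truth = small_cohort.true_labels.iloc[:-20]
    table = h.run_cv_experiment(small_cohort, truth, h.FoldSpec(5, "patient", 3))
    assert len(table) == len(truth)


def test_missing_class_in_training_split_names_the_fold():
    cohort = h.simulate_cohort(h.SimConfig(n_patients=4, cores_per_patient=(1,),
                                           patches_per_core=2, seed=8))
    # concentrate one class into a single patient so leaving it out breaks training
    patches = cohort.patches.copy()
    patches["true_class"] = ["G5", "G5", "G3", "G3", "G3", "G3", "G3", "G3"]
    cohort.patches = patches
    with pytest.raises(ValueError, match="fold"):
        h.run_cv_experiment(cohort, cohort.true_labels,
                            h.FoldSpec(4, "patient", seed=0))


def test_identical_specs_compare_with_p_equal_one(small_cohort):
    truth = small_cohort.true_labels
    spec = h.FoldSpec(5, "patient", seed=4)
    comp = h.compare_cv_methods(small_cohort, truth, [spec, spec])
    for task_name, pmat in comp.pvalues.items():
        vals = pmat.to_numpy()
        assert np.nanmin(vals) == np.nanmax(vals) == 1.0


def test_comparison_requires_two_specs(small_cohort):
    with pytest.raises(ValueError):
        h.compare_cv_methods(small_cohort, small_cohort.true_labels,
                             [h.FoldSpec(5, "patient", 0)])


def test_comparison_pvalue_matrix_is_lower_triangular(small_cohort):
    truth = small_cohort.true_labels
    specs = [h.FoldSpec(5, "patient", 1), h.FoldSpec(5, "core", 1),
             h.FoldSpec(5, "patch", 1)]
    comp = h.compare_cv_methods(small_cohort, truth, specs, tasks=(h.DETECTION,))
    pmat = comp.pvalues["detection"]
    k = len(specs)
    assert pmat.notna().to_numpy().sum() == k * (k - 1) // 2
    assert all(pmat.iloc[i, j] >= 0 for i in range(k) for j in range(i))


def test_annotator_confusions_are_recovered_from_simulated_labels():
    cfg = h.SimConfig(n_patients=150, cores_per_patient=(1,), patches_per_core=30,
                      class_prevalence=(0.25, 0.25, 0.25, 0.25), seed=19)
    cohort = h.simulate_cohort(cfg)
    profiles = [p for p in h.default_profiles() if p.coverage == 1.0]
    ann = h.simulate_annotations(cohort, profiles, seed=6)
    truth_codes = np.array([h.CLASS_INDEX[c] for c in cohort.patches["true_class"]])
    for prof in profiles:
        got = ann.codes[prof.id].to_numpy()
        for i in range(4):
            rows = truth_codes == i
            n = int(rows.sum())
            for j in range(4):
                p_ij = prof.confusion[i, j]
                observed = int((got[rows] == j).sum())
                sd = np.sqrt(n * p_ij * (1 - p_ij))
                assert abs(observed - n * p_ij) <= max(4 * sd, 1)


def test_cross_expert_requires_patient_level_folds(small_cohort):
    ann = h.simulate_annotations(small_cohort, h.default_profiles(), seed=1)
    with pytest.raises(ValueError):
        h.cross_expert_experiment(small_cohort, ann, h.FoldSpec(5, "patch", 1))


def test_identical_noiseless_annotators_give_constant_agreement_rows(noiseless_cohort):
    profiles = [h.AnnotatorProfile(id=f"a{i}", confusion=np.eye(4)) for i in range(3)]
    ann = h.simulate_annotations(noiseless_cohort, profiles, seed=2)
    result = h.cross_expert_experiment(noiseless_cohort, ann,
                                       h.FoldSpec(5, "patient", 2),
                                       classifier_kind="nearest_centroid")
    values = result.agreement.to_numpy()
    assert np.allclose(values, values[0, 0])


def test_leakage_gap_is_monotone_in_patient_effect():
    from dataclasses import replace
    gaps = []
    for sigma_p in (0.0, 0.5, 1.0, 2.0):
        cfg = replace(h.DEFAULT_SCENARIO, n_patients=60, patches_per_core=20,
                      patient_effect_sd=sigma_p)
        cohort = h.simulate_cohort(cfg)
        truth = cohort.true_labels
        comp = h.compare_cv_methods(
            cohort, truth,
            [h.FoldSpec(10, "patient", cfg.seed), h.FoldSpec(10, "patch", cfg.seed)],
            tasks=(h.DETECTION,))
        m = comp.metrics.set_index("scheme")
        gaps.append(m.loc["10-fold leave-patches-out", "accuracy_mean"]
                    - m.loc["10-fold leave-patients-out", "accuracy_mean"])
    for lo, hi in zip(gaps, gaps[1:]):
        assert hi >= lo - 1.0  # weak monotonicity, 1 pp sampling tolerance


# ---------------------------------------------------------------------------
# report bundle

def _small_study():
    cfg = h.SimConfig(n_patients=24, patches_per_core=6, seed=42)
    return h.run_full_study(config=cfg, fold_specs=[
        h.FoldSpec(4, "patient", 42), h.FoldSpec(4, "patch", 42)])


def test_report_bundle_is_deterministic(tmp_path):
    res = _small_study()
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    h.write_report(out_a, comparison=res.comparison, cross_expert=res.cross_expert,
                   manifest={"seed": 42})
    h.write_report(out_b, comparison=res.comparison, cross_expert=res.cross_expert,
                   manifest={"seed": 42})
    for name in ("cv_metrics.csv", "mcnemar_detection.csv",
                 "cross_expert_agreement.csv", "manifest.json", "summary.txt"):
        assert (out_a / name).read_bytes() == (out_b / name).read_bytes()


def test_full_pipeline_is_reproducible_under_one_seed():
    a, b = _small_study(), _small_study()
    pd.testing.assert_frame_equal(a.comparison.metrics, b.comparison.metrics)
    pd.testing.assert_frame_equal(a.cross_expert.agreement, b.cross_expert.agreement)


def test_empty_report_request_writes_nothing(tmp_path):
    out = tmp_path / "bundle"
    with pytest.raises(ValueError):
        h.write_report(out)
    assert not out.exists()


def test_p_value_formatting_follows_journal_convention():
    assert h.format_p(0.0005) == "<.001"
    assert h.format_p(0.042) == ".042"
    assert h.format_p(float("nan")) == "NA"
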