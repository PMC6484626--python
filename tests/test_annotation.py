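"""Annotator simulation, majority vote, and pairwise agreement."""

import numpy as np
import pandas as pd
import pytest

import histocv as h
from histocv.classes import MISSING_CODE, CLASS_INDEX
from conftest import kappa_oracle

IDENTITY = np.eye(4)


def _profile(pid="a", confusion=IDENTITY, coverage=1.0):
    return h.AnnotatorProfile(id=pid, confusion=confusion, coverage=coverage)


def test_noiseless_full_coverage_annotator_reproduces_truth(small_cohort):
    ann = h.simulate_annotations(small_cohort, [_profile()], seed=1)
    assert (ann.labels_of("a").to_numpy()
            == small_cohort.patches["true_class"].to_numpy()).all()


def test_zero_coverage_annotator_is_all_missing(small_cohort):
    ann = h.simulate_annotations(small_cohort, [_profile(coverage=0.0)], seed=1)
    assert (ann.codes["a"] == MISSING_CODE).all()


def test_confusion_rates_match_binomial_oracle():
    cfg = h.SimConfig(n_patients=250, cores_per_patient=(1,), patches_per_core=40,
                      class_prevalence=(0.0, 1.0, 0.0, 0.0), seed=9)
    cohort = h.simulate_cohort(cfg)  # 10 000 G3 patches
    confusion = np.array([[1, 0, 0, 0],
                          [0, 0.7, 0.3, 0],
                          [0, 0, 1, 0],
                          [0, 0, 0, 1.0]])
    ann = h.simulate_annotations(cohort, [_profile(confusion=confusion)], seed=2)
    frac_g4 = (ann.codes["a"] == CLASS_INDEX["G4"]).mean()
    n = len(cohort.patches)
    assert abs(frac_g4 - 0.3) <= 4 * np.sqrt(0.3 * 0.7 / n)


def test_non_row_stochastic_confusion_rejected():
    with pytest.raises(ValueError):
        _profile(confusion=np.full((4, 4), 0.3))


def test_coverage_realisation_is_exact():
    cohort = h.simulate_cohort(h.SimConfig(n_patients=111, cores_per_patient=(1,),
                                           patches_per_core=1, seed=4))
    for coverage in (0.25, 0.5, 191 / 333):
        ann = h.simulate_annotations(cohort, [_profile(coverage=coverage)], seed=3)
        covered_cores = (ann.codes["a"] != MISSING_CODE).sum()  # 1 patch per core
        assert covered_cores == round(coverage * 111)


def _matrix(rows: dict[str, list[str]]) -> h.AnnotationMatrix:
    codes = pd.DataFrame(
        {a: [MISSING_CODE if l == "M" else CLASS_INDEX[l] for l in col]
         for a, col in rows.items()},
        index=pd.Index([f"p{i}" for i in range(len(next(iter(rows.values()))))],
                       name="patch_id"),
        dtype=np.int64,
    )
    return h.AnnotationMatrix(codes=codes)


def test_majority_vote_strict_majority_severity_tie_and_undefined():
    ann = _matrix({
        "a": ["G3", "G3", "M"],
        "b": ["G3", "G4", "M"],
        "c": ["G4", "M", "M"],
    })
    out = h.majority_vote(ann)
    assert out.loc["p0", "consensus"] == "G3"  # strict majority
    assert out.loc["p1", "consensus"] == "G4"  # tie -> more severe
    assert bool(out.loc["p2", "undefined"])  # no votes at all
    assert out.loc["p2", "consensus"] == "MISSING"


def test_majority_vote_alternative_tie_rules():
    ann = _matrix({"a": ["G3"], "b": ["G4"]})
    assert h.majority_vote(ann, tie_rule="least_severe").loc["p0", "consensus"] == "G3"
    rand = h.majority_vote(ann, tie_rule="random", seed=1)
    assert rand.loc["p0", "consensus"] in ("G3", "G4")
    pd.testing.assert_frame_equal(rand, h.majority_vote(ann, tie_rule="random", seed=1))


def test_min_votes_flags_sparse_patches():
    ann = _matrix({"a": ["G3", "G3"], "b": ["M", "G3"]})
    out = h.majority_vote(ann, min_votes=2)
    assert bool(out.loc["p0", "undefined"]) and not bool(out.loc["p1", "undefined"])


def test_single_noiseless_annotator_consensus_is_truth(small_cohort):
    ann = h.simulate_annotations(small_cohort, [_profile()], seed=1)
    out = h.majority_vote(ann)
    assert not out["undefined"].any()
    assert (out["consensus"].to_numpy()
            == small_cohort.patches["true_class"].to_numpy()).all()


def test_majority_error_rate_non_increasing_in_panel_size():
    cohort = h.simulate_cohort(h.SimConfig(n_patients=200, cores_per_patient=(1,),
                                           patches_per_core=10, seed=31))
    symmetric = np.full((4, 4), 0.2 / 3) + np.eye(4) * (0.8 - 0.2 / 3)
    truth = cohort.patches["true_class"].to_numpy()
    errors = []
    for n_annot in (1, 3, 5):
        profiles = [_profile(f"a{i}", symmetric) for i in range(n_annot)]
        out = h.majority_vote(h.simulate_annotations(cohort, profiles, seed=12))
        errors.append((out["consensus"].to_numpy() != truth).mean())
    assert errors[0] >= errors[1] >= errors[2]


def test_pairwise_agreement_diagonal_and_no_overlap():
    ann = _matrix({"a": ["G3", "G4", "M"], "b": ["G3", "G4", "M"],
                   "c": ["M", "M", "G5"]})
    table = h.pairwise_annotator_agreement(ann)
    assert table.loc["a", "a"] == 1.0
    assert table.loc["a", "b"] == pytest.approx(1.0)
    assert np.isnan(table.loc["a", "c"])  # no common patches


def test_independent_uniform_annotators_have_near_zero_kappa():
    rng = np.random.default_rng(44)
    codes = pd.DataFrame({
        "a": rng.integers(0, 4, size=10_000),
        "b": rng.integers(0, 4, size=10_000),
    }, index=pd.Index([f"p{i}" for i in range(10_000)], name="patch_id"))
    table = h.pairwise_annotator_agreement(h.AnnotationMatrix(codes=codes))
    assert abs(table.loc["a", "b"]) < 0.05


def test_pairwise_agreement_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    rows = {a: rng.integers(0, 4, size=12) for a in ("a", "b", "c")}
    ann = h.AnnotationMatrix(codes=pd.DataFrame(
        rows, index=pd.Index([f"p{i}" for i in range(12)], name="patch_id")))
    table = h.pairwise_annotator_agreement(ann)
    for x in "abc":
        for y in "abc":
            if x < y:
                assert table.loc[x, y] == pytest.approx(
                    kappa_oracle(rows[x], rows[y]), abs=1e-12)


def test_default_panel_matches_study_design():
    profiles = h.default_profiles()
    assert len(profiles) == 6
    coverages = sorted(p.coverage for p in profiles)
    assert coverages[:2] == [92 / 333, 191 / 333]
    assert coverages[2:] == [1.0] * 4


def test_annotation_csv_round_trip(tmp_path, small_cohort):
    ann = h.simulate_annotations(small_cohort, h.default_profiles(), seed=5)
    path = tmp_path / "ann.csv"
    ann.to_csv(path)
    back = h.AnnotationMatrix.from_csv(path)
    pd.testing.assert_frame_equal(ann.codes, back.codes)
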