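"""Profiles, dissimilarities, PCoA and confusion-matrix metrics.

Independent cross-checks: scipy's Bray–Curtis, scikit-bio's PCoA and
scikit-learn's Cohen kappa.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampliscope.classifiers import ClassificationResult
from ampliscope.community_eval import (METRICS, AbundanceProfile,
                                       ConfusionMatrix, confusion_from_calls,
                                       confusion_metrics, dissimilarity,
                                       distance_matrix, pcoa,
                                       profile_from_classifications,
                                       profiles_from_tsv, profiles_to_tsv,
                                       sti_positivity)
from ampliscope.reference_io import TaxonomyLineage


def prof(sample_id, **ab):
    ab = {k.replace("_", " "): v for k, v in ab.items()}
    return AbundanceProfile(sample_id, ab)


def res(qid, species):
    lineage = (TaxonomyLineage(("Bacteria", "P", "C", "O", "F",
                                species.split()[0], species))
               if species else TaxonomyLineage())
    return ClassificationResult(qid, lineage, 1.0, "nb", "db")


class TestProfiles:
    def test_counts_normalized(self):
        results = [res(f"q{i}", "Genus alpha") for i in range(80)] + \
                  [res(f"p{i}", "Genus beta") for i in range(20)]
        p = profile_from_classifications(results, "s1")
        assert p.get("Genus alpha") == pytest.approx(0.8)
        assert p.get("Genus beta") == pytest.approx(0.2)
        assert p.n_reads == 100

    def test_unassigned_pooled_into_unclassified(self):
        results = [res("q0", "Genus alpha"), res("q1", ""), res("q2", "")]
        p = profile_from_classifications(results, "s1")
        assert p.get("unclassified") == pytest.approx(2 / 3)
        assert sum(p.abundances.values()) == pytest.approx(1.0)

    def test_all_unassigned(self):
        p = profile_from_classifications([res("q0", ""), res("q1", "")], "s1")
        assert p.abundances == {"unclassified": 1.0}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            profile_from_classifications([], "s1")

    def test_tsv_roundtrip(self, tmp_path):
        ps = [prof("s1", Genus_alpha=0.8, Genus_beta=0.2),
              prof("s2", Genus_alpha=0.5, Genus_gamma=0.5)]
        p = tmp_path / "profiles.tsv"
        profiles_to_tsv(ps, p)
        loaded = {x.sample_id: x for x in profiles_from_tsv(p)}
        assert loaded["s1"].get("Genus alpha") == pytest.approx(0.8)
        assert loaded["s2"].get("Genus gamma") == pytest.approx(0.5)


class TestDissimilarity:
    X = prof("x", a=0.8, b=0.2)
    Y = prof("y", a=0.4, b=0.4, c=0.2)

    def test_worked_values(self):
        assert dissimilarity(self.X, self.Y, "bray-curtis") == pytest.approx(0.4)
        assert dissimilarity(self.X, self.Y, "kulczynski") == pytest.approx(0.4)
        assert dissimilarity(self.X, self.Y, "jaccard") == \
            pytest.approx(2 * 0.4 / 1.4)
        assert dissimilarity(self.X, self.Y, "euclidean") == \
            pytest.approx(math.sqrt(0.16 + 0.04 + 0.04))

    def test_identity_is_zero_for_all_metrics(self):
        for m in METRICS:
            assert dissimilarity(self.X, self.X, m) == pytest.approx(0.0)

    def test_disjoint_supports_are_maximal(self):
        a, b = prof("a", x=1.0), prof("b", y=1.0)
        for m in ("bray-curtis", "jaccard", "kulczynski"):
            assert dissimilarity(a, b, m) == pytest.approx(1.0)

    def test_bray_curtis_matches_scipy(self):
        from scipy.spatial.distance import braycurtis
        rng = np.random.default_rng(0)
        for _ in range(20):
            xv = rng.dirichlet(np.ones(6))
            yv = rng.dirichlet(np.ones(6))
            keys = [f"s{i}" for i in range(6)]
            x = AbundanceProfile("x", dict(zip(keys, xv)))
            y = AbundanceProfile("y", dict(zip(keys, yv)))
            assert dissimilarity(x, y, "bray-curtis") == \
                pytest.approx(braycurtis(xv, yv), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=8))
    def test_symmetry_and_bounds_on_random_profiles(self, xs, ys):
        n = max(len(xs), len(ys))
        xs = (xs + [0.0] * n)[:n]
        ys = (ys + [0.0] * n)[:n]
        keys = [f"s{i}" for i in range(n)]
        x = AbundanceProfile("x", {k: v / sum(xs) for k, v in zip(keys, xs) if v})
        y = AbundanceProfile("y", {k: v / sum(ys) for k, v in zip(keys, ys) if v})
        for m in METRICS:
            d_xy = dissimilarity(x, y, m)
            assert d_xy == pytest.approx(dissimilarity(y, x, m), abs=1e-12)
            assert d_xy >= -1e-12
            if m != "euclidean":
                assert d_xy <= 1 + 1e-12

    def test_binary_jaccard_variant(self):
        a = prof("a", x=0.5, y=0.5)
        b = prof("b", x=0.5, z=0.5)
        assert dissimilarity(a, b, "jaccard", binary_jaccard=True) == \
            pytest.approx(1 - 1 / 3)

    def test_all_zero_profile_errors(self):
        with pytest.raises(Exception):
            AbundanceProfile("z", {})  # sums to 0, invalid profile


class TestPCoA:
    def test_collinear_points_recovered_on_first_axis(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = np.abs(pts - pts.T)
        r = pcoa(d)
        assert r.coordinates.shape[1] == 1
        spacing = np.diff(np.sort(r.coordinates[:, 0]))
        assert np.allclose(spacing, 1.0, atol=1e-10)

    def test_two_samples_single_axis_equals_distance(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        r = pcoa(d)
        assert r.coordinates.shape == (2, 1)
        assert abs(r.coordinates[0, 0] - r.coordinates[1, 0]) == \
            pytest.approx(0.7, abs=1e-12)

    def test_recovers_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        r = pcoa(d)
        rec = np.linalg.norm(r.coordinates[:, None] - r.coordinates[None, :],
                             axis=-1)
        assert np.allclose(rec, d, atol=1e-8)

    def test_matches_scikit_bio(self):
        import skbio
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d), method="eigh")
        k = ours.coordinates.shape[1]
        ref = theirs.samples.values[:, :k]
        for axis in range(k):
            a, b = ours.coordinates[:, axis], ref[:, axis]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_asymmetric_input_errors(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_axis_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        r1, r2 = pcoa(d), pcoa(d.copy())
        assert np.allclose(r1.coordinates, r2.coordinates)
        for axis in range(r1.coordinates.shape[1]):
            i = np.argmax(np.abs(r1.coordinates[:, axis]))
            assert r1.coordinates[i, axis] > 0


class TestStiPositivity:
    P = AbundanceProfile("s", {"Chlamydia trachomatis": 0.0010,
                               "Ureaplasma parvum": 0.000999,
                               "other": 0.998001})

    def test_threshold_boundary_inclusive(self):
        calls = sti_positivity(self.P, ["Chlamydia trachomatis",
                                        "Ureaplasma parvum",
                                        "Neisseria gonorrhoeae"])
        assert calls["Chlamydia trachomatis"] == "positive"   # exactly 0.1%
        assert calls["Ureaplasma parvum"] == "negative"       # just below
        assert calls["Neisseria gonorrhoeae"] == "negative"   # absent

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            sti_positivity(self.P, ["x"], threshold=0.0)


class TestConfusionMetrics:
    def test_worked_example(self):
        """TP=40 FP=10 FN=5 TN=45: verified by hand from the definitions:
        accuracy .85, Pe = (50·45 + 50·55)/100² = .5, kappa = .35/.5 = .7."""
        rep = confusion_metrics(ConfusionMatrix(tp=40, fp=10, tn=45, fn=5))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.kappa == pytest.approx(0.7)
        assert rep.sensitivity == pytest.approx(8 / 9)
        assert rep.precision == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))
        assert rep.recall == rep.sensitivity

    def test_degenerate_all_positive(self):
        with pytest.warns(UserWarning):
            rep = confusion_metrics(ConfusionMatrix(tp=10, fp=0, tn=0, fn=0))
        assert rep.sensitivity == 1.0 and rep.precision == 1.0
        assert rep.accuracy == 1.0
        assert math.isnan(rep.kappa)  # Pe = 1

    def test_perfect_balanced_classifier(self):
        rep = confusion_metrics(ConfusionMatrix(tp=50, fp=0, tn=50, fn=0))
        assert rep.kappa == pytest.approx(1.0)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_kappa_matches_sklearn_on_random_matrices(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fp + tn + fn == 0:
                continue
            y_true = [1] * (tp + fn) + [0] * (fp + tn)
            y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            expected = cohen_kappa_score(y_true, y_pred)
            with pytest.warns() if _expect_warn(tp, fp, tn, fn) else _nullcontext():
                got = confusion_metrics(ConfusionMatrix(tp, fp, tn, fn)).kappa
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked > 950

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50))
    def test_f1_is_harmonic_mean_when_defined(self, tp, fp, tn, fn):
        rep = confusion_metrics(ConfusionMatrix(tp, fp, tn, fn))
        hm = 2 / (1 / rep.precision + 1 / rep.recall)
        assert rep.f1 == pytest.approx(hm)

    def test_confusion_from_calls(self):
        seq = {"s1": "positive", "s2": "positive", "s3": "negative",
               "s4": "negative", "s5": "positive"}
        ref = {"s1": "positive", "s2": "negative", "s3": "negative",
               "s4": "positive"}  # s5 has no reference: ignored
        cm = confusion_from_calls(seq, ref)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 1, 1)


def _expect_warn(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
    return (tp == 0 or tp + fn == 0 or tn + fp == 0 or tp + fp == 0
            or abs(1 - pe) < 1e-15)


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False
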