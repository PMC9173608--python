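import numpy as np
import pandas as pd
import pytest

from reefscore.modeling import (
    CvPlan,
    RegressorConfig,
    correlation_filter,
    fit_feature_model,
    make_cv_plan,
    project_pca,
    species_score,
    train_image_regressor,
)


def _frame(arrs: dict) -> pd.DataFrame:
    return pd.DataFrame(arrs)


class TestCorrelationFilter:
    def test_uncorrelated_all_retained(self):
        rng = np.random.default_rng(0)
        X = _frame({c: rng.standard_normal(200) for c in "abcd"})
        y = rng.standard_normal(200)
        assert correlation_filter(X, y) == ["a", "b", "c", "d"]

    def test_duplicated_column_one_survives(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(100)
        X = _frame({"a": a, "a_copy": a, "b": rng.standard_normal(100)})
        y = a + rng.standard_normal(100)
        kept = correlation_filter(X, y)
        assert "b" in kept
        assert len([c for c in kept if c in ("a", "a_copy")]) == 1

    def test_planted_trio_keeps_most_response_correlated(self):
        # A and B correlated at ~0.9; y built from A so A must survive
        rng = np.random.default_rng(2)
        a = rng.standard_normal(2000)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(2000)
        c = rng.standard_normal(2000)
        y = a + 0.1 * rng.standard_normal(2000)
        kept = correlation_filter(_frame({"A": a, "B": b, "C": c}), y)
        assert kept == ["A", "C"]

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = _frame({"a": rng.standard_normal(50), "k": np.full(50, 3.0)})
        with pytest.warns(UserWarning, match="constant"):
            kept = correlation_filter(X, rng.standard_normal(50))
        assert kept == ["a"]

    def test_transitive_closure_groups_chains(self):
        # a-b and b-c each >= 0.7 but a-c < 0.7: still one group
        rng = np.random.default_rng(4)
        a = rng.standard_normal(5000)
        b = 0.8 * a + 0.6 * rng.standard_normal(5000)
        c = 0.8 * b / np.std(b) + 0.6 * rng.standard_normal(5000)
        X = _frame({"a": a, "b": b, "c": c})
        assert abs(np.corrcoef(a, c)[0, 1]) < 0.7
        y = a
        assert correlation_filter(X, y) == ["a"]


class TestFitFeatureModel:
    def test_noise_term_eliminated_signal_recovered(self):
        # simulation study: x2 is pure noise and must vanish; x1's
        # coefficient must sit inside its own 95% CI around truth
        hits_ci, x2_dropped = 0, 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            x1 = rng.standard_normal(500)
            x2 = rng.standard_normal(500)
            y = 2.0 * x1 + rng.standard_normal(500)
            fm = fit_feature_model(_frame({"x1": x1, "x2": x2}), y)
            if "x2" not in fm.terms:
                x2_dropped += 1
            if "x1" in fm.terms:
                # scaled coefficient: truth is 2 * sd(x1)
                truth = 2.0 * x1.std()
                lo = fm.coefficients["x1"] - 1.96 * fm.std_errors["x1"]
                hi = fm.coefficients["x1"] + 1.96 * fm.std_errors["x1"]
                if lo <= truth <= hi:
                    hits_ci += 1
        assert x2_dropped >= 0.9 * n_rep
        assert hits_ci >= 0.95 * n_rep * 0.9

    def test_all_active_terms_empty_trace(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.standard_normal(300), rng.standard_normal(300)
        y = 3 * x1 - 2 * x2 + 0.1 * rng.standard_normal(300)
        fm = fit_feature_model(_frame({"x1": x1, "x2": x2}), y)
        assert fm.elimination_trace == []
        assert set(fm.terms) == {"x1", "x2"}

    def test_final_terms_all_significant(self):
        rng = np.random.default_rng(6)
        X = _frame({c: rng.standard_normal(300) for c in "abcdef"})
        y = X["a"].to_numpy() + rng.standard_normal(300)
        fm = fit_feature_model(X, y, alpha=0.05)
        assert (fm.p_values <= 0.05).all()

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(100)
        X = _frame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="collinear|constant"):
            fit_feature_model(X, rng.standard_normal(100))

    def test_needs_enough_rows(self):
        X = _frame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            fit_feature_model(X, [0.0, 1.0])


class TestProjectPca:
    def test_two_feature_toy_matches_eigendecomposition(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(400)
        b = 0.5 * a + rng.standard_normal(400)
        X = _frame({"a": a, "b": b})
        y = a + b + 0.05 * rng.standard_normal(400)
        fm = fit_feature_model(X, y)
        pca = project_pca(X, fm)
        # oracle: eigendecomposition of the 2x2 correlation matrix
        Z = (X - X.mean()) / X.std(ddof=0)
        evals = np.linalg.eigvalsh(np.corrcoef(Z.T))[::-1]
        assert np.allclose(pca.variance_fractions, evals / evals.sum(), atol=1e-6)
        cov = np.cov(pca.scores.T)
        assert abs(cov[0, 1]) < 1e-8
        assert pca.variance_fractions.sum() == pytest.approx(1.0)


class TestCvPlan:
    def _species_map(self, n_species=20, imgs_per=3):
        return {
            f"sp{s}_img{i}": f"sp{s}" for s in range(n_species) for i in range(imgs_per)
        }

    def test_species_integrity(self):
        m = self._species_map()
        plan = make_cv_plan(m, k=5, seed=0)
        for sp in set(m.values()):
            folds = {plan.fold_of(img) for img, s in m.items() if s == sp}
            assert len(folds) == 1

    def test_fold_sizes_within_one_species(self):
        m = self._species_map(23)
        plan = make_cv_plan(m, k=5, seed=1)
        sizes = [len({m[i] for i in plan.images_in_fold(f)}) for f in range(1, 6)]
        assert max(sizes) - min(sizes) <= 1

    def test_reproducible(self):
        m = self._species_map()
        assert make_cv_plan(m, seed=3).image_fold == make_cv_plan(m, seed=3).image_fold

    def test_no_leakage_any_fold(self):
        m = self._species_map(17)
        plan = make_cv_plan(m, k=5, seed=4)
        for f in range(1, 6):
            val = {m[i] for i in plan.images_in_fold(f)}
            train = {m[i] for i, ff in plan.image_fold.items() if ff != f}
            assert not val & train

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            make_cv_plan({"i1": "sp1", "i2": "sp2"}, k=5)


def _toy_images(n_species=15, imgs_per=2, canvas=60, seed=0):
    from reefscore.synth.images import FishSpec, generate_fish_image

    rng = np.random.default_rng(seed)
    images, species_map = {}, {}
    for s in range(n_species):
        hue = rng.random(3)
        for i in range(imgs_per):
            img_id = f"sp{s}_i{i}"
            color = tuple(np.clip(hue + rng.normal(0, 0.05, 3), 0.05, 0.95))
            images[img_id] = generate_fish_image(
                FishSpec(body_aspect=float(rng.uniform(1, 2.5)), n_stripes=0,
                         palette=(color,), canvas_px=canvas)
            )
            species_map[img_id] = f"sp{s}"
    return images, species_map


class TestImageRegressor:
    CFG = RegressorConfig(side=32, epochs=60, seed=0, n_augment=0, augment=False)

    def test_constant_targets_flat_predictions(self):
        images, smap = _toy_images()
        targets = {i: 1500.0 for i in images}
        plan = make_cv_plan(smap, k=5, seed=0)
        res = train_image_regressor(images, targets, plan, self.CFG, smap)
        assert res.mean_r2 == pytest.approx(0.0, abs=1e-6)
        preds = res.model.predict(list(images.values())[:4])
        assert np.allclose(preds, 1500.0, atol=20.0)

    def test_mean_color_targets_recovered(self):
        images, smap = _toy_images(n_species=20, imgs_per=3, seed=1)
        targets = {
            i: 1000.0 + 800.0 * im.masked_pixels()[:, 0].mean() for i, im in images.items()
        }
        plan = make_cv_plan(smap, k=5, seed=1)
        res = train_image_regressor(images, targets, plan, self.CFG, smap)
        assert res.mean_r2 >= 0.5

    def test_zero_rotation_range_identical_stream(self):
        from reefscore.modeling import ImageRegressor

        images, _ = _toy_images(n_species=6, imgs_per=1, seed=2)
        imgs = list(images.values())
        cfg_off = RegressorConfig(side=32, augment=False, seed=0)
        cfg_zero = RegressorConfig(side=32, augment=True, n_augment=1,
                                   rotation_range=(0.0, 0.0), seed=0)
        f_off = ImageRegressor(cfg_off).training_stream(imgs, np.random.default_rng(0))
        f_zero = ImageRegressor(cfg_zero).training_stream(imgs, np.random.default_rng(0))
        # zero-degree augmentation duplicates the unaugmented stream
        assert np.array_equal(np.tile(f_off, (2, 1)), f_zero)

    def test_augmentation_changes_stream(self):
        from reefscore.modeling import ImageRegressor

        images, _ = _toy_images(n_species=6, imgs_per=1, seed=3)
        imgs = list(images.values())
        cfg = RegressorConfig(side=32, augment=True, n_augment=1,
                              rotation_range=(-5.0, 5.0), seed=0)
        F = ImageRegressor(cfg).training_stream(imgs, np.random.default_rng(1))
        n = len(imgs)
        assert not np.allclose(F[:n], F[n:])


class TestSpeciesScore:
    def test_single_image_unchanged(self):
        scores = {"i1": 1600.0}
        smap = {"i1": "spA"}
        assert species_score(scores, smap, "max")["spA"] == 1600.0
        assert species_score(scores, smap, "mean")["spA"] == 1600.0

    def test_direct_arithmetic(self):
        scores = {"a": 1200.0, "b": 1500.0, "c": 1400.0}
        smap = {k: "sp" for k in scores}
        assert species_score(scores, smap, "max")["sp"] == 1500.0
        assert species_score(scores, smap, "mean")["sp"] == pytest.approx(1366.6667, abs=0.01)

    def test_max_dominates_mean(self):
        rng = np.random.default_rng(9)
        scores = {f"i{k}": float(v) for k, v in enumerate(rng.uniform(1000, 2000, 60))}
        smap = {f"i{k}": f"sp{k % 12}" for k in range(60)}
        mx = species_score(scores, smap, "max")
        mn = species_score(scores, smap, "mean")
        assert (mx >= mn).all()

    def test_unmapped_image_listed(self):
        with pytest.raises(ValueError, match="i2"):
            species_score({"i1": 1.0, "i2": 2.0}, {"i1": "sp"}, "max")

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            species_score({"i1": 1.0}, {"i1": "sp"}, "median")
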