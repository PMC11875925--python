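"""Image-quality metrics, tumor ROIs, detection task and ROC analysis."""

import itertools

import numpy as np
import pytest
from scipy import stats

from usct.evaltask import (ObserverConfig, build_observer, fit_roc_auc,
                           metric_nrmse, metric_psnr, metric_report, metric_ssim,
                           sample_patches, train_observer, tumor_roi_masks)
from usct.evaltask import test_mannwhitney as mannwhitney_p
from usct.phantom import TUMOR, LabelMap


class TestNRMSE:
    def test_trivial_cases(self):
        t = np.array([[1.5, 1.6], [1.5, 1.5]])
        assert metric_nrmse(t, t, 1.5) == 0.0
        assert metric_nrmse(np.full_like(t, 1.5), t, 1.5) == pytest.approx(1.0)

    def test_hand_worked_two_by_two(self):
        t = np.array([[1.5, 1.6], [1.5, 1.5]])
        pred = t + 0.01
        assert metric_nrmse(pred, t, 1.5) == pytest.approx(0.2)

    def test_all_water_target_rejected(self):
        t = np.full((2, 2), 1.5)
        with pytest.raises(ValueError, match="water"):
            metric_nrmse(t, t, 1.5)


class TestPSNRSSIM:
    def test_psnr_closed_form(self):
        t = np.full((32, 32), 1.45)
        pred = t + 0.02  # scaled error 0.1 -> MSE 0.01 -> 20 dB
        assert metric_psnr(pred, t) == pytest.approx(20.0)
        assert metric_psnr(t, t) == np.inf

    def test_ssim_identity_and_contrast_ordering(self):
        rng = np.random.default_rng(0)
        t = 1.5 + 0.05 * rng.standard_normal((64, 64))
        assert metric_ssim(t, t) == pytest.approx(1.0)
        neg = 3.0 - t  # contrast-inverted about 1.5
        assert metric_ssim(neg, t) < metric_ssim(t, t)

    def test_report_summary(self):
        t = [np.full((16, 16), 1.45), np.full((16, 16), 1.55)]
        p = [x + 0.02 for x in t]
        df = metric_report(p, t, 1.5)
        assert len(df) == 2
        assert df.attrs["summary"].loc["mean", "psnr"] == pytest.approx(20.0)


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        a = np.arange(10.0)
        assert mannwhitney_p(a, a) > 0.9

    def test_matches_exhaustive_permutation(self):
        """n=3+3 separated samples: p equals the exact two-sided permutation
        value of the rank-sum statistic."""
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        p = mannwhitney_p(a, b)
        pooled = a + b
        obs = sum(1 for x in a for y in b if x > y)  # observed U of sample a
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            aa = [pooled[i] for i in combo]
            bb = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in aa for y in bb if x > y)
            total += 1
            if min(u, 9 - u) <= min(obs, 9 - obs):
                count += 1
        assert p == pytest.approx(count / total)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        assert mannwhitney_p(a, b) == pytest.approx(
            mannwhitney_p(np.exp(a), np.exp(b)))


class TestTumorROI:
    def _labels(self, shape=(64, 64)):
        lab = np.zeros(shape, np.int16)
        lab[10:54, 10:54] = 1  # breast
        return lab

    def test_no_tumors(self):
        lm = LabelMap(self._labels(), 1.0)
        rois, normal = tumor_roi_masks(lm)
        assert rois == []
        assert np.array_equal(normal, lm.labels > 0)

    def test_single_tumor_roi_side_length(self):
        lab = self._labels()
        lab[20:30, 24:30] = TUMOR  # 10 rows × 6 cols
        rois, normal = tumor_roi_masks(LabelMap(lab, 1.0))
        assert len(rois) == 1
        roi = rois[0]
        assert roi.side == 10 + 8
        assert roi.mask.sum() == 18 * 18
        assert not roi.clipped
        assert not np.any(normal & roi.mask)

    def test_two_distant_tumors_disjoint(self):
        lab = self._labels()
        lab[14:18, 14:18] = TUMOR
        lab[44:48, 44:48] = TUMOR
        rois, _ = tumor_roi_masks(LabelMap(lab, 1.0))
        assert len(rois) == 2
        assert not np.any(rois[0].mask & rois[1].mask)

    def test_edge_clipped_roi_flagged(self):
        lab = np.zeros((32, 32), np.int16)
        lab[1:5, 1:5] = TUMOR
        rois, _ = tumor_roi_masks(LabelMap(lab, 1.0))
        assert rois[0].clipped


class TestPatches:
    def _image_labels(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((128, 128))
        lab = np.zeros((128, 128), np.int16)
        lab[20:124, 20:124] = 1
        lab[60:66, 70:76] = TUMOR
        return img, lab

    def test_label_correct_by_construction(self):
        img, lab = self._image_labels()
        patches = sample_patches(img, lab, n_sp=10, n_sa=10, seed=3, patch_size=48)
        for p in patches:
            i0, j0 = p.corner
            has = np.any(lab[i0:i0 + 48, j0:j0 + 48] == TUMOR)
            assert has == bool(p.label)

    def test_seed_reproducibility(self):
        img, lab = self._image_labels()
        a = sample_patches(img, lab, 5, 5, seed=7, patch_size=48)
        b = sample_patches(img, lab, 5, 5, seed=7, patch_size=48)
        assert [p.corner for p in a] == [p.corner for p in b]

    def test_tumor_free_image_yields_only_sa(self):
        img, lab = self._image_labels()
        lab[lab == TUMOR] = 1
        patches = sample_patches(img, lab, 0, 4, seed=1, patch_size=48)
        assert all(p.label == 0 for p in patches)
        with pytest.raises(ValueError, match="signal-present"):
            sample_patches(img, lab, 1, 0, seed=1, patch_size=48)

    def test_no_sa_location_raises(self):
        img = np.zeros((48, 48))
        lab = np.full((48, 48), TUMOR, np.int16)
        with pytest.raises(ValueError, match="signal-absent"):
            sample_patches(img, lab, 0, 1, seed=0, patch_size=48)


def _disk_task_data(n_img=12, size=64, seed=0, contrast=0.2):
    """Trivially separable detection task: bright disks on smooth noise."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n_img):
        img = 1.5 + 0.005 * rng.standard_normal((size, size))
        lab = np.ones((size, size), np.int16)
        if i % 2 == 0:
            ci, cj = rng.integers(12, size - 12, 2)
            yy, xx = np.indices((size, size))
            disk = (yy - ci) ** 2 + (xx - cj) ** 2 <= 25
            img[disk] += contrast
            lab[disk] = TUMOR
        images.append(img)
        labels.append(lab)
    return images, labels


class TestObserver:
    def test_untrained_observer_is_at_chance_on_invisible_signal(self):
        """With zero-contrast 'signals' the SP and SA patches are statistically
        identical, so a random-weight observer scores at chance AUC."""
        images, labels = _disk_task_data(n_img=60, contrast=0.0)
        cfg = ObserverConfig(channels=8, patch_size=32, seed=0)
        net, n_params = build_observer(cfg)
        assert n_params > 0
        patches = []
        for i in range(60):
            kind_sp = bool(np.any(labels[i] == TUMOR))
            patches.extend(sample_patches(images[i], labels[i], int(kind_sp),
                                          int(not kind_sp), seed=i, patch_size=32))
        scores = net.predict([p.patch for p in patches])
        truth = [p.label for p in patches]
        assert np.all((scores > 0) & (scores < 1))
        auc = fit_roc_auc(scores, truth).auc
        assert abs(auc - 0.5) < 3 * np.sqrt(1.0 / 30)  # binomial-scale scatter

    def test_trained_observer_separates_easy_task(self):
        """High-contrast disk vs no disk: a briefly trained observer reaches
        AUC > 0.95."""
        images, labels = _disk_task_data(n_img=16, seed=1)
        cfg = ObserverConfig(channels=8, patch_size=32, seed=1)
        net = train_observer(images, labels, train_ids=range(12), val_ids=range(12, 16),
                             cfg=cfg, epochs=80, batch=16, batches_per_epoch=2,
                             lr_max=3e-3, seed=2)
        test_imgs, test_labs = _disk_task_data(n_img=20, seed=99)
        scores, truth = [], []
        for i in range(20):
            kind_sp = np.any(test_labs[i] == TUMOR)
            p = sample_patches(test_imgs[i], test_labs[i], int(kind_sp),
                               int(not kind_sp), seed=i, patch_size=32)[0]
            scores.append(net.predict([p.patch])[0])
            truth.append(p.label)
        assert fit_roc_auc(scores, truth).auc > 0.95

    def test_single_class_training_rejected(self):
        images, labels = _disk_task_data()
        labels = [np.where(l == TUMOR, 1, l) for l in labels]
        with pytest.raises(ValueError, match="single-class"):
            train_observer(images, labels, range(8), range(8, 12),
                           cfg=ObserverConfig(channels=4, patch_size=32))


class TestROC:
    def test_perfect_separation(self):
        r = fit_roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)

    def test_binormal_closed_form(self):
        """N(0,1) vs N(1,1) scores: AUC → Φ(1/√2) ≈ 0.7602 at n = 10⁵."""
        rng = np.random.default_rng(5)
        s0 = rng.normal(0, 1, 50000)
        s1 = rng.normal(1, 1, 50000)
        scores = np.concatenate([s0, s1])
        truth = np.concatenate([np.zeros(50000), np.ones(50000)])
        r = fit_roc_auc(scores, truth, binormal=True)
        expected = stats.norm.cdf(1 / np.sqrt(2))
        assert r.auc == pytest.approx(expected, abs=0.01)
        assert r.binormal["auc"] == pytest.approx(expected, abs=0.01)
        assert 0 < r.auc_se < 0.01

    def test_rank_invariance(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=200)
        truth = rng.integers(0, 2, 200)
        a = fit_roc_auc(scores, truth).auc
        b = fit_roc_auc(np.tanh(scores) * 7 + 3, truth).auc
        assert a == pytest.approx(b)

    def test_auc_equals_normalized_mannwhitney_u(self):
        """Empirical AUC ≡ U/(n1·n0) computed independently by the rank test."""
        rng = np.random.default_rng(7)
        s0 = rng.normal(0, 1, 60)
        s1 = rng.normal(0.5, 1.2, 40)
        scores = np.concatenate([s0, s1])
        truth = np.concatenate([np.zeros(60, int), np.ones(40, int)])
        auc = fit_roc_auc(scores, truth).auc
        u = stats.mannwhitneyu(s1, s0, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (60 * 40), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_roc_auc([0.1, 0.5], [1, 1])
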