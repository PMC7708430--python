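"""Evaluation metrics against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from panseg.metrics import (
    SSIMParams,
    dice,
    evaluate_cohort,
    mann_whitney_u,
    spearman,
    ssim,
)


class TestDice:
    def test_identity_and_disjoint(self, rng):
        x = rng.random((10, 10)) > 0.5
        assert dice(x, x) == 1.0
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[1, 1] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_closed_form(self):
        x = np.array([[1, 1, 0, 0]], bool)
        y = np.array([[0, 1, 1, 0]], bool)
        assert dice(x, y) == 0.5  # 2*1/(2+2)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z) == 1.0

    def test_symmetry_bounds_and_oracle(self, rng):
        for _ in range(200):
            x = rng.random((8, 8)) > rng.random()
            y = rng.random((8, 8)) > rng.random()
            d = dice(x, y)
            # brute-force loop oracle
            inter = sum(
                1 for i in range(8) for j in range(8) if x[i, j] and y[i, j]
            )
            sx = int(x.sum())
            sy = int(y.sum())
            expected = 1.0 if sx + sy == 0 else 2 * inter / (sx + sy)
            assert d == pytest.approx(expected, abs=1e-9)
            assert d == dice(y, x)
            assert 0.0 <= d <= 1.0


class TestSSIM:
    def test_identity_is_exactly_one(self, rng):
        for _ in range(10):
            x = rng.integers(0, 256, (32, 32)).astype(float)
            assert ssim(x, x) == 1.0

    def test_constant_images_closed_form(self):
        # for two constant images the windowed SSIM reduces to
        # (2ab + C1) / (a^2 + b^2 + C1) in every window
        a, b = 40.0, 90.0
        x = np.full((16, 16), a)
        y = np.full((16, 16), b)
        L = b - a  # joint max - min
        c1 = (0.01 * L) ** 2
        expected = (2 * a * b + c1) / (a * a + b * b + c1)
        assert ssim(x, y) == pytest.approx(expected, rel=1e-12)

    def test_symmetry(self, rng):
        x = rng.random((20, 20)) * 255
        y = rng.random((20, 20)) * 255
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_bounds_on_random_pairs(self, rng):
        vals = [
            ssim(rng.random((12, 12)) * 255, rng.random((12, 12)) * 255)
            for _ in range(100)
        ]
        assert min(vals) >= -1.0 and max(vals) <= 1.0

    def test_pre_blur_changes_value_smoothly(self, rng):
        x = (rng.random((24, 24)) > 0.5).astype(float)
        y = (rng.random((24, 24)) > 0.5).astype(float)
        v0 = ssim(x, y)
        v1 = ssim(x, y, SSIMParams(pre_blur_sigma=1.0))
        assert -1.0 <= v1 <= 1.0 and v1 != v0

    def test_window_validation(self):
        with pytest.raises(ValueError):
            SSIMParams(window=4)
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.zeros((4, 4)))  # smaller than window


class TestSpearman:
    def test_monotone_extremes(self):
        inc = [(i, i * 2 + 1) for i in range(6)]
        dec = [(i, -3 * i) for i in range(6)]
        assert spearman(inc) == 1.0
        assert spearman(dec) == -1.0

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(100):
            x = rng.random(6)
            y = rng.random(6)
            rho = spearman(zip(x, y))
            # midrank + Pearson brute force
            def midrank(v):
                order = np.argsort(v)
                ranks = np.empty(len(v))
                i = 0
                sv = v[order]
                while i < len(v):
                    j = i
                    while j + 1 < len(v) and sv[j + 1] == sv[i]:
                        j += 1
                    ranks[order[i : j + 1]] = (i + j) / 2 + 1
                    i = j + 1
                return ranks

            rx, ry = midrank(x), midrank(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(expected, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        base = spearman(zip(x, y))
        assert spearman(zip(np.exp(x), y)) == pytest.approx(base, abs=1e-12)
        assert spearman(zip(x, y**3 + 5)) == pytest.approx(base, abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError):
            spearman([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])


class TestMannWhitneyU:
    def test_identical_groups_half_u(self):
        a = [1.0, 2.0, 3.0]
        u, _ = mann_whitney_u(a, a)
        assert u == len(a) * len(a) / 2

    def test_complete_separation(self):
        u, p = mann_whitney_u([10, 11, 12, 13], [1, 2, 3, 4])
        assert u == 16
        assert p == pytest.approx(2 / 70, abs=1e-12)  # most extreme of C(8,4)

    def test_exact_p_matches_enumeration(self, rng):
        def ucount(x, y):
            return float(
                (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
            )

        for _ in range(100):
            a = rng.normal(size=4)
            b = rng.normal(size=4)
            u, p = mann_whitney_u(a, b)
            pooled = np.concatenate([a, b])
            us = []
            for idx in itertools.combinations(range(8), 4):
                ia = list(idx)
                ib = [i for i in range(8) if i not in idx]
                us.append(ucount(pooled[ia], pooled[ib]))
            us = np.array(us)
            u_obs = ucount(a, b)
            p_oracle = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
            assert u == u_obs
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_shift_invariance_and_u_complement(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=9)
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(a + 10, b + 10)
        assert u1 == u2 and p1 == pytest.approx(p2, abs=1e-12)
        ub, _ = mann_whitney_u(b, a)
        assert u1 + ub == len(a) * len(b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestEvaluateCohort:
    @staticmethod
    def _frames(n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            amy = rng.uniform(0.2, 0.6)
            pank = rng.uniform(0.1, 0.3)
            rows.append(
                {"sample_id": i, "amy": amy, "pank": pank, "other": 1 - amy - pank}
            )
        return pd.DataFrame(rows)

    def test_identical_predictions_perfect(self):
        f = self._frames()
        res = evaluate_cohort(f, f.copy())
        assert all(v == 1.0 for v in res["spearman"].values())

    def test_permuted_references_degrade(self):
        f = self._frames()
        shuffled = f.copy()
        shuffled[["amy", "pank", "other"]] = (
            f[["amy", "pank", "other"]].iloc[::-1].to_numpy()
        )
        res = evaluate_cohort(f, shuffled)
        assert any(v < 1.0 for v in res["spearman"].values())

    def test_ssim_on_identical_masks(self, rng):
        f = self._frames(3)
        masks = {
            i: {"amy": rng.random((16, 16)) > 0.5} for i in range(3)
        }
        res = evaluate_cohort(f, f.copy(), pred_masks=masks, ref_masks=masks)
        assert (res["ssim"]["ssim"] == 1.0).all()

    def test_sample_mismatch_rejected(self):
        f = self._frames(4)
        with pytest.raises(ValueError):
            evaluate_cohort(f, f.iloc[:3])
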