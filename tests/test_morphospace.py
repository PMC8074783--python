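"""Morphospace: pruning, Ward groups, association stats, DA, Wilks' Lambda,
Stewart-Love redundancy, lasso selection, morphoclouds and aberrance."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from haplomorph.io import MorphoTable, UnitAssignment
from haplomorph.morphospace import (
    classify_aberrance,
    fit_da,
    glm_r2,
    goodman_kruskal_lambda,
    kruskal_wallis_axes,
    morphoclouds,
    prune_collinear,
    select_variables_lasso,
    stewart_love,
    ward_morphotypes,
)


def table(values, kinds=None, accessions=None, names=None) -> MorphoTable:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"v{i}" for i in range(p)]
    return MorphoTable(
        accessions=accessions or [f"a{i}" for i in range(n)],
        variables=names,
        kinds={v: (kinds or {}).get(v, "continuous") for v in names},
        values=values,
    )


def units_for(groups: list[str], accessions=None) -> UnitAssignment:
    accessions = accessions or [f"a{i}" for i in range(len(groups))]
    return UnitAssignment(unit_of=dict(zip(accessions, groups)))


class TestPruneCollinear:
    def test_duplicate_column_removed(self, rng):
        X = rng.normal(size=(40, 3))
        X = np.column_stack([X, X[:, 0]])
        out = prune_collinear(table(X), 0.8)
        assert len(out.variables) == 3

    def test_weak_correlation_untouched(self, rng):
        base = rng.normal(size=(200, 1))
        X = 0.5 * base + rng.normal(size=(200, 4))
        out = prune_collinear(table(X), 0.8)
        assert len(out.variables) == 4

    def test_no_pair_exceeds_bound_posthoc(self, rng):
        base = rng.normal(size=(60, 2))
        X = np.column_stack(
            [base[:, 0], base[:, 0] + 0.1 * rng.normal(size=60),
             base[:, 1], base[:, 1] + 0.1 * rng.normal(size=60),
             rng.normal(size=60)]
        )
        out = prune_collinear(table(X), 0.8)
        R = np.corrcoef(out.values, rowvar=False)
        np.fill_diagonal(R, 0)
        assert np.abs(R).max() <= 0.8

    def test_matches_exhaustive_minimum_on_small_instance(self, rng):
        """Greedy removal keeps as many variables as the exhaustive optimum
        on a 5-variable instance with one hub variable."""
        z = rng.normal(size=(120, 1))
        X = np.column_stack(
            [z, z + 0.2 * rng.normal(size=(120, 1)),
             z + 0.2 * rng.normal(size=(120, 1)),
             rng.normal(size=(120, 2))]
        )
        mt = table(X)
        out = prune_collinear(mt, 0.8)
        # exhaustive: largest subset with all |r| <= 0.8
        R = np.abs(np.corrcoef(X, rowvar=False))
        best = 0
        for r in range(5, 0, -1):
            for keep in combinations(range(5), r):
                if all(R[i, j] <= 0.8 for i, j in combinations(keep, 2)):
                    best = max(best, r)
            if best:
                break
        assert len(out.variables) == best

    def test_r_max_validated(self, rng):
        with pytest.raises(ValueError):
            prune_collinear(table(rng.normal(size=(10, 3))), 1.5)


class TestWard:
    def test_two_blobs_recovered(self, rng):
        X = np.vstack([rng.normal(-5, 1, (10, 3)), rng.normal(5, 1, (10, 3))])
        groups = ward_morphotypes(table(X), 2)
        vals = list(groups.values())
        assert vals[:10] == [vals[0]] * 10 and vals[10:] == [vals[10]] * 10
        assert set(vals) == {1, 2}

    def test_k_one(self, rng):
        groups = ward_morphotypes(table(rng.normal(size=(8, 3))), 1)
        assert set(groups.values()) == {1}

    def test_k_exceeds_n(self, rng):
        with pytest.raises(ValueError):
            ward_morphotypes(table(rng.normal(size=(4, 2))), 5)

    def test_ranking_stable_under_row_order(self, rng):
        X = np.vstack([rng.normal(-5, 1, (8, 3)), rng.normal(5, 1, (8, 3))])
        mt = table(X)
        perm = rng.permutation(16)
        mt2 = table(X[perm], accessions=[f"a{i}" for i in perm])
        g1 = ward_morphotypes(mt, 2)
        g2 = ward_morphotypes(mt2, 2)
        assert g1 == g2


class TestGoodmanKruskal:
    def test_identical_partitions(self):
        g = {f"a{i}": i % 3 for i in range(12)}
        assert goodman_kruskal_lambda(g, g) == pytest.approx(1.0)

    def test_contingency_example(self):
        # [[10, 0], [2, 8]] -> (18 - 12) / (20 - 12) = 0.75
        g1, g2 = {}, {}
        idx = 0
        for r, c, n in [(0, 0, 10), (1, 0, 2), (1, 1, 8)]:
            for _ in range(n):
                g1[f"a{idx}"] = r
                g2[f"a{idx}"] = c
                idx += 1
        assert goodman_kruskal_lambda(g1, g2) == pytest.approx(0.75)

    def test_uninformative_predictor(self):
        g1 = {f"a{i}": 0 for i in range(10)}
        g2 = {f"a{i}": i % 2 for i in range(10)}
        assert goodman_kruskal_lambda(g1, g2) == pytest.approx(0.0)

    def test_single_predicted_category_warns(self):
        g1 = {f"a{i}": i % 2 for i in range(10)}
        g2 = {f"a{i}": 0 for i in range(10)}
        with pytest.warns(UserWarning, match="single category"):
            assert goodman_kruskal_lambda(g1, g2) == 0.0


class TestKruskalWallis:
    def test_disjoint_supports(self):
        scores = np.concatenate([np.arange(20), np.arange(100, 120)]).reshape(-1, 1)
        labels = [f"a{i}" for i in range(40)]
        groups = {lab: int(i >= 20) for i, lab in enumerate(labels)}
        p = kruskal_wallis_axes(scores.astype(float), labels, groups)
        assert p[0] < 1e-4

    def test_two_groups_matches_rank_sum(self, rng):
        x = rng.normal(size=20)
        labels = [f"a{i}" for i in range(20)]
        groups = {lab: int(i >= 10) for i, lab in enumerate(labels)}
        p_kw = kruskal_wallis_axes(x.reshape(-1, 1), labels, groups)[0]
        z = stats.ranksums(x[:10], x[10:]).statistic
        assert p_kw == pytest.approx(stats.chi2.sf(z**2, df=1), rel=1e-6)

    def test_all_tied_scores(self):
        scores = np.ones((10, 1))
        labels = [f"a{i}" for i in range(10)]
        groups = {lab: i % 2 for i, lab in enumerate(labels)}
        with pytest.warns(UserWarning, match="tied"):
            assert kruskal_wallis_axes(scores, labels, groups) == [1.0]

    def test_null_calibration(self, rng):
        """Under identical group distributions the test rejects at its
        nominal rate."""
        rej = 0
        n_sims = 400
        for _ in range(n_sims):
            x = rng.normal(size=30).reshape(-1, 1)
            labels = [f"a{i}" for i in range(30)]
            groups = {lab: i % 3 for i, lab in enumerate(labels)}
            rej += kruskal_wallis_axes(x, labels, groups)[0] < 0.05
        assert 0.02 <= rej / n_sims <= 0.08


class TestDA:
    def _instance(self, rng, shift=4.0, n_units=4, n_per=8, p=3):
        means = rng.normal(0, shift, size=(n_units, p))
        X = np.vstack([rng.normal(means[u], 1.0, size=(n_per, p)) for u in range(n_units)])
        groups = [f"u{u}" for u in range(n_units) for _ in range(n_per)]
        return table(X), units_for(groups, [f"a{i}" for i in range(len(groups))])

    def test_wilks_determinant_ratio(self, rng):
        """Lambda from the eigenvalues equals det(W) / det(W + B)."""
        mt, ua = self._instance(rng)
        da = fit_da(mt, ua)
        X = mt.values
        grand = X.mean(0)
        W = np.zeros((3, 3))
        B = np.zeros((3, 3))
        for u in set(ua.unit_of.values()):
            idx = [i for i, a in enumerate(mt.accessions) if ua.unit_of[a] == u]
            mu = X[idx].mean(0)
            W += (X[idx] - mu).T @ (X[idx] - mu)
            B += len(idx) * np.outer(mu - grand, mu - grand)
        assert da.wilks_lambda == pytest.approx(
            np.linalg.det(W) / np.linalg.det(W + B), rel=1e-8
        )

    def test_equal_means_lambda_near_one(self, rng):
        mt, ua = self._instance(rng, shift=0.0)
        da = fit_da(mt, ua)
        assert da.wilks_lambda > 0.5
        assert da.wilks_p > 0.001

    def test_one_dimensional_separation(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 0] += np.repeat([0.0, 10.0, 20.0], 10)
        ua = units_for([f"u{i // 10}" for i in range(30)])
        da = fit_da(table(X), ua)
        assert da.dispersion_share[0] > 95.0

    def test_dispersion_shares_sum_to_100(self, rng):
        mt, ua = self._instance(rng)
        da = fit_da(mt, ua)
        assert da.dispersion_share.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(da.dispersion_share) <= 1e-9)

    def test_separation_decreases_lambda(self, rng):
        """Moving unit means apart strictly increases 1 - Lambda."""
        lams = []
        for shift in (0.0, 2.0, 6.0):
            r = np.random.default_rng(3)
            X = r.normal(size=(30, 2))
            X[:, 0] += np.repeat([0.0, shift, 2 * shift], 10)
            ua = units_for([f"u{i // 10}" for i in range(30)])
            lams.append(fit_da(table(X), ua).wilks_lambda)
        assert lams[0] > lams[1] > lams[2]

    def test_matches_r_mass_lda_scores(self, rng):
        """Cross-check axis-1 scores against R's MASS::lda on a fixed
        instance (correlation 1 up to scale and sign)."""
        import shutil
        import subprocess
        import tempfile
        from pathlib import Path

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        mt, ua = self._instance(rng, n_units=3, n_per=6)
        da = fit_da(mt, ua)
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "d.csv"
            import pandas as pd

            df = mt.to_frame()
            df["unit"] = [ua.unit_of[a] for a in mt.accessions]
            df.to_csv(csv, index=False)
            script = Path(td) / "lda.R"
            script.write_text(
                'd <- read.csv(commandArgs(TRUE)[1]);'
                'f <- MASS::lda(unit ~ v0 + v1 + v2, data=d);'
                'cat(predict(f)$x[,1], sep="\\n")\n'
            )
            out = subprocess.run(
                ["Rscript", "--vanilla", str(script), str(csv)],
                capture_output=True, text=True, check=True,
            )
        ref = np.array([float(x) for x in out.stdout.split()])
        r = np.corrcoef(ref, da.scores[:, 0])[0, 1]
        assert abs(r) > 0.9999


class TestStewartLove:
    def test_self_prediction_is_one(self, rng):
        X = rng.normal(size=(50, 4))
        assert stewart_love(X, X) == pytest.approx(1.0)

    def test_independent_sets_near_zero(self, rng):
        X = rng.normal(size=(500, 3))
        Y = rng.normal(size=(500, 3))
        assert stewart_love(X, Y) <= 0.05

    def test_equals_mean_regression_r2(self, rng):
        """With all canonical pairs retained the redundancy equals the mean
        R^2 of regressing each Y variable on X."""
        X = rng.normal(size=(40, 3))
        Y = 0.6 * X @ rng.normal(size=(3, 3)) + rng.normal(size=(40, 3))
        sl = stewart_love(X, Y)
        Zy = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        design = np.column_stack([X, np.ones(40)])
        r2s = []
        for j in range(3):
            beta, *_ = np.linalg.lstsq(design, Zy[:, j], rcond=None)
            resid = Zy[:, j] - design @ beta
            r2s.append(1 - resid.var() / Zy[:, j].var())
        assert sl == pytest.approx(np.mean(r2s), abs=1e-8)

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(60, 3))
        Y = X @ rng.normal(size=(3, 3)) + 0.5 * rng.normal(size=(60, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert stewart_love(X @ Q, Y) == pytest.approx(stewart_love(X, Y), abs=1e-8)
        assert 0.0 <= stewart_love(X, Y) <= 1.0


class TestGlmR2:
    def test_exact_linear_ranks(self):
        # unit means exactly linear in rank, zero within-unit variance
        X = np.repeat([1.0, 2.0, 3.0, 4.0], 5).reshape(-1, 1)
        X = np.column_stack([X, np.zeros_like(X) + [[0.0]]])
        ua = units_for([f"u{i // 5}" for i in range(20)])
        mt = table(np.column_stack([X[:, 0], X[:, 0] * 0.5]))
        da = fit_da(mt, ua, ridge=1e-6)
        assert glm_r2(da, ua) == pytest.approx(1.0, abs=1e-6)

    def test_null_near_zero(self, rng):
        X = rng.normal(size=(500, 2))
        ua = units_for([f"u{i % 5}" for i in range(500)])
        da = fit_da(table(X), ua)
        assert glm_r2(da, ua) <= 0.05

    def test_matches_ols_oracle(self, rng):
        X = rng.normal(size=(25, 2))
        X[:, 0] += np.repeat([0, 1, 2, 3, 4], 5) * 2.0
        ua = units_for([f"u{i // 5}" for i in range(25)])
        da = fit_da(table(X), ua)
        y = da.scores[:, 0]
        means = {u: y[[i for i in range(25) if ua.unit_of[f"a{i}"] == u]].mean()
                 for u in sorted(set(ua.unit_of.values()))}
        ranked = sorted(means, key=lambda u: (means[u], u))
        rank = {u: r + 1 for r, u in enumerate(ranked)}
        x = np.array([rank[ua.unit_of[f"a{i}"]] for i in range(25)], dtype=float)
        A = np.column_stack([x, np.ones(25)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        r2 = 1 - resid.var() / y.var()
        assert glm_r2(da, ua) == pytest.approx(r2, abs=1e-10)


class TestLasso:
    def test_unpenalized_limit_keeps_all(self, rng):
        X = rng.normal(size=(40, 6))
        X[:, 0] += np.repeat([0, 3], 20)
        ua = units_for(["u0"] * 20 + ["u1"] * 20, [f"a{i}" for i in range(40)])
        mt = table(X)
        subsets = select_variables_lasso(mt, ua, penalty_grid=np.array([1e-6]))
        assert subsets[0].n_variables == 6

    def test_support_recovery(self, rng):
        """Two informative variables among 20 noise ones are selected with
        few false positives."""
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            n_per, k = 20, 3
            shift = np.array([0.0, 3.0, 6.0])
            X = r.normal(size=(n_per * k, 22))
            for u in range(k):
                X[u * n_per:(u + 1) * n_per, 0] += shift[u]
                X[u * n_per:(u + 1) * n_per, 1] -= shift[u]
            ua = units_for(
                [f"u{i // n_per}" for i in range(n_per * k)],
                [f"a{i}" for i in range(n_per * k)],
            )
            subsets = select_variables_lasso(table(X), ua, seed=s)
            chosen = min(subsets, key=lambda sub: sub.n_variables)
            sel = set(chosen.variables)
            noise = sel - {"v0", "v1"}
            hits += {"v0", "v1"} <= sel and len(noise) <= 2
        assert hits >= 9

    def test_small_units_excluded(self, rng):
        X = rng.normal(size=(11, 3))
        groups = ["u0"] * 5 + ["u1"] * 5 + ["u2"]
        ua = units_for(groups, [f"a{i}" for i in range(11)])
        with pytest.warns(UserWarning, match="excluded"):
            select_variables_lasso(table(X), ua, penalty_grid=np.array([0.1, 1.0]))


class TestMorphoclouds:
    def _da(self, rng, centers):
        X = np.vstack([rng.normal(c, 1.0, size=(10, 3)) for c in centers])
        n = len(X)
        ua = units_for([f"u{i // 10}" for i in range(n)])
        return fit_da(table(X), ua), ua

    def test_two_blobs_two_clouds(self, rng):
        da, _ = self._da(rng, [[-8, 0, 0], [8, 0, 0]])
        res = morphoclouds(da)
        assert len(set(res.cloud_of.values())) == 2

    def test_order_invariant(self, rng):
        X = np.vstack([rng.normal(-6, 1, (8, 3)), rng.normal(6, 1, (8, 3))])
        ua = units_for([f"u{i // 8}" for i in range(16)])
        da1 = fit_da(table(X), ua)
        res1 = morphoclouds(da1)
        perm = rng.permutation(16)
        mt2 = table(X[perm], accessions=[f"a{i}" for i in perm])
        da2 = fit_da(mt2, ua)
        res2 = morphoclouds(da2)
        for a in res1.cloud_of:
            peers1 = {b for b in res1.cloud_of if res1.cloud_of[b] == res1.cloud_of[a]}
            peers2 = {b for b in res2.cloud_of if res2.cloud_of[b] == res2.cloud_of[a]}
            assert peers1 == peers2

    def test_low_structure_warns(self, rng):
        X = rng.normal(size=(30, 3))
        ua = units_for([f"u{i % 3}" for i in range(30)])
        da = fit_da(table(X), ua)
        with pytest.warns(UserWarning, match="weak cloud structure"):
            morphoclouds(da)


class TestAberrance:
    def _setup(self, rng, n_per=10, planted=0):
        """Two genetic clusters with distinct morphologies; ``planted``
        accessions of cluster 1 carry cluster-2 morphology."""
        X = np.vstack(
            [rng.normal(-6, 1, (n_per, 3)), rng.normal(6, 1, (n_per, 3))]
        )
        for i in range(planted):
            X[i] = rng.normal(6, 1, 3)
        accs = [f"a{i}" for i in range(2 * n_per)]
        ua = UnitAssignment(
            unit_of={a: ("1.0" if i < n_per else "2.0") for i, a in enumerate(accs)},
            cluster_of={"1.0": "1", "2.0": "2"},
        )
        mt = table(X, accessions=accs)
        da = fit_da(mt, ua)
        clouds = morphoclouds(da)
        return classify_aberrance(clouds, ua, da), accs

    def test_concordant_world_all_consistent(self, rng):
        res, _ = self._setup(rng)
        assert res.proportions["consistent"] == pytest.approx(100.0)
        assert sum(res.proportions.values()) == pytest.approx(100.0)

    def test_planted_aberrants_found(self, rng):
        res, accs = self._setup(rng, planted=2)
        flagged = {a for a, lab in res.label_of.items() if lab != "consistent"}
        assert {"a0", "a1"} <= flagged

    def test_half_half_cloud_is_mixed(self, rng):
        X = rng.normal(0, 1, (20, 3))
        accs = [f"a{i}" for i in range(20)]
        ua = UnitAssignment(
            unit_of={a: ("1.0" if i % 2 == 0 else "2.0") for i, a in enumerate(accs)},
            cluster_of={"1.0": "1", "2.0": "2"},
        )
        mt = table(X, accessions=accs)
        da = fit_da(mt, ua)
        from haplomorph.morphospace import MorphocloudResult

        clouds = MorphocloudResult(cloud_of={a: 1 for a in accs})
        res = classify_aberrance(clouds, ua, da)
        assert all(lab == "mixed" for lab in res.label_of.values())

    def test_lookalike_override(self, rng):
        res, accs = self._setup(rng, planted=1)
        X_labels = [a for a, lab in res.label_of.items() if lab in ("aberrant", "borderline")]
        if X_labels:
            # re-run with the override list
            rng2 = np.random.default_rng(12345)
            res2, _ = self.__class__._setup_with_override(self, rng2, X_labels)
            for a in X_labels:
                assert res2.label_of[a] == "lookalike"

    def _setup_with_override(self, rng, lookalikes):
        X = np.vstack([rng.normal(-6, 1, (10, 3)), rng.normal(6, 1, (10, 3))])
        X[0] = rng.normal(6, 1, 3)
        accs = [f"a{i}" for i in range(20)]
        ua = UnitAssignment(
            unit_of={a: ("1.0" if i < 10 else "2.0") for i, a in enumerate(accs)},
            cluster_of={"1.0": "1", "2.0": "2"},
        )
        mt = table(X, accessions=accs)
        da = fit_da(mt, ua)
        clouds = morphoclouds(da)
        return classify_aberrance(clouds, ua, da, lookalikes=lookalikes), accs
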