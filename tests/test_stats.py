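import numpy as np
import pandas as pd
import pytest

import dmnmeg as dm
from dmnmeg.stats import compare_conditions, difference_map


def brute_force_bh(p, alpha=0.05):
    """Independent step-up oracle: q_i = min_{j>=rank(i)} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q < alpha


class TestKruskalWallis:
    def test_worked_rank_example(self):
        h, _ = dm.kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2, abs=1e-9)

    def test_fully_tied_data(self):
        assert dm.kruskal_wallis([3, 3], [3, 3, 3]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dm.kruskal_wallis([1, 2], [])

    def test_chi_square_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(size=15)
        h, p = dm.kruskal_wallis(a, b)
        pool = np.concatenate([a, b])
        prng = np.random.default_rng(7)
        exceed = 0
        for _ in range(10_000):
            perm = prng.permutation(pool)
            hp, _ = dm.kruskal_wallis(perm[:15], perm[15:])
            exceed += hp >= h - 1e-12
        assert abs(p - exceed / 10_000) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=8), rng.normal(size=10), rng.normal(size=6)]
        h0, p0 = dm.kruskal_wallis(*groups)
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            h1, p1 = dm.kruskal_wallis(*[f(g) for g in groups])
            assert h1 == pytest.approx(h0, abs=1e-9)


class TestFdrBh:
    def test_all_rejected_when_under_step_line(self):
        q, reject = dm.fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert reject.all()

    def test_single_p_identity(self):
        q, reject = dm.fdr_bh([0.04])
        assert q[0] == pytest.approx(0.04) and reject[0]

    def test_large_ps_not_rejected(self):
        _, reject = dm.fdr_bh([0.5, 0.6, 0.9])
        assert not reject.any()

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            q, reject = dm.fdr_bh(p)
            q_ref, reject_ref = brute_force_bh(p)
            np.testing.assert_allclose(q, q_ref, atol=1e-12)
            assert np.array_equal(reject, reject_ref)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dm.fdr_bh([0.5, 1.2])


class TestChiSquare:
    def test_cohort_sex_table(self):
        chi2, p = dm.chi_square_2x2([[20, 16], [13, 10]])
        assert round(chi2, 3) == 0.005
        assert p == pytest.approx(0.942, abs=5e-4)

    def test_proportional_table_is_zero(self):
        chi2, _ = dm.chi_square_2x2([[20, 10], [20, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table(self):
        chi2, _ = dm.chi_square_2x2([[5, 0], [0, 5]])
        assert chi2 == pytest.approx(10.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            dm.chi_square_2x2([[0, 0], [3, 4]])


def make_measure_table(rng, n_per_condition=12, shift=None, rois=("r1", "r2"), bands=("delta", "alpha")):
    rows = []
    for cond in ("ictal", "interictal", "control"):
        for k in range(n_per_condition):
            for roi in rois:
                for band in bands:
                    mu = 0.0
                    if shift and (cond, roi, band) in shift:
                        mu = shift[(cond, roi, band)]
                    rows.append(
                        dict(subject=f"{cond}{k}", condition=cond, roi=roi, band=band,
                             measure="rel_power", value=mu + rng.normal())
                    )
    return pd.DataFrame(rows)


class TestCompareConditions:
    def test_planted_shift_detected_and_null_cells_not(self):
        rng = np.random.default_rng(4)
        table = make_measure_table(rng, shift={("ictal", "r1", "delta"): 3.0})
        res = compare_conditions(table)
        hit = res[(res["roi"] == "r1") & (res["band"] == "delta")
                  & (res["contrast"] == "ictal_vs_interictal")]
        assert hit["significant"].item()
        null = res[(res["roi"] == "r2") & (res["band"] == "alpha")
                   & (res["contrast"] == "interictal_vs_control")]
        assert not null["significant"].item()

    def test_q_at_least_p(self):
        rng = np.random.default_rng(5)
        res = compare_conditions(make_measure_table(rng))
        ok = res["p"].notna()
        assert (res.loc[ok, "q"] >= res.loc[ok, "p"] - 1e-12).all()
        assert ((res.loc[ok, "q"] < 0.05) == res.loc[ok, "significant"]).all()

    def test_difference_map_of_condition_with_itself_is_zero(self):
        rng = np.random.default_rng(6)
        table = make_measure_table(rng)
        dmap = difference_map(table, "rel_power", "control", "control")
        assert (dmap.to_numpy() == 0).all()

    def test_missing_cell_excluded_with_nan(self):
        rng = np.random.default_rng(7)
        table = make_measure_table(rng)
        table = table[~((table["condition"] == "control") & (table["roi"] == "r1")
                        & (table["band"] == "delta"))]
        res = compare_conditions(table)
        cell = res[(res["roi"] == "r1") & (res["band"] == "delta")
                   & (res["contrast"] == "interictal_vs_control")]
        assert np.isnan(cell["p"].item()) and not cell["significant"].item()

    def test_per_subject_averaging_reduces_observations(self):
        rng = np.random.default_rng(8)
        table = make_measure_table(rng)
        # duplicate every segment row so each subject has two segments
        doubled = pd.concat([table, table.assign(value=table["value"] + 0.1)])
        res_seg = compare_conditions(doubled, per_subject=False)
        res_subj = compare_conditions(doubled, per_subject=True)
        assert res_seg.shape == res_subj.shape
        assert not np.allclose(
            res_seg["H"].to_numpy(dtype=float), res_subj["H"].to_numpy(dtype=float), equal_nan=True
        )


class TestPlantedDeltaEffectPower:
    def test_interictal_delta_elevation_recovered(self):
        """The generator's interictal regime raises delta power over the
        control regime; with 20 subjects per arm the interictal-vs-control
        delta contrast should survive FDR in most ROIs, in >= 80% of
        seeded replicates."""
        import dmnmeg as dm
        from conftest import as_segment

        successes = 0
        n_rep = 20
        for rep in range(n_rep):
            rows = []
            for arm, regime in (("control", "control"), ("interictal", "interictal")):
                for k in range(20):
                    seed = 100_000 + rep * 1000 + (0 if arm == "control" else 500) + k
                    rec = dm.simulate_roi_timeseries(
                        dm.SyntheticConfig(seed=seed), regime, seed=seed, duration=30.0
                    )
                    bp = dm.band_power(dm.relative_psd(dm.welch_psd(as_segment(rec, arm))))
                    for roi in bp.index:
                        for band in bp.columns:
                            rows.append(dict(subject=f"{arm}{k}", condition=arm, roi=roi,
                                             band=band, measure="rel_power",
                                             value=float(bp.loc[roi, band])))
            res = compare_conditions(pd.DataFrame(rows), contrasts=(("interictal", "control"),))
            delta = res[(res["band"] == "delta") & (res["contrast"] == "interictal_vs_control")]
            n_sig_up = int((delta["significant"] & (delta["median_diff"] > 0)).sum())
            if n_sig_up >= 10:
                successes += 1
        assert successes / n_rep >= 0.8
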