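"""Experiment orchestration and the three statistical analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from virtualsdm.experiment import (
    ExperimentConfig,
    ancova,
    range_size_regression,
    run_experiment,
    species_residual_summary,
    tss_stability,
)
from virtualsdm.virtual_species import AutomatonParams

rng = np.random.default_rng(2024)


def synthetic_table(
    n_species=8,
    predictor_sets=("RAW", "PCA4", "PCA6"),
    algorithms=("ES", "MAHAL", "LQ_BG", "KERNEL_BG"),
    replicates=5,
    alg_effect=0.0,
    env_effect=0.0,
    noise=0.05,
    species_shift=None,
    seed=0,
):
    """Balanced factorial table with controllable ground-truth effects."""
    r = np.random.default_rng(seed)
    prev = {f"sp{i:02d}": r.uniform(0.01, 0.2) for i in range(n_species)}
    tol = {f"sp{i:02d}": ("narrow" if i % 2 else "wide") for i in range(n_species)}
    rows = []
    for sid, ps, alg, rep in itertools.product(
        prev, predictor_sets, algorithms, range(1, replicates + 1)
    ):
        base = 0.6
        base += alg_effect * algorithms.index(alg)
        base += env_effect * predictor_sets.index(ps)
        if species_shift:
            base += species_shift.get(sid, 0.0)
        tss = base + r.normal(0, noise)
        real = int(prev[sid] * 10000)
        rows.append(
            {
                "species_id": sid,
                "tolerance_class": tol[sid],
                "prevalence": prev[sid],
                "predictor_set": ps,
                "algorithm": alg,
                "replicate": rep,
                "rule": "balance",
                "TSS": tss,
                "OP": 1 - tss,
                "UP": (1 - tss) / 2,
                "real_range": real,
                "predicted_range": real,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def smoke_result():
    cfg = ExperimentConfig(
        nrows=90,
        ncols=90,
        n_centroids=2,
        tolerance_fractions=(0.6,),
        predictor_sets=("RAW",),
        algorithms=("ES",),
        n_occurrences=20,
        n_replicates=2,
        n_background=2000,
        automaton=AutomatonParams(n_iterations=50),
        master_seed=3,
    )
    return cfg, run_experiment(cfg)


class TestRunExperiment:
    def test_smoke_design_row_count(self, smoke_result):
        cfg, res = smoke_result
        n_species = res.manifest["n_species"]
        assert n_species >= 1
        per_rule = n_species * 1 * 1 * 2
        assert len(res.table) == per_rule * 2  # balance + lpt
        assert set(res.table.rule) == {"balance", "lpt"}

    def test_prevalence_constant_within_species(self, smoke_result):
        _, res = smoke_result
        assert (res.table.groupby("species_id").prevalence.nunique() == 1).all()

    def test_determinism(self, smoke_result):
        cfg, res = smoke_result
        res2 = run_experiment(cfg)
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_manifest_records_conditions(self, smoke_result):
        _, res = smoke_result
        assert res.manifest["master_seed"] == 3
        assert res.manifest["failures"] == []
        assert "config" in res.manifest


class TestAncova:
    def test_response_equal_to_prevalence_gives_full_covariate_share(self):
        tb = synthetic_table(noise=0.0)
        tb["TSS"] = tb["prevalence"]
        res = ancova(tb, "TSS")
        assert res.prevalence_partial_eta_sq > 0.999
        ss = res.table.set_index("term").sum_sq
        # every factor's share of variation is numerically nil
        assert (ss.drop("Prevalence") < 1e-12 * ss["Prevalence"]).all()

    def test_known_algorithm_effect_detected(self):
        tb = synthetic_table(alg_effect=0.1, env_effect=0.0, noise=0.02, seed=5)
        res = ancova(tb, "TSS")
        f = dict(zip(res.table.term, res.table["F"]))
        assert f["ALG"] > 100
        assert f["ALG"] > 20 * f["ENV"]

    def test_null_env_effect_f_near_one(self):
        fs = []
        for seed in range(8):
            tb = synthetic_table(alg_effect=0.0, env_effect=0.0, noise=0.05, seed=seed)
            res = ancova(tb, "TSS")
            fs.append(dict(zip(res.table.term, res.table["F"]))["ENV"])
        assert np.mean(fs) < 5  # F under the null has mean ~1

    def test_balanced_two_level_anova_matches_hand_computation(self):
        # 2 predictor sets x 2 algorithms x 2 tolerances, 4 reps, no covariate
        r = np.random.default_rng(9)
        rows = []
        means = {}
        for i, ps in enumerate(("RAW", "PCA4")):
            for j, alg in enumerate(("ES", "MAHAL")):
                for k, tol in enumerate(("narrow", "wide")):
                    mu = 0.5 + 0.2 * i - 0.1 * j + 0.05 * k + 0.03 * i * j
                    means[(ps, alg, tol)] = mu
                    for rep in range(4):
                        rows.append(
                            dict(
                                species_id=f"s{k}",
                                tolerance_class=tol,
                                prevalence=0.1,
                                predictor_set=ps,
                                algorithm=alg,
                                replicate=rep,
                                rule="balance",
                                TSS=mu + r.normal(0, 0.01),
                            )
                        )
        tb = pd.DataFrame(rows)
        res = ancova(tb, "TSS", include_covariate=False)
        # textbook balanced-ANOVA main-effect sum of squares
        y = tb.TSS.to_numpy()
        grand = y.mean()
        ss_env_hand = sum(
            len(g) * (g.TSS.mean() - grand) ** 2 for _, g in tb.groupby("predictor_set")
        )
        ss_env = float(res.table.set_index("term").loc["ENV", "sum_sq"])
        assert ss_env == pytest.approx(ss_env_hand, rel=1e-6)
        assert res.error_df == 32 - 8  # N - cells (full interactions, no covariate)

    def test_missing_response_rows_dropped_and_counted(self):
        tb = synthetic_table()
        tb.loc[:10, "TSS"] = np.nan
        res = ancova(tb, "TSS")
        assert res.n_dropped == 11


class TestTssStability:
    def test_constant_replicates_zero_variance(self):
        tb = synthetic_table(noise=0.0)
        st = tss_stability(tb)
        assert np.allclose(st.mean_tss_variance, 0.0)
        assert np.allclose(st.ci_high - st.ci_low, 0.0)

    def test_two_replicate_arithmetic(self):
        tb = synthetic_table(n_species=1, predictor_sets=("RAW",), algorithms=("ES",),
                             replicates=2, noise=0.0)
        tb.loc[:, "TSS"] = [0.5, 0.7]
        st = tss_stability(tb)
        assert st.mean_tss_variance.iloc[0] == pytest.approx(0.02)

    def test_heteroscedastic_algorithm_detected(self):
        r = np.random.default_rng(3)
        tb = synthetic_table(replicates=40, noise=0.0, n_species=12)
        sigma = {"ES": 0.1, "MAHAL": 0.05, "LQ_BG": 0.05, "KERNEL_BG": 0.05}
        tb["TSS"] += [r.normal(0, sigma[a]) for a in tb.algorithm]
        st = tss_stability(tb).groupby("algorithm").mean_tss_variance.mean()
        assert st["ES"] / st["MAHAL"] == pytest.approx(4.0, rel=0.35)

    def test_single_replicate_rejected(self):
        tb = synthetic_table(replicates=1)
        with pytest.raises(ValueError):
            tss_stability(tb)


class TestRangeSizeRegression:
    def test_identity_relation(self):
        tb = synthetic_table()
        rr = range_size_regression(tb)
        assert np.allclose(rr.a, 0.0, atol=1e-8)
        assert np.allclose(rr.b, 1.0, atol=1e-10)
        assert np.allclose(rr.r_squared, 1.0)

    def test_affine_relation_recovered_exactly(self):
        tb = synthetic_table()
        tb["predicted_range"] = 2 * tb["real_range"] + 100
        rr = range_size_regression(tb)
        assert np.allclose(rr.a, 100.0, atol=1e-8)
        assert np.allclose(rr.b, 2.0, atol=1e-10)

    def test_noisy_parameters_within_two_se(self):
        r = np.random.default_rng(11)
        tb = synthetic_table(n_species=40, predictor_sets=("RAW",), algorithms=("ES",))
        a_true, b_true = 50.0, 1.3
        tb["predicted_range"] = a_true + b_true * tb["real_range"] + r.normal(0, 30, len(tb))
        from scipy import stats as sps

        row = range_size_regression(tb).iloc[0]
        x = tb.real_range.to_numpy(float)
        res = sps.linregress(x, tb.predicted_range.to_numpy(float))
        assert abs(row.b - b_true) < 2 * res.stderr
        assert abs(row.a - a_true) < 2 * res.intercept_stderr

    def test_degenerate_group_skipped_with_reason(self):
        tb = synthetic_table(n_species=4)
        tb["real_range"] = 100
        rr = range_size_regression(tb)
        assert rr.note.str.contains("degenerate").all()
        assert rr.r_squared.isna().all()


class TestSpeciesResiduals:
    def test_overall_residual_mean_zero(self):
        tb = synthetic_table(noise=0.05, seed=2)
        res = ancova(tb, "TSS")
        out = species_residual_summary(tb, res)
        pooled = (out.residual_mean * out.n).sum() / out.n.sum()
        assert abs(pooled) < 1e-10

    def test_shifted_species_shows_in_residuals(self):
        tb = synthetic_table(species_shift={"sp03": -0.2}, noise=0.02, seed=4)
        res = ancova(tb, "TSS")
        out = species_residual_summary(tb, res)
        shifted = out[out.species_id == "sp03"].residual_mean.mean()
        others = out[out.species_id != "sp03"].residual_mean.mean()
        assert shifted < -0.1
        assert shifted < others - 0.1


class TestFiveAlgorithmDesign:
    def test_factorial_error_degrees_of_freedom(self):
        # 30 species x 3 predictor sets x 5 algorithms x 10 replicates
        # = 4,500 rows; the ANCOVA consumes 1 + 1 + 2 + 4 + 1 + 8 + 2 + 4
        # + 8 = 31 model df, leaving 4,469 for error.
        tb = synthetic_table(
            n_species=30,
            predictor_sets=("RAW", "PCA4", "PCA6"),
            algorithms=("ES", "MAHAL", "MXLQ", "MXDEF", "SVM"),
            replicates=10,
            noise=0.05,
        )
        assert len(tb) == 4500
        res = ancova(tb, "TSS")
        assert res.error_df == 4469
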