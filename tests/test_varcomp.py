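import numpy as np
import pandas as pd
import pytest
from oracles import random_pedigree

from spatialqg.lattice import LatticeIndex
from spatialqg.pedigree import additive_relationship
from spatialqg.varcomp import (
    FittedModel,
    FixedTerm,
    ModelError,
    ModelSpec,
    RandomTerm,
    VarianceEstimate,
    aic,
    animal_term,
    build_design,
    compare_aic,
    lrt,
    partition,
    reml_fit,
    sac_term,
    smatrix_term,
    wald_fixed,
)


def one_way_data(seed, n_groups=20, n_reps=10, vb=1.0, vw=1.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_reps)
    u = rng.normal(0, np.sqrt(vb), n_groups)
    y = 2.0 + u[g] + rng.normal(0, np.sqrt(vw), len(g))
    return pd.DataFrame({"y": y, "grp": [f"g{i:02d}" for i in g]})


def anova_reml(df, n_reps):
    y = df["y"].to_numpy()
    groups = df.groupby("grp")["y"]
    msb = n_reps * groups.mean().var(ddof=1)
    msw = groups.var(ddof=1).mean()
    return max((msb - msw) / n_reps, 0.0), msw


ONE_WAY_SPEC = ModelSpec(response="y", random=[RandomTerm("grp", "grp", "V_G")])


class TestBuildDesign:
    def test_polynomial_and_factor_coding(self):
        df = pd.DataFrame(
            {
                "y": np.arange(10.0),
                "age": np.arange(10.0) + 1,
                "status": list("abcde") * 2,
            }
        )
        spec = ModelSpec(
            response="y",
            fixed=[FixedTerm("age", degree=2), FixedTerm("status")],
        )
        b = build_design(spec, df)
        i_sq = b.x_names.index("age^2")
        assert np.allclose(b.X[:, i_sq], (np.arange(10.0) + 1) ** 2)
        assert len(b.term_slices["status"]) == 4  # 5 levels, reference coded
        assert b.X.shape[1] == 1 + 2 + 4

    def test_all_missing_covariate_named(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "age": [np.nan, np.nan]})
        with pytest.raises(ModelError, match="'age'"):
            build_design(ModelSpec(response="y", fixed=["age"]), df)

    def test_rank_deficiency_names_aliased_columns(self):
        df = pd.DataFrame(
            {"y": np.arange(6.0), "a": [1.0] * 6, "b": [2.0] * 6}
        )
        with pytest.raises(ModelError, match="rank deficient"):
            build_design(ModelSpec(response="y", fixed=["a", "b"]), df)

    def test_missing_rows_dropped_with_count(self):
        df = pd.DataFrame(
            {"y": [1.0, np.nan, 3.0, 4.0], "grp": ["a", "a", "b", None]}
        )
        b = build_design(ONE_WAY_SPEC, df)
        assert b.n_dropped == 2
        assert len(b.y) == 2


class TestREMLFit:
    @pytest.mark.parametrize("seed", range(4))
    def test_balanced_oneway_matches_anova(self, seed):
        """REML on a balanced one-way design equals the closed-form
        ANOVA estimators."""
        df = one_way_data(seed)
        fit = reml_fit(ONE_WAY_SPEC, df)
        vb, vw = anova_reml(df, 10)
        assert fit.converged
        assert fit.variance_estimates["V_G"].value == pytest.approx(vb, abs=1e-6)
        assert fit.variance_estimates["V_Residual"].value == pytest.approx(
            vw, abs=1e-6
        )

    def test_loglik_matches_independent_dense_evaluation(self):
        """The reported restricted log-likelihood equals a from-scratch
        dense evaluation at the reported parameters, and is a local
        optimum under random perturbation."""
        df = one_way_data(11, n_groups=12, n_reps=5)
        fit = reml_fit(ONE_WAY_SPEC, df)
        g = pd.Categorical(df["grp"]).codes
        Z = np.eye(12)[g]
        X = np.ones((len(df), 1))
        y = df["y"].to_numpy()

        def loglik(vb, vw):
            V = vb * Z @ Z.T + vw * np.eye(len(y))
            Vi = np.linalg.inv(V)
            M = X.T @ Vi @ X
            beta = np.linalg.solve(M, X.T @ Vi @ y)
            r = y - X @ beta
            n, p = X.shape
            return -0.5 * (
                np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(M)[1]
                + r @ Vi @ r
                + (n - p) * np.log(2 * np.pi)
            )

        vb = fit.variance_estimates["V_G"].value
        vw = fit.variance_estimates["V_Residual"].value
        assert loglik(vb, vw) == pytest.approx(fit.restricted_loglik, abs=1e-8)
        rng = np.random.default_rng(0)
        for _ in range(25):
            f1, f2 = 1.0 + rng.uniform(-0.05, 0.05, 2)
            assert loglik(vb * f1, vw * f2) <= fit.restricted_loglik + 1e-8

    def test_pure_residual_data_leaves_va_near_zero(self):
        """With no genetic signal in the data, V_A collapses to (or near)
        its zero bound and mean heritability stays negligible."""
        h2s, bound = [], 0
        for seed in range(12):
            ped = random_pedigree(seed + 100, n=100, n_founders=20)
            A = additive_relationship(ped)
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"y": rng.normal(0, 1, 100), "individual": ped.ids}
            )
            spec = ModelSpec(response="y", random=[animal_term(A)])
            fit = reml_fit(spec, df, compute_se=False)
            est = fit.variance_estimates["V_A"]
            bound += est.bound
            h2s.append(partition(fit).h2[0])
        assert bound >= 4
        assert np.mean(h2s) < 10.0  # percent

    def test_duplicate_identity_terms_warn_and_alias(self):
        df = one_way_data(3, n_groups=10, n_reps=6)
        spec = ModelSpec(
            response="y",
            random=[
                RandomTerm("grp", "grp", "V_G1"),
                RandomTerm("grp2", "grp", "V_G2"),
            ],
        )
        with pytest.warns(UserWarning, match="not separately identifiable"):
            fit = reml_fit(spec, df)
        vb, _ = anova_reml(df, 6)
        total = (
            fit.variance_estimates["V_G1"].value
            + fit.variance_estimates["V_G2"].value
        )
        assert total == pytest.approx(vb, abs=1e-4)

    def test_zero_variance_response_rejected(self):
        df = pd.DataFrame({"y": [1.0] * 8, "grp": list("aabbccdd")})
        with pytest.raises(ModelError):
            reml_fit(ONE_WAY_SPEC, df)

    def test_log_transform_requires_positive_response(self):
        df = pd.DataFrame({"y": [1.0, -2.0, 3.0], "grp": list("abc")})
        spec = ModelSpec(response="y", random=[], log_transform=True)
        with pytest.raises(ModelError, match="positive"):
            reml_fit(spec, df)


def tiny_animal_dataset(seed=5, n=60):
    ped = random_pedigree(seed, n=n, n_founders=12)
    A = additive_relationship(ped)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(n))
    y = 1.0 + 0.6 * L @ rng.normal(size=n) + rng.normal(0, 0.7, n)
    x = rng.uniform(0, 100, n)
    yx = rng.uniform(0, 100, n)
    df = pd.DataFrame(
        {
            "y": y,
            "individual": ped.ids,
            "age": rng.integers(2, 12, n).astype(float),
            "status": rng.choice(list("wxyz"), n),
        }
    )
    from spatialqg.lattice import grid_coordinates
    from spatialqg.matrices import OverlapMatrix

    locs = {i: (float(a), float(b)) for i, a, b in zip(ped.ids, x, yx)}
    lattice = grid_coordinates(locs, origin=(0.0, 0.0), spacing=25.0)
    B = rng.random((n, 3 * n))
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    S = OverlapMatrix(ids=ped.ids, values=np.round(B @ B.T, 10), kind="S")
    return ped, A, S, lattice, df


@pytest.fixture(scope="module")
def fits():
    ped, A, S, lattice, df = tiny_animal_dataset()
    base_spec = ModelSpec(response="y", random=[animal_term(A)])
    base = reml_fit(base_spec, df, n_starts=1, compute_se=False)
    with_s = reml_fit(
        ModelSpec(response="y", random=[animal_term(A), smatrix_term(S)]),
        df, n_starts=1, compute_se=False,
    )
    with_sac = reml_fit(
        ModelSpec(
            response="y",
            random=[animal_term(A), sac_term(lattice, axes=("row", "col"))],
        ),
        df, n_starts=1, compute_se=False,
    )
    return base, with_s, with_sac


class TestInference:
    def test_identical_fits_give_null_lrt(self, fits):
        base, _, _ = fits
        chi2, df_, p = lrt(base, base)
        assert (chi2, df_, p) == (0.0, 0, 1.0)

    def test_smatrix_adds_one_df(self, fits):
        base, with_s, _ = fits
        chi2, df_, p = lrt(base, with_s)
        assert df_ == 1
        assert chi2 >= 0.0

    def test_row_and_column_sac_adds_three_df(self, fits):
        base, _, with_sac = fits
        _, df_, _ = lrt(base, with_sac)
        assert df_ == 3

    def test_mismatched_data_rejected(self, fits):
        base, _, _ = fits
        df2 = one_way_data(0)
        other = reml_fit(ONE_WAY_SPEC, df2, compute_se=False)
        with pytest.raises(ModelError, match="identical data"):
            lrt(base, other)

    def test_refit_reproduces_aic(self, fits):
        base, with_s, _ = fits
        ped, A, S, lattice, df = tiny_animal_dataset()
        again = reml_fit(
            ModelSpec(response="y", random=[animal_term(A)]),
            df, n_starts=1, compute_se=False,
        )
        assert aic(again) == pytest.approx(aic(base), abs=1e-6)
        table = compare_aic({"base": base, "smatrix": with_s})
        assert set(table["model"]) == {"base", "smatrix"}

    def test_aic_incomparable_across_fixed_effects(self, fits):
        base, _, _ = fits
        ped, A, S, lattice, df = tiny_animal_dataset()
        other = reml_fit(
            ModelSpec(response="y", fixed=["age"], random=[animal_term(A)]),
            df, n_starts=1, compute_se=False,
        )
        with pytest.raises(ModelError, match="not comparable"):
            compare_aic({"a": base, "b": other})


class TestWald:
    def test_single_and_joint_terms(self):
        rng = np.random.default_rng(8)
        n = 200
        age = rng.uniform(0, 10, n)
        status = rng.choice(list("pqrs"), n)
        y = 1.0 + 0.5 * age + (status == "q") * 1.5 + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "age": age, "status": status})
        spec = ModelSpec(response="y", fixed=["age", "status"])
        fit = reml_fit(spec, df)
        w = wald_fixed(fit).set_index("term")
        row = fit.fixed_effects.set_index("term").loc["age"]
        assert w.loc["age", "wald_chi2"] == pytest.approx(
            (row["estimate"] / row["se"]) ** 2, rel=1e-6
        )
        assert w.loc["age", "df"] == 1
        assert w.loc["status", "df"] == 3  # 4 levels, reference coded
        assert w.loc["status", "p"] < 0.01


def manual_fit(components: dict, cov=None) -> FittedModel:
    syms = list(components)
    k = len(syms)
    return FittedModel(
        variance_estimates={
            s: VarianceEstimate(v, 0.1, False) for s, v in components.items()
        },
        phi_estimates={},
        fixed_effects=pd.DataFrame(
            {"term": ["(Intercept)"], "estimate": [0.0], "se": [1.0]}
        ),
        fixed_cov=np.eye(1),
        term_slices={},
        restricted_loglik=-10.0,
        n_parameters=k,
        converged=True,
        iterations=1,
        trace=[-10.0],
        n_obs=100,
        param_names=syms,
        param_cov=cov if cov is not None else 0.01 * np.eye(k),
        data_fingerprint="x",
        fixed_fingerprint="x",
    )


class TestPartition:
    def test_quarter_heritability(self):
        part = partition(manual_fit({"V_A": 1.0, "V_Residual": 3.0}))
        assert part.h2[0] == pytest.approx(25.0)
        assert part.sum_v == pytest.approx(4.0)
        assert sum(p for p, _ in part.proportions.values()) == pytest.approx(1.0)

    def test_zero_va_gives_zero_h2(self):
        part = partition(manual_fit({"V_A": 0.0, "V_Residual": 1.0}))
        assert part.h2[0] == 0.0

    def test_credibility_flag_on_sumv_explosion(self):
        part = partition(
            manual_fit({"V_A": 5.0, "V_Residual": 5.0}), baseline_sum_v=1.0
        )
        assert part.credibility_flag
        part2 = partition(
            manual_fit({"V_A": 0.5, "V_Residual": 0.6}), baseline_sum_v=1.0
        )
        assert not part2.credibility_flag

    def test_delta_method_se_matches_parametric_bootstrap(self):
        """Delta-method SE of a variance proportion agrees with a
        1000-replicate parametric bootstrap on the same small design."""
        df = one_way_data(21, n_groups=10, n_reps=6, vb=1.0, vw=1.0)
        fit = reml_fit(ONE_WAY_SPEC, df)
        part = partition(fit)
        delta_se = part.proportions["V_G"][1]
        vb = fit.variance_estimates["V_G"].value
        vw = fit.variance_estimates["V_Residual"].value
        rng = np.random.default_rng(99)
        props = []
        for _ in range(1000):
            sim = pd.DataFrame(
                {
                    "y": np.repeat(rng.normal(0, np.sqrt(vb), 10), 6)
                    + rng.normal(0, np.sqrt(vw), 60),
                    "grp": np.repeat([f"g{i}" for i in range(10)], 6),
                }
            )
            bfit = reml_fit(ONE_WAY_SPEC, sim, n_starts=1, compute_se=False)
            est = bfit.variance_estimates
            tot = est["V_G"].value + est["V_Residual"].value
            props.append(est["V_G"].value / tot)
        boot_se = np.std(props, ddof=1)
        assert delta_se == pytest.approx(boot_se, rel=0.15)
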