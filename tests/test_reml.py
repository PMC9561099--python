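"""REML likelihood paths, oracles, fits, ratios and significance flags."""

import numpy as np
import pandas as pd
import pytest

from flockparam.model_design import ConfigError, ModelSpec, RandomTerm, build_design
from flockparam.pedigree import Pedigree
from flockparam.reml import (
    VarianceComponents,
    fit_bivariate,
    fit_univariate,
    restricted_loglik,
    significance,
)
from flockparam.simulate import simulate_repeatability_records

from conftest import dense_projection_loglik, random_pedigree_triples

REPEATABILITY_SPEC = ModelSpec(
    response="y",
    random_terms=[
        RandomTerm("animal", ("animal",), "pedigree"),
        RandomTerm("pe", ("animal",), "identity"),
    ],
)


def random_instance(rng: np.random.Generator):
    """Small random pedigree + records with up to 3 random terms."""
    triples = random_pedigree_triples(rng, int(rng.integers(8, 16)), p_founder=0.4)
    ped = Pedigree.from_triples(triples)
    rows = []
    for a in ped.ids:
        for r in range(int(rng.integers(1, 4))):
            rows.append(
                dict(
                    animal=a,
                    grp=int(rng.integers(0, 3)),
                    rnd=r,
                    y=float(rng.normal()),
                )
            )
    df = pd.DataFrame(rows)
    spec = ModelSpec(
        response="y",
        fixed_factors=[("grp",)],
        random_terms=[
            RandomTerm("animal", ("animal",), "pedigree"),
            RandomTerm("pe", ("animal",), "identity"),
            RandomTerm("wg", ("animal", "rnd"), "identity"),
        ],
    )
    design = build_design(df, spec, ped)
    comps = VarianceComponents(
        {
            "animal": float(rng.uniform(0.2, 1.0)),
            "pe": float(rng.uniform(0.1, 0.8)),
            "wg": float(rng.uniform(0.1, 0.8)),
        },
        float(rng.uniform(0.3, 1.5)),
    )
    return design, comps, ped


class TestRestrictedLoglik:
    def test_no_random_terms_reduces_to_ols_reml(self):
        rng = np.random.default_rng(0)
        n = 25
        df = pd.DataFrame({"animal": [f"A{i}" for i in range(n)], "y": rng.normal(2, 1, n)})
        ped = Pedigree.from_triples([(f"A{i}", None, None) for i in range(n)])
        design = build_design(df, ModelSpec(response="y"), ped)
        s2 = 0.9
        ll = restricted_loglik(design, VarianceComponents({}, s2), ped)
        # closed form: -(n-1)/2 [log 2pi + log s2] - log(n)/2 - SSE/(2 s2)
        ybar = df.y.mean()
        sse = ((df.y - ybar) ** 2).sum()
        expected = -0.5 * (
            (n - 1) * np.log(2 * np.pi * s2) + np.log(n) + sse / s2
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_identity_kinship_matches_one_way_random_effects(self):
        """With A = I and one record per animal-level term, the MME value
        equals the dense one-way random-effects REML likelihood."""
        rng = np.random.default_rng(1)
        ped = Pedigree.from_triples([(f"A{i}", None, None) for i in range(10)])
        rows = [
            dict(animal=f"A{i}", y=float(rng.normal())) for i in range(10) for _ in range(3)
        ]
        design = build_design(
            pd.DataFrame(rows),
            ModelSpec(
                response="y",
                random_terms=[RandomTerm("animal", ("animal",), "pedigree")],
            ),
            ped,
        )
        comps = VarianceComponents({"animal": 0.7}, 1.3)
        assert restricted_loglik(design, comps, ped) == pytest.approx(
            dense_projection_loglik(design, comps, ped), abs=1e-8
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_mme_equals_dense_projection_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        design, comps, ped = random_instance(rng)
        assert restricted_loglik(design, comps, ped) == pytest.approx(
            dense_projection_loglik(design, comps, ped), abs=1e-8
        )


class TestFitUnivariate:
    def test_balanced_identity_kinship_equals_anova(self):
        """Expected-mean-squares oracle on a balanced one-way layout."""
        rng = np.random.default_rng(5)
        n_a, m = 40, 4
        ped = Pedigree.from_triples([(f"A{i}", None, None) for i in range(n_a)])
        a = rng.normal(0, np.sqrt(0.5), n_a)
        rows = [
            dict(animal=f"A{i}", y=float(5 + a[i] + rng.normal()))
            for i in range(n_a)
            for _ in range(m)
        ]
        df = pd.DataFrame(rows)
        design = build_design(
            df,
            ModelSpec(
                response="y",
                random_terms=[RandomTerm("animal", ("animal",), "pedigree")],
            ),
            ped,
        )
        fit = fit_univariate(design, ped)
        means = df.groupby("animal").y.mean()
        gm = df.y.mean()
        msb = m * ((means - gm) ** 2).sum() / (n_a - 1)
        msw = (
            df.join(means.rename("mu"), on="animal")
            .eval("(y - mu) ** 2")
            .sum()
            / (n_a * (m - 1))
        )
        assert fit.converged
        assert fit.components.residual == pytest.approx(msw, abs=1e-6)
        assert fit.components.terms["animal"] == pytest.approx((msb - msw) / m, abs=1e-6)

    def test_zero_genetic_variance_flagged_at_boundary(self):
        rng = np.random.default_rng(6)
        ped, df = simulate_repeatability_records(
            40, 8, G=1e-12, PE=0.0, E=1.0, seed=rng
        )
        fit = fit_univariate(build_design(df, REPEATABILITY_SPEC, ped), ped)
        assert fit.h2 < 0.05
        assert fit.boundary

    def test_identity_kinship_plus_pe_is_refused(self):
        rng = np.random.default_rng(7)
        ped = Pedigree.from_triples([(f"A{i}", None, None) for i in range(10)])
        rows = [
            dict(animal=f"A{i}", y=float(rng.normal())) for i in range(10) for _ in range(2)
        ]
        design = build_design(pd.DataFrame(rows), REPEATABILITY_SPEC, ped)
        with pytest.raises(ConfigError, match="separable"):
            fit_univariate(design, ped)

    def test_single_record_term_confounded_with_residual_is_refused(self):
        ped = Pedigree.from_triples([(f"A{i}", None, None) for i in range(8)])
        rows = [dict(animal=f"A{i}", y=float(i)) for i in range(8)]
        spec = ModelSpec(
            response="y", random_terms=[RandomTerm("pe", ("animal",), "identity")]
        )
        design = build_design(pd.DataFrame(rows), spec, ped)
        with pytest.raises(ConfigError, match="residual"):
            fit_univariate(design, ped)

    def test_scale_invariance_of_ratios(self):
        """Rescaling y by c multiplies components by c^2, leaves ratios put."""
        ped, df = simulate_repeatability_records(30, 8, seed=8)
        d1 = build_design(df, REPEATABILITY_SPEC, ped)
        df2 = df.assign(y=df.y * 10.0)
        d2 = build_design(df2, REPEATABILITY_SPEC, ped)
        f1 = fit_univariate(d1, ped)
        f2 = fit_univariate(d2, ped)
        assert f2.components.residual == pytest.approx(
            100.0 * f1.components.residual, rel=1e-4
        )
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-5)
        assert f2.repeatability == pytest.approx(f1.repeatability, abs=1e-5)

    def test_table3_style_ratios_from_components(self):
        """sigma2_a=2.32, pe=1.43, e=5.19 gives h2=0.26, repeatability=0.42."""
        comps = VarianceComponents({"animal": 2.32, "pe": 1.43}, 5.19)
        s2p = comps.phenotypic()
        assert 2.32 / s2p == pytest.approx(0.26, abs=0.005)
        assert (2.32 + 1.43) / s2p == pytest.approx(0.42, abs=0.005)

    def test_fit_value_matches_mme_likelihood(self):
        ped, df = simulate_repeatability_records(25, 6, seed=12)
        design = build_design(df, REPEATABILITY_SPEC, ped)
        fit = fit_univariate(design, ped)
        comps = VarianceComponents(
            {k: float(v) for k, v in fit.components.terms.items()},
            float(fit.components.residual),
        )
        assert fit.loglik == pytest.approx(
            restricted_loglik(design, comps, ped), abs=1e-6
        )


class TestFitBivariate:
    def test_duplicated_trait_gives_unit_correlations(self):
        ped, df = simulate_repeatability_records(40, 8, seed=21)
        df = df.assign(y1=df.y, y2=df.y)
        mk = lambda r: ModelSpec(
            response=r,
            random_terms=[
                RandomTerm("animal", ("animal",), "pedigree"),
                RandomTerm("pe", ("animal",), "identity"),
            ],
        )
        d1 = build_design(df, mk("y1"), ped)
        d2 = build_design(df, mk("y2"), ped)
        fit = fit_bivariate(d1, d2, ped)
        assert fit.r_g == pytest.approx(1.0, abs=0.01)
        assert fit.r_p == pytest.approx(1.0, abs=0.01)

    def test_definition_of_genetic_correlation(self):
        # r_g = s_a12 / sqrt(s_a11 s_a22) = 0.5 / sqrt(1*4) = 0.25
        assert 0.5 / np.sqrt(1.0 * 4.0) == 0.25

    def test_trait_without_variance_raises(self):
        ped, df = simulate_repeatability_records(10, 4, seed=22)
        df = df.assign(y2=0.0)
        mk = lambda r: ModelSpec(
            response=r,
            random_terms=[RandomTerm("animal", ("animal",), "pedigree")],
        )
        with pytest.raises(Exception, match="variance"):
            fit_bivariate(
                build_design(df, mk("y"), ped),
                build_design(df, mk("y2"), ped),
                ped,
            )

    def test_disjoint_traits_have_zero_residual_covariance(self):
        rg = 0.5
        G = np.array([[0.25, rg * 0.25], [rg * 0.25, 0.25]])
        ped, df = simulate_repeatability_records(
            60, 10, G=G, PE=np.diag([0.15, 0.15]), E=np.diag([0.6, 0.6]), seed=23
        )
        tail = df.animal.str.slice(-3).astype(int)
        mk = lambda r: ModelSpec(
            response=r,
            random_terms=[
                RandomTerm("animal", ("animal",), "pedigree"),
                RandomTerm("pe", ("animal",), "identity"),
            ],
        )
        d1 = build_design(df[tail < 5], mk("y1"), ped)
        d2 = build_design(df[tail >= 5], mk("y2"), ped)
        fit = fit_bivariate(d1, d2, ped)
        res = np.asarray(fit.components.residual)
        assert res[0, 1] == 0.0
        assert fit.r_e is None
        assert fit.r_g_se > 0

    def test_mean_null_genetic_correlation_near_zero(self):
        """Monte-Carlo null: independent traits give mean r_g about 0."""
        G = np.diag([0.25, 0.25])
        PE = np.diag([0.15, 0.15])
        E = np.diag([0.6, 0.6])
        mk = lambda r: ModelSpec(
            response=r,
            random_terms=[
                RandomTerm("animal", ("animal",), "pedigree"),
                RandomTerm("pe", ("animal",), "identity"),
            ],
        )
        rgs = []
        for s in range(15):
            ped, df = simulate_repeatability_records(
                100, 10, G=G, PE=PE, E=E, seed=3000 + s
            )
            d1 = build_design(df, mk("y1"), ped)
            d2 = build_design(df, mk("y2"), ped)
            rgs.append(fit_bivariate(d1, d2, ped).r_g)
        # per-replicate SD of r_g here is ~0.23, so the 15-replicate mean
        # has Monte-Carlo SE ~0.06
        assert abs(np.mean(rgs)) < 0.15


class TestSignificance:
    @pytest.mark.parametrize(
        "est,se,expected",
        [(0.31, 0.09, True), (0.13, 0.15, False), (0.0, 0.2, False)],
    )
    def test_wald_flags(self, est, se, expected):
        assert significance(est, se) is expected

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            significance(0.1, -0.1)
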