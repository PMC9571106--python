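import numpy as np
import pandas as pd
import pytest
from scipy import stats

from litterlab.massloss import (
    ModelFit, aic_score, build_design, fit_ols, records_to_model_frame,
    sequential_anova, stepwise_select, term_label, two_way_anova,
)


def factor_frame(n_rep=3, seed=0, factors=("species", "litter_type",
                                           "treatment", "forest",
                                           "time_months")):
    """A balanced full-factorial frame over the requested design factors."""
    from litterlab.massloss import FACTOR_LEVELS
    idx = pd.MultiIndex.from_product(
        [FACTOR_LEVELS[f] for f in factors] + [range(n_rep)],
        names=list(factors) + ["rep"])
    return idx.to_frame(index=False)


def test_design_column_counts():
    data = factor_frame()
    X, slices, names = build_design(
        data, ["species", "litter_type", "treatment", "forest", "time_months"])
    assert X.shape[1] == 1 + 2 + 1 + 1 + 2 + 1  # intercept + dummies
    assert names[0] == "Intercept"
    X0, _, _ = build_design(data, [])
    assert X0.shape[1] == 1


def test_design_rejects_duplicates_and_unknown_factors():
    data = factor_frame()
    with pytest.raises(ValueError, match="duplicate"):
        build_design(data, ["species", "species"])
    with pytest.raises(ValueError, match="unknown factor"):
        build_design(data, ["elevation"])


def test_interaction_block_size():
    data = factor_frame()
    X, slices, _ = build_design(data, ["species", "forest",
                                       ("species", "forest")])
    assert slices[("species", "forest")].stop - \
        slices[("species", "forest")].start == 4


def test_fit_ols_exact_orthogonal_and_toy_cases():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(20), rng.normal(size=20)])
    beta = np.array([1.0, 2.0])
    exact = fit_ols(X, X @ beta)
    assert exact.rss == pytest.approx(0.0, abs=1e-18)
    assert exact.r2 == pytest.approx(1.0)
    # response orthogonal to the non-intercept column
    x = np.concatenate([np.ones(10), -np.ones(10)])
    y = np.concatenate([np.ones(5), -np.ones(5), np.ones(5), -np.ones(5)])
    ortho = fit_ols(np.column_stack([np.ones(20), x]), y)
    assert ortho.r2 == pytest.approx(0.0, abs=1e-12)
    # two points, slope and intercept in closed form
    toy = fit_ols(np.array([[1.0, 0.0], [1.0, 1.0]]), np.array([1.0, 3.0]))
    assert toy.coef == pytest.approx([1.0, 2.0])
    with pytest.raises(ValueError, match="singular"):
        fit_ols(np.ones((5, 2)), np.arange(5.0))


def test_aic_convention():
    fit = ModelFit(terms=(), coef=np.zeros(1), column_names=["i"],
                   rss=10.0, tss=20.0, n=10, k=1)
    assert aic_score(fit) == pytest.approx(4.0)
    bigger = ModelFit(terms=(), coef=np.zeros(2), column_names=["i", "x"],
                      rss=10.0, tss=20.0, n=10, k=2)
    assert aic_score(bigger) == pytest.approx(6.0)  # +2 per extra parameter
    perfect = ModelFit(terms=(), coef=np.zeros(1), column_names=["i"],
                       rss=0.0, tss=20.0, n=10, k=1)
    assert aic_score(perfect) == -np.inf


def test_stepwise_retains_strong_main_effects_and_only_weak_extras():
    """True main effects survive selection; anything else AIC keeps is
    negligible (AIC admits weak spurious terms by construction)."""
    rng = np.random.default_rng(12)
    data = factor_frame(n_rep=6)
    y = (5.0 * (data.species == "Qilex")
         + 3.0 * (data.forest == "Phalepensis_forest")
         + 2.0 * (data.time_months == 24)
         + rng.normal(0, 1.0, len(data)))
    data["y"] = y
    fit = stepwise_select(data, response="y")
    labels = {term_label(t) for t in fit.terms}
    assert {"species", "forest", "time_months"} <= labels
    table = sequential_anova(data, "y", list(fit.terms)).set_index("term")
    planted = {"species", "forest", "time_months"}
    for term in labels - planted:
        assert table.loc[term, "pct_ss"] < 1.0
    for term in planted:
        assert table.loc[term, "pct_ss"] > 5.0


def test_stepwise_on_noise_explains_almost_nothing():
    rng = np.random.default_rng(5)
    data = factor_frame(n_rep=6)
    data["y"] = rng.normal(size=len(data))
    fit = stepwise_select(data, response="y")
    assert fit.r2 < 0.1
    # selection descended from the full model and pruned most of it
    from litterlab.massloss import DEFAULT_SCOPE, _fit_terms
    full_fit = _fit_terms(data, "y", list(DEFAULT_SCOPE))
    assert fit.aic < full_fit.aic
    assert fit.k < full_fit.k / 2


def test_stepwise_retains_planted_interaction():
    rng = np.random.default_rng(7)
    data = factor_frame(n_rep=6)
    inter = ((data.species == "Qilex") & (data.forest == "Qilex_forest"))
    data["y"] = 4.0 * inter + rng.normal(0, 1.0, len(data))
    fit = stepwise_select(data, response="y")
    assert ("species", "forest") in fit.terms
    # hierarchy: margins of a retained interaction are retained
    assert ("species",) in fit.terms and ("forest",) in fit.terms


def test_sequential_anova_single_factor_hand_case():
    data = pd.DataFrame({
        "litter_type": ["ND"] * 4 + ["AD"] * 4,
        "y": [0.0] * 4 + [2.0] * 4,
    })
    table = sequential_anova(data, response="y", terms=["litter_type"])
    between = table.loc[table.term == "litter_type"].iloc[0]
    assert between["ss"] == pytest.approx(8.0)  # n/2 * (mean gap)^2 per group
    assert between["pct_ss"] == pytest.approx(100.0)
    assert table.loc[table.term == "Residuals", "ss"].iloc[0] == \
        pytest.approx(0.0, abs=1e-18)


def test_sequential_ss_order_free_for_balanced_design():
    rng = np.random.default_rng(3)
    data = factor_frame(n_rep=4)
    data["y"] = rng.normal(size=len(data))
    a = sequential_anova(data, "y", ["species", "forest", "treatment"])
    b = sequential_anova(data, "y", ["treatment", "forest", "species"])
    for term in ["species", "forest", "treatment"]:
        assert a.loc[a.term == term, "ss"].iloc[0] == pytest.approx(
            b.loc[b.term == term, "ss"].iloc[0], rel=1e-9)


def test_pct_ss_telescopes_to_100(default_litterbags):
    data = records_to_model_frame(default_litterbags)
    table = sequential_anova(data)
    assert table["pct_ss"].sum() == pytest.approx(100.0, abs=1e-9)
    assert table["df"].sum() == len(data) - 1


def test_sequential_anova_matches_statsmodels(default_litterbags):
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = records_to_model_frame(default_litterbags)
    terms = ["species", "litter_type", "treatment", "forest", "time_months",
             ("species", "forest"), ("treatment", "time_months")]
    ours = sequential_anova(data, terms=terms).set_index("term")
    formula = ("remaining_mass_pct ~ C(species) + C(litter_type) + "
               "C(treatment) + C(forest) + C(time_months) + "
               "C(species):C(forest) + C(treatment):C(time_months)")
    ref = anova_lm(smf.ols(formula, data).fit())
    pairs = [("species", "C(species)"), ("forest", "C(forest)"),
             ("species:forest", "C(species):C(forest)"),
             ("treatment:time_months", "C(treatment):C(time_months)")]
    for mine, theirs in pairs:
        assert ours.loc[mine, "ss"] == pytest.approx(
            ref.loc[theirs, "sum_sq"], rel=1e-9)
        assert ours.loc[mine, "F"] == pytest.approx(
            ref.loc[theirs, "F"], rel=1e-9)


def test_default_litterbag_model_matches_published_significance_pattern(
        default_litterbags):
    """Litter origin is inert; site, species, treatment and time are not."""
    data = records_to_model_frame(default_litterbags)
    table = sequential_anova(data).set_index("term")
    assert table.loc["litter_type", "p"] > 0.05
    for term in ["species", "treatment", "forest", "time_months",
                 "species:forest", "species:time_months",
                 "treatment:time_months", "forest:time_months"]:
        assert table.loc[term, "p"] < 0.01


def test_two_way_anova_hand_interaction():
    data = pd.DataFrame({
        "litter_type": ["ND", "ND", "ND", "ND", "AD", "AD", "AD", "AD"],
        "species": ["Qilex", "Qilex", "Qpubescens", "Qpubescens"] * 2,
        "value": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 4.0, 4.0],
    })
    table = two_way_anova(data).set_index("term")
    assert table.loc["species:litter_type", "ss"] == pytest.approx(8.0)
    assert "zero residual variance" in table.attrs["flag"]


def test_two_way_anova_flags_constant_data():
    data = pd.DataFrame({
        "litter_type": ["ND", "ND", "AD", "AD"] * 3,
        "species": ["Qilex"] * 4 + ["Qpubescens"] * 4 + ["Phalepensis"] * 4,
        "value": [7.0] * 12,
    })
    table = two_way_anova(data)
    assert "zero residual variance" in table.attrs["flag"]
    assert table.loc[table.term != "Residuals", "F"].isna().all()


def test_two_way_anova_null_p_is_uniform():
    """Interaction p-values under a pure-noise 2 x 3 design are U(0,1)."""
    rng = np.random.default_rng(2024)
    pvals = []
    base = pd.DataFrame({
        "litter_type": np.repeat(["ND", "AD"], 15),
        "species": np.tile(np.repeat(["Qilex", "Qpubescens", "Phalepensis"], 5), 2),
    })
    for _ in range(400):
        data = base.copy()
        data["value"] = rng.normal(size=len(data))
        table = two_way_anova(data).set_index("term")
        pvals.append(table.loc["species:litter_type", "p"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
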