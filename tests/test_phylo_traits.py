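"""Trait classification, PGLS fitting, and permutation importance."""

import json
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

from aquathreat import synthetic_world as world
from aquathreat.phylo_traits import (
    assign_climate_zone,
    build_design,
    classify_habitat,
    classify_trophic,
    fit_pgls,
    log_response,
    variable_importance,
)


# --- classification --------------------------------------------------------

@pytest.mark.parametrize(
    "level, group",
    [(3.5, "Carnivore"), (2.80, "Carnivore"), (2.79, "Omnivore"),
     (2.20, "Omnivore"), (2.19, "Herbivore"), (1.0, "Herbivore")],
)
def test_trophic_group_cutoffs(level, group):
    assert classify_trophic(level) == group


def test_trophic_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_trophic(0.0)


@pytest.mark.parametrize(
    "keywords, kwargs, expected",
    [
        (["rivers", "estuaries"], {}, "lotic"),
        (["streams", "ponds"], {}, "lotic-lentic"),
        (["lake shallows"], {}, "lentic"),
        (["rivers"], {"marine": True}, "lotic-marine"),
        (["hot springs"], {}, "unknown"),
    ],
)
def test_habitat_keyword_classification(keywords, kwargs, expected):
    assert classify_habitat(keywords, **kwargs) == expected


def test_climate_zone_majority_area_and_tie_rule():
    zones = pd.Series({0: "A", 1: "A", 2: "B"})
    areas = pd.Series({0: 30.0, 1: 30.0, 2: 40.0})
    assert assign_climate_zone([0, 1, 2], zones, areas) == "A"
    tie_areas = pd.Series({0: 20.0, 1: 20.0, 2: 40.0})
    assert assign_climate_zone([0, 1, 2], zones, tie_areas) == "A"  # precedence order
    assert assign_climate_zone([2], zones, areas) == "B"


def test_log_response_offset_admits_zero_threat():
    out = log_response(np.array([0.0, 99.99]), offset=0.01)
    assert out[0] == pytest.approx(-2.0)
    assert out[1] == pytest.approx(2.0)


# --- PGLS ------------------------------------------------------------------

def _star_tree(ids, depth=1.0):
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    for label in ids:
        leaf = dendropy.Node(edge_length=depth)
        leaf.taxon = taxa.get_taxon(label)
        tree.seed_node.add_child(leaf)
    return tree


def _ols(X, y):
    return np.linalg.lstsq(X, y, rcond=None)[0]


def simple_traits(n, seed, beta=(1.0, -0.5, 0.8), sd=0.4):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "species_id": [f"sp{i:03d}" for i in range(n)],
            "log10_range_km2": rng.normal(3, 0.8, n),
            "log10_body_length_cm": rng.normal(1.2, 0.3, n),
        }
    )
    X = np.column_stack([np.ones(n), df["log10_range_km2"], df["log10_body_length_cm"]])
    df["response"] = X @ np.array(beta) + rng.normal(0, sd, n)
    return df


COVS = ["log10_range_km2", "log10_body_length_cm"]


def test_star_phylogeny_equals_ols():
    df = simple_traits(50, seed=0)
    tree = _star_tree(df["species_id"].tolist())
    fit = fit_pgls(df, tree, covariates=COVS, collinearity_screen=False)
    X, _, _ = build_design(df, COVS)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), _ols(X, df["response"]), atol=1e-6)


def test_lambda_fixed_zero_is_ols_regardless_of_tree():
    df = simple_traits(50, seed=1)
    tree = world.simulate_tree(df["species_id"].tolist(), seed=2)
    fit = fit_pgls(df, tree, covariates=COVS, lambda_fixed=0.0, collinearity_screen=False)
    X, _, _ = build_design(df, COVS)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), _ols(X, df["response"]), atol=1e-8)


def test_rank_deficient_design_rejected_naming_columns():
    df = simple_traits(30, seed=3)
    df["dup"] = df["log10_range_km2"]
    tree = _star_tree(df["species_id"].tolist())
    with pytest.raises(ValueError, match="aliased"):
        fit_pgls(df, tree, covariates=COVS + ["dup"], collinearity_screen=False)


def test_interior_lambda_beats_both_endpoints():
    ids = [f"sp{i:03d}" for i in range(120)]
    traits, tree, _ = world.generate_traits_and_tree(
        ids, {"intercept": 1.0, "log10_range_km2": -0.5}, lam=0.5, noise_sd=0.6, seed=11
    )
    fit = fit_pgls(traits, tree, covariates=COVS, collinearity_screen=False)
    if 0.0 < fit.lambda_ < 1.0:
        for endpoint in (0.0, 1.0):
            fixed = fit_pgls(
                traits, tree, covariates=COVS, lambda_fixed=endpoint,
                collinearity_screen=False,
            )
            assert fit.log_likelihood >= fixed.log_likelihood - 1e-9


def test_matches_r_nlme_corpagel_oracle():
    """Independent oracle: ape/nlme GLS with a Pagel correlation, via Rscript."""
    ids = [f"sp{i:03d}" for i in range(40)]
    traits, tree, _ = world.generate_traits_and_tree(
        ids, {"intercept": 1.0, "log10_range_km2": -0.5}, lam=0.6, noise_sd=0.5, seed=7
    )
    fit = fit_pgls(traits, tree, covariates=COVS, collinearity_screen=False)
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        tree.write(path=str(tmp / "t.nwk"), schema="newick")
        traits[["species_id", *COVS, "response"]].to_csv(tmp / "d.csv", index=False)
        rscript = tmp / "fit.R"
        rscript.write_text(
            'suppressMessages({library(ape); library(nlme); library(jsonlite)})\n'
            'tr <- read.tree("t.nwk"); d <- read.csv("d.csv"); rownames(d) <- d$species_id\n'
            'fit <- gls(response ~ log10_range_km2 + log10_body_length_cm, data=d,\n'
            '           correlation=corPagel(0.5, tr, form=~species_id), method="ML")\n'
            'cat(toJSON(list(lambda=as.numeric(fit$modelStruct$corStruct),\n'
            '                beta=as.numeric(coef(fit)),\n'
            '                logLik=as.numeric(logLik(fit))), digits=10))\n'
        )
        out = subprocess.run(
            ["Rscript", "fit.R"], cwd=tmp, capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
    assert fit.lambda_ == pytest.approx(ref["lambda"][0], abs=0.02)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), ref["beta"], atol=5e-3)
    assert fit.log_likelihood == pytest.approx(ref["logLik"][0], abs=0.05)


def test_lambda_and_beta_recovery_on_simulated_trees():
    """Moderate Monte-Carlo: lambda and beta recovered from planted data."""
    ids = [f"sp{i:03d}" for i in range(150)]
    beta = {"intercept": 1.0, "log10_range_km2": -0.5, "log10_body_length_cm": 0.8}
    lam_hats, cover = [], []
    for s in range(12):
        traits, tree, _ = world.generate_traits_and_tree(ids, beta, 0.5, 0.6, seed=400 + s)
        fit = fit_pgls(traits, tree, covariates=COVS, collinearity_screen=False)
        lam_hats.append(fit.lambda_)
        for term, true in (("log10_range_km2", -0.5), ("log10_body_length_cm", 0.8)):
            cover.append(
                abs(fit.coefficients[term] - true) <= 2 * fit.std_errors[term]
            )
    assert abs(np.mean(lam_hats) - 0.5) < 0.15
    assert np.mean(cover) >= 0.9


# --- permutation importance ------------------------------------------------

def test_zero_coefficient_covariate_has_zero_importance():
    df = simple_traits(40, seed=5)
    tree = _star_tree(df["species_id"].tolist())
    fit = fit_pgls(df, tree, covariates=COVS, collinearity_screen=False)
    fit.coefficients["log10_body_length_cm"] = 0.0
    imp = variable_importance(fit, df, n_iterations=10, seed=0)
    assert imp.mean["log10_body_length_cm"] == pytest.approx(0.0, abs=1e-12)
    assert imp.mean["log10_range_km2"] > 0.1


def test_constant_column_permutation_has_zero_importance():
    # permuting a constant column is the identity, whatever its coefficient
    df = simple_traits(40, seed=6)
    tree = _star_tree(df["species_id"].tolist())
    fit = fit_pgls(df, tree, covariates=COVS, collinearity_screen=False)
    df_const = df.copy()
    df_const["log10_body_length_cm"] = 1.5
    imp = variable_importance(fit, df_const, n_iterations=5, seed=1)
    assert imp.mean["log10_body_length_cm"] == pytest.approx(0.0, abs=1e-12)


def test_importance_matches_hand_loop_oracle():
    df = simple_traits(30, seed=8)
    df["extra"] = np.random.default_rng(9).normal(size=30)
    covs = COVS + ["extra"]
    tree = _star_tree(df["species_id"].tolist())
    fit = fit_pgls(df, tree, covariates=covs, collinearity_screen=False)
    seed, iters = 123, 7
    imp = variable_importance(fit, df, n_iterations=iters, seed=seed)
    # hand loop with an identically-seeded generator
    rng = np.random.default_rng(seed)
    X0, _, refs = build_design(df, covs, fit.reference_levels)
    pred0 = X0 @ fit.coefficients.to_numpy()
    for cov in covs:
        scores = []
        for _ in range(iters):
            perm = df.copy()
            perm[cov] = rng.permutation(perm[cov].to_numpy())
            Xp, _, _ = build_design(perm, covs, refs)
            predp = Xp @ fit.coefficients.to_numpy()
            scores.append(1.0 - np.corrcoef(pred0, predp)[0, 1])
        assert imp.mean[cov] == pytest.approx(float(np.mean(scores)), rel=1e-12)


def test_importance_invariant_to_affine_response_rescaling():
    df = simple_traits(40, seed=10)
    tree = _star_tree(df["species_id"].tolist())
    fit1 = fit_pgls(df, tree, covariates=COVS, collinearity_screen=False)
    df2 = df.copy()
    df2["response"] = 3.0 * df2["response"] + 7.0
    fit2 = fit_pgls(df2, tree, covariates=COVS, collinearity_screen=False)
    i1 = variable_importance(fit1, df, n_iterations=10, seed=2)
    i2 = variable_importance(fit2, df2, n_iterations=10, seed=2)
    np.testing.assert_allclose(i1.mean.to_numpy(), i2.mean.to_numpy(), atol=1e-10)


def test_replicate_trees_report_mean_and_sd():
    ids = [f"sp{i:03d}" for i in range(60)]
    fits, tabs = [], []
    for s in range(3):
        traits, tree, _ = world.generate_traits_and_tree(
            ids, {"intercept": 1.0, "log10_range_km2": -0.6}, 0.4, 0.5, seed=700 + s
        )
        fits.append(fit_pgls(traits, tree, covariates=COVS, collinearity_screen=False))
        tabs.append(traits)
    imp = variable_importance(fits, tabs, n_iterations=5, seed=3)
    assert imp.n_replicates == 3
    assert (imp.sd >= 0).all()
    assert imp.mean["log10_range_km2"] > imp.mean["log10_body_length_cm"]
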