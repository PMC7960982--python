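"""Phylogenetic regression of threat level on species traits.

Threat (log RT%) is regressed on traits with GLS whose residual
covariance follows the phylogeny under Pagel's lambda; variable
importance is the permutation score 1 - r(original predictions,
predictions after shuffling one covariate).  Here the generator plants
a known coefficient vector and lambda, and the fit recovers them.
"""

from aquathreat import fit_pgls, generate_traits_and_tree, variable_importance

species = [f"sp{i:03d}" for i in range(200)]
planted = {"intercept": 1.0, "log10_range_km2": -0.6, "log10_body_length_cm": 0.4}
traits, tree, truth = generate_traits_and_tree(
    species, beta=planted, lam=0.6, noise_sd=0.5, seed=21
)

covariates = ["log10_range_km2", "log10_body_length_cm", "trophic_group"]
fit = fit_pgls(traits, tree, covariates=covariates)
print(f"Pagel's lambda: planted 0.60, estimated {fit.lambda_:.2f}")
print(f"Pearson r (predicted vs observed): {fit.pearson_r_pred_obs:.2f}\n")
print("coefficients (planted -> estimated +/- SE):")
for term in fit.coefficients.index:
    print(f"  {term:28s} {planted.get(term, 0.0):+5.2f} -> "
          f"{fit.coefficients[term]:+5.2f} +/- {fit.std_errors[term]:.2f}")

imp = variable_importance(fit, traits, n_iterations=50, seed=1)
print("\npermutation importance (larger = predictions depend more on it):")
for cov, score in imp.mean.sort_values(ascending=False).items():
    print(f"  {cov:28s} {score:.3f}")
print("range size dominates, as planted; trophic group has no planted effect")
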