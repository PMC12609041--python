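"""Build the trait-weighted kinship Gt and estimate genetic parameters.

The marker panel is split into a GWAS-prior subset (G1) and the remainder
(G2); each subset's additive variance is estimated with its own
repeatability-model REML fit, the variances set the weight
omega = var_G1 / (var_G1 + var_G2), and the combined Gt feeds a final fit
whose heritability and repeatability are reported.
"""

from priorgs import (
    TraitSpec,
    adjust_phenotypes,
    blend,
    blink,
    estimate_subset_variances,
    fit_repeatability_model,
    select_top_fraction,
    simulate_genotypes,
    simulate_phenotypes,
    vanraden,
    weight_combine,
)

geno = simulate_genotypes(n_individuals=400, n_snps=2000, seed=21)
spec = TraitSpec(h2_true=0.30, rep_true=0.45, n_qtl=60,
                 qtl_effect_dist=("gamma", 1.0), name="cashmere_yield")
records, _ = simulate_phenotypes(geno, spec, seed=22)

assoc = blink(geno, adjust_phenotypes(records))
prior = select_top_fraction(assoc, 0.05)
rest = [i for i in geno.snps["id"] if i not in set(prior)]

G_all = blend(vanraden(geno), 0.01)
G1 = blend(vanraden(geno, prior, kind="prior"), 0.01)
G2 = blend(vanraden(geno, rest, kind="remainder"), 0.01)

var1, var2, fits = estimate_subset_variances(records, G1, G2)
wk = weight_combine(G1, G2, var1, var2)
fit_all = fit_repeatability_model(records, G_all)
fit_gt = fit_repeatability_model(records, wk.Gt)

print(f"var_G1 = {var1:.4f}, var_G2 = {var2:.4f}  ->  omega = {wk.omega:.2f}")
print(f"all-SNP G : h2 = {fit_all.h2:.2f}  rep = {fit_all.rep:.2f}")
print(f"weighted Gt: h2 = {fit_gt.h2:.2f}  rep = {fit_gt.rep:.2f}  (true 0.30 / 0.45)")
# With a concentrated architecture the prior subset soaks up most additive
# variance, omega approaches 1, and Gt recovers the heritability the plain
# all-SNP matrix underestimates.
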