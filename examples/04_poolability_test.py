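"""Should regions share one model?  The poolability LR test.

Fits one pooled logit and one logit per region (then per region-year),
and compares LR = 2(sum of group LLs - pooled LL) to the chi-square
critical value with (G-1)*k degrees of freedom.  Rejection means the
regions need separate models.
"""

import foodsec as fs

cfg = fs.ScenarioConfig(n_regions=6, years=(2016, 2017, 2018),
                        households_per_stratum=300, seed=3)
design = fs.simulate_design(cfg)  # covariates + hidden labels, no baskets

predictors = ["ig2", "ig3", "ig4", "ig5", "size_ge3", "food_share", "hdds"]
suite = fs.run_aggregation_suite(design.matrix, predictor_set=predictors)
print(suite.table.round(2).to_string(index=False))

res = suite.overall
verdict = "rejected" if res.reject_pooling else "not rejected"
print(f"\noverall: LR = {res.lr_stat:.1f} vs chi2 critical "
      f"{res.critical_value:.1f} (df = {res.df}) -> pooling {verdict}")
# The default scenario draws different true coefficients per region, so
# the test should reject pooling: one national model would mask the
# regional differences.
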