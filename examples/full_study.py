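"""End-to-end: simulate a study, extract features, screen, match, score.

Uses a strong texture effect (progressors lose spatial organisation at
follow-up) at small desk scale, so the change models should discriminate
well while the initial models are weaker.  Prints the six-model results
table: odds ratio per SD of composite texture score (in-sample,
optimistic), calibrated held-out p-value, and cross-validated c-statistic.
"""

from ostex.pipeline import AnalysisSettings, run_study
from ostex.synthetic import CohortParams, TextureParams, make_study

cohort = CohortParams(n_cases=24, n_controls_pool=34, n_duplicate=5,
                      rater_jitter_px=0.5, seed=7).strong_effect()
texture = TextureParams(image_size=64, slice_count=3, roi_depth_px=10,
                        roi_margin_frac=0.15)

study = make_study(cohort, texture)
result = run_study(study, settings=AnalysisSettings(n_iter=20, n_folds=10,
                                                    n_lambda=30, base_seed=0))

print(f"retained features: {result.retained_features}")
print(f"matched pairs: {result.matched.n_pairs}; "
      f"worst covariate imbalance (SMD): {result.balance.max():.3f}\n")
cols = ["region", "timebase", "n", "odds_ratio", "validated_or", "p",
        "c_statistic", "top_features"]
print(result.results_table[cols].round(3).to_string(index=False))
print(
    "\nc_statistic is the mean 10-fold cross-validated AUC over repeated"
    "\nfold draws; odds_ratio is the in-sample association (optimistic),"
    "\nvalidated_or the median held-out OR per SD; p comes from the"
    "\nheld-out split-validation permutation test (significant at"
    "\np < 0.008, adjusted for six models)."
)
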