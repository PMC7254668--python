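"""Run the full pipeline on a phantom cohort and report ROC metrics.

Uses a reduced cohort and forest size so the example finishes in about a
minute; the acceptance script runs the full 278-lesion configuration.
"""

from deltarad import ModelingConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    n_lesions=40,
    pcr_fraction=0.3,
    seed=5,
    modeling=ModelingConfig(n_trees=200, n_trees_cv=80, cv_repeats=1),
)
result = run_pipeline(config)

cv = result.train_report
test = result.test_report
print(f"selected features ({len(result.model.features)}):")
for name, imp in result.model.importances.head(5).items():
    print(f"  {name:28s} gini importance {imp:.3f}")
print(f"cross-validation AUROC: {cv.auroc:.3f}  (95% CI {cv.auroc_ci[0]:.3f}-{cv.auroc_ci[1]:.3f})")
print(f"test AUROC            : {test.auroc:.3f}  (95% CI {test.auroc_ci[0]:.3f}-{test.auroc_ci[1]:.3f})")
print(f"test sensitivity (no-pCR): {test.sensitivity[0]:.2f}")
print(f"test specificity (pCR)   : {test.specificity[0]:.2f}")

# With the default strong post-treatment effect the classifier separates
# responders almost perfectly; the interesting outputs are which delta
# features carry the signal (typically post-NAC and diff intensity and
# texture features).
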