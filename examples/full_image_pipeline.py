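"""End-to-end run: images -> clusters -> features -> case matrix -> analysis.

Generates a small two-class image cohort with a dispersion effect, detects
clusters, extracts texture/intensity/geometry features, aggregates to one
row per case and evaluates discrimination.  Takes a few minutes.
"""

from lbcquant import (
    CohortSpec,
    DetectionParams,
    SearchConfig,
    analyze_matrix,
    cases_to_matrix,
    generate_cohort,
)

spec = CohortSpec(n_normal=20, n_lesion=20, effect_size=1.5, seed=9)
cases = generate_cohort(spec)

detection = DetectionParams(min_area_px=50, max_area_px=10**8)
matrix, excluded = cases_to_matrix(cases, detection=detection)
print(f"case matrix: {matrix.shape[0]} cases x {matrix.shape[1]} columns")
print(f"excluded cases: {[(e.case_id, e.reason) for e in excluded]}")

result = analyze_matrix(matrix, SearchConfig.fast(seed=9, beam_width=1, n_trees=(10,)))
print("\ntop univariable features:")
print(
    result.univariable.head(5)[["feature_name", "auc", "direction"]]
    .round(3)
    .to_string(index=False)
)
ev = result.evaluation
print(
    f"\nnested-CV evaluation: CV AUC {ev.cv_auc:.3f} "
    f"(95% CI {ev.delong_ci[0]:.3f}-{ev.delong_ci[1]:.3f}), "
    f"Youden sens {ev.sensitivity:.2f} / spec {ev.specificity:.2f}"
)
print(
    "\nDispersion-type summaries (SD-style texture/intensity features)\n"
    "should dominate the univariable ranking when the planted effect\n"
    "targets within-cluster intensity spread."
)
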