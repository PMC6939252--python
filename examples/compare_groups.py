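"""Run the full pairwise comparison battery on a simulated 3-group dataset.

Simulates mandibles for three dog populations (two of which share a similar
shape), runs GPA, PCA with dimensionality reduction, and for every pair the
six-block battery — size (Wilcoxon), shape and form (MANOVA), allometry
(MANCOVA interaction), size variance (Fligner-Killeen) and shape variance
(permutation) — plus balanced cross-validated LDA, with BH-corrected
p-values, and prints the resulting comparison table.
"""

import arcmorph as am
from arcmorph.io import join_metadata
from arcmorph.pipeline import AnalysisParams, analyze_element, report_to_rows

template = am.make_template("toy_mandible")
spec = am.SimulationSpec(
    template,
    groups=[
        am.GroupSpec("palaeo_inuit", n=14, size_log_mean=3.90),
        am.GroupSpec("inuit", n=16, offset=0.06, size_log_mean=4.00),
        am.GroupSpec("modern_greenland", n=12, offset=0.055, size_log_mean=4.05),
    ],
    landmark_noise_sd=0.015,
    seed=11,
)
data = am.simulate_landmarks(spec)
dataset = join_metadata(data.configs, data.metadata)

report = analyze_element(
    dataset,
    comparisons=[("palaeo_inuit", "inuit"), ("inuit", "modern_greenland")],
    params=AnalysisParams(n_cv_replicates=100, n_perm=999, seed=1),
)

table = report_to_rows(report)
cols = ["comparison", "block", "statistic_label", "statistic",
        "p_value", "p_adjusted", "cv_mean", "cv_ci_low", "cv_ci_high"]
print(table[cols].round(4).to_string(index=False))
print()
print("Each pair gets six test blocks; cv_mean is the mean leave-one-out")
print("accuracy over 100 balanced resamples with its empirical 90% interval.")
print(f"Neighbour-joining phenogram over all groups: {report.nj_newick}")
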