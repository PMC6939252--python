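"""Superimpose simulated tooth outlines with sliding semilandmarks.

Builds an elliptical outline template (2 fixed landmarks + 20 sliding
semilandmarks), simulates two groups of specimens that differ in mean shape,
runs generalized Procrustes analysis with tangent sliding, and prints the
convergence record and the per-group shape disparity (Procrustes variance).
"""

import numpy as np

import arcmorph as am

template = am.make_template("ellipse_outline", n_semilandmarks=20)
spec = am.SimulationSpec(
    template,
    groups=[
        am.GroupSpec("palaeo_inuit", n=15, size_log_mean=3.9),
        am.GroupSpec("inuit", n=15, offset=0.05, size_log_mean=4.0),
    ],
    landmark_noise_sd=0.01,
    seed=7,
)
data = am.simulate_landmarks(spec)

result = am.gpa(data.configs, sliders=data.sliders)
labels = [m.group for m in data.metadata]

print(f"GPA converged: {result.converged} after {result.iterations} iterations "
      f"(final consensus change {result.final_change:.2e})")
print(f"aligned {len(result.aligned)} specimens of "
      f"{result.consensus.shape[0]} landmarks each")
for group in ("palaeo_inuit", "inuit"):
    sizes = [a.log_size for a, g in zip(result.aligned, labels) if g == group]
    print(f"  {group}: mean log centroid size {np.mean(sizes):.3f}")

variances = am.procrustes_variances(result.flat, labels)
for group, v in variances.items():
    print(f"  {group}: Procrustes variance {v:.5f}")
print("Procrustes variance measures within-group shape disparity; the log")
print("centroid sizes reflect the simulated group size difference.")
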