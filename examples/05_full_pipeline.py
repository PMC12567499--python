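"""Run the complete two-posture pipeline and print the evaluation report.

Simulates neutral and supinated elbow-flexion trials, separates and
localizes the muscle-tendon units in each, extracts windowed RMS features,
trains the backprop force model with an 8:2 split and 5-fold cross-
validation, and evaluates held-out force prediction.
"""
import numpy as np

from mtuforce import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=0))

for pr in result.postures:
    errs = [float(x) for x in np.round(pr.localization_errors_mm, 2)]
    print(f"posture {pr.posture}: {len(pr.locations)} EMG components, "
          f"centroid errors {errs} mm")

print(f"cross-validation PCC: "
      f"{np.round([r.pcc for r in result.cv_reports], 4).tolist()}")
rep = result.report
print(f"held-out test set (n={rep.n_samples}): PCC {rep.pcc:.4f}, "
      f"mean relative error {rep.mean_relative_error_pct}%, "
      f"max {rep.max_relative_error_pct}%")
print("PCC >= 0.9 with ~10% mean error on active windows indicates the "
      "pipeline recovered the simulated envelope-to-force relationship")
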