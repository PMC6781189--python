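"""Train the same backbone with and without lesion supervision and compare
how well the Grad-CAM regions localize the true lesions.

This is a miniature of the package's headline experiment (a full-size run
uses ~120 patients; see the repository README).  Expect a couple of
minutes of CPU time.
"""

from lesioncam import run_mode_comparison

result = run_mode_comparison(seed=102, n_patients=60)

print(f"cohort: {result['n_patients']} patients, "
      f"{result['n_images']} frames, task: {result['task']}")
for mode in ("plain", "lesion"):
    m = result["modes"][mode]
    auc = "n/a" if m["auc"] is None else f"{m['auc']:.3f}"
    print(f"{mode:>6}: detection AUC {auc}, "
          f"correct ratio at 0.5 overlap {m['correct_ratio']:.3f} "
          f"({m['n_test']} test frames)")
print(f"correct-ratio gain from lesion supervision: "
      f"{result['correct_ratio_gain']:+.3f}")

# Both models start from identical weights and see identical batches; only
# the objective differs.  The composite loss steers the class-evidence map
# onto the annotated lesion, so the lesion-mode correct ratio (fraction of
# test frames whose activated region overlaps the true lesion at IoU >=
# 0.5) is the number that should improve most.
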