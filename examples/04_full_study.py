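"""Run the full pipeline on a reduced synthetic study.

Simulates a 2-animals-per-phenotype test/retest study at 64x64
resolution, extracts all features, selects the four-feature radiomic
signature, and classifies the phenotypes with a cross-validated linear
SVM. Takes ~20 s.
"""

import tempfile

from ceus_radiomics import RunConfig, run_all

cfg = RunConfig(
    out_dir=tempfile.mkdtemp(prefix="ceus_example_"),
    seed=7,
    n_per_class=(2, 2, 2),
    phantom_overrides={p: dict(image_size=(64, 64), n_frames=40,
                               destruction_frame=14)
                       for p in ("P1", "P2", "P3")},
)
report = run_all(cfg)

print(f"scans: {report['n_scans_dataset1']} + {report['n_scans_dataset2']}, "
      f"features per scan: {report['n_features']}")
print("signature (one per biomarker class):")
for cls, name in report["signature"].items():
    print(f"  {cls:12s} -> {name}")
lo, hi = report["wilson_ci"]
print(f"4-fold CV accuracy: {100 * report['accuracy']:.1f}% "
      f"(95% Wilson CI [{lo:.2f}, {hi:.2f}])")
print(f"cluster sizes: {report['cluster_sizes']}, "
      f"enrichment p: {report['cluster_multinomial_p']}")
print(f"artifacts in {cfg.out_dir}")
# The signature holds exactly one feature per biomarker class with all
# pairwise |r| <= 0.75; accuracy reflects the engineered class
# separation of the phantom study.
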