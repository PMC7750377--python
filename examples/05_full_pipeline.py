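"""Run the whole pipeline: simulate -> CD features -> select -> boost -> CV.

A scaled-down configuration (12 records/class, 16 channels, 640 samples)
runs in seconds; the full-size study configuration (40+ records/class,
64 x 2560) behaves the same way and is what scripts/acceptance.py runs.
All intermediates (feature CSVs, selection metadata, model summary, report
JSON) are written to the output directory.
"""

import tempfile

from cdboost import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as out:
    cfg = PipelineConfig(
        n_records_per_class=12,
        n_channels=16,
        n_samples=640,
        metric="chebyshev",
        k_features=8,
        model="mod-adaboost-ridge",
        cv_folds=4,
        seed=2,
        out_dir=out,
    )
    report = run_pipeline(cfg)
    s = report.summary
    print(f"model: {cfg.model}, metric: {cfg.metric}, {cfg.cv_folds}-fold CV")
    print(f"  PC {s['PC']:.1f}%  MC {s['MC']:.1f}%  FA {s['FA']:.1f}%")
    print(f"  Sensitivity {s['Sensitivity']:.2f}%  Specificity {s['Specificity']:.2f}%")
    print(f"  Accuracy {s['Accuracy']:.2f}%  GDR {s['GDR']:.2f}%  MSE {s['MSE']:.4f}")
    print("PC/MC/FA partition the test records (sum 100); Accuracy is the")
    print("mean of the sensitivity and specificity ratios derived from them")
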