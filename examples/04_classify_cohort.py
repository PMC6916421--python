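"""Full pipeline: simulate, analyse, classify, validate.

Runs the default five-phenotype cohort (10 subjects per class, 7 days)
through every stage and prints the fixed-tree recovery of the generated
labels and the cross-validated per-class metrics.
"""

import tempfile

import acmkit as ak

with tempfile.TemporaryDirectory() as out:
    config = ak.PipelineConfig(mode="synthetic", out_dir=out, seed=1, plots=False)
    summary = ak.run_pipeline(config)
    print(f"subjects analysed:      {summary['n_subjects']}")
    print(f"fixed-tree accuracy:    {summary['fixed_tree_accuracy']:.2f}")
    print(f"cross-validated (k=10): {summary['cv_accuracy']:.2f}")

print("\nAccuracy is the fraction of simulated subjects whose generated "
      "phenotype is recovered by the published four-attribute decision tree; "
      "artifacts (index tables, features, predictions, validation report) "
      "are written to the output directory.")
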