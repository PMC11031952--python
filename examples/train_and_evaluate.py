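"""Train the attention network and evaluate TFBS prediction on held-out data.

The pipeline splits the data 80/10/10 (stratified), builds the graph on the
training sequences, trains with Adam and keeps the epoch with the best
validation F1, then reports the six standard metrics on the test split at a
0.5 probability threshold.
"""

import numpy as np

from motifgat import PipelineConfig, PlantedMotifSpec, generate_ppm, generate_synthetic, run_pipeline

rng = np.random.default_rng(2)
spec = PlantedMotifSpec(ppm=generate_ppm(8, 1.5, rng))
records, _ = generate_synthetic(spec, n_pos=150, seq_len=101, rng_seed=2)

config = PipelineConfig(lenk=5, d_k=16, epochs=40, seed=2)
result = run_pipeline(records, config)

m = result.metrics
print(f"train/val/test sizes: {result.counts['n_train']}/"
      f"{result.counts['n_validation']}/{result.counts['n_test']}")
print(f"precision {m.precision:.3f}  recall {m.recall:.3f}  F1 {m.f1:.3f}")
print(f"ACC {m.acc:.3f}  AUC {m.auc:.3f}  PRC {m.prc:.3f}")
tp, fp, fn, tn = m.confusion
print(f"confusion at 0.5: TP={tp} FP={fp} FN={fn} TN={tn}")
# AUC/PRC are threshold-free ranking scores; the others depend on the 0.5 cut.
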