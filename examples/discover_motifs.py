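"""Discover motifs from trained attention coefficients and compare with truth.

After training, each positive sequence's attention row is denoised by
subtracting the mean attention of the (shuffled) negatives; k-mer
occurrences with positive denoised attention become seeds, seeds at
consecutive offsets are chained when their coexisting probability is high,
overlapping candidates are merged, and equal-width instances form PPMs.
"""

import numpy as np

from motifgat import (
    PipelineConfig,
    PlantedMotifSpec,
    best_alignment_correlation,
    generate_ppm,
    generate_synthetic,
    run_pipeline,
)

rng = np.random.default_rng(5)
spec = PlantedMotifSpec(ppm=generate_ppm(8, 1.5, rng))
records, _ = generate_synthetic(spec, n_pos=300, seq_len=101, rng_seed=5)

config = PipelineConfig(lenk=5, d_k=32, epochs=60, seed=5)
result = run_pipeline(records, config)

print(f"planted consensus: {spec.consensus}")
print(f"{result.counts['n_seeds']} seeds -> {result.counts['n_instances']} "
      f"merged instances -> {len(result.motifs)} motifs\n")
print("width  support  correlation_with_planted_ppm")
for motif in result.motifs[:6]:
    corr = best_alignment_correlation(motif.ppm, spec.ppm)
    consensus = "".join("ACGT"[i] for i in motif.ppm.argmax(axis=0))
    print(f"{motif.width:>5}  {motif.support:>7}  {corr:+.3f}   {consensus}")
# A high-support motif near width 8 whose PPM correlates strongly with the
# planted matrix indicates the attention coefficients localized the motif.
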