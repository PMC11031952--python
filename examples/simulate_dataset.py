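"""Generate a synthetic planted-motif dataset and look at what it contains.

Positives are 101 bp uniform-background sequences with one motif instance
sampled from a known PPM planted at a random offset; negatives are
nucleotide shuffles of the positives (same base composition, no motif).
"""

import numpy as np

from motifgat import PlantedMotifSpec, generate_ppm, generate_synthetic
from motifgat.motifs import information_content

rng = np.random.default_rng(0)
spec = PlantedMotifSpec(ppm=generate_ppm(width=8, bits_per_column=1.5, rng=rng))
records, ground_truth = generate_synthetic(spec, n_pos=50, seq_len=101, rng_seed=0)

print(f"planted motif consensus: {spec.consensus}")
print(f"information content per column (bits): "
      f"{np.round(information_content(spec.ppm), 2)}")
print(f"{len(records)} sequences ({sum(r.label for r in records)} positive)")
seq_id, offset, instance = ground_truth[0]
print(f"first planted instance: {instance} at offset {offset} of {seq_id}")
rec = next(r for r in records if r.id == seq_id)
print(f"sequence slice at that offset: {rec.sequence[offset:offset + 8]}")
# The slice equals the instance; instances differ from the consensus at
# ~7.5% of positions because the PPM's columns are not degenerate.
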