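"""Export intermediate network activations for embedding visualization.

Trains a briefly-fitted reduced model, then dumps the feature matrices
at each named stage (raw input, first conv, both block outputs, hidden
dense layer, softmax).  These [n x d] matrices are what one would hand
to t-SNE/UMAP to inspect how class separation develops with depth.
"""

import numpy as np

from mitopo import (
    SyntheticConfig,
    build_model,
    export_activations,
    generate,
    reduced_configs,
    segments_to_tensors,
    train,
)
from mitopo.model import ACTIVATION_TAGS

trials = generate(SyntheticConfig(n_trials_per_class=20, erd_effect=0.6, seed=2))
tensors, labels = segments_to_tensors(trials)

model_cfg, train_cfg = reduced_configs(seed=2, epochs=5)
model = build_model(model_cfg, seed=2)
train(model, tensors, labels, train_cfg)

print("stage      features per trial")
for tag in ACTIVATION_TAGS:
    mat = export_activations(model, tensors[:8], tag)
    print(f"{tag:10s} {mat.shape[1]:>8d}")

probs = export_activations(model, tensors[:4], "softmax")
print("\nsoftmax rows (left, right) for four trials, "
      "true labels", [str(l) for l in labels[:4]])
print(np.round(probs, 3))
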