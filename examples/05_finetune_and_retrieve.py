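"""Fine-tune for fingerprint prediction and run library retrieval.

Uses the annotated synthetic library (real molecules, fingerprint-derived
spectra), fine-tunes the fingerprint head of a small model for a few epochs,
and evaluates retrieval accuracy@k against candidate pools of decoys.
"""

import numpy as np

from dreams.finetune import FinetuneConfig, evaluate_retrieval, finetune
from dreams.nn.model import EncoderConfig, SpectrumTransformer
from dreams.spectrum import spectra_to_matrices
from dreams.synthetic import SimConfig, generate_annotated_library

library = generate_annotated_library(SimConfig(seed=1), n_molecules=16, spectra_per_molecule=2)
train, val = library[: len(library) - 8], library[len(library) - 8 :]

cfg = EncoderConfig(
    d=32, d_m=28, d_p=4, layers=1, heads=4, c=100, n_peaks=12,
    ffn_f_depth=2, ffn_f_hidden=32, m_min=0.05, m_max=100,
)
model = SpectrumTransformer(cfg, seed=0)
result = finetune(
    model, "fingerprint", train, val, FinetuneConfig(n_peaks=12, lr=1e-3, patience=5),
    epochs=5, check_folds=False,
)
print("validation cosine loss per epoch:",
      [round(h["val_loss"], 3) for h in result.history])

vals, pads = spectra_to_matrices([r.spectrum for r in val], 12)
predicted = result.model.heads_forward(
    result.model.forward_encoder(vals, pads), "fingerprint", pad_mask=pads
).data
candidates = np.stack([r.fingerprint for r in val]).astype(float)
pools = []
for i, rec in enumerate(val):
    positive = np.array([r.inchikey14 == rec.inchikey14 for r in val])
    pools.append((predicted[i], candidates, positive))
accuracy = evaluate_retrieval(pools, ks=(1, 5))
print(f"retrieval accuracy@1 = {accuracy[1]:.2f}, @5 = {accuracy[5]:.2f} "
      "(a pool counts when a same-molecule fingerprint ranks in the top k)")
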