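"""Self-supervised pretraining of a tiny spectrum transformer.

Trains on 400 spectra from the synthetic fragment grammar for 100 steps
(desk scale: a couple of minutes at most) and shows the masked-peak loss
falling below the uniform-prediction baseline ln(c).
"""

import numpy as np

from dreams.nn.model import EncoderConfig
from dreams.pretrain import PretrainConfig, run_pretraining
from dreams.synthetic import pretraining_corpus

spectra, labels, _ = pretraining_corpus(seed=0, n_spectra=400)
model_cfg = EncoderConfig(
    d=64, d_m=56, d_p=8, layers=2, heads=4, c=1000, n_peaks=16,
    ffn_f_depth=2, ffn_f_hidden=64, m_min=0.01, m_max=1000,
)
result = run_pretraining(
    spectra, PretrainConfig(c=1000, n_peaks=16, batch_size=16), model_cfg,
    steps=100, seed=0,
)
first = np.mean([t["loss_mass_per_peak"] for t in result.loss_trace[:10]])
last = np.mean([t["loss_mass_per_peak"] for t in result.loss_trace[-10:]])
print(f"per-masked-peak cross-entropy: {first:.2f} -> {last:.2f} nats")
print(f"uniform-prediction baseline ln(1000) = {np.log(1000):.2f} nats")
print("the model is learning which fragment masses co-occur, so its")
print("masked-mass guesses concentrate on the vocabulary of the grammar")
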