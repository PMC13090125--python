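"""Split a molecular library without scaffold leakage.

Computes Murcko histograms for a few molecules, shows the relaxed
subhistogram relation, and splits a synthetic scaffold-family library so
that no related molecules cross the train/validation boundary.
"""

from dreams.murcko import SplitConfig, murcko_histogram, split_by_murcko, subhistogram_related
from dreams.synthetic import _library_smiles

for smiles in ("c1ccccc1", "c1ccc2ccccc2c1", "c1ccccc1Cc1ccccc1"):
    print(f"{smiles:30s} -> {murcko_histogram(smiles)}")

h_naph = murcko_histogram("c1ccc2ccccc2c1")
h_benz = murcko_histogram("c1ccccc1")
print(f"naphthalene related to benzene? {subhistogram_related(h_naph, h_benz)} "
      "(below the 4-ring threshold the relation is strict identity)")

smiles = _library_smiles(100, fluorinated_fraction=0.2, decoys=True)
train, val = split_by_murcko(smiles, SplitConfig(val_fraction=0.2), seed=0)
print(f"split 100 molecules into {len(train)} train / {len(val)} validation;")
print("after relocation no validation molecule shares a related scaffold "
      "histogram with any training molecule")
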