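"""Deduplicate spectra with random-projection hashing.

Plants groups of duplicate spectra, hashes them with 30 hyperplanes over
1 Da bins, and caps each hash cluster at 10 members. Duplicates collide with
probability 1 per hyperplane, so planted groups land in shared clusters.
"""

import numpy as np

from dreams.lsh import LSHModel, cluster_by_hash, clustering_quality, hash_spectra
from dreams.spectrum import Spectrum

rng = np.random.default_rng(0)
spectra = []
for mol in range(8):
    mz = np.sort(rng.uniform(100, 900, size=10))
    intensity = rng.uniform(10, 100, size=10)
    for _ in range(5):  # five replicates per molecule
        spectra.append(Spectrum(mz=mz, intensity=intensity, precursor_mz=float(mz[-1] + 1)))

model = LSHModel(n_planes=30, n_bins=1000, seed=0)
table = cluster_by_hash(hash_spectra(spectra, model), cap=10, seed=0)
quality = clustering_quality(spectra, table)
print(f"{len(spectra)} spectra -> {len(table.clusters)} clusters, retained {len(table.retained)}")
print(f"mean intra-cluster modified cosine: {quality['mean_intra_cluster_modified_cosine']:.3f} "
      "(1.0 means clusters contain identical spectra)")
print(f"mean per-cluster precursor m/z std: {quality['mean_cluster_precursor_mz_std']:.4f} Da")
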