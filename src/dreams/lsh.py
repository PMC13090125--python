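"""Locality-sensitive hashing of binned spectra via random projections.

Spectra are vectorized by summing intensities into equal-width m/z bins, then
hashed with m random hyperplanes: bit k of the hash is 1 iff the dot product
with hyperplane k is >= 0. Two binned spectra collide on a single hyperplane
with probability 1 - arccos(cos_sim)/pi, so exact-key grouping approximates
cosine-similarity clustering in linear time. Cluster sizes are capped by
seeded uniform subsampling to deduplicate repository-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .spectrum import Spectrum


@dataclass
class LSHModel:
    """m random hyperplanes over an n_bins-dimensional binned-spectrum space."""

    n_planes: int = 64
    n_bins: int = 1000
    bin_width: float = 1.0
    mz_range: tuple[float, float] = (0.0, 1000.0)
    seed: int = 0
    hyperplanes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("need at least one hyperplane")
        lo, hi = self.mz_range
        if not hi > lo:
            raise ValueError("empty m/z range")
        rng = np.random.default_rng(self.seed)
        self.hyperplanes = rng.standard_normal((self.n_planes, self.n_bins))


def make_lsh_model(preset: str = "gems-dedup", seed: int = 0) -> LSHModel:
    """Named presets: ``gems-dedup`` (64 planes) and ``gems-subset`` (30)."""
    planes = {"gems-dedup": 64, "gems-subset": 30}
    if preset not in planes:
        raise ValueError(f"unknown preset {preset!r}")
    return LSHModel(n_planes=planes[preset], seed=seed)


def bin_spectrum(
    spectrum: Spectrum | tuple[np.ndarray, np.ndarray],
    n_bins: int,
    mz_range: tuple[float, float] = (0.0, 1000.0),
) -> np.ndarray:
    """Sum peak intensities into equal-width half-open bins [lo_i, hi_i).

    Peaks outside ``mz_range`` are dropped (the upper boundary is excluded).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = mz_range
    if not hi > lo:
        raise ValueError("empty m/z range")
    if isinstance(spectrum, Spectrum):
        mz, intensity = spectrum.mz, spectrum.intensity
    else:
        mz, intensity = (np.asarray(a, dtype=np.float64) for a in spectrum)
    width = (hi - lo) / n_bins
    keep = (mz >= lo) & (mz < hi)
    idx = np.floor((mz[keep] - lo) / width).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)  # guard float roundoff at the top edge
    out = np.zeros(n_bins)
    np.add.at(out, idx, intensity[keep])
    return out


def hash_spectrum(binned: np.ndarray, model: LSHModel) -> int:
    """Map a binned spectrum to its m-bit random-projection hash key.

    Bit k is 1 iff hyperplane k dotted with the vector is >= 0 (a zero dot
    product hashes to 1).
    """
    binned = np.asarray(binned, dtype=np.float64)
    if binned.shape != (model.n_bins,):
        raise ValueError(
            f"binned vector has length {binned.shape}, model expects {model.n_bins}"
        )
    bits = (model.hyperplanes @ binned) >= 0
    key = 0
    for b in bits:
        key = (key << 1) | int(b)
    return key


def hash_spectra(
    spectra: Sequence[Spectrum],
    model: LSHModel,
) -> list[int]:
    """Bin and hash a sequence of spectra with one model."""
    return [
        hash_spectrum(bin_spectrum(s, model.n_bins, model.mz_range), model)
        for s in spectra
    ]


def collision_probability(cosine_similarity: float) -> float:
    """Single-hyperplane collision probability: 1 - arccos(c)/pi."""
    c = float(np.clip(cosine_similarity, -1.0, 1.0))
    return 1.0 - np.arccos(c) / np.pi


@dataclass
class ClusterTable:
    """Exact-key clusters and the capped member subset retained per cluster."""

    clusters: dict[int, list[int]]
    retained: list[int]


def cluster_by_hash(keys: Sequence[int], cap: int, seed: int = 0) -> ClusterTable:
    """Group indices by exact hash-key equality and cap each cluster.

    Within each cluster, ``min(cap, size)`` members are retained by seeded
    uniform sampling without replacement; retained indices are reported in
    ascending order.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    clusters: dict[int, list[int]] = {}
    for i, k in enumerate(keys):
        clusters.setdefault(int(k), []).append(i)
    rng = np.random.default_rng(seed)
    retained: list[int] = []
    for k in sorted(clusters):
        members = clusters[k]
        if len(members) <= cap:
            retained.extend(members)
        else:
            picks = rng.choice(len(members), size=cap, replace=False)
            retained.extend(members[int(p)] for p in sorted(picks))
    return ClusterTable(clusters=clusters, retained=sorted(retained))


def clustering_quality(
    spectra: Sequence[Spectrum],
    table: ClusterTable,
    mz_tolerance: float = 0.1,
) -> dict[str, float]:
    """Clustering-quality metrics for a hash clustering of annotated spectra.

    Reports the mean intra-cluster modified cosine similarity (matchms),
    the mean per-cluster precursor m/z standard deviation, and the fraction
    of clusters relative to the input size (1.0 means nothing clustered).
    """
    from matchms import Spectrum as MmsSpectrum
    from matchms.similarity import ModifiedCosine

    def to_mms(s: Spectrum) -> MmsSpectrum:
        return MmsSpectrum(
            mz=np.asarray(s.mz, dtype=np.float64),
            intensities=np.asarray(s.intensity, dtype=np.float64),
            metadata={"precursor_mz": float(s.precursor_mz or 0.0)},
            metadata_harmonization=False,
        )

    sim = ModifiedCosine(tolerance=mz_tolerance)
    pair_scores = []
    mz_stds = []
    for members in table.clusters.values():
        if len(members) < 2:
            continue
        prec = [spectra[i].precursor_mz for i in members if spectra[i].precursor_mz]
        if len(prec) >= 2:
            mz_stds.append(float(np.std(prec)))
        mms = [to_mms(spectra[i]) for i in members]
        for a in range(len(mms)):
            for b in range(a + 1, len(mms)):
                score = sim.pair(mms[a], mms[b])
                pair_scores.append(float(score["score"]))
    return {
        "mean_intra_cluster_modified_cosine": float(np.mean(pair_scores)) if pair_scores else float("nan"),
        "mean_cluster_precursor_mz_std": float(np.mean(mz_stds)) if mz_stds else 0.0,
        "cluster_fraction": len(table.clusters) / max(len(spectra), 1),
    }
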