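"""Murcko histograms and leakage-controlled train/validation splitting.

A Murcko histogram summarizes the Murcko scaffold of a molecule as a map
``(r, l) -> count``: for every ring (SSSR ring of the scaffold with more than
3 atoms), ``r`` is the number of fused ring neighbors (half the shared-atom
count, accumulated over all other rings and floored) and ``l`` is the number
of adjacent linker atoms (non-ring scaffold atoms of degree > 1). Splitting a
spectral library so that no train/validation pair of molecules is
"subhistogram related" removes near-duplicate scaffolds that plain
structure-disjoint (InChI-key) splits leak across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

MurckoHistogram = dict[tuple[int, int], int]


@dataclass
class SplitConfig:
    """Parameters of the subhistogram relation and the target split.

    ``k``: below this minimum total ring count the relation degenerates to
    histogram identity. ``m``: ring-marginal L1 distance below which two
    histograms are considered related.
    """

    k: int = 4
    m: int = 5
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.k < 1 or self.m < 1 or not (0 < self.val_fraction < 1):
            raise ValueError("invalid split configuration")


def murcko_histogram(smiles: str) -> MurckoHistogram:
    """Compute the Murcko histogram of a molecule given as SMILES.

    Acyclic molecules yield an empty histogram. Rings of size <= 3 are
    ignored. Spiro neighbors share one atom and contribute an exact half to
    ``r``; halves are accumulated and floored per ring.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    rings = [set(r) for r in scaffold.GetRingInfo().AtomRings() if len(r) > 3]
    ring_atoms = set().union(*rings) if rings else set()
    linkers = {
        a.GetIdx()
        for a in scaffold.GetAtoms()
        if a.GetDegree() > 1 and a.GetIdx() not in ring_atoms
    }
    hist: MurckoHistogram = {}
    for ring in rings:
        r = int(sum(len(ring & other) / 2.0 for other in rings if other is not ring))
        l = sum(
            1
            for v in linkers
            if any(n.GetIdx() in ring for n in scaffold.GetAtomWithIdx(v).GetNeighbors())
        )
        hist[(r, l)] = hist.get((r, l), 0) + 1
    return hist


def _ring_marginal(h: MurckoHistogram) -> dict[int, int]:
    out: dict[int, int] = {}
    for (r, _), count in h.items():
        out[r] = out.get(r, 0) + count
    return out


def subhistogram_related(
    h1: MurckoHistogram, h2: MurckoHistogram, cfg: SplitConfig | None = None
) -> bool:
    """Relaxed comparison of two Murcko histograms.

    When either molecule has fewer than ``k`` rings in total the relation is
    plain histogram equality. Otherwise histograms are marginalized over the
    linker count and compared by L1 distance on the ring-neighbor marginal:
    related iff that distance is below ``m``.
    """
    cfg = cfg or SplitConfig()
    t1 = sum(h1.values())
    t2 = sum(h2.values())
    if min(t1, t2) < cfg.k:
        return h1 == h2
    m1, m2 = _ring_marginal(h1), _ring_marginal(h2)
    d = sum(abs(m1.get(r, 0) - m2.get(r, 0)) for r in set(m1) | set(m2))
    return d < cfg.m


def split_by_murcko(
    smiles: list[str], cfg: SplitConfig | None = None, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Split molecules into (train, validation) index lists without leakage.

    Molecules are first grouped by identical histogram; groups are assigned
    to validation in seeded random order until the target fraction is
    reached. A relocation pass then moves every validation group that is
    subhistogram-related to any training group into training, guaranteeing
    that no related pair crosses the folds.
    """
    if not smiles:
        raise ValueError("empty molecule list")
    cfg = cfg or SplitConfig()
    hists = [murcko_histogram(s) for s in smiles]
    groups: dict[tuple, list[int]] = {}
    for i, h in enumerate(hists):
        key = tuple(sorted(h.items()))
        groups.setdefault(key, []).append(i)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))

    target = cfg.val_fraction * len(smiles)
    val_keys: list[tuple] = []
    n_val = 0
    for j in order:
        if len(keys) - len(val_keys) <= 1:
            break  # keep at least one training group
        if n_val >= target:
            break
        val_keys.append(keys[j])
        n_val += len(groups[keys[j]])

    key_hist = {k: dict(k) for k in keys}
    train_keys = [k for k in keys if k not in set(val_keys)]
    # relocation pass: group-wise relation check against all training groups
    moved = True
    while moved:
        moved = False
        for k in list(val_keys):
            if any(
                subhistogram_related(key_hist[k], key_hist[t], cfg) for t in train_keys
            ):
                val_keys.remove(k)
                train_keys.append(k)
                moved = True
    val_set = set(val_keys)
    train_idx = sorted(i for k in keys if k not in val_set for i in groups[k])
    val_idx = sorted(i for k in val_set for i in groups[k])
    return train_idx, val_idx
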