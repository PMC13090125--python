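"""Transfer learning: task losses, triplet mining, fine-tuning, evaluation.

Fine-tuning adapts a pretrained spectrum transformer end to end for one of
four annotation tasks: contrastive embedding refinement (triplet margin loss
on hard same-mass triplets), Morgan-fingerprint prediction (cosine loss),
joint molecular-property regression (min-max scaled MSE), and fluorine
detection (focal binary cross-entropy). Train/validation folds must be
Murcko-histogram disjoint; leakage aborts the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import (
    Crippen,
    Descriptors,
    GraphDescriptors,
    Lipinski,
    QED,
    rdFingerprintGenerator,
    rdMolDescriptors,
)
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

from .murcko import SplitConfig, murcko_histogram, subhistogram_related
from .nn.autodiff import Adam, Tensor
from .nn.model import FINGERPRINT_BITS, SpectrumTransformer
from .spectrum import Spectrum, spectra_to_matrices

#: Default property panel (the first three are the headline targets; the
#: rest are standard physicochemical descriptors). Configurable by callers.
PROPERTY_NAMES = (
    "qed",
    "heavy_atom_count",
    "bertz_complexity",
    "mol_weight",
    "logp",
    "tpsa",
    "h_bond_donors",
    "h_bond_acceptors",
    "rotatable_bonds",
    "ring_count",
    "fraction_csp3",
)

_PROPERTY_FNS: dict[str, Callable] = {
    "qed": QED.qed,
    "heavy_atom_count": lambda m: float(m.GetNumHeavyAtoms()),
    "bertz_complexity": GraphDescriptors.BertzCT,
    "mol_weight": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "h_bond_donors": Lipinski.NumHDonors,
    "h_bond_acceptors": Lipinski.NumHAcceptors,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "ring_count": rdMolDescriptors.CalcNumRings,
    "fraction_csp3": Lipinski.FractionCSP3,
}


@dataclass
class FinetuneConfig:
    margin: float = 0.1
    eps: float = 1e-8
    focal_alpha: float = 0.8
    focal_gamma: float = 0.5
    n_properties: int = 11
    negative_mass_window: float = 0.05
    n_peaks: int = 100
    lr: float = 3e-4
    batch_size: int = 32
    patience: int = 3

    def __post_init__(self) -> None:
        if self.margin <= 0 or not (0 < self.focal_alpha < 1) or self.focal_gamma < 0:
            raise ValueError("invalid finetune configuration")


@dataclass
class AnnotatedSpectrum:
    """A spectrum with its molecule-level labels."""

    spectrum: Spectrum
    smiles: str
    inchikey14: str
    fingerprint: np.ndarray
    properties: np.ndarray
    fluorine: int
    adduct: str = "[M+H]+"
    collision_energy: Optional[float] = None


def compute_properties(smiles: str, names: Sequence[str] = PROPERTY_NAMES) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return np.asarray([float(_PROPERTY_FNS[n](mol)) for n in names])


def annotate_from_smiles(spectrum: Spectrum, smiles: str, **kwargs) -> AnnotatedSpectrum:
    """Attach molecule-level labels (fingerprint, InChI-key prefix, property
    panel, fluorine flag) to a spectrum given its molecule's SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=FINGERPRINT_BITS)
    fingerprint = np.zeros(FINGERPRINT_BITS, dtype=np.int8)
    fingerprint[list(gen.GetFingerprint(mol).GetOnBits())] = 1
    return AnnotatedSpectrum(
        spectrum=spectrum,
        smiles=smiles,
        inchikey14=Chem.MolToInchiKey(mol)[:14],
        fingerprint=fingerprint,
        properties=compute_properties(smiles),
        fluorine=int(any(a.GetSymbol() == "F" for a in mol.GetAtoms())),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# losses (accept Tensors for training or arrays for direct evaluation)


def _lift(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def cosine_similarity(a, b, eps: float = 1e-8):
    """cos(a, b) with the denominator clamped at ``eps`` for stability."""
    ta, graph_a = _lift(a)
    tb, graph_b = _lift(b)
    dot = (ta * tb).sum(axis=-1)
    denom = ((ta * ta).sum(axis=-1) ** 0.5) * ((tb * tb).sum(axis=-1) ** 0.5)
    out = dot / denom.clip(eps, np.inf)
    return out if (graph_a or graph_b) else float(out.data) if out.data.ndim == 0 else out.data


def triplet_loss(z, z_pos, z_neg, cfg: FinetuneConfig | None = None):
    """Hinge triplet margin loss on cosine similarities.

    ``max{cos(z, z-) - cos(z, z+) + margin, 0}``: zero once the reference is
    closer to the positive than to the negative by at least the margin.
    """
    cfg = cfg or FinetuneConfig()
    tz, g0 = _lift(z)
    tp, g1 = _lift(z_pos)
    tn, g2 = _lift(z_neg)
    loss = (
        cosine_similarity(tz, tn, cfg.eps)
        - cosine_similarity(tz, tp, cfg.eps)
        + cfg.margin
    ).relu()
    return loss if (g0 or g1 or g2) else float(loss.data) if loss.data.ndim == 0 else loss.data


def fingerprint_loss(y_hat, y, eps: float = 1e-8):
    """1 - cos(y_hat, y); zero when the prediction points along the target."""
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    if not np.any(np.linalg.norm(np.atleast_2d(y_arr), axis=-1) > 0):
        raise ValueError("zero-vector fingerprint target")
    out = 1.0 - cosine_similarity(y_hat, y, eps)
    return out


def normalize_properties(
    raw: np.ndarray, stats: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    lo, hi = stats
    return (np.asarray(raw, dtype=np.float64) - lo) / (hi - lo)


def fit_property_scaler(
    train_props: np.ndarray, names: Sequence[str] = PROPERTY_NAMES
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max statistics from the training fold only; a constant property is
    an error naming the offender."""
    train_props = np.asarray(train_props, dtype=np.float64)
    lo = train_props.min(axis=0)
    hi = train_props.max(axis=0)
    for j, (a, b) in enumerate(zip(lo, hi)):
        if a == b:
            name = names[j] if j < len(names) else str(j)
            raise ValueError(f"property {name!r} is constant on the training fold")
    return lo, hi


def property_loss(y_hat, y):
    """Mean squared error averaged over the r properties (and the batch)."""
    ty, g0 = _lift(y_hat)
    tt, g1 = _lift(y)
    resid = ty - tt
    loss = (resid * resid).mean(axis=-1)
    if loss.data.ndim > 0:
        loss = loss.mean()
    return loss if (g0 or g1) else float(loss.data)


def focal_loss(y_hat, y, cfg: FinetuneConfig | None = None):
    """Focal binary cross-entropy, ``-alpha_F (1 - p_F)^gamma log p_F``.

    ``p_F`` is the predicted probability of the true class; ``alpha_F`` is
    ``alpha`` for positives and ``1 - alpha`` for negatives. With gamma=0 and
    alpha=0.5 this is half the standard BCE.
    """
    cfg = cfg or FinetuneConfig()
    tp, graph = _lift(y_hat)
    y_arr = np.asarray(y, dtype=np.float64)
    tp = tp.clip(np.finfo(float).eps, 1 - np.finfo(float).eps)
    p_true = tp * Tensor(y_arr) + (1.0 - tp) * Tensor(1.0 - y_arr)
    alpha = np.where(y_arr == 1, cfg.focal_alpha, 1.0 - cfg.focal_alpha)
    loss = -Tensor(alpha) * (1.0 - p_true) ** cfg.focal_gamma * p_true.log()
    if loss.data.ndim > 0:
        loss = loss.mean()
    return loss if graph else float(loss.data)


# ---------------------------------------------------------------------------
# triplet mining


def mine_triplets(
    library: Sequence[AnnotatedSpectrum],
    cfg: FinetuneConfig | None = None,
    rng: Optional[np.random.Generator] = None,
    max_triplets: Optional[int] = None,
) -> list[tuple[int, int, int]]:
    """Enumerate (reference, positive, negative) index triples.

    A positive is a different record of the same molecule (same 14-character
    InChI-key prefix); a negative is a different molecule whose precursor
    mass lies within ``negative_mass_window`` Da of the reference's. When
    ``max_triplets`` is given, a seeded uniform subsample is returned.
    """
    cfg = cfg or FinetuneConfig()
    keys = [a.inchikey14 for a in library]
    masses = np.asarray([a.spectrum.precursor_mz or np.nan for a in library])
    triples = []
    for r in range(len(library)):
        positives = [p for p in range(len(library)) if p != r and keys[p] == keys[r]]
        if not positives:
            continue
        close = np.abs(masses - masses[r]) <= cfg.negative_mass_window
        negatives = [q for q in np.flatnonzero(close) if keys[q] != keys[r]]
        for p in positives:
            for q in negatives:
                triples.append((r, p, int(q)))
    if max_triplets is not None and len(triples) > max_triplets:
        rng = rng or np.random.default_rng(0)
        picks = rng.choice(len(triples), size=max_triplets, replace=False)
        triples = [triples[int(i)] for i in sorted(picks)]
    return triples


# ---------------------------------------------------------------------------
# fine-tuning loop


def assert_murcko_disjoint(
    train: Sequence[AnnotatedSpectrum],
    val: Sequence[AnnotatedSpectrum],
    split_cfg: SplitConfig | None = None,
) -> None:
    """Abort if any train/validation molecule pair is subhistogram related."""
    split_cfg = split_cfg or SplitConfig()
    train_hists = {
        s: murcko_histogram(s) for s in {a.smiles for a in train}
    }
    val_hists = {s: murcko_histogram(s) for s in {a.smiles for a in val}}
    uniq_train = {tuple(sorted(h.items())): h for h in train_hists.values()}
    uniq_val = {tuple(sorted(h.items())): h for h in val_hists.values()}
    for hv in uniq_val.values():
        for ht in uniq_train.values():
            if subhistogram_related(hv, ht, split_cfg):
                raise ValueError(
                    "fold leakage: a validation molecule is Murcko-histogram "
                    "related to a training molecule"
                )


def _task_batches(
    records: Sequence[AnnotatedSpectrum],
    task: str,
    cfg: FinetuneConfig,
    scaler,
    rng: np.random.Generator,
):
    """Yield (values, pad_mask, target) minibatches for one epoch."""
    if task == "similarity":
        triples = mine_triplets(records, cfg, rng, max_triplets=2000)
        if not triples:
            raise ValueError("no triplets can be mined from the library")
        order = rng.permutation(len(triples))
        for start in range(0, len(order), cfg.batch_size):
            chunk = [triples[int(i)] for i in order[start : start + cfg.batch_size]]
            idx = [i for t in chunk for i in t]
            vals, pads = spectra_to_matrices([records[i].spectrum for i in idx], cfg.n_peaks)
            yield vals, pads, None
        return
    order = rng.permutation(len(records))
    for start in range(0, len(order), cfg.batch_size):
        chunk = [records[int(i)] for i in order[start : start + cfg.batch_size]]
        vals, pads = spectra_to_matrices([r.spectrum for r in chunk], cfg.n_peaks)
        if task == "fingerprint":
            target = np.stack([r.fingerprint for r in chunk]).astype(np.float64)
        elif task == "properties":
            target = np.stack([normalize_properties(r.properties, scaler) for r in chunk])
        elif task == "fluorine":
            target = np.asarray([r.fluorine for r in chunk], dtype=np.float64)
        else:
            raise ValueError(f"unknown task {task!r}")
        yield vals, pads, target


def _task_loss(model: SpectrumTransformer, task: str, cfg, vals, pads, target) -> Tensor:
    s_l = model.forward_encoder(vals, pads)
    if task == "similarity":
        z = model.heads_forward(s_l, "embedding")
        loss = triplet_loss(z[0::3], z[1::3], z[2::3], cfg)
        return loss.mean() if loss.data.ndim else loss
    if task == "fingerprint":
        y_hat = model.heads_forward(s_l, "fingerprint", pad_mask=pads)
        loss = fingerprint_loss(y_hat, target, cfg.eps)
        return loss.mean() if loss.data.ndim else loss
    if task == "properties":
        y_hat = model.heads_forward(s_l, "properties")
        return property_loss(y_hat, Tensor(target))
    if task == "fluorine":
        y_hat = model.heads_forward(s_l, "fluorine")
        return focal_loss(y_hat.reshape(-1), target, cfg)
    raise ValueError(f"unknown task {task!r}")


@dataclass
class FinetuneResult:
    model: SpectrumTransformer
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    scaler: Optional[tuple[np.ndarray, np.ndarray]] = None


def finetune(
    model: SpectrumTransformer,
    task: str,
    train: Sequence[AnnotatedSpectrum],
    val: Sequence[AnnotatedSpectrum],
    cfg: FinetuneConfig | None = None,
    epochs: int = 10,
    seed: int = 0,
    check_folds: bool = True,
) -> FinetuneResult:
    """End-to-end fine-tuning with early stopping on the validation loss.

    Training halts once the validation loss has not improved for
    ``cfg.patience`` consecutive epochs; the best-validation weights are
    restored before returning.
    """
    cfg = cfg or FinetuneConfig()
    if check_folds:
        assert_murcko_disjoint(train, val)
    scaler = None
    if task == "properties":
        scaler = fit_property_scaler(np.stack([r.properties for r in train]))
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    history: list[dict] = []
    best = (np.inf, -1, model.state_dict())
    stale = 0
    for epoch in range(epochs):
        train_losses = []
        for vals, pads, target in _task_batches(train, task, cfg, scaler, rng):
            loss = _task_loss(model, task, cfg, vals, pads, target)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            train_losses.append(float(loss.data))
        val_losses = [
            float(_task_loss(model, task, cfg, vals, pads, target).data)
            for vals, pads, target in _task_batches(
                val, task, cfg, scaler, np.random.default_rng(seed + 1)
            )
        ]
        epoch_val = float(np.mean(val_losses))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)), "val_loss": epoch_val}
        )
        if epoch_val < best[0]:
            best = (epoch_val, epoch, model.state_dict())
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_state_dict(best[2])
    return FinetuneResult(model=model, history=history, best_epoch=best[1], scaler=scaler)


# ---------------------------------------------------------------------------
# evaluation metrics


def evaluate_similarity(embedding_similarities, molecular_similarities) -> float:
    """Pearson correlation between embedding and molecular similarities."""
    x = np.asarray(embedding_similarities, dtype=np.float64)
    y = np.asarray(molecular_similarities, dtype=np.float64)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant score vector")
    return float(pearsonr(x, y).statistic)


def evaluate_binary_ranking(scores, labels) -> float:
    """AUROC of a score vector against binary labels."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


def evaluate_retrieval(
    pools: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    ks: Sequence[int] = (1, 5, 10, 20, 50, 100, 200),
) -> dict[int, float]:
    """Retrieval accuracy@k over candidate pools.

    Each pool is ``(predicted_fp, candidate_fps, positive_mask)``; candidates
    are ranked by cosine similarity to the prediction and a pool counts at k
    when a positive appears among the top k.
    """
    hits = {k: 0 for k in ks}
    for predicted, candidates, positive in pools:
        if not np.any(positive):
            raise ValueError("every pool must contain at least one positive")
        sims = np.asarray(
            [cosine_similarity(predicted, c) for c in np.asarray(candidates)]
        )
        order = np.argsort(-sims, kind="stable")
        ranked = np.asarray(positive)[order]
        for k in ks:
            if np.any(ranked[:k]):
                hits[k] += 1
    return {k: hits[k] / len(pools) for k in ks}
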