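"""Self-supervised pretraining: masked-m/z + retention-order objectives.

Each training example is a pair of spectra from the same LC-MS/MS run. A
fraction of peaks in each spectrum (sampled proportionally to intensity,
never the precursor token) has its m/z replaced by the sentinel -1.0; the
model reconstructs the masked masses as a classification over c equal-width
bins, and simultaneously predicts which spectrum of the pair eluted later.
The total loss is a fixed 0.8/0.2 weighting of the two terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn.autodiff import Adam, Tensor
from .nn.model import EncoderConfig, SpectrumTransformer
from .spectrum import MSRun, Spectrum, SpectrumMatrix, to_spectrum_matrix

MASK_SENTINEL = -1.0


@dataclass
class PretrainConfig:
    mask_ratio: float = 0.3
    mass_weight: float = 0.8
    order_weight: float = 0.2
    c: int = 20000
    mz_max: float = 1000.0
    shift_prob: float = 0.2
    shift_range: tuple[float, float] = (0.0, 50.0)
    n_peaks: int = 60
    lr: float = 3e-4
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.mass_weight + self.order_weight, 1.0):
            raise ValueError("mass_weight + order_weight must equal 1")
        if not (0 <= self.mask_ratio < 1):
            raise ValueError("mask_ratio must lie in [0, 1)")


def mass_bin_label(m: float, c: int, mz_max: float = 1000.0) -> int:
    """Half-open equal-width bin index of a mass: m in [b*mz_max/c, (b+1)*mz_max/c)."""
    if not (0 <= m < mz_max):
        raise ValueError(f"mass {m} outside [0, {mz_max})")
    return int(np.floor(m * c / mz_max))


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Successive intensity-proportional draws with renormalization."""
    weights = weights.astype(np.float64).copy()
    chosen = []
    for _ in range(k):
        total = weights.sum()
        if total <= 0:
            remaining = np.flatnonzero(weights >= 0)
            remaining = np.setdiff1d(remaining, chosen)
            chosen.extend(rng.choice(remaining, size=k - len(chosen), replace=False))
            break
        p = weights / total
        j = int(rng.choice(len(weights), p=p))
        chosen.append(j)
        weights[j] = 0.0
    return np.asarray(chosen, dtype=np.int64)


def mask_spectrum(
    matrix: SpectrumMatrix, cfg: PretrainConfig, rng: np.random.Generator
) -> tuple[SpectrumMatrix, np.ndarray, np.ndarray]:
    """Mask ``round(mask_ratio * n_real)`` peaks of one spectrum matrix.

    Peaks are drawn without replacement with probability proportional to
    intensity; the precursor column is never a candidate. Masked m/z entries
    become -1.0 while intensities stay. Returns the masked matrix, the
    masked column indices, and the true mass-bin labels.
    """
    values = matrix.values.copy()
    n_real = matrix.n_real_peaks
    k = int(round(cfg.mask_ratio * n_real))
    if k == 0:
        return SpectrumMatrix(values, matrix.pad_mask.copy()), np.empty(0, np.int64), np.empty(0, np.int64)
    real_cols = np.flatnonzero(~matrix.pad_mask)
    real_cols = real_cols[real_cols != 0]  # the precursor token is never masked
    # only binnable masses can be labeled (a shift can push peaks past mz_max)
    real_cols = real_cols[
        (values[0, real_cols] >= 0) & (values[0, real_cols] < cfg.mz_max)
    ]
    if len(real_cols) == 0:
        return (
            SpectrumMatrix(values, matrix.pad_mask.copy()),
            np.empty(0, np.int64),
            np.empty(0, np.int64),
        )
    k = min(k, len(real_cols))
    weights = values[1, real_cols]
    picks = real_cols[_weighted_sample_without_replacement(weights, k, rng)]
    labels = np.asarray(
        [mass_bin_label(values[0, j], cfg.c, cfg.mz_max) for j in picks], dtype=np.int64
    )
    values[0, picks] = MASK_SENTINEL
    return SpectrumMatrix(values, matrix.pad_mask.copy()), picks, labels


def augment_shift(
    matrix: SpectrumMatrix, cfg: PretrainConfig, rng: np.random.Generator
) -> SpectrumMatrix:
    """With probability ``shift_prob``, add one uniform scalar to all m/z values
    (precursor included); pairwise m/z differences are preserved exactly."""
    if rng.random() >= cfg.shift_prob:
        return matrix
    lo, hi = cfg.shift_range
    delta = rng.uniform(lo, hi)
    values = matrix.values.copy()
    values[0, ~matrix.pad_mask] += delta
    return SpectrumMatrix(values, matrix.pad_mask.copy())


def sample_training_pair(
    spectra: Sequence[Spectrum], rng: np.random.Generator
) -> tuple[Spectrum, Spectrum, int]:
    """Draw two distinct spectra of one run; the label is 1 iff the second
    elutes later."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to sample a pair")
    sources = {s.source_id for s in spectra}
    if len(sources) > 1:
        raise ValueError("pair sampling requires spectra from a single run")
    i, j = rng.choice(len(spectra), size=2, replace=False)
    a, b = spectra[int(i)], spectra[int(j)]
    y_order = int(b.retention_time > a.retention_time)
    return a, b, y_order


def pretrain_losses(
    mass_log_probs: Tensor,
    mass_labels: np.ndarray,
    pair_of_row: np.ndarray,
    order_probs: Tensor,
    order_labels: np.ndarray,
    cfg: PretrainConfig,
) -> tuple[Tensor, Tensor, Tensor]:
    """Masked-mass, retention-order and combined losses for a batch of pairs.

    ``mass_log_probs``: (K, c) rows for all masked peaks in the batch;
    ``pair_of_row`` maps each row to its pair index (losses are summed over
    the masked peaks of a pair, halved, then averaged over pairs).
    """
    n_pairs = len(order_labels)
    if mass_labels.size:
        nll = -mass_log_probs[np.arange(len(mass_labels)), mass_labels]
        l_mass = nll.sum() * (0.5 / n_pairs)
    else:
        l_mass = Tensor(0.0)
    p = order_probs.clip(1e-12, 1 - 1e-12)
    y = np.asarray(order_labels, dtype=np.float64).reshape(p.shape)
    l_order = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).mean()
    total = l_mass * cfg.mass_weight + l_order * cfg.order_weight
    return l_mass, l_order, total


@dataclass
class PretrainResult:
    model: SpectrumTransformer
    loss_trace: list[dict] = field(default_factory=list)


def _group_by_source(spectra: Sequence[Spectrum]) -> list[list[Spectrum]]:
    groups: dict[str, list[Spectrum]] = {}
    for s in spectra:
        groups.setdefault(s.source_id, []).append(s)
    return [g for g in groups.values() if len(g) >= 2]


def make_training_batch(
    groups: list[list[Spectrum]],
    cfg: PretrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble one batch of masked pairs as stacked arrays.

    Returns (values, pad_mask, mask_rows, mask_cols, mass_labels, pair_of_row,
    order_labels); spectrum 2k and 2k+1 form pair k.
    """
    values, pads, rows, cols, labels, pair_of_row, order = [], [], [], [], [], [], []
    for k in range(cfg.batch_size):
        g = groups[int(rng.integers(len(groups)))]
        a, b, y = sample_training_pair(g, rng)
        order.append(y)
        for s in (a, b):
            mat = to_spectrum_matrix(s, cfg.n_peaks)
            mat = augment_shift(mat, cfg, rng)
            masked, picks, labs = mask_spectrum(mat, cfg, rng)
            idx = len(values)
            values.append(masked.values)
            pads.append(masked.pad_mask)
            rows.extend([idx] * len(picks))
            cols.extend(picks.tolist())
            labels.extend(labs.tolist())
            pair_of_row.extend([k] * len(picks))
    return (
        np.stack(values),
        np.stack(pads),
        np.asarray(rows, dtype=np.int64),
        np.asarray(cols, dtype=np.int64),
        np.asarray(labels, dtype=np.int64),
        np.asarray(pair_of_row, dtype=np.int64),
        np.asarray(order, dtype=np.int64),
    )


def pretrain_step(
    model: SpectrumTransformer,
    batch,
    cfg: PretrainConfig,
    optimizer: Optional[Adam] = None,
) -> dict:
    """One forward (and optionally backward+update) pass over a batch."""
    values, pads, rows, cols, labels, pair_of_row, order = batch
    s_l = model.forward_encoder(values, pads)
    log_probs = model.head_mass_log_probs(s_l[rows, cols])
    s0 = s_l[:, 0, :]
    order_probs = model.head_order(s0[0::2], s0[1::2])
    l_mass, l_order, total = pretrain_losses(
        log_probs, labels, pair_of_row, order_probs, order, cfg
    )
    if optimizer is not None:
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
    if labels.size:
        top1 = float(np.mean(np.argmax(log_probs.data, axis=1) == labels))
        per_peak = float(
            -np.mean(log_probs.data[np.arange(len(labels)), labels])
        )
    else:
        top1 = float("nan")
        per_peak = float("nan")
    return {
        "loss_mass": float(l_mass.data),
        "loss_mass_per_peak": per_peak,
        "loss_order": float(l_order.data),
        "loss": float(total.data),
        "mass_top1": top1,
    }


def run_pretraining(
    spectra: Sequence[Spectrum] | MSRun,
    cfg: PretrainConfig,
    model_cfg: EncoderConfig,
    steps: int,
    seed: int = 0,
) -> PretrainResult:
    """Desk-scale training loop: Adam with default parameters, per-step trace.

    Aborts with a diagnostic if the loss turns non-finite.
    """
    if isinstance(spectra, MSRun):
        spectra = list(spectra.spectra)
    groups = _group_by_source(spectra)
    if not groups:
        raise ValueError("no run with at least 2 spectra to sample pairs from")
    rng = np.random.default_rng(seed)
    model = SpectrumTransformer(model_cfg, seed=seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    trace: list[dict] = []
    for step in range(steps):
        batch = make_training_batch(groups, cfg, rng)
        stats = pretrain_step(model, batch, cfg, optimizer)
        stats["step"] = step
        if not np.isfinite(stats["loss"]):
            raise FloatingPointError(
                f"training diverged at step {step}: loss={stats['loss']}"
            )
        trace.append(stats)
    return PretrainResult(model=model, loss_trace=trace)


def probe_fingerprints(
    embeddings: np.ndarray,
    bits: np.ndarray,
    epochs: int = 100,
    val_fraction: float = 0.3,
    lr: float = 0.1,
    seed: int = 0,
) -> tuple[float, float]:
    """Linear probe: logistic regression from frozen embeddings to binary
    fingerprint bits (e.g. the 166 MACCS keys).

    Trains one linear layer + sigmoid with BCE by full-batch gradient
    descent and reports the best validation recall over the epoch budget,
    with the precision at that epoch. Bits without positive validation
    labels are excluded from the averages.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(bits, dtype=np.float64)
    emb = (emb - emb.mean(axis=0)) / (emb.std(axis=0) + 1e-9)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(emb))
    n_val = max(1, int(round(val_fraction * len(emb))))
    val, train = order[:n_val], order[n_val:]
    x_tr, y_tr, x_va, y_va = emb[train], y[train], emb[val], y[val]
    w = np.zeros((emb.shape[1], y.shape[1]))
    b = np.zeros(y.shape[1])
    usable = y_va.sum(axis=0) > 0
    best_recall, best_precision = 0.0, 0.0
    for _ in range(epochs):
        p = 1.0 / (1.0 + np.exp(-(x_tr @ w + b)))
        g = (p - y_tr) / len(x_tr)
        w -= lr * x_tr.T @ g
        b -= lr * g.sum(axis=0)
        pv = 1.0 / (1.0 + np.exp(-(x_va @ w + b))) > 0.5
        tp = (pv & (y_va > 0)).sum(axis=0).astype(float)
        recall = np.mean(tp[usable] / y_va.sum(axis=0)[usable])
        pred_pos = pv.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec_bits = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), np.nan)
        prec_vals = prec_bits[usable]
        prec_vals = prec_vals[~np.isnan(prec_vals)]
        precision = float(np.mean(prec_vals)) if prec_vals.size else 0.0
        if recall > best_recall:
            best_recall, best_precision = float(recall), 0.0 if np.isnan(precision) else precision
    return best_recall, best_precision
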