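"""Seeded generators for LC-MS/MS runs and annotated spectral libraries.

The run generator emulates exactly the statistical structure the rest of the
package assumes: interleaved MS1/MS2 scans with monotone retention times,
MS1 base peaks jittered by a configurable m/z noise (driving the instrument
accuracy estimator), MS2 peak shapes rendered as centroided sticks, profile
shapes, or thresholded profiles (driving the spectrum-type classifier), a
fragment grammar with deterministic per-molecule co-occurrence (making
masked-peak prediction solvable), and uniform low-intensity noise peaks.

The library generator emits real molecules (SMILES built from scaffold
families with decorated analogs), including same-molecule replicates,
structural-isomer decoys within 0.05 Da for hard-negative mining, and a
deterministic fluorinated fraction. Spectra are derived from Morgan
fingerprint bits, so structurally similar molecules share fragments; this is
a grammar, not a physical fragmentation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt

from .finetune import AnnotatedSpectrum, annotate_from_smiles
from .spectrum import IonizationMode, MSRun, Spectrum

PROTON_MASS = 1.00728

#: Relative profile-peak shape: (m/z offset, relative height). The top of the
#: shape spans >= 4 indices above half maximum within 0.012 Da, so the type
#: classifier labels it PROFILE when the zero-height shoulder points are kept
#: and THRESHOLDED when they are clipped away.
_PROFILE_SHAPE = [
    (-0.006, 0.0),
    (-0.004, 0.6),
    (-0.002, 0.9),
    (0.0, 1.0),
    (0.002, 0.9),
    (0.004, 0.6),
    (0.006, 0.0),
]


@dataclass
class SimConfig:
    n_fragments: int = 50
    fragments_per_molecule: tuple[int, int] = (5, 10)
    n_molecules: int = 20
    neutral_loss_offsets: tuple[float, ...] = (18.0106,)
    mz_range: tuple[float, float] = (50.0, 950.0)
    jitter_sigma: float = 0.0
    noise_peak_rate: float = 2.0
    #: Each MS2 replicate observes a random subset of its molecule's
    #: fragments (at least 4), emulating collision-energy variability;
    #: fragment completion is then learnable but not directly observable.
    fragment_keep_prob: float = 0.65
    #: Precursors are assigned to shared isobaric groups, so the precursor
    #: token alone never identifies the molecule.
    n_precursor_groups: int = 5
    peak_shape: Literal["centroid", "profile", "thresholded"] = "centroid"
    rt_start: float = 10.0
    rt_step: float = 2.0
    adduct_shifts: tuple[float, ...] = (PROTON_MASS,)
    ms2_per_ms1: int = 4
    n_scans: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fragments_per_molecule
        if not (1 <= lo <= hi <= self.n_fragments):
            raise ValueError("invalid fragments_per_molecule range")
        if self.n_scans < 2 or self.n_molecules < 1:
            raise ValueError("invalid scan/molecule counts")


@dataclass
class RunGroundTruth:
    molecule_of_scan: list[Optional[int]]
    fragment_sets: list[np.ndarray]
    noise_of_scan: list[np.ndarray] = field(default_factory=list)


def _vocabulary(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Fragment base masses: distinct, >= 1 Da apart, with decimal parts."""
    lo, hi = cfg.mz_range
    nominal = rng.choice(
        np.arange(int(lo) + 1, int(hi) - 1), size=cfg.n_fragments, replace=False
    )
    decimals = rng.uniform(0.01, 0.5, size=cfg.n_fragments)
    return np.sort(nominal + decimals)


def _molecule_fragments(cfg: SimConfig, vocab: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    lo, hi = cfg.fragments_per_molecule
    sets = []
    for _ in range(cfg.n_molecules):
        k = int(rng.integers(lo, hi + 1))
        sets.append(np.sort(rng.choice(vocab, size=k, replace=False)))
    return sets


def _render_shape(mz: np.ndarray, intensity: np.ndarray, shape: str) -> tuple[np.ndarray, np.ndarray]:
    if shape == "centroid":
        return mz, intensity
    pts_mz, pts_i = [], []
    for m, h in zip(mz, intensity):
        for off, rel in _PROFILE_SHAPE:
            if shape == "thresholded" and rel == 0.0:
                continue
            pts_mz.append(m + off)
            pts_i.append(h * rel if rel > 0 else 0.0)
    order = np.argsort(pts_mz)
    return np.asarray(pts_mz)[order], np.asarray(pts_i)[order]


def generate_run(cfg: SimConfig) -> tuple[MSRun, RunGroundTruth]:
    """Generate one LC-MS/MS run; fully deterministic given ``cfg.seed``.

    Scans interleave one MS1 survey (base peak at a fixed seed mass jittered
    by ``jitter_sigma``) with ``ms2_per_ms1`` MS2 scans of molecules eluting
    in a fixed order; retention times increase monotonically.
    """
    rng = np.random.default_rng(cfg.seed)
    vocab = _vocabulary(cfg, rng)
    frag_sets = _molecule_fragments(cfg, vocab, rng)
    # deterministic per-fragment intensity profile per molecule
    intensities = [rng.uniform(0.2, 1.0, size=len(f)) for f in frag_sets]

    ms1_seed_mass = 500.0
    spectra: list[Spectrum] = []
    truth = RunGroundTruth(molecule_of_scan=[], fragment_sets=frag_sets)
    rt = cfg.rt_start
    scan = 0
    source = f"synthetic-run-{cfg.seed}"
    while scan < cfg.n_scans:
        jitter = rng.normal(0.0, cfg.jitter_sigma) if cfg.jitter_sigma > 0 else 0.0
        ms1_mz = np.asarray([200.123, ms1_seed_mass + jitter, 800.456])
        ms1_int = np.asarray([30.0, 100.0, 20.0])
        spectra.append(
            Spectrum(
                mz=ms1_mz,
                intensity=ms1_int,
                ms_level=1,
                retention_time=rt,
                ionization_mode=IonizationMode.POSITIVE,
                scan_index=scan,
                source_id=source,
            )
        )
        truth.molecule_of_scan.append(None)
        truth.noise_of_scan.append(np.empty(0))
        rt += cfg.rt_step
        scan += 1
        for _ in range(cfg.ms2_per_ms1):
            if scan >= cfg.n_scans:
                break
            mol = int(rng.integers(cfg.n_molecules))
            frags = frag_sets[mol]
            keep = rng.random(len(frags)) < cfg.fragment_keep_prob
            if keep.sum() < min(4, len(frags)):
                keep[rng.choice(len(frags), size=min(4, len(frags)), replace=False)] = True
            base = intensities[mol] * rng.uniform(0.9, 1.1, size=len(frags))
            mz = list(frags[keep])
            inten = list(base[keep] * 100.0)
            for loss in cfg.neutral_loss_offsets:
                mz.append(frags[-1] - loss)
                inten.append(base[-1] * 40.0)
            n_noise = rng.poisson(cfg.noise_peak_rate)
            floor = np.percentile(inten, 10)
            noise_mz = rng.uniform(*cfg.mz_range, size=n_noise)
            for nm in noise_mz:
                mz.append(nm)
                inten.append(rng.uniform(0.1, 0.9) * floor * 0.1)
            mz = np.asarray(mz)
            inten = np.asarray(inten)
            order = np.argsort(mz)
            mz, inten = mz[order], inten[order]
            # keep peaks well separated so rendered shapes never interleave
            keep = np.concatenate([[True], np.diff(mz) > 0.05])
            mz, inten = mz[keep], inten[keep]
            # a dominant base peak keeps the half-max window inside one shape
            inten[np.argmax(inten)] *= 4.0
            mz, inten = _render_shape(mz, inten, cfg.peak_shape)
            group = mol % cfg.n_precursor_groups
            spectra.append(
                Spectrum(
                    mz=mz,
                    intensity=inten,
                    precursor_mz=float(500.0 + 30.0 * group + cfg.adduct_shifts[0]),
                    precursor_charge=1,
                    retention_time=rt + (mol + 1) * 1e-3,  # molecule-dependent offset
                    ms_level=2,
                    ionization_mode=IonizationMode.POSITIVE,
                    scan_index=scan,
                    source_id=source,
                )
            )
            truth.molecule_of_scan.append(mol)
            truth.noise_of_scan.append(noise_mz)
            rt += cfg.rt_step
            scan += 1
    return MSRun(spectra=spectra, path=source), truth


def pretraining_corpus(
    seed: int, n_spectra: int = 2000
) -> tuple[list[Spectrum], np.ndarray, list[int]]:
    """The canonical desk-scale pretraining corpus.

    One simulated run with a 300-molecule fragment grammar, trimmed to
    ``n_spectra`` MS2 spectra. Returns the spectra, the binary
    fragment-membership label matrix (rows: spectra, columns: vocabulary
    fragments of the *generating molecule*, observed or not — the probing
    target), and the molecule id per spectrum.
    """
    cfg = SimConfig(seed=seed, n_scans=n_spectra * 5 // 4 + 20, n_molecules=300)
    run, truth = generate_run(cfg)
    idx = [i for i, m in enumerate(truth.molecule_of_scan) if m is not None][:n_spectra]
    spectra = [run.spectra[i] for i in idx]
    mols = [truth.molecule_of_scan[i] for i in idx]
    vocab = sorted({round(f, 6) for fs in truth.fragment_sets for f in fs})
    v_index = {m: i for i, m in enumerate(vocab)}
    labels = np.zeros((len(spectra), len(vocab)), dtype=np.int8)
    for r, mol in enumerate(mols):
        for f in truth.fragment_sets[mol]:
            labels[r, v_index[round(f, 6)]] = 1
    return spectra, labels, mols


# ---------------------------------------------------------------------------
# annotated library generation

_SCAFFOLDS = (
    "c1ccc(cc1)",          # benzene
    "c1ccc2ccccc2c1",       # naphthalene (decorated via append)
    "c1ccc(-c2ccccc2)cc1",  # biphenyl
    "C1CCC(CC1)",           # cyclohexane
    "c1ccc2[nH]ccc2c1",     # indole
    "c1ccc2ncccc2c1",       # quinoline
)

#: Structural-isomer substituent pairs: members share a molecular formula
#: (identical monoisotopic mass), giving hard decoys within any mass window.
_ISOMER_PAIRS = (
    ("CCC", "C(C)C"),
    ("CCCC", "C(C)CC"),
    ("CCO", "C(C)O"),
    ("CCCO", "C(O)CC"),
    ("CCN", "C(C)N"),
)

_FLUORO_ISOMER_PAIRS = (
    ("CCCF", "C(CF)C"),
    ("CCF", "C(F)C"),
    ("CCCCF", "C(C)CCF"),
)


def _library_smiles(n_molecules: int, fluorinated_fraction: float, decoys: bool) -> list[str]:
    """Deterministic molecule list: scaffold families decorated with isomer
    substituent pairs; exactly ``round(fraction * n)`` fluorinated."""
    n_fluoro = int(round(fluorinated_fraction * n_molecules))
    smiles: list[str] = []
    i = 0
    while len(smiles) < n_molecules - n_fluoro:
        scaffold = _SCAFFOLDS[i % len(_SCAFFOLDS)]
        pair = _ISOMER_PAIRS[(i // len(_SCAFFOLDS)) % len(_ISOMER_PAIRS)]
        subs = pair if decoys else pair[:1]
        for sub in subs:
            if len(smiles) < n_molecules - n_fluoro:
                candidate = scaffold + sub if scaffold.endswith(")") else scaffold + sub
                smiles.append(candidate)
        i += 1
    i = 0
    while len(smiles) < n_molecules:
        scaffold = _SCAFFOLDS[i % len(_SCAFFOLDS)]
        pair = _FLUORO_ISOMER_PAIRS[(i // len(_SCAFFOLDS)) % len(_FLUORO_ISOMER_PAIRS)]
        subs = pair if decoys else pair[:1]
        for sub in subs:
            if len(smiles) < n_molecules:
                smiles.append(scaffold + sub)
        i += 1
    # dedupe while preserving order; extend with chain homologs if collisions ate entries
    seen = set()
    out = []
    for s in smiles:
        if s not in seen:
            seen.add(s)
            out.append(s)
    k = 1
    while len(out) < n_molecules:
        s = _SCAFFOLDS[k % len(_SCAFFOLDS)] + "C" * (2 + k // len(_SCAFFOLDS))
        if s not in seen:
            seen.add(s)
            out.append(s)
        k += 1
    return out[:n_molecules]


def _spectrum_from_fingerprint(
    fingerprint: np.ndarray,
    precursor_mz: float,
    rng: np.random.Generator,
    max_fragments: int = 25,
    source_id: str = "synthetic-library",
    scan_index: int = 0,
) -> Spectrum:
    """Deterministic fragment grammar: each active fingerprint bit maps to a
    fragment mass on a 0.1 Da grid, so similar structures share peaks."""
    bits = np.flatnonzero(fingerprint)[:max_fragments]
    mz = 50.0 + (bits % 7900) / 10.0
    mz = np.unique(mz)
    mz = mz[mz < precursor_mz]
    inten = 20.0 + 80.0 * ((bits[: len(mz)] * 2654435761 % 1000) / 1000.0)
    inten = inten * rng.uniform(0.8, 1.2, size=len(mz))
    mz = np.append(mz, precursor_mz)
    inten = np.append(inten, 60.0)
    order = np.argsort(mz)
    return Spectrum(
        mz=mz[order],
        intensity=inten[order],
        precursor_mz=precursor_mz,
        precursor_charge=1,
        ms_level=2,
        ionization_mode=IonizationMode.POSITIVE,
        scan_index=scan_index,
        source_id=source_id,
    )


def generate_annotated_library(
    cfg: SimConfig,
    n_molecules: int = 40,
    spectra_per_molecule: int = 3,
    fluorinated_fraction: float = 0.2,
    decoys: bool = True,
) -> list[AnnotatedSpectrum]:
    """Generate an annotated library with replicates and same-mass decoys.

    Replicate spectra of one molecule share its InChI-key prefix (triplet
    positives); with ``decoys`` enabled each molecule has a structural isomer
    (identical formula, hence 0 Da precursor difference) as a hard negative.
    """
    if n_molecules < 2:
        raise ValueError("need at least 2 molecules")
    rng = np.random.default_rng(cfg.seed)
    records: list[AnnotatedSpectrum] = []
    scan = 0
    for smiles in _library_smiles(n_molecules, fluorinated_fraction, decoys):
        mol = Chem.MolFromSmiles(smiles)
        precursor = ExactMolWt(mol) + PROTON_MASS
        for rep in range(spectra_per_molecule):
            spec = _spectrum_from_fingerprint(
                annotate_from_smiles(
                    Spectrum(mz=[100.0], intensity=[1.0], precursor_mz=precursor),
                    smiles,
                ).fingerprint,
                precursor,
                rng,
                scan_index=scan,
            )
            spec.retention_time = float(10.0 + scan)
            records.append(annotate_from_smiles(spec, smiles))
            scan += 1
    return records
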