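"""Readers for standard MS formats and the HDF5 tensor store.

mzML/mzXML parsing goes through pyteomics; MGF (annotated libraries) likewise.
The tensor store keeps ragged peak lists as fixed-width zero-padded matrices
(`spectra/mz`, `spectra/intensity`) plus per-spectrum metadata vectors, which
is the layout deep-learning loaders want: one contiguous dataset per field,
all sharing the leading dimension.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import base64
import struct
import zlib

import h5py
import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

from .spectrum import IonizationMode, MSRun, Spectrum, top_n_peaks

STORE_VERSION = "dreams-gems-0.1"

_STORE_DATASETS = (
    "spectra/mz",
    "spectra/intensity",
    "meta/precursor_mz",
    "meta/rt",
    "meta/charge",
    "meta/file_id",
    "meta/accuracy",
    "meta/lsh",
)


class FormatError(ValueError):
    """Unsupported or malformed file format."""


class SchemaError(ValueError):
    """Tensor store does not match the expected schema."""


def _mode_from_flag(positive: bool | None) -> IonizationMode:
    if positive is None:
        return IonizationMode.UNKNOWN
    return IonizationMode.POSITIVE if positive else IonizationMode.NEGATIVE


def _decode_binary(data: str, dtype: str, compressed: bool, big_endian: bool = False) -> np.ndarray:
    raw = base64.b64decode(data.encode())
    if compressed:
        raw = zlib.decompress(raw)
    order = ">" if big_endian else "<"
    n = len(raw) // struct.calcsize(dtype)
    return np.asarray(struct.unpack(f"{order}{n}{dtype}", raw), dtype=np.float64)


def _parse_mzml(path: str) -> list[Spectrum]:
    """Direct mzML parser: cvParams are matched by PSI-MS accession."""
    spectra = []
    for idx, (_, elem) in enumerate(etree.iterparse(path, tag="{*}spectrum")):
        accs = {}
        for cv in elem.iter("{*}cvParam"):
            accs.setdefault(cv.get("accession"), []).append(cv)
        positive = True if "MS:1000130" in accs else (False if "MS:1000129" in accs else None)
        level = int(accs["MS:1000511"][0].get("value")) if "MS:1000511" in accs else 1
        rt = None
        if "MS:1000016" in accs:
            cv = accs["MS:1000016"][0]
            rt = float(cv.get("value"))
            if cv.get("unitName", "").lower() == "minute":
                rt *= 60.0
        prec_mz = float(accs["MS:1000744"][0].get("value")) if "MS:1000744" in accs else None
        charge = int(accs["MS:1000041"][0].get("value")) if "MS:1000041" in accs else None
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter("{*}binaryDataArray"):
            local = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
            dtype = "f" if "MS:1000521" in local else "d"
            compressed = "MS:1000574" in local
            binary = bda.find("{*}binary")
            values = (
                _decode_binary(binary.text or "", dtype, compressed)
                if binary is not None and binary.text
                else np.empty(0)
            )
            if "MS:1000514" in local:
                arrays["mz"] = values
            elif "MS:1000515" in local:
                arrays["intensity"] = values
        spectra.append(
            Spectrum(
                mz=arrays.get("mz", np.empty(0)),
                intensity=arrays.get("intensity", np.empty(0)),
                precursor_mz=prec_mz,
                precursor_charge=charge,
                retention_time=rt,
                ms_level=level,
                ionization_mode=_mode_from_flag(positive),
                scan_index=idx,
                source_id=os.path.basename(path),
            )
        )
        elem.clear()
    return spectra


def _parse_rt_mzxml(value: Optional[str]) -> Optional[float]:
    if not value:
        return None
    # xsd:duration, e.g. "PT123.4S" or "PT2.5M"
    v = value.upper().lstrip("PT")
    if v.endswith("S"):
        return float(v[:-1])
    if v.endswith("M"):
        return float(v[:-1]) * 60.0
    return float(v)


def _parse_mzxml(path: str) -> list[Spectrum]:
    """Direct mzXML parser: interleaved network-order peak pairs."""
    entries: list[tuple[float, Spectrum]] = []
    for idx, (_, elem) in enumerate(etree.iterparse(path, tag="{*}scan")):
        positive = {"+": True, "-": False}.get(elem.get("polarity"))
        level = int(elem.get("msLevel", "1"))
        rt = _parse_rt_mzxml(elem.get("retentionTime"))
        prec_mz = None
        charge = None
        prec = elem.find("{*}precursorMz")
        if prec is not None and prec.text:
            prec_mz = float(prec.text)
            if prec.get("precursorCharge"):
                charge = int(prec.get("precursorCharge"))
        mz = np.empty(0)
        intensity = np.empty(0)
        peaks = elem.find("{*}peaks")
        if peaks is not None and peaks.text:
            dtype = "f" if peaks.get("precision", "32") == "32" else "d"
            compressed = peaks.get("compressionType", "none") == "zlib"
            big_endian = peaks.get("byteOrder", "network") == "network"
            flat = _decode_binary(peaks.text, dtype, compressed, big_endian)
            mz, intensity = flat[0::2], flat[1::2]
        num = float(elem.get("num", idx + 1))
        entries.append(
            (
                num,
                Spectrum(
                    mz=mz,
                    intensity=intensity,
                    precursor_mz=prec_mz,
                    precursor_charge=charge,
                    retention_time=rt,
                    ms_level=level,
                    ionization_mode=_mode_from_flag(positive),
                    scan_index=idx,
                    source_id=os.path.basename(path),
                ),
            )
        )
        elem.clear()
    # nested scans end before their parents in document order; restore the
    # acquisition order via the scan number attribute
    entries.sort(key=lambda pair: pair[0])
    spectra = [s for _, s in entries]
    for i, s in enumerate(spectra):
        s.scan_index = i
    return spectra


def read_msrun(path: str) -> MSRun:
    """Read an mzML/mzXML file into an :class:`MSRun`, keeping file order.

    Corrupted spectra (negative intensities, duplicate identical m/z, empty
    peak lists) are carried through with their defects intact so quality
    control can flag them; nothing is silently dropped.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mzml":
        spectra = _parse_mzml(path)
    elif ext == ".mzxml":
        spectra = _parse_mzxml(path)
    else:
        raise FormatError(f"unsupported extension {ext!r} for {path}")
    return MSRun(spectra=spectra, path=path)


def write_mzml(run: MSRun, path: str) -> None:
    """Write a minimal, standards-enough mzML file (uncompressed 64-bit
    arrays) that round-trips through :func:`read_msrun`. Intended for
    generating small fixtures and exchanging synthetic runs."""
    import base64
    import struct
    from xml.sax.saxutils import escape

    def b64(arr: np.ndarray) -> str:
        raw = struct.pack(f"<{len(arr)}d", *np.asarray(arr, dtype=np.float64))
        return base64.b64encode(raw).decode()

    def cv(accession: str, name: str, value: str = "", extra: str = "") -> str:
        return (
            f'<cvParam cvRef="MS" accession="{accession}" '
            f'name="{escape(name)}" value="{escape(value)}"{extra}/>'
        )

    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        f'<run id="{escape(os.path.basename(path))}">',
        f'<spectrumList count="{len(run)}">',
    ]
    for idx, s in enumerate(run.spectra):
        parts.append(
            f'<spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{len(s)}">'
        )
        parts.append(cv("MS:1000511", "ms level", str(s.ms_level)))
        if s.ionization_mode == IonizationMode.POSITIVE:
            parts.append(cv("MS:1000130", "positive scan"))
        elif s.ionization_mode == IonizationMode.NEGATIVE:
            parts.append(cv("MS:1000129", "negative scan"))
        if s.retention_time is not None:
            parts.append(
                '<scanList count="1"><scan>'
                + cv(
                    "MS:1000016",
                    "scan start time",
                    repr(float(s.retention_time)),
                    ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"',
                )
                + "</scan></scanList>"
            )
        if s.precursor_mz is not None:
            ion = cv("MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)))
            if s.precursor_charge is not None:
                ion += cv("MS:1000041", "charge state", str(s.precursor_charge))
            parts.append(
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>' + ion +
                "</selectedIon></selectedIonList></precursor></precursorList>"
            )
        parts.append('<binaryDataArrayList count="2">')
        for arr, acc, name in (
            (s.mz, "MS:1000514", "m/z array"),
            (s.intensity, "MS:1000515", "intensity array"),
        ):
            payload = b64(arr)
            parts.append(f'<binaryDataArray encodedLength="{len(payload)}">')
            parts.append(cv("MS:1000523", "64-bit float"))
            parts.append(cv("MS:1000576", "no compression"))
            parts.append(cv(acc, name))
            parts.append(f"<binary>{payload}</binary></binaryDataArray>")
        parts.append("</binaryDataArrayList></spectrum>")
    parts.append("</spectrumList></run></mzML>")
    with open(path, "w") as fh:
        fh.write("".join(parts))


def read_mgf(path: str) -> list[Spectrum]:
    """Read an MGF spectral library file (annotated spectra)."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    spectra = []
    with _mgf.read(path) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            prec_mz = float(pepmass[0]) if pepmass else None
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            rt = params.get("rtinseconds")
            spectra.append(
                Spectrum(
                    mz=np.asarray(entry["m/z array"], dtype=np.float64),
                    intensity=np.asarray(entry["intensity array"], dtype=np.float64),
                    precursor_mz=prec_mz,
                    precursor_charge=charge,
                    retention_time=float(rt) if rt is not None else None,
                    ms_level=2,
                    scan_index=idx,
                    source_id=os.path.basename(path),
                )
            )
    return spectra


def write_gems_store(
    spectra: Sequence[Spectrum],
    path: str,
    max_peaks: int,
    accuracies: Optional[Sequence[float]] = None,
    lsh_hashes: Optional[Sequence[int]] = None,
) -> None:
    """Write spectra into the HDF5 tensor store.

    Spectra with more than ``max_peaks`` peaks keep the ``max_peaks`` most
    intense; shorter ones are zero-padded. Every spectrum must be valid;
    the first invalid one is rejected with its index.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    for i, s in enumerate(spectra):
        issues = s.validity_issues()
        if issues:
            raise ValueError(f"invalid spectrum at index {i}: {', '.join(issues)}")

    n = len(spectra)
    mz = np.zeros((n, max_peaks), dtype=np.float64)
    inten = np.zeros((n, max_peaks), dtype=np.float64)
    prec = np.full(n, np.nan)
    rt = np.full(n, np.nan)
    charge = np.zeros(n, dtype=np.int64)
    file_names: list[str] = []
    file_index: dict[str, int] = {}
    file_id = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(spectra):
        m, v = top_n_peaks(s.mz, s.intensity, max_peaks)
        mz[i, : len(m)] = m
        inten[i, : len(m)] = v
        if s.precursor_mz is not None:
            prec[i] = s.precursor_mz
        if s.retention_time is not None:
            rt[i] = s.retention_time
        if s.precursor_charge is not None:
            charge[i] = s.precursor_charge
        if s.source_id not in file_index:
            file_index[s.source_id] = len(file_names)
            file_names.append(s.source_id)
        file_id[i] = file_index[s.source_id]

    acc = np.full(n, np.nan) if accuracies is None else np.asarray(accuracies, dtype=np.float64)
    lsh = (
        np.zeros(n, dtype=np.uint64)
        if lsh_hashes is None
        else np.asarray(lsh_hashes, dtype=np.uint64)
    )
    if acc.shape[0] != n or lsh.shape[0] != n:
        raise ValueError("metadata vectors must share the leading dimension")

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = STORE_VERSION
        f.create_dataset("spectra/mz", data=mz)
        f.create_dataset("spectra/intensity", data=inten)
        f.create_dataset("meta/precursor_mz", data=prec)
        f.create_dataset("meta/rt", data=rt)
        f.create_dataset("meta/charge", data=charge)
        f.create_dataset("meta/file_id", data=file_id)
        f.create_dataset("meta/accuracy", data=acc)
        f.create_dataset("meta/lsh", data=lsh)
        f.create_dataset(
            "meta/file_names", data=np.array(file_names, dtype=h5py.string_dtype())
        )


def read_gems_store(path: str) -> list[Spectrum]:
    """Read a tensor store back into ragged :class:`Spectrum` records.

    Zero-padded columns (m/z == 0) are stripped. Raises :class:`SchemaError`
    when a dataset is missing or leading dimensions disagree.
    """
    with h5py.File(path, "r") as f:
        for name in _STORE_DATASETS:
            if name not in f:
                raise SchemaError(f"store {path} is missing dataset {name!r}")
        mz = f["spectra/mz"][...]
        inten = f["spectra/intensity"][...]
        prec = f["meta/precursor_mz"][...]
        rt = f["meta/rt"][...]
        charge = f["meta/charge"][...]
        file_id = f["meta/file_id"][...]
        names = [x.decode() if isinstance(x, bytes) else str(x) for x in f["meta/file_names"][...]]
        dims = {arr.shape[0] for arr in (mz, inten, prec, rt, charge, file_id)}
        if len(dims) > 1:
            raise SchemaError(f"datasets disagree on the leading dimension: {sorted(dims)}")

    spectra = []
    for i in range(mz.shape[0]):
        keep = mz[i] > 0
        spectra.append(
            Spectrum(
                mz=mz[i, keep],
                intensity=inten[i, keep],
                precursor_mz=None if np.isnan(prec[i]) else float(prec[i]),
                precursor_charge=int(charge[i]) if charge[i] != 0 else None,
                retention_time=None if np.isnan(rt[i]) else float(rt[i]),
                ms_level=2,
                scan_index=i,
                source_id=names[int(file_id[i])] if names else "",
            )
        )
    return spectra
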