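"""Centroided MS2 spectrum reading (mgf, mzML), USI parsing, noise filtering.

File parsing is delegated to :mod:`pyteomics`; this module wraps the
results in a plain :class:`Spectrum` container (parallel numpy arrays,
m/z ascending) and adds the small amount of validation and addressing the
annotation workflow needs.  Vendor raw formats are deliberately not
supported — convert to mzML first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "SpectrumIOError",
    "UnsupportedDataError",
    "SpectrumNotFoundError",
    "USIComponents",
    "read_mgf",
    "read_mzml",
    "write_mgf",
    "parse_usi",
    "noise_filter",
    "get_spectrum",
]


class SpectrumIOError(ValueError):
    """Malformed spectrum file."""


class UnsupportedDataError(SpectrumIOError):
    """Data the reader recognizes but does not support (e.g. profile mode)."""


class SpectrumNotFoundError(KeyError):
    """The requested scan / index / title does not exist in the file."""


@dataclass(frozen=True)
class Spectrum:
    """A centroided spectrum: parallel m/z (ascending) and intensity arrays."""

    mz: np.ndarray
    intensity: np.ndarray
    identifier: str = ""
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    scan_number: Optional[int] = None
    index: Optional[int] = None
    source: str = ""

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise SpectrumIOError("m/z and intensity arrays must be parallel 1-D arrays")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        if np.any(intensity < 0):
            raise SpectrumIOError("negative intensities")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def shifted(self, offset_th: float) -> "Spectrum":
        """The spectrum with every peak moved by ``offset_th`` Th."""
        return replace(self, mz=self.mz + offset_th)


def read_mgf(path: Union[str, Path]) -> List[Spectrum]:
    """Read every BEGIN IONS/END IONS block of an mgf file."""
    path = str(path)
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    n_begin = text.count("BEGIN IONS")
    n_end = text.count("END IONS")
    if n_begin != n_end:
        raise SpectrumIOError(
            f"{path}: {n_begin} BEGIN IONS but {n_end} END IONS (truncated block?)"
        )
    spectra: List[Spectrum] = []
    try:
        with _mgf.MGF(path) as reader:
            for idx, entry in enumerate(reader):
                params = entry.get("params", {})
                charge = params.get("charge")
                if charge:
                    charge = int(charge[0])
                pepmass = params.get("pepmass")
                precursor_mz = float(pepmass[0]) if pepmass else None
                title = str(params.get("title", f"index={idx}"))
                scans = params.get("scans")
                spectra.append(Spectrum(
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    identifier=title,
                    precursor_mz=precursor_mz,
                    precursor_charge=charge,
                    scan_number=int(scans) if scans is not None else None,
                    index=idx,
                    source=path,
                ))
    except SpectrumIOError:
        raise
    except Exception as exc:
        raise SpectrumIOError(f"{path}: {exc}") from exc
    return spectra


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions the reader recognizes
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE_STATE = "MS:1000041"


def _cv_params(element) -> dict:
    out = {}
    for cv in element.iter(f"{_MZML_NS}cvParam"):
        out[cv.get("accession")] = cv.get("value", "")
    return out


def _decode_binary_array(array_elem) -> Tuple[str, np.ndarray]:
    params = _cv_params(array_elem)
    binary = array_elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f8" if _ACC_64BIT in params else "<f4"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if _ACC_MZ_ARRAY in params:
        return "mz", values
    if _ACC_INTENSITY_ARRAY in params:
        return "intensity", values
    return "other", values


def read_mzml(path: Union[str, Path]) -> List[Spectrum]:
    """Read the centroided MS2 spectra of an mzML 1.1 file.

    Binary data arrays may be zlib-compressed or plain, 32- or 64-bit
    floats.  Profile spectra raise :class:`UnsupportedDataError`; MS1 scans
    are skipped.  Spectra are addressable by spectrum index and scan number.
    """
    path = str(path)
    spectra: List[Spectrum] = []
    try:
        tree = etree.parse(path)
    except (OSError, etree.XMLSyntaxError) as exc:
        raise SpectrumIOError(f"{path}: {exc}") from exc
    for idx, spec_elem in enumerate(tree.iter(f"{_MZML_NS}spectrum")):
        own_params = {}
        for child in spec_elem:
            if child.tag == f"{_MZML_NS}cvParam":
                own_params[child.get("accession")] = child.get("value", "")
        if own_params.get(_ACC_MS_LEVEL) == "1":
            continue
        if _ACC_PROFILE in own_params:
            raise UnsupportedDataError(
                f"{path}: profile-mode spectrum {spec_elem.get('id')!r}; centroid first"
            )
        sid = spec_elem.get("id", "")
        scan_number = None
        for token in sid.split():
            if token.startswith("scan="):
                scan_number = int(token[5:])
        precursor_mz = precursor_charge = None
        ion = spec_elem.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        if ion is not None:
            ion_params = _cv_params(ion)
            if _ACC_SELECTED_MZ in ion_params:
                precursor_mz = float(ion_params[_ACC_SELECTED_MZ])
            if _ACC_CHARGE_STATE in ion_params:
                precursor_charge = int(ion_params[_ACC_CHARGE_STATE])
        arrays = {}
        try:
            for array_elem in spec_elem.iter(f"{_MZML_NS}binaryDataArray"):
                kind, values = _decode_binary_array(array_elem)
                arrays[kind] = values
        except (ValueError, zlib.error) as exc:
            raise SpectrumIOError(f"{path}: bad binary data in {sid!r}: {exc}") from exc
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumIOError(f"{path}: spectrum {sid!r} lacks m/z or intensity array")
        index_attr = spec_elem.get("index")
        spectra.append(Spectrum(
            mz=arrays["mz"],
            intensity=arrays["intensity"],
            identifier=sid,
            precursor_mz=precursor_mz,
            precursor_charge=precursor_charge,
            scan_number=scan_number,
            index=int(index_attr) if index_attr is not None else idx,
            source=path,
        ))
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: Union[str, Path]) -> None:
    """Write spectra as mgf with fixed formatting (byte-stable output)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.identifier}\n")
            if s.precursor_mz is not None:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.precursor_charge is not None:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            if s.scan_number is not None:
                fh.write(f"SCANS={s.scan_number}\n")
            for mz_v, int_v in zip(s.mz, s.intensity):
                fh.write(f"{mz_v:.6f} {int_v:.6f}\n")
            fh.write("END IONS\n")


@dataclass(frozen=True)
class USIComponents:
    """Parsed Universal Spectrum Identifier (no network access implied)."""

    collection: str
    run: str
    index_type: str  # "scan" | "index"
    index: int
    interpretation: Optional[str] = None

    def text(self) -> str:
        parts = ["mzspec", self.collection, self.run, self.index_type, str(self.index)]
        if self.interpretation:
            parts.append(self.interpretation)
        return ":".join(parts)


def parse_usi(text: str) -> USIComponents:
    """Parse ``mzspec:collection:run:scan|index:number[:interpretation]``."""
    parts = text.strip().split(":")
    if parts[0] != "mzspec":
        raise SpectrumIOError(f"USI must start with 'mzspec:', got {text!r}")
    if len(parts) < 5:
        raise SpectrumIOError(f"USI {text!r} has too few components")
    collection, run, index_type, index = parts[1], parts[2], parts[3], parts[4]
    if index_type not in ("scan", "index"):
        raise SpectrumIOError(f"USI index type must be 'scan' or 'index', got {index_type!r}")
    try:
        index_num = int(index)
    except ValueError:
        raise SpectrumIOError(f"USI index {index!r} is not an integer") from None
    interpretation = ":".join(parts[5:]) if len(parts) > 5 else None
    return USIComponents(collection, run, index_type, index_num, interpretation)


def noise_filter(spectrum: Spectrum, mode: str = "absolute", value: float = 1.0) -> Spectrum:
    """Drop peaks below an intensity threshold.

    ``mode="absolute"`` keeps peaks with intensity >= ``value``;
    ``mode="relative"`` interprets ``value`` as percent of the base peak.
    Idempotent at a fixed threshold; ``value=0`` is the identity.
    """
    if value < 0:
        raise ValueError(f"noise filter value must be >= 0, got {value}")
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown noise filter mode {mode!r}")
    if value == 0 or len(spectrum) == 0:
        return spectrum
    threshold = value if mode == "absolute" else value * spectrum.base_peak_intensity / 100.0
    keep = spectrum.intensity >= threshold
    return replace(spectrum, mz=spectrum.mz[keep], intensity=spectrum.intensity[keep])


def get_spectrum(
    spectra: Sequence[Spectrum],
    scan: Optional[int] = None,
    index: Optional[int] = None,
    title: Optional[str] = None,
) -> Spectrum:
    """Select one spectrum by scan number, file index, or title."""
    for s in spectra:
        if scan is not None and s.scan_number == scan:
            return s
        if index is not None and s.index == index:
            return s
        if title is not None and s.identifier == title:
            return s
    wanted = f"scan={scan}" if scan is not None else (
        f"index={index}" if index is not None else f"title={title!r}")
    raise SpectrumNotFoundError(f"no spectrum with {wanted}")
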