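"""imzML 1.1.0 input/output.

Reads continuous- and processed-mode imzML/ibd file pairs into an
:class:`MSIDataset` and writes processed-mode pairs back out.  The XML part
follows the mzML schema with the imaging MS (IMS) controlled-vocabulary
extensions: per-spectrum pixel positions (IMS:1000050/51) and external
binary-array pointers (IMS:1000102/103/104) into the sibling ``.ibd`` file.

Pixel coordinates are 1-based, as in the standard.  Missing pixels are
simply absent spectra; downstream code treats them as background.
"""

from __future__ import annotations

import hashlib
import uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["Spectrum", "MSIDataset", "read_imzml", "write_imzml", "UnsupportedFormatError"]

_MZML_NS = "http://psi.hupo.org/ms/mzml"

# cv accessions used when reading/writing
_ACC_POSITION_X = "IMS:1000050"
_ACC_POSITION_Y = "IMS:1000051"
_ACC_EXTERNAL_OFFSET = "IMS:1000102"
_ACC_EXTERNAL_ARRAY_LENGTH = "IMS:1000103"
_ACC_EXTERNAL_ENCODED_LENGTH = "IMS:1000104"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"

_DTYPE_BY_ACCESSION = {
    "MS:1000521": np.dtype("<f4"),  # 32-bit float
    "MS:1000523": np.dtype("<f8"),  # 64-bit float
    "MS:1000519": np.dtype("<i4"),  # 32-bit integer
    "MS:1000522": np.dtype("<i8"),  # 64-bit integer
    "IMS:1000141": np.dtype("<f4"),
    "IMS:1000142": np.dtype("<f8"),
}


class UnsupportedFormatError(ValueError):
    """Raised for imzML constructs this reader does not support."""


@dataclass
class Spectrum:
    """Centroided peak list of one pixel.

    ``mz`` is strictly increasing, ``intensity`` is non-negative and the
    same length, and ``pixel`` is the 1-based (x, y) grid coordinate.
    """

    mz: np.ndarray
    intensity: np.ndarray
    pixel: tuple[int, int]

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity must have equal length")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        x, y = self.pixel
        if x < 1 or y < 1:
            raise ValueError(f"pixel coordinates are 1-based, got {self.pixel}")
        self.pixel = (int(x), int(y))

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class MSIDataset:
    """A pixel grid of spectra plus acquisition metadata."""

    spectra: list[Spectrum] = field(default_factory=list)
    grid: tuple[int, int] = (0, 0)
    polarity: Optional[str] = None  # "positive" | "negative" | None
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for s in self.spectra:
            if s.pixel in seen:
                raise ValueError(f"duplicate spectrum for pixel {s.pixel}")
            seen.add(s.pixel)
        if self.polarity not in (None, "positive", "negative"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        n_x, n_y = self.grid
        for s in self.spectra:
            if not (1 <= s.pixel[0] <= n_x and 1 <= s.pixel[1] <= n_y):
                raise ValueError(f"pixel {s.pixel} outside grid {self.grid}")

    def __len__(self) -> int:
        return len(self.spectra)

    def pixel_map(self) -> dict[tuple[int, int], Spectrum]:
        return {s.pixel: s for s in self.spectra}


def _accession_map(elem: ET.Element) -> dict[str, str]:
    """accession -> value for all cvParam descendants of *elem*."""
    out = {}
    for cv in elem.iter(f"{{{_MZML_NS}}}cvParam"):
        out[cv.get("accession", "")] = cv.get("value", "")
    return out


def _local_cvparams(elem: ET.Element) -> dict[str, str]:
    return {
        cv.get("accession", ""): cv.get("value", "")
        for cv in elem.findall(f"{{{_MZML_NS}}}cvParam")
    }


def read_imzml(path: str | Path) -> MSIDataset:
    """Parse an imzML/ibd pair into an :class:`MSIDataset`.

    Both continuous and processed binary modes are handled; in continuous
    mode the shared m/z axis is re-read per pixel (it resolves through the
    same external-offset mechanism).  Polarity is taken from scan-level or
    file-level cvParams when present, else left unset.
    """
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")
    if not path.exists():
        raise FileNotFoundError(f"imzML file not found: {path}")
    if not ibd_path.exists():
        raise FileNotFoundError(
            f"binary sibling not found: {ibd_path} (required next to {path.name})"
        )

    tree = ET.parse(path)  # ET.ParseError carries line/column context
    root = tree.getroot()

    # referenceable param groups let spectra share array metadata
    group_params: dict[str, dict[str, str]] = {}
    for grp in root.iter(f"{{{_MZML_NS}}}referenceableParamGroup"):
        group_params[grp.get("id", "")] = _local_cvparams(grp)

    polarity: Optional[str] = None
    file_content = root.find(
        f"{{{_MZML_NS}}}fileDescription/{{{_MZML_NS}}}fileContent"
    )
    if file_content is not None:
        fc = _local_cvparams(file_content)
        if _ACC_POSITIVE in fc:
            polarity = "positive"
        elif _ACC_NEGATIVE in fc:
            polarity = "negative"

    ibd = ibd_path.read_bytes()

    spectra: list[Spectrum] = []
    for spec_elem in root.iter(f"{{{_MZML_NS}}}spectrum"):
        params = _accession_map(spec_elem)
        if polarity is None:
            if _ACC_POSITIVE in params:
                polarity = "positive"
            elif _ACC_NEGATIVE in params:
                polarity = "negative"
        try:
            x = int(params[_ACC_POSITION_X])
            y = int(params[_ACC_POSITION_Y])
        except KeyError as exc:
            raise UnsupportedFormatError(
                f"spectrum {spec_elem.get('id')!r} lacks pixel position cvParams"
            ) from exc

        mz = intensity = None
        for arr_elem in spec_elem.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            arr_params = dict(_local_cvparams(arr_elem))
            for ref in arr_elem.findall(f"{{{_MZML_NS}}}referenceableParamGroupRef"):
                arr_params.update(group_params.get(ref.get("ref", ""), {}))
            dtype = None
            for acc, dt in _DTYPE_BY_ACCESSION.items():
                if acc in arr_params:
                    dtype = dt
                    break
            if dtype is None:
                raise UnsupportedFormatError(
                    f"unknown binary encoding in spectrum {spec_elem.get('id')!r}: "
                    f"no recognised data-type cvParam among {sorted(arr_params)}"
                )
            try:
                offset = int(arr_params[_ACC_EXTERNAL_OFFSET])
                length = int(arr_params[_ACC_EXTERNAL_ARRAY_LENGTH])
            except KeyError as exc:
                raise UnsupportedFormatError(
                    "inline (base64) binary arrays are not supported; "
                    "expected external ibd pointers"
                ) from exc
            values = np.frombuffer(ibd, dtype=dtype, count=length, offset=offset)
            values = values.astype(np.float64)
            if _ACC_MZ_ARRAY in arr_params:
                mz = values
            elif _ACC_INTENSITY_ARRAY in arr_params:
                intensity = values
        if mz is None or intensity is None:
            raise UnsupportedFormatError(
                f"spectrum {spec_elem.get('id')!r} lacks m/z or intensity array"
            )
        spectra.append(Spectrum(mz=mz, intensity=intensity, pixel=(x, y)))

    if spectra:
        grid = (max(s.pixel[0] for s in spectra), max(s.pixel[1] for s in spectra))
    else:
        grid = (0, 0)
    return MSIDataset(
        spectra=spectra, grid=grid, polarity=polarity, source_path=str(path)
    )


def _cv(parent: ET.Element, ref: str, accession: str, name: str, value: str = "") -> None:
    ET.SubElement(
        parent, "cvParam", cvRef=ref, accession=accession, name=name, value=value
    )


def write_imzml(
    dataset: MSIDataset,
    path: str | Path,
    mz_dtype: str = "f8",
    intensity_dtype: str = "f4",
) -> tuple[Path, Path]:
    """Write *dataset* as a processed-mode imzML/ibd pair.

    Defaults encode m/z at 64 bit (mass accuracy for ppm matching) and
    intensity at 32 bit.  Output is deterministic for identical input: the
    ibd UUID is derived from the payload hash, not drawn at random.

    Returns the (imzml_path, ibd_path) pair.
    """
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    ibd_path = path.with_suffix(".ibd")

    mz_dt = np.dtype("<" + mz_dtype)
    int_dt = np.dtype("<" + intensity_dtype)
    dtype_acc = {np.dtype("<f4"): ("MS:1000521", "32-bit float"),
                 np.dtype("<f8"): ("MS:1000523", "64-bit float")}
    if mz_dt not in dtype_acc or int_dt not in dtype_acc:
        raise UnsupportedFormatError("only f4/f8 encodings are written")

    # ibd payload: arrays in spectrum order, mz then intensity
    chunks: list[bytes] = []
    offsets: list[tuple[int, int, int, int]] = []  # per spectrum: mz off/len, int off/len
    pos = 16  # after UUID
    for s in dataset.spectra:
        mz_bytes = np.ascontiguousarray(s.mz, dtype=mz_dt).tobytes()
        int_bytes = np.ascontiguousarray(s.intensity, dtype=int_dt).tobytes()
        offsets.append((pos, len(s.mz), pos + len(mz_bytes), len(s.intensity)))
        pos += len(mz_bytes) + len(int_bytes)
        chunks.append(mz_bytes)
        chunks.append(int_bytes)
    payload = b"".join(chunks)
    ibd_uuid = uuid.UUID(bytes=hashlib.sha1(payload).digest()[:16])
    ibd_bytes = ibd_uuid.bytes + payload
    sha1 = hashlib.sha1(ibd_bytes).hexdigest()

    ET.register_namespace("", _MZML_NS)
    root = ET.Element(f"{{{_MZML_NS}}}mzML", version="1.1")
    cv_list = ET.SubElement(root, "cvList", count="3")
    for cid, full, uri in (
        ("MS", "Proteomics Standards Initiative Mass Spectrometry Ontology",
         "http://psidev.cvs.sourceforge.net/*checkout*/psidev/psi/psi-ms/mzML/controlledVocabulary/psi-ms.obo"),
        ("UO", "Unit Ontology",
         "http://obo.cvs.sourceforge.net/*checkout*/obo/obo/ontology/phenotype/unit.obo"),
        ("IMS", "Imaging MS Ontology",
         "http://www.maldi-msi.org/download/imzml/imagingMS.obo"),
    ):
        ET.SubElement(cv_list, "cv", id=cid, fullName=full, URI=uri)

    file_desc = ET.SubElement(root, "fileDescription")
    fc = ET.SubElement(file_desc, "fileContent")
    _cv(fc, "MS", "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS", "MS:1000128", "profile spectrum")
    _cv(fc, "IMS", "IMS:1000031", "processed")
    _cv(fc, "IMS", "IMS:1000080", "universally unique identifier",
        "{" + str(ibd_uuid) + "}")
    _cv(fc, "IMS", "IMS:1000091", "ibd SHA-1", sha1)
    if dataset.polarity == "positive":
        _cv(fc, "MS", _ACC_POSITIVE, "positive scan")
    elif dataset.polarity == "negative":
        _cv(fc, "MS", _ACC_NEGATIVE, "negative scan")

    rpg_list = ET.SubElement(root, "referenceableParamGroupList", count="2")
    g_mz = ET.SubElement(rpg_list, "referenceableParamGroup", id="mzArray")
    _cv(g_mz, "MS", _ACC_MZ_ARRAY, "m/z array", "")
    _cv(g_mz, "MS", dtype_acc[mz_dt][0], dtype_acc[mz_dt][1])
    _cv(g_mz, "MS", "MS:1000576", "no compression")
    _cv(g_mz, "IMS", "IMS:1000101", "external data", "true")
    g_int = ET.SubElement(rpg_list, "referenceableParamGroup", id="intensityArray")
    _cv(g_int, "MS", _ACC_INTENSITY_ARRAY, "intensity array", "")
    _cv(g_int, "MS", dtype_acc[int_dt][0], dtype_acc[int_dt][1])
    _cv(g_int, "MS", "MS:1000576", "no compression")
    _cv(g_int, "IMS", "IMS:1000101", "external data", "true")

    sw_list = ET.SubElement(root, "softwareList", count="1")
    ET.SubElement(sw_list, "software", id="msilipid", version="0.1.0")

    scan_settings_list = ET.SubElement(root, "scanSettingsList", count="1")
    scan_settings = ET.SubElement(scan_settings_list, "scanSettings", id="scansettings1")
    n_x, n_y = dataset.grid
    _cv(scan_settings, "IMS", "IMS:1000042", "max count of pixels x", str(n_x))
    _cv(scan_settings, "IMS", "IMS:1000043", "max count of pixels y", str(n_y))

    ic_list = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ET.SubElement(ic_list, "instrumentConfiguration", id="IC1")
    dp_list = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dp_list, "dataProcessing", id="export")
    pm = ET.SubElement(dp, "processingMethod", order="1", softwareRef="msilipid")
    _cv(pm, "MS", "MS:1000544", "Conversion to mzML")

    run = ET.SubElement(root, "run", id="run1", defaultInstrumentConfigurationRef="IC1")
    spec_list = ET.SubElement(
        run, "spectrumList", count=str(len(dataset.spectra)),
        defaultDataProcessingRef="export",
    )
    for i, (s, (mz_off, mz_len, int_off, int_len)) in enumerate(
        zip(dataset.spectra, offsets)
    ):
        spec = ET.SubElement(
            spec_list, "spectrum", id=f"spectrum={i + 1}", index=str(i),
            defaultArrayLength="0",
        )
        if dataset.polarity == "positive":
            _cv(spec, "MS", _ACC_POSITIVE, "positive scan")
        elif dataset.polarity == "negative":
            _cv(spec, "MS", _ACC_NEGATIVE, "negative scan")
        scan_list = ET.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS", "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, "IMS", _ACC_POSITION_X, "position x", str(s.pixel[0]))
        _cv(scan, "IMS", _ACC_POSITION_Y, "position y", str(s.pixel[1]))
        bda_list = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for ref, off, length, itemsize in (
            ("mzArray", mz_off, mz_len, mz_dt.itemsize),
            ("intensityArray", int_off, int_len, int_dt.itemsize),
        ):
            bda = ET.SubElement(bda_list, "binaryDataArray", encodedLength="0")
            ET.SubElement(bda, "referenceableParamGroupRef", ref=ref)
            _cv(bda, "IMS", _ACC_EXTERNAL_ARRAY_LENGTH, "external array length",
                str(length))
            _cv(bda, "IMS", _ACC_EXTERNAL_ENCODED_LENGTH, "external encoded length",
                str(length * itemsize))
            _cv(bda, "IMS", _ACC_EXTERNAL_OFFSET, "external offset", str(off))
            ET.SubElement(bda, "binary")

    ET.indent(root)
    tree = ET.ElementTree(root)
    try:
        tree.write(path, xml_declaration=True, encoding="utf-8")
        ibd_path.write_bytes(ibd_bytes)
    except OSError as exc:
        raise OSError(f"cannot write imzML pair at {path}: {exc}") from exc
    return path, ibd_path
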