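"""File I/O: ENVI cubes, portable ``.npz`` cubes, label masks, spectral CSV.

ENVI support covers the text ``.hdr`` header plus a flat binary payload in
``bil``/``bip``/``bsq`` interleave.  The payload file may use a ``.dat`` or
``.raw`` extension.  Wavelengths are required in the header unless supplied
explicitly.
"""

from __future__ import annotations

import os
import re

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import HyperspectralCube, SeedMask, SpectralTable

__all__ = [
    "read_envi",
    "write_envi",
    "read_cube_npz",
    "write_cube_npz",
    "read_mask",
    "write_mask",
    "read_spectral_table",
    "write_spectral_table",
]

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    """Parse ``key = value`` pairs; brace-wrapped values may span lines."""
    fields: dict[str, str] = {}
    # strip the ENVI magic and comments
    body = re.sub(r"^ENVI\s*", "", text.strip())
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        fields[key] = val
    return fields


def read_envi(hdr_path: str, wavelengths: np.ndarray | None = None) -> HyperspectralCube:
    """Read an ENVI ``.hdr``/binary pair into a ``HyperspectralCube``."""
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields.get("data type", 4))]
    interleave = fields.get("interleave", "bsq").lower()
    byte_order = int(fields.get("byte order", 0))
    if wavelengths is None:
        if "wavelength" not in fields:
            raise ValueError(
                "header has no wavelength list; pass wavelengths= explicitly"
            )
        wavelengths = np.array(
            [float(x) for x in fields["wavelength"].replace("\n", " ").split(",")]
        )
    stem = os.path.splitext(hdr_path)[0]
    data_path = None
    for ext in (".dat", ".raw", ".img", ".bin", ""):
        cand = stem + ext
        if os.path.isfile(cand) and cand != hdr_path:
            data_path = cand
            break
    if data_path is None:
        raise FileNotFoundError(f"no binary payload next to {hdr_path}")
    flat = np.fromfile(data_path, dtype=dtype)
    if byte_order == 1:
        flat = flat.astype(flat.dtype.newbyteorder(">"))
    if flat.size != samples * lines * bands:
        raise ValueError(
            f"payload has {flat.size} values; header implies {samples * lines * bands}"
        )
    if interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    return HyperspectralCube(data=np.ascontiguousarray(data, dtype=np.float64),
                             wavelengths=wavelengths)


def write_envi(cube: HyperspectralCube, hdr_path: str, interleave: str = "bip",
               dtype: str = "float32") -> str:
    """Write a cube as ENVI ``.hdr`` + ``.dat``; returns the payload path."""
    dt = np.dtype(dtype)
    if dt not in _ENVI_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    h, w, b = cube.shape
    if interleave == "bip":
        payload = cube.data
    elif interleave == "bil":
        payload = cube.data.transpose(0, 2, 1)
    elif interleave == "bsq":
        payload = cube.data.transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    stem = os.path.splitext(hdr_path)[0]
    data_path = stem + ".dat"
    np.ascontiguousarray(payload, dtype=dt).tofile(data_path)
    wl = ", ".join(f"{x:g}" for x in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dt]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(hdr_path, "w") as fh:
        fh.write(header)
    return data_path


def write_cube_npz(cube: HyperspectralCube, path: str) -> None:
    np.savez_compressed(path, data=cube.data, wavelengths=cube.wavelengths)


def read_cube_npz(path: str) -> HyperspectralCube:
    with np.load(path) as z:
        return HyperspectralCube(data=z["data"], wavelengths=z["wavelengths"])


def write_mask(mask: SeedMask, path: str) -> None:
    """Write a label mask as a 16-bit PNG/TIFF image."""
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for a 16-bit label image")
    iio.imwrite(path, mask.labels.astype(np.uint16))


def read_mask(path: str) -> SeedMask:
    return SeedMask(labels=np.asarray(iio.imread(path)).astype(np.int32))


def write_spectral_table(table: SpectralTable, path: str) -> None:
    """CSV with header row ``seed_id,label,<λ1>,<λ2>,...``."""
    labels = (
        table.class_labels
        if table.class_labels is not None
        else np.zeros(table.n_seeds, dtype=int)
    )
    df = pd.DataFrame(table.spectra, columns=[f"{w:g}" for w in table.wavelengths])
    df.insert(0, "label", np.asarray(labels))
    df.insert(0, "seed_id", table.seed_ids)
    df.to_csv(path, index=False)


def read_spectral_table(path: str) -> SpectralTable:
    df = pd.read_csv(path)
    wl = np.array([float(c) for c in df.columns[2:]])
    return SpectralTable(
        spectra=df.iloc[:, 2:].to_numpy(dtype=np.float64),
        wavelengths=wl,
        seed_ids=df["seed_id"].to_numpy(),
        class_labels=df["label"].to_numpy(),
    )
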