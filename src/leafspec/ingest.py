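"""Hypercube I/O, leaf segmentation, and per-leaf mean spectrum extraction.

The measurement geometry this module serves is a push-broom VNIR line scan
of detached leaves lying on a bright white (Teflon) board.  Leaves are dark
in the red (chlorophyll absorbs strongly near 655 nm) while the board stays
bright, so a single-band fixed threshold separates the two: a pixel is leaf
iff its reflectance at the segmentation band is *below* the threshold.
Connected leaf pixels are grouped with 8-connectivity, tiny specks are
discarded, and regions are numbered in reading order (top-to-bottom, then
left-to-right of their centroids) so sample ids are reproducible.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "SpectralCube",
    "LeafMask",
    "LabeledSpectra",
    "read_cube",
    "write_cube",
    "band_index",
    "segment_leaves",
    "extract_mean_spectra",
    "crop_bands",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpectralCube:
    """Reflectance cube indexed ``(row, col, band)`` with a wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Reflectance values, nominally in ``[0, ~1.2]`` (slightly above 1 is
        possible on specular background pixels).
    wavelengths : ndarray, shape (bands,)
        Band centers in nm, strictly increasing.
    meta : dict
        Free-form acquisition notes.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64) if not isinstance(
            self.data, np.ndarray
        ) else self.data
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band mismatch: data has {self.data.shape[2]} bands but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class LeafMask:
    """Integer label image: 0 = background, k = leaf k (reading order)."""

    labels: np.ndarray
    threshold_used: float
    band_used_nm: float

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_pixels(self, k: int) -> np.ndarray:
        """Boolean mask of region ``k`` (1-based)."""
        if not 1 <= k <= self.n_regions:
            raise ValueError(f"region {k} out of range 1..{self.n_regions}")
        return self.labels == k


@dataclass
class LabeledSpectra:
    """samples x bands reflectance matrix with polymer/concentration labels."""

    X: np.ndarray
    wavelengths: np.ndarray
    polymer: np.ndarray
    concentration: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.polymer = np.asarray(self.polymer, dtype=object)
        self.concentration = np.asarray(self.concentration)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = self.X.shape[0]
        for name, arr in (
            ("polymer", self.polymer),
            ("concentration", self.concentration),
            ("sample_ids", self.sample_ids),
        ):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} entries for {n} samples")
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but {self.wavelengths.size} wavelengths"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def class_codes(self) -> np.ndarray:
        """Concentration classes encoded 0..K-1 in increasing mg/L order."""
        levels = np.unique(self.concentration)
        lookup = {v: i for i, v in enumerate(levels)}
        return np.array([lookup[c] for c in self.concentration], dtype=np.int64)

    def subset(self, rows: np.ndarray | None = None, bands: np.ndarray | None = None) -> "LabeledSpectra":
        rows = np.arange(self.n_samples) if rows is None else np.asarray(rows)
        bands = np.arange(self.n_bands) if bands is None else np.asarray(bands)
        return LabeledSpectra(
            X=self.X[np.ix_(rows, bands)],
            wavelengths=self.wavelengths[bands],
            polymer=self.polymer[rows],
            concentration=self.concentration[rows],
            sample_ids=self.sample_ids[rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{w:.4f}" for w in self.wavelengths]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "class_mg_per_L", self.concentration)
        df.insert(0, "polymer", self.polymer)
        df.insert(0, "id", self.sample_ids)
        return df

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "LabeledSpectra":
        df = pd.read_csv(path)
        meta_cols = ["id", "polymer", "class_mg_per_L"]
        band_cols = [c for c in df.columns if c not in meta_cols]
        return cls(
            X=df[band_cols].to_numpy(dtype=np.float64),
            wavelengths=np.array([float(c) for c in band_cols]),
            polymer=df["polymer"].to_numpy(),
            concentration=df["class_mg_per_L"].to_numpy(),
            sample_ids=df["id"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# cube I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_cube(cube: SpectralCube, path: str | os.PathLike, format: str = "envi",
               interleave: str = "bsq") -> None:
    """Write a cube as ENVI header+raw (``format='envi'``) or HDF5.

    ENVI output produces ``<path>.hdr`` (text header with the wavelength
    list) plus ``<path>`` (raw binary, BSQ or BIL interleave, little
    endian).  HDF5 output stores datasets ``data`` and ``wavelengths`` plus
    a JSON-encoded ``meta`` attribute.  Round-tripping either format
    reproduces the array bitwise.
    """
    path = str(path)
    if format == "envi":
        _write_envi(cube, path, interleave)
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=cube.data)
            f.create_dataset("wavelengths", data=cube.wavelengths)
            f.attrs["meta"] = json.dumps(cube.meta)
    else:
        raise ValueError(f"unknown cube format {format!r} (expected 'envi' or 'hdf5')")


def read_cube(path: str | os.PathLike, format: str = "envi") -> SpectralCube:
    """Read a cube written by :func:`write_cube`.

    Raises a format error if the header's band count disagrees with the
    wavelength list, and refuses headers without wavelengths rather than
    inventing an index grid.
    """
    path = str(path)
    if format == "envi":
        return _read_envi(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "wavelengths" not in f:
                raise ValueError(f"{path}: no wavelengths dataset; refusing to guess")
            data = f["data"][()]
            wl = f["wavelengths"][()]
            meta = json.loads(f.attrs.get("meta", "{}"))
        if data.shape[2] != wl.size:
            raise ValueError(
                f"{path}: data declares {data.shape[2]} bands but "
                f"{wl.size} wavelengths are stored"
            )
        return SpectralCube(data=data, wavelengths=wl, meta=meta)
    raise ValueError(f"unknown cube format {format!r} (expected 'envi' or 'hdf5')")


def _write_envi(cube: SpectralCube, path: str, interleave: str) -> None:
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    rows, cols, bands = cube.shape
    dtype = cube.data.dtype
    if dtype not in _ENVI_CODES:
        raise ValueError(f"unsupported dtype {dtype} for ENVI output (float32/float64 only)")
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {leafspec reflectance cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(path + ".hdr", "w") as f:
        f.write(header)
    if interleave == "bsq":
        arr = np.ascontiguousarray(np.transpose(cube.data, (2, 0, 1)))
    else:  # bil: (lines, bands, samples)
        arr = np.ascontiguousarray(np.transpose(cube.data, (0, 2, 1)))
    arr.astype(dtype.newbyteorder("<")).tofile(path)
    if cube.meta:  # acquisition notes as a JSON sidecar (ENVI headers are flat text)
        with open(path + ".meta.json", "w") as f:
            json.dump(cube.meta, f)


def _parse_envi_header(hdr_path: str) -> dict:
    with open(hdr_path) as f:
        text = f.read()
    # collapse { ... } blocks onto single logical values
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.M | re.S):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _read_envi(path: str) -> SpectralCube:
    hdr_path = path + ".hdr"
    if not os.path.exists(hdr_path):
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path)
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as e:
        raise ValueError(f"{hdr_path}: missing required header field {e}") from None
    if "wavelength" not in fields:
        raise ValueError(f"{hdr_path}: header has no wavelength list; refusing to guess")
    wl = np.array(
        [float(t) for t in re.split(r"[,\s]+", fields["wavelength"].strip("{} \n")) if t]
    )
    if wl.size != bands:
        raise ValueError(
            f"{hdr_path}: header declares {bands} bands but lists {wl.size} wavelengths"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"{hdr_path}: unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<")
    raw = np.fromfile(path, dtype=dtype)
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(f"{path}: expected {expected} values, found {raw.size}")
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        raise ValueError(f"{hdr_path}: unsupported interleave {interleave!r}")
    meta = {}
    if os.path.exists(path + ".meta.json"):
        with open(path + ".meta.json") as f:
            meta = json.load(f)
    elif "description" in fields:
        meta = {"description": fields["description"].strip("{} ")}
    return SpectralCube(data=np.ascontiguousarray(data), wavelengths=wl, meta=meta)


# ---------------------------------------------------------------------------
# segmentation pipeline
# ---------------------------------------------------------------------------


def band_index(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band center nearest ``target_nm``; ties go to the lower wavelength.

    Targets farther than one grid spacing outside the grid are rejected.
    """
    wl = np.asarray(wavelengths, dtype=np.float64)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    if wl.size == 1:
        if target_nm != wl[0]:
            raise ValueError(f"target {target_nm} nm outside single-band grid {wl[0]} nm")
        return 0
    lo_margin = wl[1] - wl[0]
    hi_margin = wl[-1] - wl[-2]
    if target_nm < wl[0] - lo_margin or target_nm > wl[-1] + hi_margin:
        raise ValueError(
            f"target {target_nm} nm outside grid range "
            f"[{wl[0] - lo_margin}, {wl[-1] + hi_margin}] nm"
        )
    # argmin returns the first (= lower-wavelength) index on ties
    return int(np.argmin(np.abs(wl - target_nm)))


def segment_leaves(
    cube: SpectralCube,
    band_nm: float = 655.0,
    threshold: float = 0.6,
    min_area: int = 20,
) -> LeafMask:
    """Threshold-segment leaves from a bright background at one band.

    A pixel is classified as leaf iff its reflectance at the band nearest
    ``band_nm`` is strictly below ``threshold`` — chlorophyll absorbs in the
    red while the white board reflects.  Leaf pixels are grouped by
    8-connectivity; components below ``min_area`` pixels are dropped as
    noise.  Surviving regions are relabelled 1..n in reading order of their
    centroids.  An all-background or all-leaf scene is valid (0 or 1
    regions), not an error.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    b = band_index(cube.wavelengths, band_nm)
    leaf = cube.data[:, :, b] < threshold
    labels = measure.label(leaf, connectivity=2)
    if min_area > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        labels[np.isin(labels, small[small > 0])] = 0
    # relabel in reading order of centroids (top-to-bottom, then left-to-right)
    props = measure.regionprops(labels)
    order = sorted(props, key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros_like(labels)
    for new_label, p in enumerate(order, start=1):
        out[labels == p.label] = new_label
    return LeafMask(labels=out, threshold_used=threshold,
                    band_used_nm=float(cube.wavelengths[b]))


def extract_mean_spectra(
    cube: SpectralCube,
    mask: LeafMask,
    labels_metadata: Sequence[tuple[str, int]] | Mapping[int, tuple[str, int]] | None = None,
) -> LabeledSpectra:
    """Per-region arithmetic mean spectrum, one row per leaf in label order.

    ``labels_metadata`` attaches (polymer, concentration mg/L) to each
    region, either as a sequence aligned with region labels 1..n or as a
    mapping from region label.  Metadata naming a region with no pixels is
    an error.  Without metadata, placeholder labels are attached.
    """
    if mask.labels.shape != cube.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.labels.shape} != cube spatial shape {cube.data.shape[:2]}"
        )
    n = mask.n_regions
    if labels_metadata is None:
        meta = {k: ("unknown", -1) for k in range(1, n + 1)}
    elif isinstance(labels_metadata, Mapping):
        meta = dict(labels_metadata)
    else:
        meta = {k: tuple(v) for k, v in enumerate(labels_metadata, start=1)}
    counts = np.bincount(mask.labels.ravel(), minlength=n + 1)
    for k in meta:
        if not 1 <= k <= n or counts[k] == 0:
            raise ValueError(f"metadata references empty or missing region {k}")
    rows, polymers, concs, ids = [], [], [], []
    flat = cube.data.reshape(-1, cube.n_bands)
    lab = mask.labels.ravel()
    for k in range(1, n + 1):
        sel = lab == k
        if not sel.any():  # cannot happen after relabelling, guard anyway
            raise ValueError(f"region {k} has no pixels")
        rows.append(flat[sel].mean(axis=0))
        polymer, conc = meta.get(k, ("unknown", -1))
        polymers.append(polymer)
        concs.append(conc)
        ids.append(f"leaf_{k:03d}")
    X = np.array(rows) if rows else np.empty((0, cube.n_bands))
    return LabeledSpectra(
        X=X,
        wavelengths=cube.wavelengths.copy(),
        polymer=np.array(polymers, dtype=object),
        concentration=np.array(concs),
        sample_ids=np.array(ids, dtype=object),
    )


def crop_bands(
    spectra: LabeledSpectra, lo_nm: float = 425.0, hi_nm: float = 965.0
) -> LabeledSpectra:
    """Keep bands whose centers lie in the closed interval [lo_nm, hi_nm].

    The edge bands of the retained VNIR range carry most of the sensor
    noise, so spectra are cropped to the informative window before
    modelling.  Cropping to an interval covering the whole grid is the
    identity; an empty result is an error.
    """
    if lo_nm >= hi_nm:
        raise ValueError(f"invalid interval: lo {lo_nm} >= hi {hi_nm}")
    keep = np.flatnonzero((spectra.wavelengths >= lo_nm) & (spectra.wavelengths <= hi_nm))
    if keep.size == 0:
        raise ValueError(
            f"no bands inside [{lo_nm}, {hi_nm}] nm "
            f"(grid spans [{spectra.wavelengths[0]}, {spectra.wavelengths[-1]}] nm)"
        )
    return spectra.subset(bands=keep)
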