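"""Readers and writers for the connectome text formats.

The connectome is distributed as plain whitespace-delimited text: a directed
weights matrix, a symmetric tract-length matrix (mm), and a look-up table
(LUT) giving the ROI order, integer labels, names and abbreviations shared by
both matrices.  An optional labelled NIfTI volume maps ROI labels to voxels,
from which world-space centroids (and hence Euclidean inter-ROI distances)
are derived.

All matrix I/O round-trips values to at least 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger("macsim")
if not logger.handlers:  # library default: stderr handler, INFO
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class FormatError(ValueError):
    """Raised when an input file violates the expected text format."""


# --------------------------------------------------------------------------
# Parcellation / LUT
# --------------------------------------------------------------------------

#: default hemisphere grammar: a leading or trailing L/R token on the
#: abbreviation (e.g. "V1_L", "L_V1", "lV1", "V1.r").  Configurable because
#: the LUT grammar is not standardized across deposits.
HEMI_PREFIX = re.compile(r"^([lLrR])[_\-.]?(?=\S)")
HEMI_SUFFIX = re.compile(r"[_\-.]?([lLrR])$")


def infer_hemisphere(token: str, prefix: re.Pattern = HEMI_PREFIX,
                     suffix: re.Pattern = HEMI_SUFFIX) -> str | None:
    """Infer 'L'/'R' from an ROI abbreviation or name, or None."""
    m = suffix.search(token)
    if m:
        return m.group(1).upper()
    m = prefix.search(token)
    if m:
        return m.group(1).upper()
    return None


@dataclasses.dataclass
class Parcellation:
    """Ordered ROI set shared by the weights and tract-length matrices."""

    roi_ids: np.ndarray          # (N,) int, unique, LUT order
    names: list[str]
    abbreviations: list[str]
    hemisphere: np.ndarray       # (N,) unicode, 'L' or 'R'
    centroid_mm: np.ndarray | None = None   # (N, 3) world mm, NaN row = absent

    def __post_init__(self) -> None:
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        self.hemisphere = np.asarray(self.hemisphere, dtype="U1")
        if len(np.unique(self.roi_ids)) != self.n_rois:
            raise FormatError("duplicate ROI ids in parcellation")
        if not np.all(np.isin(self.hemisphere, ["L", "R"])):
            bad = np.where(~np.isin(self.hemisphere, ["L", "R"]))[0]
            raise FormatError(f"hemisphere unassigned for ROI rows {bad.tolist()}")
        if self.centroid_mm is not None:
            self.centroid_mm = np.asarray(self.centroid_mm, dtype=float)
            if self.centroid_mm.shape != (self.n_rois, 3):
                raise FormatError("centroid array must be (n_rois, 3)")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def euclidean_distances(self) -> np.ndarray:
        """Pairwise centroid distances in mm (NaN where a centroid is absent)."""
        if self.centroid_mm is None:
            raise ValueError("parcellation has no centroids")
        d = self.centroid_mm[:, None, :] - self.centroid_mm[None, :, :]
        return np.sqrt((d ** 2).sum(-1))


def read_lut(path: str | Path, *, columns: Sequence[int] = (0, 1, 2),
             hemi_from: str = "abbreviation",
             prefix: re.Pattern = HEMI_PREFIX,
             suffix: re.Pattern = HEMI_SUFFIX) -> Parcellation:
    """Read a look-up table: one whitespace-delimited record per ROI.

    ``columns`` gives the field positions of (id, name, abbreviation); the
    parser is deliberately tolerant of extra columns (colours etc.).
    Hemisphere is inferred from the ``hemi_from`` field ('abbreviation' or
    'name') with the configurable prefix/suffix grammar.
    """
    ids, names, abbrs = [], [], []
    bad_rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) <= max(columns):
            raise FormatError(f"LUT row {ln}: expected >= {max(columns)+1} fields")
        try:
            ids.append(int(parts[columns[0]]))
        except ValueError as exc:
            raise FormatError(f"LUT row {ln}: non-integer ROI id {parts[columns[0]]!r}") from exc
        names.append(parts[columns[1]])
        # abbreviation column may be absent in minimal LUTs; fall back to name
        abbrs.append(parts[columns[2]] if len(parts) > columns[2] else parts[columns[1]])
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate ROI ids in LUT: {dupes}")
    hemi = []
    source = abbrs if hemi_from == "abbreviation" else names
    for row, token in enumerate(source):
        h = infer_hemisphere(token, prefix, suffix)
        if h is None:
            bad_rows.append(row)
            h = "?"
        hemi.append(h)
    if bad_rows:
        raise FormatError(f"could not infer hemisphere for LUT rows {bad_rows}")
    return Parcellation(np.array(ids), names, abbrs, np.array(hemi))


def write_lut(path: str | Path, parc: Parcellation) -> None:
    lines = [f"{i}\t{n}\t{a}" for i, n, a in
             zip(parc.roi_ids, parc.names, parc.abbreviations)]
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Square matrices
# --------------------------------------------------------------------------

def read_square_matrix(path: str | Path, n_expected: int | None = None) -> np.ndarray:
    """Read a whitespace-delimited numeric N x N matrix (no header).

    Scientific notation is accepted; the parse is locale-independent.
    """
    path = Path(path)
    try:
        m = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric entry ({exc})") from exc
    if m.shape[0] != m.shape[1]:
        raise FormatError(f"{path.name}: non-square matrix {m.shape[0]}x{m.shape[1]}")
    if n_expected is not None and m.shape[0] != n_expected:
        raise FormatError(
            f"{path.name}: expected {n_expected} rows/columns, found {m.shape[0]}")
    if not np.all(np.isfinite(m)):
        i, j = np.argwhere(~np.isfinite(m))[0]
        raise FormatError(f"{path.name}: non-finite entry at row {i}, column {j}")
    return m


def write_square_matrix(path: str | Path, matrix: np.ndarray) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise FormatError("matrix must be square")
    np.savetxt(path, matrix, fmt="%.12e")


def read_timeseries(path: str | Path) -> np.ndarray:
    """Read an ROI x time series table (CSV or whitespace text)."""
    path = Path(path)
    delimiter = "," if path.suffix.lower() == ".csv" else None
    ts = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return ts


def write_timeseries(path: str | Path, ts: np.ndarray) -> None:
    np.savetxt(path, np.asarray(ts, dtype=float), delimiter=",", fmt="%.10g")


# --------------------------------------------------------------------------
# Labelled volumes -> centroids
# --------------------------------------------------------------------------

def roi_centroids(labelled_volume, roi_ids: Sequence[int]) -> np.ndarray:
    """Per-ROI centroid in world mm from a labelled NIfTI-like image.

    The centroid is the mean of voxel-center world coordinates over each
    label.  Labels absent from the image get a NaN centroid and a warning.
    ``labelled_volume`` is anything with ``get_fdata()``/``affine``
    (a ``nibabel`` image) or a path to one.
    """
    import nibabel as nib

    if isinstance(labelled_volume, (str, Path)):
        labelled_volume = nib.load(str(labelled_volume))
    data = np.asarray(labelled_volume.get_fdata()).round().astype(int)
    affine = labelled_volume.affine
    out = np.full((len(roi_ids), 3), np.nan)
    for k, label in enumerate(roi_ids):
        idx = np.argwhere(data == label)
        if idx.size == 0:
            logger.warning("label %d absent from labelled volume; centroid marked absent", label)
            continue
        vox = np.column_stack([idx, np.ones(len(idx))])
        world = vox @ affine.T
        out[k] = world[:, :3].mean(axis=0)
    return out


# --------------------------------------------------------------------------
# Config + run manifests
# --------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (a flat-ish mapping mirroring CLI flags)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config file must contain a mapping")
    return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def content_hash(obj) -> str:
    """Stable content hash of a JSON-serializable parameter structure."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(path: str | Path, *, stage: str, params: dict,
                   inputs: Sequence[str | Path] = (), seed: int | None = None) -> dict:
    """Write a JSON run manifest recording inputs, parameters, seed, version."""
    from macsim import __version__

    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {str(p): _hash_file(Path(p)) for p in inputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("wrote manifest %s (stage=%s)", path, stage)
    return manifest
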