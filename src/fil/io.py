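"""NIfTI categorical volumes, patch tiling, and the single-file model container.

Conventions: all spatial indexing is voxel-based, 0-based, half-open; the
affine of an input volume is carried through to outputs unchanged.  Within a
patch, voxels are ordered x fastest, then y, then z; patches are ordered the
same way on the patch grid.  Volumes whose dimensions are not multiples of
the patch size are zero-padded on the high side (pure reference-category
mass) and the padded voxels carry weight zero so they cannot bias fits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import nibabel as nib
import numpy as np

from .model import PatchModel, TrainConfig, TrainedModel
from .mrf import MRFPosterior, neighbour_ids
from .vem import PatchBasis

__all__ = [
    "CategoricalVolume",
    "VolumeHeader",
    "read_categorical",
    "read_weight",
    "write_probability",
    "write_labels",
    "tile",
    "untile",
    "pad_dims",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


@dataclass
class CategoricalVolume:
    """A 3D field of simplex scores: (X, Y, Z, M) explicit categories.

    The reference category is last and implicit; ``codes``, when present,
    gives the global integer code of each category including the reference
    (length M + 1, reference last).
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    codes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (X, Y, Z, M)")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.codes is not None:
            self.codes = np.asarray(self.codes, dtype=int)
            if self.codes.shape != (self.values.shape[-1] + 1,):
                raise ValueError("codes must have length M + 1 (reference last)")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_explicit(self) -> int:
        return self.values.shape[-1]

    @property
    def residual(self) -> np.ndarray:
        return 1.0 - self.values.sum(axis=-1)


@dataclass
class VolumeHeader:
    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    intent: str  # probability_4d | hard_label_3d | weight_3d


def _header(img, intent: str) -> VolumeHeader:
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("non-invertible affine")
    zooms = img.header.get_zooms()[:3]
    return VolumeHeader(
        dims=tuple(int(d) for d in img.shape[:3]),
        voxel_size=tuple(float(z) for z in zooms),
        affine=affine,
        intent=intent,
    )


def read_categorical(
    path: str | Path,
    n_categories: Optional[int] = None,
    codes: Optional[np.ndarray] = None,
    tol: float = 1e-3,
) -> tuple[CategoricalVolume, VolumeHeader]:
    """Read a categorical volume from NIfTI.

    Accepts a 4D probability volume whose last axis holds either the M
    explicit categories or all M + 1 categories (then the last channel is
    dropped after verifying per-voxel closure to within ``tol``), or a 3D
    integer label volume which is one-hot encoded against ``codes`` (the
    global code table, reference last; inferred from the data when omitted).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        hdr = _header(img, "probability_4d")
        data = data.astype(float)
        if data.min() < -tol or data.max() > 1.0 + tol:
            raise ValueError("probabilities outside [0, 1]")
        sums = data.sum(axis=-1)
        if n_categories is not None and data.shape[-1] == n_categories + 1:
            if np.any(np.abs(sums - 1.0) > tol):
                raise ValueError("per-voxel sums of a full simplex must be 1")
            data = data[..., :-1]
        elif n_categories is not None and data.shape[-1] != n_categories:
            raise ValueError(
                f"expected {n_categories} or {n_categories + 1} channels, "
                f"got {data.shape[-1]}"
            )
        elif n_categories is None and np.all(np.abs(sums - 1.0) <= tol):
            data = data[..., :-1]
        if data.sum(axis=-1).max() > 1.0 + tol:
            raise ValueError("explicit channel sums exceed 1")
        np.clip(data, 0.0, 1.0, out=data)
        return CategoricalVolume(data, hdr.affine, codes), hdr
    if data.ndim == 3:
        hdr = _header(img, "hard_label_3d")
        labels = np.asarray(np.rint(data), dtype=int)
        vol = one_hot(labels, codes)
        return vol, hdr
    raise ValueError("expected a 3D label or 4D probability volume")


def one_hot(labels: np.ndarray, codes: Optional[np.ndarray] = None,
            affine: Optional[np.ndarray] = None) -> CategoricalVolume:
    """One-hot encode an integer label volume against a global code table.

    When ``codes`` is omitted it is inferred: codes sorted ascending with the
    smallest (background) code rotated to the end as the reference.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if codes is None:
        codes = np.concatenate([present[1:], present[:1]])
    else:
        codes = np.asarray(codes, dtype=int)
        unknown = np.setdiff1d(present, codes)
        if unknown.size:
            raise ValueError(f"unknown label codes {unknown.tolist()}")
    explicit = codes[:-1]
    values = (labels[..., None] == explicit).astype(float)
    return CategoricalVolume(
        values, np.eye(4) if affine is None else affine, codes
    )


def write_probability(path: str | Path, vol: CategoricalVolume,
                      include_reference: bool = True) -> None:
    """Write a 4D probability NIfTI (full simplex by default)."""
    data = vol.values
    if include_reference:
        data = np.concatenate([data, vol.residual[..., None]], axis=-1)
    nib.save(nib.Nifti1Image(data.astype(np.float32), vol.affine), str(path))


def write_labels(path: str | Path, labels: np.ndarray,
                 affine: Optional[np.ndarray] = None) -> None:
    """Write a 3D integer hard-label NIfTI."""
    img = nib.Nifti1Image(
        np.asarray(labels, dtype=np.int32),
        np.eye(4) if affine is None else affine,
    )
    nib.save(img, str(path))


def read_weight(path: str | Path) -> tuple[np.ndarray, VolumeHeader]:
    """Read a 3D voxel-weight volume (e.g. Jacobian determinants)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError("weight volume must be 3D")
    if data.min() < 0 or not np.all(np.isfinite(data)):
        raise ValueError("weights must be finite and non-negative")
    return data, _header(img, "weight_3d")


# ---------------------------------------------------------------------------
# Patch tiling


def pad_dims(dims, patch_size) -> tuple[int, int, int]:
    """Volume dims rounded up to multiples of the patch size."""
    return tuple(
        -(-int(d) // int(p)) * int(p) for d, p in zip(dims, patch_size)
    )


def _pad(values: np.ndarray, patch_size) -> np.ndarray:
    dims = values.shape[:3]
    target = pad_dims(dims, patch_size)
    if tuple(dims) == target:
        return values
    pad = [(0, t - d) for d, t in zip(dims, target)]
    pad += [(0, 0)] * (values.ndim - 3)
    return np.pad(values, pad)


def tile(values: np.ndarray, patch_size) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Split a (X, Y, Z[, M]) volume into patches.

    Returns ``(patches, grid_dims)`` with ``patches`` of shape (P, I[, M]);
    the volume is zero-padded up to the grid first.  Within-patch voxel order
    is x fastest, then y, then z, and patches are ordered the same way.
    """
    scalar = values.ndim == 3
    v = values[..., None] if scalar else values
    v = _pad(v, patch_size)
    px, py, pz = patch_size
    gx, gy, gz = (s // p for s, p in zip(v.shape[:3], patch_size))
    m = v.shape[3]
    # (gx, px, gy, py, gz, pz, m) -> (gz, gy, gx, pz, py, px, m)
    blocks = v.reshape(gx, px, gy, py, gz, pz, m)
    blocks = blocks.transpose(4, 2, 0, 5, 3, 1, 6)
    patches = blocks.reshape(gx * gy * gz, px * py * pz, m)
    if scalar:
        patches = patches[..., 0]
    return np.ascontiguousarray(patches), (gx, gy, gz)


def untile(patches: np.ndarray, grid_dims, patch_size,
           out_dims=None) -> np.ndarray:
    """Inverse of :func:`tile`; crops to ``out_dims`` when given."""
    scalar = patches.ndim == 2
    p = patches[..., None] if scalar else patches
    gx, gy, gz = grid_dims
    px, py, pz = patch_size
    m = p.shape[-1]
    blocks = p.reshape(gz, gy, gx, pz, py, px, m)
    blocks = blocks.transpose(2, 5, 1, 4, 0, 3, 6)
    vol = blocks.reshape(gx * px, gy * py, gz * pz, m)
    if out_dims is not None:
        vol = vol[: out_dims[0], : out_dims[1], : out_dims[2]]
    if scalar:
        vol = vol[..., 0]
    return np.ascontiguousarray(vol)


# ---------------------------------------------------------------------------
# Model container (single HDF5 file; per-patch groups because K and the
# label subset vary across patches)


def _checksum(model: TrainedModel) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(model.label_codes, dtype=np.int64).tobytes())
    h.update(np.asarray(model.affine, dtype=np.float64).tobytes())
    for p in model.patches:
        for arr in (p.basis_image.W, p.basis_image.mu, p.basis_label.W,
                    p.basis_label.mu, p.mrf.Psi):
            h.update(np.asarray(arr, dtype=np.float64).tobytes())
        h.update(np.float64(p.mrf.nu).tobytes())
        h.update(np.asarray(p.label_subset, dtype=np.int64).tobytes())
    return h.hexdigest()


def save_model(path: str | Path, model: TrainedModel) -> None:
    """Write the model to a single HDF5 container (lossless round trip)."""
    import yaml

    with h5py.File(str(path), "w", track_order=True) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["checksum"] = _checksum(model)
        f.attrs["patch_size"] = model.patch_size
        f.attrs["grid_dims"] = model.grid_dims
        f.attrs["vol_dims"] = model.vol_dims
        f.attrs["n_image_categories"] = model.n_image_categories
        f.attrs["config"] = yaml.safe_dump(model.config.to_dict())
        f.create_dataset("label_codes", data=model.label_codes, track_times=False)
        f.create_dataset("affine", data=model.affine, track_times=False)
        for pid, p in enumerate(model.patches):
            g = f.create_group(f"patch/{pid:06d}")
            for name, arr in (
                ("W1", p.basis_image.W), ("mu1", p.basis_image.mu),
                ("W2", p.basis_label.W), ("mu2", p.basis_label.mu),
                ("Psi", p.mrf.Psi),
            ):
                g.create_dataset(name, data=np.asarray(arr, dtype=np.float64),
                                 track_times=False)
            g.attrs["nu"] = float(p.mrf.nu)
            g.attrs["k_self"] = int(p.mrf.k_self)
            g.create_dataset("label_subset", data=p.label_subset,
                             track_times=False)
            g.create_dataset(
                "mrf_layout",
                data=np.array([[q, kj] for q, kj in p.mrf.layout],
                              dtype=np.int64).reshape(-1, 2),
                track_times=False,
            )


def load_model(path: str | Path) -> TrainedModel:
    """Load a model container, verifying version and checksum."""
    import yaml

    with h5py.File(str(path), "r") as f:
        version = int(f.attrs["format_version"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        config = TrainConfig.from_dict(yaml.safe_load(f.attrs["config"]))
        grid_dims = tuple(int(x) for x in f.attrs["grid_dims"])
        patches = []
        for pid in range(int(np.prod(grid_dims))):
            g = f[f"patch/{pid:06d}"]
            layout = [(int(q), int(kj)) for q, kj in g["mrf_layout"][()]]
            patches.append(PatchModel(
                basis_image=PatchBasis(g["W1"][()], g["mu1"][()], "image"),
                basis_label=PatchBasis(g["W2"][()], g["mu2"][()], "label"),
                mrf=MRFPosterior(g["Psi"][()], float(g.attrs["nu"]),
                                 int(g.attrs["k_self"]), layout),
                label_subset=g["label_subset"][()],
            ))
        model = TrainedModel(
            patch_size=tuple(int(x) for x in f.attrs["patch_size"]),
            grid_dims=grid_dims,
            vol_dims=tuple(int(x) for x in f.attrs["vol_dims"]),
            n_image_categories=int(f.attrs["n_image_categories"]),
            label_codes=f["label_codes"][()],
            patches=patches,
            config=config,
            affine=f["affine"][()],
        )
        stored = f.attrs["checksum"]
    actual = _checksum(model)
    if stored != actual:
        raise ValueError("model container checksum mismatch (corrupt file?)")
    return model
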