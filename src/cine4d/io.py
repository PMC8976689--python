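"""Readers/writers and validation for all on-disk artifacts.

Conventions (binding package-wide): 0-based voxel indices, voxel-centre
convention, world coordinates in mm, displacement vectors in world axes.
Volumes and cine stacks are NIfTI-1 (spacing and origin in the header, RAS+
axis convention — x left-right, y posterior-anterior, z inferior-superior);
flow series, training sets and model weights use a documented array
container (NumPy ``.npz``) with a JSON manifest next to it.  Readers
validate and reject malformed input instead of silently coercing it.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import CineFrame, VolumeFrame
from .flow import FlowField, TrackedVoxelSet

FORMAT_VERSION = "1"


class ArtifactError(ValueError):
    """Malformed or inconsistent on-disk artifact."""


def config_hash(config_dict: dict) -> str:
    """Stable hash of a configuration mapping (canonical JSON, sha256)."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def make_manifest(kind: str, seed: int | None = None,
                  config: dict | None = None, **extra) -> dict:
    m = {"kind": kind, "version": FORMAT_VERSION}
    if seed is not None:
        m["seed"] = int(seed)
    if config is not None:
        m["config_hash"] = config_hash(config)
    m.update(extra)
    return m


# ---------------------------------------------------------------------------
# volumes (NIfTI-1)
# ---------------------------------------------------------------------------

def write_volume(frame: VolumeFrame, path) -> None:
    affine = np.diag(list(frame.spacing_mm) + [1.0])
    affine[:3, 3] = frame.origin_mm
    img = nib.Nifti1Image(frame.data, affine)
    img.header.set_xyzt_units("mm", "sec")
    img.header["descrip"] = f"modality={frame.modality};time_s={frame.time_s:.6f}".encode()
    nib.save(img, str(path))


def read_volume(path, modality: str | None = None, time_s: float | None = None
                ) -> VolumeFrame:
    """Read a NIfTI-1 volume, reorienting to the package axis convention.

    Non-canonical orientations (e.g. a flipped superior-inferior axis) are
    reoriented on read; oblique affines are rejected by name.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise ArtifactError(f"cannot read NIfTI volume {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-4):
        raise ArtifactError(
            f"unsupported oblique orientation in {path}: rotation part {rot.tolist()}")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ArtifactError(f"non-positive voxel spacing {spacing} in {path}")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ArtifactError(f"expected a 3D volume in {path}, got shape {data.shape}")
    descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="ignore")
    meta = dict(kv.split("=", 1) for kv in descrip.split(";") if "=" in kv)
    if modality is None:
        modality = meta.get("modality", "ct")
    if time_s is None:
        time_s = float(meta.get("time_s", 0.0))
    return VolumeFrame(data=data, spacing_mm=tuple(spacing),
                       origin_mm=tuple(aff[:3, 3]), modality=modality, time_s=time_s)


def write_volume_series(frames: list[VolumeFrame], path) -> None:
    """4D NIfTI stack plus a JSON sidecar with timestamps and modality."""
    path = Path(path)
    f0 = frames[0]
    for f in frames:
        f0.require_same_grid(f)
    affine = np.diag(list(f0.spacing_mm) + [1.0])
    affine[:3, 3] = f0.origin_mm
    stack = np.stack([f.data for f in frames], axis=-1)
    nib.save(nib.Nifti1Image(stack, affine), str(path))
    sidecar = {"kind": "volume_series", "version": FORMAT_VERSION,
               "modality": f0.modality, "times_s": [f.time_s for f in frames]}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_volume_series(path) -> list[VolumeFrame]:
    path = Path(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise ArtifactError(f"missing timestamp sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 4:
        raise ArtifactError(f"expected a 4D series in {path}")
    times = sidecar["times_s"]
    if len(times) != data.shape[3]:
        raise ArtifactError(
            f"sidecar lists {len(times)} timestamps but series has {data.shape[3]} frames")
    spacing = tuple(np.diag(img.affine[:3, :3]))
    origin = tuple(img.affine[:3, 3])
    return [VolumeFrame(data=data[..., i], spacing_mm=spacing, origin_mm=origin,
                        modality=sidecar.get("modality", "ct"), time_s=times[i])
            for i in range(data.shape[3])]


# ---------------------------------------------------------------------------
# cine stacks
# ---------------------------------------------------------------------------

def write_cine_stack(frames: list[CineFrame], path) -> None:
    """Cine sequence as one NIfTI stack (y, z, t) + JSON sidecar."""
    path = Path(path)
    f0 = frames[0]
    stack = np.stack([f.data for f in frames], axis=-1)
    affine = np.diag([f0.spacing_mm[0], f0.spacing_mm[1], 1.0, 1.0])
    affine[0, 3], affine[1, 3] = f0.origin_mm
    nib.save(nib.Nifti1Image(stack, affine), str(path))
    sidecar = {"kind": "cine_stack", "version": FORMAT_VERSION,
               "modality": f0.modality, "slab_x_mm": f0.slab_x_mm,
               "times_s": [f.time_s for f in frames],
               "frame_indices": [f.frame_index for f in frames]}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_cine_stack(path) -> list[CineFrame]:
    path = Path(path)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if not sidecar_path.exists():
        raise ArtifactError(f"missing timestamp sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ArtifactError(f"expected a (y, z, t) cine stack in {path}")
    times = sidecar["times_s"]
    if len(times) != data.shape[2]:
        raise ArtifactError("sidecar/stack frame count mismatch")
    spacing = (float(img.affine[0, 0]), float(img.affine[1, 1]))
    origin = (float(img.affine[0, 3]), float(img.affine[1, 3]))
    return [CineFrame(data=data[..., i], spacing_mm=spacing, time_s=times[i],
                      frame_index=sidecar["frame_indices"][i],
                      modality=sidecar.get("modality", "mr"),
                      slab_x_mm=sidecar.get("slab_x_mm", 0.0), origin_mm=origin)
            for i in range(data.shape[2])]


# ---------------------------------------------------------------------------
# flow series (.npz + manifest)
# ---------------------------------------------------------------------------

def write_flow_series(flows: list[FlowField], tracked: TrackedVoxelSet, path,
                      seed: int | None = None, config: dict | None = None) -> None:
    path = Path(path)
    vectors = np.stack([f.vectors_mm for f in flows])        # (T, N, 3)
    times = np.array([f.time_s for f in flows])
    ref_times = np.array([f.reference_time_s for f in flows])
    np.savez(path.with_suffix(".npz"), vectors_mm=vectors, times_s=times,
             reference_times_s=ref_times,
             voxel_indices=tracked.voxel_indices, roi_box_mm=tracked.roi_box_mm)
    manifest = make_manifest("flow_series", seed=seed, config=config,
                             n_tracked=tracked.n, n_frames=len(flows),
                             ordering="time-major; vectors (T, N, 3) mm, world axes")
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_flow_series(path) -> tuple[list[FlowField], TrackedVoxelSet]:
    path = Path(path)
    manifest_path = path.with_suffix(".json")
    if not manifest_path.exists():
        raise ArtifactError(f"missing manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("kind") != "flow_series":
        raise ArtifactError(f"{path} is not a flow series (kind={manifest.get('kind')!r})")
    try:
        with np.load(path.with_suffix(".npz")) as z:
            vectors = z["vectors_mm"]
            times = z["times_s"]
            ref_times = z["reference_times_s"]
            tracked = TrackedVoxelSet(z["voxel_indices"], z["roi_box_mm"])
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as exc:
        raise ArtifactError(f"corrupt or truncated flow series {path}: {exc}") from exc
    if vectors.ndim != 3 or vectors.shape[2] != 3:
        raise ArtifactError(f"flow array must be (T, N, 3), got {vectors.shape}")
    if vectors.shape[1] != manifest["n_tracked"] or vectors.shape[1] != tracked.n:
        raise ArtifactError(
            f"manifest N={manifest['n_tracked']} does not match array N={vectors.shape[1]}")
    if vectors.shape[0] != manifest["n_frames"]:
        raise ArtifactError("manifest/array frame count mismatch")
    flows = [FlowField(vectors_mm=vectors[i], time_s=float(times[i]),
                       reference_time_s=float(ref_times[i]))
             for i in range(vectors.shape[0])]
    return flows, tracked


# ---------------------------------------------------------------------------
# artifact checksums
# ---------------------------------------------------------------------------

def artifact_checksum(root) -> str:
    """Content checksum of an artifact tree, stable across reruns.

    Hashes decoded contents, not container bytes: ``.npz`` members as raw
    array bytes, ``.nii``/``.nii.gz`` as the decompressed NIfTI stream,
    text artifacts (``.json``/``.yaml``) as text — so archive-level
    timestamps cannot leak into the digest.  Files are visited in sorted
    relative-path order.
    """
    import gzip

    root = Path(root)
    if not root.exists():
        raise ArtifactError(f"no artifact at {root}")
    files = sorted(p for p in ([root] if root.is_file() else root.rglob("*"))
                   if p.is_file())
    h = hashlib.sha256()
    for p in files:
        rel = p.name if root.is_file() else p.relative_to(root).as_posix()
        h.update(rel.encode())
        suffixes = "".join(p.suffixes)
        if p.suffix == ".npz":
            with np.load(p) as z:
                for key in sorted(z.files):
                    arr = z[key]
                    h.update(key.encode())
                    h.update(str(arr.dtype).encode())
                    h.update(str(arr.shape).encode())
                    h.update(np.ascontiguousarray(arr).tobytes())
        elif suffixes.endswith(".nii.gz"):
            h.update(gzip.decompress(p.read_bytes()))
        elif p.suffix in (".json", ".yaml", ".yml", ".txt", ".nii"):
            h.update(p.read_bytes())
        else:
            h.update(p.read_bytes())
    return h.hexdigest()
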