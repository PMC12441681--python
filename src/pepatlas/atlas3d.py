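"""3D atlas construction from registered section stacks.

Binarized per-peptide section masks are stacked along z (section thickness
10 um by default, against an in-plane microscopy pixel size), triangulated
with marching cubes, and written out as one STL mesh per peptide plus a
JSON scene manifest carrying names and display colors.  Voxels stay
anisotropic; vertices are scaled into um rather than resampling the data.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import measure

from .colocalization import BinaryMask

DEFAULT_SECTION_THICKNESS_UM = 10.0


@dataclass
class Volume:
    """Boolean/scalar voxel grid; axis 0 is z (section index)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (z, y, x) um
    downsample: int = 1  # recorded in-plane downsampling factor

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def physical_extent(self) -> tuple[float, float, float]:
        """(z, y, x) size in um."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing))


@dataclass
class Mesh:
    """Triangle mesh in um coordinates with a display color tag."""

    vertices: np.ndarray  # (V, 3) float, (z, y, x) order in um
    faces: np.ndarray  # (F, 3) int vertex indices
    name: str = ""
    color: tuple[int, int, int] = (200, 200, 200)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices must be finite")

    @property
    def n_triangles(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) triangle corner coordinates."""
        return self.vertices[self.faces]

    def normals(self) -> np.ndarray:
        """Unit face normals from the right-hand rule (zero-area -> 0)."""
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


def assemble_volume(
    masks: Sequence[BinaryMask | np.ndarray],
    spacing: tuple[float, float, float] = (DEFAULT_SECTION_THICKNESS_UM, 1.0, 1.0),
    downsample: int = 1,
) -> Volume:
    """Stack ordered per-section masks along z into a volume.

    Section order must be physical order.  An optional integer in-plane
    ``downsample`` factor (block max, preserving thin structures) keeps
    whole-stack volumes tractable and is recorded on the result.
    """
    grids = [np.asarray(m.grid if isinstance(m, BinaryMask) else m) for m in masks]
    if grids:
        shape = grids[0].shape
        for i, g in enumerate(grids):
            if g.shape != shape:
                raise ValueError(f"section {i} shape {g.shape} != {shape}")
    vol = np.stack(grids, axis=0) if grids else np.zeros((0, 0, 0), dtype=bool)
    if downsample > 1 and vol.size:
        z, h, w = vol.shape
        h2, w2 = h // downsample * downsample, w // downsample * downsample
        vol = vol[:, :h2, :w2]
        vol = vol.reshape(z, h2 // downsample, downsample, w2 // downsample, downsample)
        vol = vol.max(axis=(2, 4))
        spacing = (spacing[0], spacing[1] * downsample, spacing[2] * downsample)
    return Volume(voxels=vol, spacing=spacing, downsample=downsample)


def volume_to_mesh(
    volume: Volume, level: float = 0.5, name: str = "", color: tuple[int, int, int] = (200, 200, 200)
) -> Mesh:
    """Marching-cubes isosurface of a volume, vertices in um.

    The volume is zero-padded by one voxel per side so foreground touching
    the stack boundary still yields a closed surface; padding is compensated
    so vertex coordinates land in the volume's physical frame (voxel i
    center at (i + 0.5) * spacing).  Level 0.5 is the natural choice for
    boolean volumes.
    """
    vox = volume.voxels.astype(float)
    if vox.size == 0 or vox.max() <= level:
        raise ValueError("volume has no foreground above the iso level")
    padded = np.pad(vox, 1, mode="constant", constant_values=0.0)
    verts, faces, _, _ = measure.marching_cubes(padded, level=level, spacing=volume.spacing)
    offset = np.asarray(volume.spacing) * 0.5  # pad shift (-1 voxel) + center convention (+0.5)
    return Mesh(vertices=verts - offset, faces=faces, name=name, color=color)


# ---------------------------------------------------------------------------
# STL I/O (binary layout: 80-byte header, uint32 count, 50 bytes/triangle)


def write_stl(mesh: Mesh, path: str | Path, mode: str = "binary") -> Path:
    """Write a mesh as binary (default) or ASCII STL."""
    if mesh.n_triangles == 0:
        raise ValueError("refusing to write an STL with zero triangles")
    path = Path(path)
    tri = mesh.triangles().astype(np.float32)
    normals = mesh.normals().astype(np.float32)
    if mode == "binary":
        with open(path, "wb") as fh:
            header = (mesh.name or "pepatlas mesh").encode()[:80]
            fh.write(header.ljust(80, b"\0"))
            fh.write(struct.pack("<I", mesh.n_triangles))
            record = np.zeros(
                mesh.n_triangles,
                dtype=np.dtype(
                    [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
                ),
            )
            record["normal"] = normals
            record["verts"] = tri
            fh.write(record.tobytes())
    elif mode == "ascii":
        lines = [f"solid {mesh.name or 'pepatlas'}"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:e} {n[1]:e} {n[2]:e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:e} {v[1]:e} {v[2]:e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {mesh.name or 'pepatlas'}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    return path


def read_stl(path: str | Path) -> Mesh:
    """Read binary or ASCII STL (autodetected) into an unmerged-vertex mesh."""
    path = Path(path)
    raw = path.read_bytes()
    is_ascii = raw.lstrip()[:5] == b"solid"
    if is_ascii:
        expected = 84 + 50 * struct.unpack("<I", raw[80:84])[0] if len(raw) >= 84 else -1
        if len(raw) == expected:
            is_ascii = False  # binary file whose header happens to start with 'solid'
    if is_ascii:
        verts = []
        for line in raw.decode().splitlines():
            parts = line.split()
            if parts and parts[0] == "vertex":
                verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        tri = np.asarray(verts, dtype=float).reshape(-1, 3, 3)
    else:
        n = struct.unpack("<I", raw[80:84])[0]
        record = np.frombuffer(
            raw,
            dtype=np.dtype(
                [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
            ),
            count=n,
            offset=84,
        )
        tri = record["verts"].astype(float)
    n_tri = len(tri)
    vertices = tri.reshape(-1, 3)
    faces = np.arange(3 * n_tri).reshape(-1, 3)
    return Mesh(vertices=vertices, faces=faces, name=path.stem)


def write_scene_manifest(
    meshes: Sequence[Mesh], stl_paths: Sequence[str | Path], path: str | Path
) -> Path:
    """JSON manifest tying STL files to peptide names and display colors."""
    if len(meshes) != len(stl_paths):
        raise ValueError("one STL path per mesh required")
    payload = {
        "meshes": [
            {
                "name": m.name,
                "stl": str(Path(p).name),
                "color": list(m.color),
                "n_triangles": m.n_triangles,
            }
            for m, p in zip(meshes, stl_paths)
        ]
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path
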