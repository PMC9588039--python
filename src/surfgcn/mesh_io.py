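"""Surface-mesh I/O, rigid alignment, template-graph assembly and feature encoding.

All downstream machinery (Laplacians, spectral filters, the network) operates on a
single *template graph*: the disjoint union of the triangulation graphs of every
structure surface (left/right cortex plus up to seven subcortical structures per
hemisphere).  Subjects are assumed registered vertex-to-vertex to the template, so
the graph is shared and only the per-vertex coordinate features differ per subject.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "STRUCTURE_ORDER",
    "CORTICAL_LABELS",
    "SUBCORTICAL_LABELS",
    "SurfaceMesh",
    "SubjectRecord",
    "TemplateGraph",
    "NodeFeatureMatrix",
    "read_surface",
    "write_surface",
    "rigid_align",
    "assemble_template_graph",
    "encode_features",
    "read_scores",
]

CORTICAL_LABELS = ("cortex_inner", "cortex_outer")
SUBCORTICAL_LABELS = (
    "amygdala",
    "accumbens",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)
VALID_LABELS = CORTICAL_LABELS + SUBCORTICAL_LABELS
HEMISPHERES = ("left", "right")

#: Canonical concatenation order of graph-node blocks.  Cortical inner/outer
#: surfaces share one node block per hemisphere (a cortical graph node carries
#: both inner and outer coordinates as features), so the node blocks are:
#: left cortex, right cortex, then each subcortical structure left-then-right.
STRUCTURE_ORDER: tuple[tuple[str, str], ...] = (
    ("cortex", "left"),
    ("cortex", "right"),
) + tuple((s, h) for s in SUBCORTICAL_LABELS for h in HEMISPHERES)


class MeshFormatError(ValueError):
    """Raised when a surface file is malformed for the requested dialect."""


class CorrespondenceError(ValueError):
    """Raised when vertex counts/orderings of two meshes do not correspond."""


@dataclass
class SurfaceMesh:
    """A triangulated surface: vertex coordinates in mm plus face indices.

    ``structure_label`` and ``hemisphere`` place the mesh within the combined
    template; they may be None for anonymous meshes read straight from disk.
    """

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int
    structure_label: str | None = None
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be triangles (m, 3)")
        n = self.vertices.shape[0]
        if n <= 3:
            raise MeshFormatError("a surface mesh needs more than 3 vertices")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshFormatError("face indices out of range")
        if self.faces.size:
            f = self.faces
            if (
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            ).any():
                raise MeshFormatError("degenerate face: repeated vertex in a face")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def edge_adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        """Symmetric adjacency of the triangulation edges.

        Unit weights by default; ``weighted=True`` uses inverse Euclidean edge
        length instead.
        """
        i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
        j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
        n = self.n_vertices
        if weighted:
            d = np.linalg.norm(self.vertices[i] - self.vertices[j], axis=1)
            w = 1.0 / np.maximum(d, 1e-12)
        else:
            w = np.ones(i.shape[0])
        a = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
        a = a.maximum(a.T)
        a.setdiag(0.0)
        a.eliminate_zeros()
        return a


@dataclass
class SubjectRecord:
    """One subject: registered meshes plus the raw (and normalized) trait score."""

    subject_id: str
    meshes: dict[tuple[str, str], SurfaceMesh]  # key: (structure_label, hemisphere)
    raw_score: float
    normalized_score: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.raw_score):
            raise ValueError(f"raw_score for {self.subject_id} is not finite")


@dataclass
class TemplateGraph:
    """The shared graph G = (V, E, A) of all structure surfaces.

    ``partition`` maps each vertex to its (structure, hemisphere) block and
    ``component_offsets`` gives each block's start index in the concatenation
    order of :data:`STRUCTURE_ORDER` (restricted to the structures present).
    """

    n: int
    adjacency: sp.csr_matrix
    coordinates: np.ndarray  # (n, 3) template positions (inner surface for cortex)
    partition: list[tuple[str, str]]  # per-block (structure, hemisphere)
    component_offsets: dict[tuple[str, str], int]
    component_sizes: dict[tuple[str, str], int]

    def block_slice(self, structure: str, hemisphere: str) -> slice:
        off = self.component_offsets[(structure, hemisphere)]
        return slice(off, off + self.component_sizes[(structure, hemisphere)])

    def vertex_blocks(self) -> np.ndarray:
        """Integer block id per vertex, in STRUCTURE_ORDER order."""
        out = np.empty(self.n, dtype=np.int64)
        for b, key in enumerate(self.partition):
            out[self.block_slice(*key)] = b
        return out

    def is_cortical(self) -> np.ndarray:
        """Boolean mask of cortical vertices."""
        mask = np.zeros(self.n, dtype=bool)
        for key in self.partition:
            if key[0] == "cortex":
                mask[self.block_slice(*key)] = True
        return mask

    def checksum(self) -> int:
        """Cheap structural fingerprint used to pair models with their template."""
        a = self.adjacency.tocoo()
        h = (
            self.n * 1_000_003
            + int(a.nnz) * 101
            + int(np.round(self.coordinates.sum() * 1e3)) % (2**31)
        )
        return h & 0x7FFFFFFF


@dataclass
class NodeFeatureMatrix:
    """Per-node input features X in [0, 1]^{n x f}.

    Layout by mode: ``subcortical_only`` -> f=3 (x, y, z); ``cortical_only`` ->
    f=6 (inner xyz, outer xyz); ``combined`` -> f=9 where subcortical rows fill
    columns 0..2 (rest zero) and cortical rows fill columns 3..8 (first three
    zero).
    """

    values: np.ndarray
    mode: str

    MODES = ("cortical_only", "subcortical_only", "combined")
    WIDTH = {"cortical_only": 6, "subcortical_only": 3, "combined": 9}

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[1] != self.WIDTH[self.mode]:
            raise ValueError(
                f"mode {self.mode} expects {self.WIDTH[self.mode]} features, "
                f"got {self.values.shape[1]}"
            )


# ---------------------------------------------------------------------------
# Surface file formats
# ---------------------------------------------------------------------------


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    mesh = trimesh.load(str(path), file_type="ply", process=False)
    if not hasattr(mesh, "faces") or mesh.faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: not a triangulated PLY surface")
    return np.asarray(mesh.vertices, dtype=np.float64), np.asarray(
        mesh.faces, dtype=np.int64
    )


def _read_gifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    img = nib.load(str(path))
    verts = faces = None
    for da in img.darrays:
        code = da.intent
        if code == 1008:  # NIFTI_INTENT_POINTSET
            verts = np.asarray(da.data, dtype=np.float64)
        elif code == 1009:  # NIFTI_INTENT_TRIANGLE
            faces = np.asarray(da.data, dtype=np.int64)
    if verts is None or faces is None:
        raise MeshFormatError(f"{path}: GIfTI file lacks pointset/triangle arrays")
    return verts, faces


def _read_freesurfer(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel.freesurfer as fsio

    verts, faces = fsio.read_geometry(str(path))
    return np.asarray(verts, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def read_surface(
    path: str | Path,
    format: str,
    structure_label: str | None = None,
    hemisphere: str | None = None,
) -> SurfaceMesh:
    """Read a triangulated surface in FreeSurfer binary, GIfTI, or PLY format.

    Vertex order is preserved exactly as stored, which is what guarantees
    vertex-to-vertex correspondence across registered subjects.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"surface file not found: {path}")
    readers = {"ply": _read_ply, "gifti": _read_gifti, "freesurfer": _read_freesurfer}
    if format not in readers:
        raise ValueError(f"unknown surface format {format!r}")
    try:
        verts, faces = readers[format](path)
    except MeshFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise IOError(f"could not read {format} surface from {path}: {exc}") from exc
    return SurfaceMesh(verts, faces, structure_label, hemisphere)


def write_surface(mesh: SurfaceMesh, path: str | Path, format: str) -> None:
    """Write a surface in the named dialect (inverse of :func:`read_surface`)."""
    path = Path(path)
    if format == "ply":
        import trimesh

        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        path.write_bytes(tm.export(file_type="ply"))
    elif format == "gifti":
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif format == "freesurfer":
        import nibabel.freesurfer as fsio

        fsio.write_geometry(str(path), mesh.vertices, mesh.faces)
    else:
        raise ValueError(f"unknown surface format {format!r}")


# ---------------------------------------------------------------------------
# Rigid alignment (orthogonal Procrustes without scaling or reflection)
# ---------------------------------------------------------------------------


def rigid_align(mesh: SurfaceMesh, template: SurfaceMesh) -> SurfaceMesh:
    """Least-squares rigid-body (rotation + translation) alignment to a template.

    Uses the Kabsch solution with the determinant sign corrected so the
    transform is a proper rotation: anatomy is preserved, mirror images are
    never introduced.  Vertex correspondence is by index.
    """
    if mesh.n_vertices != template.n_vertices:
        raise CorrespondenceError(
            f"vertex count mismatch: {mesh.n_vertices} vs {template.n_vertices}"
        )
    x = mesh.vertices
    y = template.vertices
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    h = (x - cx).T @ (y - cy)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    aligned = (x - cx) @ r.T + cy
    return SurfaceMesh(aligned, mesh.faces.copy(), mesh.structure_label, mesh.hemisphere)


# ---------------------------------------------------------------------------
# Template graph assembly
# ---------------------------------------------------------------------------


def _node_key(mesh: SurfaceMesh) -> tuple[str, str]:
    """Map a mesh to its graph-node block (cortex inner/outer share a block)."""
    if mesh.structure_label in CORTICAL_LABELS:
        return ("cortex", mesh.hemisphere)
    return (mesh.structure_label, mesh.hemisphere)


def assemble_template_graph(
    meshes: Iterable[SurfaceMesh], weighted_edges: bool = False
) -> TemplateGraph:
    """Disjoint union of per-structure triangulation graphs.

    Cortical inner and outer surfaces for a hemisphere must share a
    triangulation; they contribute one node block whose graph is the inner
    surface's edge graph.  Blocks are concatenated in the fixed
    :data:`STRUCTURE_ORDER` so that vertex indexing is stable regardless of the
    order in which meshes are supplied.
    """
    by_label: dict[tuple[str, str], SurfaceMesh] = {}
    for mesh in meshes:
        if mesh.structure_label not in VALID_LABELS or mesh.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"mesh has invalid structure/hemisphere: "
                f"{mesh.structure_label}/{mesh.hemisphere}"
            )
        key = (mesh.structure_label, mesh.hemisphere)
        if key in by_label:
            raise ValueError(f"duplicate structure: {key}")
        by_label[key] = mesh

    blocks: list[tuple[tuple[str, str], SurfaceMesh]] = []
    for key in STRUCTURE_ORDER:
        if key[0] == "cortex":
            inner = by_label.get(("cortex_inner", key[1]))
            outer = by_label.get(("cortex_outer", key[1]))
            if inner is None and outer is None:
                continue
            if inner is None or outer is None:
                raise ValueError(
                    f"{key[1]} cortex requires both inner and outer surfaces"
                )
            if inner.n_vertices != outer.n_vertices or not np.array_equal(
                inner.faces, outer.faces
            ):
                raise CorrespondenceError(
                    f"{key[1]} cortex inner/outer surfaces do not share a triangulation"
                )
            blocks.append((key, inner))
        else:
            mesh = by_label.get(key)
            if mesh is not None:
                blocks.append((key, mesh))
    if not blocks:
        raise ValueError("no meshes supplied")

    adjs = [m.edge_adjacency(weighted=weighted_edges) for _, m in blocks]
    adjacency = sp.block_diag(adjs, format="csr")
    coords = np.vstack([m.vertices for _, m in blocks])
    offsets: dict[tuple[str, str], int] = {}
    sizes: dict[tuple[str, str], int] = {}
    pos = 0
    for (key, m) in blocks:
        offsets[key] = pos
        sizes[key] = m.n_vertices
        pos += m.n_vertices
    return TemplateGraph(
        n=pos,
        adjacency=adjacency,
        coordinates=coords,
        partition=[key for key, _ in blocks],
        component_offsets=offsets,
        component_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------


def _minmax01(values: np.ndarray) -> np.ndarray:
    """Min-max normalize each column to [0, 1]; zero-range columns map to 0."""
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    rng = hi - lo
    out = np.zeros_like(values)
    ok = rng > 0
    out[:, ok] = (values[:, ok] - lo[ok]) / rng[ok]
    return out


def encode_features(
    subject: SubjectRecord, template: TemplateGraph, mode: str
) -> NodeFeatureMatrix:
    """Encode a subject's registered vertex coordinates as node features.

    Cortical nodes carry 6 coordinates (inner then outer surface xyz),
    subcortical nodes carry 3; in combined mode both live in one 9-wide matrix
    with structure-dependent zero padding.  Coordinates are min-max normalized
    to [0, 1] per subject and per axis over all vertices of the active mode.
    """
    if mode not in NodeFeatureMatrix.MODES:
        raise ValueError(f"unknown mode {mode!r}")

    want_cortex = mode in ("cortical_only", "combined")
    want_sub = mode in ("subcortical_only", "combined")

    raw_cols: dict[tuple[str, str], np.ndarray] = {}
    for key in template.partition:
        structure, hemi = key
        size = template.component_sizes[key]
        if structure == "cortex":
            if not want_cortex:
                raw_cols[key] = np.zeros((size, 0))
                continue
            inner = subject.meshes.get(("cortex_inner", hemi))
            outer = subject.meshes.get(("cortex_outer", hemi))
            if inner is None or outer is None:
                raise ValueError(
                    f"subject {subject.subject_id} lacks {hemi} cortex surfaces "
                    f"required by mode {mode}"
                )
            if inner.n_vertices != size or outer.n_vertices != size:
                raise CorrespondenceError(
                    f"subject {subject.subject_id} {hemi} cortex vertex count "
                    f"does not match the template"
                )
            raw_cols[key] = np.hstack([inner.vertices, outer.vertices])
        else:
            if not want_sub:
                raw_cols[key] = np.zeros((size, 0))
                continue
            mesh = subject.meshes.get(key)
            if mesh is None:
                raise ValueError(
                    f"subject {subject.subject_id} lacks {structure}/{hemi} "
                    f"required by mode {mode}"
                )
            if mesh.n_vertices != size:
                raise CorrespondenceError(
                    f"subject {subject.subject_id} {structure}/{hemi} vertex "
                    f"count does not match the template"
                )
            raw_cols[key] = mesh.vertices

    # Normalization: gather every active coordinate, normalize each x/y/z axis
    # over all active vertices of this subject, then scatter into the layout.
    axis_vals: list[np.ndarray] = []  # rows of (x, y, z) triples
    for key in template.partition:
        cols = raw_cols[key]
        for s in range(0, cols.shape[1], 3):
            axis_vals.append(cols[:, s : s + 3])
    if not axis_vals:
        raise ValueError(f"mode {mode} selects no structures present in the template")
    stacked = np.vstack(axis_vals)
    lo = stacked.min(axis=0)
    rng = stacked.max(axis=0) - lo

    def norm(cols: np.ndarray) -> np.ndarray:
        out = np.zeros_like(cols)
        for s in range(0, cols.shape[1], 3):
            for a in range(3):
                if rng[a] > 0:
                    out[:, s + a] = (cols[:, s + a] - lo[a]) / rng[a]
        return out

    f = NodeFeatureMatrix.WIDTH[mode]
    values = np.zeros((template.n, f))
    for key in template.partition:
        structure, _ = key
        block = template.block_slice(*key)
        cols = norm(raw_cols[key])
        if cols.shape[1] == 0:
            continue
        if mode == "combined":
            if structure == "cortex":
                values[block, 3:9] = cols
            else:
                values[block, 0:3] = cols
        else:
            values[block, : cols.shape[1]] = cols
    return NodeFeatureMatrix(values, mode)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a `subject_id,score` delimited table (comma or tab separated)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"subject_id": str})
    if "subject_id" not in df.columns or "score" not in df.columns:
        raise ValueError(f"{path}: expected columns subject_id,score")
    if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite scores present")
    return df
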