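"""Prepared-cohort container: template, hierarchy, and per-subject features.

A prepared dataset stores, per subject, the *raw* registered coordinate
triples (in mm) rather than normalized features, because training-time
augmentation (random rotations + coordinate noise) must act on raw
coordinates before the per-subject min-max normalization.  The container can
be persisted to HDF5 (`/template`, `/hierarchy`, `/subjects/<id>`).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.sparse as sp

from .graph_hierarchy import GraphHierarchy, _Level, build_laplacian
from .mesh_io import NodeFeatureMatrix, SubjectRecord, TemplateGraph

__all__ = ["PreparedDataset", "prepare_dataset", "save_dataset", "load_dataset"]


def _feature_layout(template: TemplateGraph, mode: str):
    """Rows/columns where each subject coordinate triple lands in the (n, f) matrix.

    Returns (triple_rows, triple_cols, sources) where sources names the mesh
    each triple comes from: (structure_label, hemisphere) with cortex split
    into inner/outer.
    """
    rows: list[np.ndarray] = []
    cols: list[int] = []
    sources: list[tuple[str, str]] = []
    want_cortex = mode in ("cortical_only", "combined")
    want_sub = mode in ("subcortical_only", "combined")
    cortex_base = 3 if mode == "combined" else 0
    for key in template.partition:
        structure, hemi = key
        block = template.block_slice(*key)
        idx = np.arange(block.start, block.stop)
        if structure == "cortex" and want_cortex:
            rows += [idx, idx]
            cols += [cortex_base, cortex_base + 3]
            sources += [("cortex_inner", hemi), ("cortex_outer", hemi)]
        elif structure != "cortex" and want_sub:
            rows.append(idx)
            cols.append(0)
            sources.append((structure, hemi))
    return rows, cols, sources


@dataclass
class PreparedDataset:
    """A cohort ready for training: shared graph machinery + per-subject data."""

    mode: str
    template: TemplateGraph
    hierarchy: GraphHierarchy | None
    subject_ids: list[str]
    raw_coords: np.ndarray  # (S, m, 3) active coordinate triples, mm
    raw_scores: np.ndarray  # (S,)
    normalized_scores: np.ndarray  # (S,) standard-Gaussian units
    triple_rows: list[np.ndarray]
    triple_cols: list[int]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return NodeFeatureMatrix.WIDTH[self.mode]

    def scatter_features(self, coords: np.ndarray) -> np.ndarray:
        """(m, 3) raw triples -> min-max-normalized (n, f) feature matrix."""
        lo = coords.min(axis=0)
        rng = coords.max(axis=0) - lo
        safe = np.where(rng > 0, rng, 1.0)
        normed = np.where(rng > 0, (coords - lo) / safe, 0.0)
        x = np.zeros((self.template.n, self.n_features))
        pos = 0
        for rows, col in zip(self.triple_rows, self.triple_cols):
            x[rows, col : col + 3] = normed[pos : pos + rows.shape[0]]
            pos += rows.shape[0]
        return x

    def features(self, index: int) -> np.ndarray:
        """Normalized (n, f) features of one subject (no augmentation)."""
        return self.scatter_features(self.raw_coords[index])

    def padded_features(self, indices, coords_override=None) -> np.ndarray:
        """(B, n_padded, f) batch in the hierarchy's padded ordering."""
        if self.hierarchy is None:
            raise ValueError("dataset has no hierarchy attached")
        out = []
        for j, i in enumerate(indices):
            coords = (
                self.raw_coords[i] if coords_override is None else coords_override[j]
            )
            out.append(self.hierarchy.pad_features(self.scatter_features(coords)))
        return np.stack(out)


def prepare_dataset(
    subjects: list[SubjectRecord],
    template: TemplateGraph,
    mode: str,
    hierarchy: GraphHierarchy | None = None,
) -> PreparedDataset:
    """Assemble a cohort: extract each subject's raw coordinate triples.

    ``normalized_scores`` is copied from the subject records if present (see
    :func:`surfgcn.training.quantile_normalize`); otherwise raw scores are
    carried over unchanged.
    """
    triple_rows, triple_cols, sources = _feature_layout(template, mode)
    m = sum(r.shape[0] for r in triple_rows)
    raw = np.empty((len(subjects), m, 3))
    for s, subj in enumerate(subjects):
        pos = 0
        for rows, (label, hemi) in zip(triple_rows, sources):
            mesh = subj.meshes.get((label, hemi))
            if mesh is None:
                raise ValueError(
                    f"subject {subj.subject_id} lacks {label}/{hemi} for mode {mode}"
                )
            if mesh.n_vertices != rows.shape[0]:
                raise ValueError(
                    f"subject {subj.subject_id} {label}/{hemi} vertex count "
                    f"mismatch with template"
                )
            raw[s, pos : pos + rows.shape[0]] = mesh.vertices
            pos += rows.shape[0]
    raw_scores = np.array([s.raw_score for s in subjects], dtype=float)
    normed = np.array(
        [
            s.normalized_score if s.normalized_score is not None else s.raw_score
            for s in subjects
        ],
        dtype=float,
    )
    return PreparedDataset(
        mode=mode,
        template=template,
        hierarchy=hierarchy,
        subject_ids=[s.subject_id for s in subjects],
        raw_coords=raw,
        raw_scores=raw_scores,
        normalized_scores=normed,
        triple_rows=triple_rows,
        triple_cols=triple_cols,
    )


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------


def _save_csr(group: h5py.Group, name: str, matrix: sp.csr_matrix) -> None:
    g = group.create_group(name)
    g.create_dataset("data", data=matrix.data)
    g.create_dataset("indices", data=matrix.indices)
    g.create_dataset("indptr", data=matrix.indptr)
    g.attrs["shape"] = matrix.shape


def _load_csr(group: h5py.Group, name: str) -> sp.csr_matrix:
    g = group[name]
    return sp.csr_matrix(
        (g["data"][...], g["indices"][...], g["indptr"][...]),
        shape=tuple(g.attrs["shape"]),
    )


def save_dataset(dataset: PreparedDataset, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["mode"] = dataset.mode
        t = fh.create_group("template")
        _save_csr(t, "adjacency", sp.csr_matrix(dataset.template.adjacency))
        t.create_dataset("coordinates", data=dataset.template.coordinates)
        keys = [f"{s}|{h}" for s, h in dataset.template.partition]
        t.create_dataset("partition", data=np.array(keys, dtype="S64"))
        t.create_dataset(
            "offsets",
            data=np.array(
                [dataset.template.component_offsets[k] for k in dataset.template.partition]
            ),
        )
        t.create_dataset(
            "sizes",
            data=np.array(
                [dataset.template.component_sizes[k] for k in dataset.template.partition]
            ),
        )
        if dataset.hierarchy is not None:
            h = fh.create_group("hierarchy")
            h.attrs["seed"] = dataset.hierarchy.seed
            h.create_dataset("perm0", data=dataset.hierarchy.perm0)
            _save_csr(h, "interp_weights", dataset.hierarchy.interp_weights)
            for lvl, level in enumerate(dataset.hierarchy.levels):
                g = h.create_group(f"level{lvl}")
                _save_csr(g, "adjacency", level.adjacency)
                g.create_dataset("fake_mask", data=level.fake_mask)
                g.attrs["n_real"] = level.n_real
                n = level.n_padded
                g.create_dataset("parent", data=np.arange(n) // 2)
        subs = fh.create_group("subjects")
        for i, sid in enumerate(dataset.subject_ids):
            g = subs.create_group(sid)
            g.create_dataset("raw_coords", data=dataset.raw_coords[i])
            g.create_dataset("features", data=dataset.features(i))
            g.create_dataset("score", data=dataset.raw_scores[i])
            g.create_dataset("normalized_score", data=dataset.normalized_scores[i])
        fh.attrs["subject_order"] = np.array(dataset.subject_ids, dtype="S64")


def load_dataset(path) -> PreparedDataset:
    with h5py.File(path, "r") as fh:
        mode = fh.attrs["mode"]
        t = fh["template"]
        partition = [
            tuple(k.decode().split("|")) for k in t["partition"][...]
        ]
        offsets = dict(zip(partition, (int(v) for v in t["offsets"][...])))
        sizes = dict(zip(partition, (int(v) for v in t["sizes"][...])))
        adjacency = _load_csr(t, "adjacency")
        template = TemplateGraph(
            n=adjacency.shape[0],
            adjacency=adjacency,
            coordinates=t["coordinates"][...],
            partition=partition,
            component_offsets=offsets,
            component_sizes=sizes,
        )
        hierarchy = None
        if "hierarchy" in fh:
            h = fh["hierarchy"]
            levels = []
            lvl = 0
            while f"level{lvl}" in h:
                g = h[f"level{lvl}"]
                adj = _load_csr(g, "adjacency")
                levels.append(
                    _Level(
                        adjacency=adj,
                        laplacian=build_laplacian(adj, "normalized"),
                        n_padded=adj.shape[0],
                        n_real=int(g.attrs["n_real"]),
                        fake_mask=g["fake_mask"][...].astype(bool),
                    )
                )
                lvl += 1
            hierarchy = GraphHierarchy(
                levels=levels,
                perm0=h["perm0"][...],
                n_original=template.n,
                interp_weights=_load_csr(h, "interp_weights"),
                seed=int(h.attrs["seed"]),
            )
        ids = [s.decode() for s in fh.attrs["subject_order"]]
        raw = np.stack([fh["subjects"][sid]["raw_coords"][...] for sid in ids])
        scores = np.array([float(fh["subjects"][sid]["score"][()]) for sid in ids])
        normed = np.array(
            [float(fh["subjects"][sid]["normalized_score"][()]) for sid in ids]
        )
    triple_rows, triple_cols, _ = _feature_layout(template, mode)
    return PreparedDataset(
        mode=mode,
        template=template,
        hierarchy=hierarchy,
        subject_ids=ids,
        raw_coords=raw,
        raw_scores=scores,
        normalized_scores=normed,
        triple_rows=triple_rows,
        triple_cols=triple_cols,
    )
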