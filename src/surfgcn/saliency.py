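"""Graph Grad-CAM: which mesh regions drive the network's prediction.

For a subject, let A^k be the k-th feature map of the deepest convolutional
layer (the post residual block's final conv) and y the scalar prediction.
Channel importance is the node-averaged gradient alpha^k = (1/N) sum_n
dy/dA^k_n, and the relevance map is M = ReLU(sum_k alpha^k A^k): only
positively contributing channels are kept.  Coarse maps are interpolated back
to the full template with the hierarchy's upsampling operator, averaged over
subjects (and fold ensembles), and compared between runs with a spatial
Pearson correlation across vertices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph_hierarchy import GraphHierarchy, upsample_map
from .mesh_io import TemplateGraph
from .model import Model

__all__ = [
    "SaliencyMap",
    "gradcam",
    "full_resolution_map",
    "average_maps",
    "spatial_correlation",
    "export_map",
]


@dataclass
class SaliencyMap:
    """Nonnegative per-node relevance values at a hierarchy level."""

    values: np.ndarray
    level: int
    mode: str | None = None
    subject: str | None = None
    fold: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if (self.values < -1e-12).any():
            raise ValueError("saliency values must be nonnegative")
        self.values = np.maximum(self.values, 0.0)


def gradcam(model: Model, features: np.ndarray, subject: str | None = None,
            fold: int | None = None) -> SaliencyMap:
    """Grad-CAM relevance of one subject at the deepest convolutional layer.

    ``features`` is the (n_padded, f) input of a single subject (or a
    (1, n_padded, f) batch).  Runs the network in evaluation mode, backpropagates
    d y / d activations to the last conv layer, and combines its feature maps
    with the node-averaged gradient weights followed by a ReLU.  Fake padding
    nodes are excluded from both the average and the returned map.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 2:
        features = features[None]
    if features.shape[0] != 1:
        raise ValueError("gradcam expects a single subject")
    model.eval_mode()
    pred = model.forward(features)
    model.zero_grad()
    model.backward(np.ones_like(pred))
    conv = model.last_conv
    if conv.last_output is None or conv.grad_output is None:
        raise RuntimeError("model has no cached conv activations")
    level = model.config.pool_levels
    fake = model.hierarchy.levels[level].fake_mask
    # conv caches use the network's internal (n, B, channels) layout
    acts = conv.last_output[:, 0, :].astype(np.float64)
    grads = conv.grad_output[:, 0, :].astype(np.float64)
    real = ~fake
    n_real = int(real.sum())
    alpha = grads[real].sum(axis=0) / n_real  # (channels,)
    raw = acts[real] @ alpha
    return SaliencyMap(values=np.maximum(raw, 0.0), level=level,
                       subject=subject, fold=fold)


def full_resolution_map(coarse: SaliencyMap, hierarchy: GraphHierarchy,
                        model: Model | None = None) -> SaliencyMap:
    """Interpolate a coarse relevance map back to the full template mesh."""
    if model is not None and model.hierarchy is not hierarchy:
        if model.hierarchy.n_original != hierarchy.n_original:
            raise ValueError("hierarchy does not match the model's template")
    full = upsample_map(coarse.values, hierarchy, level=coarse.level)
    return SaliencyMap(values=np.maximum(full, 0.0), level=0, mode=coarse.mode,
                       subject=coarse.subject, fold=coarse.fold)


def average_maps(maps: list[SaliencyMap]) -> SaliencyMap:
    """Elementwise arithmetic mean of same-length relevance maps."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or m.level != first.level:
            raise ValueError("maps differ in length or level")
    stacked = np.stack([m.values for m in maps])
    return SaliencyMap(values=stacked.mean(axis=0), level=first.level,
                       mode=first.mode)


def ensemble_gradcam(models: list[Model], features: np.ndarray,
                     subject: str | None = None,
                     fold: int | None = None) -> SaliencyMap:
    """Per-subject map of an ensemble: the mean of the member models' maps."""
    maps = [gradcam(m, features, subject=subject, fold=fold) for m in models]
    out = average_maps(maps)
    out.subject, out.fold = subject, fold
    return out


def spatial_correlation(map1: SaliencyMap, map2: SaliencyMap,
                        template: TemplateGraph | None = None,
                        scope: str = "all") -> float:
    """Pearson correlation of two maps across a vertex scope.

    ``scope`` selects cortical, subcortical, or all vertices via the template
    partition (required for the restricted scopes).  Raises if either map has
    zero variance over the scope.
    """
    a, b = map1.values, map2.values
    if a.shape != b.shape:
        raise ValueError("maps have different lengths")
    if scope != "all":
        if template is None:
            raise ValueError("scoped correlation requires the template graph")
        cortical = template.is_cortical()
        mask = cortical if scope == "cortical" else ~cortical
        a, b = a[mask], b[mask]
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError(f"zero variance over scope {scope!r}; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def export_map(map_: SaliencyMap, template: TemplateGraph, out_dir,
               format: str = "csv") -> list[Path]:
    """Write a full-resolution map per structure (CSV, GIfTI functional, or
    FreeSurfer curvature overlay).  Returns the written paths."""
    if map_.level != 0 or map_.values.shape[0] != template.n:
        raise ValueError("export requires a full-resolution map on this template")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for key in template.partition:
        structure, hemi = key
        vals = map_.values[template.block_slice(*key)]
        stem = out_dir / f"{hemi}_{structure}"
        if format == "csv":
            path = stem.with_suffix(".csv")
            np.savetxt(path, vals, fmt="%.8g", header="saliency", comments="")
        elif format == "gifti":
            import nibabel as nib

            img = nib.gifti.GiftiImage(
                darrays=[nib.gifti.GiftiDataArray(vals.astype(np.float32))]
            )
            path = Path(str(stem) + ".func.gii")
            nib.save(img, str(path))
        elif format == "freesurfer":
            import nibabel.freesurfer as fsio

            path = stem.with_suffix(".curv")
            fsio.write_morph_data(str(path), vals)
        else:
            raise ValueError(f"unknown export format {format!r}")
        written.append(path)
    return written
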