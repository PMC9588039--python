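"""Synthetic registered-mesh cohorts with a planted shape-score relationship.

Real cohorts (restricted-access MRI derivatives) are replaced by subdivided
icospheres standing in for the cortical hemispheres and the fourteen
subcortical structures.  Every subject shares the template triangulation;
per-subject vertex coordinates carry (a) a smooth nuisance deformation (a
random combination of low-order spherical harmonics, emulating anatomically
plausible inter-subject variation) and (b) a localized radial Gaussian bump
whose amplitude linearly determines the trait score, plus observation noise.
The planted effect region gives every pipeline stage — training, evaluation,
and saliency localization — a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .mesh_io import (
    SUBCORTICAL_LABELS,
    SubjectRecord,
    SurfaceMesh,
    TemplateGraph,
    assemble_template_graph,
)

__all__ = ["SyntheticSpec", "generate_template", "generate_cohort",
           "effect_region_vertices", "icosphere_vertex_count"]


def icosphere_vertex_count(subdivisions: int) -> int:
    """Closed form 10 * 4^s + 2 for a subdivided icosahedron."""
    return 10 * 4**subdivisions + 2


# Stand-in layout (mm): hemispheres flank the midline, small subcortical
# spheres sit beneath.  Positions are schematic, not anatomical.
_CORTEX_RADIUS_INNER = 48.0
_CORTEX_RADIUS_OUTER = 51.0
_CORTEX_CENTER_X = 55.0
_SUBCORTICAL_RADIUS = {
    "amygdala": 6.0,
    "accumbens": 5.0,
    "caudate": 9.0,
    "hippocampus": 9.0,
    "pallidum": 7.0,
    "putamen": 8.0,
    "thalamus": 10.0,
}
_SUBCORTICAL_CENTER = {
    "amygdala": (22.0, -4.0, -22.0),
    "accumbens": (10.0, 10.0, -10.0),
    "caudate": (14.0, 10.0, 12.0),
    "hippocampus": (28.0, -22.0, -14.0),
    "pallidum": (20.0, -2.0, 0.0),
    "putamen": (26.0, 2.0, 2.0),
    "thalamus": (12.0, -18.0, 8.0),
}


@dataclass
class SyntheticSpec:
    """Cohort-generation settings.

    Defaults define the package's reference study conditions: depth-3
    hemisphere stand-ins (642 vertices each), depth-1 subcortical spheres
    (42 vertices each), 300 subjects, a 20 mm-radius effect region on the
    left cortex, and score noise at 20% of the signal standard deviation
    (signal SD = |effect_beta| * bump_amplitude_sd).
    """

    cortex_subdivisions: int = 3
    subcortical_subdivisions: int = 1
    n_subjects: int = 300
    effect_structure: tuple[str, str] = ("cortex", "left")
    effect_center_vertex: int = 0
    effect_geodesic_radius: float = 20.0  # mm along the sphere surface
    effect_beta: float = 1.0  # score units per mm of bump amplitude
    bump_amplitude_sd: float = 2.0  # mm; inter-subject morphology varies at mm scale
    nuisance_sd: float = 1.0  # mm, SD of the smooth deformation field
    nuisance_n_harmonics: int = 10
    nuisance_max_degree: int = 4
    noise_sd: float = 0.4  # score units: 20% of the signal SD (beta * bump SD)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bump_amplitude_sd", "nuisance_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.effect_geodesic_radius <= 0:
            raise ValueError("effect_geodesic_radius must be positive")


def _icosphere(subdivisions: int, radius: float, center: np.ndarray,
               mirror_x: bool) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if mirror_x:
        verts = verts * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1]  # restore consistent orientation
    return verts + center, faces


def generate_template(spec: SyntheticSpec) -> tuple[dict, TemplateGraph]:
    """Build the shared template meshes and their combined graph.

    Returns ``(meshes, graph)`` where ``meshes`` maps (structure_label,
    hemisphere) to a :class:`SurfaceMesh`; the cortex appears twice per
    hemisphere (inner and outer surfaces sharing one triangulation).
    """
    meshes: dict[tuple[str, str], SurfaceMesh] = {}
    for hemi, sign in (("left", -1.0), ("right", 1.0)):
        center = np.array([sign * _CORTEX_CENTER_X, 0.0, 0.0])
        v_in, faces = _icosphere(spec.cortex_subdivisions, _CORTEX_RADIUS_INNER,
                                 center, mirror_x=(sign < 0))
        # outer surface: same unit directions, larger radius
        v_out = center + (v_in - center) * (_CORTEX_RADIUS_OUTER / _CORTEX_RADIUS_INNER)
        meshes[("cortex_inner", hemi)] = SurfaceMesh(v_in, faces, "cortex_inner", hemi)
        meshes[("cortex_outer", hemi)] = SurfaceMesh(v_out, faces, "cortex_outer", hemi)
        for label in SUBCORTICAL_LABELS:
            off = np.array(_SUBCORTICAL_CENTER[label])
            c = np.array([sign * off[0], off[1], off[2] - 30.0])
            v, f = _icosphere(spec.subcortical_subdivisions,
                              _SUBCORTICAL_RADIUS[label], c, mirror_x=(sign < 0))
            meshes[(label, hemi)] = SurfaceMesh(v, f, label, hemi)
    graph = assemble_template_graph(meshes.values())
    return meshes, graph


def _structure_center(label: str, hemi: str) -> np.ndarray:
    sign = -1.0 if hemi == "left" else 1.0
    if label.startswith("cortex"):
        return np.array([sign * _CORTEX_CENTER_X, 0.0, 0.0])
    off = np.array(_SUBCORTICAL_CENTER[label])
    return np.array([sign * off[0], off[1], off[2] - 30.0])


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic of degree l, order m (theta: polar, phi: azimuth)."""
    from scipy.special import sph_harm_y

    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return np.real(y)
    if m > 0:
        return np.sqrt(2.0) * np.real(y)
    return np.sqrt(2.0) * np.imag(y)


def _bump_profile(unit_dirs: np.ndarray, center_dir: np.ndarray, radius_mm: float,
                  sphere_radius: float) -> np.ndarray:
    """Gaussian radial-displacement profile over geodesic distance, truncated at
    the region boundary's 2-sigma point (sigma = radius / 2)."""
    cosang = np.clip(unit_dirs @ center_dir, -1.0, 1.0)
    geodesic = sphere_radius * np.arccos(cosang)
    sigma = radius_mm / 2.0
    prof = np.exp(-0.5 * (geodesic / sigma) ** 2)
    prof[geodesic > 2.0 * radius_mm] = 0.0
    return prof


def effect_region_vertices(spec: SyntheticSpec, template: TemplateGraph) -> np.ndarray:
    """Template-graph vertex indices inside the planted effect region."""
    label, hemi = spec.effect_structure
    block = template.block_slice(label, hemi)
    center = _structure_center("cortex_inner" if label == "cortex" else label, hemi)
    coords = template.coordinates[block]
    dirs = coords - center
    radii = np.linalg.norm(dirs, axis=1)
    dirs = dirs / radii[:, None]
    c_dir = dirs[spec.effect_center_vertex]
    geodesic = radii.mean() * np.arccos(np.clip(dirs @ c_dir, -1.0, 1.0))
    local = np.nonzero(geodesic <= spec.effect_geodesic_radius)[0]
    return local + block.start


def generate_cohort(
    template_meshes: dict, spec: SyntheticSpec, template: TemplateGraph | None = None
) -> tuple[list[SubjectRecord], dict]:
    """Draw a cohort of deformed subjects with planted amplitudes and scores.

    Per subject: bump amplitude a ~ N(0, bump_amplitude_sd) radially displaces
    the effect region (inner and outer surfaces move together for the cortex);
    every structure additionally receives an independent smooth harmonic
    deformation; score = effect_beta * a + N(0, noise_sd).  Returns the
    subjects plus a ground-truth dict with the planted amplitudes.
    """
    label_eff, hemi_eff = spec.effect_structure
    eff_labels = (
        {("cortex_inner", hemi_eff), ("cortex_outer", hemi_eff)}
        if label_eff == "cortex"
        else {(label_eff, hemi_eff)}
    )
    rng = np.random.default_rng(spec.seed)

    # Precompute per-mesh geometry in spherical form.
    geo: dict[tuple[str, str], dict] = {}
    for key, mesh in template_meshes.items():
        center = _structure_center(*key)
        d = mesh.vertices - center
        r = np.linalg.norm(d, axis=1)
        u = d / r[:, None]
        theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
        phi = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2.0 * np.pi)
        geo[key] = {"center": center, "r": r, "u": u, "theta": theta, "phi": phi}

    # Fixed harmonic basis (l >= 1 keeps the field zero-mean over the sphere).
    lm_pairs: list[tuple[int, int]] = []
    for l in range(1, spec.nuisance_max_degree + 1):
        for m in range(-l, l + 1):
            lm_pairs.append((l, m))
    lm_idx = rng.choice(len(lm_pairs), size=spec.nuisance_n_harmonics, replace=False)
    basis: dict[tuple[str, str], np.ndarray] = {}
    for key, g in geo.items():
        cols = [
            _real_sph_harm(*lm_pairs[i], g["theta"], g["phi"]) for i in lm_idx
        ]
        basis[key] = np.stack(cols, axis=1)  # (n_vertices, n_harmonics)
    coef_scale = spec.nuisance_sd * np.sqrt(4.0 * np.pi / spec.nuisance_n_harmonics)

    # Bump profile over the effect structure's vertices.
    eff_key = ("cortex_inner", hemi_eff) if label_eff == "cortex" else (label_eff, hemi_eff)
    g_eff = geo[eff_key]
    if not 0 <= spec.effect_center_vertex < g_eff["u"].shape[0]:
        raise ValueError("effect_center_vertex outside the effect structure")
    profile = _bump_profile(
        g_eff["u"], g_eff["u"][spec.effect_center_vertex],
        spec.effect_geodesic_radius, g_eff["r"].mean(),
    )

    # Group structures so inner/outer cortex share one nuisance field.
    struct_groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for key in template_meshes:
        gkey = ("cortex", key[1]) if key[0].startswith("cortex") else key
        struct_groups.setdefault(gkey, []).append(key)

    subjects: list[SubjectRecord] = []
    amplitudes = np.empty(spec.n_subjects)
    for s in range(spec.n_subjects):
        a = rng.normal(0.0, spec.bump_amplitude_sd)
        amplitudes[s] = a
        meshes: dict[tuple[str, str], SurfaceMesh] = {}
        for gkey, members in struct_groups.items():
            coefs = rng.normal(0.0, coef_scale, size=spec.nuisance_n_harmonics)
            for key in members:
                g = geo[key]
                disp = basis[key] @ coefs
                if key in eff_labels:
                    disp = disp + a * profile
                verts = g["center"] + (g["r"] + disp)[:, None] * g["u"]
                tm = template_meshes[key]
                meshes[key] = SurfaceMesh(verts, tm.faces, key[0], key[1])
        score = spec.effect_beta * a + (
            rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        )
        subjects.append(
            SubjectRecord(subject_id=f"sub-{s:04d}", meshes=meshes, raw_score=score)
        )
    signal_var = spec.effect_beta**2 * spec.bump_amplitude_sd**2
    truth = {
        "amplitudes": amplitudes,
        "oracle_r": (
            spec.effect_beta * spec.bump_amplitude_sd
            / np.sqrt(signal_var + spec.noise_sd**2)
            if signal_var + spec.noise_sd**2 > 0
            else 0.0
        ),
    }
    return subjects, truth
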