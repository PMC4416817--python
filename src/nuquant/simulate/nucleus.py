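"""Ground-truthed interphase nucleus stacks.

Renders a three-channel (DAPI / lamin B / NUP153) ellipsoidal nucleus in
one of two architectural phenotypes:

``pre_mga``
    Chromatin fills the space between an interior DNA-free lacuna and the
    envelope, but *touches* the envelope only over a polar cap covering
    ``chromatin_contact_fraction`` of the surface — elsewhere a
    chromatin-free gap separates it from the lamina. NPC puncta are placed
    exclusively on the contacted cap when ``npc_conditional`` is set.
``post_mga``
    A thin chromatin rim lines the entire envelope, a clumpy chromatin
    network fills the interior, and NPC puncta cover the whole surface
    uniformly.

Envelope invaginations (inward capsules of either or both marker
channels), isolated intranuclear vesicles and extranuclear marker
clusters are rendered on request, and everything rendered is echoed in a
:class:`~nuquant.simulate.params.GroundTruth` record before optics are
applied.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ..errors import ParameterError
from ..phenotypes import Immunophenotype, NucleusPhenotype
from ..stack import DAPI, LAMIN, NUP, ImageStack
from . import _fields as F
from .params import (
    NUCLEUS_STREAMS,
    GroundTruth,
    NucleusPhenotypeParams,
    TruthStructure,
    spawn_streams,
)

# rendering constants (arbitrary intensity units, pre-noise)
_CHROMATIN_AMP = 100.0
_LAMIN_AMP = 120.0
_NPC_AMP = 900.0
_STRUCT_AMP = 400.0
_RIM_FRACTION = 0.15  # post-MGA rim thickness as fraction of radius
_GAP_UM = 0.6  # pre-MGA chromatin-envelope separation outside the contact cap
_TEXTURE_SIGMA_NM = 300.0
_TUBE_RADIUS_UM = 0.15
_VESICLE_RADIUS_UM = 0.18
_CLUSTER_RADIUS_UM = 0.12
_MIN_ANGULAR_SEP = 0.45  # rad, between placed invaginations/vesicles


def _separated_directions(rng, n, existing, cos_min=-1.0, cos_max=1.0, max_tries=400):
    """Sample n directions keeping an angular separation from each other and
    from ``existing`` (list mutated in place)."""
    out = []
    tries = 0
    while len(out) < n and tries < max_tries * max(n, 1):
        tries += 1
        d = F.sample_directions(rng, 1, cos_min, cos_max)[0]
        if all(np.arccos(np.clip(np.dot(d, e), -1, 1)) >= _MIN_ANGULAR_SEP for e in existing):
            out.append(d)
            existing.append(d)
    if len(out) < n:
        raise ParameterError(
            f"could not place {n} structures with angular separation "
            f"{_MIN_ANGULAR_SEP} rad; reduce counts"
        )
    return np.array(out)


def gen_solid_ellipsoid(
    semi_axes_um=(2.0, 2.0, 2.0),
    voxel_dims_nm=(125.0, 39.5, 39.5),
    amplitude: float = 100.0,
    margin_um: float = 2.0,
    psf_fwhm_nm=(130.0, 300.0),
    noise=(1.0, 2.0),
    seed: int = 0,
) -> Tuple[ImageStack, GroundTruth]:
    """Uniformly filled ellipsoid benchmark stack (single DAPI channel).

    The analytic-volume phantom used to validate segmentation accuracy:
    truth volume is the voxelised ellipsoid, and the analytic value
    ``4/3 pi a b c`` is known in closed form.
    """
    if any(a <= 0 for a in semi_axes_um):
        raise ParameterError("semi-axes must be positive (zero-volume ellipsoid)")
    axes = np.array(semi_axes_um)
    shape, center = F.grid_for_ellipsoid(tuple(semi_axes_um), margin_um, tuple(voxel_dims_nm))
    z, y, x = F.coordinate_axes(shape, center, tuple(voxel_dims_nm))
    inside = (z / axes[0]) ** 2 + (y / axes[1]) ** 2 + (x / axes[2]) ** 2 <= 1.0
    dapi = np.where(inside, amplitude, 0.0)
    rng_noise = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    channels = F.apply_optics({DAPI: dapi}, psf_fwhm_nm, noise, tuple(voxel_dims_nm), rng_noise)
    truth = GroundTruth(nucleus_mask=inside, extras={"center_um": center, "semi_axes_um": tuple(axes)})
    return ImageStack(channels=channels, voxel_dims=tuple(voxel_dims_nm)), truth


def gen_nucleus_stack(params: NucleusPhenotypeParams) -> Tuple[ImageStack, GroundTruth]:
    """Render one nucleus; returns the stack and its ground truth.

    Deterministic: identical parameters and seed give bit-identical
    output. Random substreams are consumed in the fixed order
    ``chromatin, npc, invaginations, vesicles, clusters, noise``.
    """
    rng = spawn_streams(params.seed, NUCLEUS_STREAMS)
    axes = np.array(params.semi_axes_um)
    shape, center = F.grid_for_ellipsoid(params.semi_axes_um, params.margin_um, params.voxel_dims_nm)
    z, y, x = F.coordinate_axes(shape, center, params.voxel_dims_nm)
    uz, uy, ux = z / axes[0], y / axes[1], x / axes[2]
    rho2 = uz ** 2 + uy ** 2 + ux ** 2
    rho = np.sqrt(rho2)
    nucleus = rho2 <= 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        dirz = np.where(rho > 0, uz / np.maximum(rho, 1e-12), 1.0)

    f = params.chromatin_contact_fraction
    cos_cap = 1.0 - 2.0 * f  # polar cap of surface-area fraction f
    in_cap = dirz >= cos_cap

    # ---------------------------------------------------------------- DAPI
    g = F.gaussian_random_field(shape, _TEXTURE_SIGMA_NM, params.voxel_dims_nm, rng["chromatin"])
    # moderate contrast keeps the DNA channel bimodal against background,
    # as in counterstained nuclei; clumpiness is carried by geometry (below)
    texture = np.clip(1.0 + 0.3 * g, 0.6, 1.5)
    # chromatin flush with the envelope is rendered as a dense, nearly
    # uniform layer (the lamina-associated layer in vivo): a broken or
    # patchy rim would defeat 3-D hole filling of the enclosed volume
    rim_zone = rho > 1.0 - _RIM_FRACTION
    texture = np.where(rim_zone, np.clip(1.0 + 0.2 * g, 0.8, 1.2), texture)
    dapi = np.zeros(shape, dtype=np.float64)
    lac = params.lacuna_radius_fraction
    gap_frac = _GAP_UM / float(np.min(axes))
    if params.phenotype is NucleusPhenotype.PRE_MGA:
        outer = np.where(in_cap, 1.0, 1.0 - gap_frac)
        chrom = (rho > lac) & (rho <= outer)
        dapi[chrom] = _CHROMATIN_AMP * texture[chrom]
    else:
        rim = rim_zone & (rho <= 1.0)
        interior = (rho <= 1.0 - _RIM_FRACTION) & (rho > lac)
        clumps = interior & (g > 0.3)  # ~38% fill: chromatin domain network
        dapi[rim] = _CHROMATIN_AMP * texture[rim]
        dapi[clumps] = _CHROMATIN_AMP * texture[clumps]

    # --------------------------------------------------------------- lamin
    # ~200 nm immunostained band on the interior side of the envelope:
    # thick enough to stay contiguous after anisotropic blurring
    lamin = np.zeros(shape, dtype=np.float64)
    lam_t = 0.20 / float(np.min(axes))
    band = (rho > 1.0 - lam_t) & (rho <= 1.0)
    lamin[band] = _LAMIN_AMP

    # ----------------------------------------------------------------- NPC
    area = F.ellipsoid_surface_area_um2(params.semi_axes_um)
    if params.npc_conditional:
        n_npc = int(round(params.npc_density_per_um2 * area * f))
        dirs = F.sample_directions(rng["npc"], n_npc, cos_min=cos_cap, cos_max=1.0)
    else:
        n_npc = int(round(params.npc_density_per_um2 * area))
        dirs = F.sample_directions(rng["npc"], n_npc)
    nup = np.zeros(shape, dtype=np.float64)
    dims_um = np.array(params.voxel_dims_nm) / 1000.0
    npc_pts = F.surface_point(dirs, axes) if n_npc else np.zeros((0, 3))
    for p in npc_pts:
        idx = np.round((p + center) / dims_um).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        nup[tuple(idx)] += _NPC_AMP
    npc_contacted = dirs[:, 0] >= cos_cap if n_npc else np.zeros(0, dtype=bool)

    # -------------------------------------------------------- invaginations
    structures = []
    placed_dirs: list = []
    for spec in params.invagination_spec:
        dd = _separated_directions(rng["invaginations"], spec.count, placed_dirs)
        for d in dd:
            p0 = F.surface_point(d, axes)[0]
            inward = -p0 / np.linalg.norm(p0)
            p1 = p0 + inward * spec.depth_um
            ph = spec.phenotype
            if ph in (Immunophenotype.NUP_POS_LAM_POS, Immunophenotype.NUP_POS_LAM_NEG):
                F.paint_tube(nup, p0, p1, _TUBE_RADIUS_UM, _STRUCT_AMP, center, params.voxel_dims_nm)
            if ph in (Immunophenotype.NUP_POS_LAM_POS, Immunophenotype.NUP_NEG_LAM_POS):
                F.paint_tube(lamin, p0, p1, _TUBE_RADIUS_UM, _STRUCT_AMP, center, params.voxel_dims_nm)
            mid = 0.5 * (p0 + p1) + center
            structures.append(
                TruthStructure("invagination", ph, tuple(mid), spec.depth_um)
            )

    # -------------------------------------------------------------- vesicles
    ves_dirs = _separated_directions(rng["vesicles"], params.vesicle_count, placed_dirs)
    for d in np.atleast_2d(ves_dirs) if params.vesicle_count else []:
        r = rng["vesicles"].uniform(0.25, 0.45)
        c = F.surface_point(d, axes)[0] * r  # at fractional radius r
        F.paint_ball(lamin, c, _VESICLE_RADIUS_UM, _STRUCT_AMP, center, params.voxel_dims_nm)
        structures.append(
            TruthStructure(
                "interior_vesicle", Immunophenotype.NUP_NEG_LAM_POS, tuple(c + center), _VESICLE_RADIUS_UM
            )
        )

    # -------------------------------------------------------------- clusters
    cluster_pts = np.zeros((0, 3))
    if params.extranuclear_cluster_mode != "none" and params.extranuclear_cluster_count:
        n_cl = params.extranuclear_cluster_count
        cdirs = F.sample_directions(rng["clusters"], n_cl)
        if params.extranuclear_cluster_mode == "dispersed":
            offs = rng["clusters"].uniform(0.9, 1.8, size=n_cl)
        else:  # envelope_proximal
            offs = rng["clusters"].uniform(0.25, 0.45, size=n_cl)
        surf = F.surface_point(cdirs, axes)
        norm = surf / np.linalg.norm(surf, axis=1, keepdims=True)
        cluster_pts = surf + norm * offs[:, None]
        for c in cluster_pts:
            F.paint_ball(nup, c, _CLUSTER_RADIUS_UM, _STRUCT_AMP, center, params.voxel_dims_nm)
            structures.append(
                TruthStructure(
                    "extranuclear_segment", Immunophenotype.NUP_POS_LAM_NEG, tuple(c + center), _CLUSTER_RADIUS_UM
                )
            )

    truth = GroundTruth(
        nucleus_mask=nucleus,
        structures=structures,
        npc_positions_um=npc_pts + center if n_npc else npc_pts,
        npc_contacted=npc_contacted,
        cluster_positions_um=cluster_pts + center if len(cluster_pts) else cluster_pts,
        contact_fraction=f,
        extras={
            "cap_cos": cos_cap,
            "center_um": center,
            "semi_axes_um": tuple(axes),
            "gap_um": _GAP_UM,
            "rim_fraction": _RIM_FRACTION,
        },
    )

    channels = F.apply_optics(
        {DAPI: dapi, LAMIN: lamin, NUP: nup},
        params.psf_fwhm_nm,
        params.noise,
        params.voxel_dims_nm,
        rng["noise"],
    )
    stack = ImageStack(channels=channels, voxel_dims=params.voxel_dims_nm)
    return stack, truth
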