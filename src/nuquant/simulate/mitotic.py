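"""Ground-truthed mitotic figures for marker-enrichment analyses.

The DNA channel is a rosette of chromatid blobs with a radial intensity
gradient (densest in the chromatid cores, decaying to cytoplasmic
background), textured by a smooth random field so its noise-free
intensity distribution is continuous. The ground-truth intensity-class
map is the seven-class equal-variance partition of that noise-free
channel. Marker events are then drawn multinomially over classes with
probability proportional to ``class_weights[c] * (voxels in class c)`` —
``class_weights`` of all ones is exactly the proportional null the
enrichment test checks against.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ..intensity import classify_voxels, fit_class_boundaries
from ..stack import DAPI, LAMIN, NUP, ImageStack
from . import _fields as F
from .params import MITOTIC_STREAMS, GroundTruth, MitoticParams, spawn_streams

_DNA_AMP = 200.0
_TEXTURE_SIGMA_NM = 250.0


def gen_mitotic_stack(params: MitoticParams) -> Tuple[ImageStack, GroundTruth]:
    """Render one mitotic plate; returns the stack and its ground truth.

    Substream order: ``chromatin, marker, noise``.
    """
    rng = spawn_streams(params.seed, MITOTIC_STREAMS)
    shape = tuple(params.shape)
    dims_um = np.array(params.voxel_dims_nm) / 1000.0
    center = tuple((n - 1) * d / 2.0 for n, d in zip(shape, dims_um))
    z, y, x = F.coordinate_axes(shape, center, params.voxel_dims_nm)

    # chromatid centres on a ring in the mid-plane (metaphase rosette)
    k = params.n_chromatids
    ang = rng["chromatin"].uniform(0, 2 * np.pi) + 2 * np.pi * np.arange(k) / k
    cz = rng["chromatin"].normal(0.0, 0.15, size=k)
    cy = params.plate_radius_um * 0.6 * np.sin(ang)
    cx = params.plate_radius_um * 0.6 * np.cos(ang)

    dna = np.zeros(shape, dtype=np.float64)
    s2 = params.chromatid_sigma_um ** 2
    for j in range(k):
        d2 = (z - cz[j]) ** 2 + (y - cy[j]) ** 2 + (x - cx[j]) ** 2
        dna += np.exp(-0.5 * d2 / s2)
    # radial falloff of the whole plate on top of the per-chromatid cores
    r2 = z ** 2 + y ** 2 + x ** 2
    dna *= np.exp(-0.5 * r2 / params.gradient_sigma_um ** 2)
    g = F.gaussian_random_field(shape, _TEXTURE_SIGMA_NM, params.voxel_dims_nm, rng["chromatin"])
    dna = _DNA_AMP * dna * np.clip(1.0 + 0.25 * g, 0.05, None)
    dna += 1.0 + 0.2 * np.clip(g, 0, None)  # faint cytoplasmic background

    # ground-truth class map: equal-variance partition of the clean channel
    cb = fit_class_boundaries(dna.ravel(), k=7, tol=1e-3)
    clean = ImageStack({DAPI: dna.astype(np.float32)}, tuple(params.voxel_dims_nm))
    region = np.ones(shape, dtype=bool)
    cmap = classify_voxels(clean, DAPI, region, cb)
    class_counts = cmap.class_counts()

    # marker events: multinomial over classes, weights x class size
    w = np.asarray(params.class_weights, dtype=np.float64)
    probs = w * class_counts
    probs = probs / probs.sum()
    marker_class_counts = rng["marker"].multinomial(params.n_marker_voxels, probs)
    nup = np.zeros(shape, dtype=np.float64)
    flat_labels = cmap.labels.ravel()
    marker_idx = []
    for c in range(7):
        n_c = int(marker_class_counts[c])
        if n_c == 0:
            continue
        pool = np.flatnonzero(flat_labels == c + 1)
        chosen = rng["marker"].choice(pool, size=n_c, replace=True)
        marker_idx.append(chosen)
        np.add.at(nup.ravel(), chosen, params.marker_amplitude)
    marker_idx = np.concatenate(marker_idx) if marker_idx else np.zeros(0, dtype=int)

    truth = GroundTruth(
        class_map=cmap.labels,
        class_counts=class_counts,
        marker_class_counts=marker_class_counts,
        extras={
            "boundaries": cb,
            "class_weights": tuple(params.class_weights),
            "marker_flat_indices": marker_idx,
            "center_um": center,
        },
    )

    channels = F.apply_optics(
        {DAPI: dna, NUP: nup, LAMIN: np.zeros(shape)},
        params.psf_fwhm_nm,
        params.noise,
        params.voxel_dims_nm,
        rng["noise"],
    )
    stack = ImageStack(channels=channels, voxel_dims=tuple(params.voxel_dims_nm))
    return stack, truth
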