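"""Parameter records and ground-truth containers for the simulators.

All physical sizes are micrometres unless a name says otherwise; voxel
dimensions are nanometres ``(dz, dy, dx)`` to match the imaging
convention. Every simulator consumes one integer master seed and derives
one substream per rendered component in a fixed, documented order, so the
same seed reproduces bit-identical output and adding puncta does not
perturb the chromatin texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..errors import ParameterError
from ..phenotypes import Immunophenotype, NucleusPhenotype
from ..stack import DEFAULT_VOXEL_DIMS

#: Substream order of the nucleus simulator (index into spawned seeds).
NUCLEUS_STREAMS = ("chromatin", "npc", "invaginations", "vesicles", "clusters", "noise")
#: Substream order of the mitotic simulator.
MITOTIC_STREAMS = ("chromatin", "marker", "noise")
#: Substream order of the read simulator.
READ_STREAMS = ("assignment", "starts")


def spawn_streams(seed: int, names: Sequence[str]) -> dict:
    """Independent generators, one per named component, in fixed order."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class InvaginationSpec:
    """One group of envelope invaginations to render."""

    phenotype: Immunophenotype
    count: int
    depth_um: float

    def __post_init__(self):
        self.phenotype = Immunophenotype(self.phenotype)
        if self.count < 0:
            raise ParameterError("invagination count must be >= 0")
        if self.depth_um <= 0:
            raise ParameterError("invagination depth must be positive")


@dataclass
class NucleusPhenotypeParams:
    """Geometry, phenotype and optics of one simulated interphase nucleus."""

    semi_axes_um: Tuple[float, float, float] = (2.0, 2.0, 2.0)  # (az, ay, ax)
    phenotype: NucleusPhenotype = NucleusPhenotype.PRE_MGA
    lacuna_radius_fraction: float = 0.35
    chromatin_contact_fraction: float = 0.5
    npc_density_per_um2: float = 10.0
    npc_conditional: bool = True
    invagination_spec: List[InvaginationSpec] = field(default_factory=list)
    vesicle_count: int = 0
    extranuclear_cluster_mode: str = "none"  # none | dispersed | envelope_proximal
    extranuclear_cluster_count: int = 30
    psf_fwhm_nm: Optional[Tuple[float, float]] = (130.0, 300.0)  # (lateral, axial)
    noise: Optional[Tuple[float, float]] = (1.0, 2.0)  # (Poisson scale, Gaussian sd)
    voxel_dims_nm: Tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    margin_um: float = 2.0
    seed: int = 0

    def __post_init__(self):
        self.phenotype = NucleusPhenotype(self.phenotype)
        if any(a <= 0 for a in self.semi_axes_um):
            raise ParameterError("semi-axes must be positive (zero-volume ellipsoid)")
        for name, f in (
            ("lacuna_radius_fraction", self.lacuna_radius_fraction),
            ("chromatin_contact_fraction", self.chromatin_contact_fraction),
        ):
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.npc_density_per_um2 < 0:
            raise ParameterError("npc_density must be >= 0")
        if self.vesicle_count < 0 or self.extranuclear_cluster_count < 0:
            raise ParameterError("counts must be >= 0")
        if self.extranuclear_cluster_mode not in ("none", "dispersed", "envelope_proximal"):
            raise ParameterError(f"unknown cluster mode {self.extranuclear_cluster_mode!r}")
        if any(d <= 0 for d in self.voxel_dims_nm):
            raise ParameterError("voxel dimensions must be positive")
        if self.margin_um < 2.0:
            raise ParameterError("cytoplasm margin must be >= 2 um")
        self.invagination_spec = [
            s if isinstance(s, InvaginationSpec) else InvaginationSpec(*s)
            for s in self.invagination_spec
        ]
        min_axis = min(self.semi_axes_um)
        for s in self.invagination_spec:
            if s.depth_um >= min_axis:
                raise ParameterError(
                    f"invagination depth {s.depth_um} um exceeds smallest semi-axis {min_axis} um"
                )


@dataclass
class MitoticParams:
    """One simulated mitotic figure (metaphase plate / anaphase rosette)."""

    shape: Tuple[int, int, int] = (40, 160, 160)
    n_chromatids: int = 8
    plate_radius_um: float = 2.2
    chromatid_sigma_um: float = 0.7
    gradient_sigma_um: float = 1.6  # radial intensity falloff scale
    class_weights: Tuple[float, ...] = (1.0,) * 7
    n_marker_voxels: int = 10_000
    marker_amplitude: float = 1000.0
    psf_fwhm_nm: Optional[Tuple[float, float]] = (130.0, 300.0)
    noise: Optional[Tuple[float, float]] = (1.0, 2.0)
    voxel_dims_nm: Tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    seed: int = 0

    def __post_init__(self):
        if len(self.class_weights) != 7:
            raise ParameterError("class_weights must have length 7")
        if any(w <= 0 for w in self.class_weights):
            raise ParameterError("class_weights must be strictly positive")
        if self.n_marker_voxels < 1:
            raise ParameterError("n_marker_voxels must be >= 1")
        if self.n_marker_voxels > int(np.prod(self.shape)):
            raise ParameterError("n_marker_voxels exceeds available voxels")
        if self.n_chromatids < 1:
            raise ParameterError("need at least one chromatid")
        if any(d <= 0 for d in self.voxel_dims_nm):
            raise ParameterError("voxel dimensions must be positive")


@dataclass
class TruthStructure:
    """Ground-truth record of one rendered envelope structure."""

    location: str  # invagination | interior_vesicle | extranuclear_segment
    phenotype: Immunophenotype
    centroid_um: Tuple[float, float, float]  # (z, y, x) from grid origin
    size_um: float  # depth for invaginations, radius otherwise


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    nucleus_mask: Optional[np.ndarray] = None
    class_map: Optional[np.ndarray] = None  # mitotic case, labels 1..7
    class_counts: Optional[np.ndarray] = None
    marker_class_counts: Optional[np.ndarray] = None
    structures: List[TruthStructure] = field(default_factory=list)
    npc_positions_um: Optional[np.ndarray] = None  # (n, 3) as (z, y, x)
    npc_contacted: Optional[np.ndarray] = None
    cluster_positions_um: Optional[np.ndarray] = None
    contact_fraction: Optional[float] = None
    extras: dict = field(default_factory=dict)


@dataclass
class ReadSimParams:
    """Simulated RNA-seq alignments at a controlled unspliced fraction."""

    gene_models: list  # of rinp.GeneModel
    unspliced_fraction: float = 0.0
    n_reads: int = 1000
    read_length: int = 80
    seed: int = 0

    def __post_init__(self):
        if not self.gene_models:
            raise ParameterError("gene model list must not be empty")
        if not 0.0 <= self.unspliced_fraction <= 1.0:
            raise ParameterError("unspliced_fraction must lie in [0, 1]")
        if self.n_reads < 0:
            raise ParameterError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ParameterError("read_length must be >= 1")
        shortest_exon = min(
            e[1] - e[0] + 1 for m in self.gene_models for e in m.exons
        )
        if self.read_length > shortest_exon:
            raise ParameterError(
                f"read_length {self.read_length} exceeds shortest exon span {shortest_exon}"
            )
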