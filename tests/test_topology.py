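"""Envelope shell, concordance, structure detection and censuses."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from nuquant.errors import InputError, ParameterError
from nuquant.phenotypes import Immunophenotype
from nuquant.segmentation import RegionMask
from nuquant.simulate import NucleusPhenotypeParams, gen_nucleus_stack
from nuquant.stack import ImageStack
from nuquant.topology import (
    ConcordanceResult,
    TopologyConfig,
    detect_structures,
    extranuclear_clusters,
    lamina_shell,
    npc_chromatin_concordance,
    structure_census,
)


def _blank_stack(shape, voxel_dims=(100.0, 100.0, 100.0)):
    zeros = np.zeros(shape, np.float32)
    return ImageStack(
        {"DAPI": zeros.copy(), "laminB": zeros.copy(), "NUP153": zeros.copy()},
        voxel_dims,
    )


def test_shell_band_volume_matches_analytic_sphere():
    """Shell voxel count ~ analytic band volume / voxel volume (sphere r=2um)."""
    r_um, t_nm = 2.0, 200.0
    dims = (100.0, 100.0, 100.0)
    n = 55
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    mask = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * 0.1**2 <= r_um**2
    stack = _blank_stack((n, n, n), dims)
    shell = lamina_shell(RegionMask(mask, voxel_dims=dims), stack, t_nm)
    t_um = t_nm / 1000.0
    band_um3 = 4 / 3 * np.pi * ((r_um + t_um) ** 3 - (r_um - t_um) ** 3)
    got = shell.n_voxels * np.prod(np.array(dims)) * 1e-9
    assert abs(got - band_um3) / band_um3 < 0.10


def test_shell_rejects_single_voxel_mask():
    mask = np.zeros((9, 9, 9), bool)
    mask[4, 4, 4] = True
    with pytest.raises(ParameterError):
        lamina_shell(RegionMask(mask, voxel_dims=(100.0,) * 3), _blank_stack((9, 9, 9)), 200.0)


def test_contact_fraction_recovers_generator_setting():
    """Measured contacted-surface fraction ~ the generator's contact cap."""
    p = NucleusPhenotypeParams(semi_axes_um=(3.0, 3.0, 3.0), phenotype="pre_mga", seed=4)
    stack, truth = gen_nucleus_stack(p)
    shell = lamina_shell(RegionMask(truth.nucleus_mask, voxel_dims=stack.voxel_dims), stack)
    frac = shell.chromatin_contact[shell.shell].mean()
    assert frac == pytest.approx(p.chromatin_contact_fraction, abs=0.05)


def test_concordance_worked_2x2_example():
    """Table ((90,10),(5,95)): odds ratio 171, Fisher p << 1e-15."""
    res = ConcordanceResult.__new__(ConcordanceResult)  # build via the op instead:
    shell_mask = np.zeros((1, 1, 200), bool)
    shell_mask[0, 0, :] = True
    contact = np.zeros_like(shell_mask)
    npc = np.zeros_like(shell_mask)
    contact[0, 0, :100] = True
    npc[0, 0, :90] = True  # contact & npc = 90, contact only = 10
    npc[0, 0, 100:105] = True  # non-contact & npc = 5
    from nuquant.topology import ShellMask

    sh = ShellMask(
        shell=shell_mask, chromatin_contact=contact, npc_present=npc,
        thickness_nm=200.0, voxel_dims=(100.0,) * 3,
        dapi_intensity=np.zeros(200), nup_intensity=np.zeros(200),
    )
    res = npc_chromatin_concordance(sh)
    assert res.table.tolist() == [[90, 10], [5, 95]]
    assert res.odds_ratio == pytest.approx(171.0)
    _, ref_p = stats.fisher_exact([[90, 10], [5, 95]])
    assert res.fisher_p == pytest.approx(ref_p)
    assert res.fisher_p < 1e-15


def test_degenerate_contact_flagged():
    shell_mask = np.ones((1, 1, 50), bool)
    sh_all = np.ones_like(shell_mask)
    from nuquant.topology import ShellMask

    sh = ShellMask(
        shell=shell_mask, chromatin_contact=sh_all, npc_present=sh_all.copy(),
        thickness_nm=200.0, voxel_dims=(100.0,) * 3,
        dapi_intensity=np.zeros(50), nup_intensity=np.zeros(50),
    )
    res = npc_chromatin_concordance(sh)
    assert res.degenerate_contact
    assert np.isnan(res.odds_ratio)
    assert res.fisher_p == 1.0
    assert res.frac_npc_contacted == pytest.approx(1.0)


def test_structures_match_generator_truth_exactly(clean_fixture_nucleus):
    """Noise-free fixture: counts, locations and immunophenotypes recover
    the generator inventory; centroids agree to sub-structure distance."""
    params, stack, truth = clean_fixture_nucleus
    mask = RegionMask(truth.nucleus_mask, voxel_dims=stack.voxel_dims)
    shell = lamina_shell(mask, stack)
    structs = detect_structures(stack, mask, shell)
    got = Counter((s.location, s.phenotype.value) for s in structs)
    want = Counter((s.location, s.phenotype.value) for s in truth.structures)
    assert got == want
    det = sorted(s.centroid_um for s in structs if s.location == "invagination")
    tru = sorted(s.centroid_um for s in truth.structures if s.location == "invagination")
    for a, b in zip(det, tru):
        assert np.linalg.norm(np.array(a) - np.array(b)) < 0.3


def test_interior_ring_classified_as_vesicle():
    shape = (21, 21, 21)
    dims = (100.0,) * 3
    zz, yy, xx = np.ogrid[:21, :21, :21]
    mask = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 9**2
    stack = _blank_stack(shape, dims)
    # lamin ring well inside the nucleus, detached from the shell band
    ring = ((zz - 10) ** 2 + (yy - 10) ** 2 <= 2**2) & (np.abs(xx - 10) <= 1)
    stack.channels["laminB"][ring & mask] = 100.0
    shell = lamina_shell(RegionMask(mask, voxel_dims=dims), stack, 200.0)
    structs = detect_structures(stack, RegionMask(mask, voxel_dims=dims), shell)
    assert len(structs) == 1
    assert structs[0].location == "interior_vesicle"
    assert not structs[0].connected_to_envelope
    assert structs[0].phenotype is Immunophenotype.NUP_NEG_LAM_POS


def test_empty_marker_channels_give_empty_list():
    shape = (15, 15, 15)
    dims = (100.0,) * 3
    zz, yy, xx = np.ogrid[:15, :15, :15]
    mask = (zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 7) ** 2 <= 6**2
    stack = _blank_stack(shape, dims)
    shell = lamina_shell(RegionMask(mask, voxel_dims=dims), stack, 200.0)
    assert detect_structures(stack, RegionMask(mask, voxel_dims=dims), shell) == []


class _Struct:
    def __init__(self, location, phenotype):
        self.location = location
        self.phenotype = phenotype


def test_census_reproduces_printed_percentage_partition():
    """90 invaginations at counts (62, 16, 12) give 68.9 / 17.8 / 13.3%,
    rounding to the 69 / 18 / 13 partition."""
    structs = (
        [_Struct("invagination", "NUP+/LamB+")] * 62
        + [_Struct("invagination", "NUP-/LamB+")] * 16
        + [_Struct("invagination", "NUP+/LamB-")] * 12
    )
    census = structure_census(structs)
    pct = dict(zip(census.invagination_percentages["phenotype"], census.invagination_percentages["percent"]))
    assert pct["NUP+/LamB+"] == pytest.approx(68.9, abs=0.05)
    assert pct["NUP-/LamB+"] == pytest.approx(17.8, abs=0.05)
    assert pct["NUP+/LamB-"] == pytest.approx(13.3, abs=0.05)
    assert [round(pct[k]) for k in ("NUP+/LamB+", "NUP-/LamB+", "NUP+/LamB-")] == [69, 18, 13]
    assert census.invagination_percentages["percent"].sum() == pytest.approx(100.0)


def test_census_single_structure_and_empty():
    census = structure_census([_Struct("invagination", "NUP+/LamB-")])
    assert census.invagination_percentages["percent"].tolist() == [0.0, 0.0, 100.0]
    empty = structure_census([])
    assert empty.n_structures == 0


def test_census_conservation():
    structs = [_Struct("invagination", "NUP+/LamB+")] * 4 + [_Struct("interior_vesicle", "NUP-/LamB+")] * 3
    census = structure_census(structs)
    assert census.counts["count"].sum() == len(structs)


@pytest.mark.parametrize("mode,expected", [("dispersed", "dispersed"), ("envelope_proximal", "envelope_proximal")])
def test_cluster_mode_recovered(mode, expected):
    p = NucleusPhenotypeParams(
        phenotype="pre_mga", seed=31, extranuclear_cluster_mode=mode, extranuclear_cluster_count=20,
        npc_density_per_um2=0.0,
    )
    stack, truth = gen_nucleus_stack(p)
    mask = RegionMask(truth.nucleus_mask, voxel_dims=stack.voxel_dims)
    prof = extranuclear_clusters(stack, mask)
    assert prof.classification == expected
    if mode == "dispersed":
        assert prof.median_distance_um > 0.5


def test_cluster_mode_none_gives_empty_profile():
    p = NucleusPhenotypeParams(
        phenotype="pre_mga", seed=32, extranuclear_cluster_mode="none", npc_density_per_um2=0.0,
        psf_fwhm_nm=None, noise=None,
    )
    stack, truth = gen_nucleus_stack(p)
    prof = extranuclear_clusters(stack, RegionMask(truth.nucleus_mask, voxel_dims=stack.voxel_dims))
    assert prof.classification == "empty"
    assert len(prof.clusters) == 0
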