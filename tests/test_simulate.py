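"""Synthetic-data generators: determinism, conservation, placement laws."""

import numpy as np
import pytest

from nuquant.errors import ParameterError
from nuquant.simulate import (
    InvaginationSpec,
    MitoticParams,
    NucleusPhenotypeParams,
    ReadSimParams,
    default_gene_models,
    gen_mitotic_stack,
    gen_nucleus_stack,
    gen_reads,
)
from tests.conftest import small_mitotic_params


def _fast_nucleus(**kw):
    base = dict(psf_fwhm_nm=None, noise=None, voxel_dims_nm=(250.0, 120.0, 120.0), seed=1)
    base.update(kw)
    return NucleusPhenotypeParams(**base)


class TestNucleusGenerator:
    def test_same_seed_bit_identical(self):
        p = NucleusPhenotypeParams(seed=4, vesicle_count=1, voxel_dims_nm=(250.0, 120.0, 120.0))
        s1, _ = gen_nucleus_stack(p)
        s2, _ = gen_nucleus_stack(NucleusPhenotypeParams(seed=4, vesicle_count=1, voxel_dims_nm=(250.0, 120.0, 120.0)))
        for ch in s1.channels:
            assert np.array_equal(s1.channels[ch], s2.channels[ch])

    def test_conditional_npc_placement_on_contacted_cap(self):
        """With conditional placement every pore centre sits on the cap and
        within the contact distance of truth chromatin."""
        p = _fast_nucleus(phenotype="pre_mga", chromatin_contact_fraction=0.5, npc_conditional=True)
        stack, truth = gen_nucleus_stack(p)
        cap_cos = truth.extras["cap_cos"]
        center = np.array(truth.extras["center_um"])
        pts = truth.npc_positions_um - center
        dirz = pts[:, 0] / np.linalg.norm(pts, axis=1)
        assert np.all(dirz >= cap_cos - 1e-9)
        assert np.all(truth.npc_contacted)
        # contact-distance property: chromatin rim is flush with the surface
        # in the cap, so each pore centre has chromatin within ~1 voxel
        dapi = stack.channel("DAPI")
        dims = np.array(p.voxel_dims_nm) / 1000.0
        for pt in truth.npc_positions_um[:50]:
            idx = np.round(pt / dims).astype(int)
            lo = np.maximum(idx - 2, 0)
            hi = np.minimum(idx + 3, dapi.shape)
            assert dapi[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].max() > 0

    def test_unconditional_npcs_cover_whole_sphere(self):
        p = _fast_nucleus(phenotype="post_mga", chromatin_contact_fraction=1.0, npc_conditional=False)
        _, truth = gen_nucleus_stack(p)
        center = np.array(truth.extras["center_um"])
        pts = truth.npc_positions_um - center
        dirz = pts[:, 0] / np.linalg.norm(pts, axis=1)
        assert dirz.min() < -0.5 and dirz.max() > 0.5

    def test_invagination_spec_echoed_exactly(self):
        p = _fast_nucleus(
            invagination_spec=[
                ("NUP+/LamB+", 3, 1.0),
                ("NUP-/LamB+", 2, 0.8),
                ("NUP+/LamB-", 1, 0.5),
            ]
        )
        _, truth = gen_nucleus_stack(p)
        inv = [s for s in truth.structures if s.location == "invagination"]
        assert len(inv) == 6
        types = sorted(s.phenotype.value for s in inv)
        assert types == sorted(["NUP+/LamB+"] * 3 + ["NUP-/LamB+"] * 2 + ["NUP+/LamB-"])

    def test_truth_coordinates_inside_grid(self):
        p = _fast_nucleus(vesicle_count=2, extranuclear_cluster_mode="dispersed", extranuclear_cluster_count=5)
        stack, truth = gen_nucleus_stack(p)
        dims = np.array(p.voxel_dims_nm) / 1000.0
        extent = np.array(stack.shape) * dims
        for s in truth.structures:
            assert np.all(np.array(s.centroid_um) >= 0) and np.all(np.array(s.centroid_um) <= extent)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(invagination_spec=[("NUP+/LamB+", 1, 5.0)]),  # depth > semi-axis
            dict(semi_axes_um=(0.0, 2.0, 2.0)),
            dict(chromatin_contact_fraction=1.5),
            dict(margin_um=1.0),
        ],
    )
    def test_parameter_errors(self, kw):
        with pytest.raises(ParameterError):
            NucleusPhenotypeParams(**kw)


class TestMitoticGenerator:
    def test_same_seed_bit_identical(self):
        s1, _ = gen_mitotic_stack(small_mitotic_params(3))
        s2, _ = gen_mitotic_stack(small_mitotic_params(3))
        for ch in s1.channels:
            assert np.array_equal(s1.channels[ch], s2.channels[ch])

    def test_dna_channel_has_at_least_seven_distinct_values(self):
        stack, _ = gen_mitotic_stack(small_mitotic_params(5))
        assert np.unique(stack.channel("DAPI")).size >= 7

    def test_uniform_weights_are_proportional_null(self):
        """With unit weights the marker fraction tracks the class fraction
        within multinomial error."""
        _, truth = gen_mitotic_stack(small_mitotic_params(8, n_marker_voxels=30_000))
        frac_class = truth.class_counts / truth.class_counts.sum()
        frac_marker = truth.marker_class_counts / truth.marker_class_counts.sum()
        se = np.sqrt(frac_class * (1 - frac_class) / 30_000)
        assert np.all(np.abs(frac_marker - frac_class) < 5 * se + 1e-9)

    def test_weight_ratio_recovered_at_large_n(self):
        """class_weights=(1,2,2,1,1,1,1) at 1e6 markers: the empirical
        class2/class1 density ratio is 2.0 +- 0.01 (law of large numbers;
        averaged over pre-chosen seeds to beat per-draw multinomial noise)."""
        ratios = []
        for seed in range(5):
            _, truth = gen_mitotic_stack(
                MitoticParams(
                    seed=seed,
                    n_marker_voxels=10**6,
                    class_weights=(1, 2, 2, 1, 1, 1, 1),
                    psf_fwhm_nm=None,
                    noise=None,
                )
            )
            dens = truth.marker_class_counts / truth.class_counts
            ratios.append(dens[1] / dens[0])
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.01)

    def test_marker_count_errors(self):
        with pytest.raises(ParameterError):
            MitoticParams(n_marker_voxels=0)
        with pytest.raises(ParameterError):
            MitoticParams(shape=(4, 4, 4), n_marker_voxels=100)
        with pytest.raises(ParameterError):
            MitoticParams(class_weights=(1, 1, 1, 1, 1, 1))
        with pytest.raises(ParameterError):
            MitoticParams(class_weights=(1, 1, 1, 1, 1, 1, 0))


class TestReadSimulator:
    def test_spliced_reads_avoid_introns_entirely(self):
        from nuquant.rinp import derive_introns

        models = default_gene_models(n_genes=2)
        recs = gen_reads(ReadSimParams(gene_models=models, unspliced_fraction=0.0, n_reads=500, seed=2))
        introns = {m.gene_id: derive_introns(m) for m in models}
        for r in recs:
            gene_introns = introns[r["gene"]]
            pos = r["pos0"]
            for op, ln in r["cigar"]:
                if op == 0:  # aligned match block
                    for a, b in gene_introns:
                        assert not (pos < b and pos + ln > a - 1)
                pos += ln

    def test_u1_expected_intronic_overlap_by_enumeration(self):
        """At u=1 the intronic-read fraction matches exhaustive enumeration
        of uniform start positions."""
        model = default_gene_models(n_genes=1, exon_length=300, intron_length=400)[0]
        from nuquant.rinp import derive_introns

        introns = derive_introns(model)
        L = 80
        starts = np.arange(model.start, model.end - L + 2)  # genomic, 1-based
        overlaps = np.zeros(starts.size, bool)
        for a, b in introns:
            overlaps |= (starts <= b) & (starts + L - 1 >= a)
        expected_frac = overlaps.mean()
        n = 4000
        recs = gen_reads(ReadSimParams(gene_models=[model], unspliced_fraction=1.0, n_reads=n, seed=3))
        n_intronic = 0
        for r in recs:
            s1 = r["pos0"] + 1
            if any(s1 <= b and s1 + L - 1 >= a for a, b in introns):
                n_intronic += 1
        se = np.sqrt(expected_frac * (1 - expected_frac) / n)
        assert abs(n_intronic / n - expected_frac) < 4 * se

    def test_same_seed_identical_records(self):
        models = default_gene_models()
        p = dict(gene_models=models, unspliced_fraction=0.4, n_reads=300, seed=6)
        assert gen_reads(ReadSimParams(**p)) == gen_reads(ReadSimParams(**p))

    def test_read_sim_parameter_errors(self):
        with pytest.raises(ParameterError):
            ReadSimParams(gene_models=[], unspliced_fraction=0.5)
        models = default_gene_models(exon_length=50)
        with pytest.raises(ParameterError):
            ReadSimParams(gene_models=models, read_length=80)
        with pytest.raises(ParameterError):
            ReadSimParams(gene_models=default_gene_models(), unspliced_fraction=1.5)
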