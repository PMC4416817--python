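"""End-to-end orchestration: simulate -> analyse -> report.

A single :class:`PipelineConfig` drives both pipelines:

* the image pipeline — for every configured (or loaded) nucleus stack:
  segmentation, volume, envelope shell, contact-pore concordance,
  structure detection + census, extranuclear clusters; for every mitotic
  stack: seven-class intensity classification, marker enrichment profile,
  goodness-of-fit and pairwise class tests;
* the read pipeline — simulate alignments per stage x replicate at the
  stage's unspliced fraction and tabulate per-gene / pooled / per-stage
  intron-coverage (RINP) values.

Runs are deterministic: the master seed spawns one child seed per scene
in configuration order, and the report carries a provenance block
(package version, config hash, seed) so a rerun can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import enrichment_profile, gof_test, marker_mask, pairwise_class_test
from .errors import InputError
from .intensity import classify_voxels, fit_class_boundaries
from .rinp import aggregate_rinp, intronic_coverage
from .segmentation import RegionMask, nuclear_volume, segment_nucleus
from .simulate import (
    MitoticParams,
    NucleusPhenotypeParams,
    ReadSimParams,
    default_gene_models,
    gen_mitotic_stack,
    gen_nucleus_stack,
    gen_reads,
    write_sam,
)
from .stack import DAPI, NUP, ImageStack
from .topology import (
    TopologyConfig,
    detect_structures,
    extranuclear_clusters,
    lamina_shell,
    npc_chromatin_concordance,
    structure_census,
)

__all__ = ["PipelineConfig", "RunReport", "run_image_pipeline", "run_rinp_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    nuclei: List[Dict[str, Any]] = field(default_factory=list)
    mitoses: List[Dict[str, Any]] = field(default_factory=list)
    stack_paths: List[Dict[str, Any]] = field(default_factory=list)
    k_classes: int = 7
    class_tol: float = 1e-3
    shell_thickness_nm: float = 200.0
    topology: Dict[str, Any] = field(default_factory=dict)
    pairwise: List[Dict[str, Any]] = field(default_factory=list)
    rinp: Optional[Dict[str, Any]] = None

    def __post_init__(self):
        for blk in self.nuclei:
            if "stage" not in blk:
                raise InputError("every nucleus block needs a 'stage' label")
        for p in self.stack_paths:
            if not Path(p["path"]).exists():
                raise InputError(f"stack path {p['path']} does not exist")
        if self.rinp is not None:
            if not self.rinp.get("stages"):
                raise InputError("rinp config needs a stages -> unspliced_fraction map")
            if self.rinp.get("n_genes", 4) < 1:
                raise InputError("rinp config needs a non-empty gene list")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables of one run plus its provenance block."""

    tables: Dict[str, pd.DataFrame]
    provenance: Dict[str, Any]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def _provenance(config: PipelineConfig) -> Dict[str, Any]:
    return {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }


def _scene_seeds(master: int, n: int) -> List[int]:
    # stable 32-bit scene seeds in configuration order
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master).spawn(n)]


def run_image_pipeline(config: PipelineConfig) -> RunReport:
    """Run segmentation/topology on nuclei and classification/enrichment
    on mitoses; returns every table keyed by name."""
    topo_cfg = TopologyConfig(**config.topology) if config.topology else TopologyConfig()
    n_scenes = len(config.nuclei) + len(config.mitoses)
    seeds = _scene_seeds(config.seed, n_scenes)

    vol_rows, conc_rows, census_structs, census_nuc, census_grp = [], [], [], [], []
    cluster_rows = []
    for i, blk in enumerate(config.nuclei):
        blk = dict(blk)
        stage = blk.pop("stage")
        nid = blk.pop("id", f"nucleus_{i}")
        params = NucleusPhenotypeParams(seed=seeds[i], **blk)
        stack, truth = gen_nucleus_stack(params)
        mask = segment_nucleus(stack)
        vol_rows.append({"stage": stage, "nucleus": nid, "volume_um3": nuclear_volume(mask)})
        shell = lamina_shell(mask, stack, config.shell_thickness_nm, topo_cfg)
        conc = npc_chromatin_concordance(shell)
        conc_rows.append(
            {
                "stage": stage,
                "nucleus": nid,
                "n_contact_npc": int(conc.table[0, 0]),
                "n_contact_nonpc": int(conc.table[0, 1]),
                "n_noncontact_npc": int(conc.table[1, 0]),
                "n_noncontact_nonpc": int(conc.table[1, 1]),
                "odds_ratio": conc.odds_ratio,
                "fisher_p": conc.fisher_p,
                "degenerate_contact": conc.degenerate_contact,
            }
        )
        structs = detect_structures(stack, mask, shell, topo_cfg)
        census_structs.extend(structs)
        census_nuc.extend([nid] * len(structs))
        census_grp.extend([stage] * len(structs))
        prof = extranuclear_clusters(stack, mask, topo_cfg)
        cluster_rows.append(
            {
                "stage": stage,
                "nucleus": nid,
                "n_clusters": len(prof.clusters),
                "classification": prof.classification,
                "median_distance_um": prof.median_distance_um,
            }
        )

    enr_rows, test_rows = [], []
    for j, blk in enumerate(config.mitoses):
        blk = dict(blk)
        cid = blk.pop("id", f"mitosis_{j}")
        params = MitoticParams(seed=seeds[len(config.nuclei) + j], **blk)
        stack, truth = gen_mitotic_stack(params)
        region = np.ones(stack.shape, dtype=bool)
        cb = fit_class_boundaries(stack.channel(DAPI)[region], config.k_classes, config.class_tol)
        cmap = classify_voxels(stack, DAPI, region, cb)
        marker_counts = np.bincount(
            cmap.labels.ravel()[truth.extras["marker_flat_indices"]],
            minlength=config.k_classes + 1,
        )[1:]
        prof = enrichment_profile(cmap, None, marker_counts=marker_counts)
        for c, D, M, e, o, r in zip(
            prof.classes, prof.region_counts, prof.marker_counts,
            prof.expected_fraction, prof.observed_fraction, prof.relative_enrichment,
        ):
            enr_rows.append(
                {"cell": cid, "class": int(c), "region_voxels": int(D), "marker_voxels": int(M),
                 "expected_fraction": e, "observed_fraction": o, "relative_enrichment": r}
            )
        g = gof_test(prof)
        test_rows.append(
            {"cell": cid, "test": g.test_name, "comparison": g.comparison,
             "statistic": g.statistic, "p": g.p_value, "p_display": g.p_display}
        )
        for pw in config.pairwise or [{"class_a": 7, "class_set_b": [2, 3]}]:
            t = pairwise_class_test(prof, pw["class_a"], pw["class_set_b"])
            test_rows.append(
                {"cell": cid, "test": t.test_name, "comparison": t.comparison,
                 "statistic": t.statistic, "p": t.p_value, "p_display": t.p_display}
            )

    census = structure_census(census_structs, census_nuc, census_grp)
    tables = {
        "volumes": pd.DataFrame(vol_rows),
        "concordance": pd.DataFrame(conc_rows),
        "census_counts": census.counts,
        "census_per_nucleus": census.per_nucleus,
        "invagination_percentages": census.invagination_percentages,
        "clusters": pd.DataFrame(cluster_rows),
        "enrichment": pd.DataFrame(enr_rows),
        "tests": pd.DataFrame(test_rows),
    }
    return RunReport(tables=tables, provenance=_provenance(config))


def run_rinp_pipeline(config: PipelineConfig, workdir: str | Path | None = None) -> RunReport:
    """Simulate stage x replicate libraries and tabulate RINP values."""
    import tempfile

    if config.rinp is None:
        raise InputError("config has no rinp block")
    rc = config.rinp
    stages: Dict[str, float] = dict(rc["stages"])  # stage -> unspliced fraction
    n_rep = int(rc.get("replicates", 3))
    n_reads = int(rc.get("n_reads", 2000))
    read_length = int(rc.get("read_length", 80))
    models = default_gene_models(
        n_genes=int(rc.get("n_genes", 4)),
        intron_length=int(rc.get("intron_length", 2000)),
    )
    own_tmp = workdir is None
    workdir = Path(tempfile.mkdtemp()) if own_tmp else Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    seeds = _scene_seeds(config.seed, len(stages) * n_rep)
    records = []
    idx = 0
    for stage, u in stages.items():
        for rep in range(1, n_rep + 1):
            prm = ReadSimParams(
                gene_models=models, unspliced_fraction=float(u),
                n_reads=n_reads, read_length=read_length, seed=seeds[idx],
            )
            idx += 1
            sam = workdir / f"{stage}_rep{rep}.sam"
            write_sam(gen_reads(prm), models, sam)
            for m in models:
                records.append((stage, f"rep{rep}", intronic_coverage(sam, m)))
    table = aggregate_rinp(records, stage_order=list(stages))
    tables = {
        "rinp_per_gene": table.per_gene,
        "rinp_pooled": table.pooled,
        "rinp_stage_mean": table.stage_mean,
    }
    return RunReport(tables=tables, provenance=_provenance(config))
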