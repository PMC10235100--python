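"""End-to-end pipeline: cohort -> scaling -> simulation -> degeneration -> stats.

This module binds the stages together behind one configuration object;
the command-line interface is a thin wrapper over :func:`run_pipeline`.
Outputs are CSV tables with provenance headers plus a ``provenance.json``
recording the seed, configuration hash and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as kio
from .atlas import load_atlas, load_gait_waveform
from .cohort_synth import (
    cohort_dataframe,
    cohort_to_cases,
    generate_cohort,
    load_default_cohort_config,
)
from .degeneration import progression_8y
from .joint_surrogate import batch_simulate
from .stats_eval import (
    bland_altman,
    group_tests,
    paired_from_results,
    roc_auc,
    scaling_regression,
)

log = logging.getLogger(__name__)

MATERIALS = ("frpve", "htipe", "tipe")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_per_group: int | None = None        # override every group size
    materials: tuple[str, ...] = MATERIALS
    n_stance_points: int = 26
    mesh_density: tuple[int, int, int, int] = (14, 5, 14, 4)
    material_file: str | None = None
    atlas_file: str | None = None
    gait_file: str | None = None
    cohort_file: str | None = None
    sides: tuple[str, ...] = ("left",)
    output_dir: str = "kneedeg_out"
    radius_spread: float = 0.05
    horizon_years: float = 8.0
    extra: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write the output bundle.

    Returns a dict with the in-memory artifacts (cohort table, per-model
    degeneration scores, statistics tables, AUCs).
    """
    from . import materials as M

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from dataclasses import asdict
    hash_payload = asdict(cfg)
    hash_payload.pop("output_dir")           # where, not what
    cfg_hash = kio.config_hash(hash_payload)

    for pth in (cfg.material_file, cfg.atlas_file, cfg.gait_file, cfg.cohort_file):
        if pth is not None and not Path(pth).exists():
            raise FileNotFoundError(f"missing input file: {pth}")

    library = M.load_default_materials(cfg.material_file)
    atlas = load_atlas(cfg.atlas_file)
    gait_cfg = atlas.get("gait", {})
    gait = load_gait_waveform(
        cfg.gait_file,
        medial_share=float(gait_cfg.get("medial_load_share", 0.65)),
        stance_duration=float(gait_cfg.get("stance_duration_s", 0.6)))

    ccfg = load_default_cohort_config(cfg.cohort_file, seed=cfg.seed)
    ccfg = ccfg.subset(sides=cfg.sides)
    if cfg.n_per_group is not None:
        from dataclasses import replace
        for side in ccfg.groups:
            for g in ccfg.groups[side]:
                gs = ccfg.groups[side][g]
                n = cfg.n_per_group
                ccfg.groups[side][g] = replace(
                    gs, n=n, pain=min(gs.pain, n))
    records = generate_cohort(ccfg)
    cases = cohort_to_cases(records, atlas["dims"], atlas["geometry"],
                            seed=cfg.seed, radius_spread=cfg.radius_spread)
    # propagate assigned thickness factors back into the record table
    tf = {c.knee_id: c.thickness_factor for c in cases}
    cohort_df = cohort_dataframe(records)
    cohort_df["thickness_factor"] = cohort_df["subject_id"].map(tf)
    kio.write_table(cohort_df, out / "cohort.csv", cfg.seed, cfg_hash)

    results, D = {}, {}
    for mat in cfg.materials:
        log.info("simulating %d knees with %s", len(cases), mat)
        res = batch_simulate(cases, mat, gait, library=library,
                             n_stance_points=cfg.n_stance_points,
                             mesh_density=cfg.mesh_density)
        results[mat] = res
        D[mat] = {}
        rows = []
        for kid, r in res.items():
            prog = progression_8y(r.max_tensile_stress, r.elem_volumes,
                                  r.baseline_age, cfg.horizon_years)
            D[mat][kid] = prog.D
            rows.append({"knee_id": kid, "kl_group": r.kl_group,
                         "pain": r.pain, "baseline_age": r.baseline_age,
                         "thickness_factor": r.thickness_factor,
                         "DEG_baseline_mm3": prog.deg_baseline,
                         "DEG_followup_mm3": prog.deg_followup,
                         "D_mm3": prog.D})
        kio.write_table(pd.DataFrame(rows), out / f"degeneration_{mat}.csv",
                        cfg.seed, cfg_hash)

    artifacts = {"cohort": cohort_df, "D": D, "config_hash": cfg_hash}

    # model-vs-model statistics against the reference (first material)
    ref = cfg.materials[0]
    stats_rows, ba_rows, reg_rows = [], [], []
    for mat in cfg.materials[1:]:
        paired = paired_from_results(results[mat], results[ref], mat, ref,
                                     D_a=D[mat], D_b=D[ref])
        t = paired.table
        if len(t) >= 2:
            ba = bland_altman(t["tensile_stress_mean_a"], t["tensile_stress_mean_b"])
            ba_rows.append({"pair": f"{mat} vs {ref}",
                            "response": "tensile_stress_mean",
                            "mean_diff": ba["mean_diff"],
                            "lower": ba["lower_limit"], "upper": ba["upper_limit"]})
        if len(t) >= 3:
            diffs = (t["tensile_stress_mean_a"] - t["tensile_stress_mean_b"]).abs()
            reg = scaling_regression(diffs, t["thickness_factor"])
            reg_rows.append({"pair": f"{mat} vs {ref}",
                             "response": "tensile_stress_mean", **reg})
        arms = {}
        for g, sub in t.groupby("kl_group"):
            if len(sub) >= 2 and "D_a" in sub:
                arms[f"{g}: {mat} vs {ref}"] = (sub["D_a"].to_numpy(),
                                                sub["D_b"].to_numpy())
        if arms:
            stats_rows.append(group_tests({}, arms))

    auc_rows = []
    kl_tests = []
    for mat in cfg.materials:
        d = D[mat]
        groups = {}
        for kid, val in d.items():
            g = results[mat][kid].kl_group
            groups.setdefault(g, []).append(val)
        if {"KL01", "KL34"} <= set(groups):
            scores = np.array(groups["KL01"] + groups["KL34"])
            labels = np.array([0] * len(groups["KL01"]) + [1] * len(groups["KL34"]))
            if len(set(labels)) == 2:
                auc_rows.append({"material": mat,
                                 "auc_KL34_vs_KL01": roc_auc(scores, labels)["auc"]})
        testable = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(testable) >= 2:
            gt = group_tests(testable)
            gt.insert(0, "material", mat)
            kl_tests.append(gt)

    if auc_rows:
        kio.write_table(pd.DataFrame(auc_rows), out / "roc_auc.csv",
                        cfg.seed, cfg_hash)
        artifacts["auc"] = pd.DataFrame(auc_rows)
    if ba_rows:
        kio.write_table(pd.DataFrame(ba_rows), out / "bland_altman.csv",
                        cfg.seed, cfg_hash)
    if reg_rows:
        kio.write_table(pd.DataFrame(reg_rows), out / "thickness_regression.csv",
                        cfg.seed, cfg_hash)
    all_tests = kl_tests + stats_rows
    if all_tests:
        merged = pd.concat(all_tests, ignore_index=True)
        kio.write_table(merged, out / "group_tests.csv", cfg.seed, cfg_hash)
        artifacts["group_tests"] = merged

    with open(out / "provenance.json", "w") as fh:
        json.dump({"seed": cfg.seed, "config_hash": cfg_hash,
                   "version": __version__,
                   "materials": list(cfg.materials),
                   "n_knees": len(cases),
                   "note": "two-sided tests, no multiple-testing correction"},
                  fh, indent=2)
    return artifacts
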