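"""End-to-end orchestration: simulate -> preprocess -> quantify -> compare ->
attack -> progression -> export, with deterministic seeding and a manifest.

The group-averaged network is the attack substrate (average raw matrices,
normalize, threshold at the configured density), while subject-level group
statistics run on individually thresholded matrices.  Every output CSV is
tagged with the hash of the run configuration, and re-running the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attack import (
    DEFAULT_TRACKED,
    AttackTrajectory,
    random_attack_ensemble,
    run_targeted_attack,
)
from .core import ConnectivityMatrix, ConnectomeError, RegionAtlas
from .io import write_atlas, write_brainnet_files, write_matrix
from .preprocess import binarize, binary_subtract, group_average, normalize, threshold_proportional
from .progression import progression_result
from .quantifiers import compute_global_quantifiers, nodal_metrics
from .stats import compare_quantifiers
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

#: attack scheme/quantifier combinations run by default: the degradation
#: figures' panel set (degree, strength, betweenness, eigenvector as basis
#: and iterative schemes, collective influence as basis only) plus random.
DEFAULT_ATTACKS: tuple[tuple[str, str], ...] = (
    ("basis", "degree"),
    ("basis", "strength"),
    ("basis", "betweenness"),
    ("basis", "eigenvector"),
    ("basis", "ci"),
    ("iterative", "degree"),
    ("iterative", "strength"),
    ("iterative", "betweenness"),
    ("iterative", "eigenvector"),
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    density: float = 0.10
    attacks: tuple[tuple[str, str], ...] = DEFAULT_ATTACKS
    ci_ell: int = 2
    n_random_reps: int = 100
    louvain_restarts: int = 100
    snapshot_restarts: int = 10
    tracked_metrics: tuple[str, ...] = DEFAULT_TRACKED
    seed: int = 0
    out_dir: str = "percolome-run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["attacks"] = [list(a) for a in self.attacks]
        d["tracked_metrics"] = list(self.tracked_metrics)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where outputs land must not change what they say
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "attacks" in d:
            d["attacks"] = tuple((s, q) for s, q in d["attacks"])
        if "tracked_metrics" in d:
            d["tracked_metrics"] = tuple(d["tracked_metrics"])
        return cls(**d)


def preprocess_group(
    subjects: list[ConnectivityMatrix], density: float
) -> ConnectivityMatrix:
    """Average raw subject matrices, normalize and threshold."""
    return threshold_proportional(normalize(group_average(subjects)), density)


def subject_quantifier_tables(
    subjects: list[ConnectivityMatrix],
    density: float,
    seed: int,
    restarts: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject global and nodal quantifier tables.

    Each subject matrix is individually normalized and thresholded before
    quantification.  Returns ``(global_df, nodal_df)``: the global frame
    has one row per subject and one column per metric; the nodal frame
    one row per subject, flattened ``label|metric`` columns.
    """
    global_rows, nodal_rows = [], []
    for i, subj in enumerate(subjects):
        m = threshold_proportional(normalize(subj), density)
        gq = compute_global_quantifiers(m, seed=seed + i, restarts=restarts)
        global_rows.append(pd.Series(gq.as_dict(), name=subj.subject_id))
        table = nodal_metrics(m, seed=seed + i, restarts=restarts)
        flat = {
            f"{region}|{metric}": table.loc[region, metric]
            for region in table.index
            for metric in table.columns
        }
        nodal_rows.append(pd.Series(flat, name=subj.subject_id))
    return pd.DataFrame(global_rows), pd.DataFrame(nodal_rows)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline; returns the manifest dictionary.

    Writes under ``cfg.out_dir``: group-average matrices, subject-level
    global/nodal quantifier tables, group comparison tables, attack
    trajectories for both group-average networks, the progression report
    (control attacks vs the unattacked disease baseline), BrainNet Viewer
    exports of both binarized networks and their signed difference, and a
    ``manifest.json`` recording the config, its hash, seeds and library
    versions.
    """
    if not 0.0 < cfg.density <= 1.0:
        raise ConnectomeError(f"density must be in (0, 1], got {cfg.density}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    written: list[str] = []

    def save(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# percolome config_hash={cfg.config_hash()}\n")
            df.to_csv(fh, **kwargs)
        written.append(name)
        logger.info("wrote %s (%.1fs elapsed)", name, time.time() - t_start)

    logger.info("stage: simulate")
    control, disease, atlas = generate_cohort(cfg.cohort)
    write_atlas(atlas, out / "atlas.tsv")
    written.append("atlas.tsv")

    logger.info("stage: preprocess")
    averages = {
        "control": preprocess_group(control, cfg.density),
        "disease": preprocess_group(disease, cfg.density),
    }
    for name, m in averages.items():
        write_matrix(m, out / f"group_average_{name}.csv")
        written.append(f"group_average_{name}.csv")

    logger.info("stage: quantify group averages")
    avg_global = pd.DataFrame(
        {
            name: compute_global_quantifiers(
                m, seed=cfg.seed, restarts=cfg.louvain_restarts, include_sigma=True
            ).as_dict()
            for name, m in averages.items()
        }
    ).T
    save(avg_global, "global_quantifiers_group_average.csv", index_label="group")

    logger.info("stage: quantify subjects")
    glob_c, nodal_c = subject_quantifier_tables(
        control, cfg.density, cfg.seed, cfg.louvain_restarts
    )
    glob_d, nodal_d = subject_quantifier_tables(
        disease, cfg.density, cfg.seed + 10_000, cfg.louvain_restarts
    )
    save(pd.concat([glob_c, glob_d]), "global_quantifiers_subjects.csv", index_label="subject")

    logger.info("stage: compare groups")
    drop = [c for c in glob_c.columns if glob_c[c].isna().all()]
    save(
        compare_quantifiers(glob_c.drop(columns=drop), glob_d.drop(columns=drop)),
        "comparison_global.csv",
        index=False,
    )
    save(compare_quantifiers(nodal_c, nodal_d), "comparison_nodal.csv", index=False)

    logger.info("stage: attacks")
    trajectories: dict[str, list[AttackTrajectory]] = {}
    frames = []
    for gname, m in averages.items():
        trajs = []
        for scheme, quant in cfg.attacks:
            traj = run_targeted_attack(
                m,
                scheme,
                quant,
                seed=cfg.seed,
                metrics=cfg.tracked_metrics,
                restarts=cfg.snapshot_restarts,
                ci_ell=cfg.ci_ell,
            )
            trajs.append(traj)
        trajs.append(
            random_attack_ensemble(
                m,
                n_reps=cfg.n_random_reps,
                seed=cfg.seed,
                metrics=cfg.tracked_metrics,
                restarts=cfg.snapshot_restarts,
            )
        )
        trajectories[gname] = trajs
        for traj in trajs:
            df = traj.to_frame()
            df.insert(0, "group", gname)
            frames.append(df)
    save(pd.concat(frames, ignore_index=True), "trajectories.csv", index=False)

    logger.info("stage: progression")
    baseline = compute_global_quantifiers(
        averages["disease"], seed=cfg.seed, restarts=cfg.louvain_restarts
    )
    prog_rows, curve_frames = [], []
    for traj in trajectories["control"]:
        for metric in cfg.tracked_metrics:
            base_val = getattr(baseline, metric)
            if not np.isfinite(base_val):
                continue
            res = progression_result(traj, baseline, metric)
            prog_rows.append(
                {
                    "scheme": traj.scheme,
                    "attack_quantifier": traj.quantifier_name,
                    "metric": metric,
                    "baseline": base_val,
                    "crossing_step": res.crossing_step,
                }
            )
            curve_frames.append(
                pd.DataFrame(
                    {
                        "scheme": traj.scheme,
                        "attack_quantifier": traj.quantifier_name,
                        "metric": metric,
                        "step": np.arange(len(res.diff_curve)),
                        "delta": res.diff_curve,
                    }
                )
            )
    save(pd.DataFrame(prog_rows), "progression.csv", index=False)
    save(pd.concat(curve_frames, ignore_index=True), "progression_curves.csv", index=False)

    logger.info("stage: BrainNet export")
    binarized = {name: binarize(m) for name, m in averages.items()}
    for name, m in binarized.items():
        write_brainnet_files(m, atlas, out / f"brainnet_{name}")
        written += [f"brainnet_{name}.node", f"brainnet_{name}.edge"]
    diff, _ = binary_subtract(binarized["control"], binarized["disease"])
    np.savetxt(out / "brainnet_difference.edge", diff, fmt="%.6f", delimiter=" ")
    written.append("brainnet_difference.edge")

    manifest = {
        "package": "percolome",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_trajectories": sum(len(v) for v in trajectories.values()),
        "outputs": written,
        "library_versions": _library_versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("done in %.1fs", time.time() - t_start)
    return manifest


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
    }
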