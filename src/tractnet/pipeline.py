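"""End-to-end orchestration: manifest -> QC -> networks -> backbone ->
metrics -> null models -> group comparison -> report bundle on disk.

Every stage writes plain-text output (CSV/JSON/delimited matrices) that the
package's own readers can load back, and a run log records the full
configuration, seeds and every QC exclusion, so a run is exactly
reproducible from its log. Outputs carry no timestamps; two runs with the
same inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import GROUPS
from .io import ScanRecord, read_manifest, write_matrix
from .metrics import global_metrics, nodal_metrics
from .network import (
    BackboneConfig,
    QCThresholds,
    WeightedNetwork,
    average_networks,
    build_weight_matrix,
    extract_backbone,
    screen_motion,
)
from .nullmodels import small_world_assessment
from .stats import compare_global_metrics, compare_nodal_metrics, correlate_onset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("tractnet")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full analysis run."""

    qc: QCThresholds = QCThresholds()
    backbone: BackboneConfig = BackboneConfig()
    ensemble_size: int = 100
    n_swap_per_edge: int = 10
    small_world_margin: float = 1.0
    welch: bool = False
    fdr: bool = False
    significance_level: float = 0.05
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "qc": dataclasses.asdict(self.qc),
            "backbone": dataclasses.asdict(self.backbone),
            "ensemble_size": self.ensemble_size,
            "n_swap_per_edge": self.n_swap_per_edge,
            "small_world_margin": self.small_world_margin,
            "welch": self.welch,
            "fdr": self.fdr,
            "significance_level": self.significance_level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        qc = QCThresholds(**data.pop("qc", {}))
        backbone = BackboneConfig(**data.pop("backbone", {}))
        return cls(qc=qc, backbone=backbone, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class PipelineResult:
    out_dir: Path
    networks: dict[str, WeightedNetwork]
    nodal_tables: dict[str, pd.DataFrame]
    global_values: dict[str, dict[str, float]]
    nodal_comparison: pd.DataFrame
    global_comparison: pd.DataFrame
    onset_correlations: pd.DataFrame
    excluded_scans: list[dict]
    excluded_subjects: list[str]


def _subject_seed(base_seed: int, subject_index: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), subject_index]).generate_state(1)[0] % (2**31))


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full analysis on a cohort manifest and write a report bundle.

    Stages: motion QC (scans over threshold are dropped; subjects with no
    surviving scan are excluded with a warning) -> voxel-normalised weight
    matrix per scan -> per-subject averaging -> backbone extraction ->
    nodal and global metrics -> small-world assessment against a rewired
    ensemble -> two-group comparison tables -> onset-age correlations for
    nodes that reach significance.
    """
    out = Path(out_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    (out / "metrics").mkdir(exist_ok=True)
    records = read_manifest(manifest_path)

    by_subject: dict[str, list[ScanRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)

    excluded_scans: list[dict] = []
    excluded_subjects: list[str] = []
    networks: dict[str, WeightedNetwork] = {}
    groups: dict[str, str] = {}
    onset_ages: dict[str, float | None] = {}
    nodal_tables: dict[str, pd.DataFrame] = {}
    global_values: dict[str, dict[str, float]] = {}

    for subject_index, (subject_id, recs) in enumerate(by_subject.items()):
        kept_nets = []
        for rec in recs:
            try:
                tc, log = rec.load()
            except Exception as err:  # pragma: no cover - error plumbing
                raise RuntimeError(
                    f"stage=load subject={subject_id} scan={rec.scan_id}: {err}"
                ) from err
            decision = screen_motion(log, config.qc)
            if not decision.keep:
                logger.warning(
                    "excluding %s %s: %s over threshold", subject_id, rec.scan_id,
                    decision.reason,
                )
                excluded_scans.append(
                    {
                        "subject_id": subject_id,
                        "scan_id": rec.scan_id,
                        "reason": decision.reason,
                        "peak_translation": decision.peak_translation,
                        "peak_rotation": decision.peak_rotation,
                    }
                )
                continue
            kept_nets.append(build_weight_matrix(tc))
        if not kept_nets:
            logger.warning("subject %s has no scan passing QC; excluded", subject_id)
            excluded_subjects.append(subject_id)
            continue
        try:
            mean_net = average_networks(kept_nets)
            backbone = extract_backbone(mean_net, config.backbone)
        except Exception as err:
            raise RuntimeError(f"stage=backbone subject={subject_id}: {err}") from err
        networks[subject_id] = backbone
        groups[subject_id] = recs[0].group
        onset_ages[subject_id] = recs[0].onset_age
        write_matrix(out / "networks" / f"{subject_id}_backbone.txt",
                     backbone.weights, backbone.labels)

        table = nodal_metrics(backbone)
        table.to_csv(out / "metrics" / f"{subject_id}_nodal.csv", index=False)
        nodal_tables[subject_id] = table

        gset = global_metrics(backbone)
        sw = small_world_assessment(
            backbone,
            ensemble_size=config.ensemble_size,
            n_swap_per_edge=config.n_swap_per_edge,
            margin=config.small_world_margin,
            seed=_subject_seed(config.seed, subject_index),
        )
        gvals = gset.as_dict() | {
            "eloc_ratio": sw.eloc_ratio,
            "eglob_ratio": sw.eglob_ratio,
            "is_small_world": sw.is_small_world,
        }
        with (out / "metrics" / f"{subject_id}_global.json").open("w") as fh:
            json.dump(gvals, fh, indent=2, sort_keys=True)
            fh.write("\n")
        global_values[subject_id] = gvals

    group_order = [g for g in GROUPS if g in groups.values()]
    if len(set(groups.values())) != 2:
        raise RuntimeError(
            f"stage=compare: need exactly two groups, found {sorted(set(groups.values()))}"
        )
    if not group_order or len(group_order) != 2:
        group_order = sorted(set(groups.values()))
    comparable = {
        s: {k: v for k, v in vals.items() if isinstance(v, (int, float)) and not isinstance(v, bool)}
        for s, vals in global_values.items()
    }
    nodal_cmp = compare_nodal_metrics(nodal_tables, groups, group_order,
                                      welch=config.welch, fdr=config.fdr)
    global_cmp = compare_global_metrics(comparable, groups, group_order,
                                        welch=config.welch, fdr=config.fdr)
    nodal_cmp.to_csv(out / "nodal_comparison.csv", index=False)
    global_cmp.to_csv(out / "global_comparison.csv", index=False)

    onset_rows = []
    trained = [s for s, g in groups.items() if g == group_order[1]
               and onset_ages.get(s) is not None]
    if len(trained) >= 3:
        ages = [onset_ages[s] for s in trained]
        significant = nodal_cmp[nodal_cmp["p"] < config.significance_level]
        for _, row in significant.iterrows():
            vals = []
            for s in trained:
                t = nodal_tables[s]
                vals.append(float(t.loc[t["label"] == row["node"], row["feature"]].iloc[0]))
            try:
                res = correlate_onset(vals, ages)
            except ValueError:
                continue
            onset_rows.append((row["feature"], row["node"], res.r, res.pvalue, res.n))
    onset_cmp = pd.DataFrame(onset_rows, columns=["feature", "node", "r", "p", "n"])
    onset_cmp.to_csv(out / "onset_correlations.csv", index=False)

    run_log = {
        "tractnet_version": __version__,
        "config": config.as_dict(),
        "manifest": str(manifest_path),
        "n_subjects_analyzed": len(networks),
        "group_order": group_order,
        "excluded_scans": excluded_scans,
        "excluded_subjects": excluded_subjects,
        "subject_seeds": {
            s: _subject_seed(config.seed, i) for i, s in enumerate(by_subject) if s in networks
        },
    }
    with (out / "run_log.json").open("w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        out_dir=out,
        networks=networks,
        nodal_tables=nodal_tables,
        global_values=global_values,
        nodal_comparison=nodal_cmp,
        global_comparison=global_cmp,
        onset_correlations=onset_cmp,
        excluded_scans=excluded_scans,
        excluded_subjects=excluded_subjects,
    )
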