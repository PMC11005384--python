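"""End-to-end orchestration: simulate → template → z-maps → potholes →
ROI tables → group statistics, with a machine-readable run report.

A run is fully determined by its :class:`RunConfig` (one seed feeds every
random draw), so repeated runs produce byte-identical reports. Controls are
scored leave-one-out against the normative template by default; injured
subjects are scored against the full control template. When ground truth is
available (always, for simulated cohorts) the report carries a recovery block
with voxel-level recall/precision and per-subject count errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .group_stats import (
    anova_oneway,
    bonferroni_adjust,
    spearman,
    summarize_groups,
    ttest_pooled,
)
from .normative import CohortMoments, DEFAULT_SD_FLOOR
from .potholes import (
    PotholeCluster,
    compute_zmap,
    detect_potholes,
    prevalence_map,
    summarize_potholes,
)
from .roi_metrics import region_table, regionwise_group_test, roi_mean_fa
from .synthetic import (
    CohortSpec,
    GroundTruth,
    LesionSpec,
    MetadataSpec,
    generate_control_cohort,
    generate_metadata,
    generate_tbi_subject,
    make_toy_anatomy,
)
from .volume_io import FAVolume, write_volume

__all__ = ["RunConfig", "run_pipeline", "recovery_metrics"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run; every field has a deterministic effect."""

    out_dir: str = "fapothole_run"
    n_control: int = 21
    n_mtbi: int = 52
    n_mstbi: int = 17
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.04, 3.0)
    noise_sd: float = 0.05
    n_regions: int = 8
    mean_lesions_mtbi: float = 3.0
    mean_lesions_mstbi: float = 4.0
    lesion_size_range: tuple[int, int] = (20, 40)
    lesion_depth: float = 6.0
    lesion_shape: str = "blob"
    z_threshold: float = -3.0
    min_size: float = 10
    size_units: str = "voxels"
    connectivity: int = 26
    loo_controls: bool = True
    sd_floor: float = DEFAULT_SD_FLOOR
    alpha: float = 0.05
    seed: int = 0
    write_volumes: bool = False

    def cohort_spec(self) -> CohortSpec:
        from .volume_io import VoxelGrid

        grid = VoxelGrid(shape=self.grid_shape, voxel_size=self.voxel_size,
                         orientation_tag="synthetic")
        return CohortSpec(n_control=self.n_control, n_mtbi=self.n_mtbi,
                          n_mstbi=self.n_mstbi, grid=grid, noise_sd=self.noise_sd,
                          n_regions=self.n_regions, seed=self.seed)

    def mean_lesions(self, group: str) -> float:
        return self.mean_lesions_mtbi if group == "mTBI" else self.mean_lesions_mstbi

    def lesion_spec(self, group: str, n_lesions: int) -> LesionSpec:
        return LesionSpec(n_lesions=n_lesions,
                          size_range_voxels=self.lesion_size_range,
                          depth=self.lesion_depth, shape=self.lesion_shape)


def recovery_metrics(
    detected: dict[str, list[PotholeCluster]],
    truth: dict[str, GroundTruth],
) -> dict:
    """Score detected clusters against planted ground truth.

    Voxel-level recall/precision pool over all subjects; precision is defined
    as 1.0 when nothing was detected (no false positives were produced).
    Count metrics report the per-subject (detected − planted) distribution.
    """
    if set(detected) != set(truth):
        raise ValueError("subject sets of detected and truth differ")
    tp = fp = fn = 0
    count_errors: list[int] = []
    per_subject_recall: list[float] = []
    exact = 0
    for sid in sorted(detected):
        det_vox: set[tuple[int, int, int]] = set()
        for c in detected[sid]:
            det_vox |= c.voxel_indices
        true_vox = truth[sid].all_voxels()
        inter = len(det_vox & true_vox)
        tp += inter
        fp += len(det_vox - true_vox)
        fn += len(true_vox - det_vox)
        if true_vox:
            per_subject_recall.append(inter / len(true_vox))
        err = len(detected[sid]) - truth[sid].n_lesions
        count_errors.append(err)
        exact += err == 0
    n = len(detected)
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    return {
        "n_subjects": n,
        "voxel_recall": recall,
        "voxel_precision": precision,
        "exact_count_fraction": exact / n if n else 1.0,
        "mean_count_error": float(np.mean(count_errors)) if count_errors else 0.0,
        "max_abs_count_error": int(np.max(np.abs(count_errors))) if count_errors else 0,
        "mean_subject_recall": float(np.mean(per_subject_recall))
        if per_subject_recall else 1.0,
    }


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-cohort pipeline and write its outputs.

    Writes ``tables/`` (TSV), optionally ``volumes/`` (NIfTI), and
    ``report.json`` under ``config.out_dir``; returns the report dict.
    """
    out = Path(config.out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)

    spec = config.cohort_spec()
    controls, atlas, base = generate_control_cohort(spec)
    mask = controls[0][1]

    # injured subjects: fresh control draws + planted lesions, one child seed each
    root = np.random.default_rng(spec.seed + 1)
    subjects: dict[str, FAVolume] = {}
    groups: dict[str, str] = {}
    truths: dict[str, GroundTruth] = {}
    for i, (fa, _) in enumerate(controls):
        sid = f"sub-{i:03d}"
        subjects[sid] = fa
        groups[sid] = "noTBI"
    idx = len(controls)
    for group, n in (("mTBI", config.n_mtbi), ("msTBI", config.n_mstbi)):
        for _ in range(n):
            sid = f"sub-{idx:03d}"
            idx += 1
            draw = _fresh_draw(base, mask, spec, root)
            # per-subject lesion count is Poisson: injured cohorts show
            # over-dispersed, sometimes-zero pothole counts
            n_lesions = int(root.poisson(config.mean_lesions(group)))
            fa, gt = generate_tbi_subject(draw, mask,
                                          config.lesion_spec(group, n_lesions),
                                          base, spec.noise_sd, root)
            subjects[sid] = fa
            groups[sid] = group
            truths[sid] = gt

    moments = CohortMoments.from_controls(controls)
    full_template = moments.full(config.sd_floor)

    clusters: dict[str, list[PotholeCluster]] = {}
    summaries = []
    control_ids = [f"sub-{i:03d}" for i in range(len(controls))]
    for sid, fa in subjects.items():
        if groups[sid] == "noTBI" and config.loo_controls and len(controls) >= 3:
            template = moments.leave_one_out(control_ids.index(sid), config.sd_floor)
        else:
            template = full_template
        zmap = compute_zmap(fa, mask, template)
        cl = detect_potholes(zmap, z_threshold=config.z_threshold,
                             min_size=config.min_size, size_units=config.size_units,
                             connectivity=config.connectivity, atlas=atlas)
        clusters[sid] = cl
        summaries.append(summarize_potholes(sid, cl))

    summary_df = pd.DataFrame(
        [{
            "subject_id": s.subject_id,
            "group": groups[s.subject_id],
            "n_potholes": s.n_potholes,
            "total_pothole_volume_mm3": s.total_pothole_volume_mm3,
            "mean_cluster_volume_mm3": s.mean_cluster_volume_mm3,
        } for s in summaries]
    )
    summary_df.to_csv(tables / "pothole_summary.tsv", sep="\t", index=False)

    cluster_rows = []
    for sid, cl in clusters.items():
        for c in cl:
            top_roi = max(c.roi_overlap, key=c.roi_overlap.get) if c.roi_overlap else 0
            cluster_rows.append({
                "subject_id": sid, "cluster_id": c.cluster_id,
                "n_voxels": c.n_voxels, "volume_mm3": c.volume_mm3,
                "min_z": c.min_z, "peak_i": c.peak_index[0],
                "peak_j": c.peak_index[1], "peak_k": c.peak_index[2],
                "top_region": atlas.label_names.get(top_roi, "none"),
            })
    pd.DataFrame(cluster_rows).to_csv(tables / "clusters.tsv", sep="\t", index=False)

    prevalence: dict[str, dict[int, float]] = {}
    for group in ("noTBI", "mTBI", "msTBI"):
        members = [clusters[s] for s in clusters if groups[s] == group]
        if members:
            per_label, _vox = prevalence_map(members, atlas)
            prevalence[group] = per_label
    prev_rows = [{"group": g, "region_label": lab,
                  "region_name": atlas.label_names.get(lab, str(lab)),
                  "percent_with_pothole": pct}
                 for g, d in prevalence.items() for lab, pct in sorted(d.items())]
    pd.DataFrame(prev_rows).to_csv(tables / "prevalence.tsv", sep="\t", index=False)

    # ROI mean FA table + region-wise ANOVA
    per_subject_fa = {sid: roi_mean_fa(fa, mask, atlas)
                      for sid, fa in subjects.items()}
    roi_df = region_table(per_subject_fa, groups, atlas)
    roi_df.to_csv(tables / "roi_mean_fa.tsv", sep="\t", index=False)
    region_results = regionwise_group_test(roi_df, alpha=config.alpha)

    # group statistics on pothole counts (the cohort's primary endpoint)
    counts = {g: summary_df.loc[summary_df["group"] == g, "n_potholes"].to_numpy()
              for g in ("noTBI", "mTBI", "msTBI")
              if (summary_df["group"] == g).sum() >= 2}
    stats_block: dict = {}
    if len(counts) >= 2:
        count_anova = anova_oneway(counts)
        pairs = [(a, b) for i, a in enumerate(sorted(counts))
                 for b in sorted(counts)[i + 1:]]
        posthoc = {}
        for a, b in pairs:
            try:
                posthoc[f"{a}_vs_{b}"] = ttest_pooled(counts[a], counts[b]).to_dict()
            except ValueError:
                # degenerate pair (zero pooled variance); skip rather than fail
                continue
        ps = [v["p_value"] for v in posthoc.values()]
        for name, adj in zip(posthoc, bonferroni_adjust(ps)):
            posthoc[name]["adjusted_p"] = adj
        gs = summarize_groups({g: v for g, v in counts.items()})
        stats_block = {
            "pothole_count_anova": count_anova.to_dict(),
            "pothole_count_posthoc": posthoc,
            "pothole_count_groups": {
                label: {"n": n, "mean": m, "sd": s}
                for label, n, m, s in zip(gs.labels, gs.ns, gs.means, gs.sds)
            },
        }

    metadata = generate_metadata(MetadataSpec(
        group_sizes={"noTBI": config.n_control, "mTBI": config.n_mtbi,
                     "msTBI": config.n_mstbi},
        seed=spec.seed + 2))
    metadata = metadata.merge(summary_df[["subject_id", "n_potholes"]],
                              on="subject_id")
    metadata.to_csv(tables / "metadata.tsv", sep="\t", index=False)
    if len(metadata) >= 3:
        rho = spearman(metadata["n_potholes"], metadata["nsi_total"])
        stats_block["potholes_vs_nsi_spearman"] = rho.to_dict()

    recovery = recovery_metrics({s: clusters[s] for s in truths}, truths) \
        if truths else None

    if config.write_volumes:
        voldir = out / "volumes"
        voldir.mkdir(exist_ok=True)
        write_volume(mask, voldir / "wm_mask.nii.gz")
        write_volume(atlas, voldir / "atlas.nii.gz")
        for sid, fa in subjects.items():
            write_volume(fa, voldir / f"{sid}_fa.nii.gz")

    report = {
        "tool": {"name": "fapothole", "version": __version__},
        "config": asdict(config),
        "stages": {
            "simulate": {"n_subjects": len(subjects),
                         "n_mask_voxels": int(mask.n_voxels)},
            "template": {"n_controls": full_template.n_controls,
                         "n_valid_voxels": int(full_template.valid_mask.sum())},
            "potholes": {"total_clusters": int(sum(len(c) for c in clusters.values()))},
            "roi": {"n_regions_tested": len(region_results)},
        },
        "group_potholes": {
            g: {
                "n": int((summary_df["group"] == g).sum()),
                "count_mean": float(summary_df.loc[summary_df["group"] == g,
                                                   "n_potholes"].mean()),
                "count_sd": float(summary_df.loc[summary_df["group"] == g,
                                                 "n_potholes"].std(ddof=1)),
                "volume_mean": float(summary_df.loc[
                    summary_df["group"] == g, "total_pothole_volume_mm3"].mean()),
            }
            for g in ("noTBI", "mTBI", "msTBI")
            if (summary_df["group"] == g).any()
        },
        "region_tests": [
            {
                "region_label": r.region_label,
                "region_name": r.region_name,
                "F": r.anova.statistic,
                "df": list(r.anova.df),
                "p_value": r.anova.p_value,
                "adjusted_p": r.anova.adjusted_p,
                "eta_squared": r.anova.effect_size,
            }
            for r in region_results
        ],
        "statistics": stats_block,
        "prevalence_percent": {g: {str(k): v for k, v in d.items()}
                               for g, d in prevalence.items()},
        "recovery": recovery,
    }
    report = _round_floats(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _fresh_draw(base: np.ndarray, mask, spec: CohortSpec,
                rng: np.random.Generator) -> FAVolume:
    noise = rng.normal(0.0, spec.noise_sd, size=spec.grid.shape)
    values = np.where(mask.values, np.clip(base + noise, 0.0, 1.0), 0.0)
    return FAVolume(grid=spec.grid, values=values)
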