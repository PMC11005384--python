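"""Atlas-ROI extraction of regional measures and region-wise group tests.

`roi_mean_fa` averages a subject's FA over each atlas label restricted to the
subject's own white-matter mask; a label with no in-mask voxels yields a
missing value (never a fabricated zero). `regionwise_group_test` runs a
one-way ANOVA per region with η², Bonferroni adjustment over the regions
actually tested, and pairwise Bonferroni post hocs (pooled t-tests) for the
regions that survive adjustment. `tiv_scale` applies proportional
head-size normalization: value × (cohort mean TIV / subject TIV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group_stats import (
    StatResult,
    anova_oneway,
    bonferroni_adjust,
    ttest_pooled,
)
from .volume_io import AtlasVolume, FAVolume, MaskVolume, check_grid_compatible

__all__ = ["roi_mean_fa", "region_table", "tiv_scale", "regionwise_group_test",
           "RegionTestResult"]


def roi_mean_fa(subject: FAVolume, subject_mask: MaskVolume,
                atlas: AtlasVolume) -> dict[int, float]:
    """Mean FA per nonzero atlas label over (label ∩ subject mask).

    Labels with no overlapping in-mask voxels map to NaN.
    """
    check_grid_compatible([subject, subject_mask])
    check_grid_compatible([subject.grid, atlas.grid])
    out: dict[int, float] = {}
    masked = subject_mask.values
    for lab in atlas.present_labels():
        sel = masked & (atlas.labels == lab)
        out[lab] = float(subject.values[sel].mean()) if sel.any() else float("nan")
    return out


def region_table(per_subject: dict[str, dict[int, float]],
                 groups: dict[str, str],
                 atlas: AtlasVolume,
                 measure_kind: str = "mean_fa") -> pd.DataFrame:
    """Assemble per-subject per-region values into a long-format table."""
    rows = []
    for sid, values in per_subject.items():
        for lab, val in values.items():
            rows.append({
                "subject_id": sid,
                "group": groups[sid],
                "region_label": lab,
                "region_name": atlas.label_names.get(lab, f"region_{lab}"),
                "measure_kind": measure_kind,
                "value": val,
            })
    return pd.DataFrame(rows)


def tiv_scale(value: float | np.ndarray, tiv: float,
              cohort_mean_tiv: float) -> float | np.ndarray:
    """Proportionally scale a regional measure by total intracranial volume."""
    if tiv <= 0 or cohort_mean_tiv <= 0:
        raise ValueError("TIV values must be positive")
    return value * (cohort_mean_tiv / tiv)


@dataclass
class RegionTestResult:
    """ANOVA outcome for one region, with post hocs when adjusted-significant."""

    region_label: int
    region_name: str
    anova: StatResult
    n_used: int
    posthoc: dict[tuple[str, str], StatResult]

    @property
    def significant_raw(self) -> bool:
        return self.anova.p_value < 0.05

    @property
    def significant_adjusted(self) -> bool:
        return self.anova.adjusted_p is not None and self.anova.adjusted_p < 0.05


def regionwise_group_test(table: pd.DataFrame, alpha: float = 0.05,
                          correction: str = "bonferroni"
                          ) -> list[RegionTestResult]:
    """One-way ANOVA per region across groups, with Bonferroni family control.

    Rows with missing values are dropped listwise within each region; regions
    left with fewer than two groups of n ≥ 2 are excluded, and the Bonferroni
    family size is the number of regions actually tested.
    """
    if correction not in {"bonferroni", "none"}:
        raise ValueError("correction must be 'bonferroni' or 'none'")
    results: list[RegionTestResult] = []
    tested: list[tuple[int, str, dict[str, np.ndarray]]] = []
    for lab, sub in table.groupby("region_label"):
        sub = sub.dropna(subset=["value"])
        samples = {g: grp["value"].to_numpy() for g, grp in sub.groupby("group")}
        samples = {g: v for g, v in samples.items() if v.size >= 2}
        if len(samples) < 2:
            continue
        name = str(sub["region_name"].iloc[0])
        tested.append((int(lab), name, samples))

    raw_ps = []
    anovas = []
    for lab, name, samples in tested:
        res = anova_oneway(samples)
        anovas.append(res)
        raw_ps.append(res.p_value)
    m = len(tested)
    adj = bonferroni_adjust(raw_ps, m) if (correction == "bonferroni" and m) else raw_ps

    for (lab, name, samples), res, ap in zip(tested, anovas, adj):
        res_adj = StatResult(res.test_name, res.statistic, res.df, res.p_value,
                             res.effect_size, res.effect_name, adjusted_p=ap)
        posthoc: dict[tuple[str, str], StatResult] = {}
        if ap < alpha:
            labels = sorted(samples)
            pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
            pair_res = [ttest_pooled(samples[a], samples[b]) for a, b in pairs]
            pair_adj = bonferroni_adjust([r.p_value for r in pair_res], len(pairs))
            for (a, b), r, pa in zip(pairs, pair_res, pair_adj):
                posthoc[(a, b)] = StatResult(r.test_name, r.statistic, r.df,
                                             r.p_value, r.effect_size,
                                             r.effect_name, adjusted_p=pa)
        n_used = int(sum(v.size for v in samples.values()))
        results.append(RegionTestResult(lab, name, res_adj, n_used, posthoc))
    return results
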