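"""Prevalence-normalized aneuploidy counting.

Cohorts do not represent cancer types equally, so raw per-arm loss
counts conflate biological prevalence with sampling. Each cancer
type's proportion P_c = N_c / sum_c N_c is used as a weight: the raw
loss count C_raw of an arm within a type is divided by P_c to give a
normalized count C_norm = C_raw / P_c, and arms are ranked by the sum
of C_norm over cancer types. Losses and gains are counted separately;
the screens downstream are loss-focused.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .genome_arms import LOSS
from .survival_screen import PatientRecord


def cancer_type_proportions(cohort: Sequence[PatientRecord]) -> dict[str, float]:
    """P_c = N_c / total for every cancer type in the cohort."""
    if not cohort:
        raise ValueError("cohort is empty")
    counts: dict[str, int] = {}
    for p in cohort:
        counts[p.cancer_type] = counts.get(p.cancer_type, 0) + 1
    total = len(cohort)
    return {ct: n / total for ct, n in sorted(counts.items())}


def raw_loss_counts(cohort: Sequence[PatientRecord]) -> dict[tuple[str, str], int]:
    """C_raw: number of loss calls per (arm, cancer type)."""
    counts: dict[tuple[str, str], int] = {}
    for p in cohort:
        for arm, status in p.arm_status.items():
            if status == LOSS:
                key = (arm, p.cancer_type)
                counts[key] = counts.get(key, 0) + 1
    return counts


def normalize_counts(
    raw_counts: Mapping[tuple[str, str], float],
    proportions: Mapping[str, float],
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """C_norm = C_raw / P_c per (arm, cancer type), plus per-arm totals."""
    normalized: dict[tuple[str, str], float] = {}
    arm_totals: dict[str, float] = {}
    for (arm, ct), c_raw in raw_counts.items():
        p_c = proportions.get(ct)
        if p_c is None or p_c == 0:
            if c_raw:
                raise ValueError(f"cancer type {ct!r} has zero proportion but {c_raw} counts")
            continue
        c_norm = c_raw / p_c
        normalized[(arm, ct)] = c_norm
        arm_totals[arm] = arm_totals.get(arm, 0.0) + c_norm
    return normalized, arm_totals


def prevalence_table(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Full prevalence table: one row per (arm, cancer type) with counts.

    Columns: arm_id, cancer_type, n_samples, proportion, raw_count,
    normalized_count; sorted by descending per-arm normalized total so
    the most prevalent loss events lead.
    """
    props = cancer_type_proportions(cohort)
    raw = raw_loss_counts(cohort)
    normalized, arm_totals = normalize_counts(raw, props)
    n_by_ct: dict[str, int] = {}
    for p in cohort:
        n_by_ct[p.cancer_type] = n_by_ct.get(p.cancer_type, 0) + 1
    rows = [
        {
            "arm_id": arm,
            "cancer_type": ct,
            "n_samples": n_by_ct[ct],
            "proportion": props[ct],
            "raw_count": raw[(arm, ct)],
            "normalized_count": normalized[(arm, ct)],
            "arm_normalized_total": arm_totals[arm],
        }
        for (arm, ct) in sorted(raw)
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        ["arm_normalized_total", "arm_id", "cancer_type"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
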