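"""Drug-sensitivity (viability) association screen over arm losses.

Mirrors the survival screen on cell-line data: for every combination
of a treatment unit (compound or mechanism of action) and an arm loss,
optionally per cancer type, viability readouts of Loss lines are
compared with Other lines by one-way ANOVA (equivalently the squared
pooled-variance t statistic for two groups). The same minimum group
size of 10, nominal alpha of 0.05 and BH q-values apply. Direction is
classified from the group means: "lower viability in loss lines" marks
a compound preferentially cytotoxic to the aneuploid state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScreenConfig
from .survival_screen import AssociationResult, bh_adjust

logger = logging.getLogger(__name__)

LOWER_VIABILITY_IN_LOSS = "lower_viability_in_loss"
GREATER_VIABILITY_IN_LOSS = "greater_viability_in_loss"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ViabilityRecord:
    """One screen readout: a (cell line, compound[, dose]) viability value."""

    cell_line: str
    cancer_type: str
    compound: str
    viability: float
    dose: float | None = None
    moa: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.viability):
            raise ValueError("viability must be finite")


def records_to_frame(records: Sequence[ViabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def anova_two_group(
    loss_values: Sequence[float], other_values: Sequence[float]
) -> tuple[float, float]:
    """One-way ANOVA F and p for Loss vs Other viability values.

    With two groups F equals the square of the pooled-variance t
    statistic. Degenerate input with zero variance everywhere returns
    (0, 1) with a warning rather than an error.
    """
    a = np.asarray(loss_values, dtype=float)
    b = np.asarray(other_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        logger.warning("all viability values identical; returning p = 1")
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant within-group input
        f, p = stats.f_oneway(a, b)
    if not np.isfinite(f):
        # between-group variance with zero within-group variance
        return float("inf"), 0.0
    return float(f), float(p)


def run_viability_screen(
    records: Sequence[ViabilityRecord] | pd.DataFrame,
    arm_calls: pd.DataFrame,
    cfg: ScreenConfig | None = None,
    stratify_by_cancer_type: bool = False,
    unit: Literal["compound", "moa"] = "compound",
    collapse_doses: Literal["mean"] | None = None,
) -> list[AssociationResult]:
    """ANOVA screen of every (unit, arm[, cancer type]) combination.

    ``arm_calls`` is the samples x arms matrix coded {-1, 0, +1}
    (index = cell line). Lines absent from the matrix, or with a
    missing call on the tested arm, are excluded from that
    combination. Multiple doses of a compound enter as separate
    observations unless ``collapse_doses="mean"`` averages them per
    (line, compound) first.
    """
    cfg = cfg or ScreenConfig()
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    required = {"cell_line", "cancer_type", "compound", "viability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability table lacks column(s): {sorted(missing)}")
    df = df.copy()
    if "moa" not in df.columns:
        df["moa"] = None

    if collapse_doses == "mean":
        df = (
            df.groupby(["cell_line", "cancer_type", "compound", "moa"], dropna=False)
            ["viability"].mean().reset_index()
        )

    unit_col = "compound" if unit == "compound" else "moa"
    df = df[df[unit_col].notna()]
    df = df[df["cell_line"].isin(arm_calls.index)]

    units = sorted(df[unit_col].unique())
    arms = sorted(arm_calls.columns)
    cancer_types = (
        sorted(df["cancer_type"].unique()) if stratify_by_cancer_type else ["ALL"]
    )

    results: list[AssociationResult] = []
    p_values: list[float] = []
    for ct in cancer_types:
        ct_df = df if ct == "ALL" else df[df["cancer_type"] == ct]
        for u in units:
            u_df = ct_df[ct_df[unit_col] == u]
            if u_df.empty:
                continue
            codes = arm_calls.loc[u_df["cell_line"]]
            for arm in arms:
                call = codes[arm].to_numpy()
                present = ~pd.isna(call)
                is_loss = present & (call == -1)
                if cfg.include_gains_in_other:
                    is_other = present & (call != -1)
                else:
                    is_other = present & (call == 0)
                vals = u_df["viability"].to_numpy()
                loss_vals = vals[is_loss]
                other_vals = vals[is_other]
                if len(loss_vals) < cfg.min_group_n or len(other_vals) < cfg.min_group_n:
                    logger.debug(
                        "skip %s/%s/%s: groups %d/%d below %d",
                        u, arm, ct, len(loss_vals), len(other_vals), cfg.min_group_n,
                    )
                    continue
                f, p_val = anova_two_group(loss_vals, other_vals)
                mean_loss = float(np.mean(loss_vals))
                mean_other = float(np.mean(other_vals))
                if mean_loss < mean_other:
                    direction = LOWER_VIABILITY_IN_LOSS
                elif mean_loss > mean_other:
                    direction = GREATER_VIABILITY_IN_LOSS
                else:
                    direction = INDETERMINATE
                results.append(
                    AssociationResult(
                        dataset="prism",
                        unit=unit,
                        unit_name=str(u),
                        arm_id=arm,
                        cancer_type=ct,
                        n_loss=int(len(loss_vals)),
                        n_other=int(len(other_vals)),
                        statistic=f,
                        p_value=p_val,
                        q_value=float("nan"),
                        significant=p_val < cfg.alpha,
                        direction=direction,
                        loss_summary=mean_loss,
                        other_summary=mean_other,
                    )
                )
                p_values.append(p_val)

    if cfg.bh_enabled and results:
        q = bh_adjust(p_values)
        results = [
            AssociationResult(**{**r.__dict__, "q_value": float(qi)})
            for r, qi in zip(results, q)
        ]
    return results
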