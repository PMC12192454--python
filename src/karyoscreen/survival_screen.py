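"""Treatment x arm-loss survival association screen.

For every combination of a treatment unit (compound name or mechanism
of action) and a chromosome-arm loss event — optionally further split
by cancer type — patients are partitioned into a "Loss" group (arm
status = loss) and an "Other" group (euploid and polyploid alike), and
the progression-free survival distributions of the two groups are
compared with a two-sided log-rank test. Combinations where either
group has fewer than ``min_group_n`` patients are skipped. Nominal
p < alpha marks a result significant; Benjamini-Hochberg q-values over
the emitted family are reported alongside so callers can filter by FDR
instead. The direction label compares the Kaplan-Meier median survival
of the two groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .config import ScreenConfig
from .genome_arms import GAIN, LOSS, NEUTRAL

logger = logging.getLogger(__name__)

IMPROVED_IN_LOSS = "improved_in_loss"
WORSE_IN_LOSS = "worse_in_loss"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PatientRecord:
    """One clinical case: treatments received, outcome, and arm statuses.

    ``pfs_months`` is progression-free survival; ``dss_event`` is the
    disease-specific death flag used as the censoring criterion (1 =
    disease-specific death observed, 0 = censored). ``arm_status`` maps
    arm ids to ``"loss"``/``"neutral"``/``"gain"``; arms missing from
    the map are treated as not assessed and the patient is excluded
    from comparisons on those arms.
    """

    patient_id: str
    cancer_type: str
    treatments: frozenset[str] = frozenset()
    moas: frozenset[str] = frozenset()
    pfs_months: float | None = None
    dss_event: int | None = None
    arm_status: dict[str, str] = field(default_factory=dict)
    wgd: bool | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.pfs_months is not None and self.pfs_months < 0:
            raise ValueError("pfs_months must be >= 0")
        if self.dss_event is not None and self.dss_event not in (0, 1):
            raise ValueError("dss_event must be 0 or 1")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate with its median.

    ``median`` is ``math.inf`` when the curve never reaches 0.5
    (reported as "NR", not reached).
    """

    times: np.ndarray
    survival: np.ndarray
    median: float

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)

    def survival_at(self, t: float) -> float:
        """S(t), carrying the last observed value forward past follow-up."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


@dataclass(frozen=True)
class AssociationResult:
    """One screened (unit, arm[, cancer type]) combination."""

    dataset: Literal["tcga", "prism"]
    unit: Literal["treatment", "moa", "compound"]
    unit_name: str
    arm_id: str
    cancer_type: str  # "ALL" when aggregated
    n_loss: int
    n_other: int
    statistic: float
    p_value: float
    q_value: float
    significant: bool
    direction: str
    loss_summary: float  # median survival / mean viability in Loss
    other_summary: float


# ---------------------------------------------------------------------------
# Statistical kernels
# ---------------------------------------------------------------------------


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("cannot estimate a survival curve from no observations")
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)  # inf when never reached
    return SurvivalCurve(times=grid, survival=surv, median=median)


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[int]],
    group_b: tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float]:
    """Two-sided two-group log-rank test; returns (chi-square, p).

    With zero observed events in both groups there is nothing to
    compare and (0, 1) is returned.
    """
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):  # identical degenerate groups
        return 0.0, 1.0
    return stat, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Screen machinery
# ---------------------------------------------------------------------------


def assign_groups(
    patients: Sequence[PatientRecord],
    arm: str,
    include_gains_in_other: bool = True,
) -> tuple[list[str], list[str]]:
    """Partition patient ids into Loss vs Other on one arm.

    Other collects every non-loss status (neutral and, by default,
    gain); patients without a status for the arm fall in neither group.
    """
    loss: list[str] = []
    other: list[str] = []
    for pt in patients:
        status = pt.arm_status.get(arm)
        if status is None:
            continue
        if status == LOSS:
            loss.append(pt.patient_id)
        elif status == NEUTRAL or (status == GAIN and include_gains_in_other):
            other.append(pt.patient_id)
    return loss, other


def _direction_from_curves(loss_curve: SurvivalCurve, other_curve: SurvivalCurve) -> str:
    """Classify the result by median survival; NR counts as +inf.

    When both medians are NR the groups are compared by S(t) at the
    last time observed in both curves; a tie there is indeterminate.
    """
    m_loss, m_other = loss_curve.median, other_curve.median
    if m_loss != m_other:
        return IMPROVED_IN_LOSS if m_loss > m_other else WORSE_IN_LOSS
    if math.isinf(m_loss):  # both NR: fall back to S at last common time
        t = min(loss_curve.times[-1], other_curve.times[-1])
        s_loss, s_other = loss_curve.survival_at(t), other_curve.survival_at(t)
        if s_loss > s_other:
            return IMPROVED_IN_LOSS
        if s_loss < s_other:
            return WORSE_IN_LOSS
    return INDETERMINATE


def _usable(pt: PatientRecord, arm: str) -> bool:
    return (
        pt.pfs_months is not None
        and pt.dss_event is not None
        and pt.arm_status.get(arm) is not None
    )


def run_survival_screen(
    cohort: Sequence[PatientRecord],
    cfg: ScreenConfig | None = None,
    stratify_by_cancer_type: bool = False,
    unit: Literal["treatment", "moa"] = "treatment",
) -> list[AssociationResult]:
    """Screen every (unit, arm[, cancer type]) combination by log-rank.

    Returns one :class:`AssociationResult` per combination passing the
    minimum-group-size rule, with BH q-values computed across the whole
    emitted family.
    """
    cfg = cfg or ScreenConfig()
    getter = (lambda p: p.treatments) if unit == "treatment" else (lambda p: p.moas)

    units = sorted({u for p in cohort for u in getter(p)})
    arms = sorted({a for p in cohort for a in p.arm_status})
    cancer_types = sorted({p.cancer_type for p in cohort}) if stratify_by_cancer_type else ["ALL"]

    rows: list[AssociationResult] = []
    p_values: list[float] = []
    for ct in cancer_types:
        ct_pool = [p for p in cohort if ct == "ALL" or p.cancer_type == ct]
        for u in units:
            treated = [p for p in ct_pool if u in getter(p)]
            for arm in arms:
                eligible = [p for p in treated if _usable(p, arm)]
                loss_ids, other_ids = assign_groups(
                    eligible, arm, cfg.include_gains_in_other
                )
                if len(loss_ids) < cfg.min_group_n or len(other_ids) < cfg.min_group_n:
                    logger.debug(
                        "skip %s/%s/%s: groups %d/%d below %d",
                        u, arm, ct, len(loss_ids), len(other_ids), cfg.min_group_n,
                    )
                    continue
                in_loss = set(loss_ids)
                in_other = set(other_ids)
                t_l, e_l, t_o, e_o = [], [], [], []
                for p in eligible:
                    if p.patient_id in in_loss:
                        t_l.append(p.pfs_months)
                        e_l.append(p.dss_event)
                    elif p.patient_id in in_other:
                        t_o.append(p.pfs_months)
                        e_o.append(p.dss_event)
                if cfg.truncate_at_landmark:
                    t0 = cfg.landmark_months
                    e_l = [e if t <= t0 else 0 for t, e in zip(t_l, e_l)]
                    t_l = [min(t, t0) for t in t_l]
                    e_o = [e if t <= t0 else 0 for t, e in zip(t_o, e_o)]
                    t_o = [min(t, t0) for t in t_o]
                stat, p_val = logrank_test((t_l, e_l), (t_o, e_o))
                curve_l = km_estimate(t_l, e_l)
                curve_o = km_estimate(t_o, e_o)
                rows.append(
                    AssociationResult(
                        dataset="tcga",
                        unit=unit,
                        unit_name=u,
                        arm_id=arm,
                        cancer_type=ct,
                        n_loss=len(loss_ids),
                        n_other=len(other_ids),
                        statistic=stat,
                        p_value=p_val,
                        q_value=float("nan"),
                        significant=p_val < cfg.alpha,
                        direction=_direction_from_curves(curve_l, curve_o),
                        loss_summary=curve_l.median,
                        other_summary=curve_o.median,
                    )
                )
                p_values.append(p_val)

    if cfg.bh_enabled and rows:
        q = bh_adjust(p_values)
        rows = [
            AssociationResult(**{**r.__dict__, "q_value": float(qi)})
            for r, qi in zip(rows, q)
        ]
    return rows


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results; infinite medians render as 'NR'."""
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return df
    for col in ("loss_summary", "other_summary"):
        df[col] = df[col].map(lambda v: "NR" if math.isinf(v) else v)
    return df


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into a table (treatments ';'-joined)."""
    rows = []
    for p in cohort:
        row = {
            "patient_id": p.patient_id,
            "cancer_type": p.cancer_type,
            "treatments": ";".join(sorted(p.treatments)),
            "moas": ";".join(sorted(p.moas)),
            "pfs_months": p.pfs_months,
            "dss_event": p.dss_event,
            "wgd": int(p.wgd) if p.wgd is not None else "",
            "subtype": p.subtype or "",
        }
        row.update({arm: status for arm, status in sorted(p.arm_status.items())})
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(df: pd.DataFrame, arm_columns: Sequence[str] | None = None) -> list[PatientRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    fixed = {"patient_id", "cancer_type", "treatments", "moas",
             "pfs_months", "dss_event", "wgd", "subtype"}
    if arm_columns is None:
        arm_columns = [c for c in df.columns if c not in fixed]
    cohort = []
    for row in df.to_dict("records"):
        arm_status = {
            a: row[a] for a in arm_columns
            if isinstance(row.get(a), str) and row[a] in (LOSS, NEUTRAL, GAIN)
        }
        wgd = row.get("wgd")
        cohort.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                cancer_type=str(row["cancer_type"]),
                treatments=frozenset(t for t in str(row.get("treatments") or "").split(";") if t),
                moas=frozenset(m for m in str(row.get("moas") or "").split(";") if m),
                pfs_months=float(row["pfs_months"]) if pd.notna(row.get("pfs_months")) else None,
                dss_event=int(row["dss_event"]) if pd.notna(row.get("dss_event")) else None,
                arm_status=arm_status,
                wgd=bool(int(wgd)) if wgd not in ("", None) and pd.notna(wgd) else None,
                subtype=str(row["subtype"]) if row.get("subtype") not in ("", None) else None,
            )
        )
    return cohort
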