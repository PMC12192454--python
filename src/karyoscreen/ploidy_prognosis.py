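"""Whole-genome duplication versus arm loss: prognosis models.

Three analyses that disentangle ploidy state from arm-level loss:

* four-group stratified Kaplan-Meier comparisons (Euploid/Loss x
  WGD/non-WGD) within a (cancer type, arm) stratum of at least 30
  samples, testing three predefined pairs by two-sided log-rank;
* a two-covariate Cox proportional-hazards model of progression-free
  survival on the binary WGD flag and a binary "any arm loss" flag;
* a fixed-landmark comparison of subtype-specific survival at 60
  months, reporting dS = S_NoLoss(t0) - S_Loss(t0).

"Euploid" here means no loss on the tested arm (gains and polyploid
states included), matching the screen's "Other" group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .config import ScreenConfig
from .genome_arms import LOSS
from .survival_screen import PatientRecord, SurvivalCurve, km_estimate, logrank_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovariateEffect:
    """One Cox covariate: coefficient, hazard ratio, CI, z and p."""

    name: str
    coef: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    z: float
    p_value: float


@dataclass(frozen=True)
class CoxFit:
    effects: dict[str, CovariateEffect]
    n: int
    n_events: int

    def __getitem__(self, name: str) -> CovariateEffect:
        return self.effects[name]


@dataclass(frozen=True)
class PairComparison:
    """One pairwise log-rank comparison between two ploidy/loss groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    median_a: float  # math.inf encodes NR
    median_b: float


@dataclass(frozen=True)
class StratifiedResult:
    cancer_type: str
    arm_id: str
    n_total: int
    group_sizes: dict[str, int]
    comparisons: list[PairComparison]


@dataclass(frozen=True)
class LandmarkResult:
    """Survival-probability difference at the landmark time.

    ``delta = s_noloss - s_loss``; the ``extrapolated_*`` flags mark a
    group whose follow-up ended before the landmark, in which case the
    last observed survival value was carried forward.
    """

    subtype: str
    arm_id: str
    n_noloss: int
    n_loss: int
    s_noloss: float
    s_loss: float
    delta: float
    extrapolated_noloss: bool
    extrapolated_loss: bool


def bin_wgd(doubling_counts: Sequence[int]) -> list[int]:
    """Binarize genome-doubling counts: 1 for >= 1 doubling, else 0."""
    flags = []
    for c in doubling_counts:
        if c < 0:
            raise ValueError(f"negative doubling count: {c}")
        flags.append(int(c >= 1))
    return flags


def _usable(pt: PatientRecord, arm: str | None = None) -> bool:
    ok = pt.pfs_months is not None and pt.dss_event is not None
    if arm is not None:
        ok = ok and pt.arm_status.get(arm) is not None
    return ok


_GROUPS = ("euploid_nonwgd", "loss_nonwgd", "euploid_wgd", "loss_wgd")
# the three predefined pairwise contrasts
_PAIRS = (
    ("euploid_nonwgd", "loss_nonwgd"),
    ("euploid_wgd", "loss_nonwgd"),
    ("euploid_wgd", "loss_wgd"),
)


def wgd_stratified_comparison(
    cohort: Sequence[PatientRecord],
    cancer_type: str,
    arm: str,
    cfg: ScreenConfig | None = None,
) -> StratifiedResult | None:
    """Four-group WGD x Loss comparison within one (cancer type, arm).

    Returns ``None`` (logged) when the stratum holds fewer than
    ``cfg.min_stratum_n_wgd`` eligible samples. Each of the three
    predefined pairs is compared by two-sided log-rank, with
    Kaplan-Meier medians reported per group (inf = not reached).
    """
    cfg = cfg or ScreenConfig()
    stratum = [
        p for p in cohort
        if p.cancer_type == cancer_type and p.wgd is not None and _usable(p, arm)
    ]
    if len(stratum) < cfg.min_stratum_n_wgd:
        logger.info(
            "stratum %s/%s has %d samples (< %d); skipped",
            cancer_type, arm, len(stratum), cfg.min_stratum_n_wgd,
        )
        return None

    groups: dict[str, list[PatientRecord]] = {g: [] for g in _GROUPS}
    for p in stratum:
        is_loss = p.arm_status[arm] == LOSS
        key = ("loss" if is_loss else "euploid") + ("_wgd" if p.wgd else "_nonwgd")
        groups[key].append(p)

    comparisons = []
    for name_a, name_b in _PAIRS:
        ga, gb = groups[name_a], groups[name_b]
        if not ga or not gb:
            continue
        ta = [p.pfs_months for p in ga]
        ea = [p.dss_event for p in ga]
        tb = [p.pfs_months for p in gb]
        eb = [p.dss_event for p in gb]
        stat, p_val = logrank_test((ta, ea), (tb, eb))
        comparisons.append(
            PairComparison(
                group_a=name_a, group_b=name_b,
                n_a=len(ga), n_b=len(gb),
                statistic=stat, p_value=p_val,
                median_a=km_estimate(ta, ea).median,
                median_b=km_estimate(tb, eb).median,
            )
        )
    return StratifiedResult(
        cancer_type=cancer_type,
        arm_id=arm,
        n_total=len(stratum),
        group_sizes={g: len(v) for g, v in groups.items()},
        comparisons=comparisons,
    )


def cox_two_covariate(cohort: Sequence[PatientRecord]) -> CoxFit:
    """Cox PH fit of PFS on the WGD flag and an any-arm-loss flag.

    The any-loss covariate is 1 when at least one arm has status
    ``loss``. Ties are handled by the Efron approximation. Raises on
    degenerate input (no events, or a constant covariate pattern).
    """
    rows = []
    for p in cohort:
        if not _usable(p) or p.wgd is None or not p.arm_status:
            continue
        rows.append(
            {
                "pfs_months": p.pfs_months,
                "dss_event": p.dss_event,
                "wgd": int(p.wgd),
                "any_loss": int(any(s == LOSS for s in p.arm_status.values())),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["dss_event"].sum() == 0:
        raise ValueError("Cox fit requires at least one observed event")
    if df[["wgd", "any_loss"]].drop_duplicates().shape[0] < 2:
        raise ValueError("Cox fit requires >= 2 distinct covariate patterns")
    for name in ("wgd", "any_loss"):
        if df[name].nunique() < 2:
            raise ValueError(f"covariate {name!r} is constant; cannot estimate its effect")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="pfs_months", event_col="dss_event")
    except Exception as exc:  # convergence / separation
        raise ValueError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    effects = {}
    for name in ("wgd", "any_loss"):
        row = summary.loc[name]
        effects[name] = CovariateEffect(
            name=name,
            coef=float(row["coef"]),
            hazard_ratio=float(row["exp(coef)"]),
            ci_lower=float(row["exp(coef) lower 95%"]),
            ci_upper=float(row["exp(coef) upper 95%"]),
            z=float(row["z"]),
            p_value=float(row["p"]),
        )
    return CoxFit(effects=effects, n=len(df), n_events=int(df["dss_event"].sum()))


def landmark_delta(
    cohort: Sequence[PatientRecord],
    subtype: str,
    arm: str,
    cfg: ScreenConfig | None = None,
) -> LandmarkResult | None:
    """dS at the landmark between No-Loss and Loss groups of a subtype.

    Kaplan-Meier curves are fitted per group and read at
    ``cfg.landmark_months`` (last value carried forward when follow-up
    ends earlier, flagged in the output). Returns ``None`` when either
    group has fewer than ``cfg.min_group_n_landmark`` samples.
    """
    cfg = cfg or ScreenConfig()
    pool = [p for p in cohort if p.subtype == subtype and _usable(p, arm)]
    loss = [p for p in pool if p.arm_status[arm] == LOSS]
    noloss = [p for p in pool if p.arm_status[arm] != LOSS]
    if len(loss) < cfg.min_group_n_landmark or len(noloss) < cfg.min_group_n_landmark:
        logger.info(
            "landmark %s/%s groups %d/%d below %d; omitted",
            subtype, arm, len(noloss), len(loss), cfg.min_group_n_landmark,
        )
        return None
    t0 = cfg.landmark_months

    def _curve(group: list[PatientRecord]) -> tuple[SurvivalCurve, float, bool]:
        curve = km_estimate(
            [p.pfs_months for p in group], [p.dss_event for p in group]
        )
        extrapolated = max(p.pfs_months for p in group) < t0
        return curve, curve.survival_at(t0), extrapolated

    _, s_noloss, ex_noloss = _curve(noloss)
    _, s_loss, ex_loss = _curve(loss)
    return LandmarkResult(
        subtype=subtype,
        arm_id=arm,
        n_noloss=len(noloss),
        n_loss=len(loss),
        s_noloss=s_noloss,
        s_loss=s_loss,
        delta=s_noloss - s_loss,
        extrapolated_noloss=ex_noloss,
        extrapolated_loss=ex_loss,
    )
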