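"""Synthetic cohorts with planted aneuploidy-treatment structure.

Every downstream stage of the pipeline (arm caller, survival screen,
ploidy models, viability screen) is exercised against data whose truth
is known: arm-loss indicators are drawn per (sample, arm) as independent
Bernoulli events; SEG files are emitted with one segment per arm at a
mean log2 ratio of -1 (loss), 0 (neutral) or +1 (gain) plus optional
Gaussian noise; progression-free survival times are exponential with a
baseline hazard multiplied by the planted hazard ratio whenever a
patient both received the treatment and carries the arm loss; drug
viability readouts are Gaussian around zero (log-fold-change
convention) with a planted mean shift in Loss lines.

Exponential event and censoring times keep the generator inside the
proportional-hazards family, so the log-rank screen and the Cox model
have analytic expectations against which recovery can be judged.
All draws flow from a single integer seed; identical scenario + seed
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome_arms import GAIN, LOSS, NEUTRAL, ArmInterval, SegmentRecord
from .survival_screen import PatientRecord

# Approximate autosome sizes and p-arm extents (Mb); acrocentric
# chromosomes (13, 14, 15, 21, 22) carry no protein-coding p-arm genes,
# leaving the canonical 39 callable autosome arms.
_CHROM_MB = [248, 242, 198, 190, 182, 171, 159, 145, 138, 134, 135,
             133, 114, 107, 102, 90, 83, 80, 59, 64, 47, 51]
_P_ARM_MB = [123, 93, 91, 50, 48, 60, 60, 45, 43, 39, 53,
             35, 0, 0, 0, 37, 25, 18, 26, 28, 0, 0]
_MB = 1_000_000


def default_arm_table() -> list[ArmInterval]:
    """The 39 autosome arm intervals used by the simulator.

    Gene-bounded extents are emulated by insetting each arm 2 Mb from
    the telomere and 3 Mb from the centromere.
    """
    arms: list[ArmInterval] = []
    for i, (size, p_len) in enumerate(zip(_CHROM_MB, _P_ARM_MB), start=1):
        chrom = str(i)
        if p_len > 0:
            arms.append(ArmInterval(chrom, "p", 2 * _MB, (p_len - 3) * _MB))
        arms.append(ArmInterval(chrom, "q", (p_len + 3) * _MB, (size - 2) * _MB))
    return arms


EffectKey = tuple  # (unit, arm) or (unit, arm, cancer_type)


@dataclass
class SimScenario:
    """Parameters of one synthetic study.

    Effect maps are keyed by ``(treatment, arm)`` or
    ``(treatment, arm, cancer_type)``; a two-element key applies to all
    cancer types. ``arm_event_freqs`` keys are ``(cancer_type, arm)``
    with ``"*"`` as a wildcard cancer type.

    Defaults describe a generic advanced-cancer cohort: baseline hazard
    0.03/month (median PFS ~23 months), light random censoring at
    0.01/month with administrative censoring at 60 months of follow-up,
    ~30% whole-genome-doubled samples, and viability noise of 0.5 on
    the log-fold-change scale.
    """

    n_samples: int = 200
    cancer_type_weights: dict[str, float] = field(default_factory=lambda: {"PANCAN": 1.0})
    arm_event_freqs: dict[tuple[str, str], float] = field(default_factory=dict)
    default_loss_prob: float = 0.0
    treatment_assignment: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    treatment_moa: dict[str, str] = field(default_factory=dict)
    planted_survival_effects: dict[EffectKey, float] = field(default_factory=dict)
    baseline_hazard: float = 0.03
    censoring_rate: float = 0.01
    max_followup: float = 60.0
    compound_moa: dict[str, str] = field(default_factory=dict)
    planted_viability_effects: dict[EffectKey, float] = field(default_factory=dict)
    viability_noise_sd: float = 0.5
    wgd_prob: float = 0.3
    subtype_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in [
            ("cancer_type_weights", self.cancer_type_weights.values()),
            ("arm_event_freqs", self.arm_event_freqs.values()),
        ]:
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
        if any(hr <= 0 for hr in self.planted_survival_effects.values()):
            raise ValueError("hazard ratios must be > 0")
        if self.viability_noise_sd < 0:
            raise ValueError("viability_noise_sd must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")

    # -- stream-separated RNGs so each generator is independently stable --
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    # -- YAML round trip (tuple keys flattened to record lists) --
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["arm_event_freqs"] = [
            {"cancer_type": ct, "arm": arm, "prob": p}
            for (ct, arm), p in self.arm_event_freqs.items()
        ]
        d["treatment_assignment"] = {
            ct: [{"treatment": t, "prob": p} for t, p in pairs]
            for ct, pairs in self.treatment_assignment.items()
        }
        for fld, val_name in [("planted_survival_effects", "hr"),
                              ("planted_viability_effects", "shift")]:
            d[fld] = [
                {"unit": k[0], "arm": k[1],
                 "cancer_type": k[2] if len(k) > 2 else None, val_name: v}
                for k, v in getattr(self, fld).items()
            ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        d = yaml.safe_load(Path(path).read_text())
        d["arm_event_freqs"] = {
            (r["cancer_type"], r["arm"]): r["prob"]
            for r in d.get("arm_event_freqs", [])
        }
        d["treatment_assignment"] = {
            ct: [(r["treatment"], r["prob"]) for r in pairs]
            for ct, pairs in d.get("treatment_assignment", {}).items()
        }
        for fld, val_name in [("planted_survival_effects", "hr"),
                              ("planted_viability_effects", "shift")]:
            d[fld] = {
                ((r["unit"], r["arm"]) if r.get("cancer_type") is None
                 else (r["unit"], r["arm"], r["cancer_type"])): r[val_name]
                for r in d.get(fld, [])
            }
        return cls(**d)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def gen_arm_status(
    scenario: SimScenario,
    arms: Sequence[ArmInterval] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the planted arm-status matrix and per-sample annotations.

    Returns ``(status, samples)``: a samples x arms DataFrame of
    ``"loss"``/``"neutral"`` strings and a DataFrame with columns
    ``sample_id``, ``cancer_type``, ``wgd``.
    """
    arms = arms if arms is not None else default_arm_table()
    rng = scenario._rng(1)
    types = list(scenario.cancer_type_weights)
    weights = np.array([scenario.cancer_type_weights[t] for t in types], float)
    weights = weights / weights.sum()
    sample_ids = [f"S{i:05d}" for i in range(scenario.n_samples)]
    cancer_types = rng.choice(types, size=scenario.n_samples, p=weights)
    wgd = rng.random(scenario.n_samples) < scenario.wgd_prob

    arm_ids = [a.arm_id for a in arms]
    status = np.full((scenario.n_samples, len(arm_ids)), NEUTRAL, dtype=object)
    for j, arm_id in enumerate(arm_ids):
        probs = np.array([
            scenario.arm_event_freqs.get(
                (ct, arm_id),
                scenario.arm_event_freqs.get(("*", arm_id), scenario.default_loss_prob),
            )
            for ct in cancer_types
        ])
        status[rng.random(scenario.n_samples) < probs, j] = LOSS

    status_df = pd.DataFrame(status, index=sample_ids, columns=arm_ids)
    status_df.index.name = "sample_id"
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "cancer_type": cancer_types, "wgd": wgd}
    )
    return status_df, samples


def gen_seg_from_arms(
    arm_status: pd.DataFrame,
    arms: Sequence[ArmInterval] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[SegmentRecord]:
    """Emit one full-arm segment per (sample, arm) from a status matrix.

    Loss arms get mean log2 ratio -1, gains +1, neutral 0, each plus
    Gaussian noise of ``noise_sd``. With ``noise_sd = 0`` the round
    trip through the caller reproduces the status matrix exactly.
    """
    arms = arms if arms is not None else default_arm_table()
    by_id = {a.arm_id: a for a in arms}
    missing = set(arm_status.columns) - set(by_id)
    if missing:
        raise ValueError(f"arm intervals missing for: {sorted(missing)}")
    rng = np.random.default_rng([seed, 2])
    base = {LOSS: -1.0, NEUTRAL: 0.0, GAIN: 1.0}
    segments: list[SegmentRecord] = []
    noise = rng.normal(0.0, noise_sd, size=arm_status.shape) if noise_sd > 0 else None
    for i, (sample_id, row) in enumerate(arm_status.iterrows()):
        for j, arm_id in enumerate(arm_status.columns):
            arm = by_id[arm_id]
            mean = base[row[arm_id]] + (noise[i, j] if noise is not None else 0.0)
            segments.append(
                SegmentRecord(
                    sample_id=str(sample_id),
                    chromosome=arm.chromosome,
                    start=arm.start,
                    end=arm.end,
                    seg_mean=mean,
                )
            )
    return segments


def _effect(
    effects: Mapping[EffectKey, float],
    unit: str,
    arm: str,
    cancer_type: str,
    default: float,
) -> float:
    if (unit, arm, cancer_type) in effects:
        return effects[(unit, arm, cancer_type)]
    return effects.get((unit, arm), default)


def gen_survival_cohort(
    scenario: SimScenario,
    arm_status: pd.DataFrame,
    samples: pd.DataFrame,
) -> list[PatientRecord]:
    """Simulate treatments and censored progression-free survival.

    Each patient's hazard is ``baseline_hazard`` times the product of
    the planted hazard ratios of every (treatment, arm) effect the
    patient is exposed to (received the treatment AND carries the arm
    loss). Event times are exponential; censoring is the minimum of an
    independent exponential and administrative follow-up cutoff.
    """
    rng = scenario._rng(3)
    cohort: list[PatientRecord] = []
    for _, info in samples.iterrows():
        sid, ct = str(info["sample_id"]), str(info["cancer_type"])
        assignment = scenario.treatment_assignment.get(
            ct, scenario.treatment_assignment.get("*", [])
        )
        treatments = frozenset(
            t for t, prob in assignment if rng.random() < prob
        )
        statuses = arm_status.loc[sid]
        hazard = scenario.baseline_hazard
        for t in sorted(treatments):
            for arm_id, status in statuses.items():
                if status == LOSS:
                    hazard *= _effect(
                        scenario.planted_survival_effects, t, arm_id, ct, 1.0
                    )
        event_t = rng.exponential(1.0 / hazard)
        censor_t = (
            rng.exponential(1.0 / scenario.censoring_rate)
            if scenario.censoring_rate > 0
            else np.inf
        )
        censor_t = min(censor_t, scenario.max_followup)
        pfs = min(event_t, censor_t)
        subtype = None
        if ct in scenario.subtype_weights:
            sw = scenario.subtype_weights[ct]
            names = list(sw)
            p = np.array([sw[n] for n in names], float)
            subtype = str(rng.choice(names, p=p / p.sum()))
        cohort.append(
            PatientRecord(
                patient_id=sid,
                cancer_type=ct,
                treatments=treatments,
                moas=frozenset(
                    scenario.treatment_moa[t]
                    for t in treatments
                    if t in scenario.treatment_moa
                ),
                pfs_months=float(pfs),
                dss_event=int(event_t <= censor_t),
                arm_status={a: str(s) for a, s in statuses.items()},
                wgd=bool(info["wgd"]),
                subtype=subtype,
            )
        )
    return cohort


def gen_viability_table(
    scenario: SimScenario,
    arm_status: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Simulate one viability readout per (cell line, compound).

    Values are Gaussian around 0 for Other lines; lines with a loss on
    a planted arm receive the configured mean shift for that compound.
    """
    rng = scenario._rng(4)
    compounds = sorted(scenario.compound_moa) or sorted(
        {k[0] for k in scenario.planted_viability_effects}
    )
    ct_by_sample = dict(zip(samples["sample_id"], samples["cancer_type"]))
    rows = []
    for sid in arm_status.index:
        statuses = arm_status.loc[sid]
        ct = str(ct_by_sample[sid])
        for compound in compounds:
            shift = sum(
                _effect(scenario.planted_viability_effects, compound, arm_id, ct, 0.0)
                for arm_id, status in statuses.items()
                if status == LOSS
            )
            value = shift + rng.normal(0.0, scenario.viability_noise_sd)
            rows.append(
                (str(sid), ct, compound, np.nan,
                 scenario.compound_moa.get(compound), value)
            )
    return pd.DataFrame(
        rows,
        columns=["cell_line", "cancer_type", "compound", "dose", "moa", "viability"],
    )
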