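"""Threshold configuration for the arm caller and the association screens.

Every numeric rule of the pipeline lives in one of the two frozen
dataclasses below so that an analysis is fully described by its inputs
plus a config object.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds for arm-level aneuploidy calling from segment means.

    Parameters
    ----------
    seg_mean_threshold : float
        Magnitude of mean log2 copy ratio at or beyond which a segment
        qualifies as altered (``seg_mean <= -t`` for loss,
        ``seg_mean >= +t`` for gain). Default 0.3.
    arm_fraction_threshold : float
        Fraction of the arm (by base pairs, gaps counted as unaltered)
        that must be altered in one direction to call an event.
        Default 0.67; the boundary is inclusive.
    autosomes_only : bool
        When true, sex chromosomes are parsed but excluded from calling.
    """

    seg_mean_threshold: float = 0.3
    arm_fraction_threshold: float = 0.67
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if not self.seg_mean_threshold > 0:
            raise ValueError("seg_mean_threshold must be > 0")
        if not 0 < self.arm_fraction_threshold <= 1:
            raise ValueError("arm_fraction_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ScreenConfig:
    """Inclusion and significance rules shared by the association screens.

    ``min_group_n`` (10) gates every Loss/Other comparison; strata below
    ``min_stratum_n_wgd`` (30) are skipped in the four-group ploidy
    analysis; subtype groups below ``min_group_n_landmark`` (5) are
    omitted from the landmark comparison at ``landmark_months`` (60).
    Significance is the nominal p below ``alpha``; BH q-values are
    reported alongside whenever ``bh_enabled``.
    """

    min_group_n: int = 10
    alpha: float = 0.05
    bh_enabled: bool = True
    min_stratum_n_wgd: int = 30
    min_group_n_landmark: int = 5
    landmark_months: float = 60.0
    # "Other" is euploid plus polyploid; gains sit in Other by default but
    # can be excluded from the comparison entirely.
    include_gains_in_other: bool = True
    # Administrative censoring of survival times at the landmark before
    # testing (off by default; plots are truncated regardless).
    truncate_at_landmark: bool = False

    def __post_init__(self) -> None:
        for name in ("min_group_n", "min_stratum_n_wgd", "min_group_n_landmark"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.landmark_months <= 0:
            raise ValueError("landmark_months must be > 0")
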