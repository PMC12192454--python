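"""SEG parsing, arm-interval construction and arm-level aneuploidy calling.

An arm-level event is called from segmented copy-number data when at
least 67% of the chromosome arm (measured in base pairs between the
first and last protein-coding gene of the arm) is covered by segments
whose mean log2 ratio exceeds +/-0.3 in one direction. Uncovered bases
count as unaltered, so sparse profiles under-call rather than over-call.

Intervals are closed-start / open-end in base pairs, which makes
abutting segments sum exactly to the arm length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import CallerConfig

logger = logging.getLogger(__name__)

LOSS = "loss"
NEUTRAL = "neutral"
GAIN = "gain"

AUTOSOMES = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES = ("X", "Y")

#: matrix encoding of a call status
STATUS_CODE = {LOSS: -1, NEUTRAL: 0, GAIN: 1}
CODE_STATUS = {v: k for k, v in STATUS_CODE.items()}


class SegFormatError(ValueError):
    """Raised when a SEG or annotation table is missing required columns."""


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment: a genomic interval with a mean log2 ratio."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    seg_mean: float
    n_markers: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"segment start must precede end ({self.start} >= {self.end})"
            )
        if not np.isfinite(self.seg_mean):
            raise ValueError("seg_mean must be finite")


@dataclass(frozen=True)
class ArmInterval:
    """A chromosome arm bounded by its first and last protein-coding gene."""

    chromosome: str
    arm: Literal["p", "q"]
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("arm start must precede end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def arm_id(self) -> str:
        return f"{self.chromosome}{self.arm}"


@dataclass(frozen=True)
class ArmCall:
    """Per (sample, arm) status with the altered fractions supporting it."""

    sample_id: str
    arm_id: str
    status: str
    fraction_loss: float
    fraction_gain: float


# ---------------------------------------------------------------------------
# SEG input
# ---------------------------------------------------------------------------

# header aliases seen in cBioPortal / DepMap / IGV flavours of SEG
_SEG_ALIASES = {
    "sample": {"sample", "id", "sampleid", "samplename", "cellline", "depmapid"},
    "chromosome": {"chromosome", "chrom", "chr"},
    "start": {"start", "locstart", "chromstart"},
    "end": {"end", "locend", "chromend"},
    "n_markers": {"nummark", "numprobes", "nummarkers", "numpoints", "markers"},
    "seg_mean": {"segmean", "segmentmean", "mean", "log2ratio"},
}


def _canon(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def normalize_chromosome(label: str) -> str:
    """Strip a leading ``chr`` prefix and surrounding whitespace."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def read_seg(path: str | Path) -> list[SegmentRecord]:
    """Read a tab-delimited SEG file into :class:`SegmentRecord` objects.

    Column headers are matched case-insensitively against the common SEG
    dialects (``ID``/``Sample``, ``loc.start``/``Start`` ...); the marker
    count column is optional. Rows with non-numeric coordinates or
    segment means are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty and df.columns.size == 0:
        logger.warning("SEG file %s is empty", path)
        return []

    colmap: dict[str, str] = {}
    for col in df.columns:
        key = _canon(col)
        for field, aliases in _SEG_ALIASES.items():
            if key in aliases and field not in colmap:
                colmap[field] = col
    for required in ("sample", "chromosome", "start", "end", "seg_mean"):
        if required not in colmap:
            raise SegFormatError(
                f"SEG file {path} lacks a recognizable '{required}' column "
                f"(saw columns: {list(df.columns)})"
            )
    if df.empty:
        logger.warning("SEG file %s has a header but no data rows", path)
        return []

    start = pd.to_numeric(df[colmap["start"]], errors="coerce")
    end = pd.to_numeric(df[colmap["end"]], errors="coerce")
    mean = pd.to_numeric(df[colmap["seg_mean"]], errors="coerce")
    ok = start.notna() & end.notna() & mean.notna() & np.isfinite(mean)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropping %d malformed row(s) from %s", n_bad, path)

    markers: pd.Series | None = None
    if "n_markers" in colmap:
        markers = pd.to_numeric(df[colmap["n_markers"]], errors="coerce")

    records: list[SegmentRecord] = []
    for i in df.index[ok]:
        records.append(
            SegmentRecord(
                sample_id=str(df.at[i, colmap["sample"]]),
                chromosome=normalize_chromosome(df.at[i, colmap["chromosome"]]),
                start=int(start[i]),
                end=int(end[i]),
                seg_mean=float(mean[i]),
                n_markers=int(markers[i])
                if markers is not None and pd.notna(markers[i])
                else None,
            )
        )
    return records


def write_seg(records: Iterable[SegmentRecord], path: str | Path) -> None:
    """Write segments in the standard six-column SEG layout."""
    rows = [
        (r.sample_id, r.chromosome, r.start, r.end,
         r.n_markers if r.n_markers is not None else "", r.seg_mean)
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Arm intervals
# ---------------------------------------------------------------------------


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (100, chrom)


def build_arm_table(gene_annotation: pd.DataFrame) -> list[ArmInterval]:
    """Construct arm intervals from a gene annotation table.

    The table needs columns ``chromosome``, ``arm``, ``start``, ``end``
    and a boolean ``coding`` flag. Each arm spans from the minimum start
    to the maximum end among its protein-coding genes; arms without any
    coding gene (acrocentric p-arms, typically) are omitted with a
    warning. Output is ordered by chromosome, p before q.
    """
    required = {"chromosome", "arm", "start", "end", "coding"}
    missing = required - set(gene_annotation.columns)
    if missing:
        raise SegFormatError(f"gene annotation lacks column(s): {sorted(missing)}")

    ann = gene_annotation.copy()
    ann["chromosome"] = ann["chromosome"].map(normalize_chromosome)
    intervals: list[ArmInterval] = []
    listed = ann.groupby(["chromosome", "arm"], sort=False)
    for (chrom, arm), group in listed:
        coding = group[group["coding"].astype(bool)]
        if coding.empty:
            logger.warning("arm %s%s has no protein-coding gene; omitted", chrom, arm)
            continue
        intervals.append(
            ArmInterval(
                chromosome=str(chrom),
                arm=str(arm),
                start=int(coding["start"].min()),
                end=int(coding["end"].max()),
            )
        )
    intervals.sort(key=lambda a: (_chrom_sort_key(a.chromosome), a.arm))
    return intervals


def read_arm_table(path: str | Path) -> list[ArmInterval]:
    """Read a tab-delimited arm-definition table (chromosome, arm, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "arm": str})
    missing = {"chromosome", "arm", "start", "end"} - set(df.columns)
    if missing:
        raise SegFormatError(f"arm table lacks column(s): {sorted(missing)}")
    arms = [
        ArmInterval(
            chromosome=normalize_chromosome(row.chromosome),
            arm=row.arm,
            start=int(row.start),
            end=int(row.end),
        )
        for row in df.itertuples()
    ]
    arms.sort(key=lambda a: (_chrom_sort_key(a.chromosome), a.arm))
    return arms


def write_arm_table(arms: Iterable[ArmInterval], path: str | Path) -> None:
    pd.DataFrame(
        [(a.chromosome, a.arm, a.start, a.end) for a in arms],
        columns=["chromosome", "arm", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def altered_fraction(
    segments: Sequence[SegmentRecord],
    arm: ArmInterval,
    direction: str,
    cfg: CallerConfig | None = None,
) -> float:
    """Fraction of the arm covered by segments altered in ``direction``.

    A segment qualifies for ``"loss"`` when its mean log2 ratio is at or
    below ``-seg_mean_threshold`` and for ``"gain"`` at or above the
    positive threshold (boundaries inclusive). Qualifying segments are
    intersected with the arm, unioned, and the covered length divided by
    the arm length. Bases not covered by any qualifying segment count as
    unaltered.
    """
    cfg = cfg or CallerConfig()
    if direction not in (LOSS, GAIN):
        raise ValueError(f"direction must be '{LOSS}' or '{GAIN}', got {direction!r}")
    t = cfg.seg_mean_threshold
    intervals: list[tuple[int, int]] = []
    for seg in segments:
        if seg.chromosome != arm.chromosome:
            continue
        if direction == LOSS and not seg.seg_mean <= -t:
            continue
        if direction == GAIN and not seg.seg_mean >= t:
            continue
        lo = max(seg.start, arm.start)
        hi = min(seg.end, arm.end)
        if lo < hi:
            intervals.append((lo, hi))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return covered / arm.length


def call_arm(
    segments: Sequence[SegmentRecord],
    arm: ArmInterval,
    cfg: CallerConfig | None = None,
) -> ArmCall:
    """Call loss/gain/neutral for one sample on one arm.

    The fraction threshold is inclusive: a fraction exactly at 0.67
    calls the event. With a threshold above 0.5 the two directions are
    mutually exclusive.
    """
    cfg = cfg or CallerConfig()
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) > 1:
        raise ValueError(f"segments span multiple samples: {sorted(sample_ids)}")
    f_loss = altered_fraction(segments, arm, LOSS, cfg)
    f_gain = altered_fraction(segments, arm, GAIN, cfg)
    if f_loss >= cfg.arm_fraction_threshold:
        status = LOSS
    elif f_gain >= cfg.arm_fraction_threshold:
        status = GAIN
    else:
        status = NEUTRAL
    sample_id = next(iter(sample_ids)) if sample_ids else ""
    return ArmCall(sample_id, arm.arm_id, status, f_loss, f_gain)


def call_genome(
    all_segments: Sequence[SegmentRecord],
    arms: Sequence[ArmInterval],
    cfg: CallerConfig | None = None,
) -> list[ArmCall]:
    """Call every (sample, arm) pair; absent coverage yields neutral.

    Sex-chromosome arms are dropped when ``cfg.autosomes_only``. The
    output contains exactly one call per remaining pair, ordered by
    sample then arm.
    """
    cfg = cfg or CallerConfig()
    if not arms:
        raise ValueError("no arm intervals supplied")
    if cfg.autosomes_only:
        arms = [a for a in arms if a.chromosome in AUTOSOMES]

    by_sample_chrom: dict[tuple[str, str], list[SegmentRecord]] = {}
    samples: dict[str, None] = {}  # insertion-ordered set
    for seg in all_segments:
        samples.setdefault(seg.sample_id, None)
        by_sample_chrom.setdefault((seg.sample_id, seg.chromosome), []).append(seg)

    calls: list[ArmCall] = []
    seen: set[tuple[str, str]] = set()
    for sample_id in sorted(samples):
        for arm in arms:
            key = (sample_id, arm.arm_id)
            if key in seen:
                raise RuntimeError(f"duplicate call for {key}")
            seen.add(key)
            segs = by_sample_chrom.get((sample_id, arm.chromosome), [])
            call = call_arm(segs, arm, cfg)
            if not segs:
                call = ArmCall(sample_id, arm.arm_id, NEUTRAL, 0.0, 0.0)
            calls.append(call)
    return calls


def calls_to_matrix(calls: Sequence[ArmCall]) -> pd.DataFrame:
    """Pivot arm calls into a samples x arms matrix coded {-1, 0, +1}."""
    if not calls:
        return pd.DataFrame()
    df = pd.DataFrame(
        [(c.sample_id, c.arm_id, STATUS_CODE[c.status]) for c in calls],
        columns=["sample_id", "arm_id", "code"],
    )
    mat = df.pivot(index="sample_id", columns="arm_id", values="code")
    arm_order = sorted(
        mat.columns,
        key=lambda a: (_chrom_sort_key(a[:-1]), a[-1]),
    )
    return mat[arm_order]


def write_arm_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_arm_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
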