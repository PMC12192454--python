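"""Cross-dataset glue: MOA consensus, cell-line mapping, overlap calls.

The clinical and cell-line datasets speak different languages: the
clinical cohort records free-text treatment names without mechanism-of
-action (MOA) labels, while the drug screen annotates compounds by MOA
and encodes cancer type in the cell-line name (e.g.
``LN18_CENTRAL_NERVOUS_SYSTEM``). This module assigns MOAs to
treatments by majority vote over five replicate boolean responses read
from a table, filters out uninformative MOA labels and non-compound
treatments, harmonizes cancer-type labels via a tissue-suffix mapping,
and intersects the two screens' significant results to find MOAs with
concordant cytotoxic efficacy (improved survival in Loss patients AND
lower viability in Loss lines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .survival_screen import IMPROVED_IN_LOSS, AssociationResult
from .viability_screen import LOWER_VIABILITY_IN_LOSS

logger = logging.getLogger(__name__)

N_REPLICATES = 5

#: MOA labels too generic to be informative (they apply to most compounds)
DEFAULT_EXCLUDED_MOAS = frozenset({"anti-tumor", "anti-cancer", "anti-neoplastic"})
#: treatment entries that are not compounds
DEFAULT_NON_COMPOUNDS = frozenset({"radiation"})


@dataclass(frozen=True)
class MoaResponseSet:
    """Five replicate yes/no responses for one (treatment, MOA) pair."""

    treatment: str
    moa: str
    responses: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.responses) != N_REPLICATES:
            raise ValueError(
                f"expected {N_REPLICATES} replicate responses, got {len(self.responses)}"
            )


@dataclass(frozen=True)
class OverlapRecord:
    """An MOA/arm/cancer-type triple concordant across both screens."""

    moa: str
    arm_id: str
    cancer_type: str
    tcga_result: AssociationResult
    prism_result: AssociationResult


def consensus_moa(response_set: MoaResponseSet) -> bool:
    """Majority vote over the five replicate responses."""
    return sum(response_set.responses) > N_REPLICATES // 2


def read_moa_responses(path: str | Path) -> list[MoaResponseSet]:
    """Read a replicate-response table (treatment, moa, r1..r5)."""
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.lower().startswith("r") and c[1:].isdigit()]
    if len(rep_cols) != N_REPLICATES:
        raise ValueError(
            f"expected {N_REPLICATES} replicate columns r1..r5, found {rep_cols}"
        )
    out = []
    for row in df.itertuples():
        responses = tuple(
            str(getattr(row, c)).strip().lower() in ("true", "1", "t", "yes")
            for c in rep_cols
        )
        out.append(MoaResponseSet(str(row.treatment), str(row.moa), responses))
    return out


def assign_moas(response_sets: Iterable[MoaResponseSet]) -> list[tuple[str, str]]:
    """(treatment, moa) pairs whose consensus response is positive."""
    return [(rs.treatment, rs.moa) for rs in response_sets if consensus_moa(rs)]


def filter_moa_labels(
    assignments: Sequence[tuple[str, str]],
    excluded_moas: frozenset[str] = DEFAULT_EXCLUDED_MOAS,
    non_compounds: frozenset[str] = DEFAULT_NON_COMPOUNDS,
) -> list[tuple[str, str]]:
    """Drop over-generic MOA labels and non-compound treatments."""
    kept = []
    for treatment, moa in assignments:
        if moa.strip().lower() in excluded_moas:
            continue
        if treatment.strip().lower() in non_compounds:
            continue
        kept.append((treatment, moa))
    return kept


def map_cell_line_cancer_type(
    line_name: str, mapping: Mapping[str, str]
) -> str | None:
    """Cancer type from a cell-line name's tissue suffix, or None.

    The identifier prefix before the first underscore is stripped and
    the remaining tissue suffix looked up in the mapping
    (``LN18_CENTRAL_NERVOUS_SYSTEM`` with ``CENTRAL_NERVOUS_SYSTEM ->
    CNS`` maps to ``CNS``). Unmapped suffixes return ``None`` and are
    excluded downstream.
    """
    if not line_name:
        raise ValueError("empty cell-line name")
    _, _, suffix = line_name.partition("_")
    mapped = mapping.get(suffix)
    if mapped is None:
        logger.debug("cell line %s: tissue suffix %r unmapped", line_name, suffix)
    return mapped


def read_cancer_type_mapping(path: str | Path) -> dict[str, str]:
    """Tab-delimited two-column mapping: tissue suffix -> cancer type."""
    df = pd.read_csv(path, sep="\t")
    missing = {"suffix", "cancer_type"} - set(df.columns)
    if missing:
        raise ValueError(f"mapping table lacks column(s): {sorted(missing)}")
    return dict(zip(df["suffix"].astype(str), df["cancer_type"].astype(str)))


def find_overlaps(
    tcga_results: Sequence[AssociationResult],
    prism_results: Sequence[AssociationResult],
) -> list[OverlapRecord]:
    """Concordant (MOA, arm, cancer type) triples across the two screens.

    Keeps pairs where the clinical result is significant with improved
    survival in Loss and the viability result is significant with lower
    viability in Loss — the signature of an MOA whose cytotoxicity is
    selective for the aneuploid state in both datasets.
    """
    tcga_hits = {
        (r.unit_name, r.arm_id, r.cancer_type): r
        for r in tcga_results
        if r.significant and r.direction == IMPROVED_IN_LOSS
    }
    overlaps = []
    for r in prism_results:
        if not (r.significant and r.direction == LOWER_VIABILITY_IN_LOSS):
            continue
        key = (r.unit_name, r.arm_id, r.cancer_type)
        if key in tcga_hits:
            overlaps.append(
                OverlapRecord(
                    moa=r.unit_name,
                    arm_id=r.arm_id,
                    cancer_type=r.cancer_type,
                    tcga_result=tcga_hits[key],
                    prism_result=r,
                )
            )
    overlaps.sort(key=lambda o: (o.moa, o.arm_id, o.cancer_type))
    return overlaps


def overlaps_to_frame(overlaps: Sequence[OverlapRecord]) -> pd.DataFrame:
    rows = [
        {
            "moa": o.moa,
            "arm_id": o.arm_id,
            "cancer_type": o.cancer_type,
            "tcga_p": o.tcga_result.p_value,
            "tcga_q": o.tcga_result.q_value,
            "prism_p": o.prism_result.p_value,
            "prism_q": o.prism_result.q_value,
        }
        for o in overlaps
    ]
    return pd.DataFrame(rows)
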