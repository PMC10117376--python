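"""Set-logical filtering funnel for affinity-purification hit lists.

Four pure set-difference/intersection stages, each emitting a
:class:`FilterReport` so the whole funnel can be reconstructed:

1. remove entries from a known contaminant list (keratins, serum
   proteins, digestion enzymes),
2. subtract proteins also detected in the matched control purification,
3. exclude proteins occurring in more than ``max_occurrence`` of a panel
   of negative-control experiments (a CRAPome-style matrix),
4. intersect independent replicate hit lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DEFAULT_CONTAMINANTS",
    "FilterReport",
    "remove_known_contaminants",
    "subtract_control",
    "crapome_filter",
    "intersect_replicates",
    "occurrence_from_matrix",
    "run_funnel",
]

#: Packaged contaminant list: human keratins, bovine serum proteins
#: introduced in culture, and digestion trypsin.
DEFAULT_CONTAMINANTS = frozenset(
    {
        "KRT1", "KRT2", "KRT5", "KRT6A", "KRT9", "KRT10", "KRT14", "KRT16", "KRT17",
        "ALB", "TF", "A2M", "FGA", "FGB", "FGG", "APOA1",
        "PRSS1", "TRY1",
    }
)


@dataclass(frozen=True)
class FilterReport:
    """Accounting record for one funnel stage."""

    stage: str
    n_in: int
    n_out: int
    removed_ids: frozenset[str]
    retention_fraction: float

    @classmethod
    def build(cls, stage: str, before: set[str], after: set[str]) -> "FilterReport":
        removed = frozenset(before - after)
        n_in, n_out = len(before), len(after)
        frac = n_out / n_in if n_in else 1.0
        return cls(stage, n_in, n_out, removed, frac)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "removed_ids": sorted(self.removed_ids),
            "retention_fraction": self.retention_fraction,
        }


def remove_known_contaminants(
    hits: Iterable[str],
    contaminant_set: Iterable[str] = DEFAULT_CONTAMINANTS,
) -> tuple[frozenset[str], FilterReport]:
    """Drop hits present in the known contaminant list."""
    before = set(hits)
    after = before - set(contaminant_set)
    return frozenset(after), FilterReport.build("known_contaminants", before, after)


def subtract_control(
    bait_hits: Iterable[str], control_hits: Iterable[str]
) -> tuple[frozenset[str], FilterReport]:
    """Retain only proteins absent from the matched control purification.

    Removal is presence/absence: a protein detected in the control at any
    abundance is removed.
    """
    before = set(bait_hits)
    after = before - set(control_hits)
    return frozenset(after), FilterReport.build("control_subtraction", before, after)


def crapome_filter(
    hits: Iterable[str],
    occurrence: Mapping[str, int],
    max_occurrence: int = 1,
    n_controls: int | None = None,
) -> tuple[frozenset[str], FilterReport]:
    """Exclude proteins seen in more than ``max_occurrence`` control runs.

    Proteins missing from ``occurrence`` are treated as never observed in
    the control panel (occurrence 0) and retained.
    """
    if n_controls is not None:
        bad = {p: o for p, o in occurrence.items() if not 0 <= o <= n_controls}
        if bad:
            raise ValueError(f"occurrence counts outside [0, {n_controls}]: {bad}")
    before = set(hits)
    after = {p for p in before if occurrence.get(p, 0) <= max_occurrence}
    return frozenset(after), FilterReport.build("control_panel_occurrence", before, after)


def intersect_replicates(
    per_replicate_hits: Mapping[str, Iterable[str]],
) -> tuple[frozenset[str], dict[str, FilterReport]]:
    """Intersect replicate hit lists; report per-replicate retention.

    ``retention_fraction`` of each report is |final| / |replicate|, i.e.
    the fraction of that replicate's hits confirmed in all others.
    """
    if len(per_replicate_hits) < 2:
        raise ValueError("at least two replicate hit lists are required")
    sets = {label: set(h) for label, h in per_replicate_hits.items()}
    final: set[str] = set.intersection(*sets.values())
    reports = {
        label: FilterReport.build(f"replicate_intersection[{label}]", s, final & s)
        for label, s in sets.items()
    }
    return frozenset(final), reports


def occurrence_from_matrix(matrix: pd.DataFrame) -> tuple[dict[str, int], int]:
    """Row-sum a binary protein x control-experiment matrix.

    Returns the per-protein occurrence counts and the number of control
    experiments (columns).
    """
    values = matrix.astype(int)
    if not values.isin([0, 1]).all().all():
        raise ValueError("occurrence matrix must be binary")
    return values.sum(axis=1).to_dict(), matrix.shape[1]


@dataclass
class FunnelResult:
    """Outcome of the full four-stage funnel."""

    final_hits: frozenset[str]
    per_replicate_reports: dict[str, list[FilterReport]] = field(default_factory=dict)
    intersection_reports: dict[str, FilterReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "final_hits": sorted(self.final_hits),
            "per_replicate": {
                rep: [r.to_dict() for r in reports]
                for rep, reports in self.per_replicate_reports.items()
            },
            "intersection": {
                rep: r.to_dict() for rep, r in self.intersection_reports.items()
            },
        }


def run_funnel(
    bait_hits: Mapping[str, Iterable[str]],
    control_hits: Mapping[str, Iterable[str]],
    occurrence: Mapping[str, int],
    contaminant_set: Iterable[str] = DEFAULT_CONTAMINANTS,
    max_occurrence: int = 1,
) -> FunnelResult:
    """Run the full funnel: contaminants, control, panel occurrence, replication.

    ``bait_hits`` and ``control_hits`` are keyed by replicate label; the
    control for each replicate is looked up under the same label.
    """
    staged: dict[str, frozenset[str]] = {}
    per_rep: dict[str, list[FilterReport]] = {}
    for rep, hits in bait_hits.items():
        reports: list[FilterReport] = []
        current, report = remove_known_contaminants(hits, contaminant_set)
        reports.append(report)
        current, report = subtract_control(current, control_hits.get(rep, ()))
        reports.append(report)
        current, report = crapome_filter(current, occurrence, max_occurrence)
        reports.append(report)
        staged[rep] = current
        per_rep[rep] = reports
    final, inter_reports = intersect_replicates(staged)
    return FunnelResult(final, per_rep, inter_reports)
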