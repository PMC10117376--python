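"""End-to-end convenience wiring: PSM tables -> filtered interactome.

Per replicate: score-filter PSMs, derive the hit list, remove known
contaminants, subtract the matched control, apply the control-panel
occurrence filter; then intersect replicates and score abundance for the
surviving proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .apfilter import DEFAULT_CONTAMINANTS, FunnelResult, run_funnel
from .quant import DEFAULT_MIN_SCORE, filter_psms, protein_abundance

__all__ = ["InteractomeResult", "run_interactome_pipeline"]


@dataclass
class InteractomeResult:
    final_hits: frozenset[str]
    funnel: FunnelResult
    abundance: pd.DataFrame


def run_interactome_pipeline(
    baits: Mapping[str, pd.DataFrame],
    controls: Mapping[str, pd.DataFrame],
    observable_counts: Mapping[str, int] | pd.Series,
    occurrence: Mapping[str, int],
    contaminant_set: Iterable[str] = DEFAULT_CONTAMINANTS,
    min_score: float = DEFAULT_MIN_SCORE,
    max_occurrence: int = 1,
) -> InteractomeResult:
    """Run score filter, funnel, replication and abundance ranking.

    ``baits`` and ``controls`` are keyed by replicate label; abundance is
    computed on score-filtered bait PSMs restricted to the final hit set.
    """
    filtered_baits = {rep: filter_psms(t, min_score) for rep, t in baits.items()}
    filtered_ctrls = {rep: filter_psms(t, min_score) for rep, t in controls.items()}
    bait_hits = {
        rep: set(t["protein_id"].unique()) for rep, t in filtered_baits.items()
    }
    control_hits = {
        rep: set(t["protein_id"].unique()) for rep, t in filtered_ctrls.items()
    }
    funnel = run_funnel(
        bait_hits, control_hits, occurrence, contaminant_set, max_occurrence
    )
    final = funnel.final_hits
    survivors = {
        rep: t.loc[t["protein_id"].isin(final)]
        for rep, t in filtered_baits.items()
    }
    abundance = protein_abundance(survivors, observable_counts) if final else (
        pd.DataFrame(
            columns=[f"empai_{r}" for r in baits] + ["mean_empai", "rank",
                                                     "high_abundance"]
        )
    )
    return InteractomeResult(final, funnel, abundance)
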