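"""Peptide-level score filtering and protein abundance scoring.

Peptide-spectrum matches (PSMs) carry a search-engine score defined as
``-10 * log10(P)`` where ``P`` is the probability that the match arose by
chance.  Protein abundance is summarized by the exponentially modified
protein abundance index (emPAI), ``10**(N_observed / N_observable) - 1``,
where ``N_observed`` counts distinct peptides passing the score filter and
``N_observable`` is the theoretical number of detectable peptides.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PSM_COLUMNS",
    "mascot_probability",
    "score_from_probability",
    "filter_psms",
    "compute_empai",
    "protein_abundance",
]

#: Required columns of a PSM table.
PSM_COLUMNS = ("protein_id", "peptide_seq", "mascot_score", "experiment", "condition")

#: Default minimum acceptable match score (P <= 1e-4).
DEFAULT_MIN_SCORE = 40.0


def mascot_probability(score: float) -> float:
    """Convert a match score into the random-match probability ``P``.

    Parameters
    ----------
    score : float
        Nonnegative match score, ``-10 * log10(P)``.

    Returns
    -------
    float
        Probability in ``(0, 1]``; ``score == 0`` maps to 1.
    """
    if score < 0:
        raise ValueError(f"score must be nonnegative, got {score!r}")
    return 10.0 ** (-score / 10.0)


def score_from_probability(p: float) -> float:
    """Inverse of :func:`mascot_probability` on ``(0, 1]``."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p!r}")
    return -10.0 * math.log10(p)


def filter_psms(table: pd.DataFrame, min_score: float = DEFAULT_MIN_SCORE) -> pd.DataFrame:
    """Drop PSM rows whose score is strictly below ``min_score``.

    Rows scoring exactly ``min_score`` are retained and input row order is
    preserved.  The operation is idempotent.
    """
    _check_psm_table(table)
    return table.loc[table["mascot_score"] >= min_score].copy()


def compute_empai(n_observed: int, n_observable: int) -> float:
    """emPAI abundance score: ``10**(n_observed / n_observable) - 1``."""
    if n_observable < 1:
        raise ValueError(f"n_observable must be >= 1, got {n_observable!r}")
    if n_observed < 0:
        raise ValueError(f"n_observed must be >= 0, got {n_observed!r}")
    return 10.0 ** (n_observed / n_observable) - 1.0


def protein_abundance(
    psms_by_experiment: Mapping[str, pd.DataFrame],
    observable_counts: Mapping[str, int] | pd.Series,
    high_abundance_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-protein emPAI across experiments with mean and abundance rank.

    Parameters
    ----------
    psms_by_experiment : mapping of experiment label to PSM table
        Tables are expected to be score-filtered already (see
        :func:`filter_psms`); distinct ``peptide_seq`` values per protein
        are counted as observed peptides.
    observable_counts : mapping of protein_id to theoretical peptide count
        Must cover every protein appearing in the PSM tables.
    high_abundance_threshold : float
        Proteins with mean emPAI strictly above this are flagged.

    Returns
    -------
    pandas.DataFrame
        Indexed by ``protein_id`` with one ``empai_<experiment>`` column
        per experiment, ``mean_empai``, ``rank`` (1 = most abundant, ties
        broken lexicographically by protein id) and ``high_abundance``.
        A protein absent from an experiment contributes emPAI 0 to the
        mean for that experiment.
    """
    if isinstance(observable_counts, pd.Series):
        observable_counts = observable_counts.to_dict()
    experiments = list(psms_by_experiment)
    if not experiments:
        raise ValueError("at least one experiment is required")

    counts: dict[str, dict[str, int]] = {}
    proteins: set[str] = set()
    for exp in experiments:
        table = psms_by_experiment[exp]
        _check_psm_table(table)
        per_protein = table.groupby("protein_id")["peptide_seq"].nunique().to_dict()
        counts[exp] = per_protein
        proteins.update(per_protein)

    missing = sorted(p for p in proteins if p not in observable_counts)
    if missing:
        raise KeyError(
            "proteins missing from observable_counts: " + ", ".join(missing)
        )

    ordered = sorted(proteins)
    data: dict[str, list[float]] = {f"empai_{exp}": [] for exp in experiments}
    for protein in ordered:
        for exp in experiments:
            n_obs = counts[exp].get(protein, 0)
            data[f"empai_{exp}"].append(compute_empai(n_obs, observable_counts[protein]))

    out = pd.DataFrame(data, index=pd.Index(ordered, name="protein_id"))
    out["mean_empai"] = out[[f"empai_{e}" for e in experiments]].mean(axis=1)
    # Descending abundance, deterministic lexicographic tie-break.
    order = sorted(ordered, key=lambda p: (-out.at[p, "mean_empai"], p))
    out["rank"] = pd.Series(
        np.arange(1, len(order) + 1, dtype=int), index=order
    ).reindex(out.index)
    out["high_abundance"] = out["mean_empai"] > high_abundance_threshold
    return out.sort_values("rank")


def _check_psm_table(table: pd.DataFrame) -> None:
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
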