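"""Gene-set annotation, category counting, expression filtering, and
candidate prioritization for an interactome protein list."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneSetCollection",
    "OverlapSummary",
    "load_gmt",
    "write_gmt",
    "percent_round_half_up",
    "annotate_and_count",
    "overlap_summary",
    "expression_filter",
    "prioritize_candidates",
]


def canonical_symbol(symbol: str) -> str:
    """Uppercase, whitespace-stripped gene symbol."""
    return symbol.strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene sets with per-set provenance notes."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members: Iterable[str], provenance: str = "") -> None:
        self.sets[name] = frozenset(canonical_symbol(m) for m in members)
        self.provenance[name] = provenance

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def load_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per set
    (name, description, member...).  Duplicate members are deduplicated.
    """
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description and at least one member)"
                )
            name, description, *members = fields
            collection.add(name, (m for m in members if m.strip()), description)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name in collection.sets:
            members = sorted(collection.sets[name])
            desc = collection.provenance.get(name, "")
            handle.write("\t".join([name, desc, *members]) + "\n")


def percent_round_half_up(k: int, n: int) -> int:
    """Integer percent of ``k/n`` rounded half-up (exact integer arithmetic)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return (200 * k + n) // (2 * n)


def annotate_and_count(
    proteins: Iterable[str],
    sets: GeneSetCollection | Mapping[str, Iterable[str]],
    asd_set: str = "ASD",
    id_set: str = "ID",
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Flag membership of each protein in each gene set and count categories.

    Returns the per-protein flag table (including a derived ``ASD_or_ID``
    column when both named sets are present) and, per set, the member
    count and half-up-rounded integer percentage of the protein list.
    An empty protein list yields zero counts and 0% with a warning.
    """
    if isinstance(sets, GeneSetCollection):
        set_map = {name: sets.sets[name] for name in sets.sets}
    else:
        set_map = {name: frozenset(canonical_symbol(m) for m in members)
                   for name, members in sets.items()}
    ordered = sorted({canonical_symbol(p) for p in proteins})
    table = pd.DataFrame(index=pd.Index(ordered, name="protein_id"))
    for name, members in set_map.items():
        table[name] = [p in members for p in ordered]
    if asd_set in set_map and id_set in set_map:
        table["ASD_or_ID"] = table[asd_set] | table[id_set]

    n = len(ordered)
    if n == 0:
        warnings.warn("empty protein list: percentages reported as 0", stacklevel=2)
    counts: dict[str, dict] = {}
    for column in table.columns:
        k = int(table[column].sum())
        counts[column] = {
            "count": k,
            "total": n,
            "percent": percent_round_half_up(k, n) if n else 0,
        }
    return table, counts


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    shared: tuple[str, ...]


def overlap_summary(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapSummary:
    """Sizes, intersection, union and shared members of two symbol sets."""
    a = {canonical_symbol(s) for s in set_a}
    b = {canonical_symbol(s) for s in set_b}
    inter = a & b
    return OverlapSummary(len(a), len(b), len(inter), len(a | b), tuple(sorted(inter)))


def expression_filter(
    proteins: Iterable[str],
    tpm_table: Mapping[str, float],
    min_tpm: float = 1.0,
) -> tuple[frozenset[str], int]:
    """Subset of proteins expressed at >= ``min_tpm`` in the reference
    cell type, plus the half-up-rounded detected percentage.

    Proteins missing from the expression table count as 0 TPM.
    """
    tpm = {canonical_symbol(k): v for k, v in tpm_table.items()}
    universe = sorted({canonical_symbol(p) for p in proteins})
    missing = [p for p in universe if p not in tpm]
    if missing:
        warnings.warn(
            f"{len(missing)} proteins missing from expression table, treated as 0 TPM",
            stacklevel=2,
        )
    detected = frozenset(p for p in universe if tpm.get(p, 0.0) >= min_tpm)
    percent = percent_round_half_up(len(detected), len(universe)) if universe else 0
    return detected, percent


def prioritize_candidates(
    interactome: Iterable[str],
    annotations: pd.DataFrame,
    abundance: Mapping[str, float] | pd.Series,
    top_n: int = 10,
    shared_interactor_set: Iterable[str] = (),
    paralog_map: Mapping[str, str] | None = None,
    ndd_column: str = "ASD_or_ID",
) -> pd.DataFrame:
    """Assemble the validation candidate list.

    Stage 1 restricts the interactome to proteins flagged in
    ``ndd_column`` of ``annotations``, ranks them by mean emPAI
    (descending, ties broken lexicographically) and keeps the top
    ``top_n``.  Stage 2 appends members of ``shared_interactor_set``
    present in the interactome and not already chosen.  Stage 3 appends
    paralogs of stage-2 picks from ``paralog_map`` regardless of whether
    they replicated, flagged by source.  Duplicates keep their first
    source tag.
    """
    if isinstance(abundance, pd.Series):
        abundance = abundance.to_dict()
    paralog_map = dict(paralog_map or {})
    members = {canonical_symbol(p) for p in interactome}

    flagged = [
        p for p in members
        if p in annotations.index and bool(annotations.at[p, ndd_column])
    ]
    flagged.sort(key=lambda p: (-abundance.get(p, 0.0), p))
    if top_n > len(flagged):
        warnings.warn(
            f"top_n={top_n} exceeds NDD pool size {len(flagged)}; returning whole pool",
            stacklevel=2,
        )
    rows: list[dict] = []
    chosen: set[str] = set()

    def _append(protein: str, source: str) -> None:
        if protein in chosen:
            return
        chosen.add(protein)
        rows.append(
            {
                "candidate": protein,
                "source": source,
                "mean_empai": abundance.get(protein, 0.0),
            }
        )

    for p in flagged[:top_n]:
        _append(p, "top_empai_ndd")
    stage2 = sorted(canonical_symbol(s) for s in shared_interactor_set)
    for p in stage2:
        if p in members:
            _append(p, "shared_interactor")
    for source_protein in stage2:
        paralog = paralog_map.get(source_protein)
        if paralog:
            _append(canonical_symbol(paralog), "paralog_augment")
    return pd.DataFrame(rows, columns=["candidate", "source", "mean_empai"])
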