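"""Binding-region inference from a variant x interactor call matrix.

Truncating variants leave an intact N-terminal prefix of the protein;
comparing which truncations retain and which lose an interaction bounds
the region required for that interaction.  Missense variants cannot
bound a region: a losing missense call only marks its containing named
region as "involved" (or "unexplained" when the position lies in a
region shown dispensable by truncation evidence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantDef",
    "RegionDef",
    "RegionInference",
    "parse_variant",
    "variant_intact_interval",
    "infer_required_regions",
    "consistency_check",
]

CALLS = ("retained", "reduced", "abolished")

_NONSENSE = re.compile(r"^p\.([A-Z])(\d+)\*$")
_FRAMESHIFT = re.compile(r"^p\.([A-Z])(\d+)[A-Z]?fs\*(\d+)$")
_MISSENSE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class VariantDef:
    variant_id: str
    kind: str  # missense | nonsense | frameshift
    position: int
    provenance: str = "synthetic"  # de_novo | inherited | synthetic
    frameshift_tail: int | None = None


@dataclass(frozen=True)
class RegionDef:
    name: str
    start: int
    end: int  # closed interval

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def overlaps(self, interval: tuple[int, int]) -> bool:
        lo, hi = interval
        return lo <= self.end and hi >= self.start


def parse_variant(variant_id: str, provenance: str = "synthetic") -> VariantDef:
    """Parse protein-level variant nomenclature into a :class:`VariantDef`.

    Supports ``p.X123*`` (nonsense), ``p.X123Yfs*N`` (frameshift) and
    ``p.X123Y`` (missense).
    """
    m = _NONSENSE.match(variant_id)
    if m:
        return VariantDef(variant_id, "nonsense", int(m.group(2)), provenance)
    m = _FRAMESHIFT.match(variant_id)
    if m:
        return VariantDef(
            variant_id, "frameshift", int(m.group(2)), provenance,
            frameshift_tail=int(m.group(3)),
        )
    m = _MISSENSE.match(variant_id)
    if m:
        return VariantDef(variant_id, "missense", int(m.group(2)), provenance)
    raise ValueError(f"unrecognized variant nomenclature: {variant_id!r}")


def variant_intact_interval(
    variant: VariantDef | str, protein_length: int
) -> tuple[int, int]:
    """Residue interval left intact by a variant.

    Truncations at position X (nonsense or frameshift) leave ``[1, X-1]``;
    the aberrant frameshift tail is ignored.  Missense variants leave the
    full-length protein intact.
    """
    if isinstance(variant, str):
        variant = parse_variant(variant)
    if variant.kind == "missense":
        if variant.position > protein_length:
            raise ValueError(
                f"{variant.variant_id}: position {variant.position} exceeds "
                f"protein length {protein_length}"
            )
        return (1, protein_length)
    if variant.position > protein_length:
        raise ValueError(
            f"{variant.variant_id}: truncation position {variant.position} "
            f"exceeds protein length {protein_length}"
        )
    return (1, variant.position - 1)


@dataclass
class RegionInference:
    """Per-interactor region requirements derived from the call matrix."""

    interactor: str
    required_interval: tuple[int, int] | None = None
    required_regions: tuple[str, ...] = ()
    involved_regions: tuple[str, ...] = ()
    dispensable_intervals: tuple[tuple[int, int], ...] = ()
    supporting_pairs: tuple[tuple[str, str], ...] = ()  # (retaining, losing)
    reduced_intervals: tuple[tuple[int, int], ...] = ()
    missense_evidence: tuple[tuple[str, str], ...] = ()  # (variant, region or "?")
    unexplained: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "interactor": self.interactor,
            "required_interval": list(self.required_interval)
            if self.required_interval else None,
            "required_regions": list(self.required_regions),
            "involved_regions": list(self.involved_regions),
            "dispensable_intervals": [list(i) for i in self.dispensable_intervals],
            "supporting_pairs": [list(p) for p in self.supporting_pairs],
            "reduced_intervals": [list(i) for i in self.reduced_intervals],
            "missense_evidence": [list(m) for m in self.missense_evidence],
            "unexplained": list(self.unexplained),
            "warnings": list(self.warnings),
        }


def _as_call_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        frame = calls
    else:
        frame = pd.DataFrame(
            [(v, i, c) for (v, i), c in calls.items()],
            columns=["variant", "interactor", "call"],
        )
    bad = set(frame["call"]) - set(CALLS)
    if bad:
        raise ValueError(f"unknown call labels: {sorted(bad)}")
    return frame


def _variant_defs(variants) -> dict[str, VariantDef]:
    defs: dict[str, VariantDef] = {}
    for v in variants:
        if isinstance(v, VariantDef):
            defs[v.variant_id] = v
        else:
            defs[v] = parse_variant(v)
    return defs


def infer_required_regions(
    calls,
    variants: Iterable[VariantDef | str],
    regions: Sequence[RegionDef],
    protein_length: int,
) -> dict[str, RegionInference]:
    """Infer required / involved regions per interactor.

    ``calls`` is a DataFrame with ``variant``, ``interactor`` and ``call``
    columns (or a ``(variant, interactor) -> call`` mapping).

    For each interactor, every (retaining, losing) truncation pair with
    nested intact intervals emits a candidate required interval
    ``intact(retaining) \\ intact(losing)``; emitted intervals are
    intersected.  "Reduced" truncation calls count as retaining for the
    required-interval logic, but the interval between a reduced truncation
    and a fully retaining longer one is recorded as involvement evidence.
    Missense losses mark their containing named region as involved, or as
    unexplained when the position falls in an interval the truncation
    series proved dispensable.
    """
    frame = _as_call_frame(calls)
    defs = _variant_defs(variants)
    unknown = set(frame["variant"]) - set(defs)
    if unknown:
        raise ValueError(f"calls reference unknown variants: {sorted(unknown)}")

    results: dict[str, RegionInference] = {}
    for interactor, sub in frame.groupby("interactor"):
        inference = RegionInference(interactor=str(interactor))
        notes: list[str] = []
        call_of = dict(zip(sub["variant"], sub["call"]))

        truncs = {
            vid: variant_intact_interval(defs[vid], protein_length)
            for vid in call_of
            if defs[vid].kind in ("nonsense", "frameshift")
        }
        retainers = {v: iv for v, iv in truncs.items()
                     if call_of[v] in ("retained", "reduced")}
        losers = {v: iv for v, iv in truncs.items() if call_of[v] == "abolished"}

        if not truncs:
            notes.append("no truncation data: involvement-only inference")

        # Required interval: intersection over all nested retain/lose pairs.
        pairs: list[tuple[str, str]] = []
        lowers: list[int] = []
        uppers: list[int] = []
        for rv, (_, r_end) in sorted(retainers.items()):
            for lv, (_, l_end) in sorted(losers.items()):
                if l_end < r_end:  # intact(loser) strictly inside intact(retainer)
                    pairs.append((rv, lv))
                    lowers.append(l_end + 1)
                    uppers.append(r_end)
        if pairs:
            lo, hi = max(lowers), min(uppers)
            if lo <= hi:
                inference.required_interval = (lo, hi)
                inference.required_regions = tuple(
                    r.name for r in regions if r.overlaps((lo, hi))
                )
            else:
                notes.append("inconsistent truncation pairs: empty required interval")
            inference.supporting_pairs = tuple(pairs)

        # Dispensable suffix intervals from fully retaining truncations.
        dispensable = tuple(
            (end + 1, protein_length)
            for v, (_, end) in sorted(retainers.items())
            if call_of[v] == "retained" and end < protein_length
        )
        inference.dispensable_intervals = dispensable

        # Partial involvement from reduced truncations nested in retained ones.
        reduced_intervals: list[tuple[int, int]] = []
        involved: list[str] = []
        for dv, (_, d_end) in sorted(truncs.items()):
            if call_of[dv] != "reduced":
                continue
            for rv, (_, r_end) in sorted(retainers.items()):
                if call_of[rv] == "retained" and d_end < r_end:
                    interval = (d_end + 1, r_end)
                    reduced_intervals.append(interval)
                    involved.extend(
                        r.name for r in regions if r.overlaps(interval)
                    )
        inference.reduced_intervals = tuple(reduced_intervals)

        # Missense involvement.
        missense_evidence: list[tuple[str, str]] = []
        unexplained: list[str] = []
        for vid in sorted(call_of):
            vdef = defs[vid]
            if vdef.kind != "missense" or call_of[vid] == "retained":
                continue
            in_dispensable = any(
                lo <= vdef.position <= hi for lo, hi in dispensable
            )
            region_name = next(
                (r.name for r in regions if r.contains(vdef.position)), "?"
            )
            missense_evidence.append((vid, region_name))
            if in_dispensable:
                unexplained.append(vid)
            elif region_name != "?":
                involved.append(region_name)
        inference.missense_evidence = tuple(missense_evidence)
        inference.unexplained = tuple(unexplained)
        inference.involved_regions = tuple(dict.fromkeys(involved))
        inference.warnings = tuple(notes)
        results[str(interactor)] = inference
    return results


def consistency_check(
    calls,
    variants: Iterable[VariantDef | str],
    protein_length: int,
) -> list[tuple[str, str, str]]:
    """Monotonicity violations among truncating variants.

    Flags every (interactor, shorter_variant, longer_variant) where the
    strictly shorter intact prefix retains (or reduces) the interaction
    while the longer prefix abolishes it.
    """
    frame = _as_call_frame(calls)
    defs = _variant_defs(variants)
    violations: list[tuple[str, str, str]] = []
    for interactor, sub in frame.groupby("interactor"):
        call_of = dict(zip(sub["variant"], sub["call"]))
        truncs = {
            vid: variant_intact_interval(defs[vid], protein_length)[1]
            for vid in call_of
            if defs.get(vid) and defs[vid].kind in ("nonsense", "frameshift")
        }
        for shorter, s_end in sorted(truncs.items()):
            for longer, l_end in sorted(truncs.items()):
                if s_end < l_end and call_of[shorter] in ("retained", "reduced") \
                        and call_of[longer] == "abolished":
                    violations.append((str(interactor), shorter, longer))
    return violations


def render_region_map(
    inferences: Mapping[str, RegionInference],
    regions: Sequence[RegionDef],
    protein_length: int,
    width: int = 60,
) -> str:
    """Plain-text rendering of the inferred binding-region map."""
    lines = []
    scale = width / protein_length
    header = [" "] * width
    for region in regions:
        lo = int((region.start - 1) * scale)
        hi = max(lo + 1, int(region.end * scale))
        for i in range(lo, min(hi, width)):
            header[i] = "="
    lines.append(f"{'protein':>12} |{''.join(header)}| 1..{protein_length}")
    for name, inf in sorted(inferences.items()):
        row = ["."] * width
        if inf.required_interval:
            lo, hi = inf.required_interval
            for i in range(int((lo - 1) * scale), min(max(int(hi * scale), 1), width)):
                row[i] = "#"
        for lo, hi in inf.reduced_intervals:
            for i in range(int((lo - 1) * scale), min(max(int(hi * scale), 1), width)):
                if row[i] == ".":
                    row[i] = "+"
        labels = ",".join(inf.required_regions) or "-"
        lines.append(f"{name:>12} |{''.join(row)}| required: {labels}")
    return "\n".join(lines)
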