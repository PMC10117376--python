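"""Resonance-energy-transfer interaction calling from plate readings.

A plate carries two luminescence channels per well (``Blue1`` donor,
``Green1`` acceptor).  The corrected transfer ratio of an experimental
well is its Green1/Blue1 ratio minus the mean ratio of donor-only
control wells, after subtracting the mean background of untransfected
wells from both channels.  Group differences are tested by one-way ANOVA
with Tukey's HSD post-hoc (Tukey-Kramer for unbalanced designs) via the
studentized-range distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLATE_COLUMNS",
    "background_correct",
    "corrected_ratio",
    "anova_tukey",
    "call_interaction",
    "classify_variant",
    "analyze_screen",
    "TukeyResult",
    "VariantCall",
]

PLATE_COLUMNS = ("well", "condition", "construct_pair", "Blue1", "Green1")
CONDITIONS = ("experimental", "donor_only_control", "untransfected")


def _check_plate(plate: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    bad = set(plate["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")


def background_correct(plate: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Subtract the untransfected-well channel means from all other wells.

    Negative corrected readings are floored at 0; the number of floored
    values is returned alongside the corrected table (untransfected rows
    are dropped).
    """
    _check_plate(plate)
    background = plate[plate["condition"] == "untransfected"]
    if background.empty:
        raise ValueError("plate has no untransfected background wells")
    bg_blue = background["Blue1"].mean()
    bg_green = background["Green1"].mean()
    corrected = plate[plate["condition"] != "untransfected"].copy()
    corrected["Blue1"] = corrected["Blue1"] - bg_blue
    corrected["Green1"] = corrected["Green1"] - bg_green
    n_floored = int((corrected[["Blue1", "Green1"]] < 0).to_numpy().sum())
    if n_floored:
        warnings.warn(f"floored {n_floored} negative background-corrected readings",
                      stacklevel=2)
        corrected[["Blue1", "Green1"]] = corrected[["Blue1", "Green1"]].clip(lower=0)
    return corrected, n_floored


def _well_ratios(wells: pd.DataFrame) -> np.ndarray:
    usable = wells[wells["Blue1"] > 0]
    n_dropped = len(wells) - len(usable)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} wells with nonpositive Blue1", stacklevel=2)
    if usable.empty:
        raise ValueError("all wells excluded (Blue1 <= 0)")
    return (usable["Green1"] / usable["Blue1"]).to_numpy()


def corrected_ratio(experimental: pd.DataFrame, donor_only: pd.DataFrame) -> np.ndarray:
    """Per-well corrected transfer ratios.

    ``ratio_i = Green1_i/Blue1_i - mean(Green1/Blue1 over donor-only wells)``.
    Both tables must already be background-corrected.
    """
    control_mean = float(np.mean(_well_ratios(donor_only)))
    return _well_ratios(experimental) - control_mean


@dataclass(frozen=True)
class TukeyResult:
    f_statistic: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, diff, q, p_adj

    def p_between(self, a: str, b: str) -> float:
        rows = self.pairwise
        hit = rows[((rows.group_a == a) & (rows.group_b == b))
                   | ((rows.group_a == b) & (rows.group_b == a))]
        if hit.empty:
            raise KeyError(f"no pair ({a}, {b})")
        return float(hit["p_adj"].iloc[0])


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> TukeyResult:
    """One-way ANOVA with Tukey HSD adjusted pairwise p-values.

    Adjusted p-values come from the studentized-range distribution with
    the Tukey-Kramer standard error for unequal group sizes.  Requires at
    least two groups, each with at least two replicates.  A degenerate
    within-group variance of exactly 0 yields p = 1 for identical means
    and p = 0 otherwise.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays: dict[str, np.ndarray] = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 replicates")
        arrays[label] = arr

    labels = sorted(arrays)
    k = len(labels)
    n_total = sum(a.size for a in arrays.values())
    df_within = n_total - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_within
    means = {label: a.mean() for label, a in arrays.items()}

    f_stat, anova_p = stats.f_oneway(*(arrays[label] for label in labels))

    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            diff = means[a] - means[b]
            if msw == 0.0:
                q = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_within))
            rows.append({"group_a": a, "group_b": b, "diff": diff, "q": q,
                         "p_adj": min(max(p, 0.0), 1.0)})
    return TukeyResult(float(f_stat), float(anova_p), pd.DataFrame(rows))


def _tier(p: float, alphas: Sequence[float] = (0.05, 0.01, 0.001)) -> str:
    a1, a2, a3 = sorted(alphas, reverse=True)
    if p < a3:
        return "***"
    if p < a2:
        return "**"
    if p < a1:
        return "*"
    return "ns"


def call_interaction(
    groups: Mapping[str, Sequence[float]],
    control_label: str = "Rluc-NLS",
    alphas: Sequence[float] = (0.05, 0.01, 0.001),
    headline_alpha: float = 0.001,
    tukey: TukeyResult | None = None,
) -> pd.DataFrame:
    """Significance tiers of each construct pair against the donor control.

    Tiers use strict inequalities (p exactly at a threshold does not
    qualify).  ``positive`` marks pairs below the headline threshold.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if tukey is None:
        tukey = anova_tukey(groups)
    rows = []
    for label in sorted(groups):
        if label == control_label:
            continue
        values = np.asarray(groups[label], dtype=float)
        p = tukey.p_between(label, control_label)
        rows.append(
            {
                "construct_pair": label,
                "mean_ratio": values.mean(),
                "sd_ratio": values.std(ddof=1),
                "p_vs_control": p,
                "tier": _tier(p, alphas),
                "positive": p < headline_alpha,
            }
        )
    return pd.DataFrame(rows).set_index("construct_pair")


@dataclass(frozen=True)
class VariantCall:
    variant: str
    interactor: str
    call: str  # retained | reduced | abolished
    p_vs_control: float
    p_vs_wt: float


def classify_variant(
    variant_ratios: Sequence[float],
    wt_ratios: Sequence[float],
    control_ratios: Sequence[float],
    alpha: float = 0.05,
    variant: str = "variant",
    interactor: str = "",
) -> VariantCall:
    """Trichotomize a variant's interaction signal.

    abolished: not significant against the control fusion (p >= alpha).
    reduced:   significant against control AND significantly lower than
               the wild-type signal.
    retained:  everything else.
    """
    tukey = anova_tukey(
        {"variant": variant_ratios, "wt": wt_ratios, "control": control_ratios}
    )
    p_vc = tukey.p_between("variant", "control")
    p_vw = tukey.p_between("variant", "wt")
    mean_var = float(np.mean(variant_ratios))
    mean_wt = float(np.mean(wt_ratios))
    if p_vc >= alpha:
        call = "abolished"
    elif p_vw < alpha and mean_var < mean_wt:
        call = "reduced"
    else:
        call = "retained"
    return VariantCall(variant, interactor, call, p_vc, p_vw)


def call_variant_plate(
    plate: pd.DataFrame,
    wt_label: str = "WT",
    control_pair: str = "YFP-NLS",
    alpha: float = 0.05,
    interactor: str = "",
) -> list[VariantCall]:
    """Classify every variant group on one plate against WT and control.

    The plate must contain an experimental WT group, a donor-only control
    group labelled ``control_pair``, and untransfected background wells.
    """
    corrected, _ = background_correct(plate)
    donor = corrected[corrected["condition"] == "donor_only_control"]
    if donor.empty:
        raise ValueError("plate has no donor-only control wells")
    groups = {
        str(pair): corrected_ratio(wells, donor)
        for pair, wells in corrected.groupby("construct_pair")
    }
    if wt_label not in groups:
        raise ValueError(f"wild-type group {wt_label!r} missing from plate")
    if control_pair not in groups:
        raise ValueError(f"control group {control_pair!r} missing from plate")
    calls = []
    for label in sorted(groups):
        if label in (wt_label, control_pair):
            continue
        calls.append(
            classify_variant(
                groups[label], groups[wt_label], groups[control_pair],
                alpha=alpha, variant=label, interactor=interactor,
            )
        )
    return calls


def analyze_screen(
    plate: pd.DataFrame,
    control_pair: str = "Rluc-NLS",
    alphas: Sequence[float] = (0.05, 0.01, 0.001),
    headline_alpha: float = 0.001,
) -> pd.DataFrame:
    """Full plate analysis: background correction, corrected ratios per
    construct pair, omnibus ANOVA + Tukey, and tiers versus the donor-only
    control."""
    corrected, _ = background_correct(plate)
    donor = corrected[corrected["condition"] == "donor_only_control"]
    if donor.empty:
        raise ValueError("plate has no donor-only control wells")
    groups: dict[str, np.ndarray] = {}
    for pair, wells in corrected.groupby("construct_pair"):
        groups[str(pair)] = corrected_ratio(wells, donor)
    if control_pair not in groups:
        raise ValueError(f"control construct pair {control_pair!r} missing from plate")
    return call_interaction(groups, control_pair, alphas, headline_alpha)
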