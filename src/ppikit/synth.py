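"""Synthetic input generation with known ground truth.

Every input the pipeline consumes can be generated here: duplicate
bait/control PSM tables with planted interactors and contaminants, a
binary control-occurrence matrix, a confidence-scored edge list with
planted dense clusters, gene-set files, and two-channel plate readings
for both the candidate screen and the variant panel.

Randomness derives from one root seed with a fixed per-stream offset, so
each generator can be re-run independently and reproduces byte-identical
outputs for an identical configuration.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .annotate import GeneSetCollection, write_gmt
from .apfilter import DEFAULT_CONTAMINANTS

__all__ = [
    "ConfigError",
    "SynthConfig",
    "GroundTruth",
    "ApmsDataset",
    "gen_apms_dataset",
    "gen_control_occurrence",
    "gen_string_edges",
    "gen_bret_screen",
    "gen_variant_screen",
    "gen_gene_sets",
    "write_all",
]

BAIT_REPLICATES = ("AP1", "AP2")


class ConfigError(ValueError):
    """Invalid synthetic-data configuration; message names the field."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic universe.

    ``peptide_count_range`` and ``observable_peptide_range`` are closed
    integer intervals.  ``planted_clusters`` is a list of
    ``(size, density)`` pairs with density in (0, 1].  ``bret_truth``
    maps candidate ids to nonnegative transfer efficiencies; ``None``
    selects the packaged 15-candidate panel.
    """

    n_true_interactors: int = 50
    n_contaminant_shared: int = 10
    n_crapome_frequent: int = 8
    n_named_contaminants: int = 3
    n_control_only: int = 5
    replicate_overlap_fraction: float = 1.0
    peptide_count_range: tuple[int, int] = (2, 8)
    observable_peptide_range: tuple[int, int] = (5, 30)
    low_score_fraction: float = 0.15
    n_control_experiments: int = 30
    planted_clusters: tuple[tuple[int, float], ...] = ((6, 1.0), (6, 1.0))
    background_edge_prob: float = 0.01
    bret_truth: Mapping[str, float] | None = None
    bret_noise_cv: float = 0.02
    bret_base_ratio: float = 0.4
    bret_donor_level: float = 1e5
    bret_background: tuple[float, float] = (500.0, 250.0)
    n_wells_per_condition: int = 3
    variant_truth: Mapping[tuple[str, str], str] | None = None
    n_asd: int = 11
    n_id: int = 24
    asd_id_overlap: int = 4
    n_tf: int = 20
    n_epigenetic: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_true_interactors", "n_contaminant_shared", "n_crapome_frequent",
            "n_named_contaminants", "n_control_only", "n_wells_per_condition",
            "n_asd", "n_id", "asd_id_overlap", "n_tf", "n_epigenetic",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_control_experiments < 1:
            raise ConfigError("n_control_experiments must be >= 1")
        for name in ("replicate_overlap_fraction", "low_score_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("peptide_count_range", "observable_peptide_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ConfigError(f"{name} must be a positive ordered interval")
        for size, density in self.planted_clusters:
            if size < 0:
                raise ConfigError("planted_clusters sizes must be >= 0")
            if not 0.0 < density <= 1.0:
                raise ConfigError("planted_clusters densities must be in (0, 1]")
        if self.bret_noise_cv < 0:
            raise ConfigError("bret_noise_cv must be >= 0")
        if self.asd_id_overlap > min(self.n_asd, self.n_id):
            raise ConfigError("asd_id_overlap exceeds min(n_asd, n_id)")
        for candidate, eff in (self.bret_truth or {}).items():
            if eff < 0:
                raise ConfigError(f"bret_truth[{candidate!r}] must be >= 0")

    def effective_bret_truth(self) -> dict[str, float]:
        truth = self.bret_truth
        if truth is None:
            truth = fixtures.DEFAULT_BRET_TRUTH
        return dict(truth)

    def effective_variant_truth(self) -> dict[tuple[str, str], str]:
        truth = self.variant_truth
        if truth is None:
            truth = fixtures.INTERACTION_CALL_GRID
        return dict(truth)


@dataclass
class GroundTruth:
    """Planted facts the pipeline is expected to recover."""

    true_interactors: frozenset[str] = frozenset()
    true_in_both_replicates: frozenset[str] = frozenset()
    contaminants: frozenset[str] = frozenset()
    crapome_excluded: frozenset[str] = frozenset()
    planted_cluster_membership: dict[str, int] = field(default_factory=dict)
    bret_positive_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.true_interactors & self.contaminants:
            raise ValueError("true interactors and contaminants must be disjoint")

    def to_json(self, path) -> None:
        payload = {
            "true_interactors": sorted(self.true_interactors),
            "true_in_both_replicates": sorted(self.true_in_both_replicates),
            "contaminants": sorted(self.contaminants),
            "crapome_excluded": sorted(self.crapome_excluded),
            "planted_cluster_membership": dict(
                sorted(self.planted_cluster_membership.items())
            ),
            "bret_positive_set": sorted(self.bret_positive_set),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class ApmsDataset:
    baits: dict[str, pd.DataFrame]
    controls: dict[str, pd.DataFrame]
    observable_counts: pd.Series
    truth: GroundTruth


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    # Per-stream derivation: root seed plus a stable hash of the stream name.
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode())])


def _id_layout(cfg: SynthConfig) -> dict[str, list[str]]:
    rng = _rng(cfg, "layout")
    named_pool = sorted(DEFAULT_CONTAMINANTS)
    named = list(
        rng.choice(named_pool, size=min(cfg.n_named_contaminants, len(named_pool)),
                   replace=False)
    )
    return {
        "true": [f"INT{i:04d}" for i in range(1, cfg.n_true_interactors + 1)],
        "shared": [f"SHC{i:03d}" for i in range(1, cfg.n_contaminant_shared + 1)],
        "crapome": [f"CRP{i:03d}" for i in range(1, cfg.n_crapome_frequent + 1)],
        "named": sorted(named),
        "control_only": [f"CTL{i:03d}" for i in range(1, cfg.n_control_only + 1)],
    }


def _split_replicates(cfg: SynthConfig, true_ids: Sequence[str]) -> dict[str, list[str]]:
    n_both = int(round(cfg.replicate_overlap_fraction * len(true_ids)))
    both = list(true_ids[:n_both])
    only = {"AP1": [], "AP2": []}
    for i, protein in enumerate(true_ids[n_both:]):
        only[BAIT_REPLICATES[i % 2]].append(protein)
    return {
        "both": both,
        "AP1": both + only["AP1"],
        "AP2": both + only["AP2"],
    }


def _psm_rows(
    rng: np.random.Generator,
    cfg: SynthConfig,
    protein: str,
    n_observable: int,
    experiment: str,
    condition: str,
) -> list[dict]:
    lo, hi = cfg.peptide_count_range
    n_obs = min(int(rng.integers(lo, hi + 1)), n_observable)
    rows = []
    for i in range(n_obs):
        rows.append(
            {
                "protein_id": protein,
                "peptide_seq": f"{protein}_PEP{i + 1:02d}",
                "mascot_score": 40.0 + rng.gamma(2.0, 15.0),
                "experiment": experiment,
                "condition": condition,
            }
        )
    n_low = int(rng.binomial(max(n_obs, 1), cfg.low_score_fraction))
    for i in range(n_low):
        rows.append(
            {
                "protein_id": protein,
                "peptide_seq": f"{protein}_LOW{i + 1:02d}",
                "mascot_score": rng.uniform(10.0, 39.5),
                "experiment": experiment,
                "condition": condition,
            }
        )
    return rows


def gen_apms_dataset(cfg: SynthConfig) -> ApmsDataset:
    """Two bait and two control PSM tables with planted ground truth.

    True interactors never appear in control tables; a configurable
    fraction appears in both bait replicates.  Shared contaminants appear
    in bait and control tables; named contaminants (drawn from the
    packaged contaminant list) and panel-frequent proteins appear in both
    bait replicates only.
    """
    layout = _id_layout(cfg)
    split = _split_replicates(cfg, layout["true"])
    rng = _rng(cfg, "apms")

    all_proteins = sorted(
        set(layout["true"]) | set(layout["shared"]) | set(layout["crapome"])
        | set(layout["named"]) | set(layout["control_only"])
    )
    obs_lo, obs_hi = cfg.observable_peptide_range
    observable = pd.Series(
        rng.integers(obs_lo, obs_hi + 1, size=len(all_proteins)),
        index=pd.Index(all_proteins, name="protein_id"),
        name="n_observable",
    )

    baits: dict[str, pd.DataFrame] = {}
    controls: dict[str, pd.DataFrame] = {}
    for rep in BAIT_REPLICATES:
        bait_proteins = sorted(
            set(split[rep]) | set(layout["shared"]) | set(layout["crapome"])
            | set(layout["named"])
        )
        rows: list[dict] = []
        for protein in bait_proteins:
            rows.extend(
                _psm_rows(rng, cfg, protein, int(observable[protein]), rep, "bait")
            )
        baits[rep] = pd.DataFrame(
            rows, columns=["protein_id", "peptide_seq", "mascot_score",
                           "experiment", "condition"],
        )
        ctrl_proteins = sorted(set(layout["shared"]) | set(layout["control_only"]))
        rows = []
        for protein in ctrl_proteins:
            rows.extend(
                _psm_rows(rng, cfg, protein, int(observable[protein]), rep, "control")
            )
        controls[rep] = pd.DataFrame(
            rows, columns=["protein_id", "peptide_seq", "mascot_score",
                           "experiment", "condition"],
        )

    truth = GroundTruth(
        true_interactors=frozenset(layout["true"]),
        true_in_both_replicates=frozenset(split["both"]),
        contaminants=frozenset(layout["shared"]) | frozenset(layout["named"]),
        crapome_excluded=frozenset(layout["crapome"]),
        bret_positive_set=frozenset(
            c for c, eff in cfg.effective_bret_truth().items()
            if eff >= fixtures.POSITIVE_MIN_EFFICIENCY
        ),
    )
    return ApmsDataset(baits, controls, observable, truth)


def gen_control_occurrence(cfg: SynthConfig) -> pd.DataFrame:
    """Binary protein x control-experiment matrix.

    Panel-frequent proteins occur in at least 2 of the
    ``n_control_experiments`` columns; every other bait protein occurs in
    at most 1.
    """
    layout = _id_layout(cfg)
    rng = _rng(cfg, "occurrence")
    proteins = sorted(
        set(layout["true"]) | set(layout["shared"]) | set(layout["crapome"])
        | set(layout["named"])
    )
    frequent = set(layout["crapome"])
    n = cfg.n_control_experiments
    columns = [f"CTRL{i:02d}" for i in range(1, n + 1)]
    matrix = pd.DataFrame(
        0, index=pd.Index(proteins, name="protein_id"), columns=columns, dtype=int
    )
    for protein in proteins:
        if protein in frequent:
            occ = int(rng.integers(2, n + 1)) if n >= 2 else n
        else:
            occ = int(rng.integers(0, 2))
        if occ:
            hits = rng.choice(n, size=occ, replace=False)
            matrix.iloc[matrix.index.get_loc(protein), sorted(hits)] = 1
    return matrix


def gen_string_edges(
    protein_ids: Iterable[str] | None,
    cfg: SynthConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Scored edge table with planted dense clusters.

    Within-cluster edges appear with probability equal to the configured
    density and carry scores >= 0.700 with experimental/database
    evidence; background edges are sparse with uniform scores in
    [0.15, 1.0) and arbitrary evidence channels.  Returns the edge table
    and the planted cluster membership map.
    """
    if protein_ids is None:
        protein_ids = _id_layout(cfg)["true"]
    proteins = sorted(set(protein_ids))
    total_planted = sum(size for size, _ in cfg.planted_clusters)
    if total_planted > len(proteins):
        raise ConfigError(
            "planted_clusters sizes exceed the number of proteins"
        )
    rng = _rng(cfg, "edges")

    membership: dict[str, int] = {}
    cursor = 0
    for cluster_id, (size, _) in enumerate(cfg.planted_clusters, start=1):
        for protein in proteins[cursor:cursor + size]:
            membership[protein] = cluster_id
        cursor += size

    rows: list[dict] = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            same = membership.get(a) is not None and membership.get(a) == membership.get(b)
            if same:
                density = cfg.planted_clusters[membership[a] - 1][1]
                if rng.random() < density:
                    channels = ["experimental", "database"][: int(rng.integers(1, 3))]
                    rows.append(
                        {
                            "protein_a": a,
                            "protein_b": b,
                            "combined_score": float(rng.uniform(0.700, 1.0)),
                            "channels": ",".join(channels),
                        }
                    )
            elif rng.random() < cfg.background_edge_prob:
                pool = ["experimental", "database", "textmining"]
                picked = rng.choice(pool, size=int(rng.integers(1, 3)), replace=False)
                rows.append(
                    {
                        "protein_a": a,
                        "protein_b": b,
                        "combined_score": float(rng.uniform(0.15, 1.0)),
                        "channels": ",".join(sorted(picked)),
                    }
                )
    edges = pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "combined_score", "channels"]
    )
    return edges, membership


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _plate_rows(
    rng: np.random.Generator,
    cfg: SynthConfig,
    construct_pair: str,
    condition: str,
    efficiency: float,
    start_index: int,
) -> list[dict]:
    bg_blue, bg_green = cfg.bret_background
    n = cfg.n_wells_per_condition
    rows = []
    if condition == "untransfected":
        blue = bg_blue * _noise_factors(rng, cfg.bret_noise_cv, n)
        green = bg_green * _noise_factors(rng, cfg.bret_noise_cv, n)
    else:
        donor = cfg.bret_donor_level * _noise_factors(rng, cfg.bret_noise_cv, n)
        ratio = cfg.bret_base_ratio + efficiency
        blue = bg_blue + donor
        green = bg_green + donor * ratio * _noise_factors(rng, cfg.bret_noise_cv, n)
    for i in range(n):
        rows.append(
            {
                "well": f"W{start_index + i:03d}",
                "condition": condition,
                "construct_pair": construct_pair,
                "Blue1": float(blue[i]),
                "Green1": float(green[i]),
            }
        )
    return rows


def gen_bret_screen(
    cfg: SynthConfig, control_pair: str = "Rluc-NLS"
) -> pd.DataFrame:
    """Plate readings for the candidate screen.

    One experimental group per candidate in ``bret_truth`` plus
    donor-only control wells (zero transfer) and untransfected
    background wells.
    """
    truth = cfg.effective_bret_truth()
    for candidate, eff in truth.items():
        if eff < 0:
            raise ConfigError(f"bret_truth[{candidate!r}] must be >= 0")
    rng = _rng(cfg, "bret")
    rows: list[dict] = []
    index = 1
    for candidate in sorted(truth):
        rows.extend(
            _plate_rows(rng, cfg, candidate, "experimental", truth[candidate], index)
        )
        index += cfg.n_wells_per_condition
    rows.extend(_plate_rows(rng, cfg, control_pair, "donor_only_control", 0.0, index))
    index += cfg.n_wells_per_condition
    rows.extend(_plate_rows(rng, cfg, "none", "untransfected", 0.0, index))
    return pd.DataFrame(rows, columns=["well", "condition", "construct_pair",
                                       "Blue1", "Green1"])


def gen_variant_screen(
    cfg: SynthConfig,
    control_pair: str = "YFP-NLS",
    wt_label: str = "WT",
) -> dict[str, pd.DataFrame]:
    """One plate per interactor for the variant panel.

    Planted calls come from ``variant_truth`` (default: the packaged call
    grid); transfer efficiencies per class follow
    :data:`ppikit.fixtures.VARIANT_CLASS_EFFICIENCY`.
    """
    grid = cfg.effective_variant_truth()
    interactors = sorted({interactor for _, interactor in grid})
    rng = _rng(cfg, "variants")
    plates: dict[str, pd.DataFrame] = {}
    for interactor in interactors:
        rows: list[dict] = []
        index = 1
        rows.extend(
            _plate_rows(
                rng, cfg, wt_label, "experimental",
                fixtures.VARIANT_CLASS_EFFICIENCY["retained"], index,
            )
        )
        index += cfg.n_wells_per_condition
        variants = sorted(v for v, i in grid if i == interactor)
        for variant in variants:
            eff = fixtures.VARIANT_CLASS_EFFICIENCY[grid[(variant, interactor)]]
            rows.extend(_plate_rows(rng, cfg, variant, "experimental", eff, index))
            index += cfg.n_wells_per_condition
        rows.extend(
            _plate_rows(rng, cfg, control_pair, "donor_only_control", 0.0, index)
        )
        index += cfg.n_wells_per_condition
        rows.extend(_plate_rows(rng, cfg, "none", "untransfected", 0.0, index))
        plates[interactor] = pd.DataFrame(
            rows, columns=["well", "condition", "construct_pair", "Blue1", "Green1"]
        )
    return plates


def gen_gene_sets(
    cfg: SynthConfig, universe: Sequence[str] | None = None
) -> GeneSetCollection:
    """GMT-writable TF / epigenetic / ASD / ID sets with configured
    ASD-ID overlap."""
    layout = _id_layout(cfg)
    needed = cfg.n_tf + cfg.n_epigenetic + cfg.n_asd + cfg.n_id
    if universe is None:
        universe = list(layout["true"])
    universe = list(dict.fromkeys(universe))
    filler = [f"GSX{i:04d}" for i in range(1, max(0, needed - len(universe)) + 1)]
    pool = universe + filler
    rng = _rng(cfg, "genesets")
    order = list(rng.permutation(pool))

    def take(n: int) -> list[str]:
        picked, rest = order[:n], order[n:]
        order[:] = rest
        return picked

    asd_only = take(cfg.n_asd - cfg.asd_id_overlap)
    overlap = take(cfg.asd_id_overlap)
    id_only = take(cfg.n_id - cfg.asd_id_overlap)
    collection = GeneSetCollection()
    collection.add("TF", take(cfg.n_tf), "synthetic transcription-factor list")
    collection.add("EPI", take(cfg.n_epigenetic), "synthetic epigenetic-factor list")
    collection.add("ASD", asd_only + overlap, "synthetic ASD candidate list")
    collection.add("ID", id_only + overlap, "synthetic ID panel list")
    return collection


def write_all(cfg: SynthConfig, outdir) -> dict[str, Path]:
    """Generate every input and write it under ``outdir``.

    Returns a name -> path map of everything written.  Identical configs
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(frame: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        frame.to_csv(path, float_format="%.6f", **kwargs)
        paths[name] = path

    dataset = gen_apms_dataset(cfg)
    for rep, table in dataset.baits.items():
        _write(table, f"psm_{rep.lower()}.tsv", sep="\t", index=False)
    for rep, table in dataset.controls.items():
        _write(table, f"psm_ctrl_{rep.lower()}.tsv", sep="\t", index=False)
    _write(dataset.observable_counts.to_frame(), "observable_counts.tsv", sep="\t")

    occurrence = gen_control_occurrence(cfg)
    _write(occurrence, "control_occurrence.tsv", sep="\t")

    edges, membership = gen_string_edges(None, cfg)
    _write(edges, "edges.tsv", sep="\t", index=False)
    dataset.truth.planted_cluster_membership = membership

    plate = gen_bret_screen(cfg)
    _write(plate, "plate.csv", index=False)

    variant_plates = gen_variant_screen(cfg)
    combined = pd.concat(
        [p.assign(interactor=i) for i, p in sorted(variant_plates.items())],
        ignore_index=True,
    )
    _write(combined, "variant_plates.csv", index=False)

    panel = pd.DataFrame(
        [dataclasses.asdict(v) for v in fixtures.VARIANT_PANEL]
    )
    _write(panel, "variant_panel.tsv", sep="\t", index=False)

    sets = gen_gene_sets(cfg)
    gmt_path = outdir / "gene_sets.gmt"
    write_gmt(sets, gmt_path)
    paths["gene_sets.gmt"] = gmt_path

    truth_path = outdir / "truth.json"
    dataset.truth.to_json(truth_path)
    paths["truth.json"] = truth_path
    return paths
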