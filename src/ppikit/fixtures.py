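"""Packaged default fixtures: the validation candidate panel, the variant
panel, the published interaction-call grid, and named protein regions.

These encode the study design the toolkit reproduces (a 15-candidate
screen with five strong interactors, and a 13-variant x 5-interactor
call grid for binding-region mapping) and double as ground truth for the
synthetic generators.
"""

from __future__ import annotations

from .domains import RegionDef, VariantDef

#: Length of the bait protein (residues).
PROTEIN_LENGTH = 682

#: Named regions of the bait protein (closed residue intervals).
DEFAULT_REGIONS = (
    RegionDef("T-box", 213, 393),
    RegionDef("C-terminal", 394, 567),
)

#: The fifteen screen candidates: ten ranked by mean emPAI among
#: NDD-annotated hits, three shared-interactor picks, two paralogs.
BRET_CANDIDATES = (
    "KDM1A", "GATAD2B", "NCKAP1", "YY1", "CSNK2A1",
    "TBL1XR1", "CTNND1", "BCOR", "ADNP", "SMARCA2",
    "CTBP1", "NR2F2", "ZMYM2",
    "CTBP2", "NR2F1",
)

SHARED_INTERACTOR_SET = ("CTBP1", "NR2F2", "ZMYM2")
PARALOG_MAP = {"CTBP1": "CTBP2", "NR2F2": "NR2F1"}

#: Configured transfer efficiencies: five strong interactors, two weak
#: signals, the rest null.
DEFAULT_BRET_TRUTH = {
    "KDM1A": 0.0,
    "GATAD2B": 0.12,
    "NCKAP1": 0.0,
    "YY1": 0.0,
    "CSNK2A1": 0.0,
    "TBL1XR1": 0.0,
    "CTNND1": 0.0,
    "BCOR": 0.10,
    "ADNP": 0.11,
    "SMARCA2": 0.0,
    "CTBP1": 0.0,
    "NR2F2": 0.10,
    "ZMYM2": 0.02,
    "CTBP2": 0.018,
    "NR2F1": 0.09,
}

#: Transfer efficiency at or above which a candidate counts as a planted
#: positive (expected to reach the headline significance threshold).
POSITIVE_MIN_EFFICIENCY = 0.05

#: Variant panel: nine missense (five de novo in the DNA-binding box,
#: four inherited), two patient truncations, two synthetic truncations.
VARIANT_PANEL = (
    VariantDef("p.K228E", "missense", 228, "de_novo"),
    VariantDef("p.W271C", "missense", 271, "de_novo"),
    VariantDef("p.W271R", "missense", 271, "de_novo"),
    VariantDef("p.N374H", "missense", 374, "de_novo"),
    VariantDef("p.K389E", "missense", 389, "de_novo"),
    VariantDef("p.Q178E", "missense", 178, "inherited"),
    VariantDef("p.V356M", "missense", 356, "inherited"),
    VariantDef("p.Q418R", "missense", 418, "inherited"),
    VariantDef("p.P542R", "missense", 542, "inherited"),
    VariantDef("p.A136Pfs*80", "frameshift", 136, "de_novo", frameshift_tail=80),
    VariantDef("p.S351*", "nonsense", 351, "de_novo"),
    VariantDef("p.N394*", "nonsense", 394, "synthetic"),
    VariantDef("p.S568*", "nonsense", 568, "synthetic"),
)

VALIDATED_INTERACTORS = ("GATAD2B", "BCOR", "ADNP", "NR2F1", "NR2F2")

#: Published-shaped call grid: variant x interactor -> call.
INTERACTION_CALL_GRID = {
    # GATAD2B
    ("p.K228E", "GATAD2B"): "retained",
    ("p.W271C", "GATAD2B"): "retained",
    ("p.W271R", "GATAD2B"): "retained",
    ("p.N374H", "GATAD2B"): "retained",
    ("p.K389E", "GATAD2B"): "retained",
    ("p.Q178E", "GATAD2B"): "retained",
    ("p.V356M", "GATAD2B"): "retained",
    ("p.Q418R", "GATAD2B"): "abolished",
    ("p.P542R", "GATAD2B"): "retained",
    ("p.A136Pfs*80", "GATAD2B"): "abolished",
    ("p.S351*", "GATAD2B"): "abolished",
    ("p.N394*", "GATAD2B"): "abolished",
    ("p.S568*", "GATAD2B"): "retained",
    # BCOR
    ("p.K228E", "BCOR"): "retained",
    ("p.W271C", "BCOR"): "retained",
    ("p.W271R", "BCOR"): "reduced",
    ("p.N374H", "BCOR"): "retained",
    ("p.K389E", "BCOR"): "retained",
    ("p.Q178E", "BCOR"): "retained",
    ("p.V356M", "BCOR"): "retained",
    ("p.Q418R", "BCOR"): "reduced",
    ("p.P542R", "BCOR"): "retained",
    ("p.A136Pfs*80", "BCOR"): "abolished",
    ("p.S351*", "BCOR"): "abolished",
    ("p.N394*", "BCOR"): "abolished",
    ("p.S568*", "BCOR"): "retained",
    # ADNP
    ("p.K228E", "ADNP"): "abolished",
    ("p.W271C", "ADNP"): "abolished",
    ("p.W271R", "ADNP"): "retained",
    ("p.N374H", "ADNP"): "abolished",
    ("p.K389E", "ADNP"): "abolished",
    ("p.Q178E", "ADNP"): "retained",
    ("p.V356M", "ADNP"): "retained",
    ("p.Q418R", "ADNP"): "abolished",
    ("p.P542R", "ADNP"): "retained",
    ("p.A136Pfs*80", "ADNP"): "abolished",
    ("p.S351*", "ADNP"): "abolished",
    ("p.N394*", "ADNP"): "retained",
    ("p.S568*", "ADNP"): "retained",
    # NR2F1
    ("p.K228E", "NR2F1"): "reduced",
    ("p.W271C", "NR2F1"): "reduced",
    ("p.W271R", "NR2F1"): "reduced",
    ("p.N374H", "NR2F1"): "reduced",
    ("p.K389E", "NR2F1"): "abolished",
    ("p.Q178E", "NR2F1"): "retained",
    ("p.V356M", "NR2F1"): "retained",
    ("p.Q418R", "NR2F1"): "reduced",
    ("p.P542R", "NR2F1"): "retained",
    ("p.A136Pfs*80", "NR2F1"): "abolished",
    ("p.S351*", "NR2F1"): "abolished",
    ("p.N394*", "NR2F1"): "reduced",
    ("p.S568*", "NR2F1"): "retained",
    # NR2F2
    ("p.K228E", "NR2F2"): "retained",
    ("p.W271C", "NR2F2"): "reduced",
    ("p.W271R", "NR2F2"): "reduced",
    ("p.N374H", "NR2F2"): "reduced",
    ("p.K389E", "NR2F2"): "abolished",
    ("p.Q178E", "NR2F2"): "retained",
    ("p.V356M", "NR2F2"): "retained",
    ("p.Q418R", "NR2F2"): "reduced",
    ("p.P542R", "NR2F2"): "retained",
    ("p.A136Pfs*80", "NR2F2"): "abolished",
    ("p.S351*", "NR2F2"): "abolished",
    ("p.N394*", "NR2F2"): "reduced",
    ("p.S568*", "NR2F2"): "retained",
}

#: Effect sizes used when simulating plates from a planted call class.
VARIANT_CLASS_EFFICIENCY = {"retained": 0.40, "reduced": 0.20, "abolished": 0.0}
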