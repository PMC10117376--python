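# ppikit

Toolkit for characterizing a bait protein's interactome from
affinity-purification mass-spectrometry (AP-MS) screens, with downstream
network clustering, gene-set annotation, resonance-energy-transfer (BRET)
interaction calling, and binding-region inference from variant panels.
A synthetic-data module generates every input with planted ground truth,
so the whole pipeline is testable offline.

## Components

| module              | what it does |
|---------------------|--------------|
| `ppikit.synth`      | synthetic PSM tables, control-occurrence matrix, scored edge lists, gene sets, and plate readings, all with known ground truth |
| `ppikit.quant`      | PSM score filtering (score = −10·log10 P, threshold 40) and emPAI abundance (`10^(observed/observable) − 1`) with cross-experiment averaging and ranking |
| `ppikit.apfilter`   | four-stage set-logical funnel: known contaminants, control subtraction, control-panel occurrence (>1 of 30 excluded), replicate intersection — with per-stage retention reports |
| `ppikit.netgraph`   | graph construction from confidence-scored edges (score ≥ 0.700, experimental/database evidence) and a from-scratch MCODE-style dense-cluster detector |
| `ppikit.annotate`   | GMT gene-set annotation, category counts with half-up integer percentages, set overlaps, expression filtering, and candidate prioritization |
| `ppikit.bret`       | background correction, corrected transfer ratios, one-way ANOVA + Tukey HSD (studentized range), interaction tiers, and variant retained/reduced/abolished calls |
| `ppikit.domains`    | required/involved binding-region inference from truncation and missense call matrices, with consistency checking |
| `ppikit.pipeline`   | convenience wiring from raw PSM tables to the final ranked interactome |

## CLI

All commands live under one entry point:

```bash
ppikit synth all --seed 1 --outdir data/            # generate every input
ppikit quant --psm data/psm_ap1.tsv --psm data/psm_ap2.tsv \
    --observable data/observable_counts.tsv -o abundance.tsv
ppikit filter --ap1 data/psm_ap1.tsv --ap2 data/psm_ap2.tsv \
    --controls data/psm_ctrl_ap1.tsv data/psm_ctrl_ap2.tsv \
    --crapome data/control_occurrence.tsv -o interactome.tsv
ppikit network --edges data/edges.tsv -o netdir/
ppikit annotate --interactome interactome.tsv --gmt data/gene_sets.gmt -o anndir/
ppikit bret --plate data/plate.csv --control Rluc-NLS -o bretdir/
ppikit domains --calls calls.tsv -o domains.json
```

`ppikit synth all` accepts `--config cfg.yaml` with overrides for any
`SynthConfig` field; identical config + seed produces byte-identical
files.

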