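# memidr

Intrinsic-disorder analysis for membrane proteins: per-residue disorder
scoring, IDR calling (30-residue rule), topology-side localization and
occupancy statistics, predictor-concordance tables, amino-acid
enrichment, PTM/PPI density statistics, and disorder-guided orientation
of multi-pass membrane proteins — plus a synthetic-proteome generator
with planted ground truth so every stage is testable offline.

## Package layout

| module | what it does |
| --- | --- |
| `memidr.io` | FASTA and feature-TSV I/O (`TRANSMEM`/`TOPO_DOM`, 1-based inclusive), pass-type classification |
| `memidr.predict` | charge/hydropathy and TOP-IDP-scale disorder tracks, external-score ingestion, consensus fusion |
| `memidr.idr` | binarization, maximal-run IDR calling, IDP/FOP labels, percent-inclusion tables |
| `memidr.topology` | topology models with alternation inference, side localization, side/occupancy/length statistics |
| `memidr.orient` | two-candidate orientation scoring from IDR placement + the positive-inside rule |
| `memidr.stats` | composition and enrichment, PTM density/co-localization, interaction-degree statistics |
| `memidr.simulate` | synthetic membrane proteomes with planted IDRs, PTM sites and PPI edges |
| `memidr.pipeline` | end-to-end runs from a YAML config, manifest with content hashes, markdown report |

## CLI

```bash
memidr simulate --seed 1 --n-proteins 50 --out sim/
memidr predict --fasta sim/proteome.fasta --method foldindex --window 21 --out scores.tsv
memidr idr --scores scores.tsv --threshold 0 --lower-is-disordered --out idrs.tsv
memidr map --fasta sim/proteome.fasta --features sim/features.tsv --idrs idrs.tsv --out sides.tsv
memidr orient --fasta sim/proteome.fasta --tm sim/features.tsv --out orientation.tsv
memidr run --config run.yaml        # full pipeline, all tables + report.md
```

A `run.yaml` for a simulated dataset:

```yaml
outdir: out/
simulate: {n_proteins: 100}
seed: 7
predictor: foldindex
window: 21
```

Coordinates are 1-based inclusive everywhere. Score tracks are TSV
(`protein_id  position  score`); all outputs are TSV with headers.

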