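# rxntemplater

Automated extraction of reaction templates from heterogeneous reaction
databases. The pipeline reads reactions from identifier lists (SMILES/InChI),
MDL RXN (V2000) directories, or CHEMKIN mechanism files with identifier
comments, determines or adopts atom–atom mappings, extracts the reactive
center of each reaction, and formalizes deduplicated templates as SMARTS
patterns with an edit recipe, auto-generated molecular constraints, and
reversibility links. A built-in application engine replays any template
against arbitrary reactants, which makes end-to-end round-trip validation
possible without an external network generator.

## Command line

All stages are exposed through a single `templater` entry point. Intermediate
corpora are stored as `.rxnd` bundles — a directory of mapped RXN files plus a
JSON index — so any stage can be rerun or inspected in isolation.

```bash
# ingest a CHEMKIN network (species must carry "! <SMILES or InChI>" comments)
templater ingest --format chemkin --input mech.inp --max-reactants 2 --out corpus.rxnd

# compute atom-atom mappings (records that already carry one are left alone)
templater map --corpus corpus.rxnd --mapper baseline --out mapped.rxnd

# per-reaction change sets and reactive centers
templater extract --mapped mapped.rxnd --hetero --out changes.jsonl

# deduplicated template table + distribution report
templater templates --corpus mapped.rxnd --out templates.yaml --report distribution.csv

# apply extracted templates to new reactants
templater apply --templates templates.yaml --reactants smiles.txt

# synthetic corpus generation and round-trip validation
templater synth --families h_abstraction:0.47,beta_scission:0.2,addition:0.33 \
    --n 500 --seed 42 --out synth.rxnd
templater validate --corpus synth.rxnd

# everything at once, from a YAML config
templater run --config run.yaml
```

A `run.yaml` contains the fields of `RunConfig`:

```yaml
input_path: mech.inp
input_format: chemkin   # list | rxn | chemkin | rxnd
mapper: baseline        # baseline | premapped
include_hetero: true
max_reactants: 2
seed: 42
out_dir: out
```

`run` writes `templates.yaml`, `distribution.csv`, `records.jsonl` (per-record
mapping/mechanism status) and `manifest.json` (stage counts) into `out_dir`.

## Template file

`templates.yaml` contains, per template: the center SMARTS for every reactant
(atoms annotated with neighbor counts `X` and valences `v`), one atom-first
SMARTS per labeled center atom, the recipe (ordered bond/electron edits
against those labels), auto-generated constraints (global heavy-atom maximum,
per-reactant single-electron maximum), an empty kinetics placeholder block for
group-additivity data, and provenance (representative count, reverse-template
link, source reaction ids). The file round-trips: `templater apply` rebuilds
working templates from it.

## Data

The two networks above ship as supplementary material of the source
publication and are not redistributed in this repository. Everything else —
unit fixtures, synthetic corpora, round-trip validation — is generated
programmatically at run time.
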