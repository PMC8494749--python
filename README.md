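# sdrfkit

Public proteomics repositories hold tens of thousands of mass-spectrometry
datasets, but reanalysis routinely stalls on the same missing piece: a
machine-readable statement of which biological sample went into which data
file, through which channel, fraction and replicate. The SDRF-Proteomics
extension of MAGE-TAB answers that with two tab-delimited files — an **IDF**
(key/value study description) and an **SDRF** (one row per sample↔data-file
relationship). `sdrfkit` is a toolkit for that representation: it parses,
validates, generates, merges/splits and converts SDRF and IDF files, so
experimental designs (label-free, TMT, SILAC, fractionated, multiplexed) are
machine-checkable and directly convertible into the inputs quantification
pipelines expect.

It is aimed at dataset submitters (validate before deposition), curators
(check and repair third-party annotations at scale) and reanalysis pipeline
authors (turn an SDRF into search parameters and a design table without
hand-editing).

## The representation

An SDRF table has three sections, left to right:

* **sample metadata** — `source name` plus `characteristics[...]` columns
  (organism, organism part, biological replicate, disease, ...);
* **data-file properties** — `assay name` plus `comment[...]` columns
  (data file, label, fraction identifier, technical replicate, instrument,
  cleavage agent, tolerances, modifications);
* **variables under study** — `factor value[...]` columns.

Each row relates one sample to one acquisition. Multiplexing (TMT/SILAC)
repeats the file properties once per channel of a run; fractionation repeats
the sample metadata once per fraction. A design with S biological replicates,
T technical replicates and F fractions therefore always has S×T×F rows,
while the number of distinct data files is S×T×F for label-free and
⌈S/plex⌉×T×F for multiplexed designs.

Search-relevant cells use a small key/value micro-syntax, e.g. methionine
oxidation as

```
AC=UNIMOD:35;NT=Oxidation;MT=Variable;TA=M
```

(`AC` accession, `NT` name, `MT` Fixed/Variable/Annotated, `TA` target
residues; `PP`, `MM`, `CF`, `CS` carry position, monoisotopic mass, formula
and cleavage-site information).

Validation is rule-based and severity-graded: structural rules S1–S14
(mandatory columns, per-sample and per-file consistency, channel uniqueness,
label sanity), template rules for experiment types (default, human,
cell-line; shipped as editable YAML schemas), and vocabulary rules V1–V3
that check accessions against bundled offline snapshots of EFO, PSI-MS,
PRIDE, UNIMOD and NCBITaxon. A table is valid exactly when no ERROR-level
finding fires.

## Worked example

Expand a TMT design with three multiplexed samples and three fractions,
validate it, and flatten it into an annotation table:

```python
from sdrfkit import (DesignSpec, QuantMethod, generate_design,
                     validate, load_default_cv, to_annotation_table)

spec = DesignSpec(quant_method=QuantMethod.TMT10, n_biological=3, n_fractions=3)
table = generate_design(spec)
print(f"rows: {table.n_rows}")
print(validate(table, "default", load_default_cv()).to_text())
```

prints

```
rows: 9
WARNING [S10] (column 'comment[cleavage agent]'): recommended column missing
WARNING [S10] (column 'comment[fragment mass tolerance]'): recommended column missing
WARNING [S10] (column 'comment[modification parameters]'): recommended column missing
WARNING [S10] (column 'comment[precursor mass tolerance]'): recommended column missing
0 error(s), 4 warning(s), 0 info -> VALID
```

Nine rows: three samples repeated over three fractions, with the three
fractions sharing each mixture's channel layout, and the whole table valid
(the warnings note recommended search-parameter columns the minimal design
omits). `to_annotation_table(table).write_csv(...)` then yields one row per
relationship:

```
run,fraction,label,bio_replicate,tech_replicate,condition
run_1_1_1,1,TMT126,1,1,normal
run_1_1_1,1,TMT127N,2,1,disease
run_1_1_1,1,TMT127C,3,1,normal
run_1_1_2,2,TMT126,1,1,normal
...
```

— three runs × three channels, each row carrying the channel, fraction,
replicate and condition a quantification tool needs.

The same operations are available from the shell:

```sh
sdrfkit generate design.txt -o experiment.sdrf.tsv
sdrfkit validate experiment.sdrf.tsv --template human --json report.json
sdrfkit convert experiment.sdrf.tsv --annotation design.csv --params params/
sdrfkit merge a.sdrf.tsv b.sdrf.tsv -o merged.sdrf.tsv
sdrfkit split experiment.sdrf.tsv --by 'comment[fraction identifier]' -o parts/
sdrfkit idf build dataset.txt -o study.idf.tsv
```

Exit codes: 0 valid, 1 validation errors, 2 usage/I-O error.

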