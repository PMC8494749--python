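# Methods

## The data model

`sdrfkit` treats an SDRF file as an ordered matrix of verbatim text cells
under typed column keys. A `ColumnKey` is (category, attribute, occurrence):
the category is one of `source name`, `characteristics`, `comment`,
`factor value`, `assay name`; the attribute is the bracketed name, stored
lower-cased and whitespace-normalized so `Characteristics [Organism]` and
`characteristics[organism]` are the same column; the occurrence index
(1-based) distinguishes repeated columns such as several
`comment[modification parameters]`. Header parsing accepts the dialects seen
in circulating files (case variation, space before the bracket); writing
always emits the canonical lowercase no-space form, so parse∘format is the
identity on canonical headers and a many-to-one normalization otherwise.

Cell text is never trimmed or reinterpreted by the reader: typed meaning
(modifications, tolerances, ontology terms) is extracted on demand by the
micro-syntax parsers, and every parser has a serializer such that
parse(serialize(x)) == x. The key/value grammar splits on `;` then on the
first `=`, upper-cases keys, preserves order, and rejects duplicate keys; a
cell with no `=` at all is shorthand for `NT=<cell>`. `MT` defaults to
`Variable` when absent so the shorthand stays usable for the common case of
a single variable modification. The tolerance grammar is deliberately
minimal — `<number><ws?><unit>` with unit `ppm` or `Da`, value > 0 — the
smallest grammar that is unambiguous for the two tolerance columns.
Cleavage agents use keys `NT`/`AC`/`CS` (name, accession, cleavage-site
regular expression); no published key set exists for enzymes, so the
modification convention is reused with `CS` for the one enzyme-specific
datum. Unknown keys are preserved verbatim and surfaced by the validator at
INFO level rather than rejected, for forward compatibility.

Missing values: `not available` is emitted for cells a merge cannot fill,
and `not applicable` is additionally recognized as a missing token on read.
Only genuinely empty cells trigger the empty-required-cell rule; the
explicit tokens are deliberate annotations, not omissions.

## Row semantics and the design generator

Every row is one sample↔file relationship. Label-free: one file per
(sample, technical replicate, fraction). Multiplexed: samples are packed
into mixtures of at most one plex (channel lists in fixed order — TMT6/10/11
channel names, SILAC light/medium/heavy); one file per (mixture, technical
replicate, fraction), with the file's rows repeated once per occupied
channel. SILAC designs must fill every channel (the run is meaningless
otherwise), so the sample count must be a multiple of the plex; TMT mixtures
may leave trailing channels empty. Technical re-injections of a mixture
reuse the same sample→channel assignment, reflecting how a labeled mixture
is physically re-measured. Under these semantics the row count is always
`n_biological × n_technical × n_fractions` and the distinct-file count is
`groups × n_technical × n_fractions` with groups = samples (label-free) or
⌈samples/plex⌉ (multiplexed); both identities are exercised against a
brute-force enumeration oracle over randomized designs.

Generator defaults describe a minimal realistic human study: organism
`Homo sapiens`, organism part `liver`, factor `phenotype` with levels
(`normal`, `disease`) assigned round-robin to biological replicates, a
Q Exactive instrument cell carrying its PSI-MS accession, and deterministic
`sample {i}` / `run {j}` / `{prefix}_{mix}_{tech}_{fraction}.raw` naming.
Generation is fully deterministic; the `seed` field is accepted and stored
so randomized layouts can be added without an interface change. The
generator emulates design *structure* — multiplexing, fractionation,
replication, balanced factors — not the messiness of real submissions
(free-text vocabulary drift, missing columns, inconsistent replicate
numbering, mixed instruments within a dataset). Passing the generated-design
suites therefore demonstrates that the toolkit's operations are mutually
consistent on well-formed designs; robustness to real-world files is
covered separately by the rule tests that damage tables deliberately.

## Validation

Validation is total: it never raises on bad data, and every problem is a
finding (severity, stable rule id, message, optional row/column). The
structural registry:

| id | severity | rule |
|----|----------|------|
| S1 | ERROR | exactly one `source name` and one `assay name` column |
| S2 | ERROR | `comment[data file]` present |
| S3 | ERROR | characteristics present: organism, organism part, biological replicate |
| S4 | ERROR | comments present: fraction identifier, technical replicate |
| S5 | ERROR | no empty cell in any required column |
| S6 | ERROR | fraction identifiers are positive integers |
| S7 | ERROR | rows of one sample agree on every characteristics cell |
| S8 | ERROR | rows of one file agree on fraction id, technical replicate, instrument |
| S9 | ERROR | a (data file, label) channel belongs to at most one sample |
| S10 | WARNING | recommended comments missing (instrument, cleavage agent, tolerances, modifications) |
| S11 | WARNING | label outside the bundled channel list |
| S12 | WARNING | exact duplicate rows (preserved, never dropped) |
| S13 | INFO | factor value column with a single distinct value |
| S14 | ERROR | `comment[label]` missing (label-free rows use `label free sample`) |

The data-file requirement is S2 and is not re-checked under S4, so deleting
that one column raises exactly one error. `comment[label]` is required for
*all* designs, with the sentinel `label free sample` for unlabeled runs:
this keeps row identity uniform — (data file, label) is always the assay
key — at the cost of one extra column for label-free studies. Biological
replicate is modeled as a property of the sample, technical replicate as a
property of the data file, which is what S7 and S8 enforce.

Templates layer experiment-type policy on top: they are YAML schemas of
rules (`require_column`, `fixed_value`, `expect_value` with a severity
each), so a repository can tighten requirements by editing data, not code.
Bundled: `default` (nothing extra), `human` (disease required as ERROR,
ancestry as WARNING, organism fixed to `Homo sapiens`, INFO when no sample
carries the control value `normal`), `cell-line` (cell line required;
requesting the template is taken as opting into that check, so it is an
ERROR). Severity grades for the "should"-level policies are this package's
choice.

Vocabulary checks run against an offline store built from bundled 3-column
TSV snapshots (accession, label, prefix) of small, reviewable subsets of
EFO/UBERON/PATO/MONDO, PSI-MS, UNIMOD, NCBITaxon and channel labels. Free
text is always accepted — only cells that explicitly carry an `AC` key are
checked (unknown accession, or stored label differing from the cell's `NT`,
each a WARNING). The store is a strict bijection between accessions and
(prefix, label) pairs; later snapshot files override earlier ones on
collision, logged. No hierarchy traversal or reasoning is attempted. The
TMT/SILAC label snapshot is synthetic in its accession ids (the channel
names are the standard ones; no verified public id list was bundled) and is
named accordingly.

Reports are deterministic: findings are sorted by (rule family, rule
number, row, column), so identical inputs give byte-identical text and JSON.

## Converters

`extract_search_params` produces one record per distinct data file. Values
are collected across the file's rows and must be unanimous (ignoring
missing tokens); conflicts raise an error naming the file and column, since
a file cannot have two enzymes. All occurrence-indexed modification columns
are parsed and partitioned by `MT`: fixed and variable populate the search
lists, `Annotated` modifications (observations, not search settings) are
echoed in a separate section. Output is a neutral YAML document per file
with a stable key order — tool-specific configuration dialects are
serialization skins over this record and are out of scope.

`to_annotation_table` flattens the SDRF one-to-one into
(run, fraction, label, bio_replicate, tech_replicate, condition) rows: the
run is the data-file name with only its final extension stripped (case
preserved), and the condition joins the factor-value cells with `_` in
column order — a single printable, order-stable token. A table with no
factor value column is rejected, because the variables under study are the
point of the exercise. Both converters are pure functions of the table.

## Merging and splitting

Merging concatenates rows under the union of columns (first-appearance
order, matched by canonical key), filling absent cells with
`not available`. The one hard error: the same source name appearing in two
inputs with conflicting characteristics, since sample identity must stay
unambiguous in a meta-analysis. Merge is associative up to column order and
has the empty table as identity. Splitting partitions rows by one column's
values, keeping all columns and relative row order, so split-then-merge
reproduces the original row multiset exactly.

## IDF

IDF documents are ordered key→values entries, keys unique
case-insensitively, values possibly many per key with Person* keys
column-aligned (the i-th value of each describes the i-th person). A
neutral `DatasetDescription` record (title, description, submitters,
instruments, software, publications, keywords) maps deterministically onto
IDF keys — names split on the last whitespace into first/last — and the
mapping inverts on its own image. Only `Investigation Title` is treated as
mandatory; the key vocabulary is otherwise open and unknown keys are
preserved.

## Problem sizes and numerical notes

The property suites run 100 randomized designs with S, T, F ≤ 5 (SILAC
sample counts rounded to a full plex), a size at which brute-force
enumeration of sample–file relationships is exact and instantaneous while
still covering every quantification method and the mixture-packing edge
cases. Monoisotopic masses round-trip through `repr` (shortest exact float
rendering); fraction identifiers are validated as decimal integers with no
leading zeros; header parsing has no numeric content. Degenerate inputs are
defined: an empty table is invalid (S1–S4, S14 fire), an empty row list
writes a header-only file, splitting by a constant column returns the input
unchanged, and merging with an empty table is the identity.

## Limitations

No streaming parser (tables are held in memory); no spreadsheet input; no
protocol/term-source declarations from classic transcriptomics MAGE-TAB; no
chemical-formula validation or accession↔mass cross-checking beyond the
label comparison; CV snapshots are small curated subsets, so unknown-
accession warnings on real files may simply mean the term is outside the
snapshot; only the default/human/cell-line templates ship, though the
schema mechanism accepts user-supplied template files.
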