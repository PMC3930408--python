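# genesig

Reusable pipeline for comparing differential-expression gene lists and
scoring expression profiles against a rank-based multi-category tumour
signature:

- **genelists** — standardize heterogeneous published lists into a common
  GeneID space via an offline many-to-many mapping table, with direction
  annotations, probe-call aggregation (I/MI/NC/MD/D sums, strict ±5.5
  thresholds), and TSV/GMT I/O.
- **overlap** — hypergeometric tail probabilities P(X ≥ k) for pairwise
  list intersections against an explicit finite universe, star-graded
  (\*/\*\*/\*\*\* at 0.05/0.01/0.001), assembled into a many-vs-many
  significance matrix with optional direction stratification and
  Benjamini–Hochberg adjustment.
- **ddct** — qPCR ΔΔCt relative quantification (mean-reference ΔCt,
  control-group-mean calibrator, rq = 2^−ΔΔCt), one-way ANOVA on ΔCt, and
  thresholded up/down/unchanged calls feeding the scorer.
- **tumor_score** — per-gene contribution B = 1 − C·R with C = 1/HR per
  category, raw/complement/ideal/relative scores, diagnosability at
  relative ≥ 0.4, and category-specific marker counting.
- **synthetic** — seeded generators for universes, list pairs with forced
  or null overlap, scoring tables, direction profiles with a controlled
  match fraction, and Ct matrices with planted group shifts.
- **cli** — `genesig` command tying the stages together with manifests.

## CLI

```bash
genesig simulate --seed 1 --out sim/
genesig standardize --input raw.tsv --mapping map.tsv --out std/
genesig overlap --lists-a fshd/ --lists-b cancer/ --universe-size 20000 --out ov/
genesig ddct --ct sim/ct_values.csv --annotations sim/ct_annotations.tsv \
    --control-group control --out dd/
genesig score --table sim/scoring_table.tsv --profile dd/direction_profile.tsv \
    --out sc/
genesig run --config pipeline.yaml --out run/
```

`genesig run` executes stages declared in a YAML config
(`stages: [{stage: overlap, lists_a: ..., ...}, ...]`), validates every
input up front, and writes per-stage outputs, a combined `report.json`
(byte-identical across reruns) and a `manifest.json` with input digests.

### File formats

Everything is plain text: gene lists as 2-column TSV (`gene_id`,
`direction`) or GMT; mapping tables as 2-column TSV (repeated rows =
many-to-many); call matrices as CSV with I/MI/NC/MD/D tokens; scoring
tables as TSV (`gene`, `category`, `sign`, `rank`, `specific_category`);
Ct matrices as CSV plus a sample→group annotation TSV whose
`#reference<TAB>gene` rows flag reference genes.

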