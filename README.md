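# drugfunnel

A genomic-driven drug-repurposing pipeline, implemented as a tested,
reusable Python package. The analysis chain is:

1. **Gene universe** — a mutation-derived gene list (synthetic surrogate).
2. **Five-channel scoring** — four gene-set annotation channels scored by
   hypergeometric over-representation analysis (BH FDR < 0.05 within each
   channel) plus an expression channel (moderated two-group t, BH-adjusted
   p < 0.05 and log2 fold-change > 2, up-regulated, union across datasets).
   Each channel contributes a binary per-gene indicator; genes scoring
   **>= 2 of 5** are biological risk genes.
3. **Druggability** — risk genes intersected with a drug–target table
   (withdrawn drugs excluded by default) to produce druggable genes and the
   candidate drug pool.
4. **Connectivity ranking** — each candidate's rank profile is scored
   against a reference compound's two-tailed signature (unweighted KS
   running sum, discordance-combined, percentile-normalized to tau in
   [-100, 100] against a touchstone background); candidates keep w > 0 and
   tau > 80.
5. **Evidence triage** — each candidate is classified as clinical (max
   trial phase), preclinical (publications only) or none, and the final
   report, summary counts and drug–target edge list are emitted.

All inputs are plain-text files (gene lists, GMT, TSV matrices); a
synthetic-data module generates every input with planted structure
(risk-gene enrichment, expression shifts, reference-correlated compound
profiles), and a small packaged fixture provides a deterministic worked
example (13 candidate drugs, 12 maximum-score genes).

## CLI

```sh
# generate synthetic inputs
drugfunnel simulate --seed 1 --outdir inputs/

# run end-to-end (synthetic | fixture | files)
drugfunnel run --mode synthetic --seed 1 --outdir out/
drugfunnel run --mode fixture --outdir out-fixture/
drugfunnel run --mode files --indir inputs/ --outdir out-files/

# thresholds are flags
drugfunnel run --mode synthetic --seed 1 --outdir out/ \
    --fdr 0.05 --logfc-min 2 --score-min 2 --tau-min 80
```

A YAML config (`--config config.yaml`) can set any pipeline field plus a
`sim:` section with the synthetic-data knobs (see
`drugfunnel.synthetic.SimConfig`). Every run writes all stage artifacts,
a `funnel.json` summary and a SHA-256 `MANIFEST.txt`; identical config and
seed give byte-identical output trees. Exit codes: 0 success, 2 config
error, 3 data-format error, 4 stage failure.

## Layout

```
src/drugfunnel/
  synthetic.py     input generators + packaged fixture
  deg.py           normalization, moderated t, BH, DEG calling
  ora.py           hypergeometric ORA + channel indicators
  scoring.py       five-channel score, risk rule, diagnostics
  druggability.py  drug-target intersection
  connectivity.py  signature, KS enrichment, tau, candidate filter
  evidence.py      evidence classification and final report
  pipeline.py      orchestration, config, manifest
  io.py            text-format readers/writers
  cli.py           click CLI
tests/             unit + property + acceptance suites
scripts/acceptance.py
```
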