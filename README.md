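# slimnet

Short-linear-motif (SLiM) discovery with ortholog-conservation validation,
plus rule-based expansion of a two-paralog scaffold-protein interaction
network. The package re-implements, as tested reusable code, an in-silico
sequence analysis workflow for large multidomain scaffold proteins:

- **`slimnet.seqfeatures`** — per-sequence annotation: regex SLiM scanning
  against an ELM-style pattern table, an intrinsic-disorder proxy (TOP-IDP
  scale, window 21) with optional import of precomputed per-residue scores,
  compositionally biased region detection (serine-rich windows, poly-Q /
  poly-P runs), repeat-unit scanning against position-weighted ANK (33-mer)
  and TPR (34-mer, small/large signature) consensus profiles, residue
  periodicity detection, and global pairwise paralog alignment with
  coordinate mapping.
- **`slimnet.conservation`** — ortholog-MSA column conservation
  (identity fraction or normalised entropy), per-motif ortholog re-match
  support, and the validation gate: a motif is accepted when it lies in a
  disordered region and is conserved among orthologs (both measures
  thresholded; isoform-region overlap is reported as supporting evidence).
- **`slimnet.network`** — curated interaction-table ingestion, binding-site
  assignment via a motif/binder-domain compatibility map, cross-paralog
  interaction transfer (shared SLiM, or shared globular domain at lower
  confidence), mutual-exclusivity grouping on single-copy sites, printed
  count summaries, and GraphML/SIF/TSV export.
- **`slimnet.variants`** — HGVS-p missense parsing, region/feature mapping,
  and aggregation of external pathogenicity-predictor votes (the predictors
  themselves are never run).
- **`slimnet.synthetic`** — deterministic generator of proteins with
  ordered/disordered blocks, planted motifs/repeats/bias regions, ortholog
  families with substitution/indel noise and per-motif retention, and
  interaction tables with planted transferable edges — all with a
  JSON-serialisable truth manifest so the full pipeline is testable offline.

Packaged fixtures under `src/slimnet/data/` carry the curated reference
data (interaction table, motif placements, per-member accepted sites,
compatibility map). The motif regex table is a documented *reconstruction*
of the named ELM motif classes — the upstream motif resource does not
version-pin its regexes — and can be overridden with `--patterns`.

## CLI

```sh
slimnet features --fasta proteins.fasta --out-dir out/        # SLiMs, disorder, bias, repeats
slimnet validate --fasta ref.fasta --msa family.afa --reference ACC --out validated.json
slimnet network  --out-dir net/                               # packaged fixtures; add --recompute-motifs
slimnet variants --hgvs p.Arg760Cys --protein Q9HCD6 \
                 --regions regions.tsv --votes votes.tsv --out variants.json
slimnet simulate --scenario scenario.yaml --out-dir sim/      # synthetic data + truth manifest
```

All flags can be mirrored in a YAML config (`--config`); explicit flags win.
Coordinates are 1-based inclusive throughout.

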