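# readthru

Detection of transcription read-through — RNA-seq signal extending past the
annotated transcription termination site (TTS) — between two conditions of a
strand-specific experiment. Read-through is the standard proxy for mRNA
isoforms with lengthened 3'UTRs arising from shifts in alternative
polyadenylation (APA), e.g. after knockdown of a factor that enforces
proximal poly(A)-site usage.

The package is aimed at analysts who have per-library aligned fragment
positions (BED6) and gene models (BED12/GTF) and want reproducible,
threshold-based read-through calls, metagene profiles and the associated
statistics — plus a synthetic-data generator so the whole pipeline can be
exercised and validated without any external dataset.

## What it computes

For gene *g* with exonic length *L* and a downstream window of length *W*
(default 5 kb) past the TTS, each library contributes

* body FPKM = n_body / (L/10³) / (N/10⁶)
* read-through FPKM = n_window / (W/10³) / (N/10⁶)

with *N* the library's mapped fragments and counts taken over strand-matched
fragment 5' ends. Genes are tiered by control body FPKM (High > 500, Middle
100–500, Low 10–100); read-through is called **up** when the replicate-mean
fold change of window FPKM exceeds 1.4 and **down** below 0.5, among genes
with window FPKM > 0.5 in at least one condition; genes with an expressed
same-strand neighbour inside the window are excluded. Profiles average tags
per million in 50-bp bins around the TSS/TTS, or over a length-scaled gene
body with 3-kb flanks. Two-sample Kolmogorov–Smirnov (exact D, asymptotic
p), exact r×c Fisher, Pearson co-occupancy with clustering order, and
Welch's t-test cover the comparisons. See `docs/methods.md` for the full
model and its assumptions.

## Worked example

Simulate a 300-gene experiment in which one sixth of the genes triple their
read-through fraction in the perturbed condition, then run the full
pipeline:

```bash
cat > pipeline.yaml <<EOF
seed: 11
simulation:
  n_genes: 300
EOF
readthru run --config pipeline.yaml --out demo
```

which prints

```
calls: up=42, down=0, unchanged=168, excluded_overlap=30, excluded_low=60
```

Of the 300 genes, 30 sit too close to an expressed downstream neighbour and
are excluded (their window signal is not attributable to read-through), 60
have too little window signal to call (FPKM ≤ 0.5 in both conditions), and
42 are called up — the simulation's 50 affected genes minus those that are
silent or excluded, with a handful of noise calls (the truth table in
`demo/truth.tsv` has the per-gene answer). `demo/report.json` records row
counts, the call summary, KS comparisons of the condition profiles — e.g.
the scaled gene-body profile shifts with D = 0.31, p ≈ 5 × 10⁻⁸ — and a
sha256 manifest: rerunning with the same config and seed reproduces every
file byte-for-byte.

Individual stages are addressable (`readthru simulate / quantify / classify
/ metagene / stats`); each reads and writes plain TSV, e.g.

```bash
readthru quantify --annotation demo/genes.bed12 \
  --tags control=1=demo/control_1.bed6 --tags control=2=demo/control_2.bed6 \
  --tags perturbed=1=demo/perturbed_1.bed6 --tags perturbed=2=demo/perturbed_2.bed6 \
  --window 5000 --out quant.tsv
```

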