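# riboprof

Ribosome-profiling analysis for synaptic-fraction (synaptoneurosome)
Ribo-seq experiments — and, more generally, for any experiment that pairs a
ribosome-footprint library with a total-mRNA control aligned to transcript
references.

Ribosome profiling sequences the ~28–30 nt mRNA fragments protected from
RNase I digestion by translating ribosomes. Because elongating ribosomes
step in 3-nt codons, genuine footprints carry a geometric signature that a
randomly fragmented total-mRNA control lacks: a sharp read-length peak, a
strong preference for one reading frame, 5′-end density that begins ~12 nt
upstream of start codons (the initiating ribosome's footprint edge) and dies
~15 nt upstream of stop codons (the terminating ribosome's P-site never
being the stop codon), and a 3-nt periodicity along the CDS. `riboprof`
computes these QC statistics, estimates the 5′-end → P-site offset, and then
quantifies translation per gene:

```
RPKM_g = count_g · 10⁹ / (mapped_total · length_g)
TE_g   = RPKM_g(footprints, CDS length) / RPKM_g(total mRNA, transcript length)
```

where a footprint counts toward a gene when its inferred P-site
(5′ end + offset) falls in a sense codon of the gene's representative
transcript. Top-N gene lists ranked by mRNA abundance or translational
efficiency (TE) can be intersected with external reference lists and tested
for term enrichment with the upper-tail hypergeometric p-value and the more
conservative EASE score (the same tail with one overlapping gene removed),
Benjamini–Hochberg adjusted.

A synthetic-data generator produces a transcriptome (FASTA + annotation
TSV), footprint and total-mRNA libraries (SAM), a gene→term table and the
generative ground truth, so the whole pipeline runs and is testable without
any sequencing download.

## Worked example

Simulate a 200-gene study and run QC, quantification and enrichment
end-to-end:

```bash
cat > run.yaml <<EOF
simulation:
  n_genes: 200
  seed: 42
top_n: 100
EOF
riboprof all --config run.yaml --outdir demo
```

`demo/run_report.json` then contains (abridged):

```json
{
  "estimated_offset": 12,
  "modal_length": 29,
  "frame_fractions": [0.9024, 0.0494, 0.0482],
  "top_terms": [
    {"term_id": "term_high_te", "p_ease": 1.95e-18, "q_bh": 3.90e-17}
  ]
}
```

Reading this: the P-site offset estimator recovered 12 nt (the onset of
footprint 5′-end density upstream of start codons); the modal footprint
length is 29 nt, inside the expected 28–30 nt peak; 90% of footprint 5′
ends sit in frame 1, matching the simulated periodicity fidelity of 0.9;
and the term seeded into high-TE genes tops the enrichment table at an EASE
p far below the 10⁻⁴ reporting threshold while background terms do not.
Per-gene counts, RPKM and TE are in `demo/quant/gene_quant.tsv`, the ranked
lists in `demo/quant/top_te.txt` / `top_mrna.txt`, and the full enrichment
table in `demo/enrichment.tsv`.

Each stage is also available separately (`riboprof simulate | qc | quant |
enrich`, see `--help`), and everything the CLI does can be called as
library functions (`riboprof.metagene`, `riboprof.estimate_psite_offset`,
`riboprof.build_gene_quant_table`, `riboprof.enrich`, …).

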