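# fusiontriage

Tertiary-analysis toolkit for potentially functional **out-of-frame kinase
gene fusions** from RNA-seq fusion-caller output:

* **reading-frame recomputation** for chimeric transcripts (callers' frame
  labels are recorded but re-derived from sequence),
* **ORF-rescue scanning** — enumeration of downstream ATG start codons that
  lie in the 3′ partner's native codon frame and therefore restore a
  kinase-domain-containing open reading frame, with mapping of each start to
  its wild-type protein residue,
* the **5′/3′ exon-count expression-imbalance test** (exact, tie-aware
  Wilcoxon rank-sum on per-exon read counts, with the dual-gene significance
  rule),
* a **five-criterion triage workflow** (druggable kinase 3′ partner,
  in-strand orientation, recomputed out-of-frame, kinase-domain
  preservation, 5′/3′ imbalance) with an auditable report, including
  reclassification of caller-labeled out-of-frame fusions that recompute as
  in-frame,
* a **synthetic fixture generator** producing fully self-contained toy
  references, engineered fusions (controlled frame shift, planted premature
  stops and frame-restoring ATGs) and negative-binomial exon-count tables —
  so everything is testable offline.

## Input formats

| Input | Format |
| --- | --- |
| genome | FASTA (soft-masked bases uppercased on load) |
| annotation | Ensembl-dialect GTF (`exon`, `CDS`, `stop_codon`; attributes `gene_id`, `gene_name`, `transcript_id`, `exon_number`) |
| fusion calls | three caller dialects: `dialect_A` (Arriba-style), `dialect_F` (FusionCatcher-style), `dialect_S` (STAR-Fusion-style); see `fusiontriage/fusion_calls.py` docstring for exact columns |
| exon counts | featureCounts-style TSV: `gene transcript contig start end strand count` (1-based inclusive intervals) |
| protein domains | TSV: `gene domain start_res end_res` (1-based inclusive residues) |
| druggable-kinase list | one gene per line (optional `gene<TAB>note`); a default list ships in `fusiontriage.triage.DEFAULT_DRUGGABLE_KINASES` |

## CLI

```bash
# generate a self-contained fixture (toy reference + engineered fusion +
# caller tables in all three dialects + exon counts):
fusiontriage simulate --out-dir fixtures --seed 1
# or the nine-fusion triage demonstration panel:
fusiontriage simulate --out-dir panel --seed 1 --panel

# full five-criterion triage:
fusiontriage triage \
  --genome fixtures/genome.fa --annotation fixtures/annotation.gtf \
  --calls fixtures/calls_dialect_A.tsv --dialect dialect_A \
  --calls fixtures/calls_dialect_F.tsv --dialect dialect_F \
  --calls fixtures/calls_dialect_S.tsv --dialect dialect_S \
  --counts fixtures/exon_counts.tsv --domains fixtures/domains.tsv \
  --gene-list fixtures/gene_list.txt --out report.tsv

# frame/ORF-rescue report from a fusion cDNA:
fusiontriage frame --genome fixtures/genome.fa \
  --annotation fixtures/annotation.gtf --cdna fixtures/fusion_cdna.fa \
  --five-gene GENEA --three-gene KINB --domains fixtures/domains.tsv \
  --out frame.json

# imbalance test only:
fusiontriage imbalance --annotation fixtures/annotation.gtf \
  --counts fixtures/exon_counts.tsv \
  --calls fixtures/calls_dialect_F.tsv --dialect dialect_F --out imb.tsv
```

Options may also come from a YAML config (`--config run.yaml`; flags win).
Exit codes: 0 success, 2 usage error, 3 input format error.

## Library layout

| Module | Contents |
| --- | --- |
| `fusiontriage.reference_io` | genome/GTF/domain/gene-list I/O, transcript models, spliced sequences |
| `fusiontriage.fusion_calls` | caller-dialect parsers, breakpoint normalization, cross-caller harmonization, in-strand check |
| `fusiontriage.frame_rescue` | fusion transcript reconstruction, frame classification, downstream-start scanning, residue mapping, FASTA/JSON export |
| `fusiontriage.imbalance` | exon-count vectors, breakpoint split, exact/asymptotic rank-sum test, per-gene and dual-gene assessment |
| `fusiontriage.triage` | five-criterion evaluation, final classification, TSV/JSON reports |
| `fusiontriage.synthetic` | toy reference/fusion/count generator and the nine-fusion panel |
| `fusiontriage.cli` | `fusiontriage` command-line entry points |
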