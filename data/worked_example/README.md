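# Worked example bundle (not distributed)

Place here, to enable the index-case worked example
(`tests/test_acceptance.py::test_worked_example_cbx3_alk` and the t1/t2/t3
targets of `scripts/acceptance.py`):

* `genome.fa`       - sequence covering the CBX3 and ALK loci (contig names
                      matching the annotation; Ensembl GRCh38 works)
* `annotation.gtf`  - Ensembl-dialect GTF with the canonical CBX3 and ALK
                      transcripts (exon + CDS features)
* `fusion_cdna.fa`  - the CBX3::ALK fusion cDNA (journal supplementary
                      material)

These files are external reference data and cannot be bundled with or
downloaded by this repository.
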