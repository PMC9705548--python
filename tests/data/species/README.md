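# Per-species gene sets (not distributed)

The per-species reproduction test consumes real genome scrapes that are too
large to ship with the package. To run it, place one directory per species
here, named exactly:

    H_sapiens/  M_musculus/  D_melanogaster/  A_thaliana/
    S_cerevisiae/  S_pombe/  T_thermophila/

Each directory must contain:

- `genome.fa` or `genome.fa.gz` — the genome assembly (FASTA).
- `genes.bed` (BED12) or `annotations.tsv` (GtRNAdb-style table with header
  columns `gene_id contig start end strand isotype anticodon`, 1-based
  inclusive coordinates, optional `intron_starts`/`intron_ends`).

Sources: GtRNAdb (http://gtrnadb.ucsc.edu/) for the first six species and
the UCSC Genome Browser for the *T. thermophila* assembly, matching the
assemblies the published gene counts refer to.
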