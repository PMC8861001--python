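# splnet

**SPL gene-family identification and miR156-centred ceRNA network inference
for four-stage heteromorphic-leaf transcriptomes.**

*Populus euphratica* produces four leaf shapes with increasing tree age —
linear (Li), lanceolate (La), ovate (Ov) and broad-ovate (Bo). The
juvenile-to-adult transition behind this heteromorphy is driven by the
conserved miR156–SPL module: miR156 declines with age, de-repressing
SQUAMOSA promoter-binding protein-like (SPL/SBP-box) transcription
factors, while long non-coding RNAs and circular RNAs can buffer miR156 as
competing endogenous RNAs (ceRNAs). `splnet` re-implements the full desk
analysis of this system as a tested, seed-reproducible pipeline:

1. **Gene-family identification** — homology screen (exact affine-gap
   Smith–Waterman, BLOSUM62; aligned-region identity ≥ 0.80 and
   Karlin–Altschul E-value < 1e-5) followed by a full-length SBP-domain
   PSSM scan and longest-isoform deduplication.
2. **Physicochemical profiling** — ExPASy-convention molecular weight,
   theoretical pI (bisection on the Henderson–Hasselbalch charge curve),
   GRAVY (Kyte–Doolittle) and the Guruprasad instability index.
3. **Phylogeny** — p-distance neighbor joining on the aligned domain
   windows with column-bootstrap supports (default 1000 replicates).
4. **Expression** — FPKM (mRNA/lncRNA), TPM (miRNA) and RPM (circRNA
   back-splice junction reads) normalisation; log2 fold-change stage
   contrasts binned into the categorical fold classes Up/Down A–D
   (linear fold in (1,2], (2,5], (5,10], >10); comparative-Ct
   (2^−ΔΔCt) ratios for qPCR checks.
5. **miR156 target scoring** — plant-style penalty scoring of miRNA/target
   duplexes (mismatch 1, G:U wobble 0.5, gap 2, penalties doubled at miRNA
   positions 2–13, at most one gap, site cutoff 3.0), including circRNA
   back-splice junction pseudo-sequences.
6. **ceRNA network assembly** — ceRNA–miR156–mRNA triads per stage
   contrast from shared miRNA response elements (MREs), positive
   expression correlation, and opposite-direction differential expression
   of the miRNA; export to SIF/GraphML/TSV for Cytoscape.

Because the original sequencing data cannot be bundled, a first-class
**synthetic-data generator** reproduces the study design — four stages with
replicated negative-binomial counts, declining miR156, rising SPL targets,
planted MREs and triads, redundant splice isoforms, decoy proteins — so
that every stage can be scored against known ground truth.

## Worked example

Run the whole pipeline on a mid-sized synthetic study:

```yaml
# config.yaml
seed: 1
outdir: run1
n_bootstrap: 200
synthetic:
  n_mrna: 120
  n_lncrna: 40
  n_circrna: 12
  n_mirna: 8            # miR156 family members
  n_background_mirna: 40
  n_spl_loci: 8
  n_truncated_decoys: 4
  n_random_decoys: 4
  seed: 1
```

```text
$ splnet run-all --config config.yaml
run complete: run1
  simulate: {'n_transcripts': 220, 'n_proteins': 19}
  identify: {'n_queries': 19, 'n_screened': 11, 'n_full_length_domain': 11, 'n_canonical': 8}
  physchem: {'n_profiles': 8}
  tree: {'n_taxa': 8, 'n_bootstrap': 200}
  quantify: {'n_features': 220, 'n_samples': 12, 'n_contrasts': 6}
  targets: {'n_mirnas': 48, 'n_sites': 43}
  network: {'n_shared_mre_pairs': 50, 'n_correlated_pairs': 21, 'n_triad_pairs': 16, 'n_triads': 47, 'n_triads_per_contrast': {'La/Li': 2, 'Ov/Li': 16, 'Bo/Li': 16, 'Ov/La': 0, 'Bo/La': 13, 'Bo/Ov': 0}}
  recovery: precision=1.000 recall=1.000
```

Reading the output: 19 simulated proteins enter the screen; the 11 SPL
isoform records pass the homology thresholds while the domain-free and
truncated-domain decoys fail (identities 0.22–0.73 in this run, against
0.92 for true SPLs), all 11 carry a full-length SBP domain, and isoform
deduplication leaves the 8 canonical SPLs — exactly the planted set. Of 220 transcripts, 43 miR156
binding sites are found; shared-MRE pairing gives 50 candidate ceRNA–mRNA
pairs, positive-correlation filtering keeps 21, and the differential-
expression gates leave 16 pairs forming 47 triads across the six stage
contrasts — most in the Ov/Li, Bo/Li and Bo/La contrasts where the
simulated trends are strongest, mirroring the expected polarity (miR156
down, SPL mRNAs up, toward broad-ovate leaves). `recovery` compares the
(ceRNA, miRNA, mRNA) triples against the planted truth.

Per-stage artifacts land in `run1/`: `spl_canonical.fasta`,
`physchem.tsv`, `tree.nwk` (bootstrap supports as internal labels),
`contrasts.tsv`, `mre.tsv`, `triads.tsv`, `network.sif`,
`network.graphml`, plus `summary.json` and a checksum `manifest.json`
recording every defaulted parameter. Individual stages are also exposed as
subcommands (`simulate`, `identify`, `physchem`, `tree`, `quantify`,
`targets`, `network`) and as plain library functions.

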