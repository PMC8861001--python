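# Methods

This note documents the models, scoring conventions, defaults and known
limitations of `splnet`. Notation: the four leaf stages are ordered
Li → La → Ov → Bo; contrasts are written `late/early` (e.g. `Bo/Li`).

## Gene-family identification

**Homology screen.** Candidates are aligned to a reference SPL set by
exact local alignment (Gotoh affine-gap Smith–Waterman, BLOSUM62; a gap of
length *k* costs 11 + *k*, the BLASTP default convention). A candidate is
retained when its best hit has aligned-region identity ≥ 0.80 (inclusive;
gap columns count in the denominator) and E-value < 1e-5 (strict). The
E-value uses the Karlin–Altschul form E = K·m·n·exp(−λS) with the
ungapped BLOSUM62 parameters λ = 0.3176, K = 0.134 applied to the
Smith–Waterman score, m the query length and n the summed reference
length. Applying ungapped parameters to a gapped score is a documented
approximation: the screen's contract is the pair of thresholds, not BLAST
internals, and the E-values it produces are conservative enough to
separate homologs (E ≪ 1e-10) from chance hits (E > 1e-3) by many orders
of magnitude. Identity is computed over the aligned region, not the full
query — the choice matters only for partial homologies, which the domain
gate handles anyway.

**Domain scan.** The SBP (SQUAMOSA promoter-binding) domain is modelled as
an ungapped position-specific score matrix of width 48 built from a
consensus (match +4, mismatch −1), scanned over every placement including
overhangs at either sequence end; overhanging placements score only their
overlapping columns and are flagged `full_length=False`. A protein is
accepted as SPL when its best placement is full length and scores at or
above `domain_score_min` (default 120, i.e. roughly ≥ 75% of consensus
positions matched). The bundled consensus is a **synthetic stand-in**: the
real Pfam PF03110 seed alignment is not redistributed here, so the fixture
has the domain's characteristic width and Cys/His-rich flavour but not its
true residue frequencies. Everything the pipeline tests — window scan,
full-length requirement, rejection of truncated domains — is independent
of the particular consensus letters; a real PF03110-derived PSSM can be
dropped in via `DomainProfile.from_consensus` or a custom `pssm` array.

**Isoform deduplication.** One record per locus id: the longest, ties
broken by lexicographically smallest id. Discarded isoforms are reported
with the canonical id they collapse into.

## Physicochemical profiles

ExPASy/ProtParam conventions throughout (tables shipped with Biopython):
molecular weight as the sum of average residue masses plus one water
(18.0153 Da); GRAVY as the mean Kyte–Doolittle hydropathy; the Guruprasad
instability index II = (10/L)·Σ DIWV(xᵢ, xᵢ₊₁), with > 40 classed
unstable; a length-1 peptide has no dipeptides and is flagged
`undefined`. The theoretical pI uses the Bjellqvist pKa set and is found
by bisection on [0, 14] of the Henderson–Hasselbalch net-charge curve,
which is strictly decreasing in pH; iteration stops when the residual
charge is below 1e-6, comfortably inside the package's 1e-4 contract.
Acid/base classing splits at pI 7; no classification is attempted for
proteins sitting exactly on the boundary beyond the < 7 rule.

## Phylogeny

The tree stage consumes the fixed-width domain windows of the identified
SPLs, which are mutually aligned by construction — full progressive MSA is
deliberately out of scope. Distances are protein p-distances with pairwise
gap deletion (the simplest MEGA-style protein option); a Poisson
correction −ln(1−p) is available by flag. Trees are Saitou–Nei neighbor
joining (scikit-bio's implementation behind this module's surface);
negative branch lengths, which NJ can produce on non-additive input, are
clamped to zero with a warning. On additive matrices NJ is exact in both
topology and path lengths, and the tests hold it to that. Bootstrap
supports resample alignment columns with replacement (default 1000
replicates, per the field's convention) and report, per internal edge, the
percentage of replicate trees containing the same leaf bipartition;
supports are written as internal node labels in Newick. Replicates in
which some pair loses all comparable columns are skipped, which can only
deflate supports. Leaves can carry an `mre_class` flag (does the
corresponding transcript have a miR156 site), reproducing the
with/without-MRE split of the family's class II clade.

## Expression

Counts are normalised per biotype: FPKM = c·10⁹/(N·L) for mRNA and
lncRNA, TPM = (c/L)/Σ(c/L)·10⁶ for miRNA, RPM = j·10⁶/N for circRNA,
where c is the read count, j the back-splice junction count, L the
transcript length (bp) and N the per-sample library size. TPM columns sum
to 10⁶ by construction; FPKM and TPM rank features identically within a
sample.

Contrasts are log2((mean_a + ε)/(mean_b + ε)) over replicate means with
pseudocount ε = 1 by default. Linear folds map to the categorical classes
Up/Down A–D on the half-open intervals (1, 2], (2, 5], (5, 10], (10, ∞),
upper bound inclusive; a fold of exactly 1 is `flat`/`none`. Differential
expression is defined as |log2FC| ≥ `de_threshold` (default 1, i.e. bin A
or beyond). A negative-binomial test in the DESeq2 style is **not**
re-implemented: the downstream network logic consumes fold bins, and a
mean-fold gate keeps the pipeline transparent; this is an approximation
and is recorded as such in the manifest. Pair correlation is Pearson's r
on the four per-stage means (replicate means, not replicates — four points
make r a trend statistic, not an inferential one), threshold
`r_min` = 0.8 by default and configurable; undefined correlations (zero
variance) drop the pair. qPCR support uses the comparative-Ct ratio
2^(−ΔΔCt) against a reference gene and calibrator sample.

## miR156 target scoring

Sites are scored with a transparent Allen-type penalty scheme of the kind
psRNATarget popularised: per duplex position, 0 for a Watson–Crick pair,
0.5 for G:U, 1 for a mismatch, 2 for a gap; penalties are doubled when the
miRNA position (1-based from the 5′ end) lies in the seed 2–13; at most
one gap; a window is a site when its minimum penalty is ≤ 3.0. All values
are this package's bundled defaults — surfaced in `PenaltyScheme`,
reported in the run manifest — since upstream web tools do not publish a
single canonical parameterisation. Gap columns take the seed weight of the
skipped miRNA position (target-side gap) or of the next miRNA position,
clamped to the miRNA length (miRNA-side gap); this convention is arbitrary
but fixed, shared by the per-window scorer, the vectorised scanner and the
test oracles. Sequences are stored as DNA; T ≡ U everywhere.

`duplex_penalty` enumerates the ≤ 1-gap alignment structures of one
window; `find_sites` scans a whole transcript by an exact vectorised
decomposition of the same space (ungapped register sums plus a
prefix/suffix split at each possible gap position), then resolves
overlapping calls to the lowest-scoring site (ties to the leftmost). The
two paths are checked against each other and against an independent
recursive enumerator in the tests. circRNAs are scanned twice: on the
linearised circle and on a junction pseudo-sequence (the miRNA-length − 1
bases on each side of the back-splice join); junction hits are mapped back
to circular coordinates, flagged `spans_junction` (their end coordinate
wraps below their start), and deduplicated against linear hits by mapped
start.

## ceRNA network assembly

A candidate pair is one (lncRNA or circRNA, mRNA) pair whose MRE miRNA
sets intersect ("same MRE" is read at the family-member level: a site for
peu-miR156a and a site for peu-miR156b do not pair). Pairs must pass the
positive-correlation gate (r ≥ r_min > 0). Per stage contrast and per
shared miRNA, a triad is emitted when ceRNA and mRNA are differentially
expressed in the same direction and the miRNA in the opposite direction —
the sponge model's signature. The miRNA gates (opposite direction,
miRNA DE) are defaults, each relaxable by config, because upstream
descriptions of such analyses state only the positive ceRNA–mRNA
correlation explicitly while their worked examples show the miRNA moving
oppositely. Triad identity is (ceRNA, miRNA, mRNA, contrast); multiple
MREs for the same pair collapse. Tightening any gate — higher r_min,
higher de_threshold, lower score cutoff — can only shrink the triad set,
and the tests assert this monotonicity. Networks export as SIF
(`cerna sponges mirna`, `mirna represses mrna`), node-attribute TSV with
the Up/Down A–D class per contrast, and GraphML.

`evaluate_recovery` scores predicted (ceRNA, miRNA, mRNA) triples against
planted truth, pooled over contrasts and per contrast; empty predictions
against non-empty truth report precision 0 with an `undefined` flag.

## The synthetic study

The generator emulates the four-stage design with every random decision
derived from one seed:

- **Stages and replicates**: Li, La, Ov, Bo × 3 replicates (three
  biological replicates being the usual qPCR-scale design when sequencing
  replication is unstated).
- **Feature sizes** (defaults): 300 mRNA (~10% of loci with 2–3 splice
  isoforms as terminal truncations), 100 lncRNA, 30 circRNA, 12 miR156
  family members (a..l, 21 nt), plus 60 background miRNAs. The background
  miRNome is flat-trended and exists because TPM is compositional: in a
  library where *every* miRNA declined identically, TPM would normalise
  the decline away; the background plays the role of the rest of a real
  small-RNA library.
- **Trends**: miR156 means fall geometrically by `effect_size` (default 2)
  per stage, Li → Bo; triad-member ceRNAs and mRNAs rise by the same
  factor; everything else is flat. Per-feature base means are log-normal
  around `base_mean` = 200 (median), σ = 0.6 — a plausible mid-expressed
  regime. `effect_size` must exceed 1 so the planted trends are strictly
  monotone.
- **Counts**: negative binomial with variance μ + φμ² (global dispersion
  φ = 0.05, a typical bulk RNA-seq plant-tissue magnitude; the model
  DESeq2-style normalisation assumes), Poisson in the φ → 0 limit, means
  scaled by a per-sample library factor (uniform 0.8–1.2 by default).
- **Planted MREs**: 25% of transcripts per class receive one site — the
  reverse complement of an assigned miRNA with 0–2 substitutions opposite
  non-seed miRNA positions (each a mismatch or, where the miRNA base
  allows, a G:U), so designed penalties are ≤ 2, safely below the 3.0
  cutoff. mRNA carriers are drawn from single-isoform loci so sites stay
  unambiguous after deduplication. Half of circRNA sites span the
  back-splice junction. Half of each miRNA's carriers (at least one ceRNA
  and one mRNA) are wired into its module; `planted_triads` is the full
  per-miRNA ceRNA × mRNA cross product, because the assembly gates cannot
  — and biologically should not — distinguish pairs within one module.
- **miRNA sequences** are distinct random 21-mers, not near-identical
  paralogs. Real miR156 family members differ by a few bases and can share
  sites; here module identity *is* the ground truth being scored, so the
  members are kept orthogonal by construction. Consequently the recovery
  numbers say nothing about cross-member site ambiguity in real data.
- **Proteins**: 12 SPL loci (domain copy with ≤ 2 substitutions inside
  random flanks; ~40% of loci as isoform groups with C-terminal
  extensions), 6 truncated-domain decoys (half-width domain), 9 domain-free
  decoys, and one reference homolog per locus (a whole-protein mutated
  copy at 8% substitution rate, the way cross-species orthologs are
  similar along their full length).

What passing the planted-truth tests shows: the pipeline's gates recover
exactly the relationships its own assumptions describe, at realistic noise
levels. What it does not show: performance on real libraries with
compositional shifts, shared family sites, isoform-level quantification
ambiguity, or correlated biological replicates — none of which the
generator models.

## Numerical and design choices

- Fold-bin boundary: exact log2FC = 0 (|log2FC| < 1e-12) is `flat`; bins
  are half-open with inclusive upper bounds, as printed in their
  definition.
- Site overlap resolution: lowest score wins, ties to the leftmost start;
  deterministic for fixed input.
- Bootstrap and NJ tie-breaks follow scikit-bio's deterministic ordering;
  all supports are reproducible under a fixed seed.
- Pipeline determinism: every stage seed derives from the run seed;
  manifests hash the config minus the output directory, so two runs with
  the same config and seed are byte-identical wherever they are written.
- Default problem sizes (300/100/30/12 features, 3 replicates, 300–1000
  bootstrap replicates in bundled runs) are the package's chosen
  desk-scale study; all are configurable.

## Known limitations

- The E-value model is ungapped-parameter Karlin–Altschul on a gapped
  score; absolute E-values are approximate (threshold behaviour is what
  is tested).
- The domain profile is a synthetic consensus, not PF03110 (see above).
- No significance testing or multiple-testing correction anywhere:
  differential expression is a fold-change gate by design.
- Correlation on four stage means is descriptive; r ≥ 0.8 with four
  points is a trend filter, not a hypothesis test.
- The phylogeny stage assumes pre-aligned, equal-width domain rows; it is
  not a general MSA+tree tool.
- circRNA handling assumes one back-splice junction per molecule and
  sense-strand targeting only.
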