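"""Seed-reproducible synthetic transcriptomes with planted ground truth.

The generator emulates the four-stage heteromorphic-leaf study design: four
leaf stages (linear Li, lanceolate La, ovate Ov, broad-ovate Bo) with
replicated negative-binomial counts; miR156 family members whose expected
expression declines monotonically from Li to Bo; miR156-regulated mRNAs and
their sponging ceRNAs (lncRNA/circRNA) rising in step; planted miRNA
response elements shared between the ceRNAs and mRNAs of each miR156
module; and redundant splice isoforms for deduplication tests.

Every random decision flows from ``SimulationConfig.seed`` so that a fixed
config is byte-reproducible.  ``PlantedTruth`` records everything a
downstream evaluation needs: planted sites, planted triads (closed under
the per-miRNA ceRNA x mRNA cross product, since all such pairs share the
module's MRE and expression trend), isoform groups, and noise-free stage
means.
"""

from __future__ import annotations

import hashlib
import json
import math
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .expression import CountMatrix
from .family import DomainProfile, default_sbp_profile
from .records import (ProteinRecord, TranscriptRecord, reverse_complement,
                      write_protein_fasta, write_transcript_fasta)
from .targets import PenaltyScheme, _base_penalty

STAGES_DEFAULT = ("Li", "La", "Ov", "Bo")
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study-design defaults."""

    stage_labels: Tuple[str, ...] = STAGES_DEFAULT
    replicates_per_stage: int = 3
    n_mrna: int = 300
    n_lncrna: int = 100
    n_circrna: int = 30
    n_mirna: int = 12          # miR156 family members a..l
    n_background_mirna: int = 60  # rest of the miRNome (flat trend)
    mre_fraction: float = 0.25
    nb_dispersion: float = 0.05
    effect_size: float = 2.0   # per-stage multiplicative trend factor
    seed: int = 0
    # sequence geometry
    mrna_length: int = 500
    lncrna_length: int = 400
    circrna_length: int = 300
    mirna_length: int = 21
    mrna_isoform_fraction: float = 0.1
    # expression design
    triad_fraction: float = 0.5   # fraction of MRE carriers wired into triads
    base_mean: float = 200.0
    library_factor_range: Tuple[float, float] = (0.8, 1.2)
    # protein-set block
    n_spl_loci: int = 12
    n_truncated_decoys: int = 6
    n_random_decoys: int = 9
    spl_isoform_fraction: float = 0.4
    reference_mutation_rate: float = 0.08

    def __post_init__(self):
        if len(self.stage_labels) != 4:
            raise ConfigurationError(
                "stage_labels: exactly 4 stages are required")
        if len(set(self.stage_labels)) != 4:
            raise ConfigurationError("stage_labels: labels must be distinct")
        for name in ("replicates_per_stage", "n_mrna", "n_lncrna",
                     "n_circrna", "n_mirna", "mrna_length", "lncrna_length",
                     "circrna_length", "mirna_length", "n_spl_loci"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name}: must be >= 1")
        for name in ("n_truncated_decoys", "n_random_decoys",
                     "n_background_mirna"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        for name in ("mre_fraction", "mrna_isoform_fraction",
                     "triad_fraction", "spl_isoform_fraction",
                     "reference_mutation_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}: must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion: must be positive")
        if self.effect_size <= 1.0:
            raise ConfigurationError(
                "effect_size: must exceed 1 so stage trends are strictly "
                "monotone")
        if self.base_mean <= 0:
            raise ConfigurationError("base_mean: must be positive")
        lo, hi = self.library_factor_range
        if not 0 < lo <= hi:
            raise ConfigurationError(
                "library_factor_range: need 0 < low <= high")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    planted_sites: List[Tuple[str, str, int, int, float]] = field(
        default_factory=list)
    planted_triads: List[Tuple[str, str, str]] = field(default_factory=list)
    isoform_groups: Dict[str, List[str]] = field(default_factory=dict)
    stage_means: Dict[str, List[float]] = field(default_factory=dict)
    feature_meta: Dict[str, Dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "planted_sites": [list(s) for s in self.planted_sites],
            "planted_triads": [list(t) for t in self.planted_triads],
            "isoform_groups": self.isoform_groups,
            "stage_means": self.stage_means,
            "feature_meta": self.feature_meta,
        }, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        data = json.loads(text)
        return cls(
            planted_sites=[tuple(s) for s in data["planted_sites"]],
            planted_triads=[tuple(t) for t in data["planted_triads"]],
            isoform_groups=data["isoform_groups"],
            stage_means=data["stage_means"],
            feature_meta=data.get("feature_meta", {}),
        )


@dataclass
class ProteinTruth:
    """Labels for the synthetic protein set."""

    labels: Dict[str, str] = field(default_factory=dict)  # id -> class
    canonical: List[str] = field(default_factory=list)
    isoform_groups: Dict[str, List[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _mirna_suffix(i: int) -> str:
    letters = string.ascii_lowercase
    if i < len(letters):
        return letters[i]
    return letters[i % len(letters)] + str(i // len(letters) + 1)


def plant_mres(
    transcripts: Sequence[TranscriptRecord],
    mirnas: Sequence[TranscriptRecord],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    assignments: Optional[Dict[str, str]] = None,
) -> Tuple[List[TranscriptRecord], List[Tuple[str, str, int, int, float]]]:
    """Plant one miRNA response element into selected transcripts.

    Each planted site is the reverse complement of its miRNA with 0-2
    substitutions placed opposite miRNA positions outside the seed (2-13),
    so its designed penalty never exceeds 2.0 (below the default cutoff).
    ``assignments`` maps target id -> miRNA id; when omitted, an
    ``mre_fraction`` share of transcripts is chosen and miRNAs are assigned
    round-robin.  circRNA sites may span the back-splice junction.

    Returns the modified transcripts (same order) plus the planted-site
    records (miRNA id, target id, start, end, designed score); for a
    junction-spanning circRNA site ``end`` wraps below ``start``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mirna_by_id = {m.id: m for m in mirnas}
    if assignments is None:
        n_pick = int(round(config.mre_fraction * len(transcripts)))
        order = rng.permutation(len(transcripts))[:n_pick]
        ids = [mirnas[k % len(mirnas)].id for k in range(n_pick)]
        assignments = {transcripts[int(j)].id: mid
                       for j, mid in zip(order, ids)}
    out: List[TranscriptRecord] = []
    sites: List[Tuple[str, str, int, int, float]] = []
    scheme = PenaltyScheme()
    for tr in transcripts:
        mid = assignments.get(tr.id)
        if mid is None:
            out.append(tr)
            continue
        mi = mirna_by_id[mid]
        L = len(mi.seq)
        if L > len(tr.seq):
            raise ValidationError(
                f"miRNA {mi.id} ({L} nt) longer than target {tr.id} "
                f"({len(tr.seq)} nt)")
        site_seq = list(reverse_complement(mi.seq))
        n_edits = int(rng.integers(0, 3))
        allowed = [1] + list(range(scheme.seed_end + 1, L + 1))
        positions = rng.choice(allowed, size=n_edits, replace=False)
        score = 0.0
        for pos in sorted(int(p) for p in positions):
            m_base = mi.seq[pos - 1]
            idx = L - pos  # 0-based index in the site opposite miRNA pos
            want_gu = bool(rng.integers(0, 2)) and m_base in "GT"
            if want_gu:
                site_seq[idx] = "T" if m_base == "G" else "G"
                score += scheme.gu_wobble
            else:
                choices = [b for b in "ACGT"
                           if _base_penalty(m_base, b, scheme)
                           == scheme.mismatch]
                site_seq[idx] = choices[int(rng.integers(0, len(choices)))]
                score += scheme.mismatch
        site = "".join(site_seq)
        n = len(tr.seq)
        if tr.biotype == "circrna" and rng.random() < 0.5 and n > L:
            split = int(rng.integers(1, L))  # bases placed before the join
            seq = site[split:] + tr.seq[L - split:n - split] + site[:split]
            start = n - split + 1
            end = L - split
            rec = TranscriptRecord(tr.id, seq, tr.biotype, tr.locus,
                                   junction=n)
        else:
            start = int(rng.integers(1, n - L + 2))
            seq = tr.seq[:start - 1] + site + tr.seq[start - 1 + L:]
            end = start + L - 1
            rec = TranscriptRecord(tr.id, seq, tr.biotype, tr.locus,
                                   junction=tr.junction)
        out.append(rec)
        sites.append((mi.id, tr.id, start, end, score))
    return out, sites


def generate_transcriptome(
    config: SimulationConfig,
) -> Tuple[List[TranscriptRecord], PlantedTruth]:
    """Full synthetic transcriptome with planted sites, triads, and trends."""
    rng = np.random.default_rng(config.seed)
    truth = PlantedTruth()

    mirnas = [
        TranscriptRecord(f"peu-miR156{_mirna_suffix(i)}",
                         _random_dna(rng, config.mirna_length), "mirna",
                         locus="miR156")
        for i in range(config.n_mirna)
    ]
    # the rest of the miRNome: flat-trend background keeping miRNA TPM
    # informative (a library where every miRNA declines would normalise
    # the decline away)
    background = [
        TranscriptRecord(f"bg-miR_{i:04d}",
                         _random_dna(rng, config.mirna_length), "mirna",
                         locus="mirnome_background")
        for i in range(1, config.n_background_mirna + 1)
    ]

    # mRNA loci; a fraction carries 2-3 splice isoforms (terminal truncations)
    mrnas: List[TranscriptRecord] = []
    single_isoform: List[TranscriptRecord] = []
    locus_no = 0
    while len(mrnas) < config.n_mrna:
        locus_no += 1
        locus = f"mlocus_{locus_no:04d}"
        remaining = config.n_mrna - len(mrnas)
        k = 1
        if (remaining >= 2
                and rng.random() < config.mrna_isoform_fraction):
            k = min(int(rng.integers(2, 4)), remaining)
        base = _random_dna(rng, config.mrna_length)
        group = []
        for j in range(1, k + 1):
            seq = base if j == 1 else base[:len(base) - 50 * (j - 1)]
            rec = TranscriptRecord(f"mRNA_{locus_no:04d}.t{j}", seq,
                                   "mrna", locus)
            mrnas.append(rec)
            group.append(rec.id)
        if k > 1:
            truth.isoform_groups[locus] = group
        else:
            single_isoform.append(mrnas[-1])

    lncrnas = [
        TranscriptRecord(f"lncRNA_{i:04d}", _random_dna(
            rng, config.lncrna_length), "lncrna", f"llocus_{i:04d}")
        for i in range(1, config.n_lncrna + 1)
    ]
    circrnas = [
        TranscriptRecord(f"circRNA_{i:04d}", _random_dna(
            rng, config.circrna_length), "circrna", f"clocus_{i:04d}")
        for i in range(1, config.n_circrna + 1)
    ]

    # choose MRE carriers: mRNA carriers come from single-isoform loci so
    # planted sites stay unambiguous after isoform deduplication
    n_m = min(int(round(config.mre_fraction * config.n_mrna)),
              len(single_isoform))
    n_l = int(round(config.mre_fraction * config.n_lncrna))
    n_c = int(round(config.mre_fraction * config.n_circrna))
    m_carriers = [single_isoform[int(i)].id for i in
                  rng.permutation(len(single_isoform))[:n_m]]
    l_carriers = [lncrnas[int(i)].id for i in
                  rng.permutation(len(lncrnas))[:n_l]]
    c_carriers = [circrnas[int(i)].id for i in
                  rng.permutation(len(circrnas))[:n_c]]
    assignments: Dict[str, str] = {}
    for pool in (m_carriers, l_carriers + c_carriers):
        for k, tid in enumerate(pool):
            assignments[tid] = mirnas[k % len(mirnas)].id

    transcripts = mrnas + lncrnas + circrnas
    transcripts, sites = plant_mres(transcripts, mirnas, config, rng,
                                    assignments)
    truth.planted_sites = sites

    # wire triads: per miRNA module, a triad_fraction share of its carriers
    by_mirna: Dict[str, Dict[str, List[str]]] = {
        m.id: {"cerna": [], "mrna": []} for m in mirnas}
    cerna_ids = set(l_carriers) | set(c_carriers)
    for tid, mid in assignments.items():
        kind = "cerna" if tid in cerna_ids else "mrna"
        by_mirna[mid][kind].append(tid)
    trending: set = set()
    for mid in sorted(by_mirna):
        module = by_mirna[mid]
        picks = {}
        for kind in ("cerna", "mrna"):
            pool = sorted(module[kind])
            n_pick = max(1, int(math.ceil(
                config.triad_fraction * len(pool)))) if pool else 0
            chosen = [pool[int(i)] for i in
                      rng.permutation(len(pool))[:n_pick]]
            picks[kind] = chosen
        for c in picks["cerna"]:
            for g in picks["mrna"]:
                truth.planted_triads.append((c, mid, g))
                trending.add(c)
                trending.add(g)

    # stage means: miR156 members decline Li->Bo; triad members rise;
    # everything else (incl. the background miRNome) stays flat
    es = config.effect_size
    for rec in transcripts + mirnas + background:
        base = float(rng.lognormal(math.log(config.base_mean), 0.6))
        if rec.locus == "miR156":
            means = [base * es ** (-i) for i in range(4)]
        elif rec.id in trending:
            means = [base * es ** i for i in range(4)]
        else:
            means = [base] * 4
        truth.stage_means[rec.id] = means
        truth.feature_meta[rec.id] = {
            "biotype": rec.biotype, "length_bp": len(rec.seq),
            "locus": rec.locus,
        }
    return transcripts + mirnas + background, truth


def simulate_counts(truth: PlantedTruth,
                    config: SimulationConfig) -> CountMatrix:
    """Negative-binomial counts from the planted stage means.

    mean = stage mean x per-sample library factor; variance
    = mean + nb_dispersion * mean^2 (Poisson in the small-dispersion limit).
    """
    if not truth.stage_means:
        raise ValidationError("truth carries no stage means")
    rng = np.random.default_rng([config.seed, 101])
    features = list(truth.stage_means)
    means = np.array([truth.stage_means[f] for f in features])
    if means.shape[1] != 4:
        raise ValidationError("stage_means must have 4 stages per feature")
    disp = config.nb_dispersion
    columns = {}
    for s, stage in enumerate(config.stage_labels):
        for rep in range(1, config.replicates_per_stage + 1):
            factor = rng.uniform(*config.library_factor_range)
            mu = np.maximum(means[:, s] * factor, 1e-8)
            if disp < 1e-8:
                draws = rng.poisson(mu)
            else:
                size = 1.0 / disp
                p = size / (size + mu)
                draws = rng.negative_binomial(size, p)
            columns[f"{stage}_{rep}"] = draws.astype(int)
    counts = pd.DataFrame(columns, index=pd.Index(features,
                                                  name="feature_id"))
    meta = pd.DataFrame({
        "biotype": [truth.feature_meta[f]["biotype"] for f in features],
        "length_bp": [truth.feature_meta[f]["length_bp"] for f in features],
    }, index=counts.index)
    return CountMatrix(counts, meta, list(config.stage_labels))


def generate_protein_set(
    config: SimulationConfig,
    profile: Optional[DomainProfile] = None,
) -> Tuple[List[ProteinRecord], List[ProteinRecord], ProteinTruth]:
    """Synthetic protein set with labelled SPLs, decoys, and references.

    Emits: true SPLs carrying a full-length (lightly mutated) domain copy,
    some as isoform groups differing by C-terminal extensions; decoys with
    a half-width truncated domain; decoys with no domain; plus a reference
    SPL set for the homology screen (one full-length homolog per SPL locus,
    mutated at ``reference_mutation_rate`` so aligned-region identity stays
    near 1 - rate, the way real cross-species orthologs behave).

    Returns (protein records, reference records, truth labels).
    """
    profile = profile or default_sbp_profile()
    consensus = profile.consensus
    W = len(consensus)
    rng = np.random.default_rng([config.seed, 202])
    truth = ProteinTruth()

    def mutated_domain(n_subs: int) -> str:
        dom = list(consensus)
        for pos in rng.permutation(W)[:n_subs]:
            old = dom[int(pos)]
            choices = [a for a in _AA if a != old]
            dom[int(pos)] = choices[int(rng.integers(0, len(choices)))]
        return "".join(dom)

    def mutated_copy(seq: str, rate: float) -> str:
        out = list(seq)
        n_subs = int(round(rate * len(seq)))
        for pos in rng.permutation(len(seq))[:n_subs]:
            old = out[int(pos)]
            choices = [a for a in _AA if a != old]
            out[int(pos)] = choices[int(rng.integers(0, len(choices)))]
        return "".join(out)

    records: List[ProteinRecord] = []
    references: List[ProteinRecord] = []
    for i in range(1, config.n_spl_loci + 1):
        locus = f"spl_locus_{i:02d}"
        core = (_random_protein(rng, int(rng.integers(50, 151)))
                + mutated_domain(int(rng.integers(0, 3)))
                + _random_protein(rng, int(rng.integers(50, 151))))
        references.append(ProteinRecord(
            f"RefSPL_{i:02d}",
            mutated_copy(core, config.reference_mutation_rate),
            locus=f"ref_{i:02d}"))
        k = 1
        if rng.random() < config.spl_isoform_fraction:
            k = int(rng.integers(2, 4))
        group = []
        best_id, best_len = None, -1
        for j in range(1, k + 1):
            ext = _random_protein(rng, 20 * (j - 1)) if j > 1 else ""
            rec = ProteinRecord(f"PeuSPL{i:02d}.t{j}", core + ext,
                                locus=locus)
            records.append(rec)
            group.append(rec.id)
            truth.labels[rec.id] = "spl"
            if len(rec) > best_len:
                best_id, best_len = rec.id, len(rec)
        if k > 1:
            truth.isoform_groups[locus] = group
        truth.canonical.append(best_id)

    for i in range(1, config.n_truncated_decoys + 1):
        seq = (_random_protein(rng, int(rng.integers(50, 151)))
               + consensus[:W // 2]
               + _random_protein(rng, int(rng.integers(50, 151))))
        rec = ProteinRecord(f"TruncDecoy_{i:02d}", seq,
                            locus=f"trunc_{i:02d}")
        records.append(rec)
        truth.labels[rec.id] = "truncated_decoy"

    for i in range(1, config.n_random_decoys + 1):
        rec = ProteinRecord(
            f"RandDecoy_{i:02d}",
            _random_protein(rng, int(rng.integers(150, 401))),
            locus=f"rand_{i:02d}")
        records.append(rec)
        truth.labels[rec.id] = "random_decoy"

    truth.canonical.sort()
    return records, references, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(
    records: Sequence[TranscriptRecord],
    truth: PlantedTruth,
    counts: CountMatrix,
    directory,
    proteins: Optional[Sequence[ProteinRecord]] = None,
    references: Optional[Sequence[ProteinRecord]] = None,
    protein_truth: Optional[ProteinTruth] = None,
    seed: Optional[int] = None,
) -> Dict:
    """Write FASTA/TSV/JSON fixtures plus a checksum manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    from .expression import write_counts_tsv

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValidationError(f"unwritable fixture directory: {exc}")

    by_biotype: Dict[str, List[TranscriptRecord]] = {}
    for rec in records:
        by_biotype.setdefault(rec.biotype, []).append(rec)
    written = []
    for biotype, recs in sorted(by_biotype.items()):
        path = directory / f"{biotype}.fasta"
        write_transcript_fasta(recs, str(path))
        written.append(path)
    counts_path = directory / "counts.tsv"
    write_counts_tsv(counts, counts_path)
    written.append(counts_path)
    truth_path = directory / "truth.json"
    truth_path.write_text(truth.to_json())
    written.append(truth_path)
    if proteins is not None:
        path = directory / "proteins.fasta"
        write_protein_fasta(proteins, str(path))
        written.append(path)
    if references is not None:
        path = directory / "references.fasta"
        write_protein_fasta(references, str(path))
        written.append(path)
    if protein_truth is not None:
        path = directory / "protein_truth.json"
        path.write_text(protein_truth.to_json())
        written.append(path)
    manifest = {
        "seed": seed,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
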