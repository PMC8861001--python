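"""End-to-end orchestration: simulate -> identify -> physchem -> tree ->
quantify -> targets -> network, with a provenance manifest.

A run is driven by one :class:`PipelineConfig` holding either a synthetic
generation block or paths to input files (FASTA per biotype plus a TSV
count table), all stage thresholds, and the seed.  Every defaulted
parameter is recorded in the manifest so unstated analysis choices stay
auditable; two runs with the same config and seed produce byte-identical
tables and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineError, ValidationError
from .expression import (CountMatrix, NormalizedMatrix, contrast,
                         normalize_by_biotype, read_counts_tsv)
from .family import identify_spl
from .network import (assemble_triads, correlation_filter, evaluate_recovery,
                      export_network, shared_mre_pairs)
from .phylo import (annotate_mre_class, bootstrap_supports, supports_table,
                    write_newick)
from .physchem import profile_table
from .records import (read_protein_fasta, read_transcript_fasta,
                      write_protein_fasta)
from .synthetic import (SimulationConfig, generate_protein_set,
                        generate_transcriptome, simulate_counts,
                        write_fixtures)
from .targets import PenaltyScheme, predict_targetome

logger = logging.getLogger("splnet")

STAGE_ORDER = ("simulate", "identify", "physchem", "tree", "quantify",
               "targets", "network")


def default_contrasts(stages: Sequence[str]) -> List[str]:
    """All later-vs-earlier stage pairs, e.g. La/Li ... Bo/Ov."""
    out = []
    for i, early in enumerate(stages):
        for late in stages[i + 1:]:
            out.append(f"{late}/{early}")
    return out


@dataclass
class PipelineConfig:
    """One run: inputs or a synthetic block, plus every stage threshold."""

    outdir: str = "splnet_run"
    seed: int = 0
    synthetic: Optional[SimulationConfig] = None
    inputs: Optional[Dict[str, str]] = None  # mrna/lncrna/circrna/mirna/
    #                                          counts/proteins/references
    identity_min: float = 0.80
    evalue_max: float = 1e-5
    domain_score_min: float = 120.0
    scheme: PenaltyScheme = field(default_factory=PenaltyScheme)
    r_min: float = 0.8
    de_threshold: float = 1.0
    pseudocount: float = 1.0
    n_bootstrap: int = 1000
    require_mirna_opposite: bool = True
    require_mirna_de: bool = True
    contrasts: Optional[List[str]] = None
    stage_labels: Optional[Tuple[str, ...]] = None
    threads: int = 1

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' and 'inputs' must be set")
        if self.synthetic is not None:
            self.stage_labels = tuple(self.synthetic.stage_labels)
        elif self.stage_labels is None:
            self.stage_labels = ("Li", "La", "Ov", "Bo")
        if self.contrasts is None:
            self.contrasts = default_contrasts(self.stage_labels)
        if not 0.0 <= self.identity_min <= 1.0:
            raise ConfigurationError("identity_min must lie in [0, 1]")
        if self.evalue_max <= 0:
            raise ConfigurationError("evalue_max must be positive")
        if self.r_min <= 0 or self.r_min > 1:
            raise ConfigurationError("r_min must lie in (0, 1]")
        if self.de_threshold < 0:
            raise ConfigurationError("de_threshold must be >= 0")
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> Dict:
        data = dataclasses.asdict(self)
        data["scheme"] = dataclasses.asdict(self.scheme)
        if self.synthetic is not None:
            data["synthetic"] = dataclasses.asdict(self.synthetic)
        return data

    @classmethod
    def from_dict(cls, data: Dict) -> "PipelineConfig":
        data = dict(data)
        if data.get("synthetic") is not None:
            syn = dict(data["synthetic"])
            if "stage_labels" in syn:
                syn["stage_labels"] = tuple(syn["stage_labels"])
            if "library_factor_range" in syn:
                syn["library_factor_range"] = tuple(
                    syn["library_factor_range"])
            data["synthetic"] = SimulationConfig(**syn)
        if data.get("scheme") is not None:
            data["scheme"] = PenaltyScheme(**data["scheme"])
        if data.get("stage_labels") is not None:
            data["stage_labels"] = tuple(data["stage_labels"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def fingerprint(self) -> str:
        """Config hash over everything except the output location."""
        data = self.to_dict()
        data.pop("outdir", None)
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _derived_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2 ** 31)


def _combined_normalized(normalized: Dict[str, NormalizedMatrix],
                         stages) -> NormalizedMatrix:
    values = pd.concat([n.values for n in normalized.values()])
    features = pd.concat([n.features for n in normalized.values()])
    return NormalizedMatrix(values, features, list(stages), "mixed")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages; returns the run summary (also written as JSON).

    A stage failure raises :class:`PipelineError` naming the stage; partial
    outputs are retained next to a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: Dict = {"stages": {}, "seed": config.seed,
                     "contrasts": config.contrasts}
    state: Dict = {}

    def stage(name):
        def wrap(fn):
            logger.info("stage %s: start", name)
            try:
                fn()
            except PipelineError:
                (outdir / "FAILED").write_text(name)
                raise
            except Exception as exc:
                (outdir / "FAILED").write_text(name)
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done (%s)", name,
                        summary["stages"].get(name, {}))
        return wrap

    @stage("simulate")
    def _simulate():
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            transcripts, truth = generate_transcriptome(syn)
            counts = simulate_counts(truth, syn)
            proteins, references, protein_truth = generate_protein_set(syn)
            write_fixtures(transcripts, truth, counts, outdir / "fixtures",
                           proteins=proteins, references=references,
                           protein_truth=protein_truth, seed=config.seed)
            state.update(transcripts=transcripts, truth=truth, counts=counts,
                         proteins=proteins, references=references,
                         protein_truth=protein_truth)
        else:
            paths = config.inputs
            transcripts = []
            for biotype in ("mrna", "lncrna", "circrna", "mirna"):
                if paths.get(biotype):
                    transcripts.extend(
                        read_transcript_fasta(paths[biotype], biotype))
            counts = (read_counts_tsv(paths["counts"], config.stage_labels)
                      if paths.get("counts") else None)
            proteins = (read_protein_fasta(paths["proteins"])
                        if paths.get("proteins") else [])
            references = (read_protein_fasta(paths["references"])
                          if paths.get("references") else [])
            state.update(transcripts=transcripts, truth=None, counts=counts,
                         proteins=proteins, references=references,
                         protein_truth=None)
        summary["stages"]["simulate"] = {
            "n_transcripts": len(state["transcripts"]),
            "n_proteins": len(state["proteins"]),
        }

    @stage("identify")
    def _identify():
        if not state["proteins"] or not state["references"]:
            summary["stages"]["identify"] = {"skipped": "no protein inputs"}
            state["canonical"] = []
            state["identify_report"] = None
            return
        canonical, report = identify_spl(
            state["proteins"], state["references"],
            identity_min=config.identity_min,
            evalue_max=config.evalue_max,
            domain_score_min=config.domain_score_min)
        state["canonical"] = canonical
        state["identify_report"] = report
        write_protein_fasta(canonical, str(outdir / "spl_canonical.fasta"))
        hits = pd.DataFrame([dataclasses.asdict(h)
                             for h in report["screen_hits"]])
        hits.to_csv(outdir / "screen_hits.tsv", sep="\t", index=False)
        summary["stages"]["identify"] = {
            "n_queries": report["n_queries"],
            "n_screened": report["n_screened"],
            "n_full_length_domain": report["n_full_length_domain"],
            "n_canonical": report["n_canonical"],
        }

    @stage("physchem")
    def _physchem():
        if not state["canonical"]:
            summary["stages"]["physchem"] = {"skipped": "no SPL records"}
            return
        table = profile_table(state["canonical"])
        table.to_csv(outdir / "physchem.tsv", sep="\t", index=False)
        summary["stages"]["physchem"] = {"n_profiles": len(table)}

    @stage("tree")
    def _tree():
        canonical = state["canonical"]
        report = state["identify_report"]
        if len(canonical) < 3:
            summary["stages"]["tree"] = {"skipped": "fewer than 3 SPLs"}
            state["tree"] = None
            return
        alignment = []
        for rec in canonical:
            hit = report["domain_hits"][rec.id]
            alignment.append((rec.id, rec.seq[hit.start - 1:hit.end]))
        tree = bootstrap_supports(
            alignment, n_reps=config.n_bootstrap,
            seed=_derived_seed(config.seed, 303))
        state["tree"] = tree
        write_newick(tree, str(outdir / "tree.nwk"))
        supports_table(tree).to_csv(outdir / "supports.tsv", sep="\t",
                                    index=False)
        summary["stages"]["tree"] = {
            "n_taxa": len(alignment), "n_bootstrap": config.n_bootstrap}

    @stage("quantify")
    def _quantify():
        counts: CountMatrix = state["counts"]
        if counts is None:
            raise ValidationError("no count table available")
        normalized = normalize_by_biotype(counts)
        for biotype, norm in normalized.items():
            norm.values.to_csv(
                outdir / f"normalized_{biotype}_{norm.method}.tsv", sep="\t")
        combined = _combined_normalized(normalized, config.stage_labels)
        state["stage_means"] = combined.stage_means()
        contrasts = {}
        tables = []
        for label in config.contrasts:
            stage_a, _, stage_b = label.partition("/")
            table = contrast(combined, stage_a, stage_b, config.pseudocount)
            contrasts[label] = table
            tables.append(table)
        state["contrast_tables"] = contrasts
        pd.concat(tables).to_csv(outdir / "contrasts.tsv", sep="\t",
                                 index=False)
        summary["stages"]["quantify"] = {
            "n_features": int(len(counts.counts)),
            "n_samples": len(counts.samples),
            "n_contrasts": len(contrasts),
        }

    @stage("targets")
    def _targets():
        transcripts = state["transcripts"]
        mirnas = [t for t in transcripts if t.biotype == "mirna"]
        others = [t for t in transcripts if t.biotype != "mirna"]
        if not mirnas:
            raise ValidationError(
                "no miRNA records available: the target stage requires a "
                "miRNA input")
        mre = predict_targetome(mirnas, others, config.scheme)
        state["mre_table"] = mre
        mre.to_csv(outdir / "mre.tsv", sep="\t", index=False)
        if state.get("tree") is not None:
            # flag tree leaves whose protein locus index maps onto an
            # MRE-carrying mRNA (synthetic runs pair them by rank)
            targets_with_sites = set(mre.loc[mre.biotype == "mrna",
                                             "target_id"])
            mrna_ids = sorted(t.id for t in others if t.biotype == "mrna")
            leaf_ids = sorted(t.name for t in state["tree"].tips())
            mapping = {
                leaf: (i < len(mrna_ids)
                       and mrna_ids[i] in targets_with_sites)
                for i, leaf in enumerate(leaf_ids)
            }
            annotate_mre_class(state["tree"], mapping)
            write_newick(state["tree"], str(outdir / "tree.nwk"))
            pd.DataFrame(
                [{"leaf": k, "mre_class": v} for k, v in
                 sorted(mapping.items())]
            ).to_csv(outdir / "tree_mre_class.tsv", sep="\t", index=False)
        summary["stages"]["targets"] = {
            "n_mirnas": len(mirnas),
            "n_sites": int(len(mre)),
        }

    @stage("network")
    def _network():
        pairs = shared_mre_pairs(state["mre_table"])
        kept, dropped = correlation_filter(pairs, state["stage_means"],
                                           config.r_min)
        triads = assemble_triads(
            kept, state["contrast_tables"], config.de_threshold,
            require_mirna_opposite=config.require_mirna_opposite,
            require_mirna_de=config.require_mirna_de)
        state["triads"] = triads
        export_network(triads, outdir)
        triad_pairs = {(t.cerna_id, t.mrna_id) for t in triads}
        per_contrast = {}
        for label in config.contrasts:
            per_contrast[label] = sum(1 for t in triads
                                      if t.contrast == label)
        summary["stages"]["network"] = {
            "n_shared_mre_pairs": len(pairs),
            "n_correlated_pairs": len(kept),
            "n_triad_pairs": len(triad_pairs),
            "n_triads": len(triads),
            "n_triads_per_contrast": per_contrast,
        }
        if state.get("truth") is not None:
            report = evaluate_recovery(triads,
                                       state["truth"].planted_triads)
            summary["recovery"] = {
                "precision": report.precision,
                "recall": report.recall,
                "precision_defined": report.precision_defined,
                "n_predicted": report.n_predicted,
                "n_truth": report.n_truth,
            }
            (outdir / "recovery.json").write_text(
                json.dumps(summary["recovery"], sort_keys=True, indent=1))

    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1))
    write_manifest(config, outdir)
    summary["outdir"] = str(outdir)
    return summary


def write_manifest(config: PipelineConfig, outdir) -> Dict:
    """Provenance manifest: config hash, seed, version, defaulted
    parameters, and per-file checksums (relative paths)."""
    outdir = Path(outdir)
    files = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            rel = path.relative_to(outdir).as_posix()
            files[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    resolved = config.to_dict()
    resolved.pop("outdir", None)
    manifest = {
        "tool": "splnet",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.fingerprint(),
        "parameters": resolved,
        "files": files,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str))
    return manifest
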