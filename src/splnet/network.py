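"""ceRNA-miR156-mRNA triad construction and network export.

A candidate ceRNA pair is a (lncRNA-or-circRNA, mRNA) pair sharing at least
one miRNA response element for the same miRNA.  Pairs must show positive
correlation of their stage-mean expression profiles, and a triad is emitted
per shared miRNA and per stage contrast when the ceRNA and mRNA are
differentially expressed in the same direction while the miRNA moves in the
opposite direction (the sponge model's signature).  Networks export to SIF,
node-attribute TSV, and GraphML for Cytoscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .expression import pearson_correlation

CERNA_BIOTYPES = {"lncrna", "circrna"}


@dataclass
class CandidatePair:
    """A ceRNA-mRNA pair sharing at least one MRE miRNA."""

    cerna_id: str
    cerna_biotype: str
    mrna_id: str
    shared_mirnas: Set[str]
    r: Optional[float] = None

    def __post_init__(self):
        if not self.shared_mirnas:
            raise ValidationError("shared_mirnas must be non-empty")
        if self.cerna_biotype not in CERNA_BIOTYPES:
            raise ValidationError(
                f"cerna biotype must be lncRNA/circRNA, got "
                f"{self.cerna_biotype!r}")


@dataclass
class Triad:
    """One ceRNA-miRNA-mRNA regulatory relationship in one contrast."""

    cerna_id: str
    mirna_id: str
    mrna_id: str
    contrast: str
    cerna_bin: str
    mirna_bin: str
    mrna_bin: str
    cerna_direction: str
    mirna_direction: str
    mrna_direction: str
    r: float

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.cerna_id, self.mirna_id, self.mrna_id)


def shared_mre_pairs(mre_table: pd.DataFrame) -> List[CandidatePair]:
    """All (ceRNA, mRNA) pairs whose miRNA sets intersect."""
    if mre_table.empty:
        return []
    mirnas_by_target: Dict[str, Set[str]] = {}
    biotype_of: Dict[str, str] = {}
    for row in mre_table.itertuples():
        mirnas_by_target.setdefault(row.target_id, set()).add(row.mirna_id)
        biotype_of[row.target_id] = row.biotype
    cernas = sorted(t for t, b in biotype_of.items() if b in CERNA_BIOTYPES)
    mrnas = sorted(t for t, b in biotype_of.items() if b == "mrna")
    pairs = []
    for c in cernas:
        for g in mrnas:
            shared = mirnas_by_target[c] & mirnas_by_target[g]
            if shared:
                pairs.append(CandidatePair(c, biotype_of[c], g, shared))
    return pairs


def correlation_filter(
    pairs: Sequence[CandidatePair],
    stage_means: pd.DataFrame,
    r_min: float = 0.8,
) -> Tuple[List[CandidatePair], List[Tuple[CandidatePair, str]]]:
    """Keep pairs whose stage-mean profiles correlate at r >= r_min > 0.

    ``stage_means`` is a features x stages DataFrame covering every pair
    member.  Returns (kept pairs annotated with r, dropped pairs with
    reasons); undefined correlations (zero variance) and missing expression
    drop the pair.
    """
    if r_min <= 0:
        raise ValidationError("r_min must be positive (positive correlation)")
    kept = []
    dropped = []
    for pair in pairs:
        missing = [t for t in (pair.cerna_id, pair.mrna_id)
                   if t not in stage_means.index]
        if missing:
            dropped.append((pair, f"missing expression for {missing}"))
            continue
        r = pearson_correlation(stage_means.loc[pair.cerna_id].to_numpy(),
                                stage_means.loc[pair.mrna_id].to_numpy())
        if math.isnan(r):
            dropped.append((pair, "undefined correlation (zero variance)"))
            continue
        if r >= r_min:
            pair.r = r
            kept.append(pair)
        else:
            dropped.append((pair, f"r={r:.3f} below threshold"))
    return kept, dropped


def assemble_triads(
    pairs: Sequence[CandidatePair],
    contrasts: Dict[str, pd.DataFrame],
    de_threshold: float = 1.0,
    require_mirna_opposite: bool = True,
    require_mirna_de: bool = True,
) -> List[Triad]:
    """Intersect shared-MRE, correlated pairs with stage contrasts.

    ``contrasts`` maps contrast label -> DataFrame with columns
    (feature, log2fc, direction, fold_bin) as produced by
    :func:`splnet.expression.contrast` (all biotypes concatenated).  A triad
    is emitted per shared miRNA when ceRNA and mRNA are differentially
    expressed (|log2fc| >= de_threshold) in the same direction and the
    miRNA is differentially expressed in the opposite direction (both
    requirements relaxable by flag).
    """
    triads: List[Triad] = []
    for label, table in contrasts.items():
        for required in ("feature", "log2fc", "direction", "fold_bin"):
            if required not in table.columns:
                raise ValidationError(
                    f"contrast table {label!r} missing column {required!r}")
        lookup = table.set_index("feature")
        for pair in sorted(pairs, key=lambda p: (p.cerna_id, p.mrna_id)):
            members = (pair.cerna_id, pair.mrna_id)
            if any(m not in lookup.index for m in members):
                continue
            c_row = lookup.loc[pair.cerna_id]
            g_row = lookup.loc[pair.mrna_id]
            if abs(c_row.log2fc) < de_threshold:
                continue
            if abs(g_row.log2fc) < de_threshold:
                continue
            if c_row.direction != g_row.direction:
                continue
            if c_row.direction == "flat":
                continue
            for mid in sorted(pair.shared_mirnas):
                if mid not in lookup.index:
                    continue
                m_row = lookup.loc[mid]
                if require_mirna_de and abs(m_row.log2fc) < de_threshold:
                    continue
                if require_mirna_opposite:
                    opposite = {"up": "down", "down": "up"}[c_row.direction]
                    if m_row.direction != opposite:
                        continue
                triads.append(Triad(
                    cerna_id=pair.cerna_id, mirna_id=mid,
                    mrna_id=pair.mrna_id, contrast=label,
                    cerna_bin=c_row.fold_bin, mirna_bin=m_row.fold_bin,
                    mrna_bin=g_row.fold_bin,
                    cerna_direction=c_row.direction,
                    mirna_direction=m_row.direction,
                    mrna_direction=g_row.direction,
                    r=pair.r if pair.r is not None else math.nan,
                ))
    return triads


def triads_table(triads: Sequence[Triad]) -> pd.DataFrame:
    columns = ["cerna_id", "mirna_id", "mrna_id", "contrast",
               "cerna_bin", "mirna_bin", "mrna_bin", "cerna_direction",
               "mirna_direction", "mrna_direction", "r"]
    rows = [{c: getattr(t, c) for c in columns} for t in triads]
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(
        ["contrast", "cerna_id", "mirna_id", "mrna_id"]
    ).reset_index(drop=True)


def _bin_label(direction: str, fold_bin: str) -> str:
    if direction == "flat" or fold_bin == "none":
        return "none"
    return f"{direction.capitalize()} {fold_bin}"


def export_network(
    triads: Sequence[Triad],
    outdir,
    biotypes: Optional[Dict[str, str]] = None,
) -> Dict[str, str]:
    """Write SIF, node-attribute TSV, and GraphML network files.

    Edges: ceRNA -sponges-> miRNA and miRNA -represses-> mRNA.  Node
    attributes carry the biotype and the Up/Down fold-bin label per
    contrast.  Returns the mapping of written file roles to paths.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"unwritable network directory: {exc}")
    biotypes = biotypes or {}
    graph = nx.DiGraph()
    sif_lines = []
    node_rows = {}
    for t in sorted(triads, key=lambda t: (t.contrast,) + t.key):
        for node, bin_, direction, default_type in (
            (t.cerna_id, t.cerna_bin, t.cerna_direction, "cerna"),
            (t.mirna_id, t.mirna_bin, t.mirna_direction, "mirna"),
            (t.mrna_id, t.mrna_bin, t.mrna_direction, "mrna"),
        ):
            biotype = biotypes.get(node, default_type)
            label = _bin_label(direction, bin_)
            node_rows[(node, t.contrast)] = {
                "node": node, "biotype": biotype, "contrast": t.contrast,
                "fold_class": label,
            }
            if not graph.has_node(node):
                graph.add_node(node, biotype=biotype)
            graph.nodes[node][f"fold_class_{t.contrast}"] = label
        for src, rel, dst in ((t.cerna_id, "sponges", t.mirna_id),
                              (t.mirna_id, "represses", t.mrna_id)):
            line = f"{src}\t{rel}\t{dst}"
            if line not in sif_lines:
                sif_lines.append(line)
            graph.add_edge(src, dst, interaction=rel)
    paths = {
        "sif": outdir / "network.sif",
        "nodes": outdir / "nodes.tsv",
        "graphml": outdir / "network.graphml",
        "triads": outdir / "triads.tsv",
    }
    paths["sif"].write_text("\n".join(sif_lines) + ("\n" if sif_lines
                                                    else ""))
    pd.DataFrame(
        list(node_rows.values()),
        columns=["node", "biotype", "contrast", "fold_class"],
    ).to_csv(paths["nodes"], sep="\t", index=False)
    nx.write_graphml(graph, paths["graphml"])
    triads_table(triads).to_csv(paths["triads"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


@dataclass
class RecoveryReport:
    """Precision/recall of predicted triads against planted truth."""

    precision: float
    recall: float
    n_predicted: int
    n_truth: int
    true_positives: List[Tuple[str, str, str]] = field(default_factory=list)
    false_positives: List[Tuple[str, str, str]] = field(default_factory=list)
    false_negatives: List[Tuple[str, str, str]] = field(default_factory=list)
    precision_defined: bool = True
    per_contrast: Dict[str, Dict[str, int]] = field(default_factory=dict)


def evaluate_recovery(
    triads: Sequence[Triad],
    planted_triads: Iterable[Tuple[str, str, str]],
) -> RecoveryReport:
    """Set comparison of predicted (ceRNA, miRNA, mRNA) keys vs truth.

    Predictions are pooled over contrasts (a planted triad found in any
    contrast counts as recovered); per-contrast counts are also reported.
    Empty predictions against non-empty truth give precision 0 with
    ``precision_defined=False``.
    """
    truth = {tuple(t) for t in planted_triads}
    predicted = {t.key for t in triads}
    tp = predicted & truth
    fp = predicted - truth
    fn = truth - predicted
    per_contrast: Dict[str, Dict[str, int]] = {}
    for t in triads:
        entry = per_contrast.setdefault(
            t.contrast, {"n_triads": 0, "n_true": 0})
        entry["n_triads"] += 1
        if t.key in truth:
            entry["n_true"] += 1
    precision_defined = bool(predicted)
    precision = (len(tp) / len(predicted)) if predicted else 0.0
    recall = (len(tp) / len(truth)) if truth else 1.0
    return RecoveryReport(
        precision=precision, recall=recall,
        n_predicted=len(predicted), n_truth=len(truth),
        true_positives=sorted(tp), false_positives=sorted(fp),
        false_negatives=sorted(fn),
        precision_defined=precision_defined,
        per_contrast=per_contrast,
    )
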