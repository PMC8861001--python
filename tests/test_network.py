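"""Shared-MRE pairing, correlation gating, triad assembly, and export."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from splnet.errors import ValidationError
from splnet.expression import NormalizedMatrix, contrast
from splnet.network import (CandidatePair, Triad, assemble_triads,
                            correlation_filter, evaluate_recovery,
                            export_network, shared_mre_pairs, triads_table)

STAGES = ["Li", "La", "Ov", "Bo"]


def _mre_table(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "biotype",
                                       "start", "end", "score",
                                       "spans_junction"])


def _site(mirna, target, biotype):
    return (mirna, target, biotype, 1, 21, 0.0, False)


def _contrast_frame(entries):
    """entries: feature -> log2fc."""
    rows = []
    for feature, lfc in entries.items():
        direction = "flat" if lfc == 0 else ("up" if lfc > 0 else "down")
        fold = 2.0 ** abs(lfc)
        if lfc == 0:
            bin_ = "none"
        elif fold <= 2:
            bin_ = "A"
        elif fold <= 5:
            bin_ = "B"
        elif fold <= 10:
            bin_ = "C"
        else:
            bin_ = "D"
        rows.append({"feature": feature, "contrast": "Bo/Li",
                     "log2fc": lfc, "direction": direction,
                     "fold_bin": bin_})
    return pd.DataFrame(rows)


class TestSharedMrePairs:
    def test_cross_product_when_all_share_one_mirna(self):
        table = _mre_table([
            _site("miR156a", "lnc1", "lncrna"),
            _site("miR156a", "lnc2", "lncrna"),
            _site("miR156a", "m1", "mrna"),
            _site("miR156a", "m2", "mrna"),
        ])
        pairs = shared_mre_pairs(table)
        assert len(pairs) == 4
        assert {(p.cerna_id, p.mrna_id) for p in pairs} == {
            ("lnc1", "m1"), ("lnc1", "m2"), ("lnc2", "m1"),
            ("lnc2", "m2")}

    def test_disjoint_mirna_sets_yield_no_pair(self):
        table = _mre_table([
            _site("miR156a", "lnc1", "lncrna"),
            _site("miR156b", "m1", "mrna"),
        ])
        assert shared_mre_pairs(table) == []

    def test_empty_table_yields_empty_output(self):
        assert shared_mre_pairs(_mre_table([])) == []

    def test_empty_shared_set_rejected_on_construction(self):
        with pytest.raises(ValidationError):
            CandidatePair("lnc1", "lncrna", "m1", set())


class TestCorrelationFilter:
    def _means(self, values):
        return pd.DataFrame.from_dict(values, orient="index",
                                      columns=STAGES, dtype=float)

    def test_identical_profiles_kept_with_r_one(self):
        pairs = [CandidatePair("lnc1", "lncrna", "m1", {"miR156a"})]
        means = self._means({"lnc1": [1, 2, 3, 4], "m1": [1, 2, 3, 4]})
        kept, dropped = correlation_filter(pairs, means, 0.8)
        assert len(kept) == 1 and kept[0].r == pytest.approx(1.0)
        assert dropped == []

    def test_anticorrelated_profile_dropped(self):
        pairs = [CandidatePair("lnc1", "lncrna", "m1", {"miR156a"})]
        means = self._means({"lnc1": [4, 3, 2, 1], "m1": [1, 2, 3, 4]})
        kept, dropped = correlation_filter(pairs, means, 0.8)
        assert kept == [] and len(dropped) == 1

    def test_missing_expression_dropped_with_reason(self):
        pairs = [CandidatePair("lnc1", "lncrna", "m1", {"miR156a"})]
        means = self._means({"lnc1": [1, 2, 3, 4]})
        kept, dropped = correlation_filter(pairs, means, 0.8)
        assert kept == []
        assert "missing expression" in dropped[0][1]

    def test_tighter_threshold_is_subset(self):
        rng = np.random.default_rng(0)
        pairs = [CandidatePair(f"lnc{i}", "lncrna", f"m{i}", {"x"})
                 for i in range(30)]
        values = {}
        for i in range(30):
            values[f"lnc{i}"] = rng.uniform(0, 10, 4).tolist()
            values[f"m{i}"] = rng.uniform(0, 10, 4).tolist()
        means = self._means(values)
        loose, _ = correlation_filter(pairs, means, 0.5)
        tight, _ = correlation_filter(pairs, means, 0.8)
        loose_ids = {(p.cerna_id, p.mrna_id) for p in loose}
        assert all((p.cerna_id, p.mrna_id) in loose_ids for p in tight)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            correlation_filter([], pd.DataFrame(), 0.0)


class TestAssembleTriads:
    def _pair(self, mirnas={"miR156a"}):
        pair = CandidatePair("lnc1", "lncrna", "m1", set(mirnas))
        pair.r = 0.95
        return pair

    def test_two_shared_mirnas_give_two_triads(self):
        frame = _contrast_frame({"lnc1": 2.0, "m1": 2.5, "miR156a": -2.0,
                                 "miR156b": -1.5})
        triads = assemble_triads([self._pair({"miR156a", "miR156b"})],
                                 {"Bo/Li": frame})
        assert len(triads) == 2
        assert {t.mirna_id for t in triads} == {"miR156a", "miR156b"}

    def test_same_direction_mirna_blocks_triad(self):
        frame = _contrast_frame({"lnc1": 2.0, "m1": 2.5, "miR156a": 2.0})
        assert assemble_triads([self._pair()], {"Bo/Li": frame}) == []

    def test_discordant_cerna_mrna_blocks_triad(self):
        frame = _contrast_frame({"lnc1": 2.0, "m1": -2.5,
                                 "miR156a": -2.0})
        assert assemble_triads([self._pair()], {"Bo/Li": frame}) == []

    def test_subthreshold_fold_change_blocks_triad(self):
        frame = _contrast_frame({"lnc1": 0.5, "m1": 2.5, "miR156a": -2.0})
        assert assemble_triads([self._pair()], {"Bo/Li": frame}) == []

    def test_mirna_de_gate_relaxable(self):
        frame = _contrast_frame({"lnc1": 2.0, "m1": 2.5, "miR156a": -0.5})
        strict = assemble_triads([self._pair()], {"Bo/Li": frame})
        relaxed = assemble_triads([self._pair()], {"Bo/Li": frame},
                                  require_mirna_de=False)
        assert strict == [] and len(relaxed) == 1

    def test_emitted_triads_satisfy_all_gates(self):
        rng = np.random.default_rng(1)
        entries = {f"lnc{i}": float(rng.uniform(-3, 3)) for i in range(8)}
        entries.update({f"m{i}": float(rng.uniform(-3, 3))
                        for i in range(8)})
        entries.update({f"mi{i}": float(rng.uniform(-3, 3))
                        for i in range(4)})
        frame = _contrast_frame(entries)
        pairs = []
        for i in range(8):
            pair = CandidatePair(f"lnc{i}", "lncrna", f"m{i}",
                                 {f"mi{i % 4}"})
            pair.r = 0.9
            pairs.append(pair)
        triads = assemble_triads(pairs, {"Bo/Li": frame})
        lookup = frame.set_index("feature")
        for t in triads:
            assert abs(lookup.loc[t.cerna_id].log2fc) >= 1.0
            assert abs(lookup.loc[t.mrna_id].log2fc) >= 1.0
            assert abs(lookup.loc[t.mirna_id].log2fc) >= 1.0
            assert lookup.loc[t.cerna_id].direction == \
                lookup.loc[t.mrna_id].direction
            assert lookup.loc[t.mirna_id].direction != \
                lookup.loc[t.cerna_id].direction


class TestExport:
    def _one_triad(self):
        return Triad("lnc1", "miR156a", "m1", "Bo/Li", "B", "B", "C",
                     "up", "down", "up", 0.97)

    def test_sif_structure(self, tmp_path):
        paths = export_network([self._one_triad()], tmp_path)
        lines = (tmp_path / "network.sif").read_text().strip().split("\n")
        assert lines == ["lnc1\tsponges\tmiR156a",
                         "miR156a\trepresses\tm1"]

    def test_graphml_round_trip_counts(self, tmp_path):
        export_network([self._one_triad()], tmp_path)
        graph = nx.read_graphml(tmp_path / "network.graphml")
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2

    def test_node_fold_class_matches_contrast_output(self, tmp_path):
        """Exported node colour classes equal the fold bins computed by
        the expression module on the same data."""
        samples = [f"{s}_1" for s in STAGES]
        values = pd.DataFrame(
            {"lnc1": [1, 2, 4, 8], "miR156a": [8, 4, 2, 1],
             "m1": [1, 2, 4, 12]},
        ).T
        values.columns = samples
        features = pd.DataFrame({"biotype": ["lncrna", "mirna", "mrna"],
                                 "length_bp": [400, 21, 1000]},
                                index=values.index)
        norm = NormalizedMatrix(values.astype(float), features, STAGES,
                                "mixed")
        table = contrast(norm, "Bo", "Li", pseudocount=0.0)
        pair = CandidatePair("lnc1", "lncrna", "m1", {"miR156a"})
        pair.r = 1.0
        triads = assemble_triads([pair], {"Bo/Li": table})
        assert len(triads) == 1
        export_network(triads, tmp_path)
        nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t",
                            index_col="node")
        lookup = table.set_index("feature")
        for node in ("lnc1", "miR156a", "m1"):
            row = lookup.loc[node]
            expected = f"{row.direction.capitalize()} {row.fold_bin}"
            assert nodes.loc[node, "fold_class"] == expected

    def test_empty_triads_export_empty_files(self, tmp_path):
        paths = export_network([], tmp_path)
        assert (tmp_path / "network.sif").read_text() == ""
        assert len(triads_table([])) == 0


class TestEvaluateRecovery:
    def test_perfect_recovery(self):
        triads = [Triad("lnc1", "mi1", "m1", "Bo/Li", "B", "B", "B",
                        "up", "down", "up", 0.9)]
        report = evaluate_recovery(triads, [("lnc1", "mi1", "m1")])
        assert report.precision == 1.0 and report.recall == 1.0

    def test_empty_predictions_flagged(self):
        report = evaluate_recovery([], [("lnc1", "mi1", "m1")])
        assert report.recall == 0.0
        assert report.precision == 0.0
        assert not report.precision_defined

    def test_label_permutation_destroys_recall(self):
        """Permuting mRNA labels leaves only chance-level recovery."""
        rng = np.random.default_rng(4)
        truth = [(f"lnc{i}", f"mi{i % 5}", f"m{i}") for i in range(30)]
        perm = rng.permutation(30)
        shuffled = [Triad(f"lnc{i}", f"mi{i % 5}", f"m{int(perm[i])}",
                          "Bo/Li", "B", "B", "B", "up", "down", "up", 0.9)
                    for i in range(30)]
        report = evaluate_recovery(shuffled, truth)
        assert report.recall <= 0.2  # ~1/30 expected collision rate
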