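"""Synthetic-data generator: determinism, planted truth, count model."""

import json

import numpy as np
import pytest

from splnet.errors import ConfigurationError, ValidationError
from splnet.expression import pearson_correlation
from splnet.family import default_sbp_profile, scan_domain
from splnet.records import TranscriptRecord, read_transcript_fasta
from splnet.synthetic import (PlantedTruth, SimulationConfig,
                              generate_transcriptome, plant_mres,
                              simulate_counts, write_fixtures)
from splnet.targets import PenaltyScheme, duplex_penalty, find_circ_sites


class TestConfig:
    @pytest.mark.parametrize("field, value", [
        ("stage_labels", ("Li", "La", "Ov")),
        ("replicates_per_stage", 0),
        ("n_mrna", 0),
        ("mre_fraction", 1.5),
        ("nb_dispersion", 0.0),
        ("effect_size", 1.0),
    ])
    def test_invalid_values_name_the_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            SimulationConfig(**{field: value})


class TestGenerateTranscriptome:
    def test_deterministic_for_fixed_seed(self, small_config):
        t1, truth1 = generate_transcriptome(small_config)
        t2, truth2 = generate_transcriptome(small_config)
        assert [(r.id, r.seq, r.biotype, r.locus) for r in t1] == \
            [(r.id, r.seq, r.biotype, r.locus) for r in t2]
        assert truth1.to_json() == truth2.to_json()

    def test_mirna_family_records(self):
        config = SimulationConfig(n_mirna=12, n_mrna=10, n_lncrna=4,
                                  n_circrna=2, seed=0)
        records, _ = generate_transcriptome(config)
        family = [r for r in records if r.locus == "miR156"]
        assert len(family) == 12
        assert all(len(r.seq) == 21 for r in family)
        assert family[0].id.endswith("a") and family[11].id.endswith("l")

    def test_zero_mre_fraction_plants_nothing(self):
        config = SimulationConfig(mre_fraction=0.0, n_mrna=20, n_lncrna=5,
                                  n_circrna=2, seed=0)
        _, truth = generate_transcriptome(config)
        assert truth.planted_sites == []
        assert truth.planted_triads == []

    def test_feature_count_and_dimensions(self, small_config,
                                          small_dataset):
        transcripts, truth, counts = small_dataset
        c = small_config
        expected = (c.n_mrna + c.n_lncrna + c.n_circrna + c.n_mirna
                    + c.n_background_mirna)
        assert len(transcripts) == expected
        assert counts.counts.shape == (expected,
                                       4 * c.replicates_per_stage)

    def test_mir156_means_strictly_decreasing(self, small_dataset):
        _, truth, _ = small_dataset
        for fid, meta in truth.feature_meta.items():
            if meta["locus"] == "miR156":
                means = truth.stage_means[fid]
                assert all(a > b for a, b in zip(means, means[1:]))

    def test_triad_mrna_means_strictly_increasing(self, small_dataset):
        _, truth, _ = small_dataset
        for _, _, mrna in truth.planted_triads:
            means = truth.stage_means[mrna]
            assert all(a < b for a, b in zip(means, means[1:]))

    def test_triad_members_share_planted_mirna(self, small_dataset):
        _, truth, _ = small_dataset
        sites = {(t, m) for m, t, *_ in truth.planted_sites}
        for cerna, mirna, mrna in truth.planted_triads:
            assert (cerna, mirna) in sites
            assert (mrna, mirna) in sites

    def test_triad_profiles_perfectly_correlated_before_noise(
            self, small_dataset):
        _, truth, _ = small_dataset
        for cerna, _, mrna in truth.planted_triads:
            r = pearson_correlation(truth.stage_means[cerna],
                                    truth.stage_means[mrna])
            assert r == pytest.approx(1.0)

    def test_isoform_groups_recorded(self):
        config = SimulationConfig(n_mrna=120, mrna_isoform_fraction=0.5,
                                  n_lncrna=5, n_circrna=2, seed=3)
        records, truth = generate_transcriptome(config)
        assert truth.isoform_groups
        by_id = {r.id: r for r in records}
        for locus, members in truth.isoform_groups.items():
            assert len(members) in (2, 3)
            assert all(by_id[m].locus == locus for m in members)


class TestPlantMres:
    def test_designed_scores_recoverable_by_duplex_penalty(
            self, small_dataset):
        transcripts, truth, _ = small_dataset
        by_id = {r.id: r for r in transcripts}
        scheme = PenaltyScheme()
        mirna_seq = {r.id: r.seq for r in transcripts
                     if r.biotype == "mirna"}
        checked_linear = checked_junction = 0
        for mid, tid, start, end, designed in truth.planted_sites:
            assert designed <= scheme.cutoff
            target = by_id[tid]
            if end >= start:
                window = target.seq[start - 1:end]
                score, _ = duplex_penalty(mirna_seq[mid], window, scheme)
                assert score == pytest.approx(designed)
                checked_linear += 1
            else:  # junction-spanning circRNA site
                sites = find_circ_sites(mid, mirna_seq[mid], target,
                                        scheme)
                match = [s for s in sites
                         if s.start == start and s.spans_junction]
                assert match and match[0].score == pytest.approx(designed)
                checked_junction += 1
        assert checked_linear > 0

    def test_zero_edit_sites_exist_and_score_zero(self, small_dataset):
        _, truth, _ = small_dataset
        assert any(score == 0.0 for *_, score in truth.planted_sites)

    def test_mirna_longer_than_target_rejected(self):
        config = SimulationConfig(seed=0)
        mirna = TranscriptRecord("mi", "A" * 21, "mirna")
        target = TranscriptRecord("t", "ACGTACGT", "mrna")
        with pytest.raises(ValidationError, match="longer than target"):
            plant_mres([target], [mirna], config,
                       rng=np.random.default_rng(0),
                       assignments={"t": "mi"})


class TestSimulateCounts:
    def test_deterministic_for_fixed_seed(self, small_config,
                                          small_dataset):
        _, truth, counts = small_dataset
        again = simulate_counts(truth, small_config)
        assert counts.counts.equals(again.counts)

    def test_poisson_limit_variance_over_mean_near_one(self):
        """As dispersion -> 0 the count model approaches Poisson, so a
        high-mean feature's variance/mean ratio tends to 1 (library
        factors pinned to 1 to isolate the sampling noise)."""
        config = SimulationConfig(
            n_mrna=1, n_lncrna=1, n_circrna=1, n_mirna=1,
            n_background_mirna=0, replicates_per_stage=2500,
            nb_dispersion=1e-9, mre_fraction=0.0, base_mean=500.0,
            library_factor_range=(1.0, 1.0), seed=5)
        _, truth = generate_transcriptome(config)
        counts = simulate_counts(truth, config)
        flat = [fid for fid, meta in truth.feature_meta.items()
                if meta["biotype"] == "mrna"][0]
        draws = counts.counts.loc[flat].to_numpy(dtype=float)
        ratio = draws.var(ddof=1) / draws.mean()
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_dispersion_inflates_variance(self):
        config = SimulationConfig(
            n_mrna=1, n_lncrna=1, n_circrna=1, n_mirna=1,
            n_background_mirna=0, replicates_per_stage=2500,
            nb_dispersion=0.2, mre_fraction=0.0, base_mean=500.0,
            library_factor_range=(1.0, 1.0), seed=5)
        _, truth = generate_transcriptome(config)
        counts = simulate_counts(truth, config)
        flat = [fid for fid, meta in truth.feature_meta.items()
                if meta["biotype"] == "mrna"][0]
        draws = counts.counts.loc[flat].to_numpy(dtype=float)
        ratio = draws.var(ddof=1) / draws.mean()
        # NB: var/mean = 1 + dispersion * mean
        assert ratio == pytest.approx(1 + 0.2 * draws.mean(), rel=0.2)

    def test_empirical_mirna_stage_means_decrease(self):
        """Averaged over 50 replicates per stage, a miR156 member's
        empirical stage means fall strictly Li -> Bo at effect size 2."""
        config = SimulationConfig(
            n_mrna=5, n_lncrna=2, n_circrna=1, n_mirna=3,
            n_background_mirna=0, replicates_per_stage=50,
            effect_size=2.0, mre_fraction=0.0, seed=9)
        _, truth = generate_transcriptome(config)
        counts = simulate_counts(truth, config)
        mirna_id = [fid for fid, meta in truth.feature_meta.items()
                    if meta["locus"] == "miR156"][0]
        row = counts.counts.loc[mirna_id]
        stage_means = [row[[c for c in row.index
                            if c.startswith(stage)]].mean()
                       for stage in config.stage_labels]
        assert all(a > b for a, b in zip(stage_means, stage_means[1:]))


class TestProteinSet:
    def test_labels_cover_all_classes(self, small_proteins):
        records, references, truth = small_proteins
        labels = set(truth.labels.values())
        assert labels == {"spl", "truncated_decoy", "random_decoy"}
        assert references

    def test_truncated_decoys_never_full_length(self, small_proteins):
        records, _, truth = small_proteins
        profile = default_sbp_profile()
        for rec in records:
            if truth.labels[rec.id] == "truncated_decoy":
                hit = scan_domain(rec.seq, profile)
                assert hit is None or not hit.full_length

    def test_isoform_groups_mark_longest_canonical(self, small_proteins):
        records, _, truth = small_proteins
        by_id = {r.id: r for r in records}
        for locus, members in truth.isoform_groups.items():
            canonical = [m for m in members if m in truth.canonical]
            assert len(canonical) == 1
            longest = max(members, key=lambda m: len(by_id[m]))
            assert canonical[0] == longest


class TestWriteFixtures:
    def test_round_trip_and_checksums(self, tmp_path, small_config,
                                      small_dataset):
        transcripts, truth, counts = small_dataset
        outdir = tmp_path / "fix"
        manifest = write_fixtures(transcripts, truth, counts, outdir,
                                  seed=small_config.seed)
        again = write_fixtures(transcripts, truth, counts, outdir,
                               seed=small_config.seed)
        assert manifest == again  # unchanged content, unchanged checksums

        back = []
        for biotype in ("circrna", "lncrna", "mirna", "mrna"):
            back.extend(read_transcript_fasta(outdir / f"{biotype}.fasta",
                                              biotype))
        by_id = {r.id: r for r in back}
        for rec in transcripts:
            other = by_id[rec.id]
            assert (other.seq, other.biotype, other.locus) == \
                (rec.seq, rec.biotype, rec.locus)
            if rec.biotype == "circrna":
                assert other.junction == rec.junction

        truth_back = PlantedTruth.from_json(
            (outdir / "truth.json").read_text())
        assert truth_back.planted_triads == truth.planted_triads

        # touching one file changes exactly that checksum
        mutated = dict(truth.stage_means)
        first = next(iter(mutated))
        truth2 = PlantedTruth(truth.planted_sites, truth.planted_triads,
                              truth.isoform_groups,
                              {**mutated, first: [1.0, 2.0, 3.0, 4.0]},
                              truth.feature_meta)
        changed = write_fixtures(transcripts, truth2, counts, outdir,
                                 seed=small_config.seed)
        assert changed["files"]["truth.json"] != \
            manifest["files"]["truth.json"]
        assert changed["files"]["mrna.fasta"] == \
            manifest["files"]["mrna.fasta"]

    def test_unwritable_directory_raises(self, small_dataset):
        transcripts, truth, counts = small_dataset
        with pytest.raises(ValidationError):
            write_fixtures(transcripts, truth, counts,
                           "/proc/definitely_unwritable")
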