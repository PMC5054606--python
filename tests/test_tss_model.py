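"""Training-set geometry, SVM cross-validation, and the genome scan."""

import numpy as np
import pandas as pd
import pytest

from lincscout.core import GenomeInterval, IntervalIndex, PipelineConfig, tss_proximal_region
from lincscout.tss_model import (
    WindowScanner,
    candidate_windows,
    feature_groups,
    feature_names,
    genome_scan,
    region_features,
    train_and_cv,
)


class TestRegionGeometry:
    def test_plus_strand_definition(self):
        r = tss_proximal_region("chr1", 50000, "+")
        assert (r.start, r.end) == (49000, 50500)

    def test_minus_strand_mirror(self):
        r = tss_proximal_region("chr1", 50000, "-")
        assert (r.start, r.end) == (49500, 51000)

    def test_span_equals_scan_window(self, cfg):
        for strand in "+-":
            assert tss_proximal_region("chr1", 50000, strand).length == cfg.scan_window


class TestTrainingSet:
    def test_balanced_and_sized(self, training_set, cfg):
        assert training_set.n_pos > 0
        assert training_set.n_neg == training_set.n_pos * cfg.neg_per_pos
        assert all(r.length == cfg.scan_window for r in training_set.regions)
        assert training_set.features.shape[0] == len(training_set.regions)

    def test_negatives_overlap_no_annotated_exon(self, training_set, world):
        exons = [e for tx in world.known for e in tx.exons]
        negatives = [
            r for r, lab in zip(training_set.regions, training_set.labels) if not lab
        ]
        for neg in negatives:  # brute-force all-pairs check
            for exon in exons:
                assert not neg.overlaps(exon)

    def test_negatives_within_zone(self, training_set, world, cfg):
        pos_tss = [l.true_tss for l in world.known_lincs]
        for region, label in zip(training_set.regions, training_set.labels):
            if label:
                continue
            center_dist = min(abs(region.start - t) for t in pos_tss)
            assert center_dist <= cfg.neg_zone


class TestTrainAndCv:
    def _noise_features(self, rng, n, d=8):
        return pd.DataFrame(
            rng.normal(size=(n, d)), columns=[f"f{i}" for i in range(d)]
        )

    def test_separable_features_reach_perfect_auc(self, cfg):
        rng = np.random.default_rng(0)
        n = 100
        labels = np.array([True, False] * (n // 2))
        X = self._noise_features(rng, n)
        X["f0"] = np.where(labels, 10.0, -10.0) + rng.normal(0, 0.1, n)
        report, _ = train_and_cv(X, labels, cfg=cfg, seed=0)
        assert report.auroc == 1.0
        assert report.error_rate == 0.0

    def test_permuted_labels_near_chance(self, cfg):
        rng = np.random.default_rng(1)
        n = 200
        X = self._noise_features(rng, n)
        aucs = []
        for rep in range(10):
            labels = rng.permutation(np.array([True, False] * (n // 2)))
            report, _ = train_and_cv(X, labels, cfg=cfg, seed=rep)
            aucs.append(report.auroc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_accuracy_plus_error_is_one(self, trained):
        report, _ = trained
        assert report.accuracy + report.error_rate == pytest.approx(1.0)
        assert 0 <= report.sensitivity <= 1 and 0 <= report.specificity <= 1

    def test_single_class_raises(self, cfg):
        X = self._noise_features(np.random.default_rng(2), 30)
        with pytest.raises(ValueError):
            train_and_cv(X, np.ones(30, dtype=bool), cfg=cfg)

    def test_feature_group_columns_partition_schema(self, world):
        groups = feature_groups(world.pwms)
        names = feature_names(world.pwms)
        flat = [c for cols in groups.values() for c in cols]
        assert len(flat) == len(set(flat)) == len(names)
        assert set(flat) == set(names)
        assert len(groups["kmer"]) == 336


class TestScan:
    def test_window_count_on_bare_chromosome(self, cfg):
        starts = candidate_windows(3000, "chrT", IntervalIndex(), cfg)
        assert list(starts) == [0, 300, 600, 900, 1200, 1500]

    def test_short_chromosome_skipped_with_warning(self, cfg):
        with pytest.warns(UserWarning, match="skipped"):
            starts = candidate_windows(1000, "chrT", IntervalIndex(), cfg)
        assert starts.size == 0

    def test_annotated_windows_excluded(self, cfg):
        index = IntervalIndex([GenomeInterval("chrT", 0, 700)])
        starts = candidate_windows(3000, "chrT", index, cfg)
        assert list(starts) == [900, 1200, 1500]

    def test_scan_windows_on_lattice(self, predicted_regions, cfg):
        assert len(predicted_regions) > 0
        for region in predicted_regions.regions:
            assert region.length == cfg.scan_window
            assert region.start % cfg.scan_step == 0

    def test_scan_reproducible(self, trained, feature_inputs, world, cfg):
        _, model = trained
        a = genome_scan(model, feature_inputs, world.known, cfg)
        b = genome_scan(model, feature_inputs, world.known, cfg)
        assert [(r.chrom, r.start) for r in a.regions] == [
            (r.chrom, r.start) for r in b.regions
        ]
        assert np.array_equal(a.scores, b.scores)

    def test_merged_regions_cover_positives(self, predicted_regions):
        merged = predicted_regions.merged()
        index = IntervalIndex(merged)
        for region in predicted_regions.regions:
            assert index.any_overlap(region)


class TestFastSlowEquality:
    def test_window_scanner_matches_region_features(self, world, feature_inputs, cfg):
        scanner = WindowScanner(feature_inputs, cfg)
        chrom = "chr1"
        starts = np.array([12000, 90000, 250000, 501300], dtype=np.int64)
        fast = scanner.window_features(chrom, starts)
        regions = [
            GenomeInterval(chrom, int(s), int(s) + cfg.scan_window, "+")
            for s in starts
        ]
        slow = region_features(regions, feature_inputs, cfg)
        assert np.allclose(fast.to_numpy(), slow.to_numpy(), atol=1e-12)
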