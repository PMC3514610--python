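import numpy as np
import pytest

from tetrabin import calibration, simulate, tetra
from tetrabin.calibration import (CONFIDENCES, CalibrationTables, SigmaTable,
                                  log_probability, sample_fragments)

from tests.conftest import TINY_LENGTHS


class TestSampleFragments:
    def test_counts_and_lengths(self, tiny_genomes):
        frags = sample_fragments(tiny_genomes[0].seq, [1000, 5000], 100, seed=3)
        assert sum(len(v) for v in frags.values()) == 200
        assert all(len(f) == 5000 for f in frags[5000])

    def test_deterministic(self, tiny_genomes):
        a = sample_fragments(tiny_genomes[0].seq, [2000], 10, seed=9)
        b = sample_fragments(tiny_genomes[0].seq, [2000], 10, seed=9)
        assert a == b

    def test_too_long_skipped(self):
        frags = sample_fragments("ACGT" * 300, [500, 5000], 5, seed=1)
        assert 500 in frags and 5000 not in frags


class TestSigmaTable:
    def test_grid_node_identity(self, tiny_tables):
        st = tiny_tables.sigma_table
        i, j = 12, 3
        got = st.lookup(float(st.mean_centers[i]), float(st.lengths[j]))
        assert got == pytest.approx(max(st.sigma[i, j], calibration.SIGMA_FLOOR))

    def test_log_midpoint_is_mean(self, tiny_tables):
        st = tiny_tables.sigma_table
        i = 15
        l_mid = np.sqrt(st.lengths[2] * st.lengths[3])  # midway in log space
        got = st.lookup(float(st.mean_centers[i]), float(l_mid))
        expected = 0.5 * (st.sigma[i, 2] + st.sigma[i, 3])
        assert got == pytest.approx(max(expected, calibration.SIGMA_FLOOR), rel=1e-9)

    def test_within_neighbor_bounds(self, tiny_tables, rng):
        # brute-force neighborhood oracle for bilinear interpolation
        st = tiny_tables.sigma_table
        for _ in range(200):
            m = rng.uniform(st.mean_centers[0], st.mean_centers[-1])
            length = rng.uniform(st.lengths[0], st.lengths[-1])
            i = np.clip(np.searchsorted(st.mean_centers, m), 1, len(st.mean_centers) - 1)
            j = np.clip(np.searchsorted(st.lengths, length), 1, len(st.lengths) - 1)
            cells = st.sigma[i - 1:i + 1, j - 1:j + 1]
            got = st.lookup(float(m), float(length))
            assert cells.min() - 1e-12 <= got <= max(cells.max(), calibration.SIGMA_FLOOR) + 1e-12

    def test_clamping(self, tiny_tables):
        st = tiny_tables.sigma_table
        assert st.lookup(99.0, 1e9) == pytest.approx(
            max(st.sigma[-1, -1], calibration.SIGMA_FLOOR))
        assert st.lookup(-1.0, 1) == pytest.approx(
            max(st.sigma[0, 0], calibration.SIGMA_FLOOR))

    def test_sigma_positive(self, tiny_tables):
        assert (tiny_tables.sigma_table.sigma > 0).all()

    def test_sigma_decreases_with_length(self, tiny_tables):
        # dispersion shrinks for longer fragments (checked loosely per mean bin)
        st = tiny_tables.sigma_table
        populated = (st.sample_counts > 0).all(axis=1)
        for i in np.flatnonzero(populated):
            assert st.sigma[i, -1] < st.sigma[i, 0]


class TestThresholds:
    def test_ordering_invariant(self, tiny_tables):
        tt = tiny_tables.threshold_table
        assert (tt.log_thresholds[0] >= tt.log_thresholds[1]).all()
        assert (tt.log_thresholds[1] >= tt.log_thresholds[2]).all()

    def test_unknown_confidence(self, tiny_tables):
        with pytest.raises(ValueError):
            tiny_tables.threshold(85, 1000)

    def test_recall_calibration_on_held_out_fragments(self, tiny_genomes, tiny_tables):
        st = tiny_tables.sigma_table
        rng = np.random.default_rng(2024)
        for length in (1000, 5000, 20000):
            hits = {c: 0 for c in CONFIDENCES}
            n = 0
            for g in tiny_genomes:
                gvec = tetra.frequency_vector(g.seq)
                cls = tetra.window_classes(tetra.encode(g.seq))
                starts = rng.integers(0, g.length - length + 1, 100)
                for s in starts:
                    fv = tetra.frequency_from_classes(cls[s:s + length - 3])
                    lp, _ = log_probability(fv, gvec, length, st)
                    n += 1
                    for conf in CONFIDENCES:
                        if lp >= tiny_tables.threshold(conf, length):
                            hits[conf] += 1
            for conf in CONFIDENCES:
                rate = hits[conf] / n * 100
                assert rate == pytest.approx(conf, abs=3.5), (length, conf, rate)


class TestBuildTables:
    def test_too_few_genomes(self):
        with pytest.raises(calibration.CalibrationError):
            calibration.build_tables([("only", "ACGT" * 5000)],
                                     lengths=(500, 1000), n_per_length=5, seed=1)

    def test_undefined_genome_excluded(self, tiny_genomes):
        genomes = [(g.id, g.seq) for g in tiny_genomes[:2]] + [("bad", "N" * 50_000)]
        tables = calibration.build_tables(genomes, lengths=(500, 1000, 5000),
                                          n_per_length=10, seed=1)
        assert tables.provenance["genomes"] == 2

    def test_provenance(self, tiny_tables):
        assert tiny_tables.provenance["genomes"] == 5
        assert tiny_tables.provenance["n_per_length"] == 100

    def test_default_grid_has_38_lengths(self):
        assert len(calibration.LENGTH_GRID) == 38
        assert calibration.LENGTH_GRID[0] == 300
        assert calibration.LENGTH_GRID[-1] == 100_000


class TestLogProbability:
    def test_exact_match_value(self, tiny_tables):
        # v == m: every exponent is zero, only the normalization terms remain
        st = tiny_tables.sigma_table
        v = tetra.frequency_vector("ACGTTGCA" * 500)
        s = st.lookup_vec(v.values, 2000)
        expected = -np.sum(np.log(np.sqrt(2 * np.pi) * s))
        got, aborted = log_probability(v, v, 2000, st)
        assert not aborted
        assert got == pytest.approx(expected)

    def test_monotone_decrease_with_deviation(self, tiny_tables):
        st = tiny_tables.sigma_table
        v = tetra.frequency_vector("ACGTTGCA" * 500)
        prev = log_probability(v, v, 2000, st)[0]
        for delta in (0.05, 0.1, 0.2, 0.5):
            shifted = tetra.FrequencyVector(values=v.values.copy(), matched_windows=v.matched_windows)
            shifted.values[7] += delta
            cur = log_probability(shifted, v, 2000, st)[0]
            assert cur < prev
            prev = cur

    def test_undefined_vector_raises(self, tiny_tables):
        bad = tetra.frequency_vector("NNNN")
        good = tetra.frequency_vector("ACGT" * 100)
        with pytest.raises(ValueError):
            log_probability(bad, good, 1000, tiny_tables.sigma_table)

    def test_abort_decision_equivalence(self, tiny_tables, rng):
        # full-sum oracle: accept/reject must agree on random (v, m, l) triples
        st = tiny_tables.sigma_table
        disagreements = 0
        for _ in range(300):
            base = rng.uniform(0.2, 2.0, 136)
            v = tetra.FrequencyVector(values=base * 136 / base.sum(), matched_windows=1000)
            noise = rng.uniform(0.2, 2.0, 136)
            m = tetra.FrequencyVector(values=noise * 136 / noise.sum(), matched_windows=1000)
            length = float(rng.uniform(300, 100_000))
            full, _ = log_probability(v, m, length, st)
            threshold = full + rng.normal(scale=30.0)
            fast, aborted = log_probability(v, m, length, st, abort_below=threshold)
            if aborted:
                assert fast <= threshold
            disagreements += int((full >= threshold) != (fast >= threshold and not aborted))
        assert disagreements == 0

    def test_abort_returns_exact_sum_when_not_triggered(self, tiny_tables):
        st = tiny_tables.sigma_table
        v = tetra.frequency_vector("ACGTTGCA" * 500)
        full, _ = log_probability(v, v, 2000, st)
        fast, aborted = log_probability(v, v, 2000, st, abort_below=full - 1000)
        assert not aborted
        assert fast == pytest.approx(full, rel=1e-12)


class TestSerialization:
    def test_round_trip_bit_identical(self, tiny_tables, tmp_path):
        p = tmp_path / "tables.tsv"
        tiny_tables.save(p)
        back = CalibrationTables.load(p)
        np.testing.assert_array_equal(back.sigma_table.sigma, tiny_tables.sigma_table.sigma)
        np.testing.assert_array_equal(back.sigma_table.mean_centers,
                                      tiny_tables.sigma_table.mean_centers)
        np.testing.assert_array_equal(back.sigma_table.sample_counts,
                                      tiny_tables.sigma_table.sample_counts)
        np.testing.assert_array_equal(back.threshold_table.log_thresholds,
                                      tiny_tables.threshold_table.log_thresholds)
        # saving the loaded copy reproduces the file byte for byte
        p2 = tmp_path / "tables2.tsv"
        back.save(p2)
        prov_free = lambda text: "\n".join(l for l in text.splitlines()
                                           if not l.startswith("#prov"))
        assert prov_free(p.read_text()) == prov_free(p2.read_text())

    def test_reject_foreign_file(self, tmp_path):
        p = tmp_path / "junk.tsv"
        p.write_text("not a table\n")
        with pytest.raises(calibration.CalibrationError):
            CalibrationTables.load(p)
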