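"""Boundary detection, rate fitting, QC filters, and speed-class grouping."""

import numpy as np
import pandas as pd
import pytest

import polwave as pw
from polwave.wave import QC_TOO_SHORT, QC_TOO_SLOW

from conftest import make_gene


def naive_changepoint(signal, bin_size, min_contrast=2.0):
    """Independent exhaustive-search oracle for the wave-front changepoint."""
    s = np.asarray(signal, dtype=float)
    n = len(s)
    if not np.any(s > 0):
        return None
    best_sse, best_c = None, None
    for c in range(1, n):
        left, right = s[:c], s[c:]
        ml, mr = left.mean(), right.mean()
        if ml <= mr:
            continue
        sse = ((left - ml) ** 2).sum() + ((right - mr) ** 2).sum()
        if best_sse is None or sse < best_sse - 1e-12 or abs(sse - best_sse) <= 1e-12:
            best_sse, best_c = sse, c
    if best_c is None:
        return None
    ml = s[:best_c].mean()
    mr = s[best_c:].mean()
    if ml <= min_contrast * mr:
        return None
    return float(best_c * bin_size)


class TestBinCoverage:
    def test_hand_binning(self):
        g = make_gene(start=1000, end=31000)
        frags = pd.DataFrame(
            {"chrom": "chr1", "start": [1150, 1180], "end": [1250, 1280], "gene_id": "g"}
        )
        tr = pw.bin_coverage(frags, g, 100, 30000, total_reads=10)
        assert tr.values[1] == pytest.approx(2 / 10)
        assert tr.values.sum() == pytest.approx(2 / 10)

    def test_empty_table_all_zero(self):
        g = make_gene()
        frags = pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
        tr = pw.bin_coverage(frags, g, 200, 20000, total_reads=100)
        assert (tr.values == 0).all()
        assert tr.n_bins == 100

    def test_minus_strand_mirrored_identical(self):
        # fragments at the same transcript offsets on both strands
        gp = make_gene("gp", start=1000, end=31000, strand="+")
        gm = make_gene("gm", start=1000, end=31000, strand="-")  # tss=31000
        offs = np.array([150, 180, 999, 5000])
        fp = pd.DataFrame(
            {"chrom": "chr1", "start": 1000 + offs, "end": 1000 + offs + 75, "gene_id": "gp"}
        )
        # - strand: 5' end is `end - 1`; transcript offset d -> end = tss - d
        fm = pd.DataFrame(
            {"chrom": "chr1", "start": 31000 - offs - 75, "end": 31000 - offs, "gene_id": "gm"}
        )
        tp = pw.bin_coverage(fp, gp, 200, 30000, 10)
        tm = pw.bin_coverage(fm, gm, 200, 30000, 10)
        np.testing.assert_allclose(tp.values, tm.values)


class TestWaveSignal:
    def _track(self, values, t=5.0, bin_size=200):
        return pw.WaveTrack("g", t, bin_size, np.asarray(values, float), 1)

    def test_identical_tracks_zero_signal(self):
        v = np.random.default_rng(0).random(50)
        sig = pw.wave_signal(self._track(v), self._track(v, t=0.0), smooth_window=1)
        assert (sig == 0).all()

    def test_step_preserved_unsmoothed(self):
        step = np.r_[np.ones(20), np.zeros(30)]
        sig = pw.wave_signal(
            self._track(step), self._track(np.zeros(50), t=0.0), smooth_window=1
        )
        np.testing.assert_allclose(sig, step)

    def test_exonic_spike_removed(self):
        # a mature-RNA spike present only in the 0-min control must not
        # survive subtraction + exon-mask imputation
        t0 = np.zeros(50)
        t0[10] = 5.0
        t5 = np.r_[np.ones(25), np.zeros(25)]
        mask = np.zeros(50, dtype=bool)
        mask[10] = True
        sig = pw.wave_signal(
            self._track(t5), self._track(t0, t=0.0), exon_mask=mask, smooth_window=1
        )
        assert sig[10] == pytest.approx(1.0)  # imputed from neighbors

    def test_geometry_mismatch_fatal(self):
        with pytest.raises(ValueError):
            pw.wave_signal(self._track(np.zeros(10)), self._track(np.zeros(20), t=0.0))


class TestDetectBoundary:
    def test_step_boundary(self):
        sig = np.r_[np.ones(75), np.zeros(25)]
        assert pw.detect_boundary(sig, 200) == 15000.0

    def test_flat_nonzero_none(self):
        assert pw.detect_boundary(np.ones(50), 200) is None

    def test_all_zero_none(self):
        assert pw.detect_boundary(np.zeros(50), 200) is None

    def test_too_few_bins_fatal(self):
        with pytest.raises(ValueError):
            pw.detect_boundary(np.ones(5), 200)

    def test_simulated_wave_boundary_within_one_bin(self):
        cfg = pw.SimulationConfig(n_genes=5, rate_model=3.0, background=0.0,
                                  depth=1e4, seed=17)
        genes = pw.simulate_annotation(cfg)
        truth = pw.make_ground_truth(genes, cfg)
        frags = pw.simulate_wave(genes, truth, 5.0, cfg)
        for g in genes:
            tr = pw.bin_coverage(frags, g, 200, 50000, len(frags), 5.0)
            tr0 = pw.WaveTrack(g.gene_id, 0.0, 200, np.zeros(tr.n_bins), len(frags))
            sig = pw.wave_signal(tr, tr0, smooth_window=1)
            b = pw.detect_boundary(sig, 200)
            assert b is not None and abs(b - 15000) <= 200

    def test_oracle_equivalence_random_signals(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(10, 301))
            kind = rng.integers(0, 3)
            if kind == 0:
                sig = rng.random(n)
            elif kind == 1:  # noisy step
                c = int(rng.integers(1, n))
                sig = np.r_[rng.normal(2, 0.3, c), rng.normal(0.1, 0.05, n - c)]
                sig = np.clip(sig, 0, None)
            else:  # sparse
                sig = np.where(rng.random(n) < 0.1, rng.random(n), 0.0)
            assert pw.detect_boundary(sig, 200) == naive_changepoint(sig, 200)


class TestEstimateRate:
    @pytest.mark.parametrize(
        "boundaries, expected",
        [
            ({5.0: 15000.0}, 3.0),
            ({5.0: 10000.0, 15.0: 30000.0}, 2.0),  # sum(t*b)/sum(t^2)
            ({5.0: 2400.0}, 0.48),
        ],
    )
    def test_through_origin_fit(self, boundaries, expected):
        assert pw.estimate_rate(boundaries) == pytest.approx(expected)

    def test_no_boundary_none(self):
        assert pw.estimate_rate({5.0: None}) is None


class TestRateFilters:
    def _genes(self, specs):
        gs = pw.GeneSet()
        for gid, length in specs:
            gs.add(make_gene(gid, start=0, end=length))
        return gs

    def test_short_gene_flagged(self):
        gs = self._genes([("g1", 15000)])
        est = pw.apply_rate_filters(gs, {"g1": 10.0}, {"g1": 3.0})
        assert QC_TOO_SHORT in est["g1"].qc

    def test_rate_exactly_half_excluded(self):
        gs = self._genes([("g1", 30000)])
        est = pw.apply_rate_filters(gs, {"g1": 10.0}, {"g1": 0.5})
        assert QC_TOO_SLOW in est["g1"].qc

    def test_constructed_cohort_retains_seven_of_ten(self):
        specs = [(f"g{i}", 30000) for i in range(7)]
        specs += [("s1", 15000), ("s2", 30000), ("s3", 30000)]
        gs = self._genes(specs)
        cov = {gid: 10.0 for gid, _ in specs}
        cov["s2"] = 0.1  # fails coverage
        rates = {gid: 3.0 for gid, _ in specs}
        rates["s3"] = 0.4  # fails rate floor
        est = pw.apply_rate_filters(gs, cov, rates)
        assert sum(e.passed for e in est.values()) == 7

    def test_missing_in_other_condition(self):
        gs = self._genes([("g1", 30000), ("g2", 30000)])
        est = pw.apply_rate_filters(
            gs, {"g1": 10.0, "g2": 10.0}, {"g1": 3.0, "g2": 3.0},
            other_condition={"g1": 2.5},
        )
        assert est["g1"].passed and not est["g2"].passed


class TestSpeedGroups:
    def test_hand_quantiles_one_to_nine(self):
        rates = {f"g{i}": float(i) for i in range(1, 10)}
        cls = pw.assign_speed_groups(rates)
        assert [cls[f"g{i}"] for i in range(1, 10)] == (
            ["slow"] * 3 + ["medium"] * 3 + ["fast"] * 3
        )

    def test_degenerate_equal_rates_fatal(self):
        with pytest.raises(ValueError):
            pw.assign_speed_groups({f"g{i}": 2.0 for i in range(10)})

    def test_partition_ordered_and_balanced(self):
        rng = np.random.default_rng(42)
        rates = {f"g{i}": float(v) for i, v in enumerate(rng.lognormal(1, 0.3, 600))}
        cls = pw.assign_speed_groups(rates)
        by = {"slow": [], "medium": [], "fast": []}
        for gid, c in cls.items():
            by[c].append(rates[gid])
        assert max(by["slow"]) <= min(by["medium"])
        assert max(by["medium"]) <= min(by["fast"])
        sizes = sorted(len(v) for v in by.values())
        assert sizes[-1] - sizes[0] <= 1


class TestMetagene:
    def test_window_bin_count(self, small_cohort):
        cfg, genes, truth = small_cohort
        frags = pw.simulate_wave(genes, truth, 5.0, cfg)
        prof = pw.metagene_profile(frags, genes, total_reads=len(frags))
        assert len(prof) == 2600

    def test_opposite_strand_mirrored_identical(self):
        gp = make_gene("gp", start=10000, end=40000, strand="+")
        gm = make_gene("gm", chrom="chr2", start=10000, end=40000, strand="-")
        offs = np.arange(0, 20000, 97)
        fp = pd.DataFrame(
            {"chrom": "chr1", "start": 10000 + offs, "end": 10000 + offs + 75,
             "gene_id": "gp"}
        )
        fm = pd.DataFrame(
            {"chrom": "chr2", "start": 40000 - offs - 75, "end": 40000 - offs,
             "gene_id": "gm"}
        )
        gs_p, gs_m = pw.GeneSet(), pw.GeneSet()
        gs_p.add(gp)
        gs_m.add(gm)
        prof_p = pw.metagene_profile(fp, gs_p, total_reads=len(fp))
        prof_m = pw.metagene_profile(fm, gs_m, total_reads=len(fm))
        np.testing.assert_allclose(
            prof_p["mean_coverage"], prof_m["mean_coverage"], equal_nan=True
        )


class TestParameterRecovery:
    def test_noisy_median_error_below_quarter_kb(self):
        cfg = pw.SimulationConfig(
            n_genes=200, rate_model=("uniform", 1.0, 5.0), depth=500.0,
            background=50.0, gene_length_range=(30000, 60000), seed=31,
        )
        genes = pw.simulate_annotation(cfg)
        truth = pw.make_ground_truth(genes, cfg)
        df = pw.estimate_rates_pipeline(
            genes,
            {0.0: pw.simulate_wave(genes, truth, 0.0, cfg),
             5.0: pw.simulate_wave(genes, truth, 5.0, cfg)},
        )
        est = df.set_index("gene_id")["rate_kb_min"]
        errs = [
            abs(est[g] - truth.rates[g])
            for g in est.index
            if est[g] is not None and not np.isnan(est[g])
        ]
        assert np.median(errs) <= 0.25

    def test_monotone_in_true_rate(self):
        medians = []
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            cfg = pw.SimulationConfig(
                n_genes=50, rate_model=v, depth=500.0, background=50.0, seed=40 + i
            )
            genes = pw.simulate_annotation(cfg)
            truth = pw.make_ground_truth(genes, cfg)
            df = pw.estimate_rates_pipeline(
                genes,
                {0.0: pw.simulate_wave(genes, truth, 0.0, cfg),
                 5.0: pw.simulate_wave(genes, truth, 5.0, cfg)},
            )
            medians.append(df["rate_kb_min"].dropna().median())
        assert medians == sorted(medians)
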