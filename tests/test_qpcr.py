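import math

import numpy as np
import pytest

import pfasrpf as p
from pfasrpf.errors import (
    InsufficientDataError,
    InvalidCurveError,
    NormalizationError,
    PairingError,
    ValidationError,
)

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # -3.3219 cycles per log10 at 100% efficiency


def perfect_series(intercept=25.0, n=5):
    """2-fold dilution series with Cq rising exactly 1 cycle per step."""
    return [(0.5 ** k, intercept + k) for k in range(n)]


class TestStandardCurve:
    def test_perfect_two_fold_series(self):
        curve = p.fit_standard_curve(perfect_series(), "GAPDH")
        assert curve.slope == pytest.approx(PERFECT_SLOPE, rel=1e-12)
        assert curve.efficiency == pytest.approx(1.0, rel=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_cq_rejected(self):
        with pytest.raises(InvalidCurveError):
            p.fit_standard_curve([(1.0, 25.0), (0.5, 25.0), (0.25, 25.0)], "X")

    def test_shift_equivariance(self):
        base = p.fit_standard_curve(perfect_series(), "X")
        shifted = p.fit_standard_curve([(d, cq + 2.0) for d, cq in perfect_series()], "X")
        assert shifted.slope == pytest.approx(base.slope, rel=1e-12)
        assert shifted.efficiency == pytest.approx(base.efficiency, rel=1e-12)
        assert shifted.intercept == pytest.approx(base.intercept + 2.0, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            p.fit_standard_curve([(1.0, 25.0), (0.5, 26.0)], "X")


def curves_100pct(intercept=25.0):
    c = p.fit_standard_curve(perfect_series(intercept), "any")
    return {
        "RAG1": p.StandardCurve("RAG1", c.slope, c.intercept, c.efficiency, 1.0),
        "GAPDH": p.StandardCurve("GAPDH", c.slope, c.intercept, c.efficiency, 1.0),
    }


def records_for(samples):
    """samples: {label: (cq_target, cq_ref)}"""
    out = []
    for sample, (cq_t, cq_r) in samples.items():
        out.append(p.QpcrRecord(sample, "RAG1", cq_t))
        out.append(p.QpcrRecord(sample, "GAPDH", cq_r))
    return out


class TestQuantify:
    def test_controls_self_normalize_to_one(self):
        recs = records_for({"SC:r1": (25.0, 24.0), "SC:r2": (25.5, 24.5), "SC:r3": (24.5, 23.5)})
        folds = p.quantify(recs, curves_100pct(), "GAPDH", "SC")
        assert float(np.mean([f.fold_change for f in folds])) == pytest.approx(1.0, rel=1e-12)

    def test_one_cycle_shift_halves_fold_change(self):
        recs = records_for({"SC:r1": (25.0, 24.0), "T:r1": (26.0, 24.0)})
        folds = {f.sample: f for f in p.quantify(recs, curves_100pct(), "GAPDH", "SC")}
        assert folds["T:r1"].fold_change == pytest.approx(0.5, rel=1e-10)

    def test_common_shift_of_target_and_reference_cancels(self):
        recs = records_for({"SC:r1": (25.0, 24.0), "T:r1": (27.3, 26.3)})
        folds = {f.sample: f for f in p.quantify(recs, curves_100pct(), "GAPDH", "SC")}
        assert folds["T:r1"].normalized_quantity == pytest.approx(
            folds["SC:r1"].normalized_quantity, rel=1e-10
        )

    def test_fold_change_invariant_to_per_gene_rescaling(self):
        # shifting one gene's curve intercept rescales its quantities but
        # cancels in the control-normalized fold change
        recs = records_for({"SC:r1": (25.0, 24.0), "T:r1": (26.5, 24.2)})
        f1 = {f.sample: f.fold_change for f in p.quantify(recs, curves_100pct(25.0), "GAPDH", "SC")}
        shifted = {
            "RAG1": curves_100pct(28.0)["RAG1"],
            "GAPDH": curves_100pct(25.0)["GAPDH"],
        }
        f2 = {f.sample: f.fold_change for f in p.quantify(recs, shifted, "GAPDH", "SC")}
        for s in f1:
            assert f1[s] == pytest.approx(f2[s], rel=1e-10)

    def test_technical_replicates_averaged_on_cq_scale(self):
        recs = records_for({"SC:r1": (25.0, 24.0)})
        recs.append(p.QpcrRecord("T:r1", "RAG1", 25.6))
        recs.append(p.QpcrRecord("T:r1", "RAG1", 26.4))  # mean Cq 26.0
        recs.append(p.QpcrRecord("T:r1", "GAPDH", 24.0))
        folds = {f.sample: f for f in p.quantify(recs, curves_100pct(), "GAPDH", "SC")}
        assert folds["T:r1"].fold_change == pytest.approx(0.5, rel=1e-10)

    def test_missing_reference_gene(self):
        recs = [p.QpcrRecord("SC:r1", "RAG1", 25.0)]
        with pytest.raises(PairingError):
            p.quantify(recs, curves_100pct(), "GAPDH", "SC")

    def test_empty_control_group(self):
        recs = records_for({"T:r1": (25.0, 24.0)})
        with pytest.raises(NormalizationError):
            p.quantify(recs, curves_100pct(), "GAPDH", "SC")


class TestViability:
    def test_background_subtraction_and_percent(self):
        plate = [("SC:1", 0.8, 0.1), ("SC:2", 0.8, 0.1), ("T:1", 0.8, 0.1), ("T:2", 0.45, 0.1)]
        out = {v.sample: v.percent_viability for v in p.viability_percent(plate, "SC")}
        assert out["T:1"] == pytest.approx(100.0, rel=1e-12)
        assert out["T:2"] == pytest.approx(50.0, rel=1e-12)
        assert out["SC:1"] == pytest.approx(100.0, rel=1e-12)

    def test_zero_signal_gives_zero_percent(self):
        out = p.viability_percent([("SC:1", 0.7, 0.0), ("T:1", 0.2, 0.2)], "SC")
        assert out[1].percent_viability == 0.0

    def test_nonpositive_control_signal(self):
        with pytest.raises(NormalizationError):
            p.viability_percent([("SC:1", 0.1, 0.2), ("T:1", 0.5, 0.1)], "SC")


class TestSummarize:
    def _folds_and_design(self):
        folds, design = [], {}
        concs = [0.0, 2.0, 8.0, 32.0]
        for conc in concs:
            for rep, val in enumerate((1.0, 2.0, 3.0), start=1):
                sample = f"A:c{conc:g}:r{rep}"
                folds.append(p.FoldChangeRecord(sample, "RAG1", val, val * (0.9 ** conc + 0.1)))
                design[sample] = ("PFOA", "1", conc)
        return folds, design

    def test_group_statistics_sample_sd(self):
        folds, design = self._folds_and_design()
        # make one group's fold changes exactly {1, 2, 3}
        folds = [
            p.FoldChangeRecord(f.sample, f.gene, f.normalized_quantity,
                               float(f.sample.split(":r")[1]))
            for f in folds
        ]
        table = p.summarize_to_table(folds, design)
        for row in table.rows:
            assert row.mean == pytest.approx(2.0)
            # brute-force two-pass sample SD with the n-1 denominator
            vals = [1.0, 2.0, 3.0]
            m = sum(vals) / 3
            sd = math.sqrt(sum((v - m) ** 2 for v in vals) / 2)
            assert row.sd == pytest.approx(sd, rel=1e-12)
            assert row.n == 3

    def test_identical_values_give_zero_sd(self):
        folds, design = self._folds_and_design()
        folds = [p.FoldChangeRecord(f.sample, f.gene, 0.8, 0.8) for f in folds]
        table = p.summarize_to_table(folds, design)
        assert all(r.sd == pytest.approx(0.0, abs=1e-12) and r.mean == pytest.approx(0.8)
                   for r in table.rows)

    def test_unmapped_sample_rejected(self):
        folds, design = self._folds_and_design()
        del design[folds[0].sample]
        with pytest.raises(ValidationError):
            p.summarize_to_table(folds, design)
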