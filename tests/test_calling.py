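"""Calling decisions, quantitation, whole-region scan, temporal series."""

import math

import numpy as np
import pytest

import plasmut as pm
from plasmut.amplicon import DELETION_LABEL, PileupCounts, TARGET_SUBSTITUTIONS
from plasmut.calling import (
    call_exon19_deletion,
    call_sample,
    call_substitution,
    quantify,
    scan_region,
    temporal_report,
)
from plasmut.error_model import ErrorModel, MomentSummary, fit_poisson


@pytest.fixture(scope="module")
def floor_model():
    return fit_poisson(MomentSummary(0.2, 0.2), floor=True)  # lambda=1, T=7


def _pileup_with(references, amp, pos, alt, count, depth):
    ref = references[amp]
    pile = PileupCounts.empty(ref)
    pile.n_reads = depth
    for p in ref.window_positions:
        i = pile._idx(p)
        pile.base_counts[ref.base_at(p)][i] = depth
    i = pile._idx(pos)
    pile.base_counts[ref.base_at(pos)][i] -= count
    pile.base_counts[alt][i] += count
    return pile


class TestCallSubstitution:
    @pytest.mark.parametrize(
        "count,depth,called",
        [
            (7, 100_000, True),   # events == T: judged a mutation
            (6, 100_000, False),
            (7, 200_000, False),  # 3.5 per 100k after normalization
        ],
    )
    def test_threshold_boundary(self, references, floor_model, count, depth, called):
        st = TARGET_SUBSTITUTIONS["L858R"]
        pile = _pileup_with(references, "exon21", st.position, st.alt_base, count, depth)
        call = call_substitution(pile, floor_model, st, locus="L858R")
        assert call.called is called
        assert call.events_per_100k == pytest.approx(count * 100_000 / depth)
        assert call.fraction_percent == pytest.approx(100 * count / depth)

    def test_decision_consistency_across_depths(self, references, floor_model, rng):
        """called <=> normalized events >= T, for arbitrary count/depth."""
        st = TARGET_SUBSTITUTIONS["L858R"]
        for _ in range(25):
            depth = int(rng.integers(44_400, 373_000))
            count = int(rng.integers(0, 40))
            pile = _pileup_with(references, "exon21", st.position, st.alt_base, count, depth)
            call = call_substitution(pile, floor_model, st)
            assert call.called == (count * 100_000 / depth >= floor_model.threshold)

    def test_tail_probability_reported(self, references, floor_model):
        st = TARGET_SUBSTITUTIONS["L858R"]
        pile = _pileup_with(references, "exon21", st.position, st.alt_base, 7, 100_000)
        call = call_substitution(pile, floor_model, st)
        # realized size at T=7 under lambda=1
        assert call.tail_prob == pytest.approx(8.324e-5, rel=1e-3)

    def test_missing_model_is_an_error(self, references):
        st = TARGET_SUBSTITUTIONS["L858R"]
        pile = _pileup_with(references, "exon21", st.position, st.alt_base, 1, 1000)
        with pytest.raises(ValueError):
            call_substitution(pile, None, st)


class TestCallDeletion:
    def test_called_with_fraction(self, floor_model):
        call = call_exon19_deletion({"del_2235_2249": 700}, 100_000, floor_model)
        assert call.called and call.fraction_percent == pytest.approx(0.7)
        assert call.chosen_template == "del_2235_2249"

    def test_below_threshold_not_called(self, floor_model):
        assert not call_exon19_deletion({"del_2235_2249": 6}, 100_000, floor_model).called

    def test_zero_reads(self, floor_model):
        call = call_exon19_deletion({"del_2235_2249": 0}, 100_000, floor_model)
        assert not call.called and call.fraction_percent == 0.0
        assert call.chosen_template is None

    def test_tie_breaks_to_smallest_template_id(self, floor_model):
        call = call_exon19_deletion(
            {"del_2239_2247": 10, "del_2233_2247": 10}, 100_000, floor_model
        )
        assert call.chosen_template == "del_2233_2247"


class TestQuantify:
    def test_flag_below_limit(self, references, floor_model):
        st = TARGET_SUBSTITUTIONS["L858R"]
        pile = _pileup_with(references, "exon21", st.position, st.alt_base, 250, 100_000)
        call = call_substitution(pile, floor_model, st)  # 0.25%
        assert call.called and call.below_quantitation

    def test_no_flag_above_limit(self, references, floor_model):
        st = TARGET_SUBSTITUTIONS["L858R"]
        pile = _pileup_with(references, "exon21", st.position, st.alt_base, 500, 100_000)
        assert not call_substitution(pile, floor_model, st).below_quantitation

    def test_not_called_never_flagged(self, references, floor_model):
        st = TARGET_SUBSTITUTIONS["L858R"]
        pile = _pileup_with(references, "exon21", st.position, st.alt_base, 2, 100_000)
        call = call_substitution(pile, floor_model, st)
        assert not call.called and not call.below_quantitation

    def test_custom_limit(self, references, floor_model):
        st = TARGET_SUBSTITUTIONS["L858R"]
        pile = _pileup_with(references, "exon21", st.position, st.alt_base, 500, 100_000)
        call = quantify(call_substitution(pile, floor_model, st), limit_percent=1.0)
        assert call.below_quantitation


class TestScanRegion:
    def test_error_free_sample_scans_clean(self, references, fitted_models):
        result = pm.simulate_assay(pm.AssaySpec(depth=100_000, seed=0))  # no error process
        calls = scan_region(result.pileups, fitted_models)
        assert calls == []

    def test_planted_one_percent_substitution_called(self, references, fitted_models, fitted_detector):
        result = pm.simulate_assay(pm.AssaySpec(depth=100_000, seed=0))
        pile = result.pileups["exon19"]
        pos = 2240
        ref_base = references["exon19"].base_at(pos)
        alt = next(b for b in "ACGT" if b != ref_base)
        i = pile._idx(pos)
        pile.base_counts[alt][i] += 1000
        pile.base_counts[ref_base][i] -= 1000
        calls = scan_region(result.pileups, fitted_models)
        assert [c.sub_type.label for c in calls] == [f"exon19:{pos}:{ref_base}>{alt}"]

    def test_targets_and_snp_excluded(self, fitted_models):
        result = pm.simulate_assay(pm.AssaySpec(depth=100_000, seed=0))
        calls = scan_region(result.pileups, fitted_models, include_not_called=True)
        labels = {c.sub_type.label for c in calls}
        assert len(labels) == 503  # 507 types minus 3 targets minus the SNP
        for st in TARGET_SUBSTITUTIONS.values():
            assert st.label not in labels

    def test_null_scan_false_positive_rate_matches_models(self, fitted_models, rng):
        """Simulating each scanned type at its own null, the number of called
        types matches the summed realized sizes within Monte-Carlo error."""
        result = pm.simulate_assay(pm.AssaySpec(depth=100_000, seed=1))
        scanned = [
            c.sub_type.label
            for c in scan_region(result.pileups, fitted_models, include_not_called=True)
        ]
        n_rep = 400
        expected = sum(fitted_models[lab].realized_size for lab in scanned)
        total_called = 0
        for lab in scanned:
            m = fitted_models[lab]
            if m.kind == "negative_binomial":
                draws = rng.negative_binomial(m.r, m.p, size=n_rep)
            else:
                draws = rng.poisson(m.lam, size=n_rep)
            total_called += int((draws >= m.threshold).sum())
        rate = total_called / n_rep
        se = math.sqrt(max(expected, 1e-12) / n_rep)  # Poisson-count error
        assert abs(rate - expected) <= 4 * se + 0.05


class TestSampleReportAndTemporal:
    def _report(self, fitted_models, fraction, seed):
        result = pm.simulate_assay(
            pm.AssaySpec(depth=100_000, fraction=fraction, mutation="L858R", seed=seed)
        )
        return call_sample(
            f"t{seed}", result.pileups, result.template_counts,
            result.exon19_total, fitted_models,
            scan=False,
        )

    def test_every_target_locus_present_once(self, fitted_models):
        report = self._report(fitted_models, 0.01, 1)
        assert sorted(report.calls) == ["L858R", "L861Q", "T790M", "exon19del"]

    def test_temporal_series_scales_to_per_10k(self, fitted_models):
        reports = [self._report(fitted_models, f, s) for s, f in enumerate([0.5, 0.003, 0.05])]
        series = temporal_report(reports, patient_id="p1")
        assert series.timepoints == [r.sample_id for r in reports]
        for entry, report in zip(series.entries, reports):
            for name, per10k in entry.items():
                assert per10k == pytest.approx(report.calls[name].events_per_100k / 10)

    def test_uncalled_timepoint_keeps_empty_entry(self, fitted_models):
        reports = [self._report(fitted_models, 0.01, 3), self._report(fitted_models, 0.0, 4)]
        series = temporal_report(reports, patient_id="p2")
        assert "L858R" in series.entries[0]
        assert series.entries[1] == {}

    def test_double_mutation_reported_independently(self, references, fitted_models):
        result = pm.simulate_assay(
            pm.AssaySpec(depth=100_000, fraction=0.02, mutation="L858R", seed=5)
        )
        report = call_sample(
            "dbl", result.pileups, {"del_2235_2249": 1500}, 100_000,
            fitted_models, scan=False,
        )
        assert report.calls["L858R"].called and report.calls["exon19del"].called

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            temporal_report([], patient_id="p")


class TestOperatingCharacteristics:
    def test_per_test_size_matches_realized_size(self, fitted_models, rng):
        """Null simulation from representative fitted models reproduces the
        realized per-test size within Monte-Carlo error."""
        labels = [
            TARGET_SUBSTITUTIONS["L858R"].label,   # Poisson floor
            TARGET_SUBSTITUTIONS["L861Q"].label,   # Poisson
            TARGET_SUBSTITUTIONS["T790M"].label,   # negative binomial
        ]
        n = 1_000_000
        depth = 100_000
        for label in labels:
            m = fitted_models[label]
            if m.kind == "negative_binomial":
                counts = rng.negative_binomial(m.r, m.p, size=n)
            else:
                counts = rng.poisson(m.lam, size=n)
            called = (counts * 100_000.0 / depth) >= m.threshold
            p = m.realized_size
            se = math.sqrt(p * (1 - p) / n)
            assert abs(called.mean() - p) <= 3 * se

    def test_spike_in_power_at_one_in_ten_thousand(self, rng):
        """At depth 100,000 a 0.01% mutant fraction over a lambda=1 error
        floor is called in well over 85% of assays (one mutant allele in
        10,000 normal alleles is detectable)."""
        model = fit_poisson(MomentSummary(0.2, 0.2), floor=True)
        n = 10_000
        events = rng.binomial(100_000, 1e-4, size=n) + rng.poisson(1.0, size=n)
        power = float((events >= model.threshold).mean())
        assert power > 0.85

    def test_fraction_estimates_unbiased_above_quantitation_limit(self, rng):
        """Mean estimated fraction within 2% relative error of truth for
        fractions at or above 0.3%."""
        for frac in (0.005, 0.03):
            rows = pm.simulate_dilution_series(
                [100 * frac], replicates=800,
                spec=pm.AssaySpec(mutation="L858R"), seed=int(1000 * frac),
            )
            mean_est = rows["estimated_percent"].mean() / 100.0
            assert mean_est == pytest.approx(frac, rel=0.02)
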