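"""Fixation-index estimators, variant selection and ancestry validation.

The Weir-Cockerham estimator is checked against a second, independently
written transcription of the 1984 variance components that follows the
per-allele (multiallelic) formulation — summing the a, b, c components over
both alleles — rather than the biallelic closed form the package uses.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uvbclines.data_io import DataValidationError, FrequencyMatrix, SampleSet, VariantAnnotation
from uvbclines.popgen import (
    BELOW_FLOOR,
    BELOW_RANK,
    FUNCTION_CLASS,
    SelectionCriteria,
    allele_frequency,
    select_variants,
    validate_ancestry_groups,
    weir_cockerham_fst,
    wright_fst,
)
from uvbclines.reference_data import reference_variant_panel


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "counts, expected",
        [((0, 0, 5), 1.0), ((5, 0, 0), 0.0), ((2, 4, 2), 0.5), ((1, 2, 0), 2 / 6)],
    )
    def test_hand_counts(self, counts, expected):
        assert allele_frequency(*counts) == pytest.approx(expected)

    def test_no_called_samples_is_missing(self):
        assert np.isnan(allele_frequency(0, 0, 0))


class TestWrightFst:
    def test_two_population_hand_value(self):
        # var = 0.09, pbar(1-pbar) = 0.25
        assert wright_fst([0.2, 0.8]) == pytest.approx(0.36)

    def test_equal_frequencies_give_zero(self):
        assert wright_fst([0.3, 0.3, 0.3]) == 0.0

    def test_complete_differentiation(self):
        assert wright_fst([0.0, 1.0]) == pytest.approx(1.0)

    def test_fewer_than_two_populations_rejected(self):
        with pytest.raises(DataValidationError):
            wright_fst([0.5])

    def test_two_population_closed_form_on_grid(self):
        # equal weights: FST = ((p-q)/2)^2 / (pbar (1-pbar))
        for p in np.linspace(0.05, 0.95, 10):
            for q in np.linspace(0.05, 0.95, 10):
                pbar = (p + q) / 2
                expected = ((p - q) / 2) ** 2 / (pbar * (1 - pbar))
                assert wright_fst([p, q]) == pytest.approx(min(1.0, expected))

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=8),
        st.lists(st.integers(1, 500), min_size=8, max_size=8),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_always_within_unit_interval(self, freqs, weights):
        fst = wright_fst(freqs, weights[: len(freqs)])
        assert 0.0 <= fst <= 1.0


def _wc84_per_allele(counts):
    """Independent WC84 oracle: per-allele variance-component sums."""
    counts = np.asarray(counts, dtype=float)
    n_i = counts.sum(axis=1)
    r = len(n_i)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    a_sum = d_sum = 0.0
    for allele in ("ref", "alt"):
        if allele == "ref":
            p_i = (2 * counts[:, 0] + counts[:, 1]) / (2 * n_i)
        else:
            p_i = (2 * counts[:, 2] + counts[:, 1]) / (2 * n_i)
        h_i = counts[:, 1] / n_i  # hets carry one copy of each allele
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        d_sum += a + b + c
    return a_sum / d_sum if d_sum else float("nan")


class TestWeirCockerhamFst:
    def test_identical_populations_report_zero(self):
        assert weir_cockerham_fst([(30, 40, 30), (30, 40, 30)]) == 0.0

    def test_fixed_difference_is_near_one(self):
        est = weir_cockerham_fst([(50, 0, 0), (0, 0, 50)])
        assert est == pytest.approx(1.0, abs=0.01)

    def test_matches_per_allele_oracle_on_random_instances(self, rng):
        """Biallelic closed form == per-allele component sums, 100 instances."""
        checked = 0
        while checked < 100:
            r = int(rng.integers(2, 6))
            counts = rng.integers(0, 30, size=(r, 3))
            counts[counts.sum(axis=1) == 0, 0] = 5  # every pop needs a called sample
            expected = _wc84_per_allele(counts)
            if np.isnan(expected):
                continue
            got = weir_cockerham_fst([tuple(c) for c in counts], truncate=False)
            assert got == pytest.approx(expected, abs=1e-6)
            checked += 1

    def test_single_population_rejected(self):
        with pytest.raises(DataValidationError):
            weir_cockerham_fst([(10, 5, 5)])


def _ann(rsid, fst, fc="Intron"):
    return VariantAnnotation(rsid=rsid, locus="L", variant_allele="A", fst=fst,
                             function_class=fc)


class TestSelectVariants:
    def test_reference_panel_retained_by_floor(self):
        """All 46 panel fixation indices sit at or above the 0.13 floor."""
        included, excluded = select_variants(
            reference_variant_panel(), SelectionCriteria(top_fraction=1.0)
        )
        assert len(included) == 46 and not excluded

    def test_below_floor_reason(self):
        inc, exc = select_variants(
            [_ann("rs1", 0.5), _ann("rs2", 0.4), _ann("rs3", 0.1)],
            SelectionCriteria(top_fraction=1.0),
        )
        assert [a.rsid for a in inc] == ["rs1", "rs2"]
        assert exc == [(_ann("rs3", 0.1), BELOW_FLOOR)]

    def test_rank_cutoff_with_ties_broken_lexicographically(self):
        anns = [_ann(f"rs{i:02d}", 0.2) for i in range(10)]
        inc, exc = select_variants(anns, SelectionCriteria(top_fraction=0.3))
        assert [a.rsid for a in inc] == ["rs00", "rs01", "rs02"]
        assert all(reason == BELOW_RANK for _, reason in exc)

    def test_function_class_exclusion(self):
        inc, exc = select_variants(
            [_ann("rs1", 0.5), _ann("rs2", 0.4, fc="Unknown")],
            SelectionCriteria(top_fraction=1.0),
        )
        assert [a.rsid for a in inc] == ["rs1"]
        assert exc == [(_ann("rs2", 0.4, fc="Unknown"), FUNCTION_CLASS)]

    def test_output_invariant_to_input_order(self, rng):
        anns = [_ann(f"rs{i}", round(float(f), 3)) for i, f in
                enumerate(rng.uniform(0, 1, 20))]
        shuffled = list(anns)
        rng.shuffle(shuffled)
        a = select_variants(anns, SelectionCriteria())[0]
        b = select_variants(shuffled, SelectionCriteria())[0]
        assert [x.rsid for x in a] == [x.rsid for x in b]

    def test_empty_input_rejected(self):
        with pytest.raises(DataValidationError):
            select_variants([])


def _mini_sets():
    mk = lambda i, g, n: SampleSet(id=i, name=i, group=g, n=n, lat_min=0.0,
                                   lat_max=0.0, lon=0.0, source="SYNTHETIC")
    return [mk("E1", "EUR", 50), mk("E2", "EUR", 50),
            mk("S1", "EAS", 50), mk("S2", "EAS", 50),
            mk("A1", "AFR", 50), mk("A2", "AFR", 50)]


def _mini_freq(eur, eas, afr, rsid):
    idx = ["E1", "E2", "S1", "S2", "A1", "A2"]
    return pd.DataFrame({rsid: [eur, eur, eas, eas, afr, afr]}, index=idx)


class TestAncestryValidation:
    def _freq(self, rs1426654=(0.99, 0.03, 0.08), rs16891982=(0.91, 0.01, 0.00),
              rs1800414=(0.00, 0.59, 0.00)):
        frames = []
        for rsid, (e, s, a) in (
            ("rs1426654", rs1426654), ("rs16891982", rs16891982), ("rs1800414", rs1800414)
        ):
            frames.append(_mini_freq(e, s, a, rsid))
        return FrequencyMatrix(pd.concat(frames, axis=1))

    def test_published_group_means_pass_all_rules(self):
        report = validate_ancestry_groups(self._freq(), _mini_sets())
        assert report.overall_pass and not report.flagged_sets

    def test_east_asian_range_rule(self):
        report = validate_ancestry_groups(self._freq(), _mini_sets())
        eas = [o for o in report.outcomes if o.rsid == "rs1800414" and o.group == "EAS"]
        assert eas[0].passed and eas[0].observed_mean == pytest.approx(0.59)

    def test_threshold_breach_reports_rule_and_value(self):
        report = validate_ancestry_groups(self._freq(rs1426654=(0.50, 0.03, 0.08)),
                                          _mini_sets())
        fails = report.failures()
        assert len(fails) == 1
        assert fails[0].rsid == "rs1426654" and fails[0].group == "EUR"
        assert fails[0].observed_mean == pytest.approx(0.50)
        assert not report.overall_pass

    def test_sets_missing_marker_data_flagged(self):
        freq = self._freq()
        freq.freq.loc["E2", "rs1800414"] = np.nan
        report = validate_ancestry_groups(FrequencyMatrix(freq.freq), _mini_sets())
        assert report.flagged_sets == ["E2"]

    def test_missing_marker_column_rejected(self):
        freq = FrequencyMatrix(_mini_freq(0.9, 0.1, 0.1, "rs1426654"))
        with pytest.raises(DataValidationError, match="rs16891982"):
            validate_ancestry_groups(freq, _mini_sets())

    def test_validate_ancestry_groups_default(self):
        report = validate_ancestry_groups(self._freq(), _mini_sets())
        assert {o.rsid for o in report.outcomes} == {
            "rs1426654", "rs16891982", "rs1800414"
        }
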