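"""Gap-PCR band prediction, carrier classification, confirmation, frequency."""

import numpy as np
import pytest

from haplotile.cohort import SV_HGVS_C, build_sample, make_cohort
from haplotile.screen import (
    BandPattern,
    classify_pattern,
    confirm_candidates,
    estimate_frequency,
    run_gap_pcr,
    screen_cohort,
)

TRUTH_BP = (24_999, 44_971)


@pytest.mark.parametrize(
    "control, deletion, expected",
    [
        (True, True, "carrier"),
        (True, False, "wildtype"),
        (False, True, "homozygous_deletion"),
        (False, False, "invalid"),
    ],
)
def test_classification_is_pure_function_of_bands(control, deletion, expected):
    p = BandPattern("x", control, 333 if control else None,
                    deletion, 832 if deletion else None)
    assert classify_pattern(p) == expected


def test_band_patterns_by_genotype(locus):
    wt = build_sample(locus, "WT", "donor", (), ())
    het = build_sample(locus, "HET", "donor", (SV_HGVS_C,), ())
    hom = build_sample(locus, "HOM", "donor", (SV_HGVS_C,), (SV_HGVS_C,))
    p_wt = run_gap_pcr(wt, locus)
    assert (p_wt.control_band, p_wt.deletion_band) == (True, False)
    assert p_wt.control_size == 333
    p_het = run_gap_pcr(het, locus)
    assert (p_het.control_band, p_het.deletion_band) == (True, True)
    assert p_het.deletion_size == 832
    # control target (intron 7) lies outside the deletion: still present
    p_hom = run_gap_pcr(hom, locus)
    assert (p_hom.control_band, p_hom.deletion_band) == (True, True)


def test_screen_600_donors_full_accuracy(locus):
    cohort = make_cohort(locus, n=600, n_carriers=3, seed=5)
    result = screen_cohort(cohort, locus, rng=7)
    assert result.n_screened == 600
    assert set(result.carriers) == cohort.carrier_ids  # sensitivity 100%
    assert all(
        result.classes[d.sample_id] == "wildtype"
        for d in cohort.donors
        if d.sample_id not in cohort.carrier_ids
    )  # specificity 100%
    assert result.frequency == pytest.approx(3 / 600)


def test_confirmation_demotes_engineered_decoy(locus):
    """A different deletion that still yields a short gap product is flagged
    by the screen but demoted at sequencing confirmation."""
    ref = locus.reference
    decoy_var = f"g.25050_44920delins{locus.sv_truth.alt}"
    decoy = build_sample(locus, "DECOY", "donor", (decoy_var,), ())
    true_carrier = build_sample(locus, "CARRIER", "donor", (SV_HGVS_C,), ())
    assert classify_pattern(run_gap_pcr(decoy, locus)) == "carrier"
    records = confirm_candidates([true_carrier, decoy], locus, TRUTH_BP, rng=3)
    by_id = {r.sample_id: r for r in records}
    assert by_id["CARRIER"].confirmed
    assert not by_id["DECOY"].confirmed
    assert by_id["DECOY"].reason.startswith("breakpoint_mismatch")
    assert confirm_candidates([], locus, TRUTH_BP) == []


def test_wilson_interval_against_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for carriers, n in [(3, 600), (0, 600), (10, 10), (1, 50)]:
        p, lo, hi = estimate_frequency(carriers, n)
        sm_lo, sm_hi = proportion_confint(carriers, n, alpha=0.05, method="wilson")
        assert p == carriers / n
        assert lo == pytest.approx(sm_lo, abs=1e-12)
        assert hi == pytest.approx(sm_hi, abs=1e-12)
    assert estimate_frequency(0, 600)[1] == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        estimate_frequency(0, 0)


def test_wilson_interval_printed_values():
    p, lo, hi = estimate_frequency(3, 600)
    assert round(p * 100, 2) == 0.50
    assert round(lo * 100, 2) == 0.17
    assert round(hi * 100, 2) == 1.46
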