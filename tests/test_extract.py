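"""EIC construction, peak integration and isobar resolution."""

import math

import numpy as np
import pandas as pd
import pytest

from ccmscan.extract import (EIC, MatchConfig, build_eic, integrate_peak,
                             resolve_isobars, extract_peaks)
from ccmscan.ms_io import FeatureTable

CFG = MatchConfig()


def _table(rows, polarity="+"):
    df = pd.DataFrame(rows, columns=["sample_id", "role", "rt_min", "mz", "intensity"])
    return FeatureTable(polarity, df)


def _gaussian_rows(theo, rt0, height=1000.0, sigma=0.05, step=0.005,
                   ppm_offset=0.0, sid="s1", span=4.0):
    rows = []
    for rt in np.arange(rt0 - span * sigma, rt0 + span * sigma + step / 2, step):
        inten = height * math.exp(-0.5 * ((rt - rt0) / sigma) ** 2)
        rows.append((sid, "study", rt, theo * (1 + ppm_offset * 1e-6), inten))
    return rows


def test_build_eic_accepts_small_ppm_offset(panel):
    gln = panel["Glutamine"]
    t = _table(_gaussian_rows(gln.mz_pos, 8.93, ppm_offset=0.4))
    eic = build_eic(t, gln, CFG)
    assert len(eic) == len(t.data)
    assert eic.mean_ppm == pytest.approx(0.4, abs=0.01)


def test_build_eic_rejects_large_ppm_offset(panel):
    gln = panel["Glutamine"]
    t = _table(_gaussian_rows(gln.mz_pos, 8.93, ppm_offset=10.7))
    assert len(build_eic(t, gln, CFG)) == 0


def test_build_eic_rt_window(panel):
    gln = panel["Glutamine"]
    t = _table([("s1", "study", 3.0, gln.mz_pos, 500.0)])
    assert len(build_eic(t, gln, CFG)) == 0


def test_build_eic_collapses_same_scan(panel):
    gln = panel["Glutamine"]
    t = _table(
        [
            ("s1", "study", 8.93, gln.mz_pos * (1 + 1e-6), 100.0),
            ("s1", "study", 8.93, gln.mz_pos * (1 - 1e-6), 150.0),
        ]
    )
    eic = build_eic(t, gln, CFG)
    assert len(eic) == 1
    assert eic.intensity[0] == 250.0


def test_matching_equivalence_brute_force(panel):
    """Vectorized EIC membership equals the literal ppm/RT predicate scan."""
    rng = np.random.default_rng(42)
    entries = [e for e in panel.analytes if e.mz_pos is not None][::8]
    mismatches = 0
    for _ in range(120):
        n = rng.integers(5, 40)
        base = rng.choice([e.mz_pos for e in entries], n)
        mz = base * (1 + rng.normal(0, 8e-6, n))  # up to ~ +/- 20 ppm spread
        rt = rng.uniform(5.0, 16.0, n)
        inten = rng.uniform(1, 1e4, n)
        t = _table([("s", "study", r, m, i) for r, m, i in zip(rt, mz, inten)])
        for e in entries:
            got = set(np.round(build_eic(t, e, CFG).rt, 9))
            want = {
                round(r, 9)
                for r, m in zip(rt, mz)
                if abs((m - e.mz_pos) / e.mz_pos) * 1e6 <= CFG.ppm_tol
                and abs(r - e.rt_min) <= CFG.rt_tol_min
            }
            mismatches += got != want
    assert mismatches == 0


def test_gaussian_area_closed_form():
    """Dense noiseless Gaussian integrates to height*sigma*sqrt(2*pi)."""
    height, sigma = 1000.0, 0.05
    rt = np.arange(8.93 - 0.4, 8.93 + 0.4, sigma / 10)
    y = height * np.exp(-0.5 * ((rt - 8.93) / sigma) ** 2)
    m = integrate_peak(EIC("x", "+", rt, y), CFG, entry_rt=8.93)
    assert m.status == "matched"
    assert m.area == pytest.approx(height * sigma * math.sqrt(2 * math.pi), rel=0.01)
    assert m.apex_rt == pytest.approx(8.93, abs=sigma / 10)


def test_area_scales_linearly_with_height():
    sigma = 0.05
    rt = np.arange(-0.3, 0.3, 0.005) + 5.0
    areas = []
    heights = np.array([10.0, 100.0, 1000.0, 5000.0])
    for h in heights:
        y = h * np.exp(-0.5 * ((rt - 5.0) / sigma) ** 2)
        areas.append(integrate_peak(EIC("x", "+", rt, y), CFG).area)
    r = np.corrcoef(heights, areas)[0, 1]
    assert r**2 == pytest.approx(1.0, abs=1e-12)


def test_empty_eic_not_detected():
    m = integrate_peak(EIC("x", "+", np.array([]), np.array([])), CFG)
    assert m.status == "not_detected"
    assert m.area == 0.0


def test_low_snr_not_detected():
    # alternating 0/20 baseline -> robust noise 1.4826*10 = 14.8; a bump of
    # 30 counts sits below the S/N 3 detection gate
    rt = np.arange(0, 1.01, 0.01)
    y = np.where(np.arange(len(rt)) % 2, 20.0, 0.0)
    y[50] = 30.0
    m = integrate_peak(EIC("x", "+", rt, y), CFG)
    assert m.snr < 3
    assert m.status == "not_detected"


def test_second_apex_flags_ambiguous():
    sigma = 0.04
    rt = np.arange(6.2, 7.3, 0.005)
    y = 1000 * np.exp(-0.5 * ((rt - 6.64) / sigma) ** 2)
    y += 1000 * np.exp(-0.5 * ((rt - 6.86) / sigma) ** 2)
    m = integrate_peak(EIC("x", "+", rt, y), CFG)
    assert m.status == "ambiguous"


def test_apex_tie_break_earlier_rt():
    rt = np.array([1.0, 1.1, 1.2, 1.3])
    y = np.array([5.0, 100.0, 100.0, 5.0])
    m = integrate_peak(EIC("x", "+", rt, y), MatchConfig(snr_min=1))
    assert m.apex_rt == 1.1


def _measurement(name, apex, status="matched"):
    from ccmscan.extract import PeakMeasurement

    return PeakMeasurement(name, "s1", "-", status, apex_rt=apex, area=1.0,
                           height=1.0, snr=10.0)


def test_resolve_isobars_distinct_apices(panel):
    g6p = panel["Glucose-6-phosphate (G6P)"]
    f6p = panel["Fructose-6-phosphate (F6P)"]
    # single apex at 11.20 lies in F6P's window only -> F6P keeps it
    out = resolve_isobars(
        [g6p, f6p],
        [_measurement(g6p.name, 11.20, "not_detected"), _measurement(f6p.name, 11.20)],
        CFG,
    )
    assert out[f6p.name].status == "matched"
    assert out[g6p.name].status == "not_detected"


def test_resolve_isobars_leucine_isoleucine_collide(panel):
    leu, ile = panel["Leucine"], panel["Isoleucine"]
    out = resolve_isobars(
        [leu, ile], [_measurement(leu.name, 6.75), _measurement(ile.name, 6.75)], CFG
    )
    assert out[leu.name].status == "ambiguous"
    assert out[ile.name].status == "ambiguous"
    assert out[leu.name].ambiguous_with == [ile.name]


def test_resolve_single_entry_untouched(panel):
    gln = panel["Glutamine"]
    out = resolve_isobars([gln], [_measurement(gln.name, 8.93)], CFG)
    assert out[gln.name].status == "matched"


def test_extract_peaks_no_double_assignment(panel):
    """After resolution no apex is claimed by two entries of an isobar pair."""
    g6p = panel["Glucose-6-phosphate (G6P)"]
    f6p = panel["Fructose-6-phosphate (F6P)"]
    rows = _gaussian_rows(g6p.mz_neg, 10.53, sid="s1") + _gaussian_rows(
        f6p.mz_neg, 11.25, sid="s1"
    )
    t = _table(rows, "-")
    peaks = extract_peaks(t, panel)
    det = peaks[peaks["status"] == "matched"]
    by_name = det.set_index("entry")
    assert by_name.loc[g6p.name, "apex_rt"] == pytest.approx(10.53, abs=0.05)
    assert by_name.loc[f6p.name, "apex_rt"] == pytest.approx(11.25, abs=0.05)
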