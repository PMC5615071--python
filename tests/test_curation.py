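"""Normalization, exclusion, quality, winsorization and log-transform rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from iggfc.curation import (apply_quality_threshold, exclude_analytes,
                            log_transform, normalize,
                            profiles_from_extractions, quality_fraction,
                            select_replicate_plate, winsorize_5sd)


def _frame(rows):
    return pd.DataFrame(rows, columns=["subclass", "shorthand",
                                       "raw_intensity", "passes_s2b"])


def test_normalize_percentages():
    sig = _frame([("IgG1", "G0F", 10.0, True), ("IgG1", "G1F", 30.0, True),
                  ("IgG1", "G2F", 60.0, True)])
    out = normalize(sig)
    assert out.pct.tolist() == [10.0, 30.0, 60.0]
    assert out.pct.sum() == pytest.approx(100.0, abs=1e-9)


def test_normalize_single_analyte_and_scale_invariance():
    sig = _frame([("IgG1", "G0F", 7.3, True)])
    assert normalize(sig).pct.iloc[0] == 100.0
    sig3 = _frame([("IgG1", "G0F", 1.0, True), ("IgG1", "G2F", 4.0, True)])
    scaled = sig3.assign(raw_intensity=sig3.raw_intensity * 17.0)
    assert normalize(sig3).pct.tolist() == normalize(scaled).pct.tolist()


def test_normalize_all_zero_marks_excluded():
    sig = _frame([("IgG1", "G0F", 0.0, False), ("IgG1", "G1F", 0.0, False)])
    out = normalize(sig)
    assert not out.included.any()


def test_normalize_idempotent():
    sig = _frame([("IgG1", "G0F", 25.0, True), ("IgG1", "G2F", 75.0, True)])
    once = normalize(sig)
    twice = normalize(once.assign(raw_intensity=once.pct))
    np.testing.assert_allclose(once.pct, twice.pct)


def test_exclusions_removed_before_normalization():
    sig = _frame([("IgG2", "G0F", 50.0, True), ("IgG2", "G1FNS1", 1.0, True),
                  ("IgG2", "G2FNS1", 1.0, True), ("IgG2", "G2F", 48.0, True)])
    out = exclude_analytes(sig, [("IgG2", "G1FNS1"), ("IgG2", "G2FNS1")])
    assert set(out.shorthand) == {"G0F", "G2F"}
    assert exclude_analytes(sig, []).equals(sig)
    with pytest.raises(KeyError):
        exclude_analytes(sig, [("IgG2", "G9F")])
    with pytest.raises(ValueError):
        exclude_analytes(sig, [(s, g) for s, g in
                               zip(sig.subclass, sig.shorthand)])


def test_quality_threshold_rules():
    good = _frame([("IgG1", "G0F", 60.0, True), ("IgG1", "G2F", 40.0, True)])
    bad = _frame([("IgG1", "G0F", 60.0, False), ("IgG1", "G2F", 40.0, False)])
    assert quality_fraction(good)["IgG1"] == 100.0
    assert quality_fraction(bad)["IgG1"] == 0.0
    flags = pd.DataFrame({"sample_id": ["a", "b"], "subclass": ["IgG1"] * 2,
                          "included": [True, True],
                          "quality_fraction": [100.0, 0.0]})
    out = apply_quality_threshold(flags, 50.0)
    assert out.included.tolist() == [True, False]
    assert out.exclusion_reason.tolist() == ["", "low_quality_fraction"]


def test_engineered_low_signal_samples_excluded():
    """100 samples, 10 engineered to fail S/B: exactly 10 excluded at 50%."""
    rng = np.random.default_rng(41)
    extractions = {}
    for i in range(100):
        low = i < 10
        rows = []
        for g in ("G0F", "G1F", "G2F"):
            inten = rng.uniform(1e4, 1e5)
            rows.append(("IgG1", g, inten * (1e-3 if low else 1.0), not low))
        extractions[f"S{i:03d}"] = _frame(rows)
    _, flags = profiles_from_extractions(extractions)
    flags = apply_quality_threshold(flags, 50.0)
    assert (~flags.included).sum() == 10


def test_winsorize_clips_to_five_sd():
    rng = np.random.default_rng(40)
    x = np.append(rng.standard_normal(1000), 50.0)  # far outlier
    m, s = x.mean(), x.std(ddof=1)
    assert 50.0 > m + 5 * s
    out = winsorize_5sd(x)
    assert out.max() == pytest.approx(m + 5 * s)
    inliers = np.linspace(-1, 1, 50)
    np.testing.assert_array_equal(winsorize_5sd(inliers), inliers)


def test_winsorize_preserves_rank_order():
    rng = np.random.default_rng(42)
    x = rng.standard_normal(500) * np.exp(rng.standard_normal(500))
    out = winsorize_5sd(x)
    assert (np.argsort(out, kind="stable") == np.argsort(x, kind="stable")).all()
    assert np.sum(out != x) <= np.sum(np.abs(x - x.mean()) > 5 * x.std(ddof=1))


def test_winsorize_clip_rate_matches_normal_tail():
    """Pooled Monte-Carlo clip rate agrees with P(|Z|>5) within factor 3."""
    tail = 2 * st.norm.sf(5.0)
    clipped = 0
    total = 0
    for rep in range(30):
        x = np.random.default_rng(1000 + rep).standard_normal(10 ** 6)
        out = winsorize_5sd(x)
        clipped += int(np.sum(out != x))
        total += x.size
    rate = clipped / total
    assert tail / 3 <= rate <= 3 * tail


def test_winsorize_needs_two_values():
    with pytest.raises(ValueError):
        winsorize_5sd([1.0])


def test_log_transform_policies():
    df = pd.DataFrame({"crp": [1.0, np.e], "il6": [0.0, 2.0]},
                      index=["s1", "s2"])
    out = log_transform(df, ["crp"])
    assert out.crp.tolist() == pytest.approx([0.0, 1.0])
    # offset policy: ln(0 + half the smallest positive value)
    out2 = log_transform(df, ["il6"], policy="offset")
    assert out2.il6.iloc[0] == pytest.approx(np.log(1.0))
    with pytest.raises(ValueError, match="il6.*s1"):
        log_transform(df, ["il6"], policy="strict")
    out3 = log_transform(df, ["il6"], policy="drop")
    assert np.isnan(out3.il6.iloc[0])


def test_select_replicate_plate_by_median_signal():
    hi = {"a": _frame([("IgG1", "G0F", 100.0, True)])}
    lo = {"a": _frame([("IgG1", "G0F", 10.0, True)])}
    assert select_replicate_plate(hi, lo) == "a"
    assert select_replicate_plate(lo, hi) == "b"
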