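"""Signal/decoy collection, AUC, coefficient grid search and f-function
training."""

import math

import numpy as np
import pytest

import etdscore as e
from etdscore.chem import ION_TYPES
from etdscore.significance import SignificanceModel
from etdscore.training import (
    LabeledLevel,
    _LevelCache,
    position_class,
)
from tests.conftest import make_spectrum


def test_position_class_partition():
    assert [position_class(j, 10) for j in range(1, 10)] == [
        "N1", "N2", "MID", "MID", "MID", "MID", "MID", "C2", "C1",
    ]
    # degenerate small peptides: precedence N1, C1, N2, C2
    assert [position_class(j, 3) for j in (1, 2)] == ["N1", "C1"]
    assert [position_class(j, 4) for j in (1, 2, 3)] == ["N1", "N2", "C1"]
    assert [position_class(j, 5) for j in (1, 2, 3, 4)] == ["N1", "N2", "C2", "C1"]
    with pytest.raises(ValueError):
        position_class(0, 5)


def test_nearest_peak_rules():
    s = make_spectrum([100.0, 101.0, 103.0], [1.0, 5.0, 2.0], 600.0, 2)
    assert e.nearest_peak(s, 100.9, 0.8) == 1
    assert e.nearest_peak(s, 110.0, 0.8) is None
    # exact distance tie at 100.5: higher-intensity peak wins
    assert e.nearest_peak(s, 100.5, 0.8) == 1
    # outside tolerance on both sides
    assert e.nearest_peak(s, 102.0, 0.5) is None


def _pair_fixture():
    """Two tiny hand-built spectrum-peptide pairs with known y-ion matches."""
    p1 = e.Peptide("GGK")  # y ions at K+H2O+H = 147.113, GK... sites 1,2
    p2 = e.Peptide("AAK")
    out = {}
    pairs = []
    for sid, p in (("s1", p1), ("s2", p2)):
        ions = e.fragment_ions(p, [ION_TYPES["y"]])
        mzs = [i.mz for i in ions]
        # give site-1 ion a peak, leave site-2 unmatched; add bystanders
        peak_mz = sorted([mzs[0] + 0.1, mzs[1] + 300.0, 500.0, 700.0])
        out[sid] = make_spectrum(peak_mz, [5.0, 50.0, 20.0, 10.0], 600.0, 2, sid=sid)
        pairs.append(e.TrainingPair(sid, p))
    return pairs, out


def test_collect_signal_levels_cardinality_and_oracle():
    pairs, spectra = _pair_fixture()
    records = e.collect_signal_levels(pairs, spectra, ION_TYPES["y"], tol=0.8)
    assert len(records) == sum(len(p.peptide) - 1 for p in pairs)
    matched = [r for r in records if r.matched]
    assert len(matched) == 2  # only the site-1 ions
    # brute-force oracle: find the peak, recompute its level by hand
    for pair, rec in zip(pairs, matched):
        s = spectra[pair.spectrum_id]
        mz = e.fragment_ions(pair.peptide, [ION_TYPES["y"]])[0].mz
        dists = np.abs(s.mz - mz)
        j = int(np.argmin(dists))
        assert dists[j] <= 0.8
        expect = e.significance_level(e.peak_features(s, j), SignificanceModel())
        assert rec.level == pytest.approx(expect, rel=1e-12)
        assert rec.position_class == "N1"


def test_collect_signal_levels_no_miss_when_all_present():
    p = e.Peptide("GASPVKR")
    ions = e.fragment_ions(p, [ION_TYPES["c"]])
    s = make_spectrum(
        sorted(i.mz for i in ions), np.arange(1.0, len(ions) + 1), 400.0, 2
    )
    records = e.collect_signal_levels(
        [e.TrainingPair("x", p)], {"x": s}, ION_TYPES["c"], tol=0.8
    )
    assert all(r.matched for r in records)


def test_collect_signal_levels_missing_spectrum():
    pairs, spectra = _pair_fixture()
    with pytest.raises(KeyError, match="nope"):
        e.collect_signal_levels(
            [e.TrainingPair("nope", pairs[0].peptide)], spectra, ION_TYPES["y"]
        )


def test_collect_decoy_levels_count_and_determinism():
    _, spectra = _pair_fixture()
    counts = {"s1": 2, "s2": 2}
    a = e.collect_decoy_levels(spectra, counts, count_multiplier=10, seed=5)
    b = e.collect_decoy_levels(spectra, counts, count_multiplier=10, seed=5)
    assert len(a) == 10 * 4
    assert [(r.level, r.label) for r in a] == [(r.level, r.label) for r in b]
    # near-zero tolerance: essentially everything misses
    c = e.collect_decoy_levels(spectra, counts, tol=1e-12, seed=5)
    assert all(not r.matched for r in c)


def test_roc_auc_cases():
    assert e.roc_auc([0.1, 0.2], [0.5, 0.9]) == 1.0
    # concordant pairs (signal < decoy): 0.1 beats all three, 0.2 and 0.3
    # each beat {0.4, 0.5} -> 7 of 9
    assert e.roc_auc([0.1, 0.2, 0.3], [0.15, 0.4, 0.5]) == pytest.approx(7 / 9)
    rng = np.random.default_rng(0)
    x = rng.normal(size=4000)
    assert e.roc_auc(x[:2000], x[2000:]) == pytest.approx(0.5, abs=0.05)
    with pytest.raises(ValueError):
        e.roc_auc([], [0.1])


def test_roc_auc_against_sklearn():
    """Independent cross-check of the midrank AUC on tied, mixed data."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(1)
    sig = np.round(rng.normal(0.0, 1.0, size=300), 1)
    dec = np.round(rng.normal(0.8, 1.2, size=400), 1)
    y = np.concatenate([np.ones(300), np.zeros(400)])
    expect = roc_auc_score(y, -np.concatenate([sig, dec]))
    assert e.roc_auc(sig, dec) == pytest.approx(expect, rel=1e-12)


def _records(levels_by_feature, label):
    out = []
    for f in levels_by_feature:
        out.append(LabeledLevel(None, label, features=e.PeakFeatures(*f)))
    return out


def test_grid_search_degenerate_step():
    rng = np.random.default_rng(2)
    sig = [
        LabeledLevel(0.0, "signal", features=e.PeakFeatures(*np.exp(rng.random(4))))
        for _ in range(50)
    ]
    dec = [
        LabeledLevel(0.0, "decoy", features=e.PeakFeatures(*np.exp(1 + rng.random(4))))
        for _ in range(50)
    ]
    m = e.grid_search_coefficients(sig, dec, grid_step=1.0)
    assert m.as_array() == pytest.approx([0.25, 0.25, 0.25, 0.25])


def test_grid_search_prefers_informative_local_rank():
    """When only the local rank separates signal from decoys, its
    coefficient dominates after normalization."""
    rng = np.random.default_rng(3)

    def feats(rl_scale):
        noise = np.exp(rng.random(3) * 2)  # uninformative rg, tg, tl
        rl = np.exp(rl_scale * rng.random())
        return e.PeakFeatures(noise[0], rl, noise[1], noise[2])

    sig = [LabeledLevel(0.0, "signal", features=feats(0.3)) for _ in range(400)]
    dec = [LabeledLevel(0.0, "decoy", features=feats(3.0)) for _ in range(400)]
    m = e.grid_search_coefficients(sig, dec, grid_step=0.2)
    assert m.c_rl >= max(m.c_rg, m.c_tg, m.c_tl)
    assert m.as_array().sum() == pytest.approx(1.0)


def _hand_fixture():
    """8 matched signal levels, 10 signal ions, 40 decoy draws with 2
    matches per interval: every interval log-ratio is ln 4."""
    sig_levels = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    sig = [LabeledLevel(x, "signal") for x in sig_levels]
    sig += [LabeledLevel(None, "signal")] * 2  # n = 10
    dec_levels = [0.12, 0.18, 0.3, 0.4, 0.5, 0.6, 0.7, 0.72]
    dec = [LabeledLevel(x, "decoy") for x in dec_levels]
    dec += [LabeledLevel(None, "decoy")] * 32  # 40 draws
    return sig + dec


def test_train_ion_score_function_hand_oracle():
    fn = e.train_ion_score_function(_hand_fixture(), min_matched=8)
    assert fn.values[:4] == pytest.approx([math.log(4)] * 4)
    assert fn.knots[:4] == pytest.approx([0.15, 0.35, 0.55, 0.75])
    # signal interval probabilities sum to m/n
    assert sum(fn.stats.signal_probs) == pytest.approx(0.8)
    # miss value: ln[(2/10) / (32/40)]
    assert fn.miss_value == pytest.approx(math.log(0.25))
    assert fn.values[-1] == fn.miss_value


def test_train_rejects_too_few_matches():
    with pytest.raises(ValueError, match="8"):
        e.train_ion_score_function(_hand_fixture(), min_matched=40)


def test_train_sign_when_signal_strong():
    """All signal at level ~0 with decoys missing or weak: matching is
    rewarded, missing penalized."""
    sig = [LabeledLevel(x, "signal") for x in np.linspace(0, 0.01, 40)]
    sig += [LabeledLevel(None, "signal")] * 4
    dec = [LabeledLevel(x, "decoy") for x in np.linspace(2.0, 3.0, 20)]
    dec += [LabeledLevel(None, "decoy")] * 380
    fn = e.train_ion_score_function(sig + dec)
    assert fn.values[0] > 0 > fn.miss_value


def test_evaluate_f_interpolation():
    fn = e.train_ion_score_function(_hand_fixture(), min_matched=8)
    c = fn.knots
    v = fn.values
    assert e.evaluate_f(fn, c[1]) == pytest.approx(v[1])
    assert e.evaluate_f(fn, (c[1] + c[2]) / 2) == pytest.approx((v[1] + v[2]) / 2)
    assert e.evaluate_f(fn, c[-1] + 100.0) == v[-1]
    assert e.evaluate_f(fn, -5.0) == v[0]
    assert e.evaluate_f(fn, None) == fn.miss_value


def test_interval_probability_conservation(benchmark, trained_model):
    """Signal interval masses plus the miss mass sum to 1 per function."""
    model, _ = trained_model
    for fn in model.functions.values():
        st = fn.stats
        assert sum(st.signal_probs) + (st.n - st.m) / st.n == pytest.approx(1.0)


def test_reference_choice_c_beats_a_b_with_outlier_peaks():
    """With a couple of huge outlier peaks, the 3rd..10th-mean reference
    separates weak signal from noise better than choices (a)/(b)."""
    rng = np.random.default_rng(8)
    aucs = {}
    for choice in ("a", "b", "c"):
        sig_levels, dec_levels = [], []
        for _ in range(80):
            n = 40
            intens = np.concatenate(
                [[5e4, 4e4], rng.lognormal(3.0, 0.4, size=n - 2)]
            )
            # signal peaks modestly above the noise floor
            sig_idx = rng.choice(np.arange(2, n), size=8, replace=False)
            intens[sig_idx] *= 3.0
            s = make_spectrum(
                np.sort(rng.uniform(100, 1500, size=n)), intens, 700.0, 2
            )
            feats = e.spectrum_features(s, choice=choice)
            levels = np.log(feats) @ e.PUBLISHED_COEFFICIENTS.as_array()
            noise_idx = [i for i in range(2, n) if i not in set(sig_idx)]
            sig_levels.extend(levels[sig_idx])
            dec_levels.extend(levels[rng.choice(noise_idx, size=8, replace=False)])
        aucs[choice] = e.roc_auc(sig_levels, dec_levels)
    assert aucs["c"] >= aucs["a"]
    assert aucs["c"] >= aucs["b"]
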