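import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rnaori import dms_stats
from rnaori.annotator import DuplexSegment
from rnaori.dms_stats import (
    AnalysisConfig,
    DMSProfile,
    _median_top_fraction,
    compare_scaffold_vs_origami,
    load_reactivities,
    normalize_profile,
    predict_tm,
    segment_stats,
    staple_omission_comparison,
)


def profile_from(bases: str, react, control=None, coverage=1000, sample="s"):
    n = len(bases)
    return DMSProfile(
        np.arange(1, n + 1),
        np.array(list(bases)),
        np.asarray(react, float),
        np.full(n, coverage),
        control or [],
        sample,
    )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def test_load_toy_csv(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text(
        "position,base,reactivity,coverage\n"
        "1,A,0.05,900\n2,C,0.02,900\n3,G,,900\n4,U,,900\n"
    )
    prof = load_reactivities(p)
    assert len(prof) == 4
    assert prof.at(1) == 0.05 and math.isnan(prof.at(3))


def test_g_position_reactivity_masked_with_warning():
    with pytest.warns(UserWarning, match="masking"):
        prof = profile_from("AG", [0.1, 0.2])
    assert math.isnan(prof.at(2))


def test_empty_and_malformed_tables_rejected(tmp_path):
    empty = tmp_path / "e.csv"
    empty.write_text("position,base,reactivity,coverage\n")
    with pytest.raises(ValueError, match="empty"):
        load_reactivities(empty)
    bad = tmp_path / "b.csv"
    bad.write_text("position,reactivity\n1,0.5\n")
    with pytest.raises(ValueError, match="missing columns"):
        load_reactivities(bad)
    out = tmp_path / "o.csv"
    out.write_text("position,base,reactivity,coverage\n1,A,1.5,10\n")
    with pytest.raises(ValueError, match="outside"):
        load_reactivities(out)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _control_profile(scale=1.0, seed=0, sample="s"):
    rng = np.random.default_rng(seed)
    bases = "".join(rng.choice(list("AC"), 91)) + "G" * 9
    react = np.concatenate([rng.uniform(0.01, 0.2, 91) * scale, [np.nan] * 9])
    return profile_from(bases, react, control=list(range(1, 101)), sample=sample)


def test_top_half_of_91_control_bases_is_46():
    vals = np.linspace(0.01, 0.91, 91)
    # ceil(91/2) = 46 values enter; their median is the 23rd/24th average
    expected = float(np.median(np.sort(vals)[::-1][:46]))
    assert _median_top_fraction(vals, 0.5) == pytest.approx(expected)
    assert math.ceil(91 * 0.5) == 46


def test_reference_normalizes_to_itself():
    ref = _control_profile()
    out = normalize_profile(ref, ref)
    assert np.allclose(out.reactivity, ref.reactivity, equal_nan=True)


def test_doubled_control_halves_sample():
    ref = _control_profile(seed=1)
    sample = ref.copy_with(ref.reactivity * 2.0, "x2")
    out = normalize_profile(sample, ref)
    assert np.allclose(out.reactivity, ref.reactivity, equal_nan=True)


def test_normalization_scale_equivariance():
    """Multiplying a sample by any c > 0 leaves its normalized profile
    unchanged."""
    ref = _control_profile(seed=2)
    sample = _control_profile(scale=1.7, seed=3, sample="s2")
    base = normalize_profile(sample, ref)
    for c in (0.25, 0.5, 2.0):  # keeps scaled rates within [0, 1]
        scaled = sample.copy_with(sample.reactivity * c)
        out = normalize_profile(scaled, ref)
        assert np.allclose(out.reactivity, base.reactivity, equal_nan=True)


def test_too_few_control_positions_error():
    prof = profile_from("ACGU", [0.1, 0.1, np.nan, np.nan], control=[3, 4])
    with pytest.raises(ValueError, match="at least 2"):
        normalize_profile(prof, prof)


# ---------------------------------------------------------------------------
# melting temperature: independent hand summation of the published
# RNA/DNA-hybrid nearest-neighbor table (Sugimoto et al.) with the
# entropy-based monovalent-salt correction
# ---------------------------------------------------------------------------

_NN = {  # RNA dinucleotide (T=U) / DNA complement: (dH kcal/mol, dS cal/mol/K)
    "AA/TT": (-7.8, -21.9), "AC/TG": (-5.9, -12.3), "AG/TC": (-9.1, -23.5),
    "AT/TA": (-8.3, -23.9), "CA/GT": (-9.0, -26.1), "CC/GG": (-9.3, -23.2),
    "CG/GC": (-16.3, -47.1), "CT/GA": (-7.0, -19.7), "GA/CT": (-5.5, -13.5),
    "GC/CG": (-8.0, -17.1), "GG/CC": (-12.8, -31.9), "GT/CA": (-7.8, -21.6),
    "TA/AT": (-7.8, -23.2), "TC/AG": (-8.6, -22.9), "TG/AC": (-10.4, -28.4),
    "TT/AA": (-11.5, -36.4),
}
_NN_INIT = (1.9, -3.9)


def tm_oracle(rna: str, na_molar: float = 0.3, dnac1=25.0, dnac2=25.0) -> float:
    seq = rna.upper().replace("U", "T")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    dh, ds = _NN_INIT
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2] + "/" + comp[seq[i]] + comp[seq[i + 1]]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    k = (dnac1 - dnac2 / 2.0) * 1e-9
    return dh * 1000.0 / (ds + 1.987 * math.log(k)) - 273.15


@pytest.mark.parametrize(
    "seq", ["ACGUACGUACGUACGUACGU", "GCGCGCAUAUGCGCAA", "AAGGCCUUAAGGCCUU"]
)
def test_tm_matches_hand_computation(seq):
    assert predict_tm(seq, 0.3) == pytest.approx(tm_oracle(seq, 0.3), abs=0.1)


def test_tm_increases_with_salt():
    seq = "ACGUACGUACGUACGUACGU"
    assert predict_tm(seq, 1.0) > predict_tm(seq, 0.3)


def test_longer_duplex_has_higher_tm():
    short = "GCAUCA"
    extended = short + "GCGAUCCGUA"
    assert predict_tm(extended, 0.3) > predict_tm(short, 0.3)
    assert tm_oracle(extended) > tm_oracle(short)


def test_tm_input_validation():
    with pytest.raises(ValueError, match="shorter than 2"):
        predict_tm("A")
    with pytest.raises(ValueError, match="RNA"):
        predict_tm("ACGN")


# ---------------------------------------------------------------------------
# segment statistics
# ---------------------------------------------------------------------------

def _uniform_segment_case(terminal_factor=1.0):
    bases = "ACACACACAC"
    react = np.full(10, 0.04)
    react[0] *= terminal_factor
    react[-1] *= terminal_factor
    prof = profile_from(bases, react)
    segs = [DuplexSegment(1, 10, "staple_nick", "vertex")]
    return prof, segs, bases


def test_uniform_segment_ratio_is_one():
    prof, segs, bases = _uniform_segment_case()
    df = segment_stats(prof, segs, bases)
    assert df.loc[0, "ratio5"] == pytest.approx(1.0)
    assert df.loc[0, "ratio3"] == pytest.approx(1.0)


def test_terminal_three_fold_elevation_recovered():
    prof, segs, bases = _uniform_segment_case(terminal_factor=3.0)
    df = segment_stats(prof, segs, bases)
    assert df.loc[0, "ratio5"] == pytest.approx(3.0)


def test_spearman_on_monotone_construction_is_minus_one():
    rng = np.random.default_rng(0)
    n = 30
    segs, react, bases = [], [], []
    pos = 0
    tms = []
    for i in range(n):
        seq = "GC" * (i + 2) + "AUAU"  # increasing GC -> increasing Tm
        start = pos + 1
        pos += len(seq)
        segs.append(DuplexSegment(start, pos, "vertex", "vertex"))
        bases.append(seq)
        tms.append(dms_stats.predict_tm(seq))
    order = np.argsort(np.argsort(tms))
    for i, seq in enumerate(bases):
        # interior reactivity strictly decreasing in the segment's Tm rank
        level = 0.2 - 0.005 * order[i]
        react.extend([level] * len(seq))
    scaffold = "".join(bases)
    prof = profile_from(scaffold, react)
    df = segment_stats(prof, segs, scaffold)
    rho = df.attrs["correlations"]["tm_celsius"]["rho"]
    assert rho == pytest.approx(-1.0)


def test_segments_without_interior_ac_excluded_from_means():
    bases = "AGGGGA"  # interior is all G: no interior A/C signal
    react = [0.1, np.nan, np.nan, np.nan, np.nan, 0.2]
    prof = profile_from(bases, react)
    df = segment_stats(prof, [DuplexSegment(1, 6, "vertex", "vertex")], bases)
    assert math.isnan(df.loc[0, "interior_mean"])
    assert df.loc[0, "n_interior_ac"] == 0


# ---------------------------------------------------------------------------
# exact-test oracles (n <= 10)
# ---------------------------------------------------------------------------

def mwu_exact_greater(x, y) -> float:
    pool = list(x) + list(y)
    n = len(x)

    def u_stat(idx):
        xs = [pool[i] for i in idx]
        ys = [pool[i] for i in range(len(pool)) if i not in idx]
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_stat(tuple(range(n)))
    us = [u_stat(c) for c in itertools.combinations(range(len(pool)), n)]
    return sum(u >= u_obs for u in us) / len(us)


def wilcoxon_exact_two_sided(d) -> float:
    d = [x for x in d if x != 0]
    ranks = stats.rankdata([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
    )
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def test_mann_whitney_matches_exact_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = np.round(rng.normal(0.6, 1, rng.integers(3, 6)), 3)
        y = np.round(rng.normal(0.0, 1, rng.integers(3, 6)), 3)
        if len(set(np.concatenate([x, y]))) < len(x) + len(y):
            continue
        p_scipy = stats.mannwhitneyu(x, y, alternative="greater").pvalue
        assert p_scipy == pytest.approx(mwu_exact_greater(x, y), abs=1e-12)


def test_wilcoxon_matches_exact_enumeration():
    rng = np.random.default_rng(6)
    for _ in range(10):
        d = np.round(rng.normal(0.4, 1, rng.integers(4, 9)), 3)
        if (d == 0).any() or len(set(np.abs(d))) < len(d):
            continue
        p_scipy = stats.wilcoxon(d, alternative="two-sided").pvalue
        assert p_scipy == pytest.approx(wilcoxon_exact_two_sided(d), abs=1e-12)


# ---------------------------------------------------------------------------
# scaffold vs origami; staple omission
# ---------------------------------------------------------------------------

def _paired_profiles(factor, n_seg=40, seg_len=10, seed=0):
    rng = np.random.default_rng(seed)
    L = n_seg * seg_len
    bases = "".join(rng.choice(list("ACGU"), L, p=[0.3, 0.3, 0.2, 0.2]))
    scaf = np.exp(rng.normal(np.log(0.04), 0.3, L))
    ori = scaf * factor
    ac = np.isin(list(bases), ["A", "C"])
    scaf[~ac] = np.nan
    ori[~ac] = np.nan
    segs = [
        DuplexSegment(i * seg_len + 1, (i + 1) * seg_len, "vertex", "vertex")
        for i in range(n_seg)
    ]
    return (
        profile_from(bases, scaf, sample="scaffold"),
        profile_from(bases, ori, sample="origami"),
        segs,
    )


def test_identical_profiles_give_zero_reduction():
    p_s, _, segs = _paired_profiles(1.0)
    res = compare_scaffold_vs_origami(p_s, p_s, segs)
    assert res["percent_reduction"] == pytest.approx(0.0)
    assert res["wilcoxon_p"] == pytest.approx(1.0)


def test_five_fold_protection_gives_80_percent_reduction():
    p_s, p_o, segs = _paired_profiles(0.2)
    res = compare_scaffold_vs_origami(p_s, p_o, segs)
    assert res["percent_reduction"] == pytest.approx(80.0, abs=1e-9)
    assert res["wilcoxon_p"] < 1e-6


def test_printed_medians_imply_82_percent_reduction():
    # medians 0.63% (origami) vs 3.4% (scaffold): 1 - 0.63/3.4 = 81.5%
    assert 100 * (1 - 0.63 / 3.4) == pytest.approx(81.47, abs=0.01)


def test_mismatched_profiles_error():
    p_s, _, segs = _paired_profiles(1.0)
    short = profile_from("AC", [0.1, 0.1])
    with pytest.raises(ValueError, match="coordinate"):
        compare_scaffold_vs_origami(p_s, short, segs)


def test_staple_omission_fold_change_recovered():
    rng = np.random.default_rng(7)
    L = 600
    bases = "".join(rng.choice(list("ACGU"), L))
    full = np.exp(rng.normal(np.log(0.01), 0.4, L))
    omitted = full * np.exp(rng.normal(0, 0.05, L))
    target = list(range(101, 141))
    omitted[100:140] *= 6.0
    ac = np.isin(list(bases), ["A", "C"])
    full[~ac] = np.nan
    omitted[~ac] = np.nan
    res = staple_omission_comparison(
        profile_from(bases, full), profile_from(bases, omitted), target
    )
    assert res["target_fold_change"] == pytest.approx(6.0, rel=0.10)
    assert res["offtarget_fold_change"] == pytest.approx(1.0, rel=0.05)
    assert res["target_p"] < 1e-4 and res["offtarget_p"] > 0.05


def test_no_omission_gives_unit_fold_changes():
    rng = np.random.default_rng(8)
    L = 200
    bases = "".join(rng.choice(list("AC"), L))
    vals = np.exp(rng.normal(np.log(0.02), 0.4, L))
    res = staple_omission_comparison(
        profile_from(bases, vals), profile_from(bases, vals.copy()),
        list(range(1, 41)),
    )
    assert res["target_fold_change"] == pytest.approx(1.0)
    assert res["offtarget_fold_change"] == pytest.approx(1.0)


def test_empty_target_set_error():
    p = profile_from("AC", [0.1, 0.1])
    with pytest.raises(ValueError, match="empty"):
        staple_omission_comparison(p, p, [])


def test_analysis_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(window=0)
    with pytest.raises(ValueError):
        AnalysisConfig(top_fraction=0)
    assert AnalysisConfig().window == 6
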