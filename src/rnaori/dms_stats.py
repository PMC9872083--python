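"""DMS-reactivity statistics for origami secondary-structure analysis.

Dimethyl sulfate methylates accessible (unpaired) adenines and cytosines;
after mutational profiling with sequencing, the per-position mutation
rate ("DMS reactivity") reports base-pairing at single-nucleotide
resolution.  This module implements the analysis layer over such
per-position tables: spike-in normalization across samples, duplex-segment
summaries with RNA/DNA-hybrid melting temperatures, reactivity
distributions around structural features, and the non-parametric tests
used throughout (Mann-Whitney U, Wilcoxon signed-rank, Spearman rank
correlations).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt
from scipy import stats

from rnaori.annotator import FEATURE_KINDS, DesignAnnotation, DuplexSegment


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    ``window`` is the feature-window half-width in bp (6, the length of
    the shortest duplex segment); ``alpha_window``/``alpha_ratio`` are the
    significance levels used for the window and terminal-ratio analyses;
    ``top_fraction`` selects the control bases used for normalization;
    ``na_molar`` is the monovalent-salt concentration for Tm prediction.
    """

    window: int = 6
    alpha_window: float = 0.01
    alpha_ratio: float = 0.05
    top_fraction: float = 0.5
    na_molar: float = 0.3

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")


@dataclass
class DMSProfile:
    """Per-position DMS reactivities for one sample.

    ``reactivity`` is NaN wherever undefined (G/U positions, no data).
    ``control_positions`` designate the spiked-in normalization region.
    """

    positions: np.ndarray
    bases: np.ndarray
    reactivity: np.ndarray
    coverage: np.ndarray
    control_positions: list[int] = field(default_factory=list)
    sample: str = "sample"

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.bases) == len(self.reactivity) == len(self.coverage) == n):
            raise ValueError("profile columns differ in length")
        finite = self.reactivity[np.isfinite(self.reactivity)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("reactivities must lie in [0, 1]")
        if (self.coverage < 0).any():
            raise ValueError("coverage must be non-negative")
        gu = np.isin(self.bases, ["G", "U", "T"])
        if np.isfinite(self.reactivity[gu]).any():
            warnings.warn(
                "reactivity reported at G/U positions; masking (DMS probes A/C)",
                stacklevel=2,
            )
            self.reactivity = self.reactivity.copy()
            self.reactivity[gu] = np.nan

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def is_ac(self) -> np.ndarray:
        return np.isin(self.bases, ["A", "C"])

    def at(self, position: int) -> float:
        return float(self.reactivity[position - 1])

    def copy_with(self, reactivity: np.ndarray, sample: str | None = None) -> "DMSProfile":
        return DMSProfile(
            self.positions.copy(), self.bases.copy(), reactivity,
            self.coverage.copy(), list(self.control_positions),
            sample or self.sample,
        )


def load_reactivities(path, control_positions: list[int] | None = None,
                      sample: str = "sample") -> DMSProfile:
    """Read a per-position reactivity CSV (position, base, reactivity, coverage)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty reactivity table: {path}")
    missing = {"position", "base", "reactivity", "coverage"} - set(df.columns)
    if missing:
        raise ValueError(f"reactivity CSV missing columns: {sorted(missing)}")
    react = df["reactivity"].to_numpy(float)
    finite = react[np.isfinite(react)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("reactivities outside [0, 1]")
    return DMSProfile(
        df["position"].to_numpy(int),
        df["base"].astype(str).str.upper().to_numpy(),
        react,
        df["coverage"].to_numpy(int),
        control_positions or [],
        sample,
    )


def write_reactivities(profile: DMSProfile, path) -> None:
    pd.DataFrame(
        {
            "position": profile.positions,
            "base": profile.bases,
            "reactivity": profile.reactivity,
            "coverage": profile.coverage,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _median_top_fraction(values: np.ndarray, fraction: float) -> float:
    """Median of the top `fraction` of values (count rounded up)."""
    vals = np.sort(values[np.isfinite(values)])[::-1]
    if vals.size < 2:
        raise ValueError("need at least 2 finite control reactivities")
    k = math.ceil(vals.size * fraction)
    return float(np.median(vals[:k]))


def normalize_profile(
    sample: DMSProfile,
    reference: DMSProfile,
    config: AnalysisConfig | None = None,
) -> DMSProfile:
    """Scale a sample so its spike-in control matches the reference's.

    The median reactivity among the top 50% of A/C control bases is
    computed for both samples; the sample profile is divided by the ratio
    sample/reference, making the control region comparable across
    samples.  Normalizing the reference against itself is the identity.
    """
    config = config or AnalysisConfig()

    def control_values(p: DMSProfile) -> np.ndarray:
        if not p.control_positions:
            raise ValueError(f"profile {p.sample!r} lacks a control region")
        idx = np.asarray(p.control_positions, int) - 1
        vals = p.reactivity[idx]
        ac = p.is_ac[idx]
        return vals[ac]

    med_s = _median_top_fraction(control_values(sample), config.top_fraction)
    med_r = _median_top_fraction(control_values(reference), config.top_fraction)
    factor = med_s / med_r
    out = sample.reactivity / factor
    return sample.copy_with(out, sample=f"{sample.sample}_norm")


# ---------------------------------------------------------------------------
# melting temperature (RNA/DNA hybrid)
# ---------------------------------------------------------------------------

def predict_tm(segment_rna: str, na_molar: float = 0.3) -> float:
    """Nearest-neighbor Tm (deg C) of an RNA strand paired to its DNA
    complement, with monovalent-salt correction.

    Uses the RNA/DNA-hybrid nearest-neighbor parameter set of Sugimoto
    et al. with the SantaLucia entropy-based salt correction, as provided
    by Biopython's ``MeltingTemp`` (``R_DNA_NN1``, ``saltcorr=5``).
    """
    seq = segment_rna.upper().replace("T", "U")
    if len(seq) < 2:
        raise ValueError("Tm undefined for sequences shorter than 2 nt")
    if set(seq) - set("ACGU"):
        raise ValueError(f"not a pure RNA sequence: {segment_rna!r}")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.R_DNA_NN1,
            Na=na_molar * 1000.0,
            saltcorr=5,
        )
    )


# ---------------------------------------------------------------------------
# per-segment statistics
# ---------------------------------------------------------------------------

def segment_stats(
    profile: DMSProfile,
    segments: list[DuplexSegment],
    scaffold_residues: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-segment reactivity summaries, terminal/interior ratios and Tm.

    Interior means use adenines and cytosines only, excluding the single
    terminal base at each end.  Terminal ratios are defined only when the
    terminal base is A or C and the interior mean is positive.  The
    returned frame carries Spearman correlations of interior mean vs Tm,
    length and GC content in ``df.attrs["correlations"]``.
    """
    config = config or AnalysisConfig()
    rows = []
    react = profile.reactivity
    for seg in segments:
        seq = scaffold_residues[seg.start - 1 : seg.end].replace("T", "U")
        interior_idx = np.array(list(seg.interior), int) - 1
        vals = react[interior_idx] if interior_idx.size else np.array([])
        ac_vals = vals[np.isfinite(vals)]
        interior_mean = float(ac_vals.mean()) if ac_vals.size else np.nan
        t5 = react[seg.start - 1]
        t3 = react[seg.end - 1]
        ratio5 = (
            float(t5 / interior_mean)
            if np.isfinite(t5) and np.isfinite(interior_mean) and interior_mean > 0
            else np.nan
        )
        ratio3 = (
            float(t3 / interior_mean)
            if np.isfinite(t3) and np.isfinite(interior_mean) and interior_mean > 0
            else np.nan
        )
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        rows.append(
            {
                "start": seg.start,
                "end": seg.end,
                "length_bp": seg.length,
                "feature5": seg.feature5,
                "feature3": seg.feature3,
                "interior_mean": interior_mean,
                "terminal5": float(t5),
                "terminal3": float(t3),
                "ratio5": ratio5,
                "ratio3": ratio3,
                "tm_celsius": predict_tm(seq, config.na_molar),
                "gc_content": gc,
                "n_interior_ac": int(ac_vals.size),
            }
        )
    df = pd.DataFrame(rows)
    ok = df["n_interior_ac"] >= 1
    corr = {}
    for col in ("tm_celsius", "length_bp", "gc_content"):
        sub = df[ok & np.isfinite(df["interior_mean"])]
        if len(sub) >= 3:
            rho, p = stats.spearmanr(sub["interior_mean"], sub[col])
            corr[col] = {"rho": float(rho), "p": float(p), "n": int(len(sub))}
    df.attrs["correlations"] = corr
    return df


# ---------------------------------------------------------------------------
# feature windows
# ---------------------------------------------------------------------------

def feature_window_distributions(
    profile: DMSProfile,
    annotation: DesignAnnotation,
    config: AnalysisConfig | None = None,
    base_subset: str | None = None,
) -> pd.DataFrame:
    """Reactivity distributions at positions -w..-1, +1..+w of each feature.

    Offset -1/+1 lie immediately 5'/3' of the feature junction.  For each
    offset, a one-sided Mann-Whitney U tests whether reactivities exceed
    those at all positions further from the feature on the same side.
    ``base_subset`` restricts the analysis to "A" or "C" residues.
    Feature classes with no instances yield no rows.
    """
    return pooled_feature_windows([(profile, annotation)], config, base_subset)


def pooled_feature_windows(
    pairs: list[tuple[DMSProfile, DesignAnnotation]],
    config: AnalysisConfig | None = None,
    base_subset: str | None = None,
) -> pd.DataFrame:
    """Feature-window analysis pooling instances across several designs,
    the way independently probed origami objects are analyzed jointly."""
    config = config or AnalysisConfig()
    w = config.window

    values: dict[tuple[str, int], list[float]] = {}
    for profile, annotation in pairs:
        L = len(profile)
        react = profile.reactivity
        ok_base = profile.is_ac
        if base_subset is not None:
            ok_base = profile.bases == base_subset
        paired_len = max(
            (f.after_position for f in annotation.features), default=L
        )
        for f in annotation.features:
            if f.kind == "scaffold_nick":
                continue  # excluded: coverage is unreliable at scaffold ends
            p = f.after_position
            for off in range(-w, w + 1):
                if off == 0:
                    continue
                # offset -k is the k-th base 5' of the junction (p-k+1);
                # offset +k is the k-th base 3' of it (p+k)
                pos = p + off + 1 if off < 0 else p + off
                pos = (pos - 1) % paired_len + 1
                if ok_base[pos - 1] and np.isfinite(react[pos - 1]):
                    values.setdefault((f.kind, off), []).append(
                        float(react[pos - 1])
                    )

    rows = []
    for kind in FEATURE_KINDS:
        for off in list(range(-w, 0)) + list(range(1, w + 1)):
            vals = values.get((kind, off))
            if not vals:
                continue
            side = range(-w, off) if off < 0 else range(off + 1, w + 1)
            further = [v for o in side for v in values.get((kind, o), [])]
            if further and len(vals) >= 2:
                u, p = stats.mannwhitneyu(vals, further, alternative="greater")
                pval = float(p)
            else:
                pval = np.nan
            rows.append(
                {
                    "feature": kind,
                    "offset": off,
                    "n": len(vals),
                    "median": float(np.median(vals)),
                    "mean": float(np.mean(vals)),
                    "p_greater_than_further": pval,
                    "significant": bool(pval < config.alpha_window)
                    if np.isfinite(pval)
                    else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scaffold vs origami, staple omission
# ---------------------------------------------------------------------------

def _segment_means(profile: DMSProfile, segments: list[DuplexSegment]) -> np.ndarray:
    out = []
    for seg in segments:
        idx = np.arange(seg.start - 1, seg.end)
        vals = profile.reactivity[idx]
        vals = vals[np.isfinite(vals)]
        out.append(vals.mean() if vals.size else np.nan)
    return np.asarray(out)


def compare_scaffold_vs_origami(
    profile_scaffold: DMSProfile,
    profile_origami: DMSProfile,
    segments: list[DuplexSegment],
) -> dict:
    """Paired per-segment comparison of bare scaffold vs folded origami.

    Returns per-segment mean reactivities, their medians, the percent
    reduction 1 - median(origami)/median(scaffold), and a two-sided
    Wilcoxon signed-rank p-value over the segment pairs.
    """
    if len(profile_scaffold) != len(profile_origami):
        raise ValueError("profiles are on different coordinate systems")
    m_s = _segment_means(profile_scaffold, segments)
    m_o = _segment_means(profile_origami, segments)
    ok = np.isfinite(m_s) & np.isfinite(m_o)
    med_s = float(np.median(m_s[ok]))
    med_o = float(np.median(m_o[ok]))
    diffs = m_o[ok] - m_s[ok]
    nonzero = diffs[diffs != 0]
    if nonzero.size:
        res = stats.wilcoxon(nonzero, alternative="two-sided")
        pval = float(res.pvalue)
    else:
        pval = 1.0
    return {
        "segment_means_scaffold": m_s,
        "segment_means_origami": m_o,
        "median_scaffold": med_s,
        "median_origami": med_o,
        "percent_reduction": 100.0 * (1.0 - med_o / med_s) if med_s > 0 else np.nan,
        "wilcoxon_p": pval,
        "n_segments": int(ok.sum()),
    }


def staple_omission_comparison(
    profile_full: DMSProfile,
    profile_omitted: DMSProfile,
    target_positions: list[int],
) -> dict:
    """Fold-change in reactivity when one staple is left out of folding.

    Median fold-change omitted/full over the omitted staple's scaffold
    positions (A/C only), the same over all other paired A/C positions,
    each with a two-sided Wilcoxon signed-rank p-value on the paired
    log-ratios.
    """
    if not target_positions:
        raise ValueError("empty target position set")
    if len(profile_full) != len(profile_omitted):
        raise ValueError("profiles are on different coordinate systems")
    tgt = np.zeros(len(profile_full), bool)
    tgt[np.asarray(target_positions, int) - 1] = True
    valid = (
        np.isfinite(profile_full.reactivity)
        & np.isfinite(profile_omitted.reactivity)
        & (profile_full.reactivity > 0)
    )
    ctrl = np.ones(len(profile_full), bool)
    if profile_full.control_positions:
        ctrl[np.asarray(profile_full.control_positions, int) - 1] = False

    def side(mask: np.ndarray) -> tuple[float, float, int]:
        sel = mask & valid & ctrl
        fc = profile_omitted.reactivity[sel] / profile_full.reactivity[sel]
        if fc.size == 0:
            return np.nan, np.nan, 0
        logs = np.log(fc[fc > 0])
        logs = logs[logs != 0]
        p = float(stats.wilcoxon(logs, alternative="two-sided").pvalue) if logs.size else 1.0
        return float(np.median(fc)), p, int(fc.size)

    on_fc, on_p, on_n = side(tgt)
    off_fc, off_p, off_n = side(~tgt)
    return {
        "target_fold_change": on_fc,
        "target_p": on_p,
        "n_target": on_n,
        "offtarget_fold_change": off_fc,
        "offtarget_p": off_p,
        "n_offtarget": off_n,
    }
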