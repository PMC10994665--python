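"""Negative-binomial differential testing and leaky-scanning classification.

Counts between two conditions are compared with a self-contained NB Wald
test in the DESeq2 family: externally supplied (spike-in) size factors,
method-of-moments gene-wise dispersion shrunk toward a fitted
mean–dispersion trend, and a Wald test on the log2 ratio of normalized
condition means.  It deliberately omits DESeq2's Cox–Reid adjusted
dispersion MLE, LFC shrinkage, and Cook's outlier filtering, so
significant-gene counts against a DESeq2 run agree approximately, not
exactly.

Significance calling follows FDR < 0.05 with a fold change > 2 (up) or
< 0.5 (down).  A transcript is classified as leaky-scanning when its mAUG
footprints drop significantly, its internal-AUG footprints rise
significantly, and the internal gain is at least 50% of the main-AUG loss
(the reciprocity expected if complexes scan past the main AUG and
initiate downstream instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


def filter_by_depth(
    counts: pd.DataFrame, threshold: float, comparison: str = ">"
) -> pd.Index:
    """Transcripts whose total raw reads across all samples pass the cutoff.

    ``comparison`` is ">" or ">=", matching how a study states its depth
    rule (e.g. ">90 total reads in nine samples" vs ">=8 in four).
    """
    totals = counts.sum(axis=1)
    if comparison == ">":
        keep = totals > threshold
    elif comparison == ">=":
        keep = totals >= threshold
    else:
        raise ValueError("comparison must be '>' or '>='")
    return counts.index[keep]


def _rescale_size_factors(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    return s / np.exp(np.log(s).mean())


def _mom_dispersion(q: np.ndarray, inv_s_mean: float) -> np.ndarray:
    """Method-of-moments dispersion from one group's normalized counts."""
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu * inv_s_mean) / mu**2
    alpha[~np.isfinite(alpha)] = MIN_DISPERSION
    return alpha


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu over informative genes; predict for all.

    One trimming pass removes gross outliers from the fit.  Coefficients
    are clipped to be non-negative so the trend is a valid dispersion.
    """
    ok = (mu > 0) & (alpha > MIN_DISPERSION) & (alpha < MAX_DISPERSION)
    if ok.sum() < 10:
        fallback = float(np.median(alpha[alpha > MIN_DISPERSION])) if np.any(
            alpha > MIN_DISPERSION
        ) else 0.05
        return np.full_like(mu, max(fallback, MIN_DISPERSION))
    x = 1.0 / mu[ok]
    y = alpha[ok]
    for _ in range(2):
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        pred = design @ coef
        resid = np.abs(y - pred)
        keep = resid <= 3 * np.median(resid) + 1e-12
        if keep.all():
            break
        x, y = x[keep], y[keep]
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = a0 + a1 / mu
    trend[~np.isfinite(trend)] = a0
    return np.clip(trend, MIN_DISPERSION, MAX_DISPERSION)


def nb_test(
    counts_a: pd.DataFrame | np.ndarray,
    counts_b: pd.DataFrame | np.ndarray,
    size_factors_a: Sequence[float] | None = None,
    size_factors_b: Sequence[float] | None = None,
) -> pd.DataFrame:
    """NB Wald test of condition B versus condition A (log2FC = B/A).

    ``counts_*`` are genes x replicates raw counts; ``size_factors_*`` are
    DESeq2-sense divisors (use ``SizeFactorSet.deseq_size_factors``), which
    are rescaled jointly to geometric mean 1.  Per-gene dispersions come
    from method-of-moments on the normalized counts (floored at 1e-8) and
    are shrunk toward the fitted mean-dispersion trend, with the trend
    weight 0.5 at three replicates per condition.  The log2 fold change
    adds a 0.5-count stabilizer to each condition's normalized mean.  The
    Wald statistic is referred to a t distribution whose effective degrees
    of freedom reflect the dispersion moderation (see inline note), which
    keeps the test close to nominal at two or three replicates.  Genes
    with zero counts in both conditions get no p-value.
    """
    A = np.asarray(counts_a, dtype=float)
    B = np.asarray(counts_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError("counts must be 2D with matching gene dimension")
    nA, nB = A.shape[1], B.shape[1]
    if nA < 2 or nB < 2:
        raise ValueError("need >=2 replicates per condition")
    sA = np.ones(nA) if size_factors_a is None else np.asarray(size_factors_a, float)
    sB = np.ones(nB) if size_factors_b is None else np.asarray(size_factors_b, float)
    s = _rescale_size_factors(np.concatenate([sA, sB]))
    sA, sB = s[:nA], s[nA:]
    qA, qB = A / sA, B / sB
    muA, muB = qA.mean(axis=1), qB.mean(axis=1)
    mu = np.concatenate([qA, qB], axis=1).mean(axis=1)

    alpha_mom = 0.5 * (
        _mom_dispersion(qA, float(np.mean(1.0 / sA)))
        + _mom_dispersion(qB, float(np.mean(1.0 / sB)))
    )
    alpha_mom = np.clip(alpha_mom, MIN_DISPERSION, MAX_DISPERSION)
    trend = _fit_dispersion_trend(mu, alpha_mom)
    w_trend = min(1.0, 1.0 / (min(nA, nB) - 1))  # 0.5 at n=3
    alpha = np.clip(
        (1 - w_trend) * alpha_mom + w_trend * trend, MIN_DISPERSION, MAX_DISPERSION
    )

    muA_s, muB_s = muA + 0.5, muB + 0.5
    log2fc = np.log2(muB_s / muA_s)
    var_log = (1.0 / muA_s + alpha) / nA + (1.0 / muB_s + alpha) / nB
    se_log2 = np.sqrt(var_log) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se_log2
    # moderated Wald: the shrunk dispersion behaves like one estimated with
    # d_g/(1-w)^2 effective df (Satterthwaite), so the statistic is referred
    # to a t distribution; fully trended dispersion (w=1) recovers the normal
    d_g = nA + nB - 2
    if w_trend < 1.0:
        df_eff = d_g / (1.0 - w_trend) ** 2
        pvalue = 2 * stats.t.sf(np.abs(z), df_eff)
    else:
        pvalue = 2 * stats.norm.sf(np.abs(z))
    allzero = (A.sum(axis=1) == 0) & (B.sum(axis=1) == 0)
    pvalue[allzero] = np.nan

    index = counts_a.index if isinstance(counts_a, pd.DataFrame) else pd.RangeIndex(len(log2fc))
    return pd.DataFrame(
        {
            "baseMeanA": muA,
            "baseMeanB": muB,
            "log2FoldChange": log2fc,
            "dispersion": alpha,
            "stat": z,
            "pvalue": pvalue,
        },
        index=index,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN p-values stay NaN)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify(
    log2fc: Sequence[float],
    fdr: Sequence[float],
    fdr_max: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> np.ndarray:
    """'up' / 'down' / 'ns' per the FDR < 0.05 and FC > 2 (or < 0.5) rule."""
    lfc = np.asarray(log2fc, dtype=float)
    q = np.asarray(fdr, dtype=float)
    out = np.full(lfc.shape, "ns", dtype=object)
    sig = np.isfinite(q) & (q < fdr_max)
    out[sig & (lfc > np.log2(fc_up))] = "up"
    out[sig & (lfc < np.log2(fc_down))] = "down"
    return out


@dataclass
class OverlapResult:
    overlap: int
    expected: float
    representation_factor: float
    p_value: float


def overlap_test(
    set1: Iterable, set2: Iterable, universe_size: int
) -> OverlapResult:
    """Hypergeometric enrichment of the overlap between two gene sets.

    p = P(X >= observed) under sampling |set2| items from a universe of
    ``universe_size`` containing |set1| marked items; the representation
    factor is observed / expected overlap.
    """
    s1, s2 = set(set1), set(set2)
    if len(s1) > universe_size or len(s2) > universe_size:
        raise ValueError("sets cannot exceed the universe")
    obs = len(s1 & s2)
    if len(s1 | s2) > universe_size:
        raise ValueError("union of sets exceeds the universe")
    expected = len(s1) * len(s2) / universe_size
    p = float(stats.hypergeom.sf(obs - 1, universe_size, len(s1), len(s2)))
    rf = obs / expected if expected > 0 else float("nan")
    return OverlapResult(obs, expected, rf, p)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties; NaN if constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x[ok], y[ok])
    return float(rho)


def ratio_change_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Bootstrap test for a change in a per-replicate ratio metric (RE, RRO).

    Replicates are paired by index; the statistic is the mean log2 ratio
    B/A, and the two-sided p-value is the bootstrap probability that the
    resampled mean crosses zero.  Returns (mean log2 ratio, p).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    k = min(len(a), len(b))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(b[:k] / a[:k])
    r = r[np.isfinite(r)]
    if len(r) < 2:
        return float("nan"), float("nan")
    idx = rng.integers(0, len(r), size=(n_boot, len(r)))
    means = r[idx].mean(axis=1)
    p = 2 * min((means <= 0).mean(), (means >= 0).mean())
    return float(r.mean()), float(min(max(p, 1.0 / n_boot), 1.0))


@dataclass
class LeakyCall:
    transcript_id: str
    mRPF_down: bool
    iRPF_up: bool
    delta_mRPF: float
    delta_iRPF: float
    reciprocity: float
    leaky: bool


def leaky_scanning_calls(
    diff_m: pd.DataFrame,
    diff_i: pd.DataFrame,
    delta_m: pd.Series,
    delta_i: pd.Series,
    reciprocity_min: float = 0.5,
) -> pd.DataFrame:
    """Classify transcripts as leaky-scanning responders.

    ``diff_m`` / ``diff_i`` carry 'class' columns from :func:`classify`
    for the main-AUG and internal-AUG windows of the same contrast;
    ``delta_*`` are differences of mean normalized counts (condition B
    minus A).  A transcript is leaky when mRPF is significantly down,
    iRPF significantly up, and the iRPF gain is at least
    ``reciprocity_min`` of the mRPF loss.
    """
    ids = diff_m.index
    rows = []
    for tid in ids:
        m_down = diff_m.loc[tid, "class"] == "down"
        i_up = tid in diff_i.index and diff_i.loc[tid, "class"] == "up"
        dm = float(delta_m.get(tid, np.nan))
        di = float(delta_i.get(tid, np.nan))
        if np.isfinite(dm) and dm < 0 and np.isfinite(di):
            rec = di / abs(dm)
        else:
            rec = float("nan")
        leaky = bool(
            m_down and i_up and np.isfinite(rec) and di > 0 and rec >= reciprocity_min
        )
        rows.append(
            {
                "transcript_id": tid,
                "mRPF_down": bool(m_down),
                "iRPF_up": bool(i_up),
                "delta_mRPF": dm,
                "delta_iRPF": di,
                "reciprocity": rec,
                "leaky": leaky,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def reciprocal_uaug_calls(
    diff_u: pd.DataFrame,
    diff_m: pd.DataFrame,
    delta_u: pd.Series,
    delta_m: pd.Series,
    reciprocity_min: float = 0.5,
) -> pd.DataFrame:
    """The mirrored 5'UTR rule: uRPF significantly down, mRPF significantly
    up, and the uRPF loss at least ``reciprocity_min`` of the mRPF gain —
    the signature of suppressed upstream initiation feeding the main AUG.
    """
    rows = []
    for tid in diff_u.index:
        u_down = diff_u.loc[tid, "class"] == "down"
        m_up = tid in diff_m.index and diff_m.loc[tid, "class"] == "up"
        du = float(delta_u.get(tid, np.nan))
        dm = float(delta_m.get(tid, np.nan))
        if np.isfinite(dm) and dm > 0 and np.isfinite(du):
            rec = -du / dm
        else:
            rec = float("nan")
        rows.append(
            {
                "transcript_id": tid,
                "uRPF_down": bool(u_down),
                "mRPF_up": bool(m_up),
                "delta_uRPF": du,
                "delta_mRPF": dm,
                "reciprocity": rec,
                "reciprocal": bool(
                    u_down and m_up and np.isfinite(rec) and du < 0 and rec >= reciprocity_min
                ),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


# ---------------------------------------------------------------------------
# contrast driver
# ---------------------------------------------------------------------------

def run_contrast(
    count_table: pd.DataFrame,
    design: Mapping[str, str],
    cond_a: str,
    cond_b: str,
    size_factors: pd.Series | None = None,
    windows: Sequence[str] = ("mRPF", "iRPF", "uRPF"),
    depth_threshold: float = 0,
    depth_comparison: str = ">",
    depth_window: str = "mRPF",
    fdr_max: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    reciprocity_min: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Full differential analysis of one contrast from a tidy count table.

    ``count_table`` is the output of ``build_count_table``; ``design`` maps
    sample ids to condition labels; ``size_factors`` are the multiply-up
    spike-in factors (converted internally to DESeq2-sense divisors).
    Returns per-window differential tables (with fdr and class), leaky
    calls, and the reciprocal-uAUG calls when the needed windows are
    present.
    """
    samples_a = [s for s, c in design.items() if c == cond_a]
    samples_b = [s for s, c in design.items() if c == cond_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each condition needs >=2 replicates")

    def wide(col: str) -> pd.DataFrame:
        return count_table[col].unstack("sample")

    raw = {w: wide(w) for w in windows}
    depth_counts = raw.get(depth_window, wide(depth_window))[samples_a + samples_b]
    retained = filter_by_depth(depth_counts, depth_threshold, depth_comparison)

    if size_factors is not None:
        divisors = 1.0 / size_factors
        divisors = divisors / np.exp(np.log(divisors).mean())
        sfa = divisors[samples_a].to_numpy()
        sfb = divisors[samples_b].to_numpy()
    else:
        sfa = sfb = None

    results: dict[str, pd.DataFrame] = {}
    for w in windows:
        sub = raw[w].loc[retained]
        res = nb_test(sub[samples_a], sub[samples_b], sfa, sfb)
        res["fdr"] = bh_fdr(res["pvalue"])
        res["class"] = classify(res["log2FoldChange"], res["fdr"], fdr_max, fc_up, fc_down)
        results[w] = res

    norm = {
        w: count_table[f"{w}_norm"].unstack("sample").loc[retained] for w in windows
    }
    deltas = {
        w: norm[w][samples_b].mean(axis=1) - norm[w][samples_a].mean(axis=1)
        for w in windows
    }
    out: dict[str, pd.DataFrame] = {f"diff_{w}": results[w] for w in windows}
    if "mRPF" in windows and "iRPF" in windows:
        out["leaky"] = leaky_scanning_calls(
            results["mRPF"], results["iRPF"], deltas["mRPF"], deltas["iRPF"],
            reciprocity_min,
        )
    if "mRPF" in windows and "uRPF" in windows:
        out["reciprocal_uaug"] = reciprocal_uaug_calls(
            results["uRPF"], results["mRPF"], deltas["uRPF"], deltas["mRPF"],
            reciprocity_min,
        )
    return out
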