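"""mRNA features: PARS interval scores, start-codon context, binned summaries.

PARS (parallel analysis of RNA structure) assigns each nucleotide a score
whose higher values indicate greater double-stranded propensity.  Interval
summaries condense a transcript's track into: the summed 5'UTR score
(total), the best 30 nt window within the 5'UTR (Max30), the 30 nt
surrounding the main AUG (Start30, defined for 5'UTRs >= 15 nt), and the
sums over the first 15/30/45 CDS nt (Plus15/30/45).

The start-codon context score is a codon-adaptation-index-style geometric
mean over the nine nucleotides flanking an AUG (-6..-1 and +4..+6 in
start-codon-relative 1-based convention, i.e. excluding the AUG itself),
each weighted by its frequency among highly translated mRNAs relative to
the most frequent base at that position.  A perfect consensus scores 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from recseq.annotation_io import ParsTrack, TranscriptModel

CONTEXT_OFFSETS = (-6, -5, -4, -3, -2, -1, 4, 5, 6)


@dataclass
class ParsIntervalScores:
    transcript_id: str
    total_pars: float
    max30: float
    start30: float | None
    plus15: float
    plus30: float
    plus45: float


def pars_intervals(track: ParsTrack, transcript: TranscriptModel) -> ParsIntervalScores:
    """Interval PARS scores for one transcript.

    Max30 scans every 30 nt window fully inside the 5'UTR (start positions
    0..utr5_len-30); for 5'UTRs shorter than 30 nt it falls back to the
    total 5'UTR score.  Start30 covers [mAUG-15, mAUG+14] and is absent
    for 5'UTRs shorter than 15 nt.  PlusN windows are anchored at the A of
    the main AUG.
    """
    scores = np.asarray(track.scores, dtype=float)
    if len(scores) != len(transcript):
        raise ValueError(
            f"{transcript.transcript_id}: PARS track length {len(scores)} "
            f"!= sequence length {len(transcript)}"
        )
    u = transcript.utr5_len
    m = transcript.main_aug
    total = float(scores[:u].sum())
    if u >= 30:
        windows = np.convolve(scores[:u], np.ones(30), mode="valid")
        max30 = float(windows.max())
    else:
        max30 = total
    start30 = float(scores[m - 15 : m + 15].sum()) if u >= 15 else None
    return ParsIntervalScores(
        transcript_id=transcript.transcript_id,
        total_pars=total,
        max30=max30,
        start30=start30,
        plus15=float(scores[m : m + 15].sum()),
        plus30=float(scores[m : m + 30].sum()),
        plus45=float(scores[m : m + 45].sum()),
    )


def read_pfm(path: str | Path) -> pd.DataFrame:
    """Read a context position-frequency matrix (TSV, offset + A/C/G/T)."""
    pfm = pd.read_csv(path, sep="\t", index_col=0)
    if list(pfm.columns) != list("ACGT"):
        pfm = pfm[list("ACGT")]
    if (pfm.to_numpy() <= 0).any():
        raise ValueError("PFM frequencies must be strictly positive")
    return pfm


def context_score(
    sequence: str, aug_pos: int, pfm: pd.DataFrame
) -> float | None:
    """AUG context adaptation index against a position-frequency matrix.

    The score is the geometric mean over the nine context positions of
    w(b,i) = f(b,i) / max_b' f(b',i).  Returns ``None`` when the context
    window runs past either end of the transcript (which also covers the
    5'UTR > 5 nt requirement for main AUGs) or contains a non-ACGT base.
    """
    if aug_pos < 6 or aug_pos + 6 > len(sequence):
        return None
    weights = pfm.div(pfm.max(axis=1), axis=0)
    log_sum = 0.0
    for row, off in enumerate(CONTEXT_OFFSETS):
        delta = off if off < 0 else off - 1  # 1-based offsets skip the A at +1
        base = sequence[aug_pos + delta]
        if base not in "ACGT":
            return None
        log_sum += math.log(weights.iloc[row][base])
    return math.exp(log_sum / len(CONTEXT_OFFSETS))


def equal_count_bins(values: pd.Series, n_bins: int) -> pd.Series:
    """Assign transcripts to contiguous equal-count bins of a sorted metric.

    Transcripts are sorted ascending by value with ties broken by id, then
    split into ``n_bins`` contiguous groups whose sizes differ by at most
    one (larger bins first).  Returns a Series of bin indices 0..n_bins-1.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    values = values.dropna()
    if len(values) < n_bins:
        raise ValueError(f"cannot split {len(values)} values into {n_bins} bins")
    order = values.to_frame("v").reset_index()
    id_col = order.columns[0]
    order = order.sort_values(["v", id_col], kind="stable")
    ids = order[id_col].to_numpy()
    assignment = np.concatenate(
        [np.full(len(chunk), i) for i, chunk in enumerate(np.array_split(ids, n_bins))]
    )
    return pd.Series(assignment, index=ids, name="bin").sort_index()


def binned_summary(
    bins: pd.Series, metric: pd.Series, log2: bool = False
) -> pd.DataFrame:
    """Per-bin mean, median, quartiles, and extremes of a metric.

    Transcripts with an absent metric are excluded listwise.  With
    ``log2=True`` the metric is log2-transformed first (used for fold-
    change metrics, mirroring log-scaled axes).
    """
    df = pd.concat([bins.rename("bin"), metric.rename("metric")], axis=1, join="inner")
    df = df.dropna()
    if log2:
        df["metric"] = np.log2(df["metric"])
    out = df.groupby("bin")["metric"].agg(
        n="count",
        mean="mean",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        min="min",
        max="max",
    )
    return out


def feature_table(
    transcripts, tracks: dict[str, ParsTrack], pfm: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-transcript feature frame: lengths, PARS intervals, context score.

    Transcripts without a PARS track get NaN interval scores; main-AUG
    context scores require a 5'UTR longer than 5 nt.
    """
    rows = []
    for t in transcripts:
        if t.is_spike_in:
            continue
        row: dict = {
            "transcript_id": t.transcript_id,
            "utr5_len": t.utr5_len,
            "cds_len": t.cds_len,
            "n_internal_augs": len(t.internal_augs),
            "n_upstream_augs": len(t.upstream_augs),
        }
        if t.transcript_id in tracks:
            ps = pars_intervals(tracks[t.transcript_id], t)
            row.update(
                total_pars=ps.total_pars,
                max30=ps.max30,
                start30=np.nan if ps.start30 is None else ps.start30,
                plus15=ps.plus15,
                plus30=ps.plus30,
                plus45=ps.plus45,
            )
        if pfm is not None:
            score = context_score(t.sequence, t.main_aug, pfm)
            row["context_score"] = np.nan if score is None else score
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")
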