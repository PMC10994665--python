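"""Window counting, spike-in normalization, RE/RRO, and metagene matrices.

Footprints are counted by P-site within the four windows (all endpoints
inclusive, transcript coordinates):

====== ==========================================
mRPF   [mAUG-3, mAUG+6]
iRPF   [mAUG+9, last nt of the stop codon]
cdsRPF [mAUG,   last nt of the stop codon]
uRPF   [0,      mAUG-5]
====== ==========================================

A read contributes to every window containing its P-site, so windows are
counted independently; positions mAUG+7 and mAUG+8 belong to the CDS
window only.

Between-sample normalization uses the spike-in transcripts: the geometric
mean of 25–34 nt read counts over every spike-in AUG site (the mAUG plus
each internal AUG, each in its own [-3,+6] window) gives one number per
sample, and all samples are multiplied up to the sample with the highest
geometric mean.  Recruitment efficiency (RE) is the normalized mRPF
divided by mRNA density (input RNA-seq reads per CDS nt); relative
ribosome occupancy (RRO) is iRPF/cdsRPF.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from recseq.annotation_io import AlignedFootprint, TranscriptModel

logger = logging.getLogger(__name__)

METAGENE_LENGTHS = range(25, 35)
METAGENE_POSITIONS = range(-50, 101)


class WindowCounts(NamedTuple):
    mRPF: int
    iRPF: int
    uRPF: int
    cdsRPF: int


def _p_sites(footprints: Iterable[AlignedFootprint | int]) -> np.ndarray:
    sites = []
    for fp in footprints:
        if isinstance(fp, (int, np.integer)):
            sites.append(int(fp))
        else:
            if fp.p_site is None:
                raise ValueError("footprint lacks a P-site; run assign_p_sites first")
            sites.append(fp.p_site)
    return np.asarray(sites, dtype=int)


def count_windows(
    footprints: Iterable[AlignedFootprint | int], transcript: TranscriptModel
) -> WindowCounts:
    """Count footprint P-sites in the mRPF/iRPF/uRPF/cdsRPF windows."""
    p = _p_sites(footprints)
    m = transcript.main_aug
    stop = transcript.stop_last
    if p.size == 0:
        return WindowCounts(0, 0, 0, 0)
    return WindowCounts(
        mRPF=int(((p >= m - 3) & (p <= m + 6)).sum()),
        iRPF=int(((p >= m + 9) & (p <= stop)).sum()),
        uRPF=int(((p >= 0) & (p <= m - 5)).sum()),
        cdsRPF=int(((p >= m) & (p <= stop)).sum()),
    )


@dataclass
class SizeFactorSet:
    """Per-sample spike-in geometric means and normalization factors.

    ``factors`` multiply raw counts up to the reference sample (the one
    with the highest spike-in geometric mean), so every factor is >= 1 and
    the reference sample's factor is exactly 1.
    """

    site_counts: pd.DataFrame  # rows (transcript_id, site), cols samples
    geometric_means: pd.Series
    factors: pd.Series

    def deseq_size_factors(self) -> pd.Series:
        """Factors converted to DESeq2-sense divisors, geometric mean 1."""
        s = 1.0 / self.factors
        return s / np.exp(np.log(s).mean())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "geometric_means": self.geometric_means.to_dict(),
            "factors": self.factors.to_dict(),
            "site_counts": {
                f"{tid}:{site}": row.to_dict()
                for (tid, site), row in self.site_counts.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def spike_in_site_counts(
    footprints_by_sample: Mapping[str, Sequence[AlignedFootprint]],
    spike_ins: Sequence[TranscriptModel],
    min_len: int = 25,
    max_len: int = 34,
) -> pd.DataFrame:
    """25–34 nt read counts per spike-in AUG site ([-3,+6] windows) per sample."""
    sites = [
        (sp.transcript_id, site)
        for sp in spike_ins
        for site in [sp.main_aug] + list(sp.internal_augs)
    ]
    index = pd.MultiIndex.from_tuples(sites, names=["transcript_id", "site"])
    counts = pd.DataFrame(0, index=index, columns=list(footprints_by_sample))
    spike_ids = {sp.transcript_id for sp in spike_ins}
    for sample, fps in footprints_by_sample.items():
        by_tid: dict[str, list[int]] = {}
        for fp in fps:
            if fp.transcript_id in spike_ids and min_len <= fp.length <= max_len:
                if fp.p_site is None:
                    raise ValueError("spike-in footprint lacks a P-site")
                by_tid.setdefault(fp.transcript_id, []).append(fp.p_site)
        for tid, site in sites:
            p = np.asarray(by_tid.get(tid, []), dtype=int)
            if p.size:
                counts.loc[(tid, site), sample] = int(
                    ((p >= site - 3) & (p <= site + 6)).sum()
                )
    return counts


def spike_in_size_factors(
    footprints_by_sample: Mapping[str, Sequence[AlignedFootprint]],
    spike_ins: Sequence[TranscriptModel],
    min_len: int = 25,
    max_len: int = 34,
) -> SizeFactorSet:
    """Geometric-mean spike-in size factors, referenced to the best sample.

    Sites with zero reads in a sample are excluded from that sample's
    geometric mean (no pseudocount is added).  A sample with zero reads at
    every spike-in site cannot be normalized and raises ``ValueError``.
    """
    site_counts = spike_in_site_counts(footprints_by_sample, spike_ins, min_len, max_len)
    gms = {}
    for sample in site_counts.columns:
        values = site_counts[sample].to_numpy(dtype=float)
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError(
                f"sample {sample!r} has no spike-in reads; normalization impossible"
            )
        gms[sample] = float(np.exp(np.mean(np.log(positive))))
    geometric_means = pd.Series(gms)
    factors = geometric_means.max() / geometric_means
    return SizeFactorSet(site_counts, geometric_means, factors)


def mrna_density(
    rna_reads: Iterable[AlignedFootprint | int], transcript: TranscriptModel
) -> tuple[int, float]:
    """Input RNA-seq reads with 5' end inside the CDS, and reads per CDS nt."""
    positions = []
    for r in rna_reads:
        positions.append(r if isinstance(r, (int, np.integer)) else r.five_prime_pos)
    p = np.asarray(positions, dtype=int)
    m, stop = transcript.main_aug, transcript.stop_last
    n = int(((p >= m) & (p <= stop)).sum()) if p.size else 0
    return n, n / transcript.cds_len


def recruitment_efficiency(norm_mrpf: float, density: float) -> float:
    """RE = normalized mRPF / mRNA density; NaN (absent) when density is 0."""
    if density == 0:
        return float("nan")
    return norm_mrpf / density


def metagene(
    footprints: Iterable[AlignedFootprint],
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """2D metagene: read length (25..34) x 5'-end position (-50..+100).

    Cell (L, d) counts reads of length L whose 5' end lies d nt from the
    main AUG, summed over transcripts.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.transcript_id: t for t in transcripts}
    mat = np.zeros((len(METAGENE_LENGTHS), len(METAGENE_POSITIONS)))
    for fp in footprints:
        t = transcripts.get(fp.transcript_id)
        if t is None or not (25 <= fp.length <= 34):
            continue
        d = fp.five_prime_pos - t.main_aug
        if -50 <= d <= 100:
            mat[fp.length - 25, d + 50] += 1
    return pd.DataFrame(
        mat, index=list(METAGENE_LENGTHS), columns=list(METAGENE_POSITIONS)
    )


def build_count_table(
    footprints_by_sample: Mapping[str, Sequence[AlignedFootprint]],
    transcripts: Sequence[TranscriptModel],
    size_factors: SizeFactorSet | None = None,
    rna_by_sample: Mapping[str, Sequence[AlignedFootprint]] | None = None,
) -> pd.DataFrame:
    """Per-transcript x per-sample window counts with normalization, RE, RRO.

    Spike-in transcripts are excluded from the table (they enter only
    through the size factors).  Rows are indexed by (transcript_id,
    sample); columns: raw mRPF/iRPF/uRPF/cdsRPF, their normalized
    counterparts, mrna_reads, mrna_density, RE, RRO.  RE is NaN where
    mRNA density is zero or no RNA data were supplied; RRO is NaN where
    cdsRPF is zero.
    """
    natives = [t for t in transcripts if not t.is_spike_in]
    by_id = {t.transcript_id: t for t in natives}
    rows = []
    for sample, fps in footprints_by_sample.items():
        factor = float(size_factors.factors[sample]) if size_factors is not None else 1.0
        psites: dict[str, list[int]] = {}
        for fp in fps:
            if fp.transcript_id in by_id:
                psites.setdefault(fp.transcript_id, []).append(fp.p_site)
        rna_pos: dict[str, list[int]] = {}
        if rna_by_sample is not None:
            for r in rna_by_sample.get(sample, []):
                if r.transcript_id in by_id:
                    rna_pos.setdefault(r.transcript_id, []).append(r.five_prime_pos)
        for t in natives:
            wc = count_windows(psites.get(t.transcript_id, []), t)
            if rna_by_sample is not None:
                n_rna, density = mrna_density(rna_pos.get(t.transcript_id, []), t)
            else:
                n_rna, density = 0, float("nan")
            norm_m = wc.mRPF * factor
            re = recruitment_efficiency(norm_m, density) if density == density else float("nan")
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "sample": sample,
                    "mRPF": wc.mRPF,
                    "iRPF": wc.iRPF,
                    "uRPF": wc.uRPF,
                    "cdsRPF": wc.cdsRPF,
                    "mRPF_norm": norm_m,
                    "iRPF_norm": wc.iRPF * factor,
                    "uRPF_norm": wc.uRPF * factor,
                    "cdsRPF_norm": wc.cdsRPF * factor,
                    "mrna_reads": n_rna,
                    "mrna_density": density,
                    "RE": re,
                    "RRO": wc.iRPF / wc.cdsRPF if wc.cdsRPF > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows).set_index(["transcript_id", "sample"])


def ratio_summaries(
    count_table: pd.DataFrame,
    urpf_exclusions: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-sample translatome ratios: iRPF/cdsRPF and uRPF/mRPF.

    ``urpf_exclusions`` removes transcripts (e.g. a GCN4-like outlier that
    dominates 5'UTR footprints) from both numerator and denominator of the
    uRPF/mRPF ratio only.  Returns one row per sample plus a "mean" row
    with the arithmetic mean of the per-sample ratios.
    """
    excl = set(urpf_exclusions)
    rows = {}
    for sample, sub in count_table.groupby(level="sample"):
        irpf_ratio = (
            sub["iRPF"].sum() / sub["cdsRPF"].sum() if sub["cdsRPF"].sum() > 0 else float("nan")
        )
        keep = ~sub.index.get_level_values("transcript_id").isin(excl)
        usub = sub[keep]
        if usub["mRPF"].sum() > 0:
            urpf_ratio = usub["uRPF"].sum() / usub["mRPF"].sum()
        else:
            logger.warning("sample %s: zero mRPF denominator for uRPF ratio", sample)
            urpf_ratio = float("nan")
        rows[sample] = {"irpf_cdsrpf_ratio": irpf_ratio, "urpf_mrpf_ratio": urpf_ratio}
    out = pd.DataFrame(rows).T
    out.loc["mean"] = out.mean()
    out.index.name = "sample"
    return out
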