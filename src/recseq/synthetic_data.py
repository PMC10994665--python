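"""Synthetic Rec-Seq study generator with known ground truth.

Emulates the sequencing inputs of a 48S recruitment experiment at desk
scale: a toy transcriptome, two spike-in transcripts carrying one main and
many internal AUGs (at a roughly 1:10 molar ratio), barcoded 25–34 nt
footprint reads whose 5' ends sit ~12 nt upstream of occupied AUG codons,
input RNA-seq fragments of 50–90 nt, a multi-replicate two-condition
design, and negative-binomial count noise.  Ground truth (per-transcript
recruitment rates, planted leaky-scanning flags, per-sample library
scales) is written alongside the reads so every downstream stage can be
scored against what was planted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from recseq.annotation_io import ParsTrack, TranscriptModel

logger = logging.getLogger(__name__)

LINKER = "AGATCGGAAGAGCAC"
BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the standard desk-scale experiment: 200 transcripts,
    two conditions (a control reaction and one with added helicase) with
    three replicates each, ~2x10^5 footprint reads per library at unit
    scale, 10% of transcripts planted as leaky-scanning responders and 30%
    as helicase-responsive via a 5'UTR "structure burden" whose recruitment
    suppression the helicase relieves.
    """

    n_transcripts: int = 200
    utr5_len_range: tuple[int, int] = (15, 150)
    cds_len_range: tuple[int, int] = (300, 900)
    utr3_len: int = 50
    read_length_range: tuple[int, int] = (25, 34)
    p_site_offset_truth: int = 12
    # 5'-end jitter: a minority of footprints protect one nt more or fewer
    jitter: dict[int, float] | None = field(
        default_factory=lambda: {0: 0.8, -1: 0.1, 1: 0.1}
    )
    conditions: tuple[str, str] = ("ctrl", "helicase")
    n_replicates: int = 3
    fraction_leaky: float = 0.10
    fraction_responsive: float = 0.30
    structure_effect: float = 0.30  # log2 recruitment suppression per burden unit
    burden_range: tuple[float, float] = (0.0, 10.0)
    leaky_down_factor: float = 0.25  # helicase mAUG rate relative to control
    leaky_internal_gain: float = 0.8  # fraction of the mAUG loss moved to the iAUG
    internal_frac: float = 0.10  # baseline iAUG rate relative to mAUG
    upstream_frac: float = 0.0025  # baseline uAUG rate relative to mAUG
    mean_recruitment: float = 550.0  # reads per library at unit scale (lognormal median)
    recruitment_sigma: float = 1.0
    abundance_sigma: float = 0.8
    dispersion_mean: float = 0.05
    dispersion_shape: float = 4.0
    spike_total_rate: float = 10000.0
    spike_molar_ratio: float = 0.1  # first spike-in : second, ~1:10
    spike_dispersion: float = 0.005
    n_rna_reads: int = 50000
    rna_frag_range: tuple[int, int] = (50, 90)
    library_scale_range: tuple[float, float] = (0.6, 1.4)

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("differential testing needs >=2 replicates per condition")
        for frac in (self.fraction_leaky, self.fraction_responsive):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if self.jitter is not None and abs(sum(self.jitter.values()) - 1.0) > 1e-9:
            raise ValueError("jitter probabilities must sum to 1")
        if self.utr5_len_range[0] > self.utr5_len_range[1]:
            raise ValueError("infeasible utr5 length range")
        if self.cds_len_range[0] > self.cds_len_range[1] or self.cds_len_range[0] < 9:
            raise ValueError("infeasible CDS length range")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study.

    ``transcripts`` has one row per non-spike transcript with the planted
    rates per condition (``rate_m_<cond>``, ``rate_i_<cond>``,
    ``rate_u_<cond>``, reads per library at unit scale), abundance,
    structure burden, leaky/responsive flags, NB dispersion, and the chosen
    internal/upstream AUG coordinates.  ``samples`` has one row per sample
    with condition, replicate, barcode, and library scale.  ``spike_sites``
    maps each spike-in AUG site to its condition-independent rate.
    """

    transcripts: pd.DataFrame
    samples: pd.DataFrame
    spike_sites: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, size=n)])


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = list(motif)


def simulate_transcriptome(
    config: SimConfig, seed: int | np.random.Generator
) -> tuple[list[TranscriptModel], dict[str, ParsTrack], pd.DataFrame]:
    """Generate random transcripts, spike-ins, and matching PARS tracks.

    Every transcript has an ATG at ``cds_start``, an in-frame stop ending
    at ``cds_end``, one guaranteed internal AUG near the middle of the CDS,
    and (when the 5'UTR is long enough) one guaranteed upstream AUG.  The
    PARS track of each transcript sums over the 5'UTR to its planted
    structure burden, concentrated in a single 30 nt window so the Max30
    statistic recovers the burden.

    Returns (transcripts incl. spike-ins, PARS tracks, per-transcript frame
    with burden and planted site coordinates).
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    transcripts: list[TranscriptModel] = []
    rows = []
    tracks: dict[str, ParsTrack] = {}
    width = len(str(max(config.n_transcripts - 1, 1)))
    for i in range(config.n_transcripts):
        tid = f"SYN{i:0{width}d}"
        utr5 = int(rng.integers(config.utr5_len_range[0], config.utr5_len_range[1] + 1))
        cds = int(rng.integers(config.cds_len_range[0] // 3, config.cds_len_range[1] // 3 + 1)) * 3
        total = utr5 + cds + config.utr3_len
        seq = _random_seq(rng, total)
        _plant(seq, utr5, "ATG")
        _plant(seq, utr5 + cds - 3, "TAA")
        # guaranteed internal AUG near the middle of the CDS (any frame)
        iaug = utr5 + cds // 2 + int(rng.integers(0, 3))
        _plant(seq, iaug, "ATG")
        # guaranteed upstream AUG far enough from both ends for clean footprints
        uaug = -1
        if utr5 >= 19:
            uaug = int(min(utr5 - 6, max(13, utr5 // 2)))
            _plant(seq, uaug, "ATG")
        model = TranscriptModel.from_annotation(tid, "".join(seq), utr5, cds)
        transcripts.append(model)
        burden = float(rng.uniform(*config.burden_range))
        scores = np.zeros(total)
        if utr5 >= 30:
            w = int(rng.integers(0, utr5 - 30 + 1))
            scores[w : w + 30] = burden / 30.0
        elif utr5 > 0:
            scores[:utr5] = burden / utr5
        tracks[tid] = ParsTrack(tid, scores)
        rows.append({"transcript_id": tid, "burden": burden, "iaug": iaug, "uaug": uaug})
    transcripts.extend(make_spike_ins(rng))
    return transcripts, tracks, pd.DataFrame(rows).set_index("transcript_id")


def make_spike_ins(rng: np.random.Generator) -> list[TranscriptModel]:
    """Two spike-in transcripts with one main and many internal AUGs each."""
    spikes = []
    for name, n_internal in (("SPIKE_FLUC", 12), ("SPIKE_RLUC", 12)):
        utr5, spacing = 60, 45
        cds = spacing * (n_internal + 1) + 3
        seq = _random_seq(rng, utr5 + cds + 50)
        _plant(seq, utr5, "ATG")
        _plant(seq, utr5 + cds - 3, "TAA")
        for k in range(1, n_internal + 1):
            _plant(seq, utr5 + spacing * k + k % 3, "ATG")
        spikes.append(
            TranscriptModel.from_annotation(name, "".join(seq), utr5, cds, is_spike_in=True)
        )
    return spikes


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def simulate_truth(
    transcripts: Sequence[TranscriptModel],
    planted: pd.DataFrame,
    config: SimConfig,
    seed: int | np.random.Generator,
) -> SimulationTruth:
    """Draw per-transcript rates, flags, and per-sample library scales."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cond_a, cond_b = config.conditions
    natives = [t for t in transcripts if not t.is_spike_in]
    n = len(natives)
    base = rng.lognormal(np.log(config.mean_recruitment), config.recruitment_sigma, n)
    abundance = rng.lognormal(0.0, config.abundance_sigma, n)
    dispersion = rng.gamma(
        config.dispersion_shape, config.dispersion_mean / config.dispersion_shape, n
    )
    order = rng.permutation(n)
    n_leaky = int(round(config.fraction_leaky * n))
    n_resp = int(round(config.fraction_responsive * n))
    leaky = np.zeros(n, bool)
    responsive = np.zeros(n, bool)
    leaky[order[:n_leaky]] = True
    responsive[order[n_leaky : n_leaky + n_resp]] = True

    rows = []
    for j, t in enumerate(natives):
        burden = planted.loc[t.transcript_id, "burden"]
        # control reaction: structured 5'UTRs suppress recruitment
        rate_m_a = base[j] * 2 ** (-config.structure_effect * burden)
        if leaky[j]:
            rate_m_b = config.leaky_down_factor * rate_m_a
        elif responsive[j]:
            rate_m_b = base[j]  # helicase relieves the structure suppression
        else:
            rate_m_b = rate_m_a
        rate_i_a = config.internal_frac * rate_m_a
        rate_i_b = config.internal_frac * rate_m_b
        if leaky[j]:
            rate_i_b = rate_i_a + config.leaky_internal_gain * (rate_m_a - rate_m_b)
        has_u = planted.loc[t.transcript_id, "uaug"] >= 0
        rate_u_a = config.upstream_frac * rate_m_a if has_u else 0.0
        rate_u_b = config.upstream_frac * rate_m_b if has_u else 0.0
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "abundance": abundance[j],
                "burden": burden,
                "leaky": bool(leaky[j]),
                "responsive": bool(responsive[j]),
                "nb_dispersion": dispersion[j],
                "iaug": int(planted.loc[t.transcript_id, "iaug"]),
                "uaug": int(planted.loc[t.transcript_id, "uaug"]),
                f"rate_m_{cond_a}": rate_m_a,
                f"rate_m_{cond_b}": rate_m_b,
                f"rate_i_{cond_a}": rate_i_a,
                f"rate_i_{cond_b}": rate_i_b,
                f"rate_u_{cond_a}": rate_u_a,
                f"rate_u_{cond_b}": rate_u_b,
            }
        )
    truth_tx = pd.DataFrame(rows).set_index("transcript_id")

    barcodes = _make_barcodes(rng, len(config.conditions) * config.n_replicates)
    sample_rows = []
    k = 0
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            sample_rows.append(
                {
                    "sample_id": f"{cond}_{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "barcode": barcodes[k],
                    "library_scale": float(rng.uniform(*config.library_scale_range)),
                }
            )
            k += 1
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # spike-in sites: condition-independent rates (spike-ins are added to
    # every reaction in constant amount), split ~1:10 between the two
    # spike-ins and spread over each one's mAUG + internal AUGs
    spikes = [t for t in transcripts if t.is_spike_in]
    weights = {
        spikes[0].transcript_id: config.spike_molar_ratio / (1 + config.spike_molar_ratio),
        spikes[1].transcript_id: 1 / (1 + config.spike_molar_ratio),
    }
    site_rows = []
    for sp in spikes:
        sites = [sp.main_aug] + list(sp.internal_augs)
        site_w = rng.dirichlet(np.full(len(sites), 20.0))
        for pos, w in zip(sites, site_w):
            site_rows.append(
                {
                    "transcript_id": sp.transcript_id,
                    "site": int(pos),
                    "rate": config.spike_total_rate * weights[sp.transcript_id] * float(w),
                }
            )
    spike_sites = pd.DataFrame(site_rows)
    seed_val = int(seed) if not isinstance(seed, np.random.Generator) else -1
    return SimulationTruth(truth_tx, samples, spike_sites, seed_val)


def _make_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    barcodes: list[str] = []
    while len(barcodes) < n:
        bc = "".join(BASES[rng.integers(0, 4, size=5)])
        if bc not in barcodes and all(_hamming(bc, other) >= 2 for other in barcodes):
            barcodes.append(bc)
    return barcodes


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(
    rng: np.random.Generator, mean: float, dispersion: float
) -> int:
    """One NB draw with var = mean + dispersion * mean^2 (Poisson as limit)."""
    if mean <= 0:
        return 0
    if dispersion < 1e-8:
        return int(rng.poisson(mean))
    size = 1.0 / dispersion
    return int(rng.negative_binomial(size, size / (size + mean)))


def simulate_counts(
    truth: SimulationTruth,
    config: SimConfig,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw per-site, per-sample footprint counts.

    Rows are indexed by (transcript_id, site_kind, site); columns are
    sample ids.  Counts are negative-binomial with mean = rate x
    library_scale.  Spike-in sites use condition-independent rates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[tuple[str, str, int]] = []
    rates: list[tuple[float, float]] = []  # (rate per condition col lookup later)
    dispersions: list[float] = []
    per_cond_rates: list[dict[str, float]] = []
    for tid, row in truth.transcripts.iterrows():
        for kind, site_col, rate_prefix in (
            ("mAUG", None, "rate_m"),
            ("iAUG", "iaug", "rate_i"),
            ("uAUG", "uaug", "rate_u"),
        ):
            site = int(row[site_col]) if site_col else -2
            if site_col and site < 0:
                continue
            rows.append((tid, kind, site))
            per_cond_rates.append(
                {cond: row[f"{rate_prefix}_{cond}"] for cond in config.conditions}
            )
            dispersions.append(row["nb_dispersion"])
    for _, srow in truth.spike_sites.iterrows():
        rows.append((srow["transcript_id"], "spike", int(srow["site"])))
        per_cond_rates.append({cond: srow["rate"] for cond in config.conditions})
        dispersions.append(config.spike_dispersion)

    data = {}
    for sample_id, srow in truth.samples.iterrows():
        scale = srow["library_scale"]
        cond = srow["condition"]
        data[sample_id] = [
            _nb_draw(rng, r[cond] * scale, d)
            for r, d in zip(per_cond_rates, dispersions)
        ]
    index = pd.MultiIndex.from_tuples(rows, names=["transcript_id", "site_kind", "site"])
    return pd.DataFrame(data, index=index)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def emit_reads(
    counts: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    truth: SimulationTruth,
    config: SimConfig,
    seed: int | np.random.Generator,
    footprint_fastq: str | Path,
    rna_fastq_dir: str | Path,
) -> dict:
    """Write the barcoded footprint FASTQ and per-sample input-RNA FASTQs.

    Each footprint read is the transcript substring of a random length in
    the configured window whose 5' end lies ``p_site_offset_truth`` nt
    upstream of the occupied codon's A (plus jitter), suffixed by the 5 nt
    sample barcode and the constant linker.  Input RNA reads are 50–90 nt
    fragments sampled over transcripts with abundance weights.  Returns a
    small report (reads emitted, truncations at the 5' end).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_id = {t.transcript_id: t for t in transcripts}
    lmin, lmax = config.read_length_range
    if config.jitter:
        jit_vals = np.array(sorted(config.jitter))
        jit_p = np.array([config.jitter[v] for v in jit_vals])
    else:
        jit_vals, jit_p = np.array([0]), np.array([1.0])
    truncated = 0
    emitted = 0
    rna_dir = Path(rna_fastq_dir)
    rna_dir.mkdir(parents=True, exist_ok=True)
    with open(footprint_fastq, "w") as fq:
        for (tid, _kind, site), row in counts.iterrows():
            seq = by_id[tid].sequence
            mAUG = by_id[tid].main_aug
            site_pos = mAUG if site == -2 else site
            for sample_id, count in row.items():
                if count == 0:
                    continue
                barcode = truth.samples.loc[sample_id, "barcode"]
                lengths = rng.integers(lmin, lmax + 1, size=count)
                jitters = rng.choice(jit_vals, size=count, p=jit_p)
                for length, jit in zip(lengths, jitters):
                    start = site_pos - config.p_site_offset_truth + int(jit)
                    if start < 0:
                        truncated += 1
                        start = 0
                    insert = seq[start : start + int(length)]
                    emitted += 1
                    fq.write(
                        f"@fp{emitted}\n{insert}{barcode}{LINKER}\n+\n"
                        f"{'I' * (len(insert) + 5 + len(LINKER))}\n"
                    )
    # input RNA: fragments over non-spike transcripts, weight = abundance x length
    natives = [t for t in transcripts if not t.is_spike_in]
    weights = np.array(
        [truth.transcripts.loc[t.transcript_id, "abundance"] * len(t) for t in natives]
    )
    weights = weights / weights.sum()
    fmin, fmax = config.rna_frag_range
    rna_files = {}
    for sample_id in truth.samples.index:
        path = rna_dir / f"rna_{sample_id}.fastq"
        rna_files[sample_id] = path
        picks = rng.choice(len(natives), size=config.n_rna_reads, p=weights)
        with open(path, "w") as fq:
            for i, k in enumerate(picks):
                t = natives[k]
                frag = int(rng.integers(fmin, min(fmax, len(t) - 1) + 1))
                start = int(rng.integers(0, len(t) - frag + 1))
                fq.write(
                    f"@rna{i} {t.transcript_id}\n{t.sequence[start:start + frag]}\n+\n"
                    f"{'I' * frag}\n"
                )
    if truncated:
        logger.info("%d footprint reads truncated at the transcript 5' end", truncated)
    return {
        "footprint_reads": emitted,
        "truncated_5p": truncated,
        "rna_files": {k: str(v) for k, v in rna_files.items()},
    }


def toy_pfm(favored: str = "AAAAAATCA", strength: float = 0.55) -> pd.DataFrame:
    """A toy position-frequency matrix over the 9 context positions.

    Rows are the context offsets (-6..-1 upstream of the AUG and +4..+6
    just downstream, in start-codon-relative 1-based convention); columns
    A/C/G/T.  The favored base at each position gets ``strength``, the rest
    share the remainder.
    """
    offsets = [-6, -5, -4, -3, -2, -1, 4, 5, 6]
    rest = (1.0 - strength) / 3.0
    rows = []
    for off, base in zip(offsets, favored):
        rows.append(
            {"offset": off, **{b: (strength if b == base else rest) for b in "ACGT"}}
        )
    return pd.DataFrame(rows).set_index("offset")


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

def simulate_study(
    config: SimConfig, seed: int, outdir: str | Path
) -> tuple[dict[str, Path], SimulationTruth]:
    """Generate a complete synthetic study into ``outdir``.

    Writes the transcriptome FASTA (+ spike-ins), annotation TSV, PARS
    tracks, toy context PFM, the mixed barcoded footprint FASTQ, per-sample
    input RNA FASTQs, the sample sheet, and the ground-truth tables.  All
    randomness flows from ``seed`` via one splittable generator; re-running
    with the same seed reproduces every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    rngs = root.spawn(4)
    transcripts, tracks, planted = simulate_transcriptome(config, rngs[0])
    truth = simulate_truth(transcripts, planted, config, rngs[1])
    truth.seed = seed
    counts = simulate_counts(truth, config, rngs[2])
    paths: dict[str, Path] = {
        "fasta": outdir / "transcriptome.fasta",
        "annotation": outdir / "annotation.tsv",
        "pars": outdir / "pars.tsv",
        "pfm": outdir / "pfm.tsv",
        "footprints": outdir / "footprints.fastq",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "truth_transcripts": outdir / "truth_transcripts.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "emitted_counts": outdir / "emitted_counts.tsv",
        "config": outdir / "sim_config.yaml",
        "rna_dir": outdir,
    }
    with open(paths["fasta"], "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n{t.sequence}\n")
    with open(paths["annotation"], "w") as fh:
        fh.write("transcript_id\tutr5_len\tcds_len\tis_spike_in\n")
        for t in transcripts:
            fh.write(f"{t.transcript_id}\t{t.utr5_len}\t{t.cds_len}\t{int(t.is_spike_in)}\n")
    from recseq.annotation_io import write_pars_tracks

    write_pars_tracks(tracks, paths["pars"])
    toy_pfm().to_csv(paths["pfm"], sep="\t")
    report = emit_reads(
        counts, transcripts, truth, config, rngs[3], paths["footprints"], outdir
    )
    truth.samples.to_csv(paths["sample_sheet"], sep="\t")
    truth.transcripts.to_csv(paths["truth_transcripts"], sep="\t")
    truth.samples.to_csv(paths["truth_samples"], sep="\t")
    counts.to_csv(paths["emitted_counts"], sep="\t")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {"seed": seed, "report": report, "config": {k: _yamlable(v) for k, v in vars(config).items()}},
            fh,
        )
    return paths, truth


def _yamlable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, dict):
        return {int(k): float(val) for k, val in v.items()}
    return v
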