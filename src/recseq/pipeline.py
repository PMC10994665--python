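"""End-to-end orchestration: one config in, a reproducible output bundle out.

Stages: read processing (demultiplex/trim/map/P-site), spike-in size
factors, window counting and normalization, metagene matrix, wiggle
tracks, translatome ratio summaries, differential contrasts with leaky-
scanning calls, RE/RRO ratio tests, and feature binning.  Every output is
an addressable TSV/JSON file and a manifest records the seed, the config
digest, and the SHA-256 of every output, so identical inputs and seed
give byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from recseq import __version__
from recseq.annotation_io import (
    footprint_coverage,
    read_pars_tracks,
    read_transcriptome,
    write_wiggle,
)
from recseq.differential import ratio_change_test, run_contrast
from recseq.features import (
    binned_summary,
    equal_count_bins,
    feature_table,
    read_pfm,
)
from recseq.quantification import (
    build_count_table,
    metagene,
    ratio_summaries,
    spike_in_size_factors,
)
from recseq.read_processing import (
    SampleSheet,
    TranscriptomeIndex,
    map_rna_fastq,
    process_fastq,
)

logger = logging.getLogger(__name__)

BINNABLE_FEATURES = ("utr5_len", "cds_len", "max30", "total_pars", "context_score")


@dataclass
class PipelineConfig:
    """Paths, design, and thresholds for one pipeline run."""

    footprints_fastq: str
    transcriptome: str
    annotation: str
    sample_sheet: str
    outdir: str
    rna_fastq: dict[str, str] = field(default_factory=dict)
    pars: str | None = None
    pfm: str | None = None
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    p_site_offset: int = 12
    min_len: int = 25
    max_len: int = 34
    max_mismatches: int = 0
    depth_threshold: float = 0
    depth_comparison: str = ">"
    fdr_max: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    reciprocity_min: float = 0.5
    n_bins: int = 6
    urpf_exclusions: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["contrasts"] = [tuple(c) for c in raw.get("contrasts", [])]
        return cls(**raw)

    def validate(self, design: pd.DataFrame) -> None:
        for cond_a, cond_b in self.contrasts:
            for cond in (cond_a, cond_b):
                n = (design["condition"] == cond).sum()
                if n < 2:
                    raise ValueError(
                        f"contrast {cond_a} vs {cond_b}: condition {cond!r} has "
                        f"{n} replicates; need >=2"
                    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a name -> path map of the output bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    design = pd.read_csv(config.sample_sheet, sep="\t").set_index("sample_id")
    config.validate(design)
    transcripts = read_transcriptome(config.transcriptome, config.annotation)
    spikes = [t for t in transcripts if t.is_spike_in]
    sheet = SampleSheet(
        barcodes=design["barcode"].to_dict(),
        min_len=config.min_len,
        max_len=config.max_len,
    )

    logger.info("stage process: demultiplex/map/assign %s", config.footprints_fastq)
    footprints, report = process_fastq(
        config.footprints_fastq,
        sheet,
        transcripts,
        offset=config.p_site_offset,
        max_mismatches=config.max_mismatches,
    )
    outputs["processing_report"] = outdir / "processing_report.json"
    report.to_json(outputs["processing_report"])
    if not report.conserved():
        raise RuntimeError("stage process: read accounting does not reconcile")

    logger.info("stage normalize: spike-in size factors")
    if not spikes:
        raise RuntimeError("stage normalize: no spike-in transcripts annotated")
    sf = spike_in_size_factors(footprints, spikes, config.min_len, config.max_len)
    outputs["size_factors"] = outdir / "size_factors.json"
    sf.to_json(outputs["size_factors"])

    rna_by_sample = None
    if config.rna_fastq:
        logger.info("stage rna: mapping %d input RNA libraries", len(config.rna_fastq))
        index = TranscriptomeIndex(transcripts)
        rna_by_sample = {
            sample: map_rna_fastq(path, index, sample_id=sample)
            for sample, path in config.rna_fastq.items()
        }

    logger.info("stage quantify: window counts and RE/RRO")
    counts = build_count_table(footprints, transcripts, sf, rna_by_sample)
    outputs["counts"] = outdir / "counts.tsv"
    counts.to_csv(outputs["counts"], sep="\t")

    natives = [t for t in transcripts if not t.is_spike_in]
    mg = metagene([fp for fps in footprints.values() for fp in fps], natives)
    outputs["metagene"] = outdir / "metagene.tsv"
    mg.to_csv(outputs["metagene"], sep="\t")

    for sample, fps in footprints.items():
        track = footprint_coverage(fps)
        factor = float(sf.factors[sample])
        scaled = {
            tid: {pos: c * factor for pos, c in positions.items()}
            for tid, positions in track.items()
        }
        path = outdir / f"{sample}.wig"
        write_wiggle(scaled, path, name=sample)
        outputs[f"wiggle_{sample}"] = path

    ratios = ratio_summaries(counts, urpf_exclusions=config.urpf_exclusions)
    outputs["ratios"] = outdir / "ratio_summaries.tsv"
    ratios.to_csv(outputs["ratios"], sep="\t")

    features = None
    if config.pars or config.pfm:
        tracks = read_pars_tracks(config.pars, transcripts) if config.pars else {}
        pfm = read_pfm(config.pfm) if config.pfm else None
        features = feature_table(transcripts, tracks, pfm)
        outputs["features"] = outdir / "features.tsv"
        features.to_csv(outputs["features"], sep="\t")

    rng = np.random.default_rng(config.seed)
    for cond_a, cond_b in config.contrasts:
        tag = f"{cond_b}_vs_{cond_a}"
        logger.info("stage diff: contrast %s", tag)
        res = run_contrast(
            counts,
            design["condition"].to_dict(),
            cond_a,
            cond_b,
            size_factors=sf.factors,
            depth_threshold=config.depth_threshold,
            depth_comparison=config.depth_comparison,
            fdr_max=config.fdr_max,
            fc_up=config.fc_up,
            fc_down=config.fc_down,
            reciprocity_min=config.reciprocity_min,
        )
        for name, frame in res.items():
            path = outdir / f"{name}_{tag}.tsv"
            frame.to_csv(path, sep="\t")
            outputs[f"{name}_{tag}"] = path

        ratio_rows = []
        samples_a = design.index[design["condition"] == cond_a]
        samples_b = design.index[design["condition"] == cond_b]
        for metric in ("RE", "RRO"):
            wideview = counts[metric].unstack("sample")
            for tid, row in wideview.iterrows():
                est, p = ratio_change_test(
                    row[samples_a].to_numpy(),
                    row[samples_b].to_numpy(),
                    seed=rng,
                )
                if est == est:
                    ratio_rows.append(
                        {"transcript_id": tid, "metric": metric, "log2_change": est, "p": p}
                    )
        if ratio_rows:
            path = outdir / f"ratio_tests_{tag}.tsv"
            pd.DataFrame(ratio_rows).to_csv(path, sep="\t", index=False)
            outputs[f"ratio_tests_{tag}"] = path

        if features is not None:
            re_wide = counts["RE"].unstack("sample")
            delta_re = re_wide[samples_b].mean(axis=1) / re_wide[samples_a].mean(axis=1)
            summaries = []
            for feat in BINNABLE_FEATURES:
                if feat not in features.columns:
                    continue
                values = features[feat].dropna()
                if len(values) < config.n_bins:
                    continue
                bins = equal_count_bins(values, config.n_bins)
                summary = binned_summary(bins, delta_re, log2=True)
                summary.insert(0, "feature", feat)
                summaries.append(summary.reset_index())
            if summaries:
                path = outdir / f"feature_bins_{tag}.tsv"
                pd.concat(summaries).to_csv(path, sep="\t", index=False)
                outputs[f"feature_bins_{tag}"] = path

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": hashlib.sha256(
            json.dumps(
                {k: str(v) for k, v in vars(config).items()}, sort_keys=True
            ).encode()
        ).hexdigest(),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    outputs["manifest"] = manifest_path
    return outputs
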