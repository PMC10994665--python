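"""Transcriptome data model and readers/writers for the standard formats.

All coordinates are 0-based, half-open internally; the A of an AUG is
position 0 of that codon.  Conversion to 1-based happens only at format
boundaries (wiggle, SAM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

START_CODON = "ATG"
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    """A transcript's sequence with 5'UTR/CDS coordinates and AUG positions.

    ``cds_start`` equals ``utr5_len`` and points at the A of the main AUG
    (mAUG); ``cds_end`` is exclusive, one past the last nucleotide of the
    stop codon.  ``internal_augs`` are AUG triplets inside the CDS strictly
    downstream of the mAUG (any reading frame by default); ``upstream_augs``
    are AUG triplets fully contained in the 5'UTR.
    """

    transcript_id: str
    sequence: str
    utr5_len: int
    cds_start: int
    cds_end: int
    is_spike_in: bool = False
    internal_augs: list[int] = field(default_factory=list)
    upstream_augs: list[int] = field(default_factory=list)

    @property
    def main_aug(self) -> int:
        return self.cds_start

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def stop_last(self) -> int:
        """0-based coordinate of the last nucleotide of the stop codon."""
        return self.cds_end - 1

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_annotation(
        cls,
        transcript_id: str,
        sequence: str,
        utr5_len: int,
        cds_len: int,
        is_spike_in: bool = False,
        in_frame_only: bool = False,
    ) -> "TranscriptModel":
        """Build a model from sequence plus (utr5_len, cds_len), scanning AUGs.

        Raises ``ValueError`` if the CDS violates the model invariants
        (non-ATG start, CDS length not a positive multiple of 3, CDS running
        past the sequence end).
        """
        sequence = sequence.upper()
        cds_start = utr5_len
        cds_end = cds_start + cds_len
        if cds_len <= 0 or cds_len % 3 != 0:
            raise ValueError(
                f"{transcript_id}: CDS length {cds_len} is not a positive multiple of 3"
            )
        if cds_end > len(sequence):
            raise ValueError(
                f"{transcript_id}: CDS end {cds_end} exceeds sequence length {len(sequence)}"
            )
        if sequence[cds_start : cds_start + 3] != START_CODON:
            raise ValueError(
                f"{transcript_id}: no ATG at cds_start={cds_start} "
                f"(found {sequence[cds_start:cds_start + 3]!r})"
            )
        model = cls(
            transcript_id=transcript_id,
            sequence=sequence,
            utr5_len=utr5_len,
            cds_start=cds_start,
            cds_end=cds_end,
            is_spike_in=is_spike_in,
        )
        model.internal_augs = scan_augs(
            sequence, cds_start + 3, cds_end - 3,
            frame_anchor=cds_start if in_frame_only else None,
        )
        model.upstream_augs = scan_augs(sequence, 0, cds_start - 3)
        return model


def scan_augs(
    sequence: str, lo: int, hi: int, frame_anchor: int | None = None
) -> list[int]:
    """Positions p in [lo, hi] with sequence[p:p+3] == 'ATG'.

    With ``frame_anchor`` set, only positions in frame with the anchor
    (p ≡ anchor mod 3) are reported.
    """
    out = []
    for p in range(max(lo, 0), hi + 1):
        if sequence[p : p + 3] == START_CODON:
            if frame_anchor is None or (p - frame_anchor) % 3 == 0:
                out.append(p)
    return out


@dataclass
class AlignedFootprint:
    """One footprint read placed on a transcript (sense strand)."""

    transcript_id: str
    five_prime_pos: int
    length: int
    sample_id: str = ""
    p_site: int | None = None


@dataclass
class ParsTrack:
    """Per-nucleotide PARS scores aligned to a transcript's sequence.

    Higher values denote a higher probability of double-stranded
    conformation.  Transcripts without data are absent, never zero-filled.
    """

    transcript_id: str
    scores: np.ndarray


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_annotation(annotation_path: str | Path) -> dict[str, dict]:
    """Read a transcript annotation TSV.

    Columns: transcript_id, utr5_len, cds_len, optionally is_spike_in (0/1).
    """
    rows: dict[str, dict] = {}
    with open(annotation_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("transcript_id", "utr5_len", "cds_len"):
            if name not in idx:
                raise ValueError(f"annotation is missing required column {name!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                rows[parts[idx["transcript_id"]]] = {
                    "utr5_len": int(parts[idx["utr5_len"]]),
                    "cds_len": int(parts[idx["cds_len"]]),
                    "is_spike_in": bool(int(parts[idx["is_spike_in"]]))
                    if "is_spike_in" in idx
                    else False,
                }
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{annotation_path}:{lineno}: malformed row") from exc
    return rows


def read_transcriptome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    in_frame_only: bool = False,
) -> list[TranscriptModel]:
    """Read a transcriptome FASTA plus its annotation table.

    Every FASTA record must have an annotation row (hard error otherwise).
    Transcripts whose CDS fails the model invariants — e.g. no ATG at the
    annotated start — are skipped with a logged warning.
    """
    annotation = read_annotation(annotation_path)
    models: list[TranscriptModel] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in annotation:
            raise KeyError(f"no annotation row for transcript {record.id!r}")
        row = annotation[record.id]
        try:
            models.append(
                TranscriptModel.from_annotation(
                    record.id,
                    str(record.seq),
                    row["utr5_len"],
                    row["cds_len"],
                    is_spike_in=row["is_spike_in"],
                    in_frame_only=in_frame_only,
                )
            )
        except ValueError as exc:
            logger.warning("skipping transcript: %s", exc)
    return models


def read_alignments(
    path: str | Path,
    format: str = "tsv",
    sample_id: str | None = None,
    known_ids: set[str] | None = None,
) -> list[AlignedFootprint]:
    """Read pre-aligned footprints from a TSV dialect or a SAM file.

    TSV columns: sample_id, transcript_id, five_prime_pos, length (no
    header).  SAM records on the reverse strand, secondary and
    supplementary alignments are discarded: footprints map to the sense
    strand of the transcript, once.  ``p_site`` is left unset.  Reads on
    transcripts outside ``known_ids`` (when given) are dropped with a
    counted warning.
    """
    footprints: list[AlignedFootprint] = []
    unknown = 0
    if format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
                try:
                    fp = AlignedFootprint(
                        sample_id=parts[0],
                        transcript_id=parts[1],
                        five_prime_pos=int(parts[2]),
                        length=int(parts[3]),
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed line") from exc
                if known_ids is not None and fp.transcript_id not in known_ids:
                    unknown += 1
                    continue
                footprints.append(fp)
    elif format == "sam":
        default_sample = sample_id or Path(path).stem
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_reverse or rec.is_secondary or rec.is_supplementary:
                    continue
                tid = rec.reference_name
                if known_ids is not None and tid not in known_ids:
                    unknown += 1
                    continue
                footprints.append(
                    AlignedFootprint(
                        sample_id=default_sample,
                        transcript_id=tid,
                        five_prime_pos=rec.reference_start,
                        length=rec.query_length or len(rec.query_sequence or ""),
                    )
                )
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if unknown:
        logger.warning("dropped %d reads on unknown transcripts", unknown)
    return footprints


def write_alignments_tsv(footprints: Iterable[AlignedFootprint], path: str | Path) -> None:
    """Write footprints in the 4-column TSV alignment dialect."""
    with open(path, "w") as fh:
        for fp in footprints:
            fh.write(f"{fp.sample_id}\t{fp.transcript_id}\t{fp.five_prime_pos}\t{fp.length}\n")


def read_pars_tracks(
    path: str | Path, transcripts: Sequence[TranscriptModel]
) -> dict[str, ParsTrack]:
    """Read per-nucleotide PARS scores from a TSV (transcript_id, position, score).

    Positions are 0-based transcript coordinates.  Only transcripts present
    in the file get a track; unlisted positions within a listed transcript
    default to 0.
    """
    lengths = {t.transcript_id: len(t) for t in transcripts}
    raw: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            tid, pos, score = parts[0], int(parts[1]), float(parts[2])
            raw.setdefault(tid, []).append((pos, score))
    tracks: dict[str, ParsTrack] = {}
    for tid, entries in raw.items():
        if tid not in lengths:
            logger.warning("PARS track for unknown transcript %s ignored", tid)
            continue
        scores = np.zeros(lengths[tid])
        for pos, score in entries:
            scores[pos] = score
        tracks[tid] = ParsTrack(tid, scores)
    return tracks


def write_pars_tracks(tracks: Mapping[str, ParsTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(tracks):
            for pos, score in enumerate(tracks[tid].scores):
                if score != 0.0:
                    fh.write(f"{tid}\t{pos}\t{score:g}\n")


# ---------------------------------------------------------------------------
# wiggle
# ---------------------------------------------------------------------------

def write_wiggle(
    track: Mapping[str, Mapping[int, float]], path: str | Path, name: str = "recseq"
) -> None:
    """Write per-position counts as variableStep wiggle (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for tid in sorted(track):
            positions = track[tid]
            if not positions:
                continue
            fh.write(f"variableStep chrom={tid}\n")
            for pos in sorted(positions):
                fh.write(f"{pos + 1} {positions[pos]:g}\n")


def read_wiggle(path: str | Path) -> dict[str, dict[int, float]]:
    """Inverse of :func:`write_wiggle` (positions back to 0-based)."""
    track: dict[str, dict[int, float]] = {}
    current: dict[int, float] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                chrom = dict(
                    kv.split("=") for kv in line.split()[1:]
                )["chrom"]
                current = track.setdefault(chrom, {})
            else:
                if current is None:
                    raise ValueError("wiggle data line before variableStep header")
                pos, value = line.split()
                current[int(pos) - 1] = float(value)
    return track


def footprint_coverage(
    footprints: Iterable[AlignedFootprint], by: str = "p_site"
) -> dict[str, dict[int, float]]:
    """Aggregate footprints into a per-transcript position→count track."""
    track: dict[str, dict[int, float]] = {}
    for fp in footprints:
        pos = fp.p_site if by == "p_site" else fp.five_prime_pos
        if pos is None:
            raise ValueError("footprint lacks a P-site; run assign_p_sites first")
        sub = track.setdefault(fp.transcript_id, {})
        sub[pos] = sub.get(pos, 0.0) + 1.0
    return track
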