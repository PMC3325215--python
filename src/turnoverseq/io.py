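"""Reading and writing transcript-coordinate alignments and annotation tables.

Alignments live in transcript coordinates: the SAM reference sequences are
transcripts, and BED6 records use the transcript id as chromosome with
0-based half-open intervals.  Sample identity (wt / mut) is carried in the
read name as ``<sample>.<serial>`` so a single file round-trips a mixed
read set.  Coordinates are 0-based half-open internally; SAM's 1-based
positions are converted on the fly by pysam.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import pysam

from .model import TranscriptModel
from .simulate import READ_COLUMNS, transcripts_to_frame

logger = logging.getLogger(__name__)


class AlignmentFormatError(ValueError):
    """Raised for malformed or out-of-bounds alignment records."""


def _transcript_lengths(transcripts: Sequence[TranscriptModel]) -> dict[str, int]:
    return {t.id: t.length for t in transcripts}


def write_alignments(
    reads: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
    format: str = "sam",
    metadata: Optional[Mapping] = None,
) -> Path:
    """Write reads to SAM or BED6, plus a JSON sidecar of run metadata.

    SAM emits mandatory fields only (unmapped reads never occur); BED6 uses
    chrom = transcript id, 0-based half-open coordinates, score 0, strand
    ``+``.  Raises :class:`AlignmentFormatError` for reads on transcripts
    absent from the annotation.
    """
    path = Path(path)
    lengths = _transcript_lengths(transcripts)
    unknown = set(reads["transcript_id"]) - set(lengths) if len(reads) else set()
    if unknown:
        raise AlignmentFormatError(
            f"reads reference unknown transcript(s): {sorted(unknown)[:5]}"
        )
    if format == "sam":
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": t.id, "LN": t.length} for t in transcripts],
        }
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            ref_ids = {t.id: i for i, t in enumerate(transcripts)}
            for serial, row in enumerate(reads.itertuples(index=False)):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"{row.sample}.{serial}"
                rec.flag = 0
                rec.reference_id = ref_ids[row.transcript_id]
                rec.reference_start = int(row.start)
                rec.mapping_quality = 255
                rec.cigarstring = f"{int(row.length)}M"
                out.write(rec)
    elif format == "bed":
        with open(path, "w") as out:
            for serial, row in enumerate(reads.itertuples(index=False)):
                out.write(
                    f"{row.transcript_id}\t{int(row.start)}\t"
                    f"{int(row.start) + int(row.length)}\t"
                    f"{row.sample}.{serial}\t0\t+\n"
                )
    else:
        raise ValueError(f"unknown alignment format {format!r}")

    sidecar = {"format": format, "n_reads": int(len(reads))}
    if metadata:
        sidecar.update(metadata)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_alignments(
    path: str | Path,
    format: str = "sam",
    transcripts: Optional[Sequence[TranscriptModel]] = None,
) -> pd.DataFrame:
    """Parse alignments back into the canonical read DataFrame.

    Secondary and supplementary alignments are dropped (counted in a log
    message).  Every read is validated against the transcript bounds taken
    from the SAM header or, for BED, the supplied annotation; a violation
    raises :class:`AlignmentFormatError` naming the record.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, str]] = []
    if format == "sam":
        n_dropped = 0
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            lengths = dict(zip(fh.references, fh.lengths))
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    n_dropped += 1
                    continue
                tid = rec.reference_name
                rlen = rec.infer_query_length() or rec.query_length
                if rec.reference_start + rlen > lengths[tid]:
                    raise AlignmentFormatError(
                        f"read {rec.query_name!r} extends past the end of "
                        f"{tid} (length {lengths[tid]})"
                    )
                sample = rec.query_name.split(".", 1)[0]
                rows.append((tid, rec.reference_start, rlen, sample))
        if n_dropped:
            logger.info("dropped %d secondary/supplementary/unmapped records", n_dropped)
    elif format == "bed":
        if transcripts is None:
            raise ValueError("BED input requires the transcript annotation")
        lengths = _transcript_lengths(transcripts)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise AlignmentFormatError(
                        f"{path}:{lineno}: expected >= 6 BED fields"
                    )
                tid, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                if tid not in lengths:
                    raise AlignmentFormatError(
                        f"{path}:{lineno}: unknown transcript {tid!r}"
                    )
                if start < 0 or end > lengths[tid] or end <= start:
                    raise AlignmentFormatError(
                        f"{path}:{lineno}: interval [{start}, {end}) out of "
                        f"bounds for {tid} (length {lengths[tid]})"
                    )
                sample = name.split(".", 1)[0]
                rows.append((tid, start, end - start, sample))
    else:
        raise ValueError(f"unknown alignment format {format!r}")

    return pd.DataFrame(rows, columns=READ_COLUMNS).astype(
        {"transcript_id": "string", "start": "int64", "length": "int64", "sample": "string"}
    )


def write_transcript_table(
    transcripts: Sequence[TranscriptModel], path: str | Path
) -> Path:
    """Write the annotation as TSV with a commented header row."""
    path = Path(path)
    frame = transcripts_to_frame(transcripts)
    with open(path, "w") as fh:
        fh.write("# id\tlength[nt]\torigin\tgroup\texpression_weight[arbitrary]\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)
    return path


def read_transcript_table(path: str | Path) -> list[TranscriptModel]:
    """Read a transcript annotation TSV written by :func:`write_transcript_table`."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["id", "length", "origin", "group", "expression_weight"],
        dtype={"id": str},
    )
    return [
        TranscriptModel(
            id=row.id,
            length=int(row.length),
            origin=row.origin,
            group=row.group,
            expression_weight=float(row.expression_weight),
        )
        for row in frame.itertuples(index=False)
    ]
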