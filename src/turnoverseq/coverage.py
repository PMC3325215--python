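"""Per-transcript coverage profiles and the 1%-bin metaprofile.

A read is located by its leftmost aligned base in transcript coordinates;
``start_counts`` records read starts per position while ``depth`` aggregates
overlapping read bodies.  The covered fraction (positions with depth >= 1,
divided by length) feeds the abundance filter of the turnover index, and
the metaprofile accumulates relative read abundance in 1% bins over the
most highly expressed transcripts to check that two libraries share the
same positional bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import TranscriptModel


@dataclass
class CoverageProfile:
    """Read-start counts, per-base depth and summary statistics for one transcript."""

    transcript_id: str
    start_counts: np.ndarray
    depth: np.ndarray
    total_reads: int
    covered_fraction: float

    @classmethod
    def from_reads(
        cls, transcript_id: str, length: int, starts: np.ndarray, read_lengths: np.ndarray
    ) -> "CoverageProfile":
        """Build a profile from validated read starts and lengths."""
        starts = np.asarray(starts, dtype=np.int64)
        read_lengths = np.asarray(read_lengths, dtype=np.int64)
        start_counts = np.bincount(starts, minlength=length) if starts.size else np.zeros(
            length, dtype=np.int64
        )
        # depth via difference array: +1 at start, -1 past end
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + read_lengths, -1)
        depth = np.cumsum(diff[:-1])
        covered = float(np.count_nonzero(depth)) / length
        return cls(
            transcript_id=transcript_id,
            start_counts=start_counts.astype(np.int64),
            depth=depth,
            total_reads=int(starts.size),
            covered_fraction=covered,
        )


def build_profiles(
    reads: pd.DataFrame, transcripts: Sequence[TranscriptModel]
) -> dict[str, dict[str, CoverageProfile]]:
    """Coverage profiles per sample per transcript.

    Every annotated transcript gets a profile in every sample present in
    ``reads`` (all-zero when unobserved).  Reads must be pre-validated
    (see :func:`turnoverseq.io.read_alignments`); a read beyond transcript
    bounds raises ``ValueError``.
    """
    lengths = {t.id: t.length for t in transcripts}
    samples = sorted(reads["sample"].unique()) if len(reads) else []
    out: dict[str, dict[str, CoverageProfile]] = {s: {} for s in samples}
    for (sample, tid), grp in reads.groupby(["sample", "transcript_id"], observed=True):
        if tid not in lengths:
            raise ValueError(f"reads on unannotated transcript {tid!r}")
        starts = grp["start"].to_numpy(dtype=np.int64)
        rlens = grp["length"].to_numpy(dtype=np.int64)
        if starts.size and (starts.min() < 0 or (starts + rlens).max() > lengths[tid]):
            raise ValueError(f"read out of bounds on {tid!r}")
        out[sample][tid] = CoverageProfile.from_reads(tid, lengths[tid], starts, rlens)
    for sample in samples:
        for tid, L in lengths.items():
            if tid not in out[sample]:
                out[sample][tid] = CoverageProfile.from_reads(
                    tid, L, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
                )
    return out


@dataclass
class BinProfile:
    """Relative read abundance in percent-of-length bins, per sample."""

    bins: dict[str, np.ndarray]
    n_transcripts: int
    transcript_ids: list[str] = field(default_factory=list)
    n_bins: int = 100

    def max_abs_difference(self, a: str = "wt", b: str = "mut") -> float:
        """Largest bin-wise absolute difference between two samples' profiles."""
        return float(np.max(np.abs(self.bins[a] - self.bins[b])))


def select_top_expressed(
    profiles: Mapping[str, Mapping[str, CoverageProfile]],
    transcripts: Sequence[TranscriptModel],
    top_fraction: float = 0.1,
    rank_sample: str = "wt",
) -> list[str]:
    """Ids of the top fraction of nuclear transcripts by read count.

    Ranking uses total reads in ``rank_sample``; ties are broken by
    transcript id (lexicographic) so the cutoff is deterministic.  The same
    set serves every sample.
    """
    nuclear = [t.id for t in transcripts if t.origin == "nuclear"]
    ranked = sorted(
        nuclear, key=lambda tid: (-profiles[rank_sample][tid].total_reads, tid)
    )
    n_keep = max(1, int(np.floor(top_fraction * len(ranked))))
    return ranked[:n_keep]


def bin_metaprofile(
    profiles: Mapping[str, Mapping[str, CoverageProfile]],
    transcripts: Sequence[TranscriptModel],
    top_fraction: float = 0.1,
    n_bins: int = 100,
    rank_sample: str = "wt",
) -> BinProfile:
    """Accumulated relative read abundance in ``n_bins`` bins of relative position.

    Each read start at position ``s`` of a transcript of length ``L`` falls
    into bin ``floor(n_bins * s / L)`` (which never reaches ``n_bins`` since
    ``s < L``).  Counts are accumulated over the selected transcripts and
    normalised to sum to one per sample.
    """
    selected = select_top_expressed(profiles, transcripts, top_fraction, rank_sample)
    if not selected:
        raise ValueError("transcript selection for the metaprofile is empty")
    lengths = {t.id: t.length for t in transcripts}
    bins: dict[str, np.ndarray] = {}
    for sample, per_tid in profiles.items():
        acc = np.zeros(n_bins, dtype=float)
        for tid in selected:
            prof = per_tid[tid]
            if prof.total_reads == 0:
                continue
            L = lengths[tid]
            positions = np.nonzero(prof.start_counts)[0]
            idx = np.minimum((n_bins * positions) // L, n_bins - 1)
            np.add.at(acc, idx, prof.start_counts[positions])
        total = acc.sum()
        bins[sample] = acc / total if total > 0 else acc
    return BinProfile(
        bins=bins, n_transcripts=len(selected), transcript_ids=selected, n_bins=n_bins
    )


def write_metaprofile(profile: BinProfile, path) -> None:
    """Write the metaprofile as TSV with a commented header."""
    samples = sorted(profile.bins)
    with open(path, "w") as fh:
        fh.write(
            "# bin[percent-of-length]\t"
            + "\t".join(f"{s}[fraction-of-reads]" for s in samples)
            + f"\t# n_transcripts={profile.n_transcripts}\n"
        )
        for i in range(profile.n_bins):
            vals = "\t".join(f"{profile.bins[s][i]:.8g}" for s in samples)
            fh.write(f"{i}\t{vals}\n")
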