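"""The 5'->3' coverage index, its filters, and the alternative slope index.

The index of a transcript is the number of reads starting in its 5'-most
20% divided by the number starting in its 3'-most 20%.  Values above 1
indicate relative 3'-end depletion, the signature of 3'->5' exonucleolytic
decay intermediates captured by random-primed library preparation.

Filtering follows the published rules: transcripts with a zero count in
either window carry a ``nonsense`` flag (the index would be 0 or infinite);
transcripts with less than half their sequence covered in either sample are
``low_coverage``; indices >= 10 or <= 0.1 (inclusive bounds) are outliers.
A transcript passes only when both samples are clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .model import TranscriptModel

logger = logging.getLogger(__name__)

FLAG_NONSENSE = "nonsense"
FLAG_LOW_COVERAGE = "low_coverage"
FLAG_OUTLIER_HIGH = "outlier_high"
FLAG_OUTLIER_LOW = "outlier_low"


@dataclass
class IndexRecord:
    """Window counts and 5'->3' coverage index for one transcript in one sample."""

    transcript_id: str
    n5: int
    n3: int
    index: Optional[float]
    covered_fraction: float
    flags: set[str] = field(default_factory=set)


def coverage_index(profile: CoverageProfile, window_frac: float = 0.2) -> IndexRecord:
    """Compute the 5'->3' coverage index of one profile.

    The window width is ``floor(window_frac * L)`` for both ends, so a
    uniform start distribution yields exactly 1 whatever the length.  A zero
    count in either window sets the ``nonsense`` flag and leaves the index
    undefined (no pseudocounts).  Transcripts shorter than 1/window_frac
    (width 0) are rejected.
    """
    L = len(profile.start_counts)
    w = int(np.floor(window_frac * L))
    if w < 1:
        raise ValueError(
            f"{profile.transcript_id}: window width 0 for length {L} at "
            f"window_frac {window_frac}; transcript excluded"
        )
    if 2 * w > L:
        logger.debug("%s: 5' and 3' windows overlap (L=%d)", profile.transcript_id, L)
    n5 = int(profile.start_counts[:w].sum())
    n3 = int(profile.start_counts[L - w:].sum())
    flags: set[str] = set()
    index: Optional[float] = None
    if n5 == 0 or n3 == 0:
        flags.add(FLAG_NONSENSE)
    else:
        index = n5 / n3
    return IndexRecord(
        transcript_id=profile.transcript_id,
        n5=n5,
        n3=n3,
        index=index,
        covered_fraction=profile.covered_fraction,
        flags=flags,
    )


def index_records(
    profiles: Mapping[str, CoverageProfile], window_frac: float = 0.2
) -> dict[str, IndexRecord]:
    """Coverage index for every transcript of one sample; short transcripts skipped."""
    out: dict[str, IndexRecord] = {}
    n_skipped = 0
    for tid, prof in profiles.items():
        try:
            out[tid] = coverage_index(prof, window_frac)
        except ValueError:
            n_skipped += 1
    if n_skipped:
        logger.info("excluded %d transcripts with zero window width", n_skipped)
    return out


def pair_and_filter(
    wt_records: Mapping[str, IndexRecord],
    mut_records: Mapping[str, IndexRecord],
    transcripts: Sequence[TranscriptModel],
    min_cov: float = 0.5,
    lo: float = 0.1,
    hi: float = 10.0,
) -> pd.DataFrame:
    """Pair per-sample index records and apply the abundance/outlier filters.

    Returns one row per transcript present in both samples' record maps,
    with columns ``n5/n3/index/cov/flags`` per sample, the group label, and
    a boolean ``pass``.  A row fails when either sample has a nonsense
    index, covered fraction below ``min_cov``, or an index outside the open
    interval (``lo``, ``hi``) — the outlier bounds are inclusive removals.
    """
    if set(wt_records) != set(mut_records):
        only = set(wt_records) ^ set(mut_records)
        raise ValueError(
            f"samples indexed over different annotations; e.g. {sorted(only)[:5]}"
        )
    groups = {t.id: t.group for t in transcripts}
    rows = []
    for tid in sorted(wt_records):
        rec = {"transcript_id": tid, "group": groups.get(tid, "excluded")}
        ok = True
        for sample, r in (("wt", wt_records[tid]), ("mut", mut_records[tid])):
            flags = set(r.flags)
            if r.covered_fraction < min_cov:
                flags.add(FLAG_LOW_COVERAGE)
            if r.index is not None:
                if r.index >= hi:
                    flags.add(FLAG_OUTLIER_HIGH)
                if r.index <= lo:
                    flags.add(FLAG_OUTLIER_LOW)
            rec[f"n5_{sample}"] = r.n5
            rec[f"n3_{sample}"] = r.n3
            rec[f"index_{sample}"] = np.nan if r.index is None else r.index
            rec[f"cov_{sample}"] = r.covered_fraction
            rec[f"flags_{sample}"] = ",".join(sorted(flags))
            ok = ok and not flags
        rec["pass"] = ok
        rows.append(rec)
    columns = [
        "transcript_id", "group",
        "n5_wt", "n3_wt", "index_wt", "cov_wt", "flags_wt",
        "n5_mut", "n3_mut", "index_mut", "cov_mut", "flags_mut",
        "pass",
    ]
    return pd.DataFrame(rows, columns=columns)


def slope_index(profile: CoverageProfile) -> Optional[float]:
    """Ordinary least-squares slope of depth against relative position.

    Depth is regressed on position scaled to [0, 1] over all transcript
    positions, and the slope is normalised by the mean depth, so a profile
    falling linearly from 2d at the 5' end to 0 at the 3' end scores -2.
    Negative values indicate 5'-heavy coverage.  Undefined (None) for
    profiles with fewer than two covered positions.
    """
    depth = profile.depth.astype(float)
    L = depth.size
    if np.count_nonzero(depth) < 2:
        return None
    mean = depth.mean()
    if mean == 0:
        return None
    x = np.arange(L) / (L - 1)
    slope = np.polyfit(x, depth, 1)[0]
    return float(slope / mean)


def write_index_table(table: pd.DataFrame, path) -> None:
    """Write the paired index table as TSV with a commented header."""
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(table.columns) + "\t# index = n5/n3 (dimensionless)\n")
        table.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")
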