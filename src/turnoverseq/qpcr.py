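"""qPCR 5'/3' end-ratio arithmetic for validating coverage-based turnover calls.

For each gene, separate amplicons quantify the abundance of the 5' and 3'
mRNA ends in each genotype.  The per-genotype end ratio (mean 5' quantity /
mean 3' quantity over replicates) estimates the steady-state excess of 5'
over 3' ends; the wild-type-to-mutant ratio of these ratios exceeds 1 when
the transcript's 3' end is stabilised in the mutant.

Relative-expression normalisation against a housekeeping gene is the same
arithmetic with the reference amplicon in the denominator slot, so no
separate operation exists for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

ENDS = ("five_prime", "three_prime")
GENOTYPES = ("wt", "mut")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One amplicon measurement: either a Ct or a pre-computed relative quantity."""

    gene: str
    end: str
    genotype: str
    replicate: int
    ct: Optional[float] = None
    quantity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end not in ENDS:
            raise ValueError(f"unknown end {self.end!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.replicate < 1:
            raise ValueError("replicate numbering starts at 1")
        if (self.ct is None) == (self.quantity is None):
            raise ValueError("provide exactly one of ct / quantity")


def relative_quantity(ct: float, efficiency: float = 2.0) -> float:
    """Abundance (arbitrary scale) from a Ct value: ``efficiency ** (-ct)``.

    The default efficiency of 2 assumes perfect doubling per cycle; it is
    configurable per primer pair in (1, 2].
    """
    if not math.isfinite(ct):
        raise ValueError("Ct must be finite")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    return efficiency ** (-ct)


def _quantities(measurements: Iterable[QpcrMeasurement], efficiency: float) -> dict:
    by_end: dict[str, list[float]] = {e: [] for e in ENDS}
    for m in measurements:
        q = m.quantity if m.quantity is not None else relative_quantity(m.ct, efficiency)
        if q <= 0:
            raise ValueError(f"non-positive quantity for {m.gene} {m.end}")
        by_end[m.end].append(q)
    return by_end


def end_ratio(
    measurements: Iterable[QpcrMeasurement], efficiency: float = 2.0
) -> float:
    """Per-genotype 5'/3' end-abundance ratio for one gene.

    Replicates are combined as the mean of linear-scale quantities (not of
    Cts) before the ratio is taken.
    """
    by_end = _quantities(measurements, efficiency)
    for e in ENDS:
        if not by_end[e]:
            raise ValueError(f"no replicate measures the {e} end")
    return float(np.mean(by_end["five_prime"]) / np.mean(by_end["three_prime"]))


def ratio_of_ratios(wt_ratio: float, mut_ratio: float) -> tuple[float, bool]:
    """Wild-type to mutant ratio of the 5'/3' end ratios.

    Returns ``(value, stabilized_in_mutant)`` where the flag is True when
    the value exceeds 1 — the mutant retains relatively more 3' ends.
    """
    for name, r in (("wt_ratio", wt_ratio), ("mut_ratio", mut_ratio)):
        if not (math.isfinite(r) and r > 0):
            raise ValueError(f"{name} must be finite and positive")
    value = wt_ratio / mut_ratio
    return value, value > 1.0


def analyze_table(frame: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-gene end ratios and ratio-of-ratios from a long-format table.

    Expects columns ``gene, end, genotype, replicate`` and one of
    ``ct`` / ``quantity``.  Returns one row per gene with ``wt_ratio,
    mut_ratio, ratio_of_ratios, stabilized_in_mutant``.
    """
    rows = []
    for gene, sub in frame.groupby("gene", sort=True):
        ratios = {}
        for genotype in GENOTYPES:
            ms = [
                QpcrMeasurement(
                    gene=gene,
                    end=r.end,
                    genotype=genotype,
                    replicate=int(r.replicate),
                    ct=float(r.ct) if "ct" in frame.columns and pd.notna(r.ct) else None,
                    quantity=(
                        float(r.quantity)
                        if "quantity" in frame.columns and pd.notna(r.quantity)
                        else None
                    ),
                )
                for r in sub[sub["genotype"] == genotype].itertuples(index=False)
            ]
            if not ms:
                raise ValueError(f"gene {gene!r}: no measurements for {genotype}")
            ratios[genotype] = end_ratio(ms, efficiency)
        value, flag = ratio_of_ratios(ratios["wt"], ratios["mut"])
        rows.append(
            {
                "gene": gene,
                "wt_ratio": ratios["wt"],
                "mut_ratio": ratios["mut"],
                "ratio_of_ratios": value,
                "stabilized_in_mutant": flag,
            }
        )
    return pd.DataFrame(rows)


def read_qpcr_table(path) -> pd.DataFrame:
    """Read the long-format qPCR TSV (columns gene, end, genotype, replicate, ct|quantity)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_qpcr_results(results: pd.DataFrame, path) -> None:
    """Write per-gene ratio results as TSV with a commented header."""
    with open(path, "w") as fh:
        fh.write("# gene\twt_ratio\tmut_ratio\tratio_of_ratios\tstabilized_in_mutant\n")
        results.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")
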