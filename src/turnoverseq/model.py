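"""Domain types shared across the package.

The central objects are transcripts with group labels (nuclear control,
prime exosome target, chloroplast), a steady-state decay parameterisation,
and reads in transcript coordinates.  Bulk read data is carried as a
pandas DataFrame with columns ``transcript_id, start, length, sample``
(see :mod:`turnoverseq.io`); the :class:`AlignedRead` dataclass is the
record-level view of one row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

#: analysis-group labels
GROUPS = ("control", "exosome_target", "chloroplast", "excluded")
ORIGINS = ("nuclear", "chloroplast")
SAMPLES = ("wt", "mut")


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript.

    Parameters
    ----------
    id : str
        Transcript identifier.
    length : int
        Transcript length in nucleotides.
    origin : str
        ``"nuclear"`` or ``"chloroplast"`` genome of origin.
    group : str
        Analysis group; ``"chloroplast"`` iff origin is chloroplast.
    expression_weight : float
        Relative molar abundance (arbitrary units, > 0).
    """

    id: str
    length: int
    origin: str
    group: str
    expression_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"transcript {self.id}: length must be positive")
        if self.origin not in ORIGINS:
            raise ValueError(f"transcript {self.id}: unknown origin {self.origin!r}")
        if self.group not in GROUPS:
            raise ValueError(f"transcript {self.id}: unknown group {self.group!r}")
        if (self.group == "chloroplast") != (self.origin == "chloroplast"):
            raise ValueError(
                f"transcript {self.id}: group 'chloroplast' must coincide with "
                f"chloroplast origin"
            )
        if not self.expression_weight > 0:
            raise ValueError(f"transcript {self.id}: expression_weight must be > 0")


@dataclass(frozen=True)
class DecayParams:
    """Steady-state 3'->5' decay mixture.

    A molecule is full length with probability ``f_intact``; otherwise its
    remaining (5'-anchored) length is drawn from ``truncation_law`` on
    ``{min_remaining, ..., L}``.  The uniform law includes the full length
    in its support, so ``f_intact`` is a lower bound on the realised intact
    fraction.

    Parameters
    ----------
    f_intact : float
        Probability that a molecule is intact at steady state, in [0, 1].
    min_remaining : int
        Shortest surviving 5' fragment, in nucleotides.  Decay intermediates
        shorter than this are assumed fully degraded and invisible.
    truncation_law : str
        ``"uniform"`` or ``"geometric"``.
    geometric_rate : float, optional
        Success probability of the geometric number of nucleotides removed
        from the 3' end (support 1, 2, ...), required for the geometric law.
    """

    f_intact: float
    min_remaining: int = 150
    truncation_law: str = "uniform"
    geometric_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_intact <= 1.0:
            raise ValueError("f_intact must lie in [0, 1]")
        if self.min_remaining <= 0:
            raise ValueError("min_remaining must be positive")
        if self.truncation_law not in ("uniform", "geometric"):
            raise ValueError(f"unknown truncation law {self.truncation_law!r}")
        if self.truncation_law == "geometric":
            if self.geometric_rate is None or not 0.0 < self.geometric_rate < 1.0:
                raise ValueError("geometric law needs geometric_rate in (0, 1)")


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read in transcript coordinates (0-based leftmost base)."""

    transcript_id: str
    start: int
    length: int
    sample: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("read start must be non-negative")
        if self.length <= 0:
            raise ValueError("read length must be positive")


# Mutant stabilisation is encoded as a higher intact fraction for exosome
# targets (strong), mildly higher for nuclear controls, and unchanged for
# chloroplast-encoded transcripts, mirroring the observed group pattern.
DEFAULT_DECAY: dict[str, dict[str, DecayParams]] = {
    "control": {
        "wt": DecayParams(f_intact=0.35),
        "mut": DecayParams(f_intact=0.45),
    },
    "exosome_target": {
        "wt": DecayParams(f_intact=0.25),
        "mut": DecayParams(f_intact=0.75),
    },
    "chloroplast": {
        "wt": DecayParams(f_intact=0.60),
        "mut": DecayParams(f_intact=0.60),
    },
}


@dataclass
class SimulationConfig:
    """Full parameterisation of a two-condition simulated experiment.

    Defaults reproduce the study design: 5,617 nuclear control genes,
    68 prime exosome targets, 34 chloroplast transcripts, 75 bp single-end
    random-primed reads, and desk-scale library sizes.
    """

    n_control: int = 5617
    n_targets: int = 68
    n_chloroplast: int = 34
    #: log-normal transcript-length law (natural-log scale) with a hard floor
    length_log_mean: float = 7.3
    length_log_sd: float = 0.45
    min_length: int = 300
    #: log-normal relative molar abundance
    expression_log_sd: float = 1.0
    #: per-gene abundance multiplier for chloroplast-encoded transcripts;
    #: organellar mRNAs are high-copy and take a read share comparable to the
    #: whole nuclear transcriptome despite ~100x fewer genes
    chloroplast_expression_multiplier: float = 100.0
    read_length: int = 75
    library_size: int = 300_000
    n_molecules_per_transcript: int = 50
    decay: dict[str, dict[str, DecayParams]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_DECAY.items()}
    )
    #: optional monotone weight over relative position x in [0, 1); None = flat.
    #: Given as ("linear", slope) with weight 1 + slope * (x - 0.5), slope in (-2, 2).
    positional_bias: Optional[tuple[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_targets", "n_chloroplast"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.length_log_sd < 0:
            raise ConfigurationError("length_log_sd must be >= 0")
        if self.min_length <= 0:
            raise ConfigurationError("min_length must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        if self.n_molecules_per_transcript <= 0:
            raise ConfigurationError("n_molecules_per_transcript must be positive")
        for group, per_sample in self.decay.items():
            if group not in GROUPS:
                raise ConfigurationError(f"decay for unknown group {group!r}")
            for sample, params in per_sample.items():
                if sample not in SAMPLES:
                    raise ConfigurationError(f"decay for unknown sample {sample!r}")
                if params.min_remaining < self.read_length:
                    raise ConfigurationError(
                        f"decay[{group}][{sample}]: min_remaining "
                        f"({params.min_remaining}) must be >= read_length "
                        f"({self.read_length})"
                    )
                if params.min_remaining > self.min_length:
                    raise ConfigurationError(
                        f"decay[{group}][{sample}]: min_remaining exceeds the "
                        f"minimum transcript length {self.min_length}"
                    )
        if self.positional_bias is not None:
            kind, param = self.positional_bias
            if kind != "linear":
                raise ConfigurationError(f"unknown positional bias {kind!r}")
            if not -2.0 < param < 2.0:
                raise ConfigurationError("linear bias slope must lie in (-2, 2)")

    def bias_function(self) -> Optional[Callable[[np.ndarray], np.ndarray]]:
        """Return the positional-bias weight function, or None when flat."""
        if self.positional_bias is None:
            return None
        _, slope = self.positional_bias
        return lambda x: 1.0 + slope * (np.asarray(x, dtype=float) - 0.5)
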