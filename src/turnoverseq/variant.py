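"""Conceptual translation of frameshift deletions and protein-mass prediction.

Models the effect of a small coding-sequence deletion: remove the deleted
nucleotides, translate the standard genetic code from the start codon
through the (possibly shifted) frame, and report the predicted protein and
its average molecular mass.  A deletion whose length is not a multiple of
three shifts the downstream frame, typically reading through the original
stop codon into the 3' UTR and producing a modified, extended C-terminus —
so the input must be the full mRNA, not the CDS alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.SeqUtils import molecular_weight

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_WATER = 18.0153  # average mass of one water, Da


@dataclass(frozen=True)
class DeletionSpec:
    """A deletion in 1-based inclusive nucleotide coordinates of the ORF/mRNA."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("need 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinProduct:
    """Predicted translation product (no stop symbol) with its average mass."""

    sequence: str
    mass_da: float
    stop_found: bool

    @property
    def mass_kda(self) -> int:
        """Average mass rounded to the nearest kDa, as customarily reported."""
        return round(self.mass_da / 1000.0)


def apply_deletion(seq: str, spec: DeletionSpec) -> str:
    """Remove the specified nucleotides, preserving both flanks."""
    seq = str(seq)
    if spec.end > len(seq):
        raise ValueError(
            f"deletion {spec.start}-{spec.end} exceeds sequence length {len(seq)}"
        )
    return seq[: spec.start - 1] + seq[spec.end:]


def average_mass(protein: str) -> float:
    """Average (not monoisotopic) molecular mass of a protein, in daltons."""
    if not protein:
        raise ValueError("empty protein sequence")
    return float(molecular_weight(protein, seq_type="protein", monoisotopic=False))


def conceptual_translate(mrna: str, orf_start: int = 0) -> ProteinProduct:
    """Translate codons from ``orf_start`` until the first stop codon.

    ``orf_start`` is a 0-based offset that must begin a start codon of the
    standard genetic code (translated as Met).  If the sequence ends before
    a stop codon is reached — as happens when a frameshifted frame reads
    through the 3' UTR and off the annotated sequence — ``stop_found`` is
    False and the product covers the residues translated so far.
    """
    mrna = str(mrna).upper().replace("U", "T")
    first = mrna[orf_start:orf_start + 3]
    if len(first) < 3 or first not in _STANDARD.start_codons:
        raise ValueError(f"no start codon at offset {orf_start} (found {first!r})")
    residues = ["M"]
    stop_found = False
    pos = orf_start + 3
    while pos + 3 <= len(mrna):
        codon = mrna[pos:pos + 3]
        if any(b not in "ACGT" for b in codon):
            raise ValueError(f"ambiguous base in codon {codon!r} at position {pos}")
        if codon in _STANDARD.stop_codons:
            stop_found = True
            break
        residues.append(_STANDARD.forward_table[codon])
        pos += 3
    protein = "".join(residues)
    return ProteinProduct(
        sequence=protein, mass_da=average_mass(protein), stop_found=stop_found
    )


def predict_deletion_effect(
    mrna: str, spec: DeletionSpec, orf_start: int = 0
) -> dict:
    """Wild-type and deletion-allele translation products side by side.

    The deletion coordinates are relative to the ORF (1-based); they are
    offset by ``orf_start`` within the full mRNA.  Returns a JSON-ready
    dict with both products, their masses, and the frame shift
    (deletion length mod 3).
    """
    wt = conceptual_translate(mrna, orf_start)
    shifted = DeletionSpec(spec.start + orf_start, spec.end + orf_start)
    mut = conceptual_translate(apply_deletion(mrna, shifted), orf_start)
    return {
        "deletion": {"start": spec.start, "end": spec.end, "length": spec.length},
        "frame_shift": spec.length % 3,
        "wild_type": {
            "n_residues": len(wt.sequence),
            "mass_da": wt.mass_da,
            "mass_kda": wt.mass_kda,
            "stop_found": wt.stop_found,
            "sequence": wt.sequence,
        },
        "mutant": {
            "n_residues": len(mut.sequence),
            "mass_da": mut.mass_da,
            "mass_kda": mut.mass_kda,
            "stop_found": mut.stop_found,
            "sequence": mut.sequence,
        },
    }


def load_fasta(path: str | Path) -> str:
    """Read the first record of a FASTA file as an uppercase DNA string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def synthetic_vip3_like_mrna() -> str:
    """The packaged *synthetic* VIP3-like mRNA stand-in.

    A deterministic, artificially constructed coding sequence plus 3' UTR
    that mirrors the documented deletion arithmetic of the vip3-zwg allele:
    a 7 bp deletion of ORF nucleotides 861-867 shifts the reading frame so
    translation runs through the original stop codon into the 3' UTR,
    extending a ~32 kDa product to ~36 kDa.  It is NOT the At4g29830
    sequence; it exists so the frameshift arithmetic can be exercised
    end to end without external sequence retrieval.
    """
    ref = resources.files("turnoverseq").joinpath("data/vip3_synthetic.fasta")
    with resources.as_file(ref) as path:
        return load_fasta(path)


#: the documented deletion of the zwg allele, in ORF coordinates
ZWG_DELETION = DeletionSpec(start=861, end=867)
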