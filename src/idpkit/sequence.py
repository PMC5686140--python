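"""Protein sequence container and FASTA input/output.

The :class:`ProteinSequence` is the substrate of every sequence-level
descriptor in the toolkit.  It is a thin, validated wrapper around a string
over the 20 standard one-letter amino-acid codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

from .exceptions import InputError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Parameters
    ----------
    id : str
        Free-text identifier (FASTA header up to the first whitespace).
    residues : str
        Sequence over the 20 standard one-letter codes; validated and
        upper-cased on construction.
    """

    id: str
    residues: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        res = self.residues.upper()
        if not res:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = [(i + 1, c) for i, c in enumerate(res) if c not in _AA_SET]
        if bad:
            detail = ", ".join(f"{c!r} at position {i}" for i, c in bad[:5])
            more = "" if len(bad) <= 5 else f" (+{len(bad) - 5} more)"
            raise InputError(
                f"sequence {self.id!r} contains non-standard residues: {detail}{more}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def n(self) -> int:
        """Residue count N."""
        return len(self.residues)


def _translate_cds(nt: str, record_id: str) -> str:
    """Translate the first ORF (ATG .. stop) of a nucleotide CDS."""
    nt = nt.upper().replace("U", "T")
    start = nt.find("ATG")
    if start < 0:
        raise InputError(f"record {record_id!r}: no ATG start codon found")
    aa = str(Seq(nt[start:]).translate(to_stop=True))
    if not aa:
        raise InputError(f"record {record_id!r}: empty translation")
    return aa


def read_fasta(path, translate_cds: bool = False) -> list[ProteinSequence]:
    """Read one or more sequences from a FASTA file.

    With ``translate_cds=True`` each record is treated as a nucleotide
    coding sequence and its first ORF is translated with the standard
    genetic code (the stop codon is dropped).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq)
        if translate_cds:
            seq = _translate_cds(seq, rec.id)
        out.append(ProteinSequence(rec.id, seq, description=rec.description))
    return out


def write_fasta(sequences, path, width: int = 60) -> None:
    """Write sequences to ``path`` in FASTA format."""
    if isinstance(sequences, ProteinSequence):
        sequences = [sequences]
    with open(path, "w") as fh:
        for s in sequences:
            header = s.description if s.description else s.id
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")
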