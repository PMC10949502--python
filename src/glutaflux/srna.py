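"""Antisense sRNA design: target windows, binding sequences, cassette assembly.

A synthetic repressor sRNA is built from three parts, 5' to 3': a
target-binding residue (the reverse complement of a window over the target's
translation-initiation region), a scaffold recruiting Hfq (MicC, DsrA or
MicF families), and a transcription terminator.

Coordinates use biological numbering with no position zero: the A of the
start codon is +1, the base immediately 5' of it is -1.  The default window
(+1 .. +24) therefore spans the start codon through nucleotide +24 and gives
a 24-nt binding sequence; the wider GFP-style window (-4 .. +48) gives 52 nt.

Folding-energy optimisation of marginal residues is out of scope; pass a
hand-edited binding sequence to :func:`assemble_srna` instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TargetWindow",
    "SrnaDesign",
    "DEFAULT_WINDOW",
    "GFP_WINDOW",
    "design_binding_sequence",
    "assemble_srna",
    "reverse_complement",
    "load_fasta_sequences",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class TargetWindow:
    """A window in start-codon-relative coordinates (no position 0)."""

    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        if self.start_offset == 0 or self.end_offset == 0:
            raise ValueError("position 0 does not exist; -1 abuts +1")
        if self.end_offset < self.start_offset:
            raise ValueError("window end before start")

    @property
    def length(self) -> int:
        """Window length under the no-zero rule (crossing -1/+1 loses no base)."""
        span = self.end_offset - self.start_offset + 1
        if self.start_offset < 0 < self.end_offset:
            span -= 1  # position 0 does not exist
        return span


#: the standard design: AUG through +24, a 24-nt binding residue
DEFAULT_WINDOW = TargetWindow(1, 24)
#: the wider window used for GFP reporter silencing: -4 through +48 (52 nt)
GFP_WINDOW = TargetWindow(-4, 48)


@dataclass
class SrnaDesign:
    target_id: str
    binding_sequence: str
    scaffold_name: str
    scaffold_sequence: str
    terminator_sequence: str

    @property
    def full_sequence(self) -> str:
        return self.binding_sequence + self.scaffold_sequence + self.terminator_sequence


def _normalize(seq: str) -> str:
    seq = seq.strip().upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"sequence contains non-ACGTU characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return str(Seq(_normalize(seq)).reverse_complement())


def _offset_to_index(offset: int, start_index: int) -> int:
    # +1 maps to start_index; -1 maps to start_index - 1 (no position 0)
    return start_index + offset - 1 if offset > 0 else start_index + offset


def design_binding_sequence(
    cds_with_context: str,
    start_index: int,
    window: TargetWindow = DEFAULT_WINDOW,
) -> str:
    """Antisense binding sequence for a window over the sense strand.

    ``start_index`` is the 0-based position of the A of the start codon
    within ``cds_with_context``.  Returns the reverse complement of the
    sense window.  A non-ATG codon at the start index (GTG/TTG starts occur)
    triggers a warning, not an error.
    """
    seq = _normalize(cds_with_context)
    first = _offset_to_index(window.start_offset, start_index)
    last = _offset_to_index(window.end_offset, start_index)
    if first < 0 or last >= len(seq):
        raise ValueError(
            f"window {window.start_offset}..{window.end_offset} falls outside "
            f"the supplied sequence (length {len(seq)}, start at {start_index})"
        )
    codon = seq[start_index:start_index + 3]
    if codon != "ATG":
        warnings.warn(
            f"codon at start_index is {codon!r}, not ATG (alternative start?)",
            stacklevel=2,
        )
    sense = seq[first:last + 1]
    assert len(sense) == window.length
    return reverse_complement(sense)


# ---------------------------------------------------------------------------
# cassette assembly
# ---------------------------------------------------------------------------

def load_fasta_sequences(path: Union[str, Path]) -> Dict[str, str]:
    """Read a FASTA file into {record id: normalized sequence}."""
    return {rec.id: _normalize(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def _bundled(name: str) -> Dict[str, str]:
    ref = resources.files("glutaflux.data") / name
    with resources.as_file(ref) as p:
        return load_fasta_sequences(p)


def _bundled_scaffolds() -> Dict[str, str]:
    return _bundled("scaffolds_synthetic.fasta")


def _bundled_terminators() -> Dict[str, str]:
    return _bundled("terminators_synthetic.fasta")


def assemble_srna(
    binding: str,
    scaffold_name: str = "MicC",
    scaffold_fasta: Optional[Union[str, Path]] = None,
    terminator_fasta: Optional[Union[str, Path]] = None,
    target_id: str = "",
) -> SrnaDesign:
    """Concatenate binding residue + scaffold + terminator into a cassette.

    Named scaffolds resolve against the bundled sequence file (synthetic
    stand-ins — see its header; replace with validated scaffolds via
    ``scaffold_fasta`` for construct design).  A user FASTA gets scaffold
    name ``custom`` unless it contains a record matching ``scaffold_name``.
    """
    binding = _normalize(binding)
    if not binding:
        raise ValueError("binding sequence is empty")

    if scaffold_fasta is not None:
        seqs = load_fasta_sequences(scaffold_fasta)
        if scaffold_name in seqs:
            scaffold_seq = seqs[scaffold_name]
        elif len(seqs) == 1:
            scaffold_name = "custom"
            scaffold_seq = next(iter(seqs.values()))
        else:
            raise KeyError(
                f"scaffold {scaffold_name!r} not in {scaffold_fasta}; "
                f"records: {sorted(seqs)}"
            )
    else:
        seqs = _bundled_scaffolds()
        if scaffold_name not in seqs:
            raise KeyError(
                f"unknown scaffold {scaffold_name!r}; bundled scaffolds: "
                + ", ".join(sorted(seqs))
            )
        scaffold_seq = seqs[scaffold_name]

    if terminator_fasta is not None:
        term_seqs = load_fasta_sequences(terminator_fasta)
        terminator_seq = next(iter(term_seqs.values()))
    else:
        terminator_seq = next(iter(_bundled_terminators().values()))

    return SrnaDesign(
        target_id=target_id,
        binding_sequence=binding,
        scaffold_name=scaffold_name,
        scaffold_sequence=scaffold_seq,
        terminator_sequence=terminator_seq,
    )
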