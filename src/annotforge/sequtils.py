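"""Small shared sequence helpers (translation, six-frame scans)."""

from __future__ import annotations

from Bio.Seq import Seq

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Standard-table translation of a frame; trailing partial codon dropped.

    Stops appear as '*'; alternative starts (GTG/TTG) are NOT rewritten to M,
    so translations are position-independent and peptide matching stays exact.
    """
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def six_frame_translations(seq: str) -> list[tuple[str, int, str]]:
    """All six frame translations of a DNA string.

    Returns (strand, frame_offset, protein) where frame_offset in 0..2 is
    the offset into the reading-direction sequence (forward sequence for
    '+', reverse complement for '-').
    """
    rc = revcomp(seq)
    out = []
    for f in range(3):
        out.append(("+", f, translate(seq[f:])))
        out.append(("-", f, translate(rc[f:])))
    return out


def collapse_il(protein: str) -> str:
    """Map L to I: tandem MS cannot distinguish the isobaric pair."""
    return protein.replace("L", "I")
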