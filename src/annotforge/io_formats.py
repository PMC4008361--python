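"""Readers and writers for the external formats the pipeline touches.

One coordinate convention rules everywhere inside the package: 0-based,
half-open, genome coordinates, for every feature on either strand.
Conversion to the 1-based closed convention of GFF3 happens only at the
I/O boundary.  bedGraph and BED are already 0-based half-open and pass
through unchanged.  Minus-strand features are stored in genome
coordinates; sequence extraction reverse-complements on demand.

Genomes are treated as linear: origin-spanning features are not
supported (a documented limitation, irrelevant for the toy data this
package ships with).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "CoverageTrack",
    "FragmentAlignment",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "read_fragments_bed",
    "write_bed",
    "FRAGMENT_MIN_LEN",
    "FRAGMENT_MAX_LEN",
]

#: size window of the small-RNA gel purification (nt); fragments outside
#: this window are rejected at load time.
FRAGMENT_MIN_LEN = 15
FRAGMENT_MAX_LEN = 50

_DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome/contig sequence, uppercased on load."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end); reverse-complemented when strand == '-'."""
        if not (0 <= start <= end <= self.length):
            raise ValueError(f"interval [{start},{end}) outside genome of length {self.length}")
        s = self.seq[start:end]
        if strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


@dataclass
class GeneModel:
    """A genomic feature in internal 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"  # CDS, rRNA, tRNA, novel_ORF, RBS, region
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"{self.gene_id}: bad interval [{self.start},{self.end})")
        if (
            self.kind == "CDS"
            and (self.end - self.start) % 3 != 0
            and "broken" not in self.attributes
        ):
            raise FormatError(
                f"{self.gene_id}: CDS length {self.end - self.start} not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def frame(self) -> int:
        """Reading-frame phase (0..2) in reading direction, genome-relative."""
        return self.start % 3 if self.strand == "+" else self.end % 3

    def sequence(self, genome: GenomeSequence) -> str:
        return genome.subseq(self.start, self.end, self.strand)

    def overlaps(self, other: "GeneModel") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class CoverageTrack:
    """Per-base read coverage for one library (one time point, one strand)."""

    library_id: str
    time_point: str
    strand: str  # '+', '-' or 'both'
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise FormatError(f"{self.library_id}: negative coverage values")

    @property
    def length(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class FragmentAlignment:
    """A collapsed small-RNA fragment alignment (duplicates share one record)."""

    chrom: str
    start: int
    end: int
    strand: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"fragment strand must be '+' or '-', got {self.strand!r}")
        if self.count < 1:
            raise FormatError("fragment count must be >= 1")
        if not FRAGMENT_MIN_LEN <= self.end - self.start <= FRAGMENT_MAX_LEN:
            raise FormatError(
                f"fragment length {self.end - self.start} outside the "
                f"{FRAGMENT_MIN_LEN}-{FRAGMENT_MAX_LEN} nt size window"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Genome coordinate of the 5' terminus (end-1 on the minus strand)."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        """Genome coordinate of the 3' terminus (the last covered base)."""
        return self.end - 1 if self.strand == "+" else self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) DNA FASTA; sequences are uppercased."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            records.append(GenomeSequence(id=rec.id, seq=seq))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, s.length, width):
                fh.write(s.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def _parse_attributes(text: str) -> dict:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _format_attributes(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read GFF3 features into internal 0-based half-open GeneModels.

    GFF3 columns 4/5 are 1-based closed; internally start = col4 - 1,
    end = col5.  Malformed records raise :class:`FormatError` naming the
    offending line number.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, source, kind, start_s, end_s, score, strand, phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand {strand!r} not supported")
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("ID", f"{chrom}:{start1}-{end1}")
            if source != ".":
                attrs.setdefault("source", source)
            try:
                models.append(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=chrom,
                        start=start1 - 1,
                        end=end1,
                        strand=strand,
                        kind=kind,
                        attributes=attrs,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = dict(m.attributes)
            attrs.pop("source", None)
            attrs = {"ID": m.gene_id, **{k: v for k, v in attrs.items() if k != "ID"}}
            source = m.attributes.get("source", "annotforge")
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        source,
                        m.kind,
                        str(m.start + 1),
                        str(m.end),
                        ".",
                        m.strand,
                        ".",
                        _format_attributes(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph / BED


def read_bedgraph(
    path: str | Path,
    genome_length: int,
    library_id: str | None = None,
    time_point: str = "",
    strand: str = "both",
) -> CoverageTrack:
    """Read a bedGraph into a dense per-base track; gaps read as 0.

    Overlapping intervals with conflicting values are an error; intervals
    outside [0, genome_length) are an error.
    """
    values = np.zeros(genome_length, dtype=float)
    seen = np.zeros(genome_length, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            start, end, val = int(cols[1]), int(cols[2]), float(cols[3])
            if not (0 <= start < end <= genome_length):
                raise FormatError(
                    f"{path}:{lineno}: interval [{start},{end}) outside genome "
                    f"of length {genome_length}"
                )
            overlap = seen[start:end]
            if overlap.any() and not np.allclose(values[start:end][overlap], val):
                raise FormatError(f"{path}:{lineno}: overlapping interval with conflicting value")
            values[start:end] = val
            seen[start:end] = True
    return CoverageTrack(
        library_id=library_id or Path(path).stem,
        time_point=time_point,
        strand=strand,
        values=values,
    )


def write_bedgraph(track: CoverageTrack, chrom: str, path: str | Path) -> None:
    """Run-length encode a dense track; zero runs are omitted (sparse)."""
    v = track.values
    with open(path, "w") as fh:
        if v.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [v.size]])
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_fragments_bed(path: str | Path) -> list[FragmentAlignment]:
    """Read collapsed small-RNA fragments from BED6 (score = duplicate count).

    Fragments outside the 15-50 nt size window are dropped with a warning,
    mirroring the gel size selection of the library prep.
    """
    frags: list[FragmentAlignment] = []
    n_filtered = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, _name, score, strand = cols[:6]
            start, end = int(start), int(end)
            length = end - start
            if not FRAGMENT_MIN_LEN <= length <= FRAGMENT_MAX_LEN:
                n_filtered += 1
                continue
            count = max(1, int(float(score))) if score != "." else 1
            frags.append(
                FragmentAlignment(chrom=chrom, start=start, end=end, strand=strand, count=count)
            )
    if n_filtered:
        warnings.warn(
            f"{path}: {n_filtered} fragment(s) outside the "
            f"{FRAGMENT_MIN_LEN}-{FRAGMENT_MAX_LEN} nt size window were dropped",
            stacklevel=2,
        )
    return frags


def write_bed(
    records: Iterable[FragmentAlignment | GeneModel],
    path: str | Path,
) -> None:
    """Write fragments or feature calls as BED6."""
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, FragmentAlignment):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t{r.count}\t{r.strand}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


def validate_files(paths: Sequence[str | Path], genome_length: int | None = None) -> list[str]:
    """Best-effort validation of a mixed list of input files; returns messages."""
    messages = []
    for p in paths:
        p = Path(p)
        suffix = p.suffix.lower()
        try:
            if suffix in {".fa", ".fasta", ".fna"}:
                seqs = read_fasta(p)
                messages.append(f"{p}: OK ({len(seqs)} sequence(s))")
            elif suffix in {".gff", ".gff3"}:
                models = read_gff3(p)
                messages.append(f"{p}: OK ({len(models)} feature(s))")
            elif suffix == ".bed":
                frags = read_fragments_bed(p)
                messages.append(f"{p}: OK ({len(frags)} fragment(s))")
            elif suffix in {".bedgraph", ".bg"}:
                if genome_length is None:
                    messages.append(f"{p}: SKIP (genome length unknown)")
                else:
                    read_bedgraph(p, genome_length)
                    messages.append(f"{p}: OK")
            else:
                messages.append(f"{p}: SKIP (unrecognised extension)")
        except (FormatError, OSError) as exc:
            messages.append(f"{p}: ERROR {exc}")
    return messages
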