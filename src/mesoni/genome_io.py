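"""Sequence and annotation I/O.

Reads and writes multi-record FASTA (via Biopython), trims 3' poly-A tails,
and serializes feature sets as GFF3.  Internally every coordinate is 0-based
half-open; file output follows the 1-based inclusive GFF3 convention.  RNA
input (U) is silently normalized to the DNA alphabet, since deposited
genome records use DNA letters; all downstream motifs are stored as DNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .errors import DegenerateSequenceError, FastaFormatError, GFFError

_STRICT_ALPHABET = re.compile(r"^[ACGT]*$")
# IUPAC nucleotide codes accepted under --allow-ambiguous
_IUPAC_ALPHABET = re.compile(r"^[ACGTRYSWKMBDHVN]*$")


@dataclass(frozen=True)
class GenomeRecord:
    """One (poly-A-trimmable) genome sequence.

    ``polya_len`` records the length of a trimmed 3' tail (0 if untrimmed).
    """

    id: str
    seq: str
    polya_len: int = 0
    source: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Feature:
    """A located, named genome feature (0-based half-open coordinates)."""

    seqid: str
    name: str
    start: int
    end: int
    frame: int | None = None
    ftype: str = "region"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GFFError(f"feature {self.name}: bad span [{self.start}, {self.end})")
        if self.frame is not None and self.frame != self.start % 3:
            raise GFFError(
                f"feature {self.name}: frame {self.frame} != start mod 3 "
                f"({self.start % 3})"
            )


def normalize_seq(raw: str, record_id: str = "?", allow_ambiguous: bool = False) -> str:
    """Uppercase, U->T; reject characters outside the accepted alphabet."""
    seq = str(raw).upper().replace("U", "T")
    pattern = _IUPAC_ALPHABET if allow_ambiguous else _STRICT_ALPHABET
    if not pattern.match(seq):
        bad = sorted(set(seq) - set("ACGTRYSWKMBDHVN" if allow_ambiguous else "ACGT"))
        raise FastaFormatError(
            f"record {record_id!r}: non-nucleotide characters {bad}"
        )
    return seq


def read_fasta(path, allow_ambiguous: bool = False) -> list[GenomeRecord]:
    """Read a FASTA file into normalized :class:`GenomeRecord` objects.

    U is normalized to T and case is folded.  No poly-A trimming is applied.
    Raises :class:`FastaFormatError` on an empty file or a record containing
    characters outside the (strict or IUPAC) nucleotide alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_seq(str(rec.seq), rec.id, allow_ambiguous)
        records.append(GenomeRecord(id=rec.id, seq=seq, source=str(path)))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[GenomeRecord], path, wrap: int = 70) -> None:
    """Write records as multi-FASTA, wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def trim_polya(rec: GenomeRecord, min_run: int = 5) -> GenomeRecord:
    """Remove the trailing maximal run of A if it is at least ``min_run`` long.

    The removed length is recorded in ``polya_len``.  Idempotent: a trimmed
    record no longer ends in a qualifying run.  A genome consisting entirely
    of A is rejected as degenerate.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    seq = rec.seq
    n = len(seq)
    run = n - len(seq.rstrip("A"))
    if run == n and n > 0:
        raise DegenerateSequenceError(f"record {rec.id!r} is entirely poly-A")
    if run >= min_run:
        return replace(rec, seq=seq[: n - run], polya_len=rec.polya_len + run)
    return rec


def _gff3_escape(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
        .replace("\t", "%09")
        .replace("\n", "%0A")
    )


def write_gff3(features: list[Feature], path) -> None:
    """Serialize features as a GFF3 v3 file.

    Coordinates are converted to 1-based inclusive; strand is always "+"
    ((+)ssRNA genome, no reverse-strand scan).  Rows are ordered
    deterministically by (seqid, start, name).  Identical (name, start, end)
    duplicates are rejected.
    """
    seen = set()
    for f in features:
        key = (f.seqid, f.name, f.start, f.end)
        if key in seen:
            raise GFFError(f"duplicate feature {f.name} [{f.start}, {f.end})")
        seen.add(key)
    ordered = sorted(features, key=lambda f: (f.seqid, f.start, f.name))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ordered:
            phase = "0" if f.ftype == "CDS" else "."
            attrs = [f"Name={_gff3_escape(f.name)}"]
            attrs += [f"{k}={_gff3_escape(v)}" for k, v in sorted(f.attributes.items())]
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        "mesoni",
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        "+",
                        phase,
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[Feature]:
    """Parse a GFF3 file back into :class:`Feature` objects (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    features = []
    for f in db.all_features():
        attributes = {
            k: v[0] for k, v in f.attributes.items() if k != "Name" and v
        }
        name = f.attributes.get("Name", [f.id])[0]
        start = f.start - 1  # back to 0-based half-open
        frame = start % 3 if f.featuretype == "CDS" else None
        features.append(
            Feature(
                seqid=f.seqid,
                name=name,
                start=start,
                end=f.end,
                frame=frame,
                ftype=f.featuretype,
                attributes=attributes,
            )
        )
    return features
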