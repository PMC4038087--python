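"""ORF discovery, canonical mesonivirus genome-plan assignment, and -1 PRF
conceptual translation.

Mesonivirus genomes (~20 kb, (+)ssRNA) carry a fixed plan: a long 5'UTR,
ORF1a overlapped at its 3' end by ORF1b in the -1 frame (expressed as the
pp1ab replicase polyprotein via a programmed -1 ribosomal frameshift at a
GGAUUUU slippery heptamer), ORF2a (spike) with the nucleoprotein ORF2b
nested in its 5' third in an alternative frame, overlapping ORF3a/ORF3b
(with a candidate CACUUUU heptamer permitting a read-through p3ab product),
a small conserved ORF4, and a long 3' terminal region before the poly-A
tail.  The paper-level plan gives no algorithm; the rule set implemented by
:func:`assign_architecture` (size thresholds, overlap requirements,
longest-candidate tie-breaks) is this package's operationalization, with
every threshold exposed in :class:`ArchitectureParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import ArchitectureError, FrameshiftError
from .genome_io import Feature, GenomeRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SLIPPERY_MOTIFS = ("GGATTTT", "CACTTTT")  # DNA alphabet (U==T)


def translate(nt: str) -> str:
    """Standard-code translation (table 1); ``nt`` length must be a codon multiple."""
    if len(nt) % 3:
        raise ValueError("length not a multiple of 3")
    return str(Seq(nt).translate(table=1))


@dataclass(frozen=True)
class Orf:
    """An open reading frame: [start, end) with ``end`` after the stop codon."""

    start: int
    end: int
    frame: int
    has_start_codon: bool
    protein: str

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Orf") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class FusionProduct:
    """A conceptual -1 frameshift polyprotein (pp1ab or p3ab).

    ``join_pos`` is the first position read in the new frame; the nucleotide
    at ``join_pos - 1`` is read twice (shared base at the shift site).
    """

    name: str
    join_pos: int
    protein: str
    slippery_motif: str


@dataclass
class Architecture:
    """The named feature set of one genome under the canonical plan."""

    genome_id: str
    utr5: tuple[int, int]
    orf1a: Orf
    orf1b: Orf
    orf2a: Orf
    orf2b: Orf
    orf3a: Orf
    orf3b: Orf
    orf4: Orf | None
    term3: tuple[int, int]
    small_orfs: list[Orf] = field(default_factory=list)
    slippery_sites: list[tuple[str, int]] = field(default_factory=list)

    def named_orfs(self) -> dict[str, Orf]:
        out = {
            "ORF1a": self.orf1a,
            "ORF1b": self.orf1b,
            "ORF2a": self.orf2a,
            "ORF2b": self.orf2b,
            "ORF3a": self.orf3a,
            "ORF3b": self.orf3b,
        }
        if self.orf4 is not None:
            out["ORF4"] = self.orf4
        return out

    def overlap_1a1b(self) -> tuple[int, int]:
        return (max(self.orf1a.start, self.orf1b.start), min(self.orf1a.end, self.orf1b.end))

    def overlap_3a3b(self) -> tuple[int, int]:
        return (max(self.orf3a.start, self.orf3b.start), min(self.orf3a.end, self.orf3b.end))

    def features(self) -> list[Feature]:
        feats = []
        for name, orf in self.named_orfs().items():
            feats.append(
                Feature(
                    seqid=self.genome_id,
                    name=name,
                    start=orf.start,
                    end=orf.end,
                    frame=orf.frame,
                    ftype="CDS",
                    attributes={"protein_length": str(len(orf.protein))},
                )
            )
        if self.utr5[1] > self.utr5[0]:
            feats.append(
                Feature(self.genome_id, "UTR5", self.utr5[0], self.utr5[1], ftype="five_prime_UTR")
            )
        if self.term3[1] > self.term3[0]:
            feats.append(
                Feature(self.genome_id, "term3", self.term3[0], self.term3[1], ftype="region")
            )
        for motif, pos in self.slippery_sites:
            feats.append(
                Feature(
                    self.genome_id,
                    f"slippery_{motif}",
                    pos,
                    pos + 7,
                    ftype="sequence_motif",
                    attributes={"motif": motif},
                )
            )
        return feats

    def to_dict(self) -> dict:
        d = {
            "genome_id": self.genome_id,
            "utr5": list(self.utr5),
            "term3": list(self.term3),
            "orfs": {
                name: {
                    "start": orf.start,
                    "end": orf.end,
                    "frame": orf.frame,
                    "has_start_codon": orf.has_start_codon,
                    "protein_length": len(orf.protein),
                }
                for name, orf in self.named_orfs().items()
            },
            "small_orfs": [[o.start, o.end] for o in self.small_orfs],
            "slippery_sites": [[m, p] for m, p in self.slippery_sites],
        }
        return d


@dataclass(frozen=True)
class ArchitectureParams:
    """Config-exposed thresholds of the canonical assignment rule set."""

    min_orf1a_nt: int = 3000
    min_orf2a_nt: int = 2000
    min_orf3a_nt: int = 500
    orf4_range_nt: tuple[int, int] = (120, 200)
    min_small_orf_nt: int = 180
    orf3a_overlap_tolerance: int = 30


def find_orfs(seq: str, min_len_nt: int = 180, require_start: bool = True) -> list[Orf]:
    """Scan all three (+)-strand frames for ORFs of at least ``min_len_nt``.

    With ``require_start`` the ORF runs ATG..stop; otherwise the maximal
    stop-to-stop open segments are reported (no start codon needed).  Only
    stop-terminated ORFs are returned: an open run truncated by the genome
    end is not a complete reading frame.  Sorted by start coordinate.
    """
    if min_len_nt < 6 or min_len_nt % 3:
        raise ValueError("min_len_nt must be >= 6 and divisible by 3")
    n = len(seq)
    orfs: list[Orf] = []
    for frame in range(3):
        prev = frame
        for s in range(frame, n - 2, 3):
            if seq[s : s + 3] in STOP_CODONS:
                seg_start, seg_end = prev, s + 3
                prev = s + 3
                start = seg_start
                if require_start:
                    start = -1
                    for a in range(seg_start, seg_end - 3, 3):
                        if seq[a : a + 3] == "ATG":
                            start = a
                            break
                    if start < 0:
                        continue
                if seg_end - start < min_len_nt:
                    continue
                orfs.append(
                    Orf(
                        start=start,
                        end=seg_end,
                        frame=frame,
                        has_start_codon=seq[start : start + 3] == "ATG",
                        protein=translate(seq[start : seg_end - 3]),
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def _longest(cands: list[Orf]) -> Orf | None:
    # ties broken by smaller start coordinate
    if not cands:
        return None
    return max(cands, key=lambda o: (len(o), -o.start))


def assign_architecture(
    rec: GenomeRecord,
    orfs: list[Orf] | None = None,
    slippery_sites: list[tuple[str, int]] | None = None,
    params: ArchitectureParams | None = None,
) -> Architecture:
    """Map ORFs onto the canonical mesonivirus genome plan.

    Raises :class:`ArchitectureError` naming the first element that cannot
    be assigned.  ``slippery_sites`` (from the motif module) are carried
    through; pass [] when scanning has not yet been done.
    """
    p = params or ArchitectureParams()
    seq = rec.seq
    started = orfs if orfs is not None else find_orfs(seq, min_len_nt=120, require_start=True)
    started = [o for o in started if o.has_start_codon]
    open_segments = find_orfs(seq, min_len_nt=120, require_start=False)

    orf1a = next((o for o in started if len(o) >= p.min_orf1a_nt), None)
    if orf1a is None:
        raise ArchitectureError("ORF1a")

    f1b = (orf1a.frame + 2) % 3
    orf1b = _longest(
        [
            s
            for s in open_segments
            if s.frame == f1b and s.start < orf1a.end and s.end > orf1a.end
        ]
    )
    if orf1b is None:
        raise ArchitectureError("ORF1b")

    # Candidates nested inside the replicase region are excluded: ORF1b's
    # interior almost always contains internal ATGs that would otherwise
    # open a >=2000-nt reading frame ending at ORF1b's own stop.
    orf2a = next(
        (
            o
            for o in started
            if len(o) >= p.min_orf2a_nt
            and o.start >= orf1a.end
            and o.end > orf1b.end
        ),
        None,
    )
    if orf2a is None:
        raise ArchitectureError("ORF2a")

    third = orf2a.start + len(orf2a) // 3
    orf2b = _longest(
        [
            o
            for o in started
            if o.frame != orf2a.frame
            and o.start >= orf2a.start
            and o.start < third
            and o.end <= orf2a.end
        ]
    )
    if orf2b is None:
        raise ArchitectureError("ORF2b")

    orf3a = next(
        (
            o
            for o in started
            if len(o) >= p.min_orf3a_nt
            and o.start >= orf2a.end - p.orf3a_overlap_tolerance
            and o.end > orf2a.end
            and o is not orf2a
        ),
        None,
    )
    if orf3a is None:
        raise ArchitectureError("ORF3a")

    half = orf3a.start + len(orf3a) // 2
    orf3b = _longest(
        [
            o
            for o in started
            if o.frame != orf3a.frame and half <= o.start < orf3a.end
        ]
    )
    if orf3b is None:
        raise ArchitectureError("ORF3b")

    lo, hi = p.orf4_range_nt
    orf4 = next(
        (o for o in started if lo <= len(o) <= hi and o.start >= orf3b.end), None
    )

    assigned = {orf1a, orf1b, orf2a, orf2b, orf3a, orf3b} | ({orf4} if orf4 else set())
    small = [
        o
        for o in started
        if o not in assigned and len(o) >= p.min_small_orf_nt
    ]
    last_end = max(o.end for o in assigned)
    return Architecture(
        genome_id=rec.id,
        utr5=(0, orf1a.start),
        orf1a=orf1a,
        orf1b=orf1b,
        orf2a=orf2a,
        orf2b=orf2b,
        orf3a=orf3a,
        orf3b=orf3b,
        orf4=orf4,
        term3=(last_end, len(seq)),
        small_orfs=small,
        slippery_sites=list(slippery_sites or []),
    )


def translate_prf(
    rec: GenomeRecord,
    upstream: Orf,
    downstream: Orf,
    slippery_pos: int,
    name: str | None = None,
) -> FusionProduct:
    """Conceptually translate a -1 programmed ribosomal frameshift product.

    The fused coding sequence is ``genome[upstream.start:j] +
    genome[j-1:downstream.end]`` where ``j`` is the smallest upstream-codon
    boundary at least 7 nt past the slippery heptamer: one nucleotide
    (``j-1``) is read twice, the shared base at the shift site.  ``j`` is
    advanced codon-wise (within 9 nt of the first boundary) until the fusion
    is stop-free; if none works a :class:`FrameshiftError` is raised.
    """
    seq = rec.seq
    if downstream.frame != (upstream.frame + 2) % 3:
        raise FrameshiftError(
            f"downstream frame {downstream.frame} is not -1 relative to "
            f"upstream frame {upstream.frame}"
        )
    motif = seq[slippery_pos : slippery_pos + 7]
    if motif not in SLIPPERY_MOTIFS:
        raise FrameshiftError(
            f"no slippery heptamer at {slippery_pos} (found {motif!r})"
        )
    ov_start = max(upstream.start, downstream.start)
    ov_end = min(upstream.end, downstream.end)
    if not (ov_start <= slippery_pos and slippery_pos + 7 <= ov_end):
        raise FrameshiftError("slippery site outside the ORF overlap")

    first = slippery_pos + 7
    first += (-(first - upstream.start)) % 3  # round up to a codon boundary
    for j in range(first, slippery_pos + 17, 3):
        if j - 1 < downstream.start or j > upstream.end:
            continue
        fused = seq[upstream.start : j] + seq[j - 1 : downstream.end]
        if len(fused) % 3:
            continue
        aa = translate(fused)
        body, stop = aa[:-1], aa[-1]
        if stop == "*" and "*" not in body:
            return FusionProduct(
                name=name or "pp1ab",
                join_pos=j,
                protein=body,
                slippery_motif=motif,
            )
    raise FrameshiftError(
        f"no stop-free -1 fusion join in [{slippery_pos + 7}, {slippery_pos + 16}]"
    )
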