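"""Synthetic mesonivirus-like genomes with a fully known truth table.

The generator emits ~20-kb genomes following the canonical plan — 5'UTR
(~360 nt) with leader TRS elements, ORF1a with an optional block insertion
carrying imperfect SKRKGK-type repeats, a GGAUUUU slippery heptamer at a
valid -1 frameshift join into a stop-free ORF1b, body TRS elements before
ORF2a and ORF3a, the nucleoprotein ORF2b nested in ORF2a's 5' third, an
overlapping ORF3a/ORF3b pair with a CACUUUU heptamer, a small ORF4, a long
3' terminal region and a poly-A tail — together with the exact coordinates,
fusion-protein texts and motif positions that a correct annotation must
recover.  Reference replicase-domain amino-acid sequences are encoded into
ORF1a/ORF1b (optionally pre-evolved at a controlled WAG distance) so the
demarcation stage is exercisable end to end.

Construction is by constrained sampling: every planted element is written
as fixed bases, the remaining positions are drawn uniformly and locally
resampled until no constrained reading frame contains a stray stop codon,
no intergenic zone contains a start codon (which could seed a spurious
ORF4-sized reading frame), and no ORF overlap contains an unplanned
slippery heptamer.  A final verification pass re-annotates the genome with
the package's own pipeline and compares against the truth table; the rare
failing draw (chance TRS matches etc.) is retried on a deterministic child
seed.  Everything is reproducible from the single spec seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .demarcation import AA_ORDER, load_model, load_reference_domains
from .errors import GenerationError
from .genome_io import GenomeRecord
from .motifs import TRS_PATTERNS, scan_motif
from .orf_architecture import (
    STOP_CODONS,
    ArchitectureParams,
    assign_architecture,
    translate,
    translate_prf,
)

BASES = "ACGT"

# one fixed sense codon per amino acid, used to encode planted proteins
CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "AGT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

TRS1_INSTANCE = "ATCGTACTACTACTA"   # ATxxTACTACTACTA with x -> C, G
TRS2_INSTANCE = "AGATTACTCTCCCA"    # AGAx(x)ACTCTCCCA with both optionals
SLIP1 = "GGATTTT"
SLIP3 = "CACTTTT"


def encode_protein_nt(aa: str) -> str:
    return "".join(CODON_OF[x] for x in aa)


@dataclass(frozen=True)
class GenomeSpec:
    """Layout and randomness parameters of one synthetic genome.

    Defaults emulate the study conditions: ~20.1-kb genomes with a 360-nt
    5'UTR, a ~1790-nt 3' terminal region, ORF1ab spanning roughly two
    thirds of the genome, and optional ORF1a block insertions of
    180/573/588 nt starting ~1300 nt from the 5' terminus.
    """

    utr5_len: int = 360
    orf1a_len: int = 9300            # excluding any insertion
    insertion_len: int = 0           # 0, 180, 573 or 588 typical
    insertion_offset: int = 939      # nt into ORF1a; ~1300 from 5' end
    orf1b_len: int = 4200
    orf1b_overlap: int = 46          # must be == 1 (mod 3)
    intergenic_2a: int = 60
    orf2a_len: int = 3300
    orf2b_offset: int = 151          # must be == 1 (mod 3); in 5' third
    orf2b_len: int = 660
    intergenic_3a: int = 60
    orf3a_len: int = 690
    orf3b_offset: int = 440          # must be == 2 (mod 3); in 3' half
    orf3b_len: int = 420
    intergenic_4: int = 80
    orf4_len: int = 150
    term3_len: int = 1790
    polya_len: int = 25
    repeat_seed: str = "SKRKGK"
    trs_positions: tuple | None = None  # ((pattern_id, pos), ...) or default
    domain_divergence: float = 0.0   # WAG distance of planted domains from reference
    plant_domains: bool = True
    seed: int = 0
    max_attempts: int = 8


@dataclass
class TruthTable:
    """Everything a correct annotation of the emitted genome must recover."""

    genome_id: str
    seed: int
    body_len: int
    polya_len: int
    utr5: tuple[int, int]
    term3: tuple[int, int]
    orfs: dict  # name -> {"start", "end", "frame"}
    slippery: list  # [(motif, pos)]
    trs: list  # [(pattern_id, pos, text)]
    pp1ab: str
    pp1ab_join: int
    p3ab: str
    p3ab_join: int
    insertion_span: tuple[int, int] | None
    repeats: list  # [(genome_pos, mismatches)]
    domain_spans_nt: dict  # name -> (start, end) genome coords
    domain_spans_aa: dict  # name -> (start, end) in pp1ab coords
    protected: list  # positions that isolate mutations must avoid
    nostop_frames: list  # [(frame, lo, hi)] codon spans kept stop-free
    noatg_zones: list  # [(lo, hi)] zones kept free of ATG
    overlap_spans: dict  # {"1a1b": (lo, hi), "3a3b": (lo, hi)}
    construction_attempts: int = 1
    schema_version: str = "1"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _validate(spec: GenomeSpec) -> None:
    msgs = []
    for name in ("orf1a_len", "insertion_len", "orf1b_len", "orf2a_len",
                 "orf2b_len", "orf3a_len", "orf3b_len", "orf4_len"):
        if getattr(spec, name) % 3:
            msgs.append(f"{name} not a codon multiple")
    if spec.orf1b_overlap % 3 != 1:
        msgs.append("orf1b_overlap must be 1 (mod 3) for a -1 frame overlap")
    if spec.orf2b_offset % 3 != 1:
        msgs.append("orf2b_offset must be 1 (mod 3) for an alternative frame")
    if spec.orf3b_offset % 3 != 2:
        msgs.append("orf3b_offset must be 2 (mod 3) for a -1 frame overlap")
    if spec.insertion_len and spec.insertion_offset % 3:
        msgs.append("insertion_offset must lie on a codon boundary")
    if spec.insertion_len and not (
        3 <= spec.insertion_offset <= 6000 - spec.insertion_len
    ):
        msgs.append("insertion must fall in the 5' region of ORF1a, before the domains")
    if spec.orf1a_len < 6600:
        msgs.append("orf1a_len too short to host 3CLpro and the 1b overlap")
    if spec.orf1b_len < 2600:
        msgs.append("orf1b_len too short to host RdRp and ZnHel1")
    if not spec.orf2b_offset + 6 < spec.orf2b_len:
        msgs.append("orf2b_offset too large relative to orf2b_len")
    if not (spec.orf2b_offset + spec.orf2b_len + 3 <= spec.orf2a_len):
        msgs.append("ORF2b does not fit inside ORF2a")
    if not (spec.orf2b_offset < spec.orf2a_len // 3):
        msgs.append("ORF2b start not in the 5' third of ORF2a")
    if not (spec.orf3a_len // 2 <= spec.orf3b_offset < spec.orf3a_len - 14):
        msgs.append("ORF3b start not in the 3' half of ORF3a")
    if not (spec.orf3b_offset + spec.orf3b_len >= spec.orf3a_len + 8):
        msgs.append("ORF3b must extend at least 8 nt past the ORF3a stop")
    if not (spec.orf3b_len > spec.orf3a_len - spec.orf3a_len // 2 + 6):
        msgs.append(
            "orf3b_len too short to dominate chance third-frame reading frames"
        )
    if not (120 <= spec.orf4_len <= 200):
        msgs.append("orf4_len outside the 120-200 nt ORF4 range")
    if spec.utr5_len < 240:
        msgs.append("utr5_len too short to host the leader TRS elements")
    for name in ("intergenic_2a", "intergenic_3a", "intergenic_4"):
        if getattr(spec, name) < 56:
            msgs.append(f"{name} too short to host a body TRS element")
    if spec.polya_len < 0 or spec.term3_len < 10:
        msgs.append("nonsensical tail lengths")
    if msgs:
        raise GenerationError("; ".join(msgs))


class _Layout:
    """Deterministic coordinate arithmetic for a validated spec."""

    def __init__(self, spec: GenomeSpec):
        self.spec = spec
        self.s1a = spec.utr5_len
        self.e1a = self.s1a + spec.orf1a_len + spec.insertion_len
        self.o1b = self.e1a - spec.orf1b_overlap
        self.e1b = self.o1b + spec.orf1b_len
        self.s2a = self.e1b + spec.intergenic_2a
        self.e2a = self.s2a + spec.orf2a_len
        self.s2b = self.s2a + spec.orf2b_offset
        self.e2b = self.s2b + spec.orf2b_len
        self.s3a = self.e2a + spec.intergenic_3a
        self.e3a = self.s3a + spec.orf3a_len
        self.s3b = self.s3a + spec.orf3b_offset
        self.e3b = self.s3b + spec.orf3b_len
        self.s4 = self.e3b + spec.intergenic_4
        self.e4 = self.s4 + spec.orf4_len
        self.body_end = self.e4 + spec.term3_len
        self.f1 = self.s1a % 3
        self.f1b = self.o1b % 3
        self.f2a = self.s2a % 3
        self.f2b = self.s2b % 3
        self.f3a = self.s3a % 3
        self.f3b = self.s3b % 3
        self.f4 = self.s4 % 3
        assert self.f1b == (self.f1 + 2) % 3
        assert self.f3b == (self.f3a + 2) % 3
        self.slip1 = self.o1b + 7      # codon-aligned in ORF1a's frame
        self.slip3 = self.s3b + 4      # codon-aligned in ORF3a's frame
        self.join1 = self.slip1 + 9
        self.join3 = self.slip3 + 9
        if spec.insertion_len:
            self.ins = (self.s1a + spec.insertion_offset,
                        self.s1a + spec.insertion_offset + spec.insertion_len)
        else:
            self.ins = None
        # domains at fixed codon offsets, downstream of any insertion
        self.d3cl = self.s1a + spec.insertion_len + 6000
        self.drdrp = self.o1b + 300
        self.dznh = self.o1b + 1800
        if spec.trs_positions is not None:
            self.trs = [(pid, pos) for pid, pos in spec.trs_positions]
        else:
            self.trs = [
                ("TRS1", 170),
                ("TRS2", 190),
                ("TRS1", self.s2a - 40),
                ("TRS2", self.s3a - 40),
            ]
        allowed = [
            (0, self.s1a - 3),
            (self.e1b, self.s2a - 3),
            (self.e2a, self.s3a - 3),
            (self.e3b, self.s4 - 3),
        ]
        for pid, pos in self.trs:
            length = len(TRS1_INSTANCE if pid == "TRS1" else TRS2_INSTANCE)
            if not any(lo <= pos and pos + length <= hi for lo, hi in allowed):
                raise GenerationError(
                    f"TRS {pid}@{pos} outside the 5'UTR/intergenic regions"
                )


def _planted_domains(spec: GenomeSpec, rng: np.random.Generator) -> dict[str, str]:
    """Reference domain amino-acid sequences, optionally pre-evolved."""
    refs = {r.name: r.seq for r in load_reference_domains()}
    if spec.domain_divergence > 0:
        refs = {
            name: evolve_sequence(seq, spec.domain_divergence, "WAG-aa",
                                  rng.integers(0, 2**31 - 1))
            for name, seq in refs.items()
        }
    return refs


def _fixed_bases(lay: _Layout, spec: GenomeSpec, domains: dict[str, str]):
    """All planted content as position -> base, plus repeat annotations."""
    fixed: dict[int, str] = {}

    def put(pos: int, text: str):
        for i, ch in enumerate(text):
            if fixed.get(pos + i, ch) != ch:
                raise GenerationError(
                    f"planted elements collide at position {pos + i}"
                )
            fixed[pos + i] = ch

    # Each planted ATG start is preceded by an in-frame delimiter stop, so
    # the discovered ORF cannot extend upstream through a chance stop-free
    # run (e.g. a UTR ATG merging into ORF1a's stop-to-stop segment).
    put(lay.s1a - 3, "TAA")
    put(lay.s1a, "ATG")
    put(lay.e1a - 3, "TAA")
    put(lay.o1b - 3, "TAA")            # ORF1b 5' delimiter stop (-1 frame)
    put(lay.slip1, SLIP1)
    put(lay.e1b - 3, "TAA")
    put(lay.s2a - 3, "TAA")
    put(lay.s2a, "ATG")
    put(lay.e2a - 3, "TAA")
    put(lay.s2b - 3, "TAA")            # ORF2b delimiter stop
    put(lay.s2b, "ATG")
    put(lay.e2b - 3, "TAA")
    put(lay.s3a - 3, "TAA")
    put(lay.s3a, "ATG")
    put(lay.e3a - 3, "TAA")
    put(lay.s3b - 3, "TAA")            # ORF3b delimiter stop
    put(lay.s3b, "ATG")
    put(lay.slip3, SLIP3)
    put(lay.e3b - 3, "TAA")
    # Bound third-frame reading frames crossing ORF3a's end: without this a
    # chance ATG in ORF3a's 3' half can run stop-free into ORF4's stop and
    # outcompete the planted ORF3b under the longest-candidate rule.
    put(lay.e3a + 1, "TAA")
    put(lay.s4 - 3, "TAA")
    put(lay.s4, "ATG")
    put(lay.e4 - 3, "TAA")
    fixed[lay.body_end - 1] = "T"      # keep the body from ending in A

    trs_truth = []
    for pid, pos in lay.trs:
        text = TRS1_INSTANCE if pid == "TRS1" else TRS2_INSTANCE
        put(pos, text)
        trs_truth.append((pid, pos, text))

    repeats = []
    if lay.ins:
        lo, hi = lay.ins
        seed_aa = spec.repeat_seed
        seed_nt = encode_protein_nt(seed_aa)
        imperfect_aa = seed_aa[:-1] + ("R" if seed_aa[-1] != "R" else "K")
        if hi - lo >= 2 * len(seed_nt) + 9:
            put(lo, seed_nt)
            repeats.append((lo, 0))
            put(hi - len(seed_nt), encode_protein_nt(imperfect_aa))
            repeats.append((hi - len(seed_nt), 1))
            mid = lo + ((hi - lo) // 2 // 3) * 3
            frag = seed_nt[:9]
            if mid + len(frag) <= hi - len(seed_nt):
                put(mid, frag)
        elif hi - lo >= len(seed_nt):
            put(lo, seed_nt)
            repeats.append((lo, 0))

    if spec.plant_domains:
        put(lay.d3cl, encode_protein_nt(domains["3CLpro"]))
        put(lay.drdrp, encode_protein_nt(domains["RdRp"]))
        put(lay.dznh, encode_protein_nt(domains["ZnHel1"]))
    return fixed, trs_truth, repeats


def _constraints(lay: _Layout):
    nostop = [
        (lay.f1, lay.s1a, lay.e1a - 3),
        (lay.f1b, lay.o1b, lay.e1b - 3),
        (lay.f2a, lay.s2a, lay.e2a - 3),
        (lay.f2b, lay.s2b, lay.e2b - 3),
        (lay.f3a, lay.s3a, lay.e3a - 3),
        (lay.f3b, lay.s3b, lay.e3b - 3),
        (lay.f4, lay.s4, lay.e4 - 3),
    ]
    noatg = [
        (lay.e1b, lay.s2a),
        (lay.e2a, lay.s3a),
        (lay.e3b, lay.s4),
    ]
    overlaps = {"1a1b": (lay.o1b, lay.e1a), "3a3b": (lay.s3b, lay.e3a)}
    return nostop, noatg, overlaps


def _violations(seq: list[str], nostop, noatg, overlaps, slips) -> list[tuple[int, int]]:
    """Spans (lo, hi) whose free positions must be resampled."""
    bad = []
    s = "".join(seq)
    for frame, lo, hi in nostop:
        start = lo + ((frame - lo) % 3)
        for c in range(start, hi, 3):
            if s[c : c + 3] in STOP_CODONS:
                bad.append((c, c + 3))
    for lo, hi in noatg:
        at = s.find("ATG", max(0, lo - 2), hi + 2)
        while at != -1 and at < hi:
            bad.append((at, at + 3))
            at = s.find("ATG", at + 1, hi + 2)
    for key, (lo, hi) in overlaps.items():
        for motif in (SLIP1, SLIP3):
            at = s.find(motif, lo, hi)
            while at != -1:
                if (motif, at) not in slips:
                    bad.append((at, at + 7))
                at = s.find(motif, at + 1, hi - 6)
    return bad


def _build(spec: GenomeSpec, rng: np.random.Generator):
    lay = _Layout(spec)
    domains = _planted_domains(spec, rng)
    fixed, trs_truth, repeats = _fixed_bases(lay, spec, domains)
    nostop, noatg, overlaps = _constraints(lay)
    slips = {(SLIP1, lay.slip1), (SLIP3, lay.slip3)}

    n = lay.body_end
    seq = [BASES[i] for i in rng.integers(0, 4, size=n)]
    for pos, ch in fixed.items():
        seq[pos] = ch

    for _sweep in range(200):
        bad = _violations(seq, nostop, noatg, overlaps, slips)
        if not bad:
            break
        for lo, hi in bad:
            free = [p for p in range(lo, hi) if p not in fixed]
            if not free:
                raise GenerationError(
                    f"planted content conflicts with constraints in [{lo}, {hi})"
                )
            for p in free:
                seq[p] = BASES[rng.integers(0, 4)]
    else:
        raise GenerationError("constraint repair did not converge")

    body = "".join(seq)
    pp1ab_nt = body[lay.s1a : lay.join1] + body[lay.join1 - 1 : lay.e1b]
    pp1ab = translate(pp1ab_nt)[:-1]
    p3ab_nt = body[lay.s3a : lay.join3] + body[lay.join3 - 1 : lay.e3b]
    p3ab = translate(p3ab_nt)[:-1]
    up_codons = (lay.join1 - lay.s1a) // 3

    def aa_span_1a(nt_start: int, nt_len: int):
        a = (nt_start - lay.s1a) // 3
        return (a, a + nt_len // 3)

    def aa_span_1b(nt_start: int, nt_len: int):
        a = up_codons + (nt_start - (lay.join1 - 1)) // 3
        return (a, a + nt_len // 3)

    d3cl_len = 3 * len(domains["3CLpro"])
    drdrp_len = 3 * len(domains["RdRp"])
    dznh_len = 3 * len(domains["ZnHel1"])
    truth = TruthTable(
        genome_id=f"synth-{spec.seed}",
        seed=spec.seed,
        body_len=n,
        polya_len=spec.polya_len,
        utr5=(0, lay.s1a),
        term3=(lay.e4, n),
        orfs={
            "ORF1a": {"start": lay.s1a, "end": lay.e1a, "frame": lay.f1},
            "ORF1b": {"start": lay.o1b, "end": lay.e1b, "frame": lay.f1b},
            "ORF2a": {"start": lay.s2a, "end": lay.e2a, "frame": lay.f2a},
            "ORF2b": {"start": lay.s2b, "end": lay.e2b, "frame": lay.f2b},
            "ORF3a": {"start": lay.s3a, "end": lay.e3a, "frame": lay.f3a},
            "ORF3b": {"start": lay.s3b, "end": lay.e3b, "frame": lay.f3b},
            "ORF4": {"start": lay.s4, "end": lay.e4, "frame": lay.f4},
        },
        slippery=[(SLIP1, lay.slip1), (SLIP3, lay.slip3)],
        trs=trs_truth,
        pp1ab=pp1ab,
        pp1ab_join=lay.join1,
        p3ab=p3ab,
        p3ab_join=lay.join3,
        insertion_span=lay.ins,
        repeats=repeats,
        domain_spans_nt={
            "3CLpro": (lay.d3cl, lay.d3cl + d3cl_len),
            "RdRp": (lay.drdrp, lay.drdrp + drdrp_len),
            "ZnHel1": (lay.dznh, lay.dznh + dznh_len),
        } if spec.plant_domains else {},
        domain_spans_aa={
            "3CLpro": aa_span_1a(lay.d3cl, d3cl_len),
            "RdRp": aa_span_1b(lay.drdrp, drdrp_len),
            "ZnHel1": aa_span_1b(lay.dznh, dznh_len),
        } if spec.plant_domains else {},
        protected=sorted(fixed),
        nostop_frames=nostop,
        noatg_zones=noatg,
        overlap_spans=overlaps,
    )
    record = GenomeRecord(
        id=truth.genome_id,
        seq=body + "A" * spec.polya_len,
        polya_len=0,
        source="mesoni.synthetic_data",
    )
    return record, truth


def _verify(body: str, truth: TruthTable) -> str | None:
    """Re-annotate with the package's own pipeline; None if fully recovered."""
    from .motifs import find_slippery

    rec = GenomeRecord(id=truth.genome_id, seq=body)
    try:
        arch = assign_architecture(rec, params=ArchitectureParams())
    except Exception as exc:  # noqa: BLE001 - report as mismatch
        return f"architecture: {exc}"
    for name, want in truth.orfs.items():
        got = arch.named_orfs().get(name)
        if got is None or (got.start, got.end) != (want["start"], want["end"]):
            return f"feature {name}: want {want}, got {got}"
    if arch.utr5 != tuple(truth.utr5) or arch.term3 != tuple(truth.term3):
        return "utr5/term3 mismatch"
    for key, motif in (("1a1b", SLIP1), ("3a3b", SLIP3)):
        lo, hi = truth.overlap_spans[key]
        want = [p for m, p in truth.slippery if m == motif and lo <= p < hi]
        if find_slippery(rec, (lo, hi), motif) != want:
            return f"slippery {motif} mismatch in {key}"
    for pid, pattern in TRS_PATTERNS.items():
        want = sorted(pos for p, pos, _ in truth.trs if p == pid)
        got = [h.start for h in scan_motif(body, pattern, pid)]
        if got != want:
            return f"TRS {pid}: want {want}, got {got}"
    orfs = arch.named_orfs()
    pp = translate_prf(rec, orfs["ORF1a"], orfs["ORF1b"],
                       dict((m, p) for m, p in truth.slippery)[SLIP1], name="pp1ab")
    if pp.protein != truth.pp1ab or pp.join_pos != truth.pp1ab_join:
        return "pp1ab mismatch"
    p3 = translate_prf(rec, orfs["ORF3a"], orfs["ORF3b"],
                       dict((m, p) for m, p in truth.slippery)[SLIP3], name="p3ab")
    if p3.protein != truth.p3ab or p3.join_pos != truth.p3ab_join:
        return "p3ab mismatch"
    return None


def make_genome(spec: GenomeSpec | None = None) -> tuple[GenomeRecord, TruthTable]:
    """Generate one genome + truth table; deterministic for a fixed seed."""
    spec = spec or GenomeSpec()
    _validate(spec)
    last = "no attempts"
    for attempt in range(spec.max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        record, truth = _build(spec, rng)
        problem = _verify(record.seq[: truth.body_len], truth)
        if problem is None:
            truth.construction_attempts = attempt + 1
            return record, truth
        last = problem
    raise GenerationError(f"could not construct a verified genome: {last}")


def excise_insertion(rec: GenomeRecord, truth: TruthTable) -> GenomeRecord:
    """The no-insertion sibling of a genome built with ``insertion_len > 0``.

    Removing the planted block (which starts and ends on codon boundaries
    and is stop-free) yields exactly the reference genome the insertion was
    added to, so ``detect_insertions(rec, sibling)`` must report one block
    of the planted length.
    """
    if not truth.insertion_span:
        raise ValueError("genome has no planted insertion")
    lo, hi = truth.insertion_span
    return replace(rec, id=rec.id + "-noins", seq=rec.seq[:lo] + rec.seq[hi:])


def evolve_sequence(seq: str, d: float, model: str, seed: int) -> str:
    """I.i.d. site evolution for duration ``d`` (JC on nucleotides or WAG on
    amino acids); deterministic for a fixed seed."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if d == 0:
        return seq
    rng = np.random.default_rng(seed)
    if model == "JC-nt":
        p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hit = rng.random(arr.size) < p
        lut = {b: [c for c in b"ACGT" if c != b] for b in b"ACGT"}
        idx = np.flatnonzero(hit)
        choices = rng.integers(0, 3, size=idx.size)
        for k, i in enumerate(idx):
            arr[i] = lut[arr[i]][choices[k]]
        return arr.tobytes().decode()
    if model == "WAG-aa":
        m = load_model("WAG")
        P = m.transition_matrix(d)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        src = np.array([AA_ORDER.index(aa) for aa in seq])
        u = rng.random(src.size)
        out = np.empty(src.size, dtype=np.int64)
        for a in range(20):
            sel = src == a
            if sel.any():
                out[sel] = np.searchsorted(cum[a], u[sel], side="right")
        return "".join(AA_ORDER[i] for i in out)
    raise ValueError(f"unknown evolution model {model!r}")


def _check_substitution(body: list[str], pos: int, truth: TruthTable) -> bool:
    """Local constraint check after a tentative substitution."""
    s = body
    for frame, lo, hi in truth.nostop_frames:
        if lo - 2 <= pos < hi + 2:
            c = pos - ((pos - frame) % 3)
            if lo <= c < hi and "".join(s[c : c + 3]) in STOP_CODONS:
                return False
    for lo, hi in truth.noatg_zones:
        if lo - 2 <= pos < hi + 2:
            for a in range(max(0, pos - 2), pos + 1):
                if a < hi and "".join(s[a : a + 3]) == "ATG":
                    return False
    for key, (lo, hi) in truth.overlap_spans.items():
        if lo - 6 <= pos < hi:
            window = "".join(s[max(lo, pos - 6) : min(hi, pos + 7)])
            for motif in (SLIP1, SLIP3):
                if motif in window:
                    return False
    return True


def make_isolate_set(
    base_spec: GenomeSpec | None = None,
    n: int = 1,
    substitutions_per_isolate: list[int] | None = None,
    seed: int = 0,
    indel_lengths: list[list[int]] | None = None,
) -> tuple[GenomeRecord, list[GenomeRecord], TruthTable, list[dict]]:
    """Near-identical isolates: exact substitution counts (and optional
    deletions) planted on a common base genome.

    Substitutions avoid all planted motif/boundary positions and never
    create a stop codon in a constrained frame, a start codon in a
    sanitized intergenic zone, or a stray slippery heptamer, so the
    isolates remain fully annotatable with unchanged truth coordinates.
    Deletions are placed in the 3' terminal region (coordinate-neutral for
    all named features).  Returns (base, isolates, truth, per-isolate info).
    """
    base_spec = base_spec or GenomeSpec()
    counts = substitutions_per_isolate or [0] * n
    if len(counts) != n:
        raise ValueError("substitutions_per_isolate length must equal n")
    if indel_lengths is not None and len(indel_lengths) != n:
        raise ValueError("indel_lengths length must equal n")
    base, truth = make_genome(base_spec)
    body = base.seq[: truth.body_len]
    protected = set(truth.protected)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10_000]))
    isolates = []
    infos = []
    for k in range(n):
        muts: dict[int, str] = {}
        tries = 0
        arr = list(body)
        while len(muts) < counts[k]:
            tries += 1
            if tries > 200 * (counts[k] + 1):
                raise GenerationError("substitution placement exhausted retry budget")
            pos = int(rng.integers(0, truth.body_len))
            if pos in protected or pos in muts:
                continue
            old = arr[pos]
            new = BASES[rng.integers(0, 4)]
            if new == old:
                continue
            arr[pos] = new
            if _check_substitution(arr, pos, truth):
                muts[pos] = new
            else:
                arr[pos] = old
        dels = []
        if indel_lengths and indel_lengths[k]:
            t_lo, t_hi = truth.term3
            slot = (t_hi - 50 - (t_lo + 50)) // max(1, len(indel_lengths[k]))
            for i, L in enumerate(indel_lengths[k]):
                lo = t_lo + 50 + i * slot
                pos = int(rng.integers(lo, lo + slot - L - 60))
                while any(p in muts for p in range(pos - 1, pos + L + 1)):
                    pos = int(rng.integers(lo, lo + slot - L - 60))
                dels.append((pos, L))
            for pos, L in sorted(dels, reverse=True):
                del arr[pos : pos + L]
        iso = GenomeRecord(
            id=f"{truth.genome_id}-iso{k}",
            seq="".join(arr) + "A" * base_spec.polya_len,
            source="mesoni.synthetic_data",
        )
        isolates.append(iso)
        infos.append({"substitutions": dict(sorted(muts.items())), "deletions": dels})
    return base, isolates, truth, infos
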