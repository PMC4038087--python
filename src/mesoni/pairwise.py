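"""Pairwise global alignment, difference counting, block-insertion detection
and imperfect-repeat search.

Nucleotide alignment is an affine-gap Needleman-Wunsch written here (numba
kernels) because insertion detection on ~20-kb genome pairs needs a banded
variant to keep memory bounded: the banded path stores traceback only inside
a diagonal window of half-width ``band`` and must, by contract, reproduce
the full-matrix result whenever the optimal path stays inside the band.
A gap of length L costs ``gap_open + L * gap_extend``; adjacent opposite
gaps are two separate events.  Ties are broken deterministically: diagonal
step over a gap in the second sequence over a gap in the first.

Protein-sequence calls are routed through Biopython's PairwiseAligner with
a standard log-odds substitution matrix (default BLOSUM62).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import HomologyError
from .genome_io import GenomeRecord
from .orf_architecture import translate

_NEG = -1e30

_NT = set("ACGT")
_NT_AMBIG = set("ACGTRYSWKMBDHVN")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters (EDNAFULL-style defaults for nucleotides)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    protein_matrix: str = "BLOSUM62"


@dataclass(frozen=True)
class PairwiseAlignment:
    rows: tuple[str, str]
    score: float
    params: AlignParams

    def __post_init__(self):
        a, b = self.rows
        assert len(a) == len(b), "alignment rows differ in length"


@dataclass(frozen=True)
class DiffSummary:
    substitutions: int
    indel_events: list[int]
    aligned_identity: float


@dataclass(frozen=True)
class RepeatHit:
    seed: str
    position: int
    mismatches: int


@dataclass(frozen=True)
class InsertionBlock:
    query_span: tuple[int, int]
    length_nt: int
    length_aa: int | None  # None when the block is frame-disrupting
    repeats: list[RepeatHit] = field(default_factory=list)


@njit(cache=True)
def _nw_affine(a, b, match, mismatch, go, ge, bl, br):  # pragma: no cover - numba
    """Banded affine NW; full matrix when the band covers everything.

    Returns (score, ops) where ops is the edit path from the end:
    0 = diagonal, 1 = gap in b (consume a), 2 = gap in a (consume b).
    """
    n = a.shape[0]
    m = b.shape[0]
    W = bl + br + 1
    # rolling score rows, full traceback (predecessor state per state)
    mp = np.full(W + 2, _NEG)
    xp = np.full(W + 2, _NEG)
    yp = np.full(W + 2, _NEG)
    mc = np.full(W + 2, _NEG)
    xc = np.full(W + 2, _NEG)
    yc = np.full(W + 2, _NEG)
    tbm = np.full((n + 1, W), 3, dtype=np.uint8)
    tbx = np.full((n + 1, W), 3, dtype=np.uint8)
    tby = np.full((n + 1, W), 3, dtype=np.uint8)

    # row 0: only gaps in a (state 2); k index = j - i + bl, offset by 1 in rows
    for j in range(0, min(m, br) + 1):
        k = j + bl
        if j == 0:
            mp[k + 1] = 0.0
        else:
            yp[k + 1] = -(go + ge * j)
            tby[0, k] = 2 if j > 1 else 0

    for i in range(1, n + 1):
        jlo = i - bl
        if jlo < 0:
            jlo = 0
        jhi = i + br
        if jhi > m:
            jhi = m
        for k in range(W + 2):
            mc[k] = _NEG
            xc[k] = _NEG
            yc[k] = _NEG
        for j in range(jlo, jhi + 1):
            k = j - i + bl  # 0..W-1
            # state M: diagonal from (i-1, j-1) -> same k in previous row
            if j >= 1:
                best = mp[k + 1]
                src = 0
                if xp[k + 1] > best:
                    best = xp[k + 1]
                    src = 1
                if yp[k + 1] > best:
                    best = yp[k + 1]
                    src = 2
                if best > _NEG / 2:
                    s = match if a[i - 1] == b[j - 1] else mismatch
                    mc[k + 1] = best + s
                    tbm[i, k] = src
            # state Ix: from (i-1, j) -> k+1 in previous row
            best = mp[k + 2] - go - ge
            src = 0
            if xp[k + 2] - ge > best:
                best = xp[k + 2] - ge
                src = 1
            if yp[k + 2] - go - ge > best:
                best = yp[k + 2] - go - ge
                src = 2
            if best > _NEG / 2:
                xc[k + 1] = best
                tbx[i, k] = src
            # state Iy: from (i, j-1) -> k-1 in current row
            best = mc[k] - go - ge
            src = 0
            if xc[k] - go - ge > best:
                best = xc[k] - go - ge
                src = 1
            if yc[k] - ge > best:
                best = yc[k] - ge
                src = 2
            if best > _NEG / 2:
                yc[k + 1] = best
                tby[i, k] = src
        for k in range(W + 2):
            mp[k] = mc[k]
            xp[k] = xc[k]
            yp[k] = yc[k]

    kf = m - n + bl
    score = mp[kf + 1]
    state = 0
    if xp[kf + 1] > score:
        score = xp[kf + 1]
        state = 1
    if yp[kf + 1] > score:
        score = yp[kf + 1]
        state = 2

    ops = np.empty(n + m, dtype=np.uint8)
    nops = 0
    i = n
    j = m
    while i > 0 or j > 0:
        k = j - i + bl
        ops[nops] = state
        nops += 1
        if state == 0:
            state = tbm[i, k]
            i -= 1
            j -= 1
        elif state == 1:
            state = tbx[i, k]
            i -= 1
        else:
            state = tby[i, k]
            j -= 1
    return score, ops[:nops]


def _classify(a: str, b: str) -> str:
    sa, sb = set(a), set(b)
    if sa <= _NT and sb <= _NT:
        return "nt"
    if sa <= _NT_AMBIG and sb <= _NT_AMBIG:
        return "nt-ambiguous"
    if sa <= _AA and sb <= _AA:
        return "aa"
    raise ValueError("mixed or unknown alphabets in alignment inputs")


def _encode(s: str, sentinel: int = 0) -> np.ndarray:
    """ASCII codes; ambiguity codes become a per-sequence sentinel so they
    mismatch everything, including each other."""
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
    if sentinel:
        known = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        arr[~known] = sentinel
    return arr


def align_global(
    a: str,
    b: str,
    params: AlignParams | None = None,
    band: int | None = None,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment.

    ``band=None`` computes the full matrix; an integer restricts the search
    to a diagonal corridor of half-width ``band`` (plus the length
    difference), bounding memory for genome-scale pairs.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    p = params or AlignParams()
    kind = _classify(a, b)
    if kind == "aa":
        return _align_protein(a, b, p)
    n, m = len(a), len(b)
    if band is None:
        bl, br = n, m
    else:
        if band < 1:
            raise ValueError("band must be >= 1")
        bl = band + max(0, n - m)
        br = band + max(0, m - n)
    ea = _encode(a, sentinel=1 if kind == "nt-ambiguous" else 0)
    eb = _encode(b, sentinel=2 if kind == "nt-ambiguous" else 0)
    score, ops = _nw_affine(
        ea, eb, p.match, p.mismatch, p.gap_open, p.gap_extend, bl, br
    )
    ra, rb = [], []
    i = j = 0
    for op in ops[::-1]:
        if op == 0:
            ra.append(a[i])
            rb.append(b[j])
            i += 1
            j += 1
        elif op == 1:
            ra.append(a[i])
            rb.append("-")
            i += 1
        else:
            ra.append("-")
            rb.append(b[j])
            j += 1
    return PairwiseAlignment(rows=("".join(ra), "".join(rb)), score=float(score), params=p)


def _align_protein(a: str, b: str, p: AlignParams) -> PairwiseAlignment:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(p.protein_matrix)
    aligner.open_gap_score = -(p.gap_open + p.gap_extend)
    aligner.extend_gap_score = -p.gap_extend
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(rows=(ra, rb), score=float(aln.score), params=p)


def count_differences(aln: PairwiseAlignment) -> DiffSummary:
    """Substitutions = gap-free mismatch columns; each maximal gap run is one
    indel event (gap-adjacent columns are never counted as substitutions)."""
    ra, rb = aln.rows
    subs = matches = 0
    indels: list[int] = []
    run = 0
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            run += 1
            continue
        if run:
            indels.append(run)
            run = 0
        if x == y:
            matches += 1
        else:
            subs += 1
    if run:
        indels.append(run)
    denom = matches + subs
    identity = matches / denom if denom else 0.0
    return DiffSummary(substitutions=subs, indel_events=indels, aligned_identity=identity)


def find_repeats(seq: str, seed: str, max_mismatch: int = 0) -> list[RepeatHit]:
    """Every window of ``len(seed)`` within Hamming distance ``max_mismatch``."""
    if len(seed) < 3:
        raise ValueError("seed length must be >= 3")
    if max_mismatch >= len(seed):
        raise ValueError("max_mismatch must be < seed length")
    L = len(seed)
    hits = []
    for i in range(len(seq) - L + 1):
        d = sum(1 for x, y in zip(seq[i : i + L], seed) if x != y)
        if d <= max_mismatch:
            hits.append(RepeatHit(seed=seed, position=i, mismatches=d))
    return hits


def detect_insertions(
    query: GenomeRecord,
    reference: GenomeRecord,
    region: tuple[int, int] | None = None,
    ref_region: tuple[int, int] | None = None,
    params: AlignParams | None = None,
    min_block: int = 30,
    min_identity: float = 0.30,
    band: int | None = None,
    frame_start: int | None = None,
    repeat_seed: str = "SKRKGK",
    repeat_max_mismatch: int = 2,
) -> list[InsertionBlock]:
    """Query-relative insertion blocks versus a homologous reference region.

    The query region is globally aligned to the reference region; maximal
    runs of gaps in the *reference* row of at least ``min_block`` nt are
    reported as insertion blocks.  When ``frame_start`` (a genome position
    where codons begin, e.g. the ORF1a start) is given and a block length is
    divisible by 3, the in-frame window covering the block is translated and
    scanned for imperfect repeats of ``repeat_seed``; blocks whose length is
    not a codon multiple are flagged frame-disrupting (``length_aa=None``).
    """
    qlo, qhi = region if region else (0, len(query.seq))
    if not (0 <= qlo < qhi <= len(query.seq)):
        raise ValueError(f"invalid query region {region}")
    if ref_region is None:
        ref_region = (min(qlo, len(reference.seq)), min(qhi, len(reference.seq)))
    rlo, rhi = ref_region
    qseq = query.seq[qlo:qhi]
    rseq = reference.seq[rlo:rhi]
    if band is None and max(len(qseq), len(rseq)) > 5000:
        band = 2000
    aln = align_global(qseq, rseq, params, band=band)
    summary = count_differences(aln)
    if summary.aligned_identity < min_identity:
        raise HomologyError(
            f"aligned identity {summary.aligned_identity:.3f} below floor {min_identity}"
        )
    ra, rb = aln.rows
    blocks: list[InsertionBlock] = []
    qpos = qlo
    run_start = None
    for x, y in zip(ra + "$", rb + "$"):
        if x != "$" and y == "-":
            if run_start is None:
                run_start = qpos
        else:
            if run_start is not None:
                length = qpos - run_start
                if length >= min_block:
                    blocks.append(
                        _make_block(query, run_start, qpos, frame_start,
                                    repeat_seed, repeat_max_mismatch)
                    )
                run_start = None
        if x not in ("-", "$"):
            qpos += 1
    return blocks


def _make_block(
    query: GenomeRecord,
    start: int,
    end: int,
    frame_start: int | None,
    repeat_seed: str,
    repeat_max_mismatch: int,
) -> InsertionBlock:
    length = end - start
    length_aa = length // 3 if length % 3 == 0 else None
    repeats: list[RepeatHit] = []
    if length_aa is not None and frame_start is not None:
        a = start + (-(start - frame_start)) % 3  # first codon boundary in block
        b = a + ((end - a) // 3) * 3
        if b - a >= 3 * len(repeat_seed):
            aa = translate(query.seq[a:b])
            for hit in find_repeats(aa, repeat_seed, repeat_max_mismatch):
                repeats.append(
                    RepeatHit(
                        seed=repeat_seed,
                        position=a + 3 * hit.position,  # genome coordinate
                        mismatches=hit.mismatches,
                    )
                )
    return InsertionBlock(
        query_span=(start, end), length_nt=length, length_aa=length_aa, repeats=repeats
    )
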