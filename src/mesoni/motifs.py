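"""Motif scanning and protein-level feature computation.

Nucleotide side: degenerate TRS patterns (mini-language: exact bases, ``x``
for any base, a parenthesized symbol for an optional base) and exact
slippery heptamers.  Protein side: signalase and S1-S2 cleavage motifs,
N-glycosylation sequons (N-X-S/T, X != P), cysteine census, average
molecular weight, and isoelectric point by charge bisection.

Mesonivirus TRS elements as printed are AUxxUACUACUACUA and
AGAx(x)ACUCUCCCA; patterns are compiled over the DNA alphabet (U == T).
Only ``x`` is treated as a wildcard; any further sub-element structure the
typography of the source motifs may imply is not modeled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.SeqUtils import molecular_weight

from .errors import AlphabetError, PatternError
from .genome_io import GenomeRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# TRS element patterns as conserved across mesoniviruses (DNA alphabet).
TRS_PATTERNS = {
    "TRS1": "ATxxTACTACTACTA",
    "TRS2": "AGAx(x)ACTCTCCCA",
}

# EMBOSS-style pKa values (iep defaults); swappable via protein_pi(pka=...).
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    start: int
    end: int
    matched_text: str


@dataclass(frozen=True)
class CleavageSite:
    """A proteolytic cleavage site; the bond after residue ``cut_after`` is cleaved."""

    kind: str  # "signalase" | "S1S2"
    cut_after: int
    context: str


@dataclass(frozen=True)
class ProteinFeatures:
    length_aa: int
    mw_kda: float
    pi: float
    cys_positions: list[int]
    sequons: list[int]


def compile_pattern(pattern: str) -> re.Pattern:
    """Compile the degenerate mini-language to a regex over ACGT.

    Exact bases match themselves (U == T), ``x`` matches any base, and a
    single parenthesized symbol is optional.  Optional symbols are greedy,
    so the longest match at a position is reported.
    """
    out = []
    i = 0
    pat = pattern.upper().replace("U", "T")
    while i < len(pat):
        c = pat[i]
        if c == "(":
            if i + 2 >= len(pat) or pat[i + 2] != ")":
                raise PatternError(f"unbalanced optional group in {pattern!r}")
            sym = pat[i + 1]
            if sym == "X":
                out.append("[ACGT]?")
            elif sym in "ACGT":
                out.append(f"{sym}?")
            else:
                raise PatternError(f"bad optional symbol {sym!r} in {pattern!r}")
            i += 3
        elif c in "ACGT":
            out.append(c)
            i += 1
        elif c == "X":
            out.append("[ACGT]")
            i += 1
        else:
            raise PatternError(f"bad symbol {c!r} in {pattern!r}")
    return re.compile("".join(out))


def scan_motif(seq: str, pattern: str, pattern_id: str | None = None) -> list[MotifHit]:
    """All (possibly overlapping) hits of a degenerate pattern, sorted by start."""
    cre = compile_pattern(pattern)
    seq = seq.upper().replace("U", "T")
    hits = []
    for i in range(len(seq)):
        m = cre.match(seq, i)
        if m and m.end() > m.start():
            hits.append(
                MotifHit(
                    pattern_id=pattern_id or pattern,
                    start=i,
                    end=m.end(),
                    matched_text=seq[i : m.end()],
                )
            )
    return hits


def find_slippery(rec: GenomeRecord, arch_overlap: tuple[int, int], motif: str) -> list[int]:
    """Positions of exact slippery-heptamer matches inside an ORF overlap span."""
    motif = motif.upper().replace("U", "T")
    if motif not in ("GGATTTT", "CACTTTT"):
        raise ValueError(f"unsupported slippery motif {motif!r}")
    lo, hi = arch_overlap
    if not (0 <= lo <= hi <= len(rec.seq)):
        raise ValueError(f"invalid span {arch_overlap}")
    window = rec.seq[lo:hi]
    out = []
    at = window.find(motif)
    while at != -1:
        out.append(lo + at)
        at = window.find(motif, at + 1)
    return out


_SIGNALASE = re.compile(r"[CS](?=[LAS]TRIDL)")
_S1S2 = re.compile(r"R(?=WDSSYV)")


def find_cleavage_sites(protein: str) -> list[CleavageSite]:
    """Signalase ([C/S]|[L/A/S]TRIDL) and S1-S2 (R|WDSSYV) cleavage sites."""
    if not protein:
        raise ValueError("empty protein")
    sites = []
    for kind, cre in (("signalase", _SIGNALASE), ("S1S2", _S1S2)):
        for m in cre.finditer(protein):
            i = m.start()
            sites.append(
                CleavageSite(kind=kind, cut_after=i, context=protein[max(0, i - 3) : i + 7])
            )
    sites.sort(key=lambda s: s.cut_after)
    return sites


def _check_alphabet(protein: str) -> None:
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise AlphabetError(f"non-standard residues {sorted(bad)}")


def protein_mw(protein: str) -> float:
    """Average-isotopic molecular weight in kDa (residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein")
    _check_alphabet(protein)
    return molecular_weight(protein, seq_type="protein", monoisotopic=False) / 1000.0


def net_charge(protein: str, ph: float, pka: dict | None = None) -> float:
    """Henderson-Hasselbalch net charge of the protein at a given pH."""
    table = pka or EMBOSS_PKA
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in protein:
        counts[aa] = counts.get(aa, 0) + 1
    charge = 0.0
    for group in _POSITIVE:
        n = counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - table[group]))
    for group in _NEGATIVE:
        n = counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (table[group] - ph))
    return charge


def protein_pi(protein: str, pka: dict | None = None, tol: float = 1e-4) -> float:
    """Isoelectric point: the pH of zero net charge, found by bisection.

    Bisection runs on [0, 14] until ``|charge| < tol``; the charge is a
    strictly decreasing function of pH so the root is unique.
    """
    if not protein:
        raise ValueError("empty protein")
    _check_alphabet(protein)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(protein, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


_SEQUON = re.compile(r"N(?=[^P][ST])")


def find_sequons(protein: str) -> list[int]:
    """Positions of N-glycosylation sequons N-X-S/T with X != P (overlapping)."""
    return [m.start() for m in _SEQUON.finditer(protein)]


def protein_features(protein: str) -> ProteinFeatures:
    """Length, average MW (kDa), pI, cysteine positions and sequon positions."""
    if not protein:
        raise ValueError("empty protein")
    _check_alphabet(protein)
    return ProteinFeatures(
        length_aa=len(protein),
        mw_kda=protein_mw(protein),
        pi=protein_pi(protein),
        cys_positions=[i for i, aa in enumerate(protein) if aa == "C"],
        sequons=find_sequons(protein),
    )
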