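"""Exception hierarchy shared across the package."""


class MesoniError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(MesoniError):
    """Malformed or empty FASTA input, or a rejected alphabet."""


class DegenerateSequenceError(MesoniError):
    """A sequence that is structurally unusable (e.g. all-A genome)."""


class GFFError(MesoniError):
    """Invalid feature set for GFF3 output (duplicates, bad coordinates)."""


class ArchitectureError(MesoniError):
    """A canonical genome element could not be assigned.

    ``element`` names the missing/ambiguous feature (e.g. ``"ORF1a"``).
    """

    def __init__(self, element: str, message: str | None = None):
        self.element = element
        super().__init__(message or f"cannot assign genome element {element}")


class FrameshiftError(MesoniError):
    """No valid -1 PRF join produces a stop-free fusion protein."""


class PatternError(MesoniError):
    """Malformed degenerate motif pattern."""


class AlphabetError(MesoniError):
    """Residue outside the expected alphabet."""


class HomologyError(MesoniError):
    """Aligned identity below the floor; regions are not comparable."""


class DomainMissingError(MesoniError):
    """A conserved replicase domain could not be located in pp1ab."""

    def __init__(self, domain: str, message: str | None = None):
        self.domain = domain
        super().__init__(message or f"domain {domain} not found above score threshold")


class PrecisionError(MesoniError):
    """Too few comparable sites for a meaningful distance estimate."""


class GenerationError(MesoniError):
    """Synthetic genome spec is unconstructible or construction failed."""
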