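"""Exception hierarchy.

All package errors derive from :class:`ParalogTrapError`, itself a
``ValueError`` so callers that do not care about the finer distinctions can
catch the built-in type.
"""


class ParalogTrapError(ValueError):
    """Base class for all errors raised by paralogtrap."""


class FastaFormatError(ParalogTrapError):
    """Malformed FASTA input or a sequence containing disallowed characters."""


class CatalogueError(ParalogTrapError):
    """Invalid SNP-catalogue content (bad counts, duplicated sites, ...)."""


class CoordinateError(ParalogTrapError):
    """A genomic coordinate or interval outside its permitted range."""


class AlignmentError(ParalogTrapError):
    """Invalid alignment input (e.g. empty sequences)."""


class SimulationError(ParalogTrapError):
    """Invalid read-simulation parameters or inconsistent variant injections."""


class LDError(ParalogTrapError):
    """Linkage-disequilibrium statistics requested on unusable sites."""
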