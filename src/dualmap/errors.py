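"""Exception hierarchy for the dualmap pipeline.

Every error raised by the library derives from :class:`DualmapError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class DualmapError(Exception):
    """Base class for all dualmap errors."""


class MissingEvidence(DualmapError):
    """Edit distance cannot be determined: neither NM nor MD tag present."""


class MalformedTag(DualmapError):
    """An optional tag (MD) disagrees structurally with the CIGAR."""


class EmptyAlignment(DualmapError):
    """A mapped record has no query-consuming aligned CIGAR operation."""


class DuplicatePrimary(DualmapError):
    """Two primary records share one read name."""


class EmptyProfile(DualmapError):
    """An operation requiring a non-empty edit-distance profile got none."""


class OrphanRecord(DualmapError):
    """A mapped record's read name was never profiled."""


class UnextractableRead(DualmapError):
    """A primary record cannot be turned back into a FASTQ read
    (hard-clipped or sequence-less)."""


class BackendFailure(DualmapError):
    """An external mapper exited non-zero; carries captured stderr."""

    def __init__(self, message: str, stderr: str = ""):
        super().__init__(message)
        self.stderr = stderr


class MissingNM(DualmapError):
    """A mapper produced mapped records with neither NM nor MD tags."""


class UnsupportedPreset(DualmapError):
    """The requested platform preset is not defined for this backend."""


class HeaderMismatch(DualmapError):
    """Two BAMs to be merged carry different @SQ dictionaries."""


class CrossContamination(DualmapError):
    """A read name is present in both inputs of a merge."""


class InconsistentManifest(DualmapError):
    """A fixture manifest contradicts itself (e.g. CIGAR vs sequence length)."""


class OverlapError(DualmapError):
    """Structural-variant implant intervals overlap."""


class OutOfBounds(DualmapError):
    """A structural-variant implant falls outside the reference."""
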