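"""Exception hierarchy shared across the pipeline."""


class DomarchError(Exception):
    """Base class for all package errors."""


class MalformedRecord(DomarchError):
    """A data row violates the format contract (too few columns, bad types)."""


class MissingHeader(DomarchError):
    """A tabular input that requires a header line lacks one."""


class DuplicateProteinId(DomarchError):
    """The same protein id occurs twice in a gene table."""


class EmptySequence(DomarchError):
    """A FASTA record or query sequence has no residues."""


class WrongLabel(DomarchError):
    """An operation was applied to a domain with an unexpected label."""


class MissingGeneRecord(DomarchError):
    """A protein participating in a genomic analysis has no gene-table entry."""


class InvalidContigLength(DomarchError):
    """Stated contig length is shorter than a gene placed on it."""


class EmptyCohort(DomarchError):
    """A cohort statistic was requested on zero CheA calls."""


class EmptyClass(DomarchError):
    """A chemosensory class is present in the label set but has no members."""


class MissingPhosphataseData(DomarchError):
    """A genome participates in the phosphate-sink test without phosphatase data."""


class ManifestMismatch(DomarchError):
    """Observed protein set differs from the planted truth manifest."""


class InvalidConfig(DomarchError):
    """Generator or run configuration fails validation."""


class ConfigError(DomarchError):
    """CLI configuration is inconsistent or incomplete."""


class InputMissing(DomarchError):
    """A required input path does not exist."""
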