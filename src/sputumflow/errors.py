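"""Exception types shared across the package."""


class SputumFlowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SputumFlowError):
    """An FCS container is truncated, garbled or uses an unsupported layout."""


class PanelMismatchError(SputumFlowError):
    """A marker required by the panel map is absent from the file."""


class TransformStateError(SputumFlowError):
    """An operation was asked to run on data in the wrong transform state."""


class ConfigurationError(SputumFlowError):
    """A profile / sample / cohort configuration violates its invariants."""


class CalibrationError(SputumFlowError):
    """Bead calibration failed (missing or indistinct diameter cluster)."""


class InsufficientEventsError(SputumFlowError):
    """Too few events to derive a robust statistic or threshold."""


class GateTreeError(SputumFlowError):
    """A gating hierarchy references a missing parent or channel."""


class LedgerError(SputumFlowError):
    """Exclusion-ledger categories overlap or fail to cover the intake."""


class MissingControlError(SputumFlowError):
    """A control tube required to derive a threshold is absent."""


class MissingMetadataError(SputumFlowError):
    """Per-sample metadata required for QC is absent."""
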