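"""Exception hierarchy for the haplotyping pipeline."""


class PhoenixBarcodeError(Exception):
    """Base class for all package errors."""


class ConstructionError(PhoenixBarcodeError):
    """Reference-scaffold constraint satisfaction failed after bounded retries."""


class NovelAlleleError(PhoenixBarcodeError):
    """A minisatellite region could not be decomposed into known motif units.

    Carries the successfully consumed unit prefix and the unmatchable residual
    so callers can report exactly where decomposition broke down.
    """

    def __init__(self, consumed, residual):
        self.consumed = tuple(consumed)
        self.residual = residual
        super().__init__(
            f"undecomposable minisatellite region: consumed {list(self.consumed)!r}, "
            f"residual {residual!r}"
        )


class AmbiguousAnchorError(PhoenixBarcodeError):
    """A locus anchor matched more than one position in the query sequence."""


class IndelLengthError(PhoenixBarcodeError):
    """The gap between the indel-locus anchors has an unexpected length."""

    def __init__(self, observed_gap):
        self.observed_gap = observed_gap
        super().__init__(
            f"indel locus gap of {observed_gap} bp (expected 0 or 9)"
        )


class HomopolymerStructureError(PhoenixBarcodeError):
    """The homopolymer locus does not start with a C-run followed by an A-run."""


class UndefinedDistanceError(PhoenixBarcodeError):
    """Two records share no comparable alignment columns."""


class CohortSpecError(PhoenixBarcodeError):
    """A cohort specification is internally inconsistent."""


class TruthFileError(PhoenixBarcodeError):
    """A truth TSV is malformed; message names the offending line."""


class LabelError(PhoenixBarcodeError):
    """A profiled sample has no species label."""
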