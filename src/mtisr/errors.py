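"""Exception hierarchy shared across the package.

ValidationError: an input value violates its own declared constraints
(bad threshold, duplicate ids, out-of-range p-value).  ContractError: two
otherwise-valid inputs are inconsistent with each other (sample missing from
a matrix, mismatched gene universes, shape mismatch).  The CLI maps them to
exit codes 2 and 3 respectively.
"""


class MtisrError(Exception):
    """Base class for package errors."""


class ValidationError(MtisrError):
    """An input violates its declared invariants."""


class ContractError(MtisrError):
    """Inputs are individually valid but mutually inconsistent."""


class PlacementError(MtisrError):
    """Shape placement failed after bounded retries during mask generation."""
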