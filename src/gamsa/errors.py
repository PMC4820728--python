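"""Exception hierarchy for gamsa.

All gamsa errors derive from :class:`GamsaError` so callers can catch the
package's failures with a single ``except`` clause while still letting
programming errors (``TypeError`` etc.) propagate.
"""


class GamsaError(Exception):
    """Base class for all gamsa errors."""


class FormatError(GamsaError, ValueError):
    """A sequence or alignment file violates its format contract."""


class AlphabetError(GamsaError, ValueError):
    """A symbol outside the 20-letter amino-acid alphabet (or gap) was seen."""


class DuplicateIdError(GamsaError, ValueError):
    """Two records in one input share an identifier."""


class ContractError(GamsaError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class CorruptionError(GamsaError, RuntimeError):
    """A chromosome no longer decodes to its source sequences.

    This is a bug trap: genetic operators must move gaps, never residues,
    so a decode mismatch indicates an operator defect and is never silently
    repaired.
    """
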