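"""Exception hierarchy for panel validation and pipeline stage failures."""


class AmpselError(Exception):
    """Base class for all ampsel errors."""


class PanelValidationError(AmpselError):
    """A marker panel, primer scheme, or sample sheet violates an invariant."""


class DuplicateMarkerError(PanelValidationError):
    """Two markers in a panel share a name."""


class DuplicateIndexPairError(PanelValidationError):
    """Two samples share the same (i5, i7) index combination."""


class MalformedSequenceError(PanelValidationError):
    """A DNA field contains characters outside {A, C, G, T}."""


class ThresholdError(PanelValidationError):
    """A frequency threshold lies outside the open interval (0, 1)."""


class AmbiguousPrimerError(PanelValidationError):
    """One marker's forward primer is a prefix of another's.

    Prefix-nested forward primers make read-to-marker assignment ambiguous
    by construction, which silently corrupts every downstream allele
    frequency, so this is a hard error rather than a warning.
    """


class StageError(AmpselError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
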