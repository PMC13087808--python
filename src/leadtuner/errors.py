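"""Exception types shared across the package."""


class LeadtunerError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(LeadtunerError, ValueError):
    """A SMILES string could not be parsed; carries the offending string."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class UnsupportedMoleculeError(LeadtunerError, ValueError):
    """A valid molecule falls outside the supported chemistry subset
    (charged atoms, isotopes, radicals, or elements without a token)."""


class SeriesExhaustedError(LeadtunerError, ValueError):
    """The substituent pool cannot yield the requested number of distinct
    molecules; carries the shortfall."""

    def __init__(self, requested: int, available: int):
        self.requested = requested
        self.available = available
        super().__init__(
            f"substituent pool exhausted: {requested} molecules requested but the "
            f"combinatorial pool only yields {available} distinct structures "
            f"(shortfall {requested - available})"
        )


class StageError(LeadtunerError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending ids."""

    def __init__(self, stage: str, message: str, ids=()):
        self.stage = stage
        self.ids = list(ids)
        detail = f" [ids: {', '.join(map(str, self.ids))}]" if self.ids else ""
        super().__init__(f"stage {stage!r}: {message}{detail}")
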