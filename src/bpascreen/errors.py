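"""Exception hierarchy shared across the screening pipeline."""


class BpaScreenError(Exception):
    """Base class for all package errors."""


class StructureParseError(BpaScreenError):
    """A SMILES/SDF record could not be parsed into a single molecule."""

    def __init__(self, source: str, detail: str = "") -> None:
        self.source = source
        self.detail = detail
        msg = f"could not parse structure {source!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class PanelError(BpaScreenError):
    """A compound panel violates its invariants (empty, duplicate ids...)."""


class DescriptorError(BpaScreenError):
    """A descriptor could not be computed (missing element, embedding...)."""


class ScoringError(BpaScreenError):
    """A score could not be computed from the supplied descriptors."""


class RuleError(BpaScreenError):
    """A metabolite transformation rule produced an invalid result."""


class AssayError(BpaScreenError):
    """An assay computation received invalid measurements."""
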