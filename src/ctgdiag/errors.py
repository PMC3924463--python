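"""Exception hierarchy shared across the package.

The CLI maps these onto its exit-code contract (usage=1, degenerate
input=2, I/O=3), so library code raises the most specific type it can.
"""


class CTGError(Exception):
    """Base class for all ctgdiag errors."""


class FormatError(CTGError, ValueError):
    """A file was readable but not in the expected format."""


class CriteriaError(CTGError, ValueError):
    """An abnormality-criteria document violated the dialect or an invariant."""


class DegenerateInputError(CTGError, ValueError):
    """Input too short / too empty for the requested analysis."""


class SpecValidationError(CTGError, ValueError):
    """A synthetic-trace specification is internally inconsistent.

    Carries the list of offending event descriptions in ``problems``.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid synthetic spec: " + "; ".join(self.problems))
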