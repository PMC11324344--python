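"""Exception hierarchy for binderopt."""


class BinderoptError(Exception):
    """Base class for all binderopt errors."""


class MalformedComplexError(BinderoptError):
    """A complex violates a structural invariant (empty partition, bad numbering...)."""


class MutationError(BinderoptError):
    """A mutation is invalid for the complex it is applied to."""


class ChooserExhaustionError(BinderoptError):
    """Fewer distinct mutation sets exist than were requested.

    ``achievable`` carries the number of distinct sets that could be produced
    (or that were produced before retries ran out).
    """

    def __init__(self, message: str, achievable: int | None = None):
        super().__init__(message)
        self.achievable = achievable


class NotDecomposableError(BinderoptError):
    """Per-residue decomposition requested from a scorer that cannot provide it."""


class AdapterValidationError(BinderoptError):
    """Output of an external adapter (mutator/sampler/scorer) failed validation.

    Signals a broken external tool, not a protocol failure.
    """


class PDBFormatError(BinderoptError):
    """A PDB file violates the supported dialect."""


class ConfigValidationError(BinderoptError):
    """Aggregated configuration problems; ``problems`` lists every one found."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration (%d problem%s):\n  - %s"
            % (len(self.problems), "s" if len(self.problems) != 1 else "",
               "\n  - ".join(self.problems))
        )


class AllLineagesFailedError(BinderoptError):
    """Every active lineage failed; the optimization cannot continue."""
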