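"""Named exception types raised across the pipeline.

Every validation failure has a distinct class so callers (and the CLI)
can report precisely which contract was violated.
"""


class IronNmaError(Exception):
    """Base class for all package errors."""


class ValidationError(IronNmaError):
    """Invalid input data or configuration."""


class UnknownTreatmentError(ValidationError):
    """A treatment label does not resolve against the node registry."""


class EventsExceedTotalError(ValidationError):
    """An arm reports more non-responders than randomized participants."""


class SingleArmStudyError(ValidationError):
    """A study contributes fewer than two arms."""


class MixedSubgroupError(ValidationError):
    """Arms of one study are assigned to different subgroups."""


class DuplicateNodeError(ValidationError):
    """The same treatment node appears twice within one study."""


class DisconnectedNetworkError(ValidationError):
    """The comparison graph is not connected; components are listed."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        parts = "; ".join("{" + ", ".join(c) + "}" for c in self.components)
        super().__init__(f"comparison graph is disconnected: components {parts}")


class UninformativeStudyError(IronNmaError):
    """Both arms are all-events or both zero-events: the odds ratio is undefined.

    This is an exclusion signal for pairwise pooling, not a data error.
    """


class InestimableError(IronNmaError):
    """A pooled quantity has a zero denominator and cannot be estimated."""


class InsufficientStudiesError(ValidationError):
    """Too few studies for the requested statistic (e.g. Egger needs k >= 3)."""


class CollinearityError(IronNmaError):
    """Exact collinearity in a regression design (all precisions equal)."""


class NonIdentifiableNodeError(ValidationError):
    """A treatment node appears only in studies with no events anywhere."""


class SingleChainError(ValidationError):
    """Convergence diagnostics require at least two MCMC chains."""
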