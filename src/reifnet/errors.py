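"""Exception hierarchy for reifnet."""


class ReifnetError(Exception):
    """Base class for all reifnet errors."""


class ParameterError(ReifnetError):
    """A combination-function parameter is outside its admissible range."""


class DomainError(ReifnetError):
    """A combination-function argument is outside the function's domain."""


class SpecificationError(ReifnetError):
    """A network specification (role matrices, scenario, assignment) is ill-formed."""


class EngineError(ReifnetError):
    """A runtime failure inside the simulation engine (non-finite value, missing state)."""
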