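"""Combination functions for temporal-causal networks.

A state ``Y`` in a temporal-causal network aggregates the single causal
impacts ``omega_{X_i,Y} * X_i(t)`` of its incoming connections with a
per-state *combination function* ``c_Y``.  This module provides the three
families the bundled agent model uses, plus an identity convenience:

``eucl``
    scaled Euclidean (n-th power) sum, ``((V_1^n + ... + V_k^n)/lambda)^(1/n)``.
``alogistic``
    the *advanced logistic*: a logistic threshold function rescaled so that
    it is exactly 0 at summed impact 0 and approaches 1 as the summed impact
    grows, with steepness ``sigma`` and threshold ``tau``.
``hebb``
    Hebbian learning with persistence ``mu``:
    ``hebb_mu(V1, V2, W) = V1*V2*(1 - W) + mu*W``, used by connection-weight
    self-model states (W-states).
``identity``
    ``eucl`` with n = 1, lambda = 1.

Functions are pure and stateless; adaptive parameters (e.g. a persistence
factor supplied by an M-state) are resolved by the caller before invocation.
Functions that need state context beyond the incoming impacts (``hebb`` needs
the current weight value ``W``) receive it through the ``extra`` mapping of
:func:`combine` / :func:`evaluate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .errors import DomainError, ParameterError, SpecificationError

__all__ = [
    "FunctionAssignment",
    "CombinationFunction",
    "REGISTRY",
    "get_function",
    "eucl",
    "alogistic",
    "hebb",
    "identity",
    "evaluate",
    "combine",
]

_INT_TOL = 1e-12


def _expit(x: float) -> float:
    # numerically stable logistic
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def eucl(values: Sequence[float], n: float = 1.0, lam: float = 1.0) -> float:
    """Scaled Euclidean combination ``((sum_i V_i^n)/lam)^(1/n)``.

    Parameters
    ----------
    values : incoming single impacts.
    n : positive order of the function. Odd integer orders admit negative
        values (signed root); fractional orders require all values >= 0.
    lam : positive scaling factor (typically the sum of the incoming
        weights raised to ``n``, normalising the output to [0, 1]).

    Returns 0.0 on empty input.
    """
    if lam <= 0.0 or not math.isfinite(lam):
        raise ParameterError(f"eucl: scaling factor lam must be positive, got {lam}")
    if n <= 0.0 or not math.isfinite(n):
        raise ParameterError(f"eucl: order n must be positive, got {n}")
    vals = [float(v) for v in values]
    if not vals:
        return 0.0
    is_int = abs(n - round(n)) < _INT_TOL
    if not is_int and any(v < 0.0 for v in vals):
        raise DomainError(
            f"eucl: negative value with fractional order n={n} is outside the domain"
        )
    if is_int:
        ni = int(round(n))
        s = sum(v**ni for v in vals) / lam
        if ni == 1:
            return s
        if s < 0.0:  # odd integer order, negative sum: signed root
            return -((-s) ** (1.0 / ni))
        return s ** (1.0 / ni)
    s = sum(v**n for v in vals) / lam
    return s ** (1.0 / n)


def alogistic(
    values: Sequence[float],
    sigma: float = 1.0,
    tau: float = 0.0,
    clamp: bool = True,
) -> float:
    """Advanced logistic combination with steepness ``sigma``, threshold ``tau``.

    ``[(1/(1+e^{-sigma (V - tau)})) - 1/(1+e^{sigma tau})] * (1+e^{-sigma tau})``
    with ``V = sum(values)``.  The raw formula is slightly negative for ``V``
    far below ``tau``; because activation levels are read on [0, 1] the result
    is clamped below at 0 by default (``clamp=False`` gives the exact
    formula).  The output never exceeds 1.
    """
    if sigma <= 0.0 or not math.isfinite(sigma):
        raise ParameterError(f"alogistic: steepness sigma must be positive, got {sigma}")
    V = float(sum(float(v) for v in values))
    st = sigma * tau
    low = _expit(-st)  # 1/(1+e^{sigma tau})
    # (1 + e^{-sigma tau}); guard the exp for strongly negative tau
    scale = 1.0 + math.exp(-st) if st > -700.0 else math.inf
    out = (_expit(sigma * (V - tau)) - low) * scale
    if out > 1.0:  # the algebraic supremum is 1; trim float round-off
        return 1.0
    if clamp and out < 0.0:
        return 0.0
    return out


def hebb(v1: float, v2: float, w: float, mu: float, clamp: bool = False) -> float:
    """Hebbian learning update ``V1*V2*(1 - W) + mu*W``.

    ``v1``/``v2`` are the activations of the connected (pre/post-synaptic)
    states, ``w`` the current weight value and ``mu`` in [0, 1] the
    persistence of the learned effect.  All arguments must lie in [0, 1];
    with ``clamp=True`` out-of-range arguments are clipped instead of
    raising (warn-and-clamp mode).
    """
    args = {"v1": v1, "v2": v2, "w": w, "mu": mu}
    tol = 1e-9
    for name, val in args.items():
        if not math.isfinite(val):
            raise DomainError(f"hebb: argument {name}={val} is not finite")
        if val < -tol or val > 1.0 + tol:
            if clamp:
                args[name] = min(1.0, max(0.0, val))
            else:
                raise DomainError(f"hebb: argument {name}={val} outside [0, 1]")
        else:
            args[name] = min(1.0, max(0.0, val))
    v1, v2, w, mu = args["v1"], args["v2"], args["w"], args["mu"]
    return v1 * v2 * (1.0 - w) + mu * w


def identity(values: Sequence[float]) -> float:
    """Plain sum of the impacts: ``eucl`` with n = 1, lambda = 1."""
    return eucl(values, n=1.0, lam=1.0)


@dataclass(frozen=True)
class CombinationFunction:
    """Registry entry: a named combination function and its parameters."""

    name: str
    params: tuple[str, ...]
    defaults: Mapping[str, float]
    needs_state_context: bool
    _eval: Callable[[Sequence[float], Mapping[str, float], Mapping[str, float]], float]

    def __call__(
        self,
        values: Sequence[float],
        params: Mapping[str, float] | None = None,
        extra: Mapping[str, float] | None = None,
    ) -> float:
        merged = dict(self.defaults)
        if params:
            unknown = set(params) - set(self.params)
            if unknown:
                raise ParameterError(
                    f"{self.name}: unknown parameter(s) {sorted(unknown)}; "
                    f"declared: {list(self.params)}"
                )
            merged.update(params)
        return self._eval(values, merged, extra or {})


def _eval_eucl(values, p, extra):
    return eucl(values, n=p["n"], lam=p["lam"])


def _eval_alogistic(values, p, extra):
    return alogistic(values, sigma=p["sigma"], tau=p["tau"], clamp=bool(p.get("clamp", 1.0)))


def _eval_hebb(values, p, extra):
    if len(values) != 2:
        raise DomainError(
            f"hebb: expected exactly 2 incoming impacts (pre- and post-synaptic), got {len(values)}"
        )
    if "w" not in extra:
        raise DomainError("hebb: current weight value 'w' missing from extra context")
    return hebb(values[0], values[1], extra["w"], p["mu"], clamp=bool(extra.get("clamp", 0.0)))


def _eval_identity(values, p, extra):
    return identity(values)


REGISTRY: dict[str, CombinationFunction] = {
    "eucl": CombinationFunction(
        "eucl", ("n", "lam"), {"n": 1.0, "lam": 1.0}, False, _eval_eucl
    ),
    "alogistic": CombinationFunction(
        "alogistic",
        ("sigma", "tau", "clamp"),
        {"sigma": 1.0, "tau": 0.0, "clamp": 1.0},
        False,
        _eval_alogistic,
    ),
    "hebb": CombinationFunction("hebb", ("mu",), {"mu": 1.0}, True, _eval_hebb),
    "identity": CombinationFunction("identity", (), {}, False, _eval_identity),
}


def get_function(name: str) -> CombinationFunction:
    try:
        return REGISTRY[name]
    except KeyError:
        raise SpecificationError(
            f"unknown combination function {name!r}; registered: {sorted(REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class FunctionAssignment:
    """One weighted combination-function assignment of a state.

    ``params`` values and ``blend_weight`` may be numbers, or strings naming
    the M-state that supplies the value at run time (resolved from the
    current snapshot before evaluation).
    """

    function_id: str
    params: Mapping[str, float | str] = field(default_factory=dict)
    blend_weight: float | str = 1.0

    def __post_init__(self):
        fn = get_function(self.function_id)
        unknown = {k for k in self.params if k not in fn.params}
        if unknown:
            raise SpecificationError(
                f"assignment of {self.function_id!r}: undeclared parameter(s) {sorted(unknown)}"
            )
        if isinstance(self.blend_weight, (int, float)) and self.blend_weight < 0:
            raise SpecificationError(
                f"assignment of {self.function_id!r}: blend weight must be >= 0"
            )

    @property
    def is_resolved(self) -> bool:
        return not isinstance(self.blend_weight, str) and not any(
            isinstance(v, str) for v in self.params.values()
        )


def evaluate(
    function_id: str,
    values: Sequence[float],
    params: Mapping[str, float] | None = None,
    extra: Mapping[str, float] | None = None,
) -> float:
    """Evaluate a registered combination function on a sequence of impacts."""
    return get_function(function_id)(values, params, extra)


def combine(
    assignments: Sequence[FunctionAssignment],
    impacts: Sequence[float],
    extra: Mapping[str, float] | None = None,
) -> float:
    """Blend the weighted combination functions of one state.

    Returns ``sum_i gamma_i f_i(impacts) / sum_i gamma_i``. All parameter and
    blend-weight references must already be resolved to numbers.  Reduces to
    a plain function evaluation for a single assignment.
    """
    if not assignments:
        raise SpecificationError("combine: at least one function assignment required")
    num = 0.0
    den = 0.0
    for a in assignments:
        if not a.is_resolved:
            raise SpecificationError(
                f"combine: assignment {a.function_id!r} still holds unresolved "
                "state references; resolve against a snapshot first"
            )
        gamma = float(a.blend_weight)
        if gamma == 0.0:
            continue
        num += gamma * evaluate(a.function_id, impacts, dict(a.params), extra)
        den += gamma
    if den <= 0.0:
        raise SpecificationError("combine: all blend weights are zero")
    return num / den
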