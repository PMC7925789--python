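"""Declarative role-matrix specification of a reified temporal-causal network.

A network is specified by nine *role matrices* plus an initial-value table.
Each matrix describes one role a network characteristic plays for a state:

======== ==============================================================
``mb``    connectivity: ordered incoming state ids per state
``mcwv``  constant connection weights, aligned with the ``mb`` slots
``mcwa``  adaptive slots: the W-state that supplies the weight at run time
``msv``   constant speed factor (eta) per state
``msa``   adaptive speed: the H-state that supplies eta at run time
``mcfwv`` constant combination-function blend weights (gamma), per function
``mcfwa`` adaptive blend weights: the M-state supplying gamma
``mcfpv`` constant combination-function parameters
``mcfpa`` adaptive parameters: the M-state supplying the value (e.g. the
          Hebbian persistence mu of a W-state)
======== ==============================================================

Reification roles are *derived* from the matrices: an id referenced in an
``mcwa`` cell is a W-state (it reifies that connection's weight), an id in
``msa`` is an H-state (it reifies a W-state's learning speed), an id in
``mcfpa``/``mcfwa`` is an M-state.  Everything else is a base (Level I)
state.  File format: one CSV per matrix, first column the state id,
subsequent columns the slots; adaptive cells hold a state id, constant
cells a number, empty cells are unused.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .combinators import REGISTRY, FunctionAssignment, get_function
from .errors import SpecificationError

__all__ = [
    "StateSpec",
    "RoleMatrices",
    "NetworkSpec",
    "ValidationReport",
    "ResolvedState",
    "MATRIX_NAMES",
    "from_matrices",
    "load_role_matrices",
    "save_role_matrices",
    "validate",
    "in_degree",
    "resolve",
    "random_network",
]

Role = Literal["base", "W", "H", "M"]
Level = Literal["I", "II", "III"]

MATRIX_NAMES = (
    "mb",
    "mcwv",
    "mcwa",
    "msv",
    "msa",
    "mcfwv",
    "mcfwa",
    "mcfpv",
    "mcfpa",
)

_ROLE_LEVEL: dict[Role, Level] = {"base": "I", "W": "II", "H": "III", "M": "III"}


@dataclass(frozen=True)
class StateSpec:
    """One node of the network.

    ``reifies`` is ``None`` for base states, a ``(source, target)`` state-id
    pair for W-states, and the reified W-state's id for H- and M-states.
    """

    index: int  # 1-based, matching the role-matrix convention
    id: str
    level: Level
    role: Role
    reifies: tuple[str, str] | str | None = None
    initial_value: float = 0.0


@dataclass
class RoleMatrices:
    """The nine role matrices, keyed by state id (insertion order = index)."""

    mb: dict[str, list[str]] = field(default_factory=dict)
    mcwv: dict[str, list[float | None]] = field(default_factory=dict)
    mcwa: dict[str, list[str | None]] = field(default_factory=dict)
    msv: dict[str, float | None] = field(default_factory=dict)
    msa: dict[str, str | None] = field(default_factory=dict)
    mcfwv: dict[str, dict[str, float]] = field(default_factory=dict)
    mcfwa: dict[str, dict[str, str]] = field(default_factory=dict)
    mcfpv: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    mcfpa: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(
            {"ok": self.ok, "errors": self.errors, "warnings": self.warnings}, indent=2
        )


@dataclass(frozen=True)
class ResolvedState:
    """Instantaneous numeric view of one state: every characteristic a number."""

    id: str
    incoming: tuple[str, ...]
    weights: tuple[float, ...]
    speed: float
    assignments: tuple[FunctionAssignment, ...]


@dataclass
class NetworkSpec:
    """A complete reified network: states, role matrices, provenance notes."""

    states: list[StateSpec]
    matrices: RoleMatrices
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {s.id: s for s in self.states}

    # -- lookup ----------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.states]

    def state(self, state_id: str) -> StateSpec:
        try:
            return self._index[state_id]
        except KeyError:
            raise SpecificationError(f"unknown state id {state_id!r}") from None

    def __contains__(self, state_id: str) -> bool:
        return state_id in self._index

    def states_with_role(self, role: Role) -> list[StateSpec]:
        return [s for s in self.states if s.role == role]

    def in_degree(self, state_id: str) -> int:
        self.state(state_id)
        return len(self.matrices.mb.get(state_id, []))

    def initial_values(self) -> dict[str, float]:
        return {s.id: s.initial_value for s in self.states}

    def with_initial_values(self, overrides: Mapping[str, float]) -> "NetworkSpec":
        for sid in overrides:
            self.state(sid)
        states = [
            replace(s, initial_value=float(overrides.get(s.id, s.initial_value)))
            for s in self.states
        ]
        return NetworkSpec(states, self.matrices, dict(self.metadata))

    # -- function assignments -------------------------------------------
    def function_assignments(self, state_id: str) -> list[FunctionAssignment]:
        """Assignments of a state, parameter references left symbolic."""
        m = self.matrices
        fids = sorted(
            set(m.mcfwv.get(state_id, {})) | set(m.mcfwa.get(state_id, {})),
            key=lambda f: list(REGISTRY).index(f) if f in REGISTRY else 99,
        )
        out = []
        for fid in fids:
            params: dict[str, float | str] = dict(m.mcfpv.get(state_id, {}).get(fid, {}))
            params.update(m.mcfpa.get(state_id, {}).get(fid, {}))
            blend: float | str
            if fid in m.mcfwa.get(state_id, {}):
                blend = m.mcfwa[state_id][fid]
            else:
                blend = m.mcfwv[state_id][fid]
            out.append(FunctionAssignment(fid, params, blend))
        return out

    # -- validation ------------------------------------------------------
    def validate(self, dt_default: float = 0.5) -> ValidationReport:
        return validate(self, dt_default=dt_default)

    # -- serialisation ---------------------------------------------------
    def to_json(self) -> str:
        def enc_state(s: StateSpec) -> dict:
            r = s.reifies
            return {
                "index": s.index,
                "id": s.id,
                "level": s.level,
                "role": s.role,
                "reifies": list(r) if isinstance(r, tuple) else r,
                "initial_value": s.initial_value,
            }

        m = self.matrices
        return json.dumps(
            {
                "states": [enc_state(s) for s in self.states],
                "matrices": {name: getattr(m, name) for name in MATRIX_NAMES},
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        raw = json.loads(text)
        matrices = RoleMatrices(**{k: raw["matrices"][k] for k in MATRIX_NAMES})
        iv = {s["id"]: s["initial_value"] for s in raw["states"]}
        spec = from_matrices(matrices, iv, metadata=raw.get("metadata", {}))
        return spec

    def save(self, directory: str | Path) -> None:
        save_role_matrices(self, directory)

    @classmethod
    def load(cls, directory: str | Path) -> "NetworkSpec":
        return load_role_matrices(directory)


# ---------------------------------------------------------------------------
# construction: derive states (roles, levels, reified objects) from matrices
# ---------------------------------------------------------------------------


def from_matrices(
    matrices: RoleMatrices,
    initial_values: Mapping[str, float] | None = None,
    metadata: dict | None = None,
) -> NetworkSpec:
    """Build a :class:`NetworkSpec` from role matrices, deriving reification roles."""
    iv = dict(initial_values or {})
    # canonicalise nested key order (functions, parameters) so that specs
    # built in memory and specs loaded from CSV serialise identically
    matrices.mcfwv = {s: dict(sorted(e.items())) for s, e in matrices.mcfwv.items()}
    matrices.mcfwa = {s: dict(sorted(e.items())) for s, e in matrices.mcfwa.items()}
    for name in ("mcfpv", "mcfpa"):
        mat = getattr(matrices, name)
        setattr(
            matrices,
            name,
            {
                s: {f: dict(sorted(p.items())) for f, p in sorted(e.items())}
                for s, e in mat.items()
            },
        )
    ids = list(matrices.mb.keys())
    known = set(ids)

    def _check(sid: str, where: str):
        if sid not in known:
            raise SpecificationError(f"{where}: unknown state id {sid!r}")

    # W-states: referenced in mcwa cells
    w_reifies: dict[str, tuple[str, str]] = {}
    for tgt, cells in matrices.mcwa.items():
        mb_row = matrices.mb.get(tgt, [])
        if len(cells) > len(mb_row):
            raise SpecificationError(
                f"mcwa[{tgt!r}]: {len(cells)} cells but mb row has {len(mb_row)} slots"
            )
        for slot, wid in enumerate(cells):
            if wid is None:
                continue
            _check(wid, f"mcwa[{tgt!r}] slot {slot + 1}")
            conn = (mb_row[slot], tgt)
            if wid in w_reifies and w_reifies[wid] != conn:
                raise SpecificationError(
                    f"state {wid!r} referenced as weight self-model for both "
                    f"{w_reifies[wid]} and {conn}; a W-state reifies exactly one connection"
                )
            w_reifies[wid] = conn

    # H-states: referenced in msa
    h_reifies: dict[str, str] = {}
    for sid, hid in matrices.msa.items():
        if hid is None:
            continue
        _check(hid, f"msa[{sid!r}]")
        if hid in h_reifies and h_reifies[hid] != sid:
            raise SpecificationError(
                f"state {hid!r} supplies the speed of both {h_reifies[hid]!r} and "
                f"{sid!r}; an H-state reifies exactly one W-state"
            )
        h_reifies[hid] = sid

    # M-states: referenced in mcfpa (parameters) or mcfwa (blend weights)
    m_reifies: dict[str, str] = {}
    for sid, per_fn in matrices.mcfpa.items():
        for fid, params in per_fn.items():
            for pname, mid in params.items():
                _check(mid, f"mcfpa[{sid!r}][{fid}][{pname}]")
                if mid in m_reifies and m_reifies[mid] != sid:
                    raise SpecificationError(
                        f"state {mid!r} supplies parameters of both "
                        f"{m_reifies[mid]!r} and {sid!r}; an M-state reifies exactly one state"
                    )
                m_reifies[mid] = sid
    for sid, per_fn in matrices.mcfwa.items():
        for fid, mid in per_fn.items():
            _check(mid, f"mcfwa[{sid!r}][{fid}]")
            if mid in m_reifies and m_reifies[mid] != sid:
                raise SpecificationError(
                    f"state {mid!r} supplies characteristics of both "
                    f"{m_reifies[mid]!r} and {sid!r}"
                )
            m_reifies[mid] = sid

    overlap = (set(w_reifies) & set(h_reifies)) | (set(w_reifies) & set(m_reifies)) | (
        set(h_reifies) & set(m_reifies)
    )
    if overlap:
        raise SpecificationError(
            f"state(s) {sorted(overlap)} referenced in more than one reification role"
        )

    states = []
    for k, sid in enumerate(ids, start=1):
        if sid in w_reifies:
            role: Role = "W"
            reifies: tuple[str, str] | str | None = w_reifies[sid]
        elif sid in h_reifies:
            role = "H"
            reifies = h_reifies[sid]
        elif sid in m_reifies:
            role = "M"
            reifies = m_reifies[sid]
        else:
            role = "base"
            reifies = None
        states.append(
            StateSpec(
                index=k,
                id=sid,
                level=_ROLE_LEVEL[role],
                role=role,
                reifies=reifies,
                initial_value=float(iv.get(sid, 0.0)),
            )
        )
    unknown_iv = set(iv) - known
    if unknown_iv:
        raise SpecificationError(f"initial values for unknown state(s) {sorted(unknown_iv)}")
    return NetworkSpec(states, matrices, metadata or {})


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate(spec: NetworkSpec, dt_default: float = 0.5) -> ValidationReport:
    """Check every structural invariant; returns a report, never raises.

    Errors break the simulation contract (dangling references, double or
    missing weight sources, mis-wired reification); warnings flag suspicious
    but runnable input (weights outside [-1, 1], eta*dt > 1, unreachable
    states, a hebb state whose own inputs are not its reified connection).
    """
    rep = ValidationReport()
    m = spec.matrices
    known = set(spec.ids)

    ids = spec.ids
    if len(ids) != len(known):
        rep.errors.append("duplicate state ids")
    for k, s in enumerate(spec.states, start=1):
        if s.index != k:
            rep.errors.append(f"state {s.id!r}: index {s.index} not contiguous (expected {k})")

    for tgt, row in m.mb.items():
        for slot, src in enumerate(row):
            if src not in known:
                rep.errors.append(f"mb[{tgt!r}] slot {slot + 1}: unknown source {src!r}")
        wv = m.mcwv.get(tgt, [])
        wa = m.mcwa.get(tgt, [])
        for slot in range(len(row)):
            has_v = slot < len(wv) and wv[slot] is not None
            has_a = slot < len(wa) and wa[slot] is not None
            if has_v and has_a:
                rep.errors.append(
                    f"slot {slot + 1} of {tgt!r}: both a constant (mcwv) and an "
                    "adaptive (mcwa) weight"
                )
            elif not has_v and not has_a:
                rep.errors.append(
                    f"slot {slot + 1} of {tgt!r}: no weight source (neither mcwv nor mcwa)"
                )
            if has_v:
                w = wv[slot]
                if not (-1.0 <= w <= 1.0):
                    rep.warnings.append(
                        f"mcwv[{tgt!r}] slot {slot + 1}: weight {w} outside [-1, 1]"
                    )
                if w is not None and w < 0 and spec.state(tgt).level != "I":
                    rep.errors.append(
                        f"mcwv[{tgt!r}] slot {slot + 1}: negative weight on a "
                        "non-base-level connection"
                    )
    for name in ("mcwv", "mcwa"):
        for tgt, row in getattr(m, name).items():
            if tgt not in m.mb and any(c is not None for c in row):
                rep.errors.append(f"{name}[{tgt!r}]: weights for a state with no mb row")
            elif tgt in m.mb and len(row) > len(m.mb[tgt]):
                rep.errors.append(
                    f"{name}[{tgt!r}]: {len(row)} cells, mb row has only {len(m.mb[tgt])} slots"
                )

    # speed: exactly one source, msa references must be H-states reifying a W
    for sid in ids:
        has_v = m.msv.get(sid) is not None
        has_a = m.msa.get(sid) is not None
        if has_v and has_a:
            rep.errors.append(f"state {sid!r}: both constant (msv) and adaptive (msa) speed")
        if has_v:
            eta = m.msv[sid]
            if eta < 0:
                rep.errors.append(f"msv[{sid!r}]: negative speed factor {eta}")
            elif eta * dt_default > 1.0:
                rep.warnings.append(
                    f"msv[{sid!r}]: eta*dt = {eta * dt_default:.3g} > 1 at default dt"
                )
        if m.mb.get(sid) and not has_v and not has_a:
            rep.warnings.append(f"state {sid!r}: no speed factor; treated as frozen (eta=0)")

    # downward-causation well-formedness (derivation enforces most of it; a
    # spec rebuilt from JSON could disagree, so re-check against the states)
    for s in spec.states:
        if s.role == "W":
            src, tgt = s.reifies  # type: ignore[misc]
            row = m.mcwa.get(tgt, [])
            mb_row = m.mb.get(tgt, [])
            slots = [
                k
                for k, wid in enumerate(row)
                if wid == s.id and k < len(mb_row) and mb_row[k] == src
            ]
            if len(slots) != 1 or sum(wid == s.id for r in m.mcwa.values() for wid in r) != 1:
                rep.errors.append(
                    f"W-state {s.id!r} must fill exactly the mcwa slot of its reified "
                    f"connection {s.reifies}"
                )
        elif s.role == "H":
            wid = s.reifies
            if m.msa.get(wid) != s.id or spec.state(wid).role != "W":
                rep.errors.append(
                    f"H-state {s.id!r} must supply the speed (msa) of W-state {wid!r}"
                )
        elif s.role == "M":
            tgt = s.reifies
            hits = [
                1
                for fid, params in m.mcfpa.get(tgt, {}).items()
                for p, mid in params.items()
                if mid == s.id
            ] + [1 for fid, mid in m.mcfwa.get(tgt, {}).items() if mid == s.id]
            if not hits:
                rep.errors.append(
                    f"M-state {s.id!r} must supply a parameter (mcfpa/mcfwa) of {tgt!r}"
                )

    # function assignments
    for sid in ids:
        if not m.mb.get(sid):
            continue  # pure stimulus states may omit an assignment
        try:
            assignments = spec.function_assignments(sid)
        except SpecificationError as e:
            rep.errors.append(str(e))
            continue
        if not assignments:
            rep.errors.append(f"state {sid!r}: incoming connections but no combination function")
            continue
        const_pos = any(
            not isinstance(a.blend_weight, str) and a.blend_weight > 0 for a in assignments
        )
        adaptive = any(isinstance(a.blend_weight, str) for a in assignments)
        if not const_pos and not adaptive:
            rep.errors.append(f"state {sid!r}: all combination-function blend weights are zero")
        for a in assignments:
            fn = get_function(a.function_id)
            if fn.name == "hebb":
                if len(m.mb[sid]) != 2:
                    rep.errors.append(
                        f"state {sid!r}: hebb requires exactly 2 incoming impacts, "
                        f"mb row has {len(m.mb[sid])}"
                    )
                st = spec.state(sid)
                if st.role == "W" and tuple(m.mb[sid]) != st.reifies:
                    rep.warnings.append(
                        f"W-state {sid!r}: mb row {m.mb[sid]} is not its reified "
                        f"connection {st.reifies}"
                    )

    # initial values
    for s in spec.states:
        if not (0.0 <= s.initial_value <= 1.0):
            rep.warnings.append(f"state {s.id!r}: initial value {s.initial_value} outside [0, 1]")

    # reachability from stimulus states (base causal edges + reification edges)
    succ: dict[str, set[str]] = {sid: set() for sid in ids}
    for tgt, row in m.mb.items():
        for src in row:
            if src in succ:
                succ[src].add(tgt)
    for s in spec.states:
        if s.role == "W":
            succ[s.id].add(s.reifies[1])  # type: ignore[index]
        elif s.role in ("H", "M") and isinstance(s.reifies, str):
            succ[s.id].add(s.reifies)
    roots = [sid for sid in ids if not m.mb.get(sid)]
    seen = set(roots)
    frontier = list(roots)
    while frontier:
        nxt = frontier.pop()
        for t in succ[nxt]:
            if t not in seen:
                seen.add(t)
                frontier.append(t)
    for sid in ids:
        if sid not in seen:
            rep.warnings.append(f"state {sid!r}: unreachable from any stimulus (root) state")
    return rep


def in_degree(spec: NetworkSpec, state_id: str) -> int:
    """Number of incoming ``mb`` slots of a state."""
    return spec.in_degree(state_id)


# ---------------------------------------------------------------------------
# adaptive-role resolution
# ---------------------------------------------------------------------------


def resolve(spec: NetworkSpec, snapshot: Mapping[str, float]) -> dict[str, ResolvedState]:
    """Replace every adaptive slot by the referenced self-model state's value.

    ``snapshot`` maps state id -> current activation and must cover every
    state.  Constant slots pass through unchanged; on an all-constant spec
    this is the identity on the numeric content.
    """
    missing = [sid for sid in spec.ids if sid not in snapshot]
    if missing:
        raise SpecificationError(f"snapshot missing state(s) {missing[:5]}")
    m = spec.matrices
    out: dict[str, ResolvedState] = {}
    for sid in spec.ids:
        row = m.mb.get(sid, [])
        wv = m.mcwv.get(sid, [])
        wa = m.mcwa.get(sid, [])
        weights = []
        for slot in range(len(row)):
            if slot < len(wa) and wa[slot] is not None:
                weights.append(float(snapshot[wa[slot]]))
            else:
                weights.append(float(wv[slot]))
        if m.msa.get(sid) is not None:
            speed = float(snapshot[m.msa[sid]])
        else:
            speed = float(m.msv.get(sid) or 0.0)
        assignments = []
        for a in spec.function_assignments(sid):
            params = {
                k: (float(snapshot[v]) if isinstance(v, str) else float(v))
                for k, v in a.params.items()
            }
            blend = (
                float(snapshot[a.blend_weight])
                if isinstance(a.blend_weight, str)
                else float(a.blend_weight)
            )
            assignments.append(FunctionAssignment(a.function_id, params, blend))
        out[sid] = ResolvedState(sid, tuple(row), tuple(weights), speed, tuple(assignments))
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def _parse_cell(cell: str, where: str) -> float | str | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        return cell  # a state-id reference


def _read_rows(path: Path) -> list[list[str]]:
    if not path.exists():
        return []
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(c.strip() for c in row)]
    return rows[1:] if rows and rows[0] and rows[0][0].strip().lower() == "state" else rows


def load_role_matrices(
    source: str | Path | Mapping[str, str | Path], metadata: dict | None = None
) -> NetworkSpec:
    """Load a network from role-matrix CSV files.

    ``source`` is either a directory containing ``mb.csv`` ... ``iv.csv`` or
    a mapping matrix-name -> path.  Missing files are treated as empty
    matrices.  Raises :class:`SpecificationError` with row/column coordinates
    on malformed cells.
    """
    if isinstance(source, (str, Path)):
        d = Path(source)
        paths = {name: d / f"{name}.csv" for name in MATRIX_NAMES}
        paths["iv"] = d / "iv.csv"
    else:
        paths = {k: Path(v) for k, v in source.items()}

    matrices = RoleMatrices()

    def _slot_matrix(name: str, numeric: bool | None):
        out: dict[str, list] = {}
        for r, row in enumerate(_read_rows(paths.get(name, Path("/nonexistent")))):
            sid = row[0].strip()
            if sid in out:
                raise SpecificationError(f"{name}.csv row {r + 2}: duplicate state id {sid!r}")
            cells = []
            for c, cell in enumerate(row[1:]):
                val = _parse_cell(cell, f"{name}.csv row {r + 2} col {c + 2}")
                if val is not None and numeric is True and isinstance(val, str):
                    raise SpecificationError(
                        f"{name}.csv row {r + 2} col {c + 2}: expected a number, got {cell!r}"
                    )
                if val is not None and numeric is False and not isinstance(val, str):
                    raise SpecificationError(
                        f"{name}.csv row {r + 2} col {c + 2}: expected a state id, got {cell!r}"
                    )
                cells.append(val)
            while cells and cells[-1] is None:
                cells.pop()
            out[sid] = cells
        return out

    mb_raw = _slot_matrix("mb", numeric=False)
    matrices.mb = {sid: [c for c in row] for sid, row in mb_raw.items()}
    for sid, row in matrices.mb.items():
        if any(c is None for c in row):
            raise SpecificationError(f"mb.csv: row {sid!r} has an empty slot inside the row")
    matrices.mcwv = _slot_matrix("mcwv", numeric=True)
    matrices.mcwa = _slot_matrix("mcwa", numeric=False)
    # pad weight rows to the mb width
    for name in ("mcwv", "mcwa"):
        mat = getattr(matrices, name)
        for sid, row in mb_raw.items():
            mat.setdefault(sid, [])
            while len(mat[sid]) < len(row):
                mat[sid].append(None)

    for name, numeric in (("msv", True), ("msa", False)):
        out: dict = {}
        for r, row in enumerate(_read_rows(paths.get(name, Path("/nonexistent")))):
            sid = row[0].strip()
            val = _parse_cell(row[1] if len(row) > 1 else "", f"{name}.csv row {r + 2}")
            if val is not None and numeric and isinstance(val, str):
                raise SpecificationError(f"{name}.csv row {r + 2}: expected a number")
            if val is not None and not numeric and not isinstance(val, str):
                raise SpecificationError(f"{name}.csv row {r + 2}: expected a state id")
            out[sid] = val
        setattr(matrices, name, out)

    def _func_matrix(name: str, numeric: bool):
        """mcfw*: header 'state,<function-id>,...'; cells gamma or an M-state id."""
        path = paths.get(name, Path("/nonexistent"))
        out: dict[str, dict] = {}
        if not path.exists():
            return out
        with open(path, newline="") as fh:
            rows = [row for row in csv.reader(fh) if any(c.strip() for c in row)]
        if not rows:
            return out
        header = [h.strip() for h in rows[0][1:]]
        for r, row in enumerate(rows[1:]):
            sid = row[0].strip()
            entry: dict = {}
            for c, cell in enumerate(row[1:]):
                val = _parse_cell(cell, f"{name}.csv row {r + 2} col {c + 2}")
                if val is None:
                    continue
                if numeric != (not isinstance(val, str)):
                    raise SpecificationError(
                        f"{name}.csv row {r + 2} col {c + 2}: wrong cell kind {cell!r}"
                    )
                entry[header[c]] = val
            if entry:
                out[sid] = entry
        return out

    matrices.mcfwv = _func_matrix("mcfwv", numeric=True)
    matrices.mcfwa = _func_matrix("mcfwa", numeric=False)

    def _param_matrix(name: str, numeric: bool):
        """mcfp*: header 'state,<fid>.<param>,...'."""
        path = paths.get(name, Path("/nonexistent"))
        out: dict[str, dict[str, dict]] = {}
        if not path.exists():
            return out
        with open(path, newline="") as fh:
            rows = [row for row in csv.reader(fh) if any(c.strip() for c in row)]
        if not rows:
            return out
        header = []
        for h in rows[0][1:]:
            h = h.strip()
            if "." not in h:
                raise SpecificationError(f"{name}.csv: header column {h!r} is not '<fn>.<param>'")
            header.append(tuple(h.split(".", 1)))
        for r, row in enumerate(rows[1:]):
            sid = row[0].strip()
            entry: dict[str, dict] = {}
            for c, cell in enumerate(row[1:]):
                val = _parse_cell(cell, f"{name}.csv row {r + 2} col {c + 2}")
                if val is None:
                    continue
                if numeric != (not isinstance(val, str)):
                    raise SpecificationError(
                        f"{name}.csv row {r + 2} col {c + 2}: wrong cell kind {cell!r}"
                    )
                fid, pname = header[c]
                entry.setdefault(fid, {})[pname] = val
            if entry:
                out[sid] = entry
        return out

    matrices.mcfpv = _param_matrix("mcfpv", numeric=True)
    matrices.mcfpa = _param_matrix("mcfpa", numeric=False)

    iv: dict[str, float] = {}
    for r, row in enumerate(_read_rows(paths.get("iv", Path("/nonexistent")))):
        sid = row[0].strip()
        val = _parse_cell(row[1] if len(row) > 1 else "", f"iv.csv row {r + 2}")
        if isinstance(val, str):
            raise SpecificationError(f"iv.csv row {r + 2}: expected a number, got {val!r}")
        iv[sid] = float(val) if val is not None else 0.0

    return from_matrices(matrices, iv, metadata=metadata)


def save_role_matrices(spec: NetworkSpec, directory: str | Path) -> None:
    """Write the ten CSV files (nine matrices + iv.csv), deterministically."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    m = spec.matrices

    def _cell(v) -> str:
        if v is None:
            return ""
        return v if isinstance(v, str) else _fmt(v)

    def _write_slots(name: str, mat: Mapping[str, Sequence]):
        width = max((len(r) for r in mat.values()), default=0)
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["state"] + [f"s{k + 1}" for k in range(width)])
        for sid in spec.ids:
            row = list(mat.get(sid, []))
            w.writerow([sid] + [_cell(c) for c in row] + [""] * (width - len(row)))
        (d / f"{name}.csv").write_text(buf.getvalue())

    _write_slots("mb", m.mb)
    _write_slots("mcwv", m.mcwv)
    _write_slots("mcwa", m.mcwa)

    for name, col in (("msv", "speed"), ("msa", "h_state")):
        mat = getattr(m, name)
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["state", col])
        for sid in spec.ids:
            if mat.get(sid) is not None:
                w.writerow([sid, _cell(mat[sid])])
        (d / f"{name}.csv").write_text(buf.getvalue())

    for name in ("mcfwv", "mcfwa"):
        mat = getattr(m, name)
        fids = sorted({fid for entry in mat.values() for fid in entry})
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["state"] + fids)
        for sid in spec.ids:
            entry = mat.get(sid, {})
            if entry:
                w.writerow([sid] + [_cell(entry.get(fid)) for fid in fids])
        (d / f"{name}.csv").write_text(buf.getvalue())

    for name in ("mcfpv", "mcfpa"):
        mat = getattr(m, name)
        cols = sorted(
            {(fid, p) for entry in mat.values() for fid, ps in entry.items() for p in ps}
        )
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["state"] + [f"{fid}.{p}" for fid, p in cols])
        for sid in spec.ids:
            entry = mat.get(sid, {})
            if entry:
                w.writerow([sid] + [_cell(entry.get(fid, {}).get(p)) for fid, p in cols])
        (d / f"{name}.csv").write_text(buf.getvalue())

    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["state", "value"])
    for s in spec.states:
        w.writerow([s.id, _fmt(s.initial_value)])
    (d / "iv.csv").write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# random networks (property-test fixture generator)
# ---------------------------------------------------------------------------


def random_network(
    n_base: int, n_adaptive: int, density: float, seed: int
) -> NetworkSpec:
    """Generate a random, always-valid reified network.

    ``n_base`` base states are wired with directed connections drawn with
    probability ``density``; ``n_adaptive`` of those connections are made
    adaptive, each governed by a Hebbian W-state with a constant persistence
    and speed.  All constant weights are positive and each state's
    combination function is normalised so its output stays in [0, 1]; the
    result is reproducible for a fixed seed and passes :func:`validate` with
    zero errors.
    """
    if n_base < 1:
        raise SpecificationError("random_network: n_base must be >= 1")
    if not (0.0 <= density <= 1.0):
        raise SpecificationError("random_network: density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = [f"B{k + 1}" for k in range(n_base)]
    edges = [
        (base[i], base[j])
        for i in range(n_base)
        for j in range(n_base)
        if i != j and rng.random() < density
    ]
    if n_adaptive > len(edges):
        raise SpecificationError(
            f"random_network: n_adaptive={n_adaptive} exceeds the {len(edges)} generated connections"
        )
    adaptive_idx = sorted(
        rng.choice(len(edges), size=n_adaptive, replace=False).tolist()
    ) if n_adaptive else []
    adaptive = {edges[k]: f"W_{i + 1}" for i, k in enumerate(adaptive_idx)}

    m = RoleMatrices()
    for sid in base:
        m.mb[sid] = [src for (src, tgt) in edges if tgt == sid]
    for (src, tgt), wid in adaptive.items():
        m.mb[wid] = [src, tgt]

    iv: dict[str, float] = {}
    for sid in base:
        row = m.mb[sid]
        if not row:
            m.mcwv[sid] = []
            m.mcwa[sid] = []
            m.msv[sid] = 0.0
            iv[sid] = float(rng.uniform(0.2, 1.0))
            continue
        wv: list[float | None] = []
        wa: list[str | None] = []
        cap = 0.0  # maximum possible summed impact, for normalisation
        for src in row:
            if (src, sid) in adaptive:
                wv.append(None)
                wa.append(adaptive[(src, sid)])
                cap += 1.0
            else:
                w = float(rng.uniform(0.2, 1.0))
                wv.append(round(w, 6))
                wa.append(None)
                cap += w
        m.mcwv[sid] = wv
        m.mcwa[sid] = wa
        m.msv[sid] = round(float(rng.uniform(0.1, 1.0)), 6)
        if rng.random() < 0.5:
            m.mcfwv[sid] = {"alogistic": 1.0}
            m.mcfpv[sid] = {
                "alogistic": {
                    "sigma": round(float(rng.uniform(1.0, 10.0)), 6),
                    "tau": round(float(rng.uniform(0.1, 0.6)) * cap, 6),
                }
            }
        else:
            m.mcfwv[sid] = {"eucl": 1.0}
            m.mcfpv[sid] = {"eucl": {"n": 1.0, "lam": round(cap, 6)}}
        iv[sid] = float(rng.uniform(0.0, 1.0))

    for (src, tgt), wid in adaptive.items():
        m.mcwv[wid] = [1.0, 1.0]
        m.mcwa[wid] = [None, None]
        m.msv[wid] = round(float(rng.uniform(0.1, 0.5)), 6)
        m.mcfwv[wid] = {"hebb": 1.0}
        m.mcfpv[wid] = {"hebb": {"mu": round(float(rng.uniform(0.7, 0.99)), 6)}}
        iv[wid] = float(rng.uniform(0.0, 0.3))

    iv = {k: round(v, 6) for k, v in iv.items()}
    return from_matrices(
        m, iv, metadata={"generator": "random_network", "seed": int(seed)}
    )
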