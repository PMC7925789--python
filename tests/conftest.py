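"""Shared fixtures: the bundled child model, cached scenario runs, and an
independent straight-line oracle implementation of the update equations."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

import reifnet as rn
from reifnet.engine import SimulationConfig

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


def naive_step(spec, values: dict, dt: float, clamp: bool = True) -> dict:
    """Independent one-step oracle: the update equations written out directly.

    No engine abstractions: weights, speeds and function parameters are read
    straight from the role matrices (adaptive entries from ``values``), the
    combination functions are re-typed from their printed formulas, and
    Y(t+dt) = Y(t) + eta*[aggimpact - Y]*dt is applied per state.
    Assumes single-function assignments (true for every fixture it checks).
    """
    m = spec.matrices
    new = {}
    for s in spec.states:
        sid = s.id
        row = m.mb.get(sid, [])
        if not row:
            new[sid] = values[sid]
            continue
        weights = []
        for k, src in enumerate(row):
            wa = m.mcwa.get(sid, [])
            if k < len(wa) and wa[k] is not None:
                weights.append(values[wa[k]])
            else:
                weights.append(m.mcwv[sid][k])
        impacts = [w * values[src] for w, src in zip(weights, row)]
        fids = set(m.mcfwv.get(sid, {})) | set(m.mcfwa.get(sid, {}))
        assert len(fids) == 1, "oracle handles single-function states only"
        fid = fids.pop()
        params = dict(m.mcfpv.get(sid, {}).get(fid, {}))
        for pname, ref in m.mcfpa.get(sid, {}).get(fid, {}).items():
            params[pname] = values[ref]
        if fid == "eucl":
            n, lam = params["n"], params["lam"]
            agg = (sum(v**n for v in impacts) / lam) ** (1.0 / n) if n != 1 else (
                sum(impacts) / lam
            )
        elif fid == "alogistic":
            sig, tau = params["sigma"], params["tau"]
            V = sum(impacts)
            agg = (
                1.0 / (1.0 + math.exp(-sig * (V - tau)))
                - 1.0 / (1.0 + math.exp(sig * tau))
            ) * (1.0 + math.exp(-sig * tau))
            if agg < 0.0:
                agg = 0.0
        elif fid == "hebb":
            v1, v2 = impacts
            w = values[sid]
            agg = v1 * v2 * (1.0 - w) + params["mu"] * w
        elif fid == "identity":
            agg = sum(impacts)
        else:  # pragma: no cover
            raise AssertionError(fid)
        if m.msa.get(sid) is not None:
            eta = values[m.msa[sid]]
        else:
            eta = m.msv.get(sid) or 0.0
        y = values[sid] + eta * (agg - values[sid]) * dt
        if clamp:
            y = min(1.0, max(0.0, y))
        new[sid] = y
    return new


@pytest.fixture(scope="session")
def oracle_step():
    return naive_step


@pytest.fixture(scope="session")
def child_spec():
    return rn.build_child_model()


@pytest.fixture(scope="session")
def resistant_spec():
    return rn.build_child_model("resistant")


@pytest.fixture(scope="session")
def happy_offline_run(child_spec):
    return rn.simulate(child_spec, rn.scenario("happy_offline"))


@pytest.fixture(scope="session")
def happy_social_run(child_spec):
    return rn.simulate(child_spec, rn.scenario("happy_social"))


@pytest.fixture(scope="session")
def resistant_social_run(resistant_spec):
    return rn.simulate(resistant_spec, rn.scenario("happy_social"))


@pytest.fixture(scope="session")
def isolation_run(child_spec):
    return rn.simulate(child_spec, rn.scenario("unhappy_isolation"))


@pytest.fixture(scope="session")
def relief_run(child_spec):
    return rn.simulate(child_spec, rn.scenario("coping_relief"))


@pytest.fixture(scope="session")
def firm_coping_run(child_spec):
    # the firm-coping run: coping memories in place, horizon long enough for
    # the network to settle completely
    return rn.simulate(
        child_spec, rn.scenario("unhappy_coping"), SimulationConfig(horizon=800.0)
    )
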