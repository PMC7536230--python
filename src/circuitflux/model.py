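"""Kinetic ODE model of the layered NOT/NOR circuit.

Each gate i is described by an mRNA and a protein balance:

    dm_i/dt = J_i - gamma * (eta_i*(1-b) + b) * m_i
    dR_i/dt = alpha_i * m_i - mu * R_i

where the flux J_i into gate i sums the activities of its input promoters
(the repression Hill function of the cognate repressor count) plus the
read-through flux of the upstream transcription unit divided by the
intervening terminator strength.  All promoter activities are per-cell
totals (per-DNA table values times plasmid copy number).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .gates import hill

__all__ = [
    "CircuitModel",
    "SimulationResult",
    "ScanResult",
    "load_nominal_config",
    "boolean_propagate",
    "all_states",
]

SIGNALS = ("iptg", "atc", "ara")


def all_states() -> list[tuple[int, int, int]]:
    """The eight induction states as (iptg, atc, ara) bit triples."""
    return [(i, a, r) for i in (0, 1) for a in (0, 1) for r in (0, 1)]


def load_nominal_config() -> dict:
    """Load the shipped nominal topology + parameter configuration."""
    ref = importlib.resources.files("circuitflux.data") / "nominal_circuit.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass
class SimulationResult:
    """Euler trajectories of mRNA/protein counts and promoter activities."""

    times: np.ndarray  # seconds
    mrna: pd.DataFrame  # time x gene
    protein: pd.DataFrame  # time x gene
    promoter_activity: pd.DataFrame  # time x promoter, RNAP/s per cell
    steady: bool


@dataclass
class ScanResult:
    parameter: str
    values: np.ndarray  # raw parameter values scanned
    display_values: np.ndarray  # promoter parameters shown as y/N
    scores: np.ndarray
    nominal_value: float
    nonfunctional_intervals: list[tuple[float, float]]


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise KeyError(f"{context}: missing required key {key!r}")
    return mapping[key]


class CircuitModel:
    """Compiled circuit topology + parameters ready for simulation."""

    def __init__(self, config: dict):
        self.config = copy.deepcopy(config)
        self._compile()

    # ------------------------------------------------------------------ setup

    @classmethod
    def nominal(cls) -> "CircuitModel":
        return cls(load_nominal_config())

    @classmethod
    def from_yaml(cls, path) -> "CircuitModel":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def _compile(self) -> None:
        cfg = self.config
        g = _require(cfg, "globals", "config")
        self.gamma = float(g["gamma"])
        self.b = float(g["b"])
        self.mu = float(g["mu"])
        scales = cfg.get("scales", {})
        pscale = float(scales.get("promoter", 1.0))
        kscale = float(scales.get("binding_constant", 1.0))

        self.sensors = {
            name: {
                "signal": _require(s, "signal", f"sensor {name}"),
                "on": float(s["on_rnaps"]),
                "off": float(s["off_rnaps"]),
            }
            for name, s in _require(cfg, "sensors", "config").items()
        }

        gates = _require(cfg, "gates", "config")
        self.gate_names = [gate["name"] for gate in gates]
        idx = {name: i for i, name in enumerate(self.gate_names)}
        n = len(gates)

        promoters = cfg["promoters"]
        repressors = cfg["repressors"]
        ribozymes = cfg["ribozymes"]
        rbs = cfg["rbs"]
        terminators = cfg["terminators"]

        # per-cell promoter strengths for each gate output promoter
        self.promoter_of_gate: list[str | None] = []
        self.y_min = np.zeros(n)
        self.y_max = np.zeros(n)
        self.k = np.zeros(n)
        self.n_coop = np.zeros(n)
        self.eta = np.zeros(n)
        self.alpha = np.zeros(n)
        self.T_own = np.zeros(n)
        self.inputs: list[list[str]] = []
        self.readthrough_from = np.full(n, -1, dtype=int)
        self.gate_by_promoter: dict[str, int] = {}

        for i, gate in enumerate(gates):
            prom = gate.get("output_promoter")
            self.promoter_of_gate.append(prom)
            if prom is not None:
                p = _require(promoters, prom, "promoters")
                copies = float(p.get("copies", 1))
                self.y_max[i] = float(p["y_max"]) * pscale * copies
                self.y_min[i] = float(p["y_min"]) * pscale * copies
                rep = _require(repressors, prom, "repressors")
                self.k[i] = float(rep["k"]) * kscale
                self.n_coop[i] = float(rep["n"])
                self.gate_by_promoter[prom] = i
            self.eta[i] = float(_require(ribozymes, gate["ribozyme"], "ribozymes"))
            self.alpha[i] = float(_require(rbs, gate["rbs"], "rbs"))
            self.T_own[i] = float(_require(terminators, gate["terminator"], "terminators"))
            self.inputs.append(list(gate["inputs"]))
            upstream = gate.get("readthrough_from")
            if upstream is not None:
                j = idx[upstream]
                if j >= i:
                    raise ValueError(
                        "read-through chain must follow the physical gate order"
                    )
                self.readthrough_from[i] = j

        for i, names in enumerate(self.inputs):
            for name in names:
                if name not in self.sensors and name not in self.gate_by_promoter:
                    raise KeyError(
                        f"gate {self.gate_names[i]}: unknown input promoter {name!r}"
                    )

        self.mrna_loss = self.gamma * (self.eta * (1.0 - self.b) + self.b)
        self.designed_on = [tuple(s) for s in cfg.get("designed_on_states", [])]
        self.n_gates = n
        self.output_gate = n - 1  # yfp by convention: last gate

    # ------------------------------------------------------------ evaluation

    def sensor_values(self, bits: Sequence[int]) -> dict[str, float]:
        """Map (iptg, atc, ara) induction bits to sensor promoter activities."""
        by_signal = dict(zip(SIGNALS, bits))
        return {
            name: s["on"] if by_signal[s["signal"]] else s["off"]
            for name, s in self.sensors.items()
        }

    def promoter_activities(self, R: np.ndarray) -> np.ndarray:
        """Gate output promoter activity from the cognate repressor count."""
        y = np.zeros(self.n_gates)
        for i in range(self.n_gates):
            if self.promoter_of_gate[i] is None:
                continue
            y[i] = hill(R[i], self.y_min[i], self.y_max[i], self.k[i], self.n_coop[i])
        return y

    def fluxes(self, R: np.ndarray, sensor_values: Mapping[str, float]) -> np.ndarray:
        """Transcription flux into each gate, walking the DNA in order."""
        y = self.promoter_activities(R)
        J = np.zeros(self.n_gates)
        for i in range(self.n_gates):
            total = 0.0
            for name in self.inputs[i]:
                if name in self.sensors:
                    total += sensor_values[name]
                else:
                    total += y[self.gate_by_promoter[name]]
            j = self.readthrough_from[i]
            if j >= 0:
                total += J[j] / self.T_own[j]
            J[i] = total
        return J

    def derivatives(
        self,
        m: np.ndarray,
        R: np.ndarray,
        sensor_values: Mapping[str, float],
    ) -> tuple[np.ndarray, np.ndarray]:
        """Right-hand side of the mRNA and protein balances."""
        J = self.fluxes(R, sensor_values)
        dm = J - self.mrna_loss * m
        dR = self.alpha * m - self.mu * R
        return dm, dR

    # ------------------------------------------------------------ steady state

    def steady_state(
        self,
        inputs: Sequence[int] | Mapping[str, float],
        tol: float = 1e-12,
        max_iter: int = 10000,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fixed-point steady state (m*, R*, y*) of the circuit.

        Propagates promoter activities forward through the wiring; the
        weak read-through feedback (divided by large terminator folds)
        makes the iteration a contraction in practice.
        """
        sensor_values = (
            inputs if isinstance(inputs, Mapping) else self.sensor_values(inputs)
        )
        R = np.zeros(self.n_gates)
        for _ in range(max_iter):
            J = self.fluxes(R, sensor_values)
            m = J / self.mrna_loss
            R_new = self.alpha * m / self.mu
            if np.all(np.abs(R_new - R) <= tol * (np.abs(R) + 1e-30)):
                R = R_new
                break
            R = R_new
        else:
            raise RuntimeError("steady-state fixed point did not converge")
        J = self.fluxes(R, sensor_values)
        m = J / self.mrna_loss
        y = self.promoter_activities(R)
        return m, R, y

    # -------------------------------------------------------------- simulate

    def _euler_to_steady(
        self,
        m: np.ndarray,
        R: np.ndarray,
        sensor_values: Mapping[str, float],
        dt: float,
        rel_tol: float = 1e-9,
        check_every_s: float = 1000.0,
        t_cap: float = 24 * 3600.0,
    ) -> tuple[np.ndarray, np.ndarray, bool]:
        steps_per_check = max(1, int(round(check_every_s / dt)))
        t = 0.0
        while t < t_cap:
            m_prev, R_prev = m.copy(), R.copy()
            for _ in range(steps_per_check):
                dm, dR = self.derivatives(m, R, sensor_values)
                m = m + dt * dm
                R = R + dt * dR
                t += dt
            self._check_state(m, R)
            # floor the denominator so numerically-zero states don't stall
            denom = np.maximum(np.abs(R), 1e-9 * max(np.abs(R).max(), 1e-30))
            change = np.abs(R - R_prev) / denom
            denom_m = np.maximum(np.abs(m), 1e-9 * max(np.abs(m).max(), 1e-30))
            change_m = np.abs(m - m_prev) / denom_m
            if change.max() < rel_tol and change_m.max() < rel_tol:
                return m, R, True
        return m, R, False

    def _check_state(self, m: np.ndarray, R: np.ndarray) -> None:
        for vec, label in ((m, "m"), (R, "R")):
            bad = ~np.isfinite(vec) | (vec < 0)
            if bad.any():
                i = int(np.argmax(bad))
                raise RuntimeError(
                    f"unstable integration: {label}_{self.gate_names[i]} became "
                    f"{vec[i]!r}; reduce dt"
                )

    def simulate(
        self,
        initial_inputs: Sequence[int],
        final_inputs: Sequence[int],
        dt: float = 10.0,
        t_end: float = 12 * 3600.0,
    ) -> SimulationResult:
        """Forward-Euler trajectory after a step change in the inputs.

        The state is first pre-run to steady state under the initial
        inputs; at t = 0 the sensor promoters switch to the final inputs.
        """
        max_rate = max(self.mrna_loss.max(), self.mu)
        if dt * max_rate >= 1.0:
            raise ValueError(f"dt = {dt} exceeds the Euler stability bound")
        init_sensors = self.sensor_values(initial_inputs)
        final_sensors = self.sensor_values(final_inputs)
        m = np.zeros(self.n_gates)
        R = np.zeros(self.n_gates)
        m, R, pre_steady = self._euler_to_steady(m, R, init_sensors, dt)

        n_steps = int(round(t_end / dt))
        times = np.arange(n_steps + 1) * dt
        m_traj = np.empty((n_steps + 1, self.n_gates))
        r_traj = np.empty((n_steps + 1, self.n_gates))
        y_traj = np.empty((n_steps + 1, self.n_gates))
        m_traj[0], r_traj[0] = m, R
        y_traj[0] = self.promoter_activities(R)
        for step in range(1, n_steps + 1):
            dm, dR = self.derivatives(m, R, final_sensors)
            m = m + dt * dm
            R = R + dt * dR
            m_traj[step], r_traj[step] = m, R
            y_traj[step] = self.promoter_activities(R)
        self._check_state(m, R)

        cols = self.gate_names
        prom_cols = [p if p else f"({name})" for p, name in zip(self.promoter_of_gate, cols)]
        return SimulationResult(
            times=times,
            mrna=pd.DataFrame(m_traj, index=times, columns=cols),
            protein=pd.DataFrame(r_traj, index=times, columns=cols),
            promoter_activity=pd.DataFrame(y_traj, index=times, columns=prom_cols),
            steady=pre_steady,
        )

    # ----------------------------------------------------------------- score

    def designed_truth_table(self) -> dict[tuple[int, int, int], int]:
        topo = self.config
        return {state: boolean_propagate(topo, state)[0] for state in all_states()}

    def output_steady_states(
        self, method: str = "steady", dt: float = 10.0, t_end: float = 12 * 3600.0
    ) -> dict[tuple[int, int, int], float]:
        """Steady-state output protein count for all eight induction states."""
        out = {}
        for state in all_states():
            if method == "steady":
                _, R, _ = self.steady_state(state)
                out[state] = float(R[self.output_gate])
            elif method == "euler":
                result = self.simulate(state, state, dt=dt, t_end=t_end)
                out[state] = float(result.protein.iloc[-1, self.output_gate])
            else:
                raise ValueError(f"unknown method {method!r}")
        return out

    def circuit_score(self, method: str = "steady", **kwargs) -> float:
        """min(ON-state output) / max(OFF-state output); < 1 is broken logic."""
        truth = self.designed_truth_table()
        outputs = self.output_steady_states(method=method, **kwargs)
        on = [outputs[s] for s, bit in truth.items() if bit]
        off = [outputs[s] for s, bit in truth.items() if not bit]
        if not on or not off:
            raise ValueError("designed truth table must contain ON and OFF states")
        max_off = max(off)
        if max_off == 0:
            return float("inf")
        return min(on) / max_off

    # ------------------------------------------------------------ sensitivity

    def _param_ref(self, name: str):
        """Resolve 'section.key[.field]' into getter/setter on the config."""
        parts = name.split(".")
        cfg = self.config
        if len(parts) == 3:
            section, key, leaf = parts
            node = _require(_require(cfg, section, "config"), key, section)
            return (lambda: node[leaf]), (lambda v: node.__setitem__(leaf, v))
        if len(parts) == 2:
            section, key = parts
            node = _require(cfg, section, "config")
            if key not in node:
                raise KeyError(f"{section}: unknown parameter {key!r}")
            if isinstance(node[key], dict):
                raise KeyError(f"{name}: missing leaf field")
            return (lambda: node[key]), (lambda v: node.__setitem__(key, v))
        raise KeyError(f"cannot resolve parameter path {name!r}")

    def sensitivity_scan(
        self,
        parameter: str,
        lo: float | None = None,
        hi: float | None = None,
        n_points: int = 1000,
        log_spaced: bool = True,
        method: str = "steady",
    ) -> ScanResult:
        """One-at-a-time scan of a parameter against the circuit score.

        ``parameter`` addresses a config entry, e.g. ``promoters.P_Tac.y_max``,
        ``ribozymes.riboJ53``, ``terminators.ECK120033737``,
        ``repressors.P_PhlF.k`` or ``sensors.P_Tac.on``.  The default range
        spans two decades on either side of the nominal value.  Promoter
        strengths are reported as per-DNA values (y/N) in
        ``display_values``; other parameters are reported as-is.
        """
        getter, setter = self._param_ref(parameter)
        nominal = float(getter())
        if lo is None or hi is None:
            if nominal <= 0:
                raise ValueError("cannot auto-range a non-positive nominal value")
            lo = nominal * 1e-2 if lo is None else lo
            hi = nominal * 1e2 if hi is None else hi
        if not (0 <= lo < hi):
            raise ValueError("invalid scan range")
        if log_spaced:
            if lo <= 0:
                raise ValueError("log-spaced scan requires lo > 0")
            values = np.logspace(np.log10(lo), np.log10(hi), n_points)
        else:
            values = np.linspace(lo, hi, n_points)

        scores = np.empty(n_points)
        try:
            for i, value in enumerate(values):
                setter(float(value))
                self._compile()
                scores[i] = self.circuit_score(method=method)
        finally:
            setter(nominal)
            self._compile()

        # promoter-strength scans are displayed per DNA copy (y/N)
        display = values.copy()
        pscale = float(self.config.get("scales", {}).get("promoter", 1.0))
        if parameter.startswith("promoters.") and parameter.endswith(("y_max", "y_min")):
            display = values * pscale
        elif parameter.startswith("sensors.") and parameter.endswith(("on_rnaps", "off_rnaps")):
            section, key, _ = parameter.split(".")
            copies = float(self.config[section][key].get("copies", 1))
            display = values / copies

        below = scores < 1.0
        intervals: list[tuple[float, float]] = []
        i = 0
        while i < n_points:
            if below[i]:
                j = i
                while j < n_points and below[j]:
                    j += 1
                intervals.append((float(values[i]), float(values[j - 1])))
                i = j
            else:
                i += 1
        return ScanResult(
            parameter=parameter,
            values=values,
            display_values=display,
            scores=scores,
            nominal_value=nominal,
            nonfunctional_intervals=intervals,
        )


# ---------------------------------------------------------------- boolean


def boolean_propagate(
    topology: dict,
    inputs: Sequence[int],
    failures: Mapping[str, int] | None = None,
) -> tuple[int, dict[str, int]]:
    """Digital propagation of the input bits through the NOT/NOR wiring.

    Every gate outputs NOT(OR(inputs)); ``failures`` pins a gate's
    expressed-repressor bit to 0 or 1 to model observed failed states.
    Returns the output bit (the last gate) and per-wire promoter bits.
    """
    failures = dict(failures or {})
    by_signal = dict(zip(SIGNALS, inputs))
    sensors = topology["sensors"]
    gates = topology["gates"]
    wire: dict[str, int] = {
        name: int(bool(by_signal[s["signal"]])) for name, s in sensors.items()
    }
    expressed: dict[str, int] = {}
    # regulatory wiring is acyclic: iterate until stable
    for _ in range(len(gates) + 1):
        changed = False
        for gate in gates:
            name = gate["name"]
            ins = [wire.get(p) for p in gate["inputs"]]
            if any(v is None for v in ins):
                continue
            # repressor (or reporter) is transcribed when any input is active;
            # the gate's output promoter is then the inverse of expression
            value = failures.get(name, int(any(ins)))
            if expressed.get(name) != value:
                expressed[name] = value
                changed = True
            prom = gate.get("output_promoter")
            if prom is not None:
                wire[prom] = int(not expressed[name])
        if not changed:
            break
    output_gate = gates[-1]["name"]
    if output_gate not in expressed:
        raise ValueError("boolean propagation failed to resolve the output gate")
    wires = dict(wire)
    wires.update({f"R_{g}": v for g, v in expressed.items()})
    return expressed[output_gate], wires
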