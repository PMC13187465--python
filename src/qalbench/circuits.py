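"""Parameterized quantum circuits: gate lists, the three circuit builders
used by the classifier, as-soon-as-possible depth, and OpenQASM export.

Conventions: qubit 0 is the leftmost bit of a measurement bitstring.
Depth is the longest path in the gate-dependency DAG where gates sharing
any qubit are ordered by list position (ASAP layering).  The second-order
ZZ feature map on 4 features with one repetition has depth 17 and 26
gates (4 H, 10 phase, 12 CX); RealAmplitudes(4 qubits, 3 reps) has depth
11 with 25 gates; EfficientSU2(4, 3) depth 15 with 41 gates; composing
the feature map with either ansatz gives 51 and 67 gates respectively.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GateOp",
    "Param",
    "Circuit",
    "FeatureMapSpec",
    "build_zz_feature_map",
    "build_real_amplitudes",
    "build_efficient_su2",
    "depth",
    "gate_census",
    "compose",
    "to_qasm",
]

_SINGLE_QUBIT = frozenset({"H", "X", "Y", "Z", "P", "RX", "RY", "RZ"})
_PARAMETERIZED = frozenset({"P", "RX", "RY", "RZ"})


@dataclass(frozen=True)
class Param:
    """Reference to a free parameter slot of a circuit."""

    slot: int


@dataclass(frozen=True)
class GateOp:
    kind: str
    qubits: tuple[int, ...]
    angle: float | Param | None = None

    def __post_init__(self) -> None:
        if self.kind not in _SINGLE_QUBIT and self.kind != "CX":
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if len(set(self.qubits)) != len(self.qubits):
            raise ValueError("qubit indices must be distinct")
        if self.kind in _PARAMETERIZED and self.angle is None:
            raise ValueError(f"{self.kind} requires an angle")
        if self.kind not in _PARAMETERIZED and self.angle is not None:
            raise ValueError(f"{self.kind} takes no angle")

    @property
    def is_bound(self) -> bool:
        return not isinstance(self.angle, Param)


@dataclass(frozen=True)
class Circuit:
    """Immutable ordered gate list on ``n_qubits`` with ``n_params`` free
    parameter slots."""

    n_qubits: int
    gates: tuple[GateOp, ...] = ()
    n_params: int = 0

    def __post_init__(self) -> None:
        slots = set()
        for g in self.gates:
            if any(q < 0 or q >= self.n_qubits for q in g.qubits):
                raise ValueError("gate qubit outside register")
            if isinstance(g.angle, Param):
                slots.add(g.angle.slot)
        if slots and (min(slots) < 0 or max(slots) >= self.n_params):
            raise ValueError("parameter slot outside declared range")
        if len(slots) != self.n_params:
            raise ValueError("n_params must equal the number of distinct slots")

    def bind(self, values) -> "Circuit":
        """Return a fully bound copy; ``values`` has length ``n_params``."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} parameter values, got {values.shape}"
            )
        bound = tuple(
            replace(g, angle=float(values[g.angle.slot]))
            if isinstance(g.angle, Param) else g
            for g in self.gates
        )
        return Circuit(self.n_qubits, bound, 0)

    @property
    def is_bound(self) -> bool:
        return self.n_params == 0


@dataclass(frozen=True)
class FeatureMapSpec:
    """Configuration of the pairwise-entangling feature map."""

    n_features: int = 4
    reps: int = 1
    data_map: str = "product"  # 'product': phi = x_i*x_j; 'pi_minus': (pi-x_i)(pi-x_j)

    def phi(self, xi: float, xj: float) -> float:
        if self.data_map == "product":
            return xi * xj
        if self.data_map == "pi_minus":
            return (math.pi - xi) * (math.pi - xj)
        raise ValueError(f"unknown data map {self.data_map!r}")


def build_zz_feature_map(x, spec: FeatureMapSpec | None = None) -> Circuit:
    """Second-order ZZ feature map, fully bound to the feature vector ``x``.

    Per repetition: H on every qubit, a phase gate P(2*x_i) on every
    qubit, then for each qubit pair (i < j) in lexicographic order the
    entangling block CX(i,j), P(2*phi(x_i, x_j)) on j, CX(i,j).
    """
    x = np.asarray(x, dtype=float).ravel()
    if spec is None:
        spec = FeatureMapSpec(n_features=len(x))
    if len(x) != spec.n_features:
        raise ValueError("feature vector length does not match spec")
    if spec.reps < 1:
        raise ValueError("reps must be >= 1")
    n = spec.n_features
    gates: list[GateOp] = []
    for _ in range(spec.reps):
        gates.extend(GateOp("H", (q,)) for q in range(n))
        gates.extend(GateOp("P", (q,), 2.0 * float(x[q])) for q in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                gates.append(GateOp("CX", (i, j)))
                gates.append(GateOp("P", (j,), 2.0 * spec.phi(float(x[i]), float(x[j]))))
                gates.append(GateOp("CX", (i, j)))
    return Circuit(n, tuple(gates), 0)


def _linear_chain(n: int) -> list[GateOp]:
    return [GateOp("CX", (q, q + 1)) for q in range(n - 1)]


def build_real_amplitudes(n_qubits: int, reps: int = 3) -> Circuit:
    """Hardware-efficient real-amplitude ansatz: (reps+1) RY layers
    interleaved with ``reps`` linear CX entangling chains.
    m = n_qubits * (reps + 1) free parameters."""
    if reps < 0:
        raise ValueError("reps must be >= 0")
    gates: list[GateOp] = []
    slot = 0
    for layer in range(reps + 1):
        for q in range(n_qubits):
            gates.append(GateOp("RY", (q,), Param(slot)))
            slot += 1
        if layer < reps:
            gates.extend(_linear_chain(n_qubits))
    return Circuit(n_qubits, tuple(gates), slot)


def build_efficient_su2(n_qubits: int, reps: int = 3) -> Circuit:
    """SU(2)-expressive ansatz: (reps+1) rotation layers of RY then RZ on
    every qubit, interleaved with ``reps`` linear CX chains.
    m = 2 * n_qubits * (reps + 1) free parameters."""
    if reps < 0:
        raise ValueError("reps must be >= 0")
    gates: list[GateOp] = []
    slot = 0
    for layer in range(reps + 1):
        for kind in ("RY", "RZ"):
            for q in range(n_qubits):
                gates.append(GateOp(kind, (q,), Param(slot)))
                slot += 1
        if layer < reps:
            gates.extend(_linear_chain(n_qubits))
    return Circuit(n_qubits, tuple(gates), slot)


def depth(circuit: Circuit) -> int:
    """ASAP layering depth: longest chain of gates sharing qubits."""
    ready = [0] * circuit.n_qubits
    for g in circuit.gates:
        t = 1 + max(ready[q] for q in g.qubits)
        for q in g.qubits:
            ready[q] = t
    return max(ready, default=0) if circuit.gates else 0


def gate_census(circuit: Circuit) -> dict[str, int]:
    """Gate counts by kind, plus a ``total`` entry."""
    counts = Counter(g.kind for g in circuit.gates)
    out = dict(sorted(counts.items()))
    out["total"] = len(circuit.gates)
    return out


def compose(first: Circuit, second: Circuit) -> Circuit:
    """Concatenate two circuits; the second circuit's free slots are
    shifted after the first's."""
    if first.n_qubits != second.n_qubits:
        raise ValueError("circuits act on different register sizes")
    shift = first.n_params
    shifted = tuple(
        replace(g, angle=Param(g.angle.slot + shift))
        if isinstance(g.angle, Param) else g
        for g in second.gates
    )
    return Circuit(first.n_qubits, first.gates + shifted, shift + second.n_params)


_QASM_NAMES = {
    "H": "h", "X": "x", "Y": "y", "Z": "z",
    "P": "u1", "RX": "rx", "RY": "ry", "RZ": "rz", "CX": "cx",
}


def to_qasm(circuit: Circuit) -> str:
    """OpenQASM 2.0 text for a fully bound circuit."""
    if not circuit.is_bound:
        raise ValueError("cannot export a circuit with free parameters")
    lines = [
        "OPENQASM 2.0;",
        'include "qelib1.inc";',
        f"qreg q[{circuit.n_qubits}];",
        f"creg c[{circuit.n_qubits}];",
    ]
    for g in circuit.gates:
        name = _QASM_NAMES[g.kind]
        args = ",".join(f"q[{q}]" for q in g.qubits)
        if g.angle is not None:
            lines.append(f"{name}({g.angle:.12g}) {args};")
        else:
            lines.append(f"{name} {args};")
    lines.append("measure q -> c;")
    return "\n".join(lines) + "\n"
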