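"""Small-register quantum simulator: statevector and density-matrix
evolution with per-gate depolarizing Kraus noise, and seeded measurement
sampling.

The noise model applies a single-qubit depolarizing channel (identity
with probability 1-p_gate, each Pauli with probability p_gate/3) after
every single-qubit gate on its target qubit; CX gates are noiseless.
Default p_gate = 0.05, default 1024 shots per circuit execution; an
exact-probability mode (shots=None) is available for analysis.

Index convention: qubit 0 is the leftmost bit of a bitstring, i.e. the
most significant bit of the computational-basis index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import Circuit

__all__ = [
    "DepolarizingChannel",
    "SimConfig",
    "zero_state",
    "density_from_pure",
    "evolve_pure",
    "evolve_noisy",
    "outcome_probabilities",
    "sample_counts",
    "purity",
    "parity_probability",
]

_SQ2 = 1.0 / np.sqrt(2.0)
_I2 = np.eye(2, dtype=complex)
_X = np.array([[0, 1], [1, 0]], dtype=complex)
_Y = np.array([[0, -1j], [1j, 0]], dtype=complex)
_Z = np.array([[1, 0], [0, -1]], dtype=complex)
_H = np.array([[_SQ2, _SQ2], [_SQ2, -_SQ2]], dtype=complex)
_CX = np.array(
    [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=complex
).reshape(2, 2, 2, 2)


def _gate_matrix(kind: str, angle: float | None) -> np.ndarray:
    if kind == "H":
        return _H
    if kind == "X":
        return _X
    if kind == "Y":
        return _Y
    if kind == "Z":
        return _Z
    if kind == "P":
        return np.array([[1, 0], [0, np.exp(1j * angle)]], dtype=complex)
    half = angle / 2.0
    c, s = np.cos(half), np.sin(half)
    if kind == "RX":
        return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)
    if kind == "RY":
        return np.array([[c, -s], [s, c]], dtype=complex)
    if kind == "RZ":
        return np.array([[np.exp(-1j * half), 0], [0, np.exp(1j * half)]], dtype=complex)
    raise ValueError(f"unknown gate kind {kind!r}")  # pragma: no cover


@dataclass(frozen=True)
class DepolarizingChannel:
    """Single-qubit depolarizing channel with total error weight p_gate."""

    p_gate: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_gate <= 1.0:
            raise ValueError("p_gate must lie in [0, 1]")

    def kraus_operators(self) -> list[np.ndarray]:
        p = self.p_gate
        return [
            np.sqrt(1.0 - p) * _I2,
            np.sqrt(p / 3.0) * _X,
            np.sqrt(p / 3.0) * _Y,
            np.sqrt(p / 3.0) * _Z,
        ]

    def completeness_defect(self) -> float:
        """max-norm of sum(K^dag K) - I; zero for a valid channel."""
        acc = sum(K.conj().T @ K for K in self.kraus_operators())
        return float(np.max(np.abs(acc - _I2)))


@dataclass(frozen=True)
class SimConfig:
    """Execution settings: ``shots=None`` selects exact probabilities."""

    shots: int | None = 1024
    seed: int | None = None
    noise_enabled: bool = True
    p_gate: float = 0.05

    def __post_init__(self) -> None:
        if self.shots is not None and self.shots < 1:
            raise ValueError("shots must be >= 1")

    @property
    def channel(self) -> DepolarizingChannel | None:
        return DepolarizingChannel(self.p_gate) if self.noise_enabled else None


# ---------------------------------------------------------------------------
# state construction and low-level application (batched on a leading axis)

def zero_state(n_qubits: int) -> np.ndarray:
    psi = np.zeros(2 ** n_qubits, dtype=complex)
    psi[0] = 1.0
    return psi


def density_from_pure(psi: np.ndarray) -> np.ndarray:
    psi = np.asarray(psi, dtype=complex).ravel()
    return np.outer(psi, psi.conj())


def _apply_axis(arr: np.ndarray, U: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    k = len(axes)
    Ut = U.reshape((2,) * (2 * k))
    res = np.tensordot(Ut, arr, axes=(tuple(range(k, 2 * k)), axes))
    return np.moveaxis(res, tuple(range(k)), axes)


def _apply_unitary_pure(psi_t: np.ndarray, U: np.ndarray, qubits, offset: int) -> np.ndarray:
    return _apply_axis(psi_t, U, tuple(offset + q for q in qubits))


# ---------------------------------------------------------------------------
# public evolution paths

def evolve_pure(state: np.ndarray, circuit: Circuit) -> np.ndarray:
    """Noiseless statevector evolution of a fully bound circuit."""
    if not circuit.is_bound:
        raise ValueError("circuit has unbound parameters")
    n = circuit.n_qubits
    psi = np.asarray(state, dtype=complex).reshape((2,) * n)
    for g in circuit.gates:
        U = _CX.reshape(4, 4) if g.kind == "CX" else _gate_matrix(g.kind, g.angle)
        psi = _apply_unitary_pure(psi, U, g.qubits, 0)
    return psi.reshape(-1)


def evolve_noisy(
    state: np.ndarray, circuit: Circuit, channel: DepolarizingChannel
) -> np.ndarray:
    """Density-matrix evolution; the depolarizing channel follows every
    single-qubit gate on its target, CX gates are applied noiselessly."""
    if not circuit.is_bound:
        raise ValueError("circuit has unbound parameters")
    if channel.completeness_defect() > 1e-12:
        raise ValueError("Kraus completeness violated")
    n = circuit.n_qubits
    rho = np.asarray(state, dtype=complex).reshape((2,) * (2 * n))
    rho = _evolve_noisy_tensor(rho, circuit, channel, n, offset=0)
    return rho.reshape(2 ** n, 2 ** n)


def _channel_superop(channel: DepolarizingChannel) -> np.ndarray:
    """4x4 superoperator of the channel on the (row, col) index pair."""
    acc = np.zeros((4, 4), dtype=complex)
    for K in channel.kraus_operators():
        acc += np.kron(K, K.conj())
    return acc


def _evolve_noisy_tensor(rho, circuit, channel, n, offset):
    # fuse each single-qubit gate with its trailing channel into one 4x4
    # superoperator acting jointly on that qubit's row and column axes
    D = _channel_superop(channel)
    for g in circuit.gates:
        if g.kind == "CX":
            U = _CX.reshape(4, 4)
            rho = _apply_axis(rho, U, tuple(offset + q for q in g.qubits))
            rho = _apply_axis(rho, U.conj(), tuple(offset + n + q for q in g.qubits))
        else:
            U = _gate_matrix(g.kind, g.angle)
            S = D @ np.kron(U, U.conj())
            q = g.qubits[0]
            rho = _apply_axis(rho, S, (offset + q, offset + n + q))
    return rho


def evolve_noisy_batch(
    rhos: np.ndarray, circuit: Circuit, channel: DepolarizingChannel
) -> np.ndarray:
    """Evolve a stack of density matrices (B, 2^n, 2^n) through one
    circuit; used to amortise the ansatz over many encoded inputs."""
    n = circuit.n_qubits
    b = rhos.shape[0]
    t = rhos.reshape((b,) + (2,) * (2 * n))
    t = _evolve_noisy_tensor(t, circuit, channel, n, offset=1)
    return t.reshape(b, 2 ** n, 2 ** n)


def evolve_pure_batch(psis: np.ndarray, circuit: Circuit) -> np.ndarray:
    n = circuit.n_qubits
    b = psis.shape[0]
    t = psis.reshape((b,) + (2,) * n)
    for g in circuit.gates:
        U = _CX.reshape(4, 4) if g.kind == "CX" else _gate_matrix(g.kind, g.angle)
        t = _apply_axis(t, U, tuple(1 + q for q in g.qubits))
    return t.reshape(b, 2 ** n)


# ---------------------------------------------------------------------------
# measurement

def outcome_probabilities(state: np.ndarray) -> np.ndarray:
    """Computational-basis outcome distribution of a pure or mixed state."""
    state = np.asarray(state)
    if state.ndim == 1:
        probs = np.abs(state) ** 2
    else:
        probs = np.real(np.diag(state)).copy()
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("state is not normalised")
    return probs / total


def sample_counts(state: np.ndarray, config: SimConfig) -> dict[str, int]:
    """Multinomial draw of ``config.shots`` bitstrings (qubit 0 leftmost)."""
    if config.shots is None:
        raise ValueError("sample_counts requires a finite shot count")
    probs = outcome_probabilities(state)
    n = int(np.log2(probs.size))
    rng = np.random.default_rng(config.seed)
    counts = rng.multinomial(config.shots, probs)
    return {
        format(i, f"0{n}b"): int(c) for i, c in enumerate(counts) if c > 0
    }


def purity(rho: np.ndarray) -> float:
    return float(np.real(np.trace(rho @ rho)))


def _parity_mask(n_states: int) -> np.ndarray:
    idx = np.arange(n_states)
    par = np.zeros(n_states, dtype=np.int64)
    x = idx.copy()
    while x.any():
        par ^= x & 1
        x >>= 1
    return par.astype(bool)


def parity_probability(state: np.ndarray) -> float:
    """Probability that a measured bitstring has odd parity."""
    probs = outcome_probabilities(state)
    return float(probs[_parity_mask(probs.size)].sum())
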