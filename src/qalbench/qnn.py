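"""Quantum neural network classifier: ZZ feature map + variational
ansatz, measured with parity decoding.

The class-1 probability of an input is the probability that the final
bitstring has odd parity (sum of bits mod 2); class 0 is its complement.
In shot mode the parity frequency is estimated from a seeded binomial
draw at the exact parity probability, which is distributionally identical
to sampling full bitstrings and reducing them to parity.

Encoded feature states are cached per distinct input row, so training on
a cohort of binary features costs at most 2^4 encodings regardless of
cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuits import (
    Circuit,
    FeatureMapSpec,
    build_efficient_su2,
    build_real_amplitudes,
    build_zz_feature_map,
    compose,
)
from .simulator import (
    SimConfig,
    density_from_pure,
    evolve_noisy,
    evolve_noisy_batch,
    evolve_pure,
    evolve_pure_batch,
    outcome_probabilities,
    parity_probability,
    zero_state,
    _parity_mask,
)

__all__ = ["ANSATZE", "QNNClassifier", "build_ansatz", "qnn_predict_proba"]

ANSATZE = ("real_amplitudes", "efficient_su2")

_ALIASES = {
    "ra": "real_amplitudes",
    "real_amplitudes": "real_amplitudes",
    "esu2": "efficient_su2",
    "efficient_su2": "efficient_su2",
}


def build_ansatz(kind: str, n_qubits: int, reps: int = 3) -> Circuit:
    kind = _ALIASES.get(kind.lower())
    if kind == "real_amplitudes":
        return build_real_amplitudes(n_qubits, reps)
    if kind == "efficient_su2":
        return build_efficient_su2(n_qubits, reps)
    raise ValueError(f"unknown ansatz kind {kind!r}")


@dataclass
class QNNClassifier:
    """Variational classifier on ``n_features`` qubits."""

    ansatz_kind: str = "efficient_su2"
    n_features: int = 4
    reps: int = 3
    feature_map: FeatureMapSpec = None  # type: ignore[assignment]
    config: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.feature_map is None:
            self.feature_map = FeatureMapSpec(n_features=self.n_features)
        self.ansatz = build_ansatz(self.ansatz_kind, self.n_features, self.reps)
        self._cache: dict[bytes, np.ndarray] = {}

    @property
    def n_params(self) -> int:
        return self.ansatz.n_params

    def _encoded_state(self, x: np.ndarray) -> np.ndarray:
        """Post-feature-map state for one input (pure vector or density)."""
        key = x.tobytes()
        state = self._cache.get(key)
        if state is None:
            fmap = build_zz_feature_map(x, self.feature_map)
            psi0 = zero_state(self.n_features)
            if self.config.noise_enabled:
                state = evolve_noisy(density_from_pure(psi0), fmap, self.config.channel)
            else:
                state = evolve_pure(psi0, fmap)
            self._cache[key] = state
        return state

    def predict_proba(
        self, params, X, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Class-1 (odd-parity) probability for each row of ``X``."""
        params = np.asarray(params, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError("feature dimension mismatch")
        rows = [X[i] for i in range(X.shape[0])]
        keys = [r.tobytes() for r in rows]
        uniq: dict[bytes, int] = {}
        for r, k in zip(rows, keys):
            if k not in uniq:
                uniq[k] = len(uniq)
                self._encoded_state(r)
        states = np.stack([self._cache[k] for k in uniq])
        bound = self.ansatz.bind(params)
        if self.config.noise_enabled:
            final = evolve_noisy_batch(states, bound, self.config.channel)
            diag = np.real(np.einsum("bii->bi", final))
        else:
            final = evolve_pure_batch(states, bound)
            diag = np.abs(final) ** 2
        mask = _parity_mask(diag.shape[1])
        p_exact = np.clip(diag[:, mask].sum(axis=1), 0.0, 1.0)
        if self.config.shots is not None:
            if rng is None:
                rng = np.random.default_rng(self.config.seed)
            p_exact = rng.binomial(self.config.shots, p_exact) / self.config.shots
        index = np.array([uniq[k] for k in keys])
        return p_exact[index]


def qnn_predict_proba(
    params,
    x,
    ansatz_kind: str = "efficient_su2",
    spec: FeatureMapSpec | None = None,
    config: SimConfig | None = None,
) -> float:
    """Class-1 probability for a single input vector.

    Composes the feature map bound to ``x`` with the ansatz bound to
    ``params`` and simulates it under ``config`` (noisy density-matrix
    path by default, pure statevector when noise is disabled, exact
    probabilities when shots is None).
    """
    x = np.asarray(x, dtype=float).ravel()
    if spec is None:
        spec = FeatureMapSpec(n_features=len(x))
    if config is None:
        config = SimConfig()
    ansatz = build_ansatz(ansatz_kind, spec.n_features)
    params = np.asarray(params, dtype=float)
    if params.shape != (ansatz.n_params,):
        raise ValueError(f"expected {ansatz.n_params} parameters")
    circuit = compose(build_zz_feature_map(x, spec), ansatz).bind(params)
    if config.noise_enabled:
        state = evolve_noisy(
            density_from_pure(zero_state(spec.n_features)), circuit, config.channel
        )
    else:
        state = evolve_pure(zero_state(spec.n_features), circuit)
    p = parity_probability(state)
    if config.shots is not None:
        rng = np.random.default_rng(config.seed)
        p = float(rng.binomial(config.shots, p) / config.shots)
    return p
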