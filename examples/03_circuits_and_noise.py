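"""Build the classifier circuits, print their depth/gate census, and show
what the depolarizing channel does to a single noisy gate."""

import numpy as np

from qalbench.circuits import (
    build_efficient_su2,
    build_real_amplitudes,
    build_zz_feature_map,
    compose,
    depth,
    gate_census,
    Circuit,
    GateOp,
)
from qalbench.simulator import DepolarizingChannel, density_from_pure, evolve_noisy, purity, zero_state

fmap = build_zz_feature_map(np.zeros(4))
ra = build_real_amplitudes(4, 3)
esu2 = build_efficient_su2(4, 3)

print(f"{'circuit':<28}{'depth':>6}{'gates':>7}{'params':>8}")
for name, circ in [("ZZ feature map (4, 1 rep)", fmap),
                   ("RealAmplitudes (4q, 3 reps)", ra),
                   ("EfficientSU2 (4q, 3 reps)", esu2)]:
    print(f"{name:<28}{depth(circ):>6}{gate_census(circ)['total']:>7}"
          f"{circ.n_params:>8}")
for name, circ in [("feature map + RA", compose(fmap, ra)),
                   ("feature map + ESU2", compose(fmap, esu2))]:
    print(f"{name:<28}{'-':>6}{gate_census(circ)['total']:>7}{circ.n_params:>8}")

channel = DepolarizingChannel(p_gate=0.05)
rho = evolve_noisy(density_from_pure(zero_state(1)), Circuit(1, (GateOp("X", (0,)),)), channel)
print(f"\nnoisy X gate at p_gate = 0.05: P(measure 1) = {rho[1, 1].real:.5f} "
      f"(ideal 1.0), purity {purity(rho):.4f}")
print("Each Pauli error (X, Y, Z) occurs with probability p/3 after every "
      "single-qubit gate; two of the three leave the measured population "
      "intact, hence 1 - 2p/3.")
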