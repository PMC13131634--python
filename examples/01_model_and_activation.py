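"""The neural-mass network model and its activation function.

Builds a two-parcel model by hand, evaluates the parameterized sigmoid, and
takes one step of the dynamics.
"""

import numpy as np

import mindyx as mx

# A region's output psi_a(x) saturates in (-1, 1); alpha sets how step-like
# the response is (small alpha = step-like, large alpha = flat).
for alpha in (0.5, 5.0, 20.0):
    y = mx.activation(np.array([0.05, 0.15, 0.5]), np.full(3, alpha))
    slope = float(mx.activation_slope_at_zero(alpha))
    print(f"alpha={alpha:5.1f}  psi(0.05,0.15,0.5)={np.round(y, 3)}  "
          f"slope at 0 = {slope:.3f}")

# Two parcels: parcel 0 excites parcel 1; both decay toward baseline.
params = mx.MindyXParams(
    Ws=[[0.0, 0.0], [0.4, 0.0]],       # sparse connectivity (1 -> 0.4 -> 2)
    W1=np.zeros((2, 1)), W2=np.zeros((2, 1)),
    alpha=[5.0, 5.0], D=[0.3, 0.3],
    B=[[0.2], [-0.2]],                  # the task input excites 0, inhibits 1
)
x = np.array([0.2, 0.0])
print("\nstate x_t          =", x)
print("x_{t+1} (rest)     =", np.round(mx.step(params, x, np.zeros(1)), 4))
print("x_{t+1} (task u=1) =", np.round(mx.step(params, x, np.ones(1)), 4))
# The task input shifts both parcels' excitability; repeated under constant
# input the state converges to a (possibly different) fixed point.
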