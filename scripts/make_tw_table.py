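"""Regenerate the Tracy-Widom (GOE) quantile table embedded in radphylo.pca.

q'' = s q + 2 q^3, q(s) ~ Ai(s) as s -> +inf (Hastings-McLeod).
F2(s) = exp(-int_s^inf (x-s) q^2 dx); F1(s)^2 = F2(s) exp(-int_s^inf q dx).
"""
import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import airy

s0 = 10.0
ai, aip, _, _ = airy(s0)

def rhs(s, y):
    q, qp, I1, J0, J1 = y
    return [qp, s * q + 2 * q**3, -q, -q * q, -s * q * q]

sol = solve_ivp(rhs, [s0, -12.0], [ai, aip, 0.0, 0.0, 0.0],
                rtol=1e-12, atol=1e-14, dense_output=True, method='DOP853')
ss = np.linspace(-12, 9, 4201)
q, qp, I1, J0, J1 = sol.sol(ss)
I2 = J1 - ss * J0          # int (x-s) q^2
F2 = np.exp(-I2)
F1 = np.sqrt(F2) * np.exp(-0.5 * I1)
p_upper = 1.0 - F1
# check published GOE points
for ptarget in [0.05, 0.01, 0.001]:
    x = np.interp(1 - ptarget, F1, ss)
    print(f"p={ptarget}: x={x:.4f}")
# quantiles for table: p from 0.5 down to 1e-6, log-spaced-ish
ps = np.concatenate([[0.5, 0.4, 0.3, 0.2, 0.15, 0.1, 0.07, 0.05, 0.03, 0.02, 0.015, 0.01],
                     10**np.linspace(-2.2, -6, 20)])
xs = np.interp(1 - ps, F1, ss)
print("TW1_P =", np.array2string(ps, separator=', ', formatter={'float_kind': lambda v: f'{v:.6g}'}))
print("TW1_X =", np.array2string(xs, separator=', ', formatter={'float_kind': lambda v: f'{v:.6f}'}))
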