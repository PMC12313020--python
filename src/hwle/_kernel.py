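"""Numba-compiled inner loop of the panel log-likelihood.

Numerically equivalent to the numpy path in :mod:`hwle.likelihood`
(scaling-and-squaring order-10 Taylor exponential on the 3x3 living
block); kept free of Python objects so the optimizer's finite-difference
gradients stay cheap.
"""

import numpy as np
from numba import njit

# transition order must match hwle.transitions.TRANSITIONS
_TR_R = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], dtype=np.int64)
_TR_S = np.array([1, 2, 3, 0, 2, 3, 0, 1, 3], dtype=np.int64)
_DEATH_TR = np.array([2, 5, 8], dtype=np.int64)


@njit(cache=True)
def loglik_kernel(seg_age, seg_dt, itv_start, itv_nseg, itv_r, itv_s,
                  itv_dead, itv_death_age, itv_prof,
                  base, xi, profmult, x0):
    nI = itv_start.shape[0]
    total = 0.0
    nbad = 0
    P = np.empty((3, 3))
    E = np.empty((3, 3))
    A = np.empty((3, 3))
    T = np.empty((3, 3))
    for i in range(nI):
        for a in range(3):
            for b in range(3):
                P[a, b] = 1.0 if a == b else 0.0
        pr = itv_prof[i]
        for k in range(itv_nseg[i]):
            sidx = itv_start[i] + k
            agec = seg_age[sidx] - x0
            dt = seg_dt[sidx]
            for a in range(3):
                for b in range(3):
                    A[a, b] = 0.0
            for t in range(9):
                ex = xi[t] * agec
                if ex > 30.0:
                    ex = 30.0
                elif ex < -30.0:
                    ex = -30.0
                q = base[t] * np.exp(ex) * profmult[pr, t] * dt
                r = _TR_R[t]
                s = _TR_S[t]
                if s < 3:
                    A[r, s] = q
                A[r, r] -= q
            # expm(A): scale so the inf-norm drops below 0.25, order-10
            # Taylor in Horner form, then repeated squaring
            nrm = 0.0
            for a in range(3):
                rs = abs(A[a, 0]) + abs(A[a, 1]) + abs(A[a, 2])
                if rs > nrm:
                    nrm = rs
            s_ = 0
            while nrm > 0.25:
                nrm *= 0.5
                s_ += 1
            sc = 0.5 ** s_
            for a in range(3):
                for b in range(3):
                    E[a, b] = 1.0 if a == b else 0.0
            for j in range(10, 0, -1):
                for a in range(3):
                    for b in range(3):
                        acc = 0.0
                        for c in range(3):
                            acc += A[a, c] * sc * E[c, b]
                        T[a, b] = acc / j
                for a in range(3):
                    for b in range(3):
                        E[a, b] = (1.0 if a == b else 0.0) + T[a, b]
            for _ in range(s_):
                for a in range(3):
                    for b in range(3):
                        acc = 0.0
                        for c in range(3):
                            acc += E[a, c] * E[c, b]
                        T[a, b] = acc
                for a in range(3):
                    for b in range(3):
                        E[a, b] = T[a, b]
            for a in range(3):
                for b in range(3):
                    acc = 0.0
                    for c in range(3):
                        acc += P[a, c] * E[c, b]
                    T[a, b] = acc
            for a in range(3):
                for b in range(3):
                    P[a, b] = T[a, b]
        r0 = itv_r[i]
        if itv_dead[i]:
            agec = itv_death_age[i] - x0
            dens = 0.0
            for j in range(3):
                t = _DEATH_TR[j]
                ex = xi[t] * agec
                if ex > 30.0:
                    ex = 30.0
                elif ex < -30.0:
                    ex = -30.0
                dens += P[r0, j] * base[t] * np.exp(ex) * profmult[pr, t]
            if dens > 0.0:
                total += np.log(dens)
            else:
                total = total + (-np.inf)
                nbad += 1
        else:
            p = P[r0, itv_s[i]]
            if p > 0.0:
                total += np.log(p)
            else:
                total = total + (-np.inf)
                nbad += 1
    return total, nbad
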