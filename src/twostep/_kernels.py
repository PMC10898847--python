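"""Numba-compiled inner loops for the hybrid-model likelihood.

The session log-likelihood is evaluated thousands of times per subject
during multi-start MAP optimization, so the trial recursion is compiled.
`twostep.agent.session_loglik_reference` is the readable single-trial
reference the kernel is tested against.
"""

import math

import numpy as np
from numba import njit

LOG_FLOOR = math.log(1e-12)


@njit(cache=True)
def session_loglik_kernel(c1, s, c2, r, valid1, valid2,
                          alpha, bmb, bmf, brep, bcons):
    """Sum of log choice probabilities over one session.

    Arrays are int64 with -1 marking missing; valid1/valid2 are boolean.
    Latent values start at zero.  Only trials with both choices observed
    update the latent values; the previous-choice indicator tracks the last
    observed stage-1 choice.
    """
    q2_00 = 0.0  # state 0, alien 0
    q2_01 = 0.0
    q2_10 = 0.0
    q2_11 = 0.0
    qmf0 = 0.0
    qmf1 = 0.0
    prev = -1
    decay = 1.0 - alpha
    ll = 0.0
    n = c1.shape[0]
    for t in range(n):
        if not valid1[t]:
            continue
        # model-based stage-1 values: max alien value in each action's
        # common state (action a's common state is state a)
        qmb0 = q2_00 if q2_00 > q2_01 else q2_01
        qmb1 = q2_10 if q2_10 > q2_11 else q2_11
        v0 = bmb * qmb0 + bmf * qmf0
        v1 = bmb * qmb1 + bmf * qmf1
        if prev == 0:
            v0 += brep
        elif prev == 1:
            v1 += brep
        m = v0 if v0 > v1 else v1
        e0 = math.exp(v0 - m)
        e1 = math.exp(v1 - m)
        z = e0 + e1
        p1 = (e0 if c1[t] == 0 else e1) / z
        lp = math.log(p1) if p1 > 1e-12 else LOG_FLOOR
        ll += lp
        prev = c1[t]
        if not valid2[t]:
            continue
        st = s[t]
        if st == 0:
            w0 = bcons * q2_00
            w1 = bcons * q2_01
        else:
            w0 = bcons * q2_10
            w1 = bcons * q2_11
        m2 = w0 if w0 > w1 else w1
        f0 = math.exp(w0 - m2)
        f1 = math.exp(w1 - m2)
        z2 = f0 + f1
        p2 = (f0 if c2[t] == 0 else f1) / z2
        lp2 = math.log(p2) if p2 > 1e-12 else LOG_FLOOR
        ll += lp2
        # updates: chosen alien learns, everything unchosen decays
        rew = float(r[t])
        if st == 0:
            if c2[t] == 0:
                q2_00 = decay * q2_00 + rew
                chosen = q2_00
                q2_01 *= decay
            else:
                q2_01 = decay * q2_01 + rew
                chosen = q2_01
                q2_00 *= decay
            q2_10 *= decay
            q2_11 *= decay
        else:
            if c2[t] == 0:
                q2_10 = decay * q2_10 + rew
                chosen = q2_10
                q2_11 *= decay
            else:
                q2_11 = decay * q2_11 + rew
                chosen = q2_11
                q2_10 *= decay
            q2_00 *= decay
            q2_01 *= decay
        # model-free stage-1 value: chosen spaceship takes the freshly
        # updated chosen-alien value; the unchosen spaceship decays
        if c1[t] == 0:
            qmf0 = chosen
            qmf1 *= decay
        else:
            qmf1 = chosen
            qmf0 *= decay
    return ll


@njit(cache=True)
def negloglik_multi(theta, n_sessions, c1, s, c2, r, valid1, valid2, offsets,
                    ):  # pragma: no cover - exercised via fitting
    """Negative log-likelihood of 1-2 concatenated sessions.

    ``theta`` is the unconstrained 5*n_sessions vector; sessions are stored
    back-to-back in the flat arrays with ``offsets`` marking boundaries.
    """
    total = 0.0
    for k in range(n_sessions):
        a = 1.0 / (1.0 + math.exp(-theta[5 * k + 0]))
        bmb = math.exp(theta[5 * k + 1])
        bmf = math.exp(theta[5 * k + 2])
        brep = theta[5 * k + 3]
        bcons = math.exp(theta[5 * k + 4])
        lo = offsets[k]
        hi = offsets[k + 1]
        total += session_loglik_kernel(
            c1[lo:hi], s[lo:hi], c2[lo:hi], r[lo:hi],
            valid1[lo:hi], valid2[lo:hi], a, bmb, bmf, brep, bcons,
        )
    return -total
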