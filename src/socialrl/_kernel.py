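"""Compiled trial-loop kernel shared by simulation and likelihood evaluation.

A single numba routine walks through a session trial by trial and either
*evaluates* the log-likelihood of recorded choices or *simulates* choices
and outcomes from pre-drawn uniforms.  Using one code path for both
guarantees that the probability a simulated choice was drawn from and the
probability the likelihood assigns to it are bit-identical.

Condition codes: 0 = Private, 1 = Social-Choice, 2 = Social-Choice+Outcome.
The demonstrator's trial-t display influences the participant from trial
t+1 onward: in Social-Choice the previous demonstrator choice biases the
current softmax probabilities (imitation, scaled by kappa); in
Social-Choice+Outcome the demonstrator's outcome updates the value of the
demonstrator-chosen option (vicarious learning, rate alpha_o) after the
participant's own update on trial t.
"""

import numpy as np
from numba import njit

#: probability floor applied inside the likelihood to avoid -inf
PROB_FLOOR = 1e-9

MODE_EVAL = 0
MODE_SIM = 1


@njit(cache=True)
def run_session(
    block_id,
    cond,
    p0,
    p1,
    dem_choice,
    dem_outcome,
    choices,
    outcomes,
    beta_p,
    alpha_p,
    beta_s,
    alpha_s,
    kappa,
    alpha_o,
    mode,
    u_choice,
    u_outcome,
    out_choice,
    out_outcome,
    out_logp,
):  # pragma: no cover - exercised via python wrappers
    n = block_id.shape[0]
    total = 0.0
    n_floored = 0
    q0 = 0.0
    q1 = 0.0
    pending_dem = -1  # demonstrator choice displayed on the previous trial
    for t in range(n):
        if t == 0 or block_id[t] != block_id[t - 1]:
            q0 = 0.0
            q1 = 0.0
            pending_dem = -1
        c_t = cond[t]
        if c_t == 0:
            beta = beta_p
            alpha = alpha_p
        else:
            beta = beta_s
            alpha = alpha_s
        pa = 1.0 / (1.0 + np.exp(-beta * (q0 - q1)))
        pb = 1.0 - pa
        if c_t == 1 and pending_dem >= 0:
            # imitation bias in probability space toward the last displayed
            # demonstrator choice; closed under [0, 1] for kappa in [0, 1]
            if pending_dem == 0:
                pa = pa + kappa * (1.0 - pa)
                pb = 1.0 - pa
            else:
                pb = pb + kappa * (1.0 - pb)
                pa = 1.0 - pb
        if mode == MODE_SIM:
            c = 0 if u_choice[t] < pa else 1
            pr = p0[t] if c == 0 else p1[t]
            r = 1.0 if u_outcome[t] < pr else -1.0
            out_choice[t] = c
            out_outcome[t] = r
        else:
            c = choices[t]
            r = outcomes[t]
        pc = pa if c == 0 else pb
        if pc < PROB_FLOOR:
            pc = PROB_FLOOR
            n_floored += 1
        lp = np.log(pc)
        out_logp[t] = lp
        total += lp
        # delta-rule update of the chosen option from the own outcome
        if c == 0:
            q0 = q0 + alpha * (r - q0)
        else:
            q1 = q1 + alpha * (r - q1)
        # vicarious update from the displayed demonstrator outcome
        if c_t == 2 and dem_choice[t] >= 0:
            if dem_choice[t] == 0:
                q0 = q0 + alpha_o * (dem_outcome[t] - q0)
            else:
                q1 = q1 + alpha_o * (dem_outcome[t] - q1)
        pending_dem = dem_choice[t] if c_t == 1 else -1
    return total, n_floored


@njit(cache=True)
def run_qlearner(
    block_id, p0, p1, beta, alpha, u_choice, u_outcome, out_choice, out_outcome
):  # pragma: no cover - exercised via python wrappers
    """Simulate a plain Q-learner playing every block from its own outcomes."""
    n = block_id.shape[0]
    q0 = 0.0
    q1 = 0.0
    for t in range(n):
        if t == 0 or block_id[t] != block_id[t - 1]:
            q0 = 0.0
            q1 = 0.0
        pa = 1.0 / (1.0 + np.exp(-beta * (q0 - q1)))
        c = 0 if u_choice[t] < pa else 1
        pr = p0[t] if c == 0 else p1[t]
        r = 1.0 if u_outcome[t] < pr else -1.0
        out_choice[t] = c
        out_outcome[t] = r
        if c == 0:
            q0 = q0 + alpha * (r - q0)
        else:
            q1 = q1 + alpha * (r - q1)
    return 0
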