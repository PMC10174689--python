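"""Straight-line scalar reference implementation of the session likelihood.

Written independently of the package's vectorized kernel: plain dictionaries
and python floats, one trial at a time, following the generative recipe
directly (decay everything but the observed pair, then the RL delta rule and
WM one-shot storage; test trials scored from the final Q of their source
block with no updates).
"""

import math


def softmax(values, beta):
    m = max(values)
    exps = [math.exp(beta * (v - m)) for v in values]
    z = sum(exps)
    return [e / z for e in exps]


def reference_trial_probs(records, params, n_actions=3):
    """Per-trial action-probability vectors, teacher-forced on the recorded
    actions (None for missed trials).  Same stepping rules as the likelihood."""
    q0 = 1.0 / n_actions
    Q = {}
    W = {}
    nu = params["alpha_neg"] / params["alpha_pos"]
    out = []
    for rec in records:
        if rec["missed"]:
            out.append(None)
            continue
        b, s = rec["block"], rec["stimulus"]
        a = int(rec["action"]) - 1
        if (b, s) not in Q:
            Q[(b, s)] = [q0] * n_actions
            W[(b, s)] = [q0] * n_actions
        eps = params["epsilon"]
        if rec["phase"] == "learn":
            omega = params["omega3"] if rec["set_size"] == 3 else params["omega6"]
            p_rl = softmax(Q[(b, s)], params["beta_learn"])
            p_wm = softmax(W[(b, s)], params["beta_learn"])
            p = [
                (1.0 - eps) * (omega * pw + (1.0 - omega) * pr) + eps / n_actions
                for pw, pr in zip(p_wm, p_rl)
            ]
            out.append(p)
            r = float(rec["reward"])
            for (bb, ss) in list(W):
                if bb != b:
                    continue
                for aj in range(n_actions):
                    if ss == s and aj == a:
                        continue
                    W[(bb, ss)][aj] += params["phi"] * (q0 - W[(bb, ss)][aj])
            delta = r - Q[(b, s)][a]
            rate = params["alpha_pos"] if delta > 0 else params["alpha_neg"]
            Q[(b, s)][a] += rate * delta
            dw = r - W[(b, s)][a]
            if dw > 0:
                W[(b, s)][a] = r
            else:
                W[(b, s)][a] += nu * dw
        else:
            p_rl = softmax(Q[(b, s)], params["beta_test"])
            out.append([(1.0 - eps) * pr + eps / n_actions for pr in p_rl])
    return out


def reference_session_loglik(records, params, n_actions=3):
    """records: list of dicts with keys phase, block, stimulus, action,
    reward, missed, set_size (1-based action).  params: dict with alpha_pos,
    alpha_neg, beta_learn, beta_test, epsilon, phi, omega3, omega6.
    Returns dict block -> pooled log-likelihood.
    """
    q0 = 1.0 / n_actions
    Q = {}
    W = {}
    nu = params["alpha_neg"] / params["alpha_pos"]
    pointwise = {}
    for rec in records:
        b = rec["block"]
        pointwise.setdefault(b, 0.0)
        if rec["missed"]:
            continue
        s = rec["stimulus"]
        a = int(rec["action"]) - 1
        if (b, s) not in Q:
            Q[(b, s)] = [q0] * n_actions
            W[(b, s)] = [q0] * n_actions
        if rec["phase"] == "learn":
            omega = params["omega3"] if rec["set_size"] == 3 else params["omega6"]
            p_rl = softmax(Q[(b, s)], params["beta_learn"])
            p_wm = softmax(W[(b, s)], params["beta_learn"])
            eps = params["epsilon"]
            p = [
                (1.0 - eps) * (omega * pw + (1.0 - omega) * pr) + eps / n_actions
                for pw, pr in zip(p_wm, p_rl)
            ]
            pointwise[b] += math.log(p[a])
            r = float(rec["reward"])
            # decay all of the block's W entries except the observed pair
            for (bb, ss) in list(W):
                if bb != b:
                    continue
                for aj in range(n_actions):
                    if ss == s and aj == a:
                        continue
                    W[(bb, ss)][aj] += params["phi"] * (q0 - W[(bb, ss)][aj])
            delta = r - Q[(b, s)][a]
            rate = params["alpha_pos"] if delta > 0 else params["alpha_neg"]
            Q[(b, s)][a] += rate * delta
            dw = r - W[(b, s)][a]
            if dw > 0:
                W[(b, s)][a] = r
            else:
                W[(b, s)][a] += nu * dw
        else:  # test: final Q of the source block, no updates
            p_rl = softmax(Q[(b, s)], params["beta_test"])
            eps = params["epsilon"]
            p = [(1.0 - eps) * pr + eps / n_actions for pr in p_rl]
            pointwise[b] += math.log(p[a])
    return pointwise
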