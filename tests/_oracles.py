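"""Shared explicit-loop oracle for the attention network forward pass.

Kept deliberately independent of the vectorized implementation: per-node
Python loops, scalar math, no shared helper code.
"""

import math

import numpy as np


def _leaky_scalar(v, slope=0.2):
    return v if v > 0 else slope * v


def oracle_forward(params, graph):
    """Recompute every layer with explicit loops; returns all intermediates."""
    m, n = graph.m, graph.n
    d = params.d_k
    out = {}
    for tag, W_sp, Wp, a in (
        ("sim", graph.W_sim, params.Wmat_sim, params.a_sim),
        ("co", graph.W_co, params.Wmat_co, params.a_co),
    ):
        W = W_sp.toarray()
        H = np.zeros((m, m))
        nbrs = []
        for x in range(m):
            nb = [y for y in range(m) if W[x, y] > 0]
            if not nb:  # isolated node: unit self-loop
                nb = [x]
                H[x, x] = 1.0
            else:
                total = sum(W[x, y] for y in nb)
                for i in range(m):
                    H[i, x] = W[i, x] / total
            nbrs.append(nb)
        E = np.zeros((m, d))
        alpha_rows = []
        for x in range(m):
            scores = []
            for y in nbrs[x]:
                concat = np.concatenate([Wp @ H[:, x], Wp @ H[:, y]])
                scores.append(_leaky_scalar(float(a @ concat)))
            mx = max(scores)
            exps = [math.exp(s - mx) for s in scores]
            alphas = [e / sum(exps) for e in exps]
            alpha_rows.append(dict(zip(nbrs[x], alphas)))
            acc = np.zeros(d)
            for al, y in zip(alphas, nbrs[x]):
                acc += al * (Wp @ H[:, y])
            E[x] = np.maximum(acc, 0.0)
        out[f"E_{tag}"] = E
        out[f"H_{tag}"] = H
        out[f"alpha_{tag}"] = alpha_rows
    X = graph.W_inclu.toarray()
    beta_sim = np.zeros((n, m))
    beta_co = np.zeros((n, m))
    E_seq = np.zeros((n, d))
    prob = np.zeros(n)
    for z in range(n):
        h = X[:, z] @ params.Wmat_inclu
        nbr = [x for x in range(m) if X[x, z] > 0]
        for tag, E, beta in (("sim", out["E_sim"], beta_sim), ("co", out["E_co"], beta_co)):
            scores = [_leaky_scalar(float(h @ E[x])) for x in nbr]
            mx = max(scores)
            exps = [math.exp(s - mx) for s in scores]
            for x, e in zip(nbr, exps):
                beta[z, x] = e / sum(exps)
        acc = np.zeros(d)
        for x in nbr:
            acc += beta_sim[z, x] * out["E_sim"][x] + beta_co[z, x] * out["E_co"][x]
        E_seq[z] = np.maximum(acc, 0.0)
        logit = float(params.clf_w @ E_seq[z] + params.clf_b)
        prob[z] = 1.0 / (1.0 + math.exp(-logit))
    out.update(beta_sim=beta_sim, beta_co=beta_co, E_seq=E_seq, prob=prob)
    return out
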