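"""Independent reference implementations used only by the tests.

The collapsed joint score is recomputed here by the *sequential predictive*
route: units are processed one at a time and each contributes the product
of its Dirichlet-multinomial / Beta-Bernoulli predictive probabilities
given the units before it, all in plain Python loops with no shared
sufficient statistics, prefix sums or gamma functions.  Agreement with the
package's closed-form scorer is a mathematical identity of conjugate
marginals, so any bookkeeping bug in either path breaks it.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_score(cache, orient, I, Z, widths, tau_pos, tau_neg, priors) -> float:
    """Collapsed log joint P(Z, I, orient, data) by sequential predictives."""
    a = priors.pwm_alpha
    a0, b0 = priors.bern_a, priors.bern_b
    delta = priors.gamma_delta
    ws = cache.window_width
    m = len(widths)

    # background of every copy of every unit
    total = 0.0
    for i in range(cache.n):
        seq = cache.seq[i]
        total += float(cache.seq_bg.position_logprobs(seq).sum())
        for vec, p in ((cache.bin_pos[i], cache.read_bg.p_pos),
                       (cache.bin_neg[i], cache.read_bg.p_neg)):
            for r in vec:
                total += math.log(p) if r else math.log(1 - p)

    # sequential predictives, replacing background at site/window positions
    pwm_counts = [[[0, 0, 0, 0] for _ in range(widths[k])] for k in range(m)]
    win_counts = {s: [[[0, 0] for _ in range(ws)] for _ in range(m)]
                  for s in ("+", "-")}
    n_k = [0] * m
    seen = 0
    for u in range(cache.n_units):
        k = int(I[u])
        z = int(Z[u])
        i = cache.units[u][int(orient[u])]
        w = int(widths[k])
        seq = cache.seq[i]
        bg_lp = cache.seq_bg.position_logprobs(seq)
        # membership predictive
        total += math.log((n_k[k] + delta) / (seen + m * delta))
        # motif predictive vs background
        for col in range(w):
            b = int(seq[z + col])
            assert b < 4, "oracle: site contains N"
            c = pwm_counts[k][col]
            total += math.log((c[b] + a) / (sum(c) + 4 * a))
            total -= float(bg_lp[z + col])
            c[b] += 1
        # window predictives vs background
        for strand, vec, tau, p_bg in (
            ("+", cache.bin_pos[i], int(tau_pos[k]), cache.read_bg.p_pos),
            ("-", cache.bin_neg[i], int(tau_neg[k]), cache.read_bg.p_neg),
        ):
            start = z + tau
            for col in range(ws):
                r = int(vec[start + col])
                c1, c0 = win_counts[strand][k][col]
                if r:
                    total += math.log((c1 + a0) / (c1 + c0 + a0 + b0))
                    total -= math.log(p_bg)
                    win_counts[strand][k][col][0] += 1
                else:
                    total += math.log((c0 + b0) / (c1 + c0 + a0 + b0))
                    total -= math.log(1 - p_bg)
                    win_counts[strand][k][col][1] += 1
        n_k[k] += 1
        seen += 1
    return total


def enumerate_unit_conditional(cache, state, priors, u):
    """Normalized conditional over (orientation, mode, Z) for unit u by
    exhaustively scoring every full configuration with ``oracle_score``."""
    from exomodes.sampler import valid_placements

    m = state.m
    widths = [int(w) for w in state.w]
    tp = [int(t) for t in state.tau_pos]
    tn = [int(t) for t in state.tau_neg]
    keys, scores = [], []
    for o, i in enumerate(cache.units[u]):
        for k in range(m):
            ok = valid_placements(cache, i, widths[k], tp[k], tn[k])
            for z in np.flatnonzero(ok):
                orient = state.orient.copy()
                I = state.I.copy()
                Z = state.Z.copy()
                orient[u], I[u], Z[u] = o, k, int(z)
                keys.append((o, k, int(z)))
                scores.append(
                    oracle_score(cache, orient, I, Z, widths, tp, tn, priors)
                )
    scores = np.array(scores)
    p = np.exp(scores - scores.max())
    p /= p.sum()
    return dict(zip(keys, p))


def enumerate_tau_conditional(cache, state, priors, k, strand):
    """Normalized conditional over the offset grid by full-config scoring."""
    from exomodes.sampler import tau_grid

    grid = tau_grid(int(state.w[k]), strand, cache.window_width,
                    state.max_offset)
    widths = [int(w) for w in state.w]
    probs = {}
    scores = []
    valid = []
    for tau in grid:
        tp = [int(t) for t in state.tau_pos]
        tn = [int(t) for t in state.tau_neg]
        if strand == "+":
            tp[k] = int(tau)
        else:
            tn[k] = int(tau)
        # reject candidates whose window leaves any member's region
        bad = False
        for u in np.flatnonzero(state.I == k):
            i = cache.units[u][int(state.orient[u])]
            p = int(state.Z[u]) + int(tau)
            if p < 0 or p + cache.window_width > cache.L[i]:
                bad = True
                break
        if bad:
            continue
        valid.append(int(tau))
        scores.append(oracle_score(cache, state.orient, state.I, state.Z,
                                   widths, tp, tn, priors))
    scores = np.array(scores)
    p = np.exp(scores - scores.max())
    p /= p.sum()
    return dict(zip(valid, p))


def brute_force_prediction(seq, bin_pos, bin_neg, fitted, component="full"):
    """Eq-by-eq enumeration of the prediction quantities for one datapoint.

    Returns (per-mode posterior, marginal log-likelihood), computed term by
    term with plain loops and absolute probabilities (no shared code with
    the package's vectorized scorer beyond the background models).
    """
    from exomodes.model import encode_sequence

    if isinstance(seq, str):
        seq = encode_sequence(seq)
    L = len(seq)
    ws = fitted.window_width
    bg_lp = fitted.seq_bg.position_logprobs(seq)
    joint = []  # per mode: list of log P(D, Z=j) over valid j
    for k, md in enumerate(fitted.modes):
        w = md.w
        terms = []
        valid_j = []
        for j in range(L - w + 1):
            site = seq[j : j + w]
            if (site >= 4).any():
                continue
            if not (0 <= j + md.tau_pos and j + md.tau_pos + ws <= L):
                continue
            if not (0 <= j + md.tau_neg and j + md.tau_neg + ws <= L):
                continue
            valid_j.append(j)
        for j in valid_j:
            lp = math.log(fitted.gamma[k]) - math.log(len(valid_j))
            if component in ("full", "seq"):
                for col in range(w):
                    lp += math.log(md.pwm[col][int(seq[j + col])])
                for pos in range(L):
                    if not (j <= pos < j + w):
                        lp += float(bg_lp[pos])
            if component in ("full", "reads"):
                for vec, tau, bern, p_bg in (
                    (bin_pos, md.tau_pos, md.bern_pos, fitted.read_bg.p_pos),
                    (bin_neg, md.tau_neg, md.bern_neg, fitted.read_bg.p_neg),
                ):
                    start = j + tau
                    for pos in range(L):
                        r = int(vec[pos])
                        if start <= pos < start + ws:
                            p = bern[pos - start]
                        else:
                            p = p_bg
                        lp += math.log(p) if r else math.log(1 - p)
            terms.append(lp)
        joint.append(terms)
    flat = np.array([t for terms in joint for t in terms])
    mx = flat.max()
    marginal = mx + math.log(np.exp(flat - mx).sum())
    per_mode = np.array([
        np.exp(np.array(t) - mx).sum() if t else 0.0 for t in joint
    ])
    posterior = per_mode / per_mode.sum()
    return posterior, float(marginal)
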