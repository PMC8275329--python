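"""Collapsed Gibbs sampling for the joint motif/footprint mixture.

The PWM columns, window Bernoullis and mixture weights are integrated out
under their conjugate Dirichlet/Beta priors; the sampler moves only
per-unit site assignments and per-mode structural variables (read-window
offsets tau and motif widths w).

A *sampling unit* is one original region together with its
reverse-complement copy: the unit jointly chooses an orientation (which
copy carries the site), a mode label I and a motif position Z, and the
other copy contributes background only.  Tying the pair this way is what
lets a motif on either genomic strand be captured by a single mode; were
the two copies sampled independently, every mode's mirror image would be
learnable structure of its own and the selected mode count would double.

Sufficient statistics (per-mode base counts, window one-counts,
memberships, and the background log-probability mass displaced by sites
and windows) are maintained incrementally, and every accepted move updates
the running collapsed posterior score by the exact difference of the
enumerated weights, so the state can be scored after every single-variable
update at O(1) cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

from .model import DataCache, FittedModel, ModeParameters, Priors

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass
class SamplerConfig:
    """Tunable sampler settings.

    ``window_width`` is the read-window size on each strand (5 bp default —
    exonuclease stops concentrate the 5' ends within a few bases).
    ``max_offset`` bounds how far a read window may sit beyond the motif
    edges.  The stopping rule halts a chain after ``stop_mult * n``
    consecutive single-variable updates without a new best score, where n
    is the number of sampling units (``max_sweeps`` is a hard safety cap).
    """

    window_width: int = 5
    init_width: int = 12
    w_min: int = 5
    w_max: int = 50
    max_offset: int = 25
    restarts: int = 3
    stop_mult: int = 5
    max_sweeps: int = 200


def tau_grid(w: int, strand: str, window_width: int, max_offset: int) -> np.ndarray:
    """Allowed window offsets for a motif of width ``w``.

    Positive-strand windows may start up to ``max_offset + window_width``
    bp upstream of the motif and anywhere inside it; negative-strand
    windows mirror this downstream.
    """
    if strand == "+":
        return np.arange(-max_offset - window_width, w)
    return np.arange(-window_width + 1, w + max_offset + 1)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Current sampler configuration with collapsed sufficient statistics.

    ``Z``, ``I`` and ``orient`` are per sampling unit; ``orient[u]``
    indexes the unit's copy tuple (0 = forward, 1 = reverse complement).
    """

    m: int
    Z: np.ndarray
    I: np.ndarray
    orient: np.ndarray
    w: np.ndarray                      # (m,) motif widths
    tau_pos: np.ndarray                # (m,)
    tau_neg: np.ndarray                # (m,)
    motif_counts: list[np.ndarray]     # per mode (w_k, 4)
    win_ones_pos: np.ndarray           # (m, window_width)
    win_ones_neg: np.ndarray
    n_k: np.ndarray                    # (m,) memberships
    site_bg_sum: np.ndarray            # (m,) sum of site background log-probs
    win_bg_sum_pos: np.ndarray         # (m,)
    win_bg_sum_neg: np.ndarray
    cur_score: float = NEG_INF
    max_offset: int = 25

    def copy(self) -> "ModelState":
        return ModelState(
            m=self.m,
            Z=self.Z.copy(),
            I=self.I.copy(),
            orient=self.orient.copy(),
            w=self.w.copy(),
            tau_pos=self.tau_pos.copy(),
            tau_neg=self.tau_neg.copy(),
            motif_counts=[c.copy() for c in self.motif_counts],
            win_ones_pos=self.win_ones_pos.copy(),
            win_ones_neg=self.win_ones_neg.copy(),
            n_k=self.n_k.copy(),
            site_bg_sum=self.site_bg_sum.copy(),
            win_bg_sum_pos=self.win_bg_sum_pos.copy(),
            win_bg_sum_neg=self.win_bg_sum_neg.copy(),
            cur_score=self.cur_score,
            max_offset=self.max_offset,
        )

    def active_copy(self, cache: DataCache, u: int) -> int:
        return cache.units[u][self.orient[u]]

    def active_copies(self, cache: DataCache, units: np.ndarray) -> np.ndarray:
        return np.array([cache.units[u][self.orient[u]] for u in units], dtype=int)


def valid_placements(cache: DataCache, i: int, w: int, tp: int, tn: int) -> np.ndarray:
    """Boolean mask over Z in [0, L-w] of placements (in copy i) where the
    motif is in-bounds and N-free and both read windows fit."""
    L = int(cache.L[i])
    n_z = L - w + 1
    if n_z <= 0:
        return np.zeros(0, dtype=bool)
    ws = cache.window_width
    z = np.arange(n_z)
    _, _, ok = cache.site_arrays(i, w)
    ok = ok.copy()
    for tau in (tp, tn):
        ok &= (z + tau >= 0) & (z + tau + ws <= L)
    return ok


def _recount(state: ModelState, cache: DataCache) -> dict:
    """Rebuild all sufficient statistics from (Z, I, orient, w, tau)."""
    m, ws = state.m, cache.window_width
    counts = [np.zeros((state.w[k], 4)) for k in range(m)]
    wop = np.zeros((m, ws))
    won = np.zeros((m, ws))
    n_k = np.zeros(m)
    sbg = np.zeros(m)
    wbp = np.zeros(m)
    wbn = np.zeros(m)
    for u in range(cache.n_units):
        k, Z = int(state.I[u]), int(state.Z[u])
        i = state.active_copy(cache, u)
        w = int(state.w[k])
        site = cache.seq[i][Z : Z + w]
        counts[k][np.arange(w), site] += 1
        n_k[k] += 1
        sbg[k] += cache.site_bg(i, Z, w)
        pp, pn = Z + int(state.tau_pos[k]), Z + int(state.tau_neg[k])
        wop[k] += cache.bin_pos[i][pp : pp + ws]
        won[k] += cache.bin_neg[i][pn : pn + ws]
        wbp[k] += cache.win_bg(i, pp, "+")
        wbn[k] += cache.win_bg(i, pn, "-")
    return {
        "motif_counts": counts,
        "win_ones_pos": wop,
        "win_ones_neg": won,
        "n_k": n_k,
        "site_bg_sum": sbg,
        "win_bg_sum_pos": wbp,
        "win_bg_sum_neg": wbn,
    }


def audit_counts(state: ModelState, cache: DataCache, atol: float = 1e-6) -> bool:
    """Check that incrementally maintained statistics match a fresh recount."""
    fresh = _recount(state, cache)
    ok = all(
        np.allclose(a, b, atol=atol)
        for a, b in zip(state.motif_counts, fresh["motif_counts"])
    )
    for name in ("win_ones_pos", "win_ones_neg", "n_k", "site_bg_sum",
                 "win_bg_sum_pos", "win_bg_sum_neg"):
        ok &= np.allclose(getattr(state, name), fresh[name], atol=atol)
    return bool(ok)


def init_state(
    cache: DataCache, m: int, config: SamplerConfig, rng: np.random.Generator
) -> ModelState:
    """Random initialization: uniform labels, orientations and placements.

    Windows start abutting the motif (tau+ = -window_width upstream,
    tau- = w downstream) as a neutral geometry.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    w0 = int(config.init_width)
    ws = config.window_width
    tp0, tn0 = -ws, w0
    n_units = cache.n_units
    Z = np.zeros(n_units, dtype=int)
    orient = np.zeros(n_units, dtype=int)
    I = rng.integers(0, m, size=n_units)
    for u in range(n_units):
        copies = cache.units[u]
        masks = [np.flatnonzero(valid_placements(cache, i, w0, tp0, tn0))
                 for i in copies]
        total = sum(len(ix) for ix in masks)
        if total == 0:
            rid = cache.dataset.regions[copies[0]].id
            raise ValueError(
                f"datapoint {rid} admits no valid motif placement at "
                f"init width {w0}"
            )
        pick = int(rng.integers(total))
        for o, ix in enumerate(masks):
            if pick < len(ix):
                orient[u], Z[u] = o, int(ix[pick])
                break
            pick -= len(ix)
    state = ModelState(
        m=m,
        Z=Z,
        I=I.astype(int),
        orient=orient,
        w=np.full(m, w0, dtype=int),
        tau_pos=np.full(m, tp0, dtype=int),
        tau_neg=np.full(m, tn0, dtype=int),
        motif_counts=[],
        win_ones_pos=np.zeros((m, ws)),
        win_ones_neg=np.zeros((m, ws)),
        n_k=np.zeros(m),
        site_bg_sum=np.zeros(m),
        win_bg_sum_pos=np.zeros(m),
        win_bg_sum_neg=np.zeros(m),
        max_offset=config.max_offset,
    )
    for name, val in _recount(state, cache).items():
        setattr(state, name, val)
    return state


# ---------------------------------------------------------------------------
# Collapsed predictive weights
# ---------------------------------------------------------------------------

def _apply_unit(
    state: ModelState, cache: DataCache, i: int, k: int, Z: int, sign: int
) -> None:
    """Add (+1) or remove (-1) the site contributions of copy i at (k, Z)."""
    w = int(state.w[k])
    ws = cache.window_width
    site = cache.seq[i][Z : Z + w]
    state.motif_counts[k][np.arange(w), site] += sign
    state.n_k[k] += sign
    state.site_bg_sum[k] += sign * cache.site_bg(i, Z, w)
    pp = Z + int(state.tau_pos[k])
    pn = Z + int(state.tau_neg[k])
    state.win_ones_pos[k] += sign * cache.bin_pos[i][pp : pp + ws]
    state.win_ones_neg[k] += sign * cache.bin_neg[i][pn : pn + ws]
    state.win_bg_sum_pos[k] += sign * cache.win_bg(i, pp, "+")
    state.win_bg_sum_neg[k] += sign * cache.win_bg(i, pn, "-")


def _mode_weight_array(
    state: ModelState, cache: DataCache, priors: Priors, i: int, k: int
) -> np.ndarray:
    """Collapsed predictive log-weight of placing a site of mode k at every
    Z of copy i, assuming the owning unit's contributions are currently
    removed from the counts.

    Entries at invalid placements are -inf.  Includes the membership
    predictive (n_k + delta)/(n_rest + m*delta), so the value at (k, Z) is
    exactly the log-ratio of collapsed joint scores with and without the
    site placed there.
    """
    w = int(state.w[k])
    L = int(cache.L[i])
    n_z = L - w + 1
    if n_z <= 0:
        return np.zeros(0)
    ws = cache.window_width
    a = priors.pwm_alpha
    a0, b0 = priors.bern_a, priors.bern_b
    n_k = state.n_k[k]

    sw, site_bg, n_free = cache.site_arrays(i, w)
    logpred = np.empty((w, 5))
    logpred[:, :4] = np.log(state.motif_counts[k] + a) - np.log(n_k + 4 * a)
    logpred[:, 4] = NEG_INF
    fg = np.take_along_axis(logpred, sw.astype(np.intp).T, axis=1).sum(axis=0)
    weight = fg - site_bg
    weight[~n_free] = NEG_INF

    occ_norm = np.log(n_k + a0 + b0)
    for ones, rw, win_bg, tau in (
        (state.win_ones_pos[k], cache.rw_pos[i], cache.win_bg_pos[i],
         int(state.tau_pos[k])),
        (state.win_ones_neg[k], cache.rw_neg[i], cache.win_bg_neg[i],
         int(state.tau_neg[k])),
    ):
        logq1 = np.log(ones + a0) - occ_norm
        logq0 = np.log(n_k - ones + b0) - occ_norm
        win_term = logq0.sum() + rw @ (logq1 - logq0) - win_bg
        lo = max(0, -tau)
        hi = min(n_z, L - ws - tau + 1)
        if lo > 0 or hi < n_z:
            contr = np.full(n_z, NEG_INF)
            if hi > lo:
                contr[lo:hi] = win_term[lo + tau : hi + tau]
            weight = weight + contr
        else:
            weight = weight + win_term[tau : tau + n_z]

    delta = priors.gamma_delta
    weight += np.log(n_k + delta) - np.log(state.n_k.sum() + state.m * delta)
    return weight


def collapsed_weight(
    i: int, k: int, Z: int, state: ModelState, cache: DataCache, priors: Priors
) -> float:
    """Scalar collapsed predictive log-weight of copy i's site at (k, Z)
    (the owning unit's contributions must already be removed)."""
    arr = _mode_weight_array(state, cache, priors, i, k)
    if Z < 0 or Z >= len(arr):
        return NEG_INF
    return float(arr[Z])


def unit_conditional(
    u: int, state: ModelState, cache: DataCache, priors: Priors
) -> dict[tuple[int, int], np.ndarray]:
    """Normalized joint conditional over (orientation, mode, Z) for unit u.

    Removes and restores the unit; keys are (orientation index, mode) and
    values probability arrays over Z, summing to 1 overall.
    """
    ci = state.active_copy(cache, u)
    _apply_unit(state, cache, ci, int(state.I[u]), int(state.Z[u]), -1)
    arrays = {
        (o, k): _mode_weight_array(state, cache, priors, i, k)
        for o, i in enumerate(cache.units[u])
        for k in range(state.m)
    }
    _apply_unit(state, cache, ci, int(state.I[u]), int(state.Z[u]), +1)
    flat = np.concatenate(list(arrays.values()))
    lognorm = logsumexp(flat)
    return {key: np.exp(arr - lognorm) for key, arr in arrays.items()}


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

def sample_ZI(
    u: int,
    state: ModelState,
    cache: DataCache,
    priors: Priors,
    rng: np.random.Generator,
    greedy: bool = False,
) -> float:
    """Jointly resample (orientation, I, Z) for unit u; returns score delta."""
    k_old, z_old, o_old = int(state.I[u]), int(state.Z[u]), int(state.orient[u])
    ci_old = state.active_copy(cache, u)
    _apply_unit(state, cache, ci_old, k_old, z_old, -1)
    copies = cache.units[u]
    arrays = []
    keys = []
    for o, i in enumerate(copies):
        for k in range(state.m):
            arrays.append(_mode_weight_array(state, cache, priors, i, k))
            keys.append((o, k))
    flat = np.concatenate(arrays)
    offsets = np.cumsum([0] + [len(a) for a in arrays])
    old_slot = keys.index((o_old, k_old))
    w_old = arrays[old_slot][z_old]
    if greedy:
        idx = int(np.argmax(flat))
        if flat[idx] <= w_old + 1e-12:
            idx = int(offsets[old_slot] + z_old)
    else:
        p = np.exp(flat - flat.max())
        cum = np.cumsum(p)
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        idx = min(idx, len(flat) - 1)
    slot = int(np.searchsorted(offsets, idx, side="right") - 1)
    o_new, k_new = keys[slot]
    z_new = int(idx - offsets[slot])
    _apply_unit(state, cache, copies[o_new], k_new, z_new, +1)
    state.I[u], state.Z[u], state.orient[u] = k_new, z_new, o_new
    delta = float(flat[idx] - w_old)
    state.cur_score += delta
    return delta


def _tau_weights(
    k: int, strand: str, state: ModelState, cache: DataCache, priors: Priors
) -> tuple[np.ndarray, np.ndarray, list]:
    """Collapsed log-weight of each candidate offset for mode k.

    All mode-k windows move together; a candidate is invalid when any
    member's window would leave its region.  Returns (grid, weights,
    per-candidate (ones, bg_sum) stats for applying a move).
    """
    ws = cache.window_width
    a0, b0 = priors.bern_a, priors.bern_b
    grid = tau_grid(int(state.w[k]), strand, ws, state.max_offset)
    members = np.flatnonzero(state.I == k)
    cis = state.active_copies(cache, members)
    zm = state.Z[members]
    lm = cache.L[cis] if len(cis) else np.zeros(0, dtype=int)
    rs = cache.bin_pos if strand == "+" else cache.bin_neg
    cums = cache.read_bg_cum_pos if strand == "+" else cache.read_bg_cum_neg
    n_k = len(members)
    weights = np.full(len(grid), NEG_INF)
    stats: list = [None] * len(grid)
    const = -ws * betaln(a0, b0)
    for t_idx, tau in enumerate(grid):
        p = zm + tau
        if n_k and ((p < 0).any() or (p + ws > lm).any()):
            continue
        ones = np.zeros(ws)
        bg = 0.0
        for j, mi in enumerate(cis):
            ones += rs[mi][p[j] : p[j] + ws]
            c = cums[mi]
            bg += c[p[j] + ws] - c[p[j]]
        weights[t_idx] = betaln(ones + a0, n_k - ones + b0).sum() + const - bg
        stats[t_idx] = (ones, bg)
    return grid, weights, stats


def sample_tau(
    k: int,
    strand: str,
    state: ModelState,
    cache: DataCache,
    priors: Priors,
    rng: np.random.Generator,
    greedy: bool = False,
) -> float:
    """Resample the strand-s window offset of mode k; returns score delta."""
    grid, weights, stats = _tau_weights(k, strand, state, cache, priors)
    cur_tau = int(state.tau_pos[k] if strand == "+" else state.tau_neg[k])
    cur_idx = int(np.searchsorted(grid, cur_tau))
    if (cur_idx >= len(grid) or grid[cur_idx] != cur_tau
            or not np.isfinite(weights[cur_idx])):
        logger.warning("current tau not on the candidate grid; move skipped")
        return 0.0
    if greedy:
        idx = int(np.argmax(weights))
        if weights[idx] <= weights[cur_idx] + 1e-12:
            idx = cur_idx
    else:
        p = np.exp(weights - weights[np.isfinite(weights)].max())
        cum = np.cumsum(p)
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        idx = min(idx, len(grid) - 1)
    delta = float(weights[idx] - weights[cur_idx])
    ones, bg = stats[idx]
    if strand == "+":
        state.tau_pos[k] = int(grid[idx])
        state.win_ones_pos[k] = ones
        state.win_bg_sum_pos[k] = bg
    else:
        state.tau_neg[k] = int(grid[idx])
        state.win_ones_neg[k] = ones
        state.win_bg_sum_neg[k] = bg
    state.cur_score += delta
    return delta


# width moves: (name, dw, dZ, dtau); left-edge moves shift Z and compensate
# tau so the read windows keep their absolute positions
_WIDTH_MOVES = (
    ("stay", 0, 0, 0),
    ("extend_left", +1, -1, +1),
    ("extend_right", +1, 0, 0),
    ("shrink_left", -1, +1, -1),
    ("shrink_right", -1, 0, 0),
)


def _width_weights(
    k: int,
    state: ModelState,
    cache: DataCache,
    priors: Priors,
    w_min: int,
    w_max: int,
) -> tuple[np.ndarray, list]:
    a = priors.pwm_alpha
    ws = cache.window_width
    members = np.flatnonzero(state.I == k)
    cis = state.active_copies(cache, members)
    n_k = len(members)
    w_cur = int(state.w[k])
    weights = np.full(len(_WIDTH_MOVES), NEG_INF)
    stats: list = [None] * len(_WIDTH_MOVES)
    for c_idx, (_, dw, dz, dt) in enumerate(_WIDTH_MOVES):
        w_new = w_cur + dw
        if not (w_min <= w_new <= w_max):
            continue
        tp_new = int(state.tau_pos[k]) + dt
        tn_new = int(state.tau_neg[k]) + dt
        gp = tau_grid(w_new, "+", ws, state.max_offset)
        gn = tau_grid(w_new, "-", ws, state.max_offset)
        if tp_new < gp[0] or tp_new > gp[-1] or tn_new < gn[0] or tn_new > gn[-1]:
            continue
        counts = np.zeros((w_new, 4))
        sbg = 0.0
        valid = True
        for j, mi in enumerate(cis):
            z_new = int(state.Z[members[j]]) + dz
            if z_new < 0 or z_new + w_new > cache.L[mi]:
                valid = False
                break
            if cache.site_has_n(mi, z_new, w_new):
                valid = False
                break
            site = cache.seq[mi][z_new : z_new + w_new]
            counts[np.arange(w_new), site] += 1
            sbg += cache.site_bg(mi, z_new, w_new)
        if not valid:
            continue
        log_dm = (
            gammaln(counts + a).sum()
            - 4 * w_new * gammaln(a)
            + w_new * gammaln(4 * a)
            - w_new * gammaln(n_k + 4 * a)
        )
        weights[c_idx] = log_dm - sbg
        stats[c_idx] = (w_new, dz, dt, counts, sbg)
    return weights, stats


def sample_width(
    k: int,
    state: ModelState,
    cache: DataCache,
    priors: Priors,
    rng: np.random.Generator,
    w_min: int = 5,
    w_max: int = 50,
    greedy: bool = False,
) -> float:
    """Propose +-1 bp edge moves of mode k's motif width; returns delta."""
    weights, stats = _width_weights(k, state, cache, priors, w_min, w_max)
    if greedy:
        idx = int(np.argmax(weights))
        if weights[idx] <= weights[0] + 1e-12:
            idx = 0
    else:
        p = np.exp(weights - weights[np.isfinite(weights)].max())
        cum = np.cumsum(p)
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        idx = min(idx, len(weights) - 1)
    delta = float(weights[idx] - weights[0])
    if idx != 0:
        w_new, dz, dt, counts, sbg = stats[idx]
        members = np.flatnonzero(state.I == k)
        state.Z[members] += dz
        state.w[k] = w_new
        state.tau_pos[k] += dt
        state.tau_neg[k] += dt
        state.motif_counts[k] = counts
        state.site_bg_sum[k] = sbg
    state.cur_score += delta
    return delta


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_state(state: ModelState, cache: DataCache, priors: Priors) -> float:
    """Exact log of the collapsed joint P(Z, I, tau, w, data | priors).

    Dirichlet-multinomial marginals for the PWM columns and mixture
    weights, Beta-Bernoulli marginals for the window positions, and the
    background over every position not covered by a site or window.
    """
    a = priors.pwm_alpha
    a0, b0 = priors.bern_a, priors.bern_b
    delta = priors.gamma_delta
    ws = cache.window_width
    score = cache.total_bg
    for k in range(state.m):
        w = int(state.w[k])
        c = state.motif_counts[k]
        n_k = state.n_k[k]
        score += (
            gammaln(c + a).sum()
            - 4 * w * gammaln(a)
            + w * gammaln(4 * a)
            - w * gammaln(n_k + 4 * a)
        )
        score -= state.site_bg_sum[k]
        for ones, bg_sum in (
            (state.win_ones_pos[k], state.win_bg_sum_pos[k]),
            (state.win_ones_neg[k], state.win_bg_sum_neg[k]),
        ):
            score += betaln(ones + a0, n_k - ones + b0).sum() - ws * betaln(a0, b0)
            score -= bg_sum
    n = state.n_k.sum()
    score += (
        gammaln(state.m * delta)
        - gammaln(n + state.m * delta)
        + gammaln(state.n_k + delta).sum()
        - state.m * gammaln(delta)
    )
    return float(score)


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------

def run_chain(
    cache: DataCache,
    m: int,
    priors: Priors,
    config: SamplerConfig,
    seed: int,
) -> tuple[ModelState, np.ndarray]:
    """Run one chain to the stopping rule; returns (best state, score trace).

    Each sweep resamples every unit's (orientation, I, Z), then every
    mode's two window offsets, then every mode's width.  The state is
    scored after every single-variable update; the chain stops once
    ``stop_mult * n`` consecutive updates fail to improve the best score.
    """
    rng = np.random.default_rng(seed)
    state = init_state(cache, m, config, rng)
    state.cur_score = score_state(state, cache, priors)
    n = cache.n_units
    stop_after = config.stop_mult * n
    best_score = state.cur_score
    best_state = state.copy()
    since_improve = 0
    trace = [state.cur_score]

    def record() -> bool:
        nonlocal best_score, best_state, since_improve
        trace.append(state.cur_score)
        if state.cur_score > best_score + 1e-9:
            best_score = state.cur_score
            best_state = state.copy()
            since_improve = 0
        else:
            since_improve += 1
        return since_improve >= stop_after

    done = False
    for _sweep in range(config.max_sweeps):
        for u in range(n):
            sample_ZI(u, state, cache, priors, rng)
            if record():
                done = True
                break
        if not done:
            for k in range(m):
                for strand in ("+", "-"):
                    sample_tau(k, strand, state, cache, priors, rng)
                    if record():
                        done = True
                        break
                if done:
                    break
        if not done:
            for k in range(m):
                sample_width(k, state, cache, priors, rng,
                             config.w_min, config.w_max)
                if record():
                    done = True
                    break
        # resync the running score against float drift once per sweep
        state.cur_score = score_state(state, cache, priors)
        if done:
            break
    return best_state, np.asarray(trace)


def hill_climb(
    state: ModelState,
    cache: DataCache,
    priors: Priors,
    config: SamplerConfig | None = None,
) -> ModelState:
    """Greedy coordinate ascent from a sampled state to a local MAP.

    Each pass sets every (orientation, Z, I) jointly, every offset, and
    every width move to its conditional argmax; stops at a pass with no
    change.  The returned score never falls below the input score.
    """
    config = config or SamplerConfig()
    state = state.copy()
    state.cur_score = score_state(state, cache, priors)
    rng = np.random.default_rng(0)  # unused in greedy mode
    for _ in range(1000):
        before = state.cur_score
        moved = False
        for u in range(cache.n_units):
            if abs(sample_ZI(u, state, cache, priors, rng, greedy=True)) > 1e-12:
                moved = True
        for k in range(state.m):
            for strand in ("+", "-"):
                if abs(sample_tau(k, strand, state, cache, priors, rng,
                                  greedy=True)) > 1e-12:
                    moved = True
            if abs(sample_width(k, state, cache, priors, rng, config.w_min,
                                config.w_max, greedy=True)) > 1e-12:
                moved = True
        if not moved or state.cur_score <= before + 1e-9:
            break
    state.cur_score = score_state(state, cache, priors)
    return state


def estimate_parameters(
    state: ModelState, cache: DataCache, priors: Priors
) -> FittedModel:
    """Posterior-mean point estimates at the (hill-climbed) state."""
    a = priors.pwm_alpha
    a0, b0 = priors.bern_a, priors.bern_b
    delta = priors.gamma_delta
    modes = []
    n = state.n_k.sum()
    for k in range(state.m):
        n_k = state.n_k[k]
        if n_k == 0:
            logger.warning("mode %d is empty; prior-predictive parameters "
                           "reported", k)
        pwm = (state.motif_counts[k] + a) / (n_k + 4 * a)
        modes.append(
            ModeParameters(
                w=int(state.w[k]),
                pwm=pwm,
                bern_pos=(state.win_ones_pos[k] + a0) / (n_k + a0 + b0),
                bern_neg=(state.win_ones_neg[k] + a0) / (n_k + a0 + b0),
                tau_pos=int(state.tau_pos[k]),
                tau_neg=int(state.tau_neg[k]),
            )
        )
    gamma = (state.n_k + delta) / (n + state.m * delta)
    return FittedModel(
        modes=modes,
        gamma=gamma,
        seq_bg=cache.seq_bg,
        read_bg=cache.read_bg,
        priors=priors,
        log_posterior=score_state(state, cache, priors),
        n_datapoints=cache.n,
        window_width=cache.window_width,
    )
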