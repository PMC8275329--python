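"""Applying a fitted model to data: mode posteriors, confusion matrices,
marginal likelihoods and two-model log-odds classification.

A datapoint is scored by marginalizing the motif position over all valid
placements with a uniform positional prior (restricted to placements where
the motif and both read windows fit, so the prior is proper).  Posteriors
can use the full joint, the sequence factors only, or the read factors
only; the ignored factors are dropped entirely, so each restricted
posterior is invariant to the data it ignores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

from .model import FittedModel, encode_sequence
from .regions import Dataset

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")

COMPONENTS = ("full", "seq", "reads")


@dataclass
class ModePosterior:
    probs: np.ndarray
    argmax_mode: int       # 0-based
    argmax_Z: int
    component: str
    orientation: str = "+"


def _mode_logterms(
    seq: np.ndarray,
    bin_pos: np.ndarray,
    bin_neg: np.ndarray,
    fitted: FittedModel,
    component: str,
) -> list[np.ndarray]:
    """Unnormalized per-(mode, Z) log joint ratios: log gamma_k - log V_k +
    the selected component log-likelihood ratios.  Invalid placements are
    -inf; V_k counts valid placements (the uniform positional prior)."""
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    L = len(seq)
    ws = fitted.window_width
    bg = fitted.seq_bg
    bg_lp = bg.position_logprobs(seq)
    bg_cum = np.concatenate(([0.0], np.cumsum(bg_lp)))
    n_cum = np.concatenate(([0], np.cumsum(seq >= 4)))
    read_terms = {}
    for strand, r, p_bg in (("+", bin_pos, fitted.read_bg.p_pos),
                            ("-", bin_neg, fitted.read_bg.p_neg)):
        r = np.asarray(r, dtype=float)
        lp1, lp0 = np.log(p_bg), np.log1p(-p_bg)
        bg_r = np.concatenate(([0.0], np.cumsum(r * lp1 + (1 - r) * lp0)))
        read_terms[strand] = (r, bg_r)

    out = []
    min_span = min(md.w for md in fitted.modes)
    if L < min_span:
        raise ValueError("datapoint shorter than the smallest motif")
    for k, md in enumerate(fitted.modes):
        w = md.w
        n_z = L - w + 1
        if n_z <= 0:
            out.append(np.zeros(0))
            continue
        z = np.arange(n_z)
        valid = (n_cum[w:] - n_cum[:n_z]) == 0
        for tau in (md.tau_pos, md.tau_neg):
            valid &= (z + tau >= 0) & (z + tau + ws <= L)
        terms = np.zeros(n_z)
        if component in ("full", "seq"):
            with np.errstate(divide="ignore"):
                lpwm = np.log(md.pwm)
            sw = sliding_window_view(np.minimum(seq, 3), w)
            fg = lpwm[np.arange(w)[None, :], sw].sum(axis=1)
            terms = terms + fg - (bg_cum[w:] - bg_cum[:n_z])
        if component in ("full", "reads"):
            for strand, tau, bern in (("+", md.tau_pos, md.bern_pos),
                                      ("-", md.tau_neg, md.bern_neg)):
                r, bg_r = read_terms[strand]
                lq1 = np.log(bern)
                lq0 = np.log1p(-bern)
                rw = sliding_window_view(r, ws)
                win = lq0.sum() + rw @ (lq1 - lq0)
                p = z + tau
                ok = (p >= 0) & (p <= L - ws)
                contrib = np.full(n_z, 0.0)
                contrib[ok] = win[p[ok]] - (bg_r[p[ok] + ws] - bg_r[p[ok]])
                terms = terms + contrib
        terms[~valid] = NEG_INF
        v = int(valid.sum())
        if v == 0:
            out.append(np.full(n_z, NEG_INF))
            continue
        with np.errstate(divide="ignore"):
            terms = terms + np.log(fitted.gamma[k]) - np.log(v)
        out.append(terms)
    return out


def _bg_const(seq, bin_pos, bin_neg, fitted: FittedModel, component: str) -> float:
    """Background log-likelihood of the factors the component retains."""
    total = 0.0
    if component in ("full", "seq"):
        total += fitted.seq_bg.position_logprobs(seq).sum()
    if component in ("full", "reads"):
        for r, p in ((np.asarray(bin_pos, float), fitted.read_bg.p_pos),
                     (np.asarray(bin_neg, float), fitted.read_bg.p_neg)):
            total += (r * np.log(p) + (1 - r) * np.log1p(-p)).sum()
    return float(total)


def mode_posterior(
    seq,
    bin_pos,
    bin_neg,
    fitted: FittedModel,
    component: str = "full",
) -> ModePosterior:
    """Posterior over modes for one datapoint, motif position marginalized."""
    if isinstance(seq, str):
        seq = encode_sequence(seq)
    terms = _mode_logterms(seq, bin_pos, bin_neg, fitted, component)
    per_mode = np.array([
        logsumexp(t) if t.size and np.isfinite(t).any() else NEG_INF
        for t in terms
    ])
    norm = logsumexp(per_mode)
    if not np.isfinite(norm):
        raise ValueError("datapoint admits no valid placement under any mode")
    probs = np.exp(per_mode - norm)
    k = int(np.argmax(per_mode))
    z = int(np.argmax(terms[k]))
    return ModePosterior(probs=probs, argmax_mode=k, argmax_Z=z, component=component)


def marginal_loglik(
    seq, bin_pos, bin_neg, fitted: FittedModel, component: str = "full"
) -> float:
    """log P(D | model): mixture- and position-marginalized likelihood."""
    if isinstance(seq, str):
        seq = encode_sequence(seq)
    terms = _mode_logterms(seq, bin_pos, bin_neg, fitted, component)
    flat = np.concatenate([t for t in terms if t.size])
    return float(logsumexp(flat) + _bg_const(seq, bin_pos, bin_neg, fitted, component))


def log_odds(
    seq, bin_pos, bin_neg, fitted_a: FittedModel, fitted_b: FittedModel,
    component: str = "full",
) -> float:
    """S(D) = log P(D|model a) - log P(D|model b); positive favors a."""
    if fitted_a.window_width != fitted_b.window_width:
        raise ValueError("models were fitted with different read-window widths")
    return marginal_loglik(seq, bin_pos, bin_neg, fitted_a, component) - \
        marginal_loglik(seq, bin_pos, bin_neg, fitted_b, component)


def confusion_matrix(
    dataset: Dataset,
    assigned: np.ndarray,
    fitted: FittedModel,
    component: str = "full",
) -> np.ndarray:
    """Entry (u, v): mean posterior probability of mode v among datapoints
    assigned to mode u (labels 0-based)."""
    m = fitted.m
    out = np.full((m, m), np.nan)
    assigned = np.asarray(assigned)
    post = np.zeros((len(dataset), m))
    for i, (reg, trk) in enumerate(zip(dataset.regions, dataset.tracks)):
        post[i] = mode_posterior(
            reg.sequence, trk.binary_pos, trk.binary_neg, fitted, component
        ).probs
    for u in range(m):
        sel = assigned == u
        if not sel.any():
            logger.warning("no datapoints assigned to mode %d; NaN row", u)
            continue
        out[u] = post[sel].mean(axis=0)
    return out


def resolve_orientation(
    fwd: tuple, rc: tuple, fitted: FittedModel, component: str = "full"
) -> tuple[str, float, float]:
    """Choose the orientation copy with the larger marginal likelihood.

    ``fwd``/``rc`` are (seq, bin_pos, bin_neg) triples; returns
    (orientation, loglik_fwd, loglik_rc) with exact ties resolved forward.
    """
    lf = marginal_loglik(*fwd, fitted, component)
    lr = marginal_loglik(*rc, fitted, component)
    if lr > lf:
        return "-", lf, lr
    if lr == lf:
        logger.info("orientation tie; forward reported")
    return "+", lf, lr


def assign_regions(
    dataset: Dataset, fitted: FittedModel, component: str = "full"
) -> pd.DataFrame:
    """One call per original region: orientation, MAP mode, motif site.

    On an augmented dataset the first ``n_original`` entries are the
    forward copies and entry ``n_original + i`` is the reverse complement
    of entry ``i``; an unaugmented dataset is scored forward-only.
    """
    n0 = dataset.n_original
    rows = []
    for i in range(n0):
        reg, trk = dataset.regions[i], dataset.tracks[i]
        fwd = (reg.sequence, trk.binary_pos, trk.binary_neg)
        if dataset.augmented:
            reg_rc, trk_rc = dataset.regions[n0 + i], dataset.tracks[n0 + i]
            rc = (reg_rc.sequence, trk_rc.binary_pos, trk_rc.binary_neg)
            orient, lf, lr = resolve_orientation(fwd, rc, fitted, component)
        else:
            orient, lf, lr = "+", marginal_loglik(*fwd, fitted, component), np.nan
        use_reg, use_trk = (reg, trk) if orient == "+" else (reg_rc, trk_rc)
        mp = mode_posterior(
            use_reg.sequence, use_trk.binary_pos, use_trk.binary_neg,
            fitted, component,
        )
        w = fitted.modes[mp.argmax_mode].w
        g_start, g_end, strand = use_reg.local_to_genomic(mp.argmax_Z, w)
        rows.append({
            "region_id": reg.id,
            "chrom": reg.chrom,
            "mode": mp.argmax_mode + 1,
            "posterior": float(mp.probs[mp.argmax_mode]),
            "site_start": g_start,
            "site_end": g_end,
            "strand": strand,
            "orientation": orient,
            "loglik": lf if orient == "+" else lr,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluation utilities
# ---------------------------------------------------------------------------

def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    sp = np.asarray(scores_pos, float)
    sn = np.asarray(scores_neg, float)
    diff = sp[:, None] - sn[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def match_labels(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Relabel predicted modes to maximize agreement with true labels
    (Hungarian assignment on the contingency table)."""
    from scipy.optimize import linear_sum_assignment

    pred = np.asarray(pred)
    truth = np.asarray(truth)
    p_labels = np.unique(pred)
    t_labels = np.unique(truth)
    size = max(len(p_labels), len(t_labels))
    cont = np.zeros((size, size))
    for pi, p in enumerate(p_labels):
        for ti, t in enumerate(t_labels):
            cont[pi, ti] = np.sum((pred == p) & (truth == t))
    ri, ci = linear_sum_assignment(-cont)
    mapping = {p_labels[r]: (t_labels[c] if c < len(t_labels) else -1)
               for r, c in zip(ri, ci) if r < len(p_labels)}
    return np.array([mapping[p] for p in pred])


def label_agreement(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction agreeing after optimal mode-to-truth matching."""
    return float(np.mean(match_labels(pred, truth) == np.asarray(truth)))
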