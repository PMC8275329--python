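"""The joint sequence/footprint mixture model.

A binding mode couples a PWM over {A,C,G,T} with two short Bernoulli "read
windows" — one per strand — placed at fixed signed offsets from the motif
start.  Everything outside a motif site is explained by a 2nd-order Markov
sequence background; everything outside a read window by a per-strand
0th-order Bernoulli background.  All likelihoods are computed in log space
as ratios against the background, which makes them invariant to the flanks
(the proportional forms of the model equations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_INDEX = 4  # sentinel for N / masked bases


class InvalidPlacementError(ValueError):
    """Raised when a motif site or read window cannot be placed."""


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string over {A,C,G,T,N} to int8 codes (N -> 4)."""
    return np.array([BASE_INDEX.get(b, N_INDEX) for b in seq], dtype=np.int8)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class Priors:
    """Conjugate prior hyperparameters.

    Jeffreys-style 0.5 pseudocounts for PWM columns (symmetric Dirichlet)
    and window Bernoullis (Beta), and a symmetric Dirichlet(1) over mixture
    weights — non-informative defaults.
    """

    pwm_alpha: float = 0.5
    bern_a: float = 0.5
    bern_b: float = 0.5
    gamma_delta: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pwm_alpha, self.bern_a, self.bern_b, self.gamma_delta) <= 0:
            raise ValueError("prior pseudocounts must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "pwm_alpha": self.pwm_alpha,
            "bern_a": self.bern_a,
            "bern_b": self.bern_b,
            "gamma_delta": self.gamma_delta,
        }


# ---------------------------------------------------------------------------
# Backgrounds
# ---------------------------------------------------------------------------

class BackgroundSequenceModel:
    """2nd-order Markov background fitted on the augmented sequence set.

    Add-one smoothing throughout; lower-order fallbacks handle the first two
    positions of each sequence and contexts interrupted by N.  N itself is
    emitted with probability 1/4 (missing data treated as uninformative).
    """

    def __init__(self, logp2: np.ndarray, logp1: np.ndarray, logp0: np.ndarray):
        self.logp2 = logp2  # (4, 4, 4): P(b | b_{-2}, b_{-1})
        self.logp1 = logp1  # (4, 4):    P(b | b_{-1})
        self.logp0 = logp0  # (4,)

    @classmethod
    def fit(cls, seqs: list[np.ndarray]) -> "BackgroundSequenceModel":
        if not seqs:
            raise ValueError("cannot fit a background on an empty dataset")
        c2 = np.ones((4, 4, 4))
        c1 = np.ones((4, 4))
        c0 = np.ones(4)
        for s in seqs:
            valid = s < 4
            c0 += np.bincount(s[valid], minlength=4)[:4]
            if len(s) >= 2:
                a, b = s[:-1], s[1:]
                m = (a < 4) & (b < 4)
                np.add.at(c1, (a[m], b[m]), 1)
            if len(s) >= 3:
                a, b, c = s[:-2], s[1:-1], s[2:]
                m = (a < 4) & (b < 4) & (c < 4)
                np.add.at(c2, (a[m], b[m], c[m]), 1)
        return cls(
            np.log(c2 / c2.sum(axis=2, keepdims=True)),
            np.log(c1 / c1.sum(axis=1, keepdims=True)),
            np.log(c0 / c0.sum()),
        )

    def position_logprobs(self, seq: np.ndarray) -> np.ndarray:
        """Per-position log background probability under the chain.

        Position j is conditioned on the longest available non-N context of
        up to two preceding bases; N positions contribute log(1/4).
        """
        L = len(seq)
        out = np.empty(L)
        log_quarter = np.log(0.25)
        for j in range(L):
            b = seq[j]
            if b >= 4:
                out[j] = log_quarter
                continue
            p1 = seq[j - 1] if j >= 1 else N_INDEX
            p2 = seq[j - 2] if j >= 2 else N_INDEX
            if p1 < 4 and p2 < 4:
                out[j] = self.logp2[p2, p1, b]
            elif p1 < 4:
                out[j] = self.logp1[p1, b]
            else:
                out[j] = self.logp0[b]
        return out

    def to_dict(self) -> dict:
        return {
            "order": 2,
            "logp2": self.logp2.tolist(),
            "logp1": self.logp1.tolist(),
            "logp0": self.logp0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundSequenceModel":
        return cls(np.array(d["logp2"]), np.array(d["logp1"]), np.array(d["logp0"]))


class BackgroundReadModel:
    """0th-order per-strand Bernoulli background for the binarized reads."""

    def __init__(self, p_pos: float, p_neg: float):
        if not (0 < p_pos < 1 and 0 < p_neg < 1):
            raise ValueError("background read probabilities must lie in (0, 1)")
        self.p_pos = float(p_pos)
        self.p_neg = float(p_neg)

    @classmethod
    def fit(cls, bin_pos: list[np.ndarray], bin_neg: list[np.ndarray]) -> "BackgroundReadModel":
        if not bin_pos:
            raise ValueError("cannot fit a background on an empty dataset")
        ones_p = sum(int(v.sum()) for v in bin_pos)
        tot_p = sum(len(v) for v in bin_pos)
        ones_n = sum(int(v.sum()) for v in bin_neg)
        tot_n = sum(len(v) for v in bin_neg)
        return cls((ones_p + 1) / (tot_p + 2), (ones_n + 1) / (tot_n + 2))

    def to_dict(self) -> dict:
        return {"p_pos": self.p_pos, "p_neg": self.p_neg}

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundReadModel":
        return cls(d["p_pos"], d["p_neg"])


def fit_backgrounds(dataset) -> tuple[BackgroundSequenceModel, BackgroundReadModel]:
    """Fit both backgrounds directly from an augmented, binarized dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    seqs = [encode_sequence(r.sequence) for r in dataset.regions]
    seq_bg = BackgroundSequenceModel.fit(seqs)
    read_bg = BackgroundReadModel.fit(
        [t.binary_pos for t in dataset.tracks],
        [t.binary_neg for t in dataset.tracks],
    )
    return seq_bg, read_bg


# ---------------------------------------------------------------------------
# Mode parameters and fitted model
# ---------------------------------------------------------------------------

@dataclass
class ModeParameters:
    """Point estimates for one binding mode."""

    w: int
    pwm: np.ndarray           # (w, 4), rows sum to 1
    bern_pos: np.ndarray      # (w_pos,)
    bern_neg: np.ndarray      # (w_neg,)
    tau_pos: int              # window start = motif start + tau
    tau_neg: int

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.bern_pos = np.asarray(self.bern_pos, dtype=float)
        self.bern_neg = np.asarray(self.bern_neg, dtype=float)
        if self.pwm.shape != (self.w, 4):
            raise ValueError("PWM shape does not match motif width")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def w_pos(self) -> int:
        return len(self.bern_pos)

    @property
    def w_neg(self) -> int:
        return len(self.bern_neg)


@dataclass
class FittedModel:
    """MAP point estimates plus everything needed to score new data."""

    modes: list[ModeParameters]
    gamma: np.ndarray
    seq_bg: BackgroundSequenceModel
    read_bg: BackgroundReadModel
    priors: Priors
    log_posterior: float
    n_datapoints: int
    window_width: int
    bic: float | None = None
    seed: int | None = None
    binarize_threshold: float | None = None

    @property
    def m(self) -> int:
        return len(self.modes)

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "window_width": self.window_width,
            "gamma": [float(g) for g in self.gamma],
            "modes": [
                {
                    "w": md.w,
                    "pwm": md.pwm.tolist(),
                    "bern_pos": md.bern_pos.tolist(),
                    "bern_neg": md.bern_neg.tolist(),
                    "tau_pos": int(md.tau_pos),
                    "tau_neg": int(md.tau_neg),
                }
                for md in self.modes
            ],
            "seq_bg": self.seq_bg.to_dict(),
            "read_bg": self.read_bg.to_dict(),
            "priors": self.priors.to_dict(),
            "log_posterior": float(self.log_posterior),
            "n_datapoints": int(self.n_datapoints),
            "bic": None if self.bic is None else float(self.bic),
            "seed": self.seed,
            "binarize_threshold": self.binarize_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            modes=[
                ModeParameters(
                    w=md["w"],
                    pwm=np.array(md["pwm"]),
                    bern_pos=np.array(md["bern_pos"]),
                    bern_neg=np.array(md["bern_neg"]),
                    tau_pos=md["tau_pos"],
                    tau_neg=md["tau_neg"],
                )
                for md in d["modes"]
            ],
            gamma=np.array(d["gamma"]),
            seq_bg=BackgroundSequenceModel.from_dict(d["seq_bg"]),
            read_bg=BackgroundReadModel.from_dict(d["read_bg"]),
            priors=Priors(**d["priors"]),
            log_posterior=d["log_posterior"],
            n_datapoints=d["n_datapoints"],
            window_width=d["window_width"],
            bic=d.get("bic"),
            seed=d.get("seed"),
            binarize_threshold=d.get("binarize_threshold"),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Likelihood ratios (scalar reference forms)
# ---------------------------------------------------------------------------

def seq_loglik_ratio(
    seq: np.ndarray, Z: int, pwm: np.ndarray, bg: BackgroundSequenceModel
) -> float:
    """log P(site | PWM) - log P(site | background chain).

    The background term conditions each site base on its actual preceding
    bases (falling to lower order at sequence starts), so the ratio is
    exactly invariant to flanking sequence.
    """
    w = pwm.shape[0]
    if Z < 0 or Z + w > len(seq):
        raise InvalidPlacementError("motif site out of bounds")
    site = seq[Z : Z + w]
    if (site >= 4).any():
        raise InvalidPlacementError("motif site contains N")
    bg_lp = bg.position_logprobs(seq)
    with np.errstate(divide="ignore"):
        fg = np.log(pwm[np.arange(w), site]).sum()
    return float(fg - bg_lp[Z : Z + w].sum())


def reads_loglik_ratio(
    binary: np.ndarray, Z: int, tau: int, w_s: int, bern: np.ndarray, bg_p: float
) -> float:
    """log-likelihood ratio of the read window at ``Z + tau`` vs background."""
    p = Z + tau
    if p < 0 or p + w_s > len(binary):
        raise InvalidPlacementError("read window out of bounds")
    r = binary[p : p + w_s].astype(float)
    fg = r * np.log(bern) + (1 - r) * np.log1p(-bern)
    bg = r * np.log(bg_p) + (1 - r) * np.log1p(-bg_p)
    return float((fg - bg).sum())


def datapoint_loglik(
    seq: np.ndarray,
    bin_pos: np.ndarray,
    bin_neg: np.ndarray,
    mode: ModeParameters,
    Z: int,
    gamma_k: float,
    seq_bg: BackgroundSequenceModel,
    read_bg: BackgroundReadModel,
) -> float:
    """Joint log-likelihood ratio of one datapoint under one mode at one Z.

    Sequence and the two read strands are conditionally independent given
    the mode, so the ratio decomposes additively; the mixture weight enters
    as log(gamma_k).
    """
    return (
        seq_loglik_ratio(seq, Z, mode.pwm, seq_bg)
        + reads_loglik_ratio(bin_pos, Z, mode.tau_pos, mode.w_pos, mode.bern_pos, read_bg.p_pos)
        + reads_loglik_ratio(bin_neg, Z, mode.tau_neg, mode.w_neg, mode.bern_neg, read_bg.p_neg)
        + float(np.log(gamma_k))
    )


# ---------------------------------------------------------------------------
# Precomputed per-datapoint cache
# ---------------------------------------------------------------------------

class DataCache:
    """Per-datapoint arrays precomputed once for sampling and prediction.

    Holds encoded sequences, cumulative background log-probabilities for
    sequence and reads (so any contiguous stretch's background probability
    is a prefix-sum difference), and cumulative N counts (so N-free site
    checks are O(1)).
    """

    def __init__(self, dataset, seq_bg: BackgroundSequenceModel,
                 read_bg: BackgroundReadModel, window_width: int = 5):
        self.window_width = int(window_width)
        self.seq_bg = seq_bg
        self.read_bg = read_bg
        self.n = len(dataset)
        self.dataset = dataset
        self.seq: list[np.ndarray] = []
        self.L = np.empty(self.n, dtype=int)
        self.bin_pos: list[np.ndarray] = []
        self.bin_neg: list[np.ndarray] = []
        self.seq_bg_cum: list[np.ndarray] = []
        self.n_cum: list[np.ndarray] = []
        self.read_bg_cum_pos: list[np.ndarray] = []
        self.read_bg_cum_neg: list[np.ndarray] = []
        total = 0.0
        lp, l1p = np.log(read_bg.p_pos), np.log1p(-read_bg.p_pos)
        ln, l1n = np.log(read_bg.p_neg), np.log1p(-read_bg.p_neg)
        for i, (reg, trk) in enumerate(zip(dataset.regions, dataset.tracks)):
            s = encode_sequence(reg.sequence)
            self.seq.append(s)
            self.L[i] = len(s)
            bp = trk.binary_pos.astype(float)
            bn = trk.binary_neg.astype(float)
            self.bin_pos.append(bp)
            self.bin_neg.append(bn)
            slp = seq_bg.position_logprobs(s)
            self.seq_bg_cum.append(np.concatenate(([0.0], np.cumsum(slp))))
            self.n_cum.append(np.concatenate(([0], np.cumsum(s >= 4))))
            rp = bp * lp + (1 - bp) * l1p
            rn = bn * ln + (1 - bn) * l1n
            self.read_bg_cum_pos.append(np.concatenate(([0.0], np.cumsum(rp))))
            self.read_bg_cum_neg.append(np.concatenate(([0.0], np.cumsum(rn))))
            total += slp.sum() + rp.sum() + rn.sum()
        #: full-background log-likelihood of the whole dataset (the additive
        #: constant turning ratio scores into absolute marginal likelihoods)
        self.total_bg = total
        # hot-path precomputations: strand-window views over the binaries,
        # per-window background mass, and per-width site lookups (memoized)
        from numpy.lib.stride_tricks import sliding_window_view as _swv

        ws = self.window_width
        self.rw_pos = [_swv(b, ws) if len(b) >= ws else np.zeros((0, ws))
                       for b in self.bin_pos]
        self.rw_neg = [_swv(b, ws) if len(b) >= ws else np.zeros((0, ws))
                       for b in self.bin_neg]
        self.win_bg_pos = [c[ws:] - c[:-ws] if len(c) > ws else np.zeros(0)
                           for c in self.read_bg_cum_pos]
        self.win_bg_neg = [c[ws:] - c[:-ws] if len(c) > ws else np.zeros(0)
                           for c in self.read_bg_cum_neg]
        self._site_memo: dict[tuple[int, int], tuple] = {}
        # sampling units: an augmented dataset ties each region to its
        # reverse-complement copy (one site between them, the other copy is
        # background); an unaugmented dataset samples every datapoint
        n0 = dataset.n_original
        if getattr(dataset, "augmented", False) and self.n == 2 * n0:
            self.units: list[tuple[int, ...]] = [(u, n0 + u) for u in range(n0)]
        else:
            self.units = [(i,) for i in range(self.n)]
        self.n_units = len(self.units)

    def site_arrays(self, i: int, w: int) -> tuple:
        """(seq windows view, site background, N-free mask) for width w."""
        key = (i, w)
        hit = self._site_memo.get(key)
        if hit is None:
            from numpy.lib.stride_tricks import sliding_window_view as _swv

            L = int(self.L[i])
            if L < w:
                hit = (np.zeros((0, w), dtype=np.int8), np.zeros(0),
                       np.zeros(0, dtype=bool))
            else:
                c = self.seq_bg_cum[i]
                ncum = self.n_cum[i]
                hit = (
                    _swv(self.seq[i], w),
                    c[w:] - c[: L - w + 1],
                    (ncum[w:] - ncum[: L - w + 1]) == 0,
                )
            self._site_memo[key] = hit
        return hit

    # -- O(1) interval queries ------------------------------------------------

    def site_bg(self, i: int, Z: int, w: int) -> float:
        c = self.seq_bg_cum[i]
        return float(c[Z + w] - c[Z])

    def site_has_n(self, i: int, Z: int, w: int) -> bool:
        c = self.n_cum[i]
        return bool(c[Z + w] - c[Z] > 0)

    def win_bg(self, i: int, p: int, strand: str) -> float:
        w_s = self.window_width
        c = self.read_bg_cum_pos[i] if strand == "+" else self.read_bg_cum_neg[i]
        return float(c[p + w_s] - c[p])


def build_cache(dataset, window_width: int = 5) -> DataCache:
    """Fit backgrounds and build the evaluation cache in one step."""
    seq_bg, read_bg = fit_backgrounds(dataset)
    return DataCache(dataset, seq_bg, read_bg, window_width)
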