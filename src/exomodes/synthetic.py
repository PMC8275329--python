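"""Synthetic datasets with planted binding modes and known ground truth.

Each planted mode follows the model's own generative story: a PWM site at a
uniform feasible position, strand-specific binary reads drawn Bernoulli
from the footprint vectors inside width-``window_width`` windows at fixed
offsets from the site, and background elsewhere.  Background sequence comes
from a 1st-order chain parameterized by GC content (deliberately simpler
than the 2nd-order background the model fits), background reads from a
0th-order Bernoulli rate.  Datapoints are planted on either strand so that
reverse-complement augmentation is exercised downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BASES
from .regions import Dataset, ReadTrack, Region, revcomp

PAD = 20  # bp between consecutive regions on the synthetic chromosome
CHROM = "chrSim"


def pwm_from_consensus(consensus: str, match_prob: float = 0.85) -> np.ndarray:
    """PWM placing ``match_prob`` on the consensus base at each column and
    spreading the remainder evenly over the other three."""
    w = len(consensus)
    pwm = np.full((w, 4), (1 - match_prob) / 3)
    for a, b in enumerate(consensus.upper()):
        pwm[a, BASES.index(b)] = match_prob
    return pwm


@dataclass
class ModeSpec:
    """Ground-truth description of one planted binding mode."""

    label: str
    pwm: np.ndarray
    footprint_pos: np.ndarray
    footprint_neg: np.ndarray
    tau_pos: int
    tau_neg: int
    proportion: float

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, float)
        self.footprint_pos = np.asarray(self.footprint_pos, float)
        self.footprint_neg = np.asarray(self.footprint_neg, float)
        for v in (self.footprint_pos, self.footprint_neg):
            if ((v <= 0) | (v >= 1)).any():
                raise ValueError(f"spec {self.label}: footprint probabilities "
                                 "must lie strictly inside (0, 1)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError(f"spec {self.label}: PWM rows must sum to 1")

    @property
    def w(self) -> int:
        return self.pwm.shape[0]


def _background_chain(gc: float) -> tuple[np.ndarray, np.ndarray]:
    """Stationary distribution and a mildly persistent 1st-order transition
    matrix (10% probability of repeating the previous base)."""
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = np.tile(0.9 * pi, (4, 1)) + 0.1 * np.eye(4)
    return pi, T


def _draw_background_seq(L: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    pi, T = _background_chain(gc)
    seq = np.empty(L, dtype=np.int8)
    seq[0] = rng.choice(4, p=pi)
    for j in range(1, L):
        seq[j] = rng.choice(4, p=T[seq[j - 1]])
    return seq


def _feasible_z(spec: ModeSpec, L: int, window_width: int) -> np.ndarray:
    z = np.arange(max(0, L - spec.w + 1))
    ok = np.ones(len(z), dtype=bool)
    for tau in (spec.tau_pos, spec.tau_neg):
        ok &= (z + tau >= 0) & (z + tau + window_width <= L)
    return z[ok]


def generate_dataset(
    specs: list[ModeSpec],
    n: int,
    L: int = 240,
    bg_gc: float = 0.4,
    bg_read_p: float = 0.05,
    seed: int = 0,
    window_width: int = 5,
    reverse_prob: float = 0.5,
    counts_mode: bool = False,
) -> tuple[Dataset, pd.DataFrame]:
    """Generate ``n`` regions of length ``L`` with planted modes.

    Mode proportions may sum to less than 1; the remainder are
    pure-background regions (truth label ``background``).  With
    ``counts_mode`` the binary reads are wrapped in overdispersed counts
    (so that binarization has to recover them); otherwise the counts equal
    the binaries and the tracks come pre-binarized.  Output is
    pre-augmentation.
    """
    props = np.array([s.proportion for s in specs])
    if props.sum() > 1 + 1e-9:
        raise ValueError("mode proportions exceed 1")
    for s in specs:
        if len(_feasible_z(s, L, window_width)) == 0:
            raise ValueError(f"spec {s.label}: no feasible site placement in L={L}")
    rng = np.random.default_rng(seed)
    p_all = np.append(props, max(0.0, 1.0 - props.sum()))
    regions, tracks, rows = [], [], []
    base_arr = np.array(list(BASES + "N"))
    for i in range(n):
        choice = rng.choice(len(specs) + 1, p=p_all)
        seq = _draw_background_seq(L, bg_gc, rng)
        bp = (rng.random(L) < bg_read_p).astype(np.uint8)
        bn = (rng.random(L) < bg_read_p).astype(np.uint8)
        if choice < len(specs):
            spec = specs[choice]
            z = int(rng.choice(_feasible_z(spec, L, window_width)))
            for a in range(spec.w):
                seq[z + a] = rng.choice(4, p=spec.pwm[a])
            pp, pn = z + spec.tau_pos, z + spec.tau_neg
            bp[pp : pp + window_width] = rng.random(window_width) < spec.footprint_pos
            bn[pn : pn + window_width] = rng.random(window_width) < spec.footprint_neg
            label, z_rec = spec.label, z
        else:
            label, z_rec = "background", -1
        orientation = "-" if rng.random() < reverse_prob else "+"
        seq_str = "".join(base_arr[seq])
        if orientation == "-":
            seq_str = revcomp(seq_str)
            bp, bn = bn[::-1].copy(), bp[::-1].copy()
        start = PAD + i * (L + PAD)
        region = Region(
            id=f"sim{i}",
            chrom=CHROM,
            start=start,
            end=start + L,
            summit=start + L // 2,
            sequence=seq_str,
        )
        if counts_mode:
            cp = np.where(bp > 0, 2 + rng.poisson(3.0, L), 0)
            cn = np.where(bn > 0, 2 + rng.poisson(3.0, L), 0)
            noise_p = rng.random(L) < 0.2
            noise_n = rng.random(L) < 0.2
            cp = np.where((cp == 0) & noise_p, 1, cp)
            cn = np.where((cn == 0) & noise_n, 1, cn)
            track = ReadTrack(counts_pos=cp, counts_neg=cn)
        else:
            track = ReadTrack(
                counts_pos=bp.astype(int),
                counts_neg=bn.astype(int),
                binary_pos=bp,
                binary_neg=bn,
            )
        regions.append(region)
        tracks.append(track)
        rows.append({"region_id": region.id, "mode": label, "Z": z_rec,
                     "orientation": orientation})
    dataset = Dataset(
        regions=regions,
        tracks=tracks,
        n_original=n,
        binarize_threshold=None if counts_mode else 0.0,
    )
    return dataset, pd.DataFrame(rows)


def default_three_mode_specs(window_width: int = 5) -> list[ModeSpec]:
    """Three well-separated modes: distinct strong motifs, strong footprints
    (p = 0.9 inside windows vs 0.05 background), distinct offset geometries."""
    strong = np.full(window_width, 0.9)
    return [
        ModeSpec("modeA", pwm_from_consensus("TGACGTCAT", 0.9),
                 strong, strong, tau_pos=-10, tau_neg=15, proportion=1 / 3),
        ModeSpec("modeB", pwm_from_consensus("GGGCCTAAGG", 0.9),
                 strong, strong, tau_pos=-6, tau_neg=12, proportion=1 / 3),
        ModeSpec("modeC", pwm_from_consensus("CACACATTCC", 0.9),
                 strong, strong, tau_pos=8, tau_neg=18, proportion=1 / 3),
    ]


def generate_degenerate(kind: str, seed: int = 0) -> Dataset:
    """Edge-case fixtures: ``no_reads``, ``uniform_motif``, ``single_region``
    or ``all_N_flanks``."""
    rng = np.random.default_rng(seed)
    ws = 5
    if kind == "no_reads":
        specs = default_three_mode_specs(ws)[:1]
        ds, _ = generate_dataset(specs, n=20, L=80, seed=seed, bg_read_p=0.05)
        for t in ds.tracks:
            t.counts_pos[:] = 0
            t.counts_neg[:] = 0
            t.binary_pos[:] = 0
            t.binary_neg[:] = 0
        return ds
    if kind == "uniform_motif":
        spec = ModeSpec(
            "uniform", np.full((8, 4), 0.25), np.full(ws, 0.9), np.full(ws, 0.9),
            tau_pos=-ws, tau_neg=8, proportion=1.0,
        )
        ds, _ = generate_dataset([spec], n=20, L=80, bg_gc=0.5, seed=seed)
        return ds
    if kind == "single_region":
        ds, _ = generate_dataset(default_three_mode_specs(ws)[:1], n=1, L=80,
                                 seed=seed)
        return ds
    if kind == "all_N_flanks":
        ds, _ = generate_dataset(default_three_mode_specs(ws)[:1], n=10, L=80,
                                 seed=seed, reverse_prob=0.0)
        for reg, truth_z in zip(ds.regions, [None] * len(ds.regions)):
            s = list(reg.sequence)
            for j in list(range(0, 10)) + list(range(len(s) - 10, len(s))):
                s[j] = "N"
            reg.sequence = "".join(s)
        return ds
    raise ValueError(f"unknown degenerate kind {kind!r}")


def mirror_mode(w: int, pwm: np.ndarray, bern_pos: np.ndarray,
                bern_neg: np.ndarray, tau_pos: int, tau_neg: int):
    """The strand-mirrored parameterization of a mode.

    A mode learned in one orientation is equivalent to its mirror: PWM
    reverse-complemented, window vectors swapped and reversed, and offsets
    reflected about the motif (window_width ws): tau+ <- w - tau- - ws.
    """
    ws = len(bern_pos)
    return (
        pwm[::-1, ::-1].copy(),
        bern_neg[::-1].copy(),
        bern_pos[::-1].copy(),
        w - tau_neg - ws,
        w - tau_pos - ws,
    )


def evaluate_recovery(fitted, specs: list[ModeSpec],
                      max_shift: int = 3, min_overlap: int = 5) -> pd.DataFrame:
    """Match each learned mode to its best planted spec and measure errors.

    Every learned mode is compared to every spec in both orientations and
    over small column shifts (the sampler may learn a motif a column or two
    wider/narrower than planted).  The match minimizing mean per-column PWM
    total variation over the overlapping columns wins.  Window offsets are
    mapped into the spec frame (shift d moves the motif start, so the
    equivalent offset is d + tau) before taking |tau_hat - tau_true|.

    A motif can be nearly shift- or palindrome-degenerate (its reverse
    complement equals a 1-column shift of itself), leaving the PWM distance
    almost tied between orientations; a small penalty on the offset error
    breaks such ties toward the geometry-consistent reading without hiding
    genuine offset misses.
    """
    rows = []
    for k, md in enumerate(fitted.modes):
        m_pwm, _, _, m_tp, m_tn = mirror_mode(
            md.w, md.pwm, md.bern_pos, md.bern_neg, md.tau_pos, md.tau_neg
        )
        variants = [
            ("+", md.pwm, md.tau_pos, md.tau_neg),
            ("-", m_pwm, m_tp, m_tn),
        ]
        best = None
        for spec in specs:
            for orient, pwm, tp, tn in variants:
                for d in range(-max_shift, max_shift + 1):
                    lo = max(0, -d)
                    hi = min(md.w, spec.w - d)
                    if hi - lo < min_overlap:
                        continue
                    tv = 0.5 * np.abs(
                        pwm[lo:hi] - spec.pwm[lo + d : hi + d]
                    ).sum(axis=1).mean()
                    err_p = abs(d + tp - spec.tau_pos)
                    err_n = abs(d + tn - spec.tau_neg)
                    cand = {
                        "mode": k + 1,
                        "gamma": float(fitted.gamma[k]),
                        "matched_spec": spec.label,
                        "orientation": orient,
                        "shift": d,
                        "mean_pwm_tv": float(tv),
                        "err_tau_pos": err_p,
                        "err_tau_neg": err_n,
                        "_score": float(tv) + 0.005 * (err_p + err_n),
                    }
                    if best is None or cand["_score"] < best["_score"]:
                        best = cand
        best.pop("_score", None)
        rows.append(best)
    return pd.DataFrame(rows)


def write_fixture_files(dataset: Dataset, truth: pd.DataFrame, outdir: str) -> dict:
    """Write FASTA + BED + per-strand bedGraph + truth TSV so the shell
    pipeline can be exercised end to end."""
    os.makedirs(outdir, exist_ok=True)
    last = max(r.end for r in dataset.regions) + PAD
    chrom_seq = np.array(list("ACGT" * (last // 4 + 1))[:last])
    for reg in dataset.regions:
        chrom_seq[reg.start : reg.end] = list(reg.sequence)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "peaks": os.path.join(outdir, "peaks.bed"),
        "reads_pos": os.path.join(outdir, "reads_pos.bedGraph"),
        "reads_neg": os.path.join(outdir, "reads_neg.bedGraph"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    with open(paths["genome"], "w") as fh:
        fh.write(f">{CHROM}\n")
        s = "".join(chrom_seq)
        for j in range(0, len(s), 80):
            fh.write(s[j : j + 80] + "\n")
    with open(paths["peaks"], "w") as fh:
        for reg in dataset.regions:
            fh.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.id}\n")
    for key, attr in (("reads_pos", "counts_pos"), ("reads_neg", "counts_neg")):
        with open(paths[key], "w") as fh:
            for reg, trk in zip(dataset.regions, dataset.tracks):
                counts = getattr(trk, attr)
                for j in np.flatnonzero(counts):
                    fh.write(
                        f"{reg.chrom}\t{reg.start + j}\t{reg.start + j + 1}\t"
                        f"{int(counts[j])}\n"
                    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
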