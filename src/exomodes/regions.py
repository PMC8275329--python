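"""Genomic input handling: region extraction, read loading, binarization,
reverse-complement augmentation, and output writers.

Coordinates are 0-based half-open everywhere internally; BED conventions at
the file boundary.  Each candidate bound region is a fixed-width window
around a peak summit; repeat-masked (lowercase) bases become ``N`` and are
excluded from motif placements downstream.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: minimum number of non-repetitive (non-N) bases for a region to be kept
MIN_INFORMATIVE_BASES = 100


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Region:
    """One candidate bound window.

    ``start``/``end`` are genomic (0-based half-open); ``sequence`` is the
    forward-genome string unless ``is_revcomp`` is set, in which case it is
    the reverse complement of the partner region's sequence.
    """

    id: str
    chrom: str
    start: int
    end: int
    summit: int
    sequence: str
    is_revcomp: bool = False
    partner_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"region {self.id}: sequence length {len(self.sequence)} != "
                f"span {self.end - self.start}"
            )
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"region {self.id}: summit outside span")

    @property
    def length(self) -> int:
        return self.end - self.start

    def local_to_genomic(self, pos: int, width: int = 1) -> tuple[int, int, str]:
        """Map a local interval [pos, pos+width) to forward-genome coordinates.

        Returns (genomic_start, genomic_end, strand).
        """
        if self.is_revcomp:
            g_end = self.end - pos
            return g_end - width, g_end, "-"
        return self.start + pos, self.start + pos + width, "+"


@dataclass
class ReadTrack:
    """Strand-specific per-position 5'-end read counts for one region."""

    counts_pos: np.ndarray
    counts_neg: np.ndarray
    binary_pos: np.ndarray | None = None
    binary_neg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts_pos = np.asarray(self.counts_pos)
        self.counts_neg = np.asarray(self.counts_neg)
        if self.counts_pos.shape != self.counts_neg.shape:
            raise ValueError("strand count vectors differ in length")
        if (self.counts_pos < 0).any() or (self.counts_neg < 0).any():
            raise ValueError("negative read counts in input")


@dataclass
class Dataset:
    """Index-aligned regions and read tracks, before or after augmentation."""

    regions: list[Region]
    tracks: list[ReadTrack]
    n_original: int = 0
    binarize_threshold: float | None = None
    augmented: bool = False

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.tracks):
            raise ValueError("regions and tracks not index-aligned")
        if self.n_original == 0:
            self.n_original = len(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# BED / FASTA handling
# ---------------------------------------------------------------------------

def read_bed(path: str, summit_col: int | None = None) -> pd.DataFrame:
    """Read a BED-like file (>= 3 columns) into a DataFrame.

    The summit defaults to the interval midpoint; for point records
    (end - start == 1) it is the start.  ``summit_col`` (0-based column
    index) selects a column holding a summit offset relative to ``start``,
    as written by some peak callers.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "name": df[3].astype(str)
            if df.shape[1] > 3
            else [f"peak{i}" for i in range(len(df))],
        }
    )
    if summit_col is not None:
        out["summit"] = out["start"] + df[summit_col].astype(int)
    else:
        out["summit"] = (out["start"] + out["end"]) // 2
    return out


def extract_regions(
    peaks: pd.DataFrame,
    genome,
    flank: int = 120,
    min_informative: int = MIN_INFORMATIVE_BASES,
) -> list[Region]:
    """Extract fixed-width windows ``[summit - flank, summit + flank)``.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> indexable
    sequence).  Soft-masked (lowercase) bases are converted to ``N``.
    Regions with fewer than ``min_informative`` non-N bases, truncated by a
    chromosome edge, or overlapping a previously accepted region (input
    order precedence) are dropped.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    accepted: list[Region] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for rec in peaks.itertuples(index=False):
        chrom, summit, name = rec.chrom, int(rec.summit), rec.name
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        chrom_len = len(genome[chrom])
        start, end = summit - flank, summit + flank
        if start < 0 or end > chrom_len:
            logger.warning("region %s truncated by chromosome edge; dropped", name)
            continue
        # soft-masked repeats -> N; anything non-ACGT -> N
        masked = str(genome[chrom][start:end])
        seq = "".join(
            "N" if (b.islower() or b.upper() not in "ACGT") else b.upper()
            for b in masked
        )
        if sum(b != "N" for b in seq) < min_informative:
            continue
        overlaps = any(
            s < end and start < e for (s, e) in occupied.get(chrom, [])
        )
        if overlaps:
            continue
        occupied.setdefault(chrom, []).append((start, end))
        accepted.append(
            Region(id=name, chrom=chrom, start=start, end=end, summit=summit, sequence=seq)
        )
    return accepted


# ---------------------------------------------------------------------------
# Read signal
# ---------------------------------------------------------------------------

def _read_bedgraph(path: str) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        out[chrom] = (
            sub["start"].to_numpy(int),
            sub["end"].to_numpy(int),
            sub["value"].to_numpy(float),
        )
    return out


class _SignalFile:
    """Per-base signal lookup over bedGraph or bigWig."""

    def __init__(self, path: str):
        self.path = path
        self._bw = None
        self._bg = None
        if path.endswith((".bw", ".bigwig", ".bigWig")):
            import pyBigWig

            self._bw = pyBigWig.open(path)
        else:
            self._bg = _read_bedgraph(path)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=float)
        if self._bw is not None:
            if chrom not in self._bw.chroms():
                logger.warning("chromosome %s missing from %s; zeros used", chrom, self.path)
                return out
            vals = np.nan_to_num(
                np.asarray(self._bw.values(chrom, start, end), dtype=float)
            )
            return vals
        if chrom not in self._bg:
            logger.warning("chromosome %s missing from %s; zeros used", chrom, self.path)
            return out
        starts, ends, vals = self._bg[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start : b - start] = v
        return out


def load_counts(
    track_pos: str,
    track_neg: str,
    regions: list[Region],
    control_pos: str | None = None,
    control_neg: str | None = None,
    scale: float | None = None,
) -> list[ReadTrack]:
    """Load per-region strand-specific 5'-end counts, optionally subtracting
    a scaled control: ``max(0, treatment - scale * control)`` per position.

    Default ``scale`` is the library-size ratio (total treatment signal over
    total control signal, summed over the requested regions).
    """
    sig_p, sig_n = _SignalFile(track_pos), _SignalFile(track_neg)
    raw = []
    for r in regions:
        cp = sig_p.values(r.chrom, r.start, r.end)
        cn = sig_n.values(r.chrom, r.start, r.end)
        if (cp < 0).any() or (cn < 0).any():
            raise ValueError(f"negative values in treatment signal at region {r.id}")
        raw.append((cp, cn))

    if control_pos is not None or control_neg is not None:
        if control_pos is None or control_neg is None:
            raise ValueError("both control tracks are required for subtraction")
        ctl_p, ctl_n = _SignalFile(control_pos), _SignalFile(control_neg)
        ctl = []
        for r in regions:
            cp = ctl_p.values(r.chrom, r.start, r.end)
            cn = ctl_n.values(r.chrom, r.start, r.end)
            if (cp < 0).any() or (cn < 0).any():
                raise ValueError(f"negative values in control signal at region {r.id}")
            ctl.append((cp, cn))
        if scale is None:
            t_tot = sum(cp.sum() + cn.sum() for cp, cn in raw)
            c_tot = sum(cp.sum() + cn.sum() for cp, cn in ctl)
            scale = t_tot / c_tot if c_tot > 0 else 1.0
        raw = [
            (np.maximum(0.0, tp - scale * kp), np.maximum(0.0, tn - scale * kn))
            for (tp, tn), (kp, kn) in zip(raw, ctl)
        ]
    return [ReadTrack(counts_pos=cp, counts_neg=cn) for cp, cn in raw]


def binarize(
    tracks: list[ReadTrack], threshold: float | None = None
) -> tuple[list[ReadTrack], float]:
    """Discretize counts to 0/1 using ``count > threshold``.

    The default threshold is the median of all strictly positive counts,
    pooled over both strands and all regions; ties at the threshold map
    to 0 so the upper half of the nonzero signal is marked.
    """
    if threshold is None:
        pooled = np.concatenate(
            [t.counts_pos for t in tracks] + [t.counts_neg for t in tracks]
        )
        positive = pooled[pooled > 0]
        if positive.size == 0:
            logger.warning("all read counts are zero; threshold set to 0")
            threshold = 0.0
        else:
            threshold = float(np.median(positive))
    for t in tracks:
        t.binary_pos = (t.counts_pos > threshold).astype(np.uint8)
        t.binary_neg = (t.counts_neg > threshold).astype(np.uint8)
    return tracks, float(threshold)


def augment_revcomp(dataset: Dataset) -> Dataset:
    """Append the reverse complement of every datapoint.

    The copy's positive-strand binary vector is the reversed negative-strand
    vector of the original (and vice versa), so that a motif on either
    genomic strand presents the same footprint geometry to the model.
    """
    if dataset.augmented:
        raise ValueError("dataset is already reverse-complement augmented")
    new_regions, new_tracks = [], []
    for reg, trk in zip(dataset.regions, dataset.tracks):
        if trk.binary_pos is None:
            raise ValueError("binarize before augmenting")
        rc_id = reg.id + "|rc"
        reg.partner_id = rc_id
        rc = Region(
            id=rc_id,
            chrom=reg.chrom,
            start=reg.start,
            end=reg.end,
            summit=reg.summit,
            sequence=revcomp(reg.sequence),
            is_revcomp=True,
            partner_id=reg.id,
        )
        rc_trk = ReadTrack(
            counts_pos=trk.counts_neg[::-1].copy(),
            counts_neg=trk.counts_pos[::-1].copy(),
            binary_pos=trk.binary_neg[::-1].copy(),
            binary_neg=trk.binary_pos[::-1].copy(),
        )
        new_regions.append(rc)
        new_tracks.append(rc_trk)
    dataset.regions.extend(new_regions)
    dataset.tracks.extend(new_tracks)
    dataset.augmented = True
    return dataset


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_meme(fitted, path: str) -> None:
    """Write per-mode PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for k, mode in enumerate(fitted.modes):
            fh.write(f"MOTIF mode{k + 1}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {mode.w} "
                f"nsites= 20 E= 0\n"
            )
            for row in mode.pwm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def write_footprints(fitted, path: str) -> None:
    rows = []
    for k, mode in enumerate(fitted.modes):
        for strand, tau, bern in (
            ("+", mode.tau_pos, mode.bern_pos),
            ("-", mode.tau_neg, mode.bern_neg),
        ):
            for a, p in enumerate(bern):
                rows.append(
                    {
                        "mode": k + 1,
                        "strand": strand,
                        "offset": int(tau),
                        "window_pos": a,
                        "read_prob": float(p),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_outputs(fitted, dataset: Dataset, outdir: str, assignments=None) -> dict:
    """Write the standard artifact set for a fitted model.

    Produces the per-region assignment table, MEME motifs, footprint table,
    model JSON, a BED6 of motif sites, and a summary JSON.  Returns the path
    map.  ``assignments`` (a DataFrame from ``predict.assign_regions``) is
    computed on the fly when omitted.
    """
    os.makedirs(outdir, exist_ok=True)
    probe = os.path.join(outdir, ".write_probe")
    try:
        with open(probe, "w") as fh:
            fh.write("")
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable") from exc

    if assignments is None:
        from . import predict as _predict

        assignments = _predict.assign_regions(dataset, fitted)

    paths = {
        "assignments": os.path.join(outdir, "assignments.tsv"),
        "motifs": os.path.join(outdir, "motifs.meme"),
        "footprints": os.path.join(outdir, "footprints.tsv"),
        "model": os.path.join(outdir, "model.json"),
        "sites": os.path.join(outdir, "sites.bed"),
        "summary": os.path.join(outdir, "summary.json"),
    }
    assignments.to_csv(paths["assignments"], sep="\t", index=False)
    write_meme(fitted, paths["motifs"])
    write_footprints(fitted, paths["footprints"])
    with open(paths["model"], "w") as fh:
        json.dump(fitted.to_dict(), fh, indent=1)
    with open(paths["sites"], "w") as fh:
        for rec in assignments.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.site_start}\t{rec.site_end}\t"
                f"{rec.region_id}|mode{rec.mode}\t"
                f"{int(round(1000 * rec.posterior))}\t{rec.strand}\n"
            )
    summary = {
        "n_modes": len(fitted.modes),
        "gamma": [float(g) for g in fitted.gamma],
        "log_posterior": float(fitted.log_posterior),
        "bic": None if fitted.bic is None else float(fitted.bic),
        "n_datapoints": int(fitted.n_datapoints),
        "binarize_threshold": dataset.binarize_threshold,
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=1)
    return paths
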