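import numpy as np
import pytest

from exomodes.model import Priors, build_cache
from exomodes.regions import Dataset, ReadTrack, Region, augment_revcomp
from exomodes.sampler import ModelState, SamplerConfig, _recount


def make_dataset(seqs, bin_pos=None, bin_neg=None, augment=False,
                 start0=100, spacing=500):
    """Build a small in-memory dataset from raw strings/vectors."""
    regions, tracks = [], []
    for i, s in enumerate(seqs):
        L = len(s)
        start = start0 + i * spacing
        regions.append(Region(id=f"r{i}", chrom="chrT", start=start,
                              end=start + L, summit=start + L // 2,
                              sequence=s))
        bp = (np.asarray(bin_pos[i], dtype=np.uint8) if bin_pos is not None
              else np.zeros(L, dtype=np.uint8))
        bn = (np.asarray(bin_neg[i], dtype=np.uint8) if bin_neg is not None
              else np.zeros(L, dtype=np.uint8))
        tracks.append(ReadTrack(counts_pos=bp.astype(int),
                                counts_neg=bn.astype(int),
                                binary_pos=bp, binary_neg=bn))
    ds = Dataset(regions=regions, tracks=tracks, n_original=len(seqs),
                 binarize_threshold=0.0)
    if augment:
        ds = augment_revcomp(ds)
    return ds


def make_state(cache, orient, I, Z, w, tau_pos, tau_neg):
    """Assemble a ModelState with statistics recounted from scratch."""
    m = len(w)
    ws = cache.window_width
    state = ModelState(
        m=m,
        Z=np.asarray(Z, dtype=int),
        I=np.asarray(I, dtype=int),
        orient=np.asarray(orient, dtype=int),
        w=np.asarray(w, dtype=int),
        tau_pos=np.asarray(tau_pos, dtype=int),
        tau_neg=np.asarray(tau_neg, dtype=int),
        motif_counts=[],
        win_ones_pos=np.zeros((m, ws)),
        win_ones_neg=np.zeros((m, ws)),
        n_k=np.zeros(m),
        site_bg_sum=np.zeros(m),
        win_bg_sum_pos=np.zeros(m),
        win_bg_sum_neg=np.zeros(m),
    )
    for name, val in _recount(state, cache).items():
        setattr(state, name, val)
    return state


@pytest.fixture
def priors():
    return Priors()


@pytest.fixture
def tiny_cache():
    """Three short unaugmented regions with mixed reads (enumeration scale)."""
    rng = np.random.default_rng(42)
    seqs = ["ACGTACGTACGTACGTACGT",
            "TTGACGTCATGCAAGGTTAC",
            "GGCATTGACGTCATCCAGTA"]
    bp = [(rng.random(20) < 0.3).astype(np.uint8) for _ in range(3)]
    bn = [(rng.random(20) < 0.3).astype(np.uint8) for _ in range(3)]
    ds = make_dataset(seqs, bp, bn)
    return build_cache(ds, window_width=3)


@pytest.fixture
def tiny_aug_cache():
    """Two regions with RC copies (paired-unit enumeration scale)."""
    rng = np.random.default_rng(7)
    seqs = ["ACGTTGACGTCATACG", "GCATCCAGTAGGCATT"]
    bp = [(rng.random(16) < 0.3).astype(np.uint8) for _ in range(2)]
    bn = [(rng.random(16) < 0.3).astype(np.uint8) for _ in range(2)]
    ds = make_dataset(seqs, bp, bn, augment=True)
    return build_cache(ds, window_width=3)


@pytest.fixture
def fast_config():
    return SamplerConfig(window_width=5, init_width=8, restarts=1,
                         max_sweeps=30)
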