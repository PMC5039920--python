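"""Synthetic ChIP-seq window counts from the 3-state ZINM-HMM generative model.

The generator draws a hidden low/medium/high state chain per chromosome,
marks a fraction ``pi`` of windows as unmappable (structurally zero in
every profile), and for mappable windows samples counts through the
shared Gamma-Poisson construction: one Gamma(alpha) intensity per window
multiplies every profile's rate, so replicate counts are positively
correlated exactly as the ZINM prescribes.  Control profiles draw from
the baseline rate at every window regardless of the hidden state.

Defaults describe a routine mammalian ChIP-seq experiment at 300 bp
resolution: a baseline of about 4 reads per window in the control,
two replicates, ~10% unmappable windows, moderate overdispersion
(alpha = 3) and a sparse "high" state about 20-fold over background.

Optionally the counts are spelled out as BED read files whose
re-ingestion through :mod:`chipseg.io_binning` reproduces the truth
matrix exactly: reads are 36 bp, placed at distinct midpoints inside
their window (alternating strand once an offset is exhausted) so that
duplicate removal keeps all of them unless duplicates are injected on
purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .hmm_engine import HMMParams
from .io_binning import CountMatrix, WindowGrid
from .zinm_model import zinm_params_from_means

__all__ = [
    "SimConfig",
    "SimResult",
    "default_truth_params",
    "default_config",
    "simulate_states",
    "simulate_counts",
    "simulate",
    "emit_bed",
]

READ_LENGTH = 36


def default_truth_params(
    pi: float = 0.10,
    alpha: float = 3.0,
    r: int = 2,
    state_means=(2.0, 6.0, 20.0),
) -> HMMParams:
    """Well-separated 3-state truth parameters.

    ``state_means`` are the per-replicate mean reads per mappable window
    in the low, medium and high states.  The chain is sticky and spends
    most of its time in the low state, as baseline does in real data.
    """
    nu = np.array([0.90, 0.08, 0.02])
    Q = np.array(
        [
            [0.985, 0.010, 0.005],
            [0.100, 0.850, 0.050],
            [0.050, 0.100, 0.850],
        ]
    )
    emissions = [
        zinm_params_from_means(pi, alpha, np.full(r, m)) for m in state_means
    ]
    return HMMParams(nu=nu, Q=Q, emissions=emissions)


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment."""

    chrom_windows: dict = field(
        default_factory=lambda: {"chr1": 5000, "chr2": 5000}
    )
    window_size: int = 300
    hmm: HMMParams = field(default_factory=default_truth_params)
    control_mean: float = 4.0     # mean control reads per mappable window
    n_controls: int = 1
    seed: int = 0

    @property
    def r(self) -> int:
        return self.hmm.r


@dataclass
class SimResult:
    """Counts, truth states and the configuration that produced them."""

    config: SimConfig
    counts: CountMatrix
    states: np.ndarray      # truth state per window (concatenated blocks)
    mappable: np.ndarray    # False where the window is structurally zero


def default_config(seed: int = 0, **overrides) -> SimConfig:
    return replace(SimConfig(seed=seed), **overrides)


def simulate_states(config: SimConfig, rng: np.random.Generator = None) -> list:
    """Sample the hidden state chain for every chromosome."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nu, Q = config.hmm.nu, config.hmm.Q
    cum_nu = np.cumsum(nu)
    cum_Q = np.cumsum(Q, axis=1)
    out = []
    for n in config.chrom_windows.values():
        u = rng.random(n)
        states = np.empty(n, dtype=np.int64)
        states[0] = np.searchsorted(cum_nu, u[0], side="right")
        for t in range(1, n):
            states[t] = np.searchsorted(cum_Q[states[t - 1]], u[t], side="right")
        out.append(states)
    return out


def simulate_counts(states, config: SimConfig, rng: np.random.Generator = None):
    """Emit a CountMatrix given hidden states; returns a SimResult.

    Per window: with probability ``pi`` the window is unmappable and all
    profiles are zero; otherwise a shared Gamma(alpha, 1) intensity is
    drawn and every profile's count is Poisson with rate
    ``intensity * mean / alpha``, which makes the ChIP columns
    marginally ZINM with the state's parameters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    hmm = config.hmm
    pi, alpha, r = hmm.pi, hmm.alpha, hmm.r
    state_means = np.stack([em.means() for em in hmm.emissions])  # (3, r)
    all_states = np.concatenate(list(states))
    n = all_states.size

    mappable = rng.random(n) >= pi
    lam = rng.gamma(shape=alpha, scale=1.0, size=n)
    m = config.n_controls + r
    counts = np.zeros((n, m), dtype=np.int64)
    rates = np.empty((n, m))
    rates[:, : config.n_controls] = config.control_mean / alpha
    rates[:, config.n_controls:] = state_means[all_states] / alpha
    idx = np.flatnonzero(mappable)
    counts[idx] = rng.poisson(lam[idx, None] * rates[idx])

    grid = WindowGrid(
        config.window_size,
        {c: nw * config.window_size for c, nw in config.chrom_windows.items()},
    )
    roles = ["control"] * config.n_controls + ["chip"] * r
    cm = CountMatrix(grid=grid, counts=counts, roles=roles)
    return SimResult(config=config, counts=cm, states=all_states, mappable=mappable)


def simulate(config: SimConfig) -> SimResult:
    """Full generative draw, fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    states = simulate_states(config, rng)
    return simulate_counts(states, config, rng)


def emit_bed(sim: SimResult, out_dir, duplicate_factor: int = 1) -> dict:
    """Write per-profile BED files that round-trip through io_binning.

    Each count becomes one 36 bp read whose midpoint lies inside its
    window; midpoints (and then strands) are distinct within a window so
    deduplication removes nothing.  ``duplicate_factor > 1`` writes each
    read that many times to exercise duplicate removal.  Also writes
    ``truth_states.tsv`` and ``chrom_lengths.tsv``.  Returns a dict with
    the written paths under keys "controls", "chips", "truth",
    "chrom_lengths".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm = sim.counts
    grid = cm.grid
    frame = grid.to_frame()
    wsize = grid.window_size
    half = READ_LENGTH // 2
    lo_off = half                 # keeps read start >= 0 in the first window
    capacity = wsize - lo_off

    paths = {"controls": [], "chips": []}
    for col, (name, role) in enumerate(zip(cm.names, cm.roles)):
        path = out_dir / f"{name}.bed"
        with open(path, "w") as fh:
            for widx in np.flatnonzero(cm.counts[:, col] > 0):
                k = int(cm.counts[widx, col])
                if k > 2 * capacity:
                    raise ValueError(
                        f"window count {k} exceeds BED emission capacity "
                        f"{2 * capacity}"
                    )
                chrom = frame["chrom"].iloc[widx]
                start = int(frame["start"].iloc[widx])
                for i in range(k):
                    mid = start + lo_off + (i % capacity)
                    strand = "+" if i < capacity else "-"
                    line = (
                        f"{chrom}\t{mid - half}\t{mid + half}\tread\t0\t{strand}\n"
                    )
                    fh.write(line * duplicate_factor)
        paths["controls" if role == "control" else "chips"].append(path)

    truth = grid.to_frame()
    truth["state"] = sim.states
    truth_path = out_dir / "truth_states.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    cl_path = out_dir / "chrom_lengths.tsv"
    with open(cl_path, "w") as fh:
        for chrom, length in grid.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["truth"] = truth_path
    paths["chrom_lengths"] = cl_path
    return paths
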