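"""Forward simulation of a pooled overgo BAC-library screen.

Emulates the statistical structure of the screen end to end: a linear
genome, a clone library with uniform insert placement, per-probe
hybridization efficacy that depends on the probe's sequence class, and
Boolean pool calls with optional false-positive / false-negative noise.
The planted truth is returned alongside the calls so decoder recovery
is directly checkable.

The hybridization-failure model is probe-level: a probe either works
(and then every clone overlapping its locus is a true hit) or fails
everywhere. This mirrors how screen outcomes are tallied per probe, and
how a bad probe behaves on a real filter: it yields nothing anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import DEFAULT_EFFICACY
from .design import PoolingDesign

__all__ = ["SimConfig", "SimResult", "simulate_library", "assign_probe_loci", "simulate_screen"]

#: Published scale of the modeled library and genome.
FULL_GENOME_KB = 1_339_860.0
FULL_N_CLONES = 196_354
INSERT_MEAN_KB = 144.0

#: Desk-scale genome: the full genome shrunk by the same factor as the
#: clone count (2,000/196,354), preserving both fold coverages.
DESK_N_CLONES = 2_000
DESK_GENOME_KB = 13_648.0


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated library and screen.

    Defaults are the full published scale: 196,354 clones of mean insert
    144 Kb on a 1,339,860 Kb genome spread over 11 filters, of which 4
    are screened. ``insert_sd_kb`` is a modeling choice (only the mean
    is published); inserts are truncated-normal, bounded away from zero.
    Efficacy keys are probe sequence classes; pool noise rates default
    to zero. ``probe_placement`` is ``"even"`` (deterministic, equal
    spacing, like a spacing-optimized probe panel) or ``"uniform"``
    (random loci).
    """

    genome_size_kb: float = FULL_GENOME_KB
    n_clones: int = FULL_N_CLONES
    insert_mean_kb: float = INSERT_MEAN_KB
    insert_sd_kb: float = 30.0
    n_filters: int = 11
    filters_used: int = 4
    efficacy: dict = field(default_factory=lambda: dict(DEFAULT_EFFICACY))
    pool_fp_rate: float = 0.0
    pool_fn_rate: float = 0.0
    probe_placement: str = "even"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size_kb <= 0 or self.n_clones <= 0 or self.insert_mean_kb <= 0:
            raise ConfigurationError("sizes must be positive")
        if self.insert_mean_kb >= self.genome_size_kb:
            raise ConfigurationError("mean insert exceeds genome size")
        if not (0 < self.filters_used <= self.n_filters):
            raise ConfigurationError("need 0 < filters_used <= n_filters")
        for k, v in self.efficacy.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"efficacy[{k!r}] outside [0, 1]")
        for r in (self.pool_fp_rate, self.pool_fn_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("noise rates must be in [0, 1]")
        if self.probe_placement not in ("even", "uniform"):
            raise ConfigurationError(f"unknown placement {self.probe_placement!r}")

    @classmethod
    def desk(cls, **overrides) -> "SimConfig":
        """Scaled-down configuration preserving the fold coverages."""
        base = dict(n_clones=DESK_N_CLONES, genome_size_kb=DESK_GENOME_KB)
        base.update(overrides)
        return cls(**base)

    # -- derived quantities -------------------------------------------
    @property
    def full_fold(self) -> float:
        return self.n_clones * self.insert_mean_kb / self.genome_size_kb

    @property
    def n_screened(self) -> int:
        """Clones on the screened filter subset."""
        return int(round(self.n_clones * self.filters_used / self.n_filters))

    @property
    def screened_fold(self) -> float:
        return self.full_fold * self.filters_used / self.n_filters


@dataclass
class SimResult:
    """Planted truth plus observable pool calls (and the intermediates)."""

    truth: pd.DataFrame            # clone_id, probe_id (true hits)
    calls: pd.DataFrame            # clones x pool labels, bool
    library: pd.DataFrame          # screened clones: clone_id, start_kb, length_kb
    probe_positions: pd.Series     # probe_id -> locus position (Kb)
    effective_probes: pd.Series    # probe_id -> bool (efficacy draw)

    def __iter__(self):  # allows: truth, calls = simulate_screen(...)
        return iter((self.truth, self.calls))


def simulate_library(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw the full clone library: uniform starts, truncated-normal lengths."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = 1.0, cfg.genome_size_kb
    a = (lo - cfg.insert_mean_kb) / cfg.insert_sd_kb
    b = (hi - cfg.insert_mean_kb) / cfg.insert_sd_kb
    lengths = sps.truncnorm.rvs(
        a, b, loc=cfg.insert_mean_kb, scale=cfg.insert_sd_kb,
        size=cfg.n_clones, random_state=rng,
    )
    starts = rng.uniform(0.0, cfg.genome_size_kb - lengths)
    return pd.DataFrame(
        {
            "clone_id": [f"bac{i + 1:06d}" for i in range(cfg.n_clones)],
            "start_kb": starts,
            "length_kb": lengths,
        }
    )


def assign_probe_loci(
    probes: pd.DataFrame, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> pd.Series:
    """Place probe loci on the simulated genome (Kb coordinates)."""
    n = len(probes)
    if cfg.probe_placement == "even":
        pos = np.arange(1, n + 1) * cfg.genome_size_kb / (n + 1)
    else:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        pos = rng.uniform(0.0, cfg.genome_size_kb, size=n)
    return pd.Series(pos, index=probes["probe_id"].astype(str), name="pos_kb")


def simulate_screen(
    cfg: SimConfig,
    probes: pd.DataFrame,
    design: PoolingDesign,
) -> SimResult:
    """Simulate one full screening round.

    Draws the library, screens the filter-subset clones against
    per-probe efficacy draws (Bernoulli by ``seq_class``), plants hits
    wherever an effective probe's locus falls inside a clone insert,
    unions each clone's hit probes' pools into true calls, then applies
    the pool noise rates. Fully reproducible from ``cfg.seed``.
    """
    missing = set(map(str, probes["probe_id"])) - set(design.probe_order)
    if missing:
        raise ValueError(f"probes not in design: {sorted(missing)[:5]}...")
    if "seq_class" not in probes.columns:
        raise ValueError("probe table needs a seq_class column")
    unknown = set(probes["seq_class"]) - set(cfg.efficacy)
    if unknown:
        raise ValueError(f"no efficacy for classes {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    library = simulate_library(cfg, rng)
    positions = assign_probe_loci(probes, cfg, rng)
    eff_p = probes["seq_class"].map(cfg.efficacy).to_numpy(float)
    effective = rng.random(len(probes)) < eff_p
    effective = pd.Series(effective, index=positions.index, name="effective")

    screened = library.iloc[: cfg.n_screened].reset_index(drop=True)
    starts = screened["start_kb"].to_numpy()
    ends = starts + screened["length_kb"].to_numpy()
    pos = positions.to_numpy()
    # hits: clone interval [start, end) contains an effective probe's locus
    hit = (
        (starts[:, None] <= pos[None, :])
        & (pos[None, :] < ends[:, None])
        & effective.to_numpy()[None, :]
    )

    ci, pi = np.nonzero(hit)
    truth = pd.DataFrame(
        {
            "clone_id": screened["clone_id"].to_numpy()[ci],
            "probe_id": positions.index.to_numpy()[pi],
        }
    ).sort_values(["clone_id", "probe_id"], ignore_index=True)

    # align hit columns to design probe order, then project to pools
    order = {pid: j for j, pid in enumerate(design.probe_order)}
    cols = np.array([order[p] for p in positions.index])
    hit_by_design = np.zeros((len(screened), design.n_probes), dtype=bool)
    hit_by_design[:, cols] = hit
    m = design.membership_matrix().astype(np.int32)
    # union of hit probes' pools: positive count -> positive call
    calls_arr = (hit_by_design.astype(np.int32) @ m) > 0

    if cfg.pool_fn_rate > 0:
        drop = rng.random(calls_arr.shape) < cfg.pool_fn_rate
        calls_arr = calls_arr & ~drop
    if cfg.pool_fp_rate > 0:
        add = rng.random(calls_arr.shape) < cfg.pool_fp_rate
        calls_arr = calls_arr | add

    calls = pd.DataFrame(
        calls_arr,
        index=pd.Index(screened["clone_id"], name="clone_id"),
        columns=[p.label for p in design.pools],
    )
    return SimResult(truth, calls, screened, positions, effective)
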