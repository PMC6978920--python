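"""Synthetic inputs with planted ground truth.

Every downstream stage of the pipeline is exercised on data this module
generates: ROI time series drawn from a planted block/hub correlation
structure, T-maze trial logs with a tunable lateral response bias, and
catFISH cell populations whose nuclear/cytoplasmic labels are known by
construction.  All generators are deterministic given their seed.

Default study conditions: 150 ROIs (75 bilateral regions), 300 volumes at
2 s sampling (a 10 min acquisition), 32 object-choice trials per testing day,
and 20-plane confocal z-stacks at 1 um spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .types import NuisanceSet, RoiTimeSeriesSet

__all__ = [
    "TimeSeriesSimConfig",
    "BehaviorSimConfig",
    "CellSimConfig",
    "SimCellRecord",
    "default_roi_labels",
    "planted_correlation",
    "gen_roi_timeseries",
    "gen_trial_log",
    "gen_cell_population",
]


# ---------------------------------------------------------------------------
# ROI time series
# ---------------------------------------------------------------------------

def default_roi_labels(n_rois: int, special: Sequence[str] = ("ACC", "DLS", "DMS")) -> list[str]:
    """Bilateral label scheme: ``special`` regions first, then ``rNNN``, each
    with ``_L``/``_R`` hemisphere suffixes.  Odd ``n_rois`` gets one final
    midline region."""
    n_regions = n_rois // 2
    names = list(special)[:n_regions]
    names += [f"r{i:03d}" for i in range(len(names), n_regions)]
    labels: list[str] = []
    for name in names:
        labels += [f"{name}_L", f"{name}_R"]
    if n_rois % 2:
        labels.append("midline")
    return labels


@dataclass
class TimeSeriesSimConfig:
    """Parameters of one simulated resting-state acquisition.

    ``block_structure`` partitions ROI indices into modules, each with a
    within-module correlation target; ``hub_set`` indices additionally get
    elevated cross-module correlation (``hub_r`` among hubs, ``hub_out_r``
    from hubs to non-hubs) — the planted rich club.  ``seed_pair_r``
    overrides the correlation of one named ROI pair, which is how group- or
    session-specific seed connectivity (e.g. an ACC-DS increase) is planted.
    """

    n_rois: int = 150
    n_volumes: int = 300
    dt: float = 2.0
    block_structure: Optional[list[tuple[list[int], float]]] = None
    base_r: float = 0.05
    hub_set: tuple[int, ...] = ()
    hub_r: float = 0.45
    hub_out_r: float = 0.25
    seed_pair: Optional[tuple[str, str] | list[tuple[str, str]]] = None
    seed_pair_r: Optional[float] = None
    roi_labels: Optional[list[str]] = None
    signal_band: Optional[tuple[float, float]] = (0.01, 0.1)
    drift_amplitude: float = 1.0
    nuisance_amplitude: float = 0.5
    noise_sd: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2 or self.n_volumes < 4 or self.dt <= 0:
            raise ValueError("need n_rois >= 2, n_volumes >= 4, dt > 0")
        if self.roi_labels is None:
            self.roi_labels = default_roi_labels(self.n_rois)
        if len(self.roi_labels) != self.n_rois:
            raise ValueError("roi_labels length must equal n_rois")
        if self.block_structure is None:
            self.block_structure = self._default_blocks()
        covered = sorted(i for members, _ in self.block_structure for i in members)
        if covered != list(range(self.n_rois)):
            raise ValueError("block_structure must partition all ROIs exactly once")
        targets = [r for _, r in self.block_structure] + [self.base_r, self.hub_r, self.hub_out_r]
        if self.seed_pair_r is not None:
            targets.append(self.seed_pair_r)
        for r in targets:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"correlation target {r} outside [0, 1]")

    def _default_blocks(self, n_blocks: int = 6, within_r: float = 0.35) -> list[tuple[list[int], float]]:
        bounds = np.linspace(0, self.n_rois, min(n_blocks, self.n_rois) + 1).astype(int)
        return [(list(range(a, b)), within_r) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def planted_correlation(config: TimeSeriesSimConfig) -> np.ndarray:
    """Target ROI x ROI correlation matrix, projected to the nearest valid
    (positive semidefinite, unit-diagonal) correlation matrix by eigenvalue
    clipping."""
    n = config.n_rois
    C = np.full((n, n), config.base_r)
    for members, r in config.block_structure:
        idx = np.asarray(members)
        C[np.ix_(idx, idx)] = r
    if config.hub_set:
        hubs = np.asarray(config.hub_set)
        others = np.asarray([i for i in range(n) if i not in set(config.hub_set)])
        if others.size:
            C[np.ix_(hubs, others)] = np.maximum(C[np.ix_(hubs, others)], config.hub_out_r)
            C[np.ix_(others, hubs)] = C[np.ix_(hubs, others)].T
        C[np.ix_(hubs, hubs)] = np.maximum(C[np.ix_(hubs, hubs)], config.hub_r)
    if config.seed_pair is not None:
        if config.seed_pair_r is None:
            raise ValueError("seed_pair given without seed_pair_r")
        pairs = config.seed_pair
        if pairs and isinstance(pairs[0], str):
            pairs = [pairs]  # single (a, b) pair
        for a, b in pairs:
            i = config.roi_labels.index(a)
            j = config.roi_labels.index(b)
            C[i, j] = C[j, i] = config.seed_pair_r
    np.fill_diagonal(C, 1.0)
    # nearest-PSD projection: clip negative eigenvalues, restore unit diagonal
    w, V = np.linalg.eigh((C + C.T) / 2)
    if w.min() < 0:
        C = (V * np.clip(w, 0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    return C


def _motion_like(rng: np.random.Generator, t: np.ndarray, n: int = 6) -> np.ndarray:
    """Six smooth motion-like regressors: sums of slow sinusoids with random
    frequencies below 0.01 Hz plus a small random-walk component."""
    out = np.empty((n, t.size))
    for i in range(n):
        freqs = rng.uniform(0.001, 0.009, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = rng.uniform(0.3, 1.0, size=3)
        out[i] = sum(a * np.sin(2 * np.pi * f * t + p) for a, f, p in zip(amps, freqs, phases))
        walk = np.cumsum(rng.normal(0, 0.02, size=t.size))
        out[i] += walk - walk.mean()
    return out


def gen_roi_timeseries(config: TimeSeriesSimConfig) -> RoiTimeSeriesSet:
    """Simulate one subject/session of ROI signals.

    Latent signals are drawn from a multivariate normal with the planted
    correlation matrix, band-limited to ``signal_band`` so they survive the
    preprocessing chain, then contaminated with per-ROI linear+quadratic
    drift, shared nuisance components (two slow sinusoids, the ventricular
    and white-matter proxies, and six motion-like regressors with random
    per-ROI loadings) and white noise.  The generated confounds ride along on
    the returned set (``.confounds``) as ground truth for nuisance
    regression.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, T = config.n_rois, config.n_volumes
    C = planted_correlation(config)
    w, V = np.linalg.eigh(C)
    A = V * np.sqrt(np.clip(w, 0, None))  # C = A @ A.T
    latent = rng.standard_normal((T, n)) @ A.T  # time x roi

    if config.signal_band is not None:
        low, high = config.signal_band
        nyq = 1.0 / (2 * config.dt)
        if not 0 < low < high < nyq:
            raise ValueError("signal_band must satisfy 0 < low < high < Nyquist")
        b, a = sps.butter(2, [low / nyq, high / nyq], btype="band")
        latent = sps.filtfilt(b, a, latent, axis=0)
    sd = latent.std(axis=0)
    sd[sd == 0] = 1.0
    latent = latent / sd

    t = np.arange(T, dtype=float) * config.dt
    tc = (t - t.mean()) / (t.max() - t.min() if T > 1 else 1.0)
    drift = (
        rng.normal(0, 1, size=(n, 1)) * tc
        + rng.normal(0, 1, size=(n, 1)) * (tc**2 - np.mean(tc**2))
    ) * config.drift_amplitude

    slow = np.vstack([
        np.sin(2 * np.pi * 0.003 * t + rng.uniform(0, 2 * np.pi)),
        np.sin(2 * np.pi * 0.007 * t + rng.uniform(0, 2 * np.pi)),
    ])
    motion = _motion_like(rng, t)
    csf = slow[0] + rng.normal(0, 0.1, size=T)
    wm = slow[1] + rng.normal(0, 0.1, size=T)
    confounds = np.vstack([motion, csf, wm])
    loadings = rng.normal(0, 1, size=(n, confounds.shape[0]))
    nuisance = config.nuisance_amplitude * loadings @ confounds

    noise = config.noise_sd * rng.standard_normal((n, T))
    signals = latent.T + drift + nuisance + noise

    names = [f"motion{i}" for i in range(6)] + ["csf", "white_matter"]
    return RoiTimeSeriesSet(
        signals=signals,
        roi_labels=list(config.roi_labels),
        dt=config.dt,
        confounds=NuisanceSet(confounds, names=names),
    )


# ---------------------------------------------------------------------------
# Behavioral trial logs
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """One simulated rat's testing block on the continuous T-maze.

    ``side_bias`` is the probability that an object choice lands on the
    rat's fixed preferred side (left well); 0.5 means no lateral preference.
    ``p_wme`` is the per-attempt probability of a same-direction turn, which
    is recorded as a working-memory error and not logged as a trial.
    """

    n_trials_per_day: int = 32
    n_days: int = 1
    side_bias: float = 0.5
    p_correct: Sequence[float] = (0.5,)
    p_wme: float = 0.0
    preferred_side: str = "left_well"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_day < 1 or self.n_days < 1:
            raise ValueError("need at least one trial and one day")
        probs = [self.side_bias, self.p_wme, *self.p_correct]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.p_correct) != self.n_days:
            raise ValueError("p_correct trajectory length must equal n_days")
        if self.preferred_side not in ("left_well", "right_well"):
            raise ValueError("preferred_side must be left_well or right_well")


def gen_trial_log(config: BehaviorSimConfig):
    """Simulate an ordered trial log.

    Turn directions alternate; each attempt fails to alternate with
    probability ``p_wme`` (a WME record carrying no object choice).  Object
    choices land on the preferred side with probability ``side_bias`` and are
    correct with that day's ``p_correct``.  Days run until the configured
    number of object-choice trials is logged.
    """
    from .behavior import TrialLog, TrialRecord  # local import avoids a cycle

    rng = np.random.default_rng(config.rng_seed)
    other = "right_well" if config.preferred_side == "left_well" else "left_well"
    records: list[TrialRecord] = []
    for day in range(config.n_days):
        direction = "left" if rng.random() < 0.5 else "right"
        logged = 0
        while logged < config.n_trials_per_day:
            if rng.random() < config.p_wme:
                # failed to alternate: same turn direction, no object choice
                records.append(TrialRecord(day=day, kind="wme", turn=direction))
                continue
            direction = "right" if direction == "left" else "left"
            side = config.preferred_side if rng.random() < config.side_bias else other
            correct = bool(rng.random() < config.p_correct[day])
            records.append(
                TrialRecord(day=day, kind="object_choice", turn=direction,
                            side=side, correct=correct)
            )
            logged += 1
    return TrialLog(records)


# ---------------------------------------------------------------------------
# catFISH cell populations
# ---------------------------------------------------------------------------

@dataclass
class CellSimConfig:
    """A simulated imaged cell population for the catFISH classifier.

    Class fractions are the planted ground truth: nuclear-only cells carry
    1-2 foci on >= 4 consecutive planes, cytoplasmic-only cells carry
    perimeter coverage >= 1/3 on >= 2 adjacent planes, double-labelled cells
    both, negatives neither (sub-threshold runs only).
    """

    n_cells: int = 500
    n_planes: int = 20
    frac_nuclear: float = 0.2
    frac_cytoplasmic: float = 0.1
    frac_double: float = 0.05
    frac_negative: float = 0.65
    edge_cut_fraction: float = 0.0
    region: str = "ACC"
    hemisphere: str = "left"
    rat_id: str = "rat0"
    image_id: str = "img0"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_nuclear + self.frac_cytoplasmic + self.frac_double + self.frac_negative
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        if self.n_planes < 5:
            raise ValueError("need at least 5 optical planes")
        if not 0.0 <= self.edge_cut_fraction <= 1.0:
            raise ValueError("edge_cut_fraction must lie in [0, 1]")


@dataclass
class SimCellRecord:
    """Ground-truth wrapper: a generated cell plus its planted class label."""

    cell: "object"  # catfish.CellRecord
    true_label: str


def _nuclear_planes(rng: np.random.Generator, foci: np.ndarray, lo: int, hi: int) -> None:
    """Plant a run of 1-2 foci on 4-6 consecutive planes inside [lo, hi)."""
    run = int(rng.integers(4, 7))
    run = min(run, hi - lo)
    start = int(rng.integers(lo, hi - run + 1))
    foci[start:start + run] = rng.integers(1, 3, size=run)


def _cyto_planes(rng: np.random.Generator, cov: np.ndarray, lo: int, hi: int) -> None:
    """Plant coverage >= 1/3 on 2-4 adjacent planes inside [lo, hi)."""
    run = int(rng.integers(2, 5))
    run = min(run, hi - lo)
    start = int(rng.integers(lo, hi - run + 1))
    cov[start:start + run] = rng.uniform(0.34, 0.85, size=run)


def gen_cell_population(config: CellSimConfig) -> list[SimCellRecord]:
    """Generate cells with known labels.

    Negatives get only sub-threshold patterns (foci runs of at most 3
    planes, or isolated single planes of high coverage) so the rule-based
    classifier must respect the run-length boundaries exactly.
    """
    from .catfish import CellRecord

    rng = np.random.default_rng(config.rng_seed)
    # exact class counts (largest-remainder rounding) so the planted
    # fractions are population ground truth, not a multinomial draw
    names = ["nuclear", "cytoplasmic", "double", "negative"]
    fracs = np.array([config.frac_nuclear, config.frac_cytoplasmic,
                      config.frac_double, config.frac_negative])
    counts = np.floor(fracs * config.n_cells).astype(int)
    remainder = fracs * config.n_cells - counts
    for i in np.argsort(-remainder)[: config.n_cells - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    n_p = config.n_planes
    out: list[SimCellRecord] = []
    for i, label in enumerate(labels):
        # visible range always spans the central window of the stack and is
        # wide enough (>= 6 planes) to host the longest planted run
        mid = n_p // 2
        first = int(rng.integers(0, max(1, mid - 3))) + 1
        last = int(rng.integers(min(mid + 2, n_p - 1), n_p)) + 1
        lo, hi = first - 1, last  # 0-based plane span the cell occupies
        foci = np.zeros(n_p, dtype=int)
        cov = np.zeros(n_p)
        cov[lo:hi] = rng.uniform(0.0, 0.30, size=hi - lo)
        if label in ("nuclear", "double"):
            _nuclear_planes(rng, foci, lo, hi)
        if label in ("cytoplasmic", "double"):
            _cyto_planes(rng, cov, lo, hi)
        if label == "negative" and hi - lo >= 1:
            if rng.random() < 0.5:  # sub-threshold foci run (<= 3 planes)
                run = min(int(rng.integers(1, 4)), hi - lo)
                start = int(rng.integers(lo, hi - run + 1))
                foci[start:start + run] = rng.integers(1, 3, size=run)
            if rng.random() < 0.3:  # isolated high-coverage plane
                cov[int(rng.integers(lo, hi))] = rng.uniform(0.34, 0.8)
        cell = CellRecord(
            cell_id=f"{config.image_id}_c{i:04d}",
            n_planes_in_stack=n_p,
            foci_per_plane=foci,
            coverage_per_plane=cov,
            visible_plane_range=(first, last),
            edge_cut=bool(rng.random() < config.edge_cut_fraction),
            region=config.region,
            hemisphere=config.hemisphere,
            rat_id=config.rat_id,
            image_id=config.image_id,
        )
        out.append(SimCellRecord(cell=cell, true_label=str(label)))
    return out
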