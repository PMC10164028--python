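"""Synthetic study generator with planted condition-specific connectivity.

Emulates the structure of a two-group block-design meditation fMRI study:
an expert group (n=12) and a novice group (n=10), each subject scanned in
2 conditions (focused attention, FA; open monitoring, OM) x 3 blocks, with
~88 volumes per 6-minute block at TR = 4.087 s.

The forward model is a stationary multivariate Gaussian per block.  A
baseline correlation structure places correlation ``rho_net`` on
within-network ROI pairs and 0 elsewhere; condition effects are planted on a
chosen set of edges in Fisher-z units, split symmetrically about the FA/OM
midpoint (+dz/2 in FA, -dz/2 in OM, sign flipped for OM-tagged effects) and
scaled per group.  Because the downstream analysis consumes only Pearson
correlations, Gaussian structure is sufficient; no hemodynamic response or
scanner noise spectrum is modelled (an optional AR(1) coefficient adds
temporal smoothness without changing the stationary covariance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .parcellation import ParcellationTable, build_edge_table, parcellation_from_lists
from .util import ConfigurationError, ValidationError, log, rng_stream

CONDITIONS = ("FA", "OM")
GROUPS = ("expert", "novice")


# ---------------------------------------------------------------------------
# containers

@dataclass
class ROITimeSeries:
    """ROI-averaged BOLD-like series: (n_volumes x n_rois) plus volume mask."""

    values: np.ndarray          # (n_volumes, n_rois) float
    tr: float                   # seconds
    volume_mask: np.ndarray | None = None  # bool per *original* volume

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValidationError("time series must be (n_volumes >= 2, n_rois)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if self.volume_mask is None:
            self.volume_mask = np.ones(self.values.shape[0], dtype=bool)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionParams:
    """Rigid-body motion estimates: 3 translations (mm) + 3 rotations (rad)."""

    values: np.ndarray  # (n_volumes, 6)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValidationError("motion parameters must be (n_volumes, 6)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("motion parameters contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EffectSpec:
    """One planted connectivity effect.

    ``dz`` is the full FA-minus-OM Fisher-z difference at group scale 1;
    ``condition`` names the condition in which the edge is *more* correlated.
    """

    roi_i: int
    roi_j: int
    dz: float
    condition: Literal["FA", "OM"] = "FA"

    @property
    def signed_dz(self) -> float:
        """FA-positive signed z-difference (z_FA - z_OM)."""
        return self.dz if self.condition == "FA" else -self.dz


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: {"expert": 12, "novice": 10})
    n_blocks_per_condition: int = 3
    n_volumes: int = 88
    tr: float = 4.087
    rho_net: float = 0.35
    effects: tuple[EffectSpec, ...] | None = None  # None -> default_effects
    n_effect_edges: int = 20
    effect_dz: float = 0.5
    group_scale: Mapping[str, float] = field(
        default_factory=lambda: {"expert": 1.0, "novice": 0.15})
    noise_sd: float = 0.2
    subject_jitter_sd: float = 0.02
    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"expert": (37.9, 9.4), "novice": (33.0, 4.0)})
    motion_spike_prob: float = 0.05
    motion_spike_mm: float = 1.0
    motion_drift_sd: float = 0.02
    n_confounds: int = 2
    confound_loading: float = 0.1
    age_confound_scale: float = 0.0  # optional per-year feature shift (z units)
    ar_coef: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_subjects.items():
            if n < 1:
                raise ConfigurationError(f"n_subjects[{g}] must be >= 1")
        if self.n_blocks_per_condition < 1 or self.n_volumes < 2:
            raise ConfigurationError("block/volume counts must be positive")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if not -0.99 < self.rho_net < 0.99:
            raise ConfigurationError("rho_net must lie in (-0.99, 0.99)")
        if not 0 <= self.ar_coef < 1:
            raise ConfigurationError("ar_coef must lie in [0, 1)")


@dataclass
class BlockRecord:
    group: str
    subject: str
    condition: str
    block: int
    ts: ROITimeSeries
    motion: MotionParams | None = None
    confounds: np.ndarray | None = None  # (n_volumes, n_confounds)
    usable: bool = True


@dataclass
class StudyDataset:
    """All blocks of a simulated (or loaded) study plus ground truth."""

    blocks: list[BlockRecord]
    ages: dict[tuple[str, str], float]         # (group, subject) -> years
    true_dz: dict[str, np.ndarray]             # group -> (n_edges,) z_FA - z_OM
    parcellation: ParcellationTable
    config: SimulationConfig | None = None

    def group_blocks(self, group: str) -> list[BlockRecord]:
        return [b for b in self.blocks if b.group == group]

    def subjects(self, group: str) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.blocks:
            if b.group == group:
                seen.setdefault(b.subject, None)
        return list(seen)


# ---------------------------------------------------------------------------
# covariance construction

def _nearest_spd(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and restore a unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    floor = eps * max(vals.max(), 1.0)
    if vals.min() < floor:
        vals = np.clip(vals, floor, None)
        sym = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(sym))
    sym = sym / np.outer(d, d)
    np.fill_diagonal(sym, 1.0)
    return sym


def baseline_correlation(parcellation: ParcellationTable, rho_net: float) -> np.ndarray:
    nets = parcellation.network_labels
    same = nets[:, None] == nets[None, :]
    corr = np.where(same, rho_net, 0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def default_effects(parcellation: ParcellationTable,
                    n_edges: int, dz: float, seed: int) -> tuple[EffectSpec, ...]:
    """Draw ``n_edges`` distinct random edges; alternate FA/OM attribution."""
    edges = build_edge_table(parcellation)
    rng = rng_stream(seed, "planted-effects")
    if n_edges > edges.n_edges:
        log.info("default_effects: capping planted edges at %d", edges.n_edges)
        n_edges = edges.n_edges
    chosen = rng.choice(edges.n_edges, size=n_edges, replace=False)
    chosen.sort()
    return tuple(
        EffectSpec(int(edges.roi_i[e]), int(edges.roi_j[e]), dz,
                   "FA" if k % 2 == 0 else "OM")
        for k, e in enumerate(chosen)
    )


def resolve_effects(parcellation: ParcellationTable,
                    config: SimulationConfig) -> tuple[EffectSpec, ...]:
    if config.effects is not None:
        return tuple(config.effects)
    if config.n_effect_edges == 0:
        return ()
    return default_effects(parcellation, config.n_effect_edges,
                           config.effect_dz, config.seed)


def build_condition_covariance(parcellation: ParcellationTable,
                               config: SimulationConfig,
                               condition: str,
                               subject_seed: int,
                               group_scale: float = 1.0,
                               effects: Sequence[EffectSpec] | None = None,
                               ) -> np.ndarray:
    """Per-subject, per-condition correlation (= covariance, unit variance).

    Starts from the network-block baseline, adds a subject-specific symmetric
    jitter in Fisher-z space (shared across conditions for the subject), then
    shifts each planted edge by +/- group_scale*dz/2 in z so that, to first
    order, z(FA) - z(OM) on that edge equals group_scale * signed dz.  The
    result is repaired to the nearest SPD correlation matrix if needed.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"condition must be one of {CONDITIONS}")
    if effects is None:
        effects = resolve_effects(parcellation, config)
    corr = baseline_correlation(parcellation, config.rho_net)
    n = parcellation.n_rois
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(corr, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, 0.0)
    if config.subject_jitter_sd > 0:
        rng = rng_stream(config.seed, "subject-jitter", subject_seed)
        jit = rng.normal(0.0, config.subject_jitter_sd, size=(n, n))
        jit = np.triu(jit, k=1)
        z = z + jit + jit.T
    sign = 1.0 if condition == "FA" else -1.0
    for eff in effects:
        delta = sign * group_scale * eff.signed_dz / 2.0
        z[eff.roi_i, eff.roi_j] += delta
        z[eff.roi_j, eff.roi_i] += delta
    corr = np.tanh(z)
    np.fill_diagonal(corr, 1.0)
    corr = _nearest_spd(corr)
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ConfigurationError("covariance not repairable to SPD")
    return corr


# ---------------------------------------------------------------------------
# sampling

def simulate_block(cov: np.ndarray, n_volumes: int, noise_sd: float,
                   rng_seed: int, tr: float = 4.087,
                   ar_coef: float = 0.0) -> ROITimeSeries:
    """Draw a block of BOLD-like samples from N(0, cov) + white noise.

    With ``ar_coef`` = phi > 0 the latent signal follows a stationary AR(1)
    process whose marginal covariance is still ``cov`` (innovations scaled by
    sqrt(1 - phi^2)), adding temporal smoothness without biasing correlations.
    """
    cov = np.asarray(cov, dtype=float)
    n_rois = cov.shape[0]
    if n_volumes < n_rois:
        warnings.warn(
            f"n_volumes ({n_volumes}) < n_rois ({n_rois}): sample correlation "
            "matrices will be rank-deficient", stacklevel=2)
    rng = rng_stream(rng_seed, "block")
    chol = np.linalg.cholesky(cov)
    innov = rng.standard_normal((n_volumes, n_rois)) @ chol.T
    if ar_coef > 0:
        sig = np.empty_like(innov)
        scale = np.sqrt(1.0 - ar_coef ** 2)
        sig[0] = innov[0]
        for t in range(1, n_volumes):
            sig[t] = ar_coef * sig[t - 1] + scale * innov[t]
    else:
        sig = innov
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    return ROITimeSeries(values=sig, tr=tr)


def simulate_motion(n_volumes: int, spike_prob: float, spike_mm: float,
                    seed: int, drift_sd: float = 0.02) -> MotionParams:
    """Smooth low-amplitude drift plus Bernoulli displacement spikes.

    Spikes place a translation jump of ``spike_mm`` on one axis so that the
    framewise displacement at that volume exceeds the jump size.
    """
    if not 0 <= spike_prob <= 1:
        raise ConfigurationError("spike_prob must lie in [0, 1]")
    rng = rng_stream(seed, "motion")
    # translations drift in mm; rotation drift scaled so its FD contribution
    # (x50 mm head radius) matches the translational one
    scales = np.array([drift_sd] * 3 + [drift_sd / 50.0] * 3)
    drift = np.cumsum(rng.normal(0.0, 1.0, size=(n_volumes, 6)) * scales, axis=0)
    if drift_sd == 0:
        drift = np.zeros((n_volumes, 6))
    vals = drift.copy()
    if spike_prob > 0 and spike_mm != 0:
        spikes = rng.random(n_volumes) < spike_prob
        spikes[0] = False
        axis = rng.integers(0, 3, size=n_volumes)
        for t in np.nonzero(spikes)[0]:
            vals[t:, axis[t]] += spike_mm  # step displacement at volume t
    return MotionParams(values=vals)


def generate_study(parcellation: ParcellationTable,
                   config: SimulationConfig) -> StudyDataset:
    """Simulate both groups: subjects x 2 conditions x blocks, plus ages.

    The ground-truth effect map records, per group, the planted z(FA)-z(OM)
    difference on every edge (0 off the planted set).
    """
    edges = build_edge_table(parcellation)
    effects = resolve_effects(parcellation, config)
    true_dz: dict[str, np.ndarray] = {}
    blocks: list[BlockRecord] = []
    ages: dict[tuple[str, str], float] = {}
    for gi, group in enumerate(sorted(config.n_subjects)):
        scale = config.group_scale.get(group, 1.0)
        dz_map = np.zeros(edges.n_edges)
        for eff in effects:
            dz_map[edges.encode(eff.roi_i, eff.roi_j)] = scale * eff.signed_dz
        true_dz[group] = dz_map
        mean, sd = config.age_mean_sd.get(group, (35.0, 8.0))
        age_rng = rng_stream(config.seed, "ages", gi)
        for si in range(config.n_subjects[group]):
            subject = f"{group}{si:02d}"
            subject_seed = gi * 1000 + si
            ages[(group, subject)] = float(age_rng.normal(mean, sd))
            covs = {
                c: build_condition_covariance(
                    parcellation, config, c, subject_seed,
                    group_scale=scale, effects=effects)
                for c in CONDITIONS
            }
            if config.age_confound_scale:
                covs = {c: _inject_age_confound(
                    covs[c], ages[(group, subject)], config) for c in CONDITIONS}
            for condition in CONDITIONS:
                for b in range(config.n_blocks_per_condition):
                    block_seed = ((gi * 1000 + si) * 10 + CONDITIONS.index(condition)) * 10 + b
                    ts = simulate_block(
                        covs[condition], config.n_volumes, config.noise_sd,
                        rng_seed=config.seed * 100003 + block_seed,
                        tr=config.tr, ar_coef=config.ar_coef)
                    motion = simulate_motion(
                        config.n_volumes, config.motion_spike_prob,
                        config.motion_spike_mm,
                        seed=config.seed * 100003 + block_seed + 7,
                        drift_sd=config.motion_drift_sd)
                    conf = _simulate_confounds(ts, config, block_seed)
                    blocks.append(BlockRecord(group, subject, condition, b,
                                              ts, motion, conf))
    log.info("generated study: %d blocks, %d planted effects",
             len(blocks), len(effects))
    return StudyDataset(blocks=blocks, ages=ages, true_dz=true_dz,
                        parcellation=parcellation, config=config)


def _simulate_confounds(ts: ROITimeSeries, config: SimulationConfig,
                        block_seed: int) -> np.ndarray | None:
    """WM/CSF-like surrogate channels, mixed into every ROI with small loading."""
    if config.n_confounds == 0:
        return None
    rng = rng_stream(config.seed, "confounds", block_seed)
    conf = rng.standard_normal((ts.n_volumes, config.n_confounds))
    if config.confound_loading:
        ts.values += config.confound_loading * conf.sum(axis=1, keepdims=True)
    return conf


def _inject_age_confound(corr: np.ndarray, age: float,
                         config: SimulationConfig) -> np.ndarray:
    """Optional control-analysis knob: shift all correlations linearly in age."""
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(corr, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(z, 0.0)
    z = z + config.age_confound_scale * (age - 35.0) * (1 - np.eye(corr.shape[0]))
    out = np.tanh(z)
    np.fill_diagonal(out, 1.0)
    return _nearest_spd(out)


def toy_parcellation(n_rois: int = 20, n_networks: int = 4) -> ParcellationTable:
    """Small balanced parcellation for fast simulations and tests.

    ROIs alternate left/right within each network (midline-free).
    """
    names, nets, hemis = [], [], []
    per = max(n_rois // n_networks, 1)
    for i in range(n_rois):
        net = f"net{min(i // per, n_networks - 1)}"
        h = "L" if i % 2 == 0 else "R"
        names.append(f"roi{i:02d}_{h}")
        nets.append(net)
        hemis.append(h)
    return parcellation_from_lists(names, nets, hemis)


def null_config(**overrides) -> SimulationConfig:
    """Config with no planted effects (null study)."""
    base = dict(n_effect_edges=0, effects=())
    base.update(overrides)
    return SimulationConfig(**base)
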