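"""Synthetic BOLD-like cohorts with piecewise-stationary covariance
regimes, structural connectomes coupled to the functional states, and an
ordered "arousal" axis.

The generator emulates the statistical structure the downstream analysis
assumes: region-by-time series whose instantaneous covariance switches
between a small set of states (first-order Markov regimes with tunable
dwell time and transition smoothness), optionally anchored to a
structural connectome. A cohort spans ordered conditions from least to
most aware; lower-awareness conditions are planted with longer regime
dwell times, wider (more sluggish) transitions, and tighter
structure-function coupling, so that recovering the corresponding
contrasts is a meaningful end-to-end test of the analysis pipeline.

Everything is a pure function of its configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .windows import RegionTimeSeries

__all__ = [
    "SimulationConfig",
    "CohortSpec",
    "StructuralConnectome",
    "Subject",
    "generate_structural_connectome",
    "generate_regime_sequence",
    "generate_bold",
    "generate_cohort",
    "arousal_overrides",
]

log = logging.getLogger(__name__)

#: number of latent factors in each state's random covariance component
N_FACTORS = 3
#: diagonal floor added to the factor-model covariance
DIAG_FLOOR = 0.1
#: inverse temperature of the communicability SC-derived covariance
SC_COMM_BETA = 4.0


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric nonnegative R x R weight matrix with zero diagonal
    (stands in for a streamline-count connectome)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.diag(w).any():
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        """Nonzero strict-upper-triangle cells."""
        iu = np.triu_indices(self.n_regions, k=1)
        return int((self.weights[iu] > 0).sum())


@dataclass(frozen=True)
class SimulationConfig:
    """Single-subject generator settings.

    Defaults emulate a 5-minute resting-state acquisition less the first
    five volumes (145 volumes at TR = 2 s) parcellated into 30 regions,
    with five covariance states.
    """

    n_regions: int = 30
    n_timepoints: int = 145
    tr_seconds: float = 2.0
    n_states: int = 5
    mean_dwell: float = 20.0          # timepoints
    transition_width: int = 8         # timepoints of linear covariance blending
    noise_sd: float = 0.3
    sc_coupling: float = 0.26         # in [0, 1]
    ar_coefficient: float = 0.4       # in [0, 1)
    state_jitter: float = 0.11        # in [0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_timepoints < 2:
            raise ValueError("n_regions >= 1 and n_timepoints >= 2 required")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.mean_dwell < 1:
            raise ValueError("mean_dwell must be >= 1 timepoint")
        if self.transition_width < 0:
            raise ValueError("transition_width must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.sc_coupling <= 1.0:
            raise ValueError("sc_coupling must be in [0, 1]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if not 0.0 <= self.state_jitter < 1.0:
            raise ValueError("state_jitter must be in [0, 1)")


#: default condition labels, least -> most aware
DEFAULT_CONDITIONS = ("UWS", "MCS", "SED", "CON")
#: default per-condition cohort sizes (least -> most aware)
DEFAULT_N_SUBJECTS = (12, 11, 18, 18)

# Arousal mapping end points (arousal 0 = least aware, 1 = most aware).
# Less-aware subjects dwell longer in each covariance state, blend states
# more sluggishly, track their structural connectome more tightly, and
# show fewer transient co-activation events (state_jitter).
_DWELL_RANGE = (32.0, 8.0)
_WIDTH_RANGE = (14, 2)
_COUPLING_RANGE = (0.40, 0.12)
_JITTER_RANGE = (0.0, 0.22)


def arousal_overrides(arousal: float) -> dict[str, float | int]:
    """Map an arousal level in [0, 1] (0 = least aware) to the planted
    generator parameters."""
    if not 0.0 <= arousal <= 1.0:
        raise ValueError("arousal must be in [0, 1]")
    lo, hi = _DWELL_RANGE
    dwell = lo + (hi - lo) * arousal
    wlo, whi = _WIDTH_RANGE
    width = int(round(wlo + (whi - wlo) * arousal))
    clo, chi = _COUPLING_RANGE
    coupling = clo + (chi - clo) * arousal
    jlo, jhi = _JITTER_RANGE
    jitter = jlo + (jhi - jlo) * arousal
    return {"mean_dwell": dwell, "transition_width": width,
            "sc_coupling": coupling, "state_jitter": jitter}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: ordered condition labels (least -> most aware),
    per-condition sizes, optional per-condition config overrides, and a
    base seed from which all subject seeds derive."""

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_subjects_per_condition: int | tuple[int, ...] = DEFAULT_N_SUBJECTS
    base_config: SimulationConfig = field(default_factory=SimulationConfig)
    overrides: dict | None = None  # condition label -> config field overrides
    sc_density: float = 0.3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        n = self.n_subjects_per_condition
        if isinstance(n, int):
            n = (n,) * len(self.conditions)
        else:
            n = tuple(int(v) for v in n)
            if len(n) != len(self.conditions):
                raise ValueError("one cohort size per condition required")
        if any(v < 1 for v in n):
            raise ValueError("cohort sizes must be positive")
        object.__setattr__(self, "n_subjects_per_condition", n)

    def condition_config(self, rank: int) -> SimulationConfig:
        """Resolved config for condition ``rank`` (0 = least aware):
        arousal-mapped defaults, then explicit overrides."""
        arousal = rank / (len(self.conditions) - 1)
        fields = arousal_overrides(arousal)
        label = self.conditions[rank]
        if self.overrides and label in self.overrides:
            fields.update(self.overrides[label])
        return replace(self.base_config, **fields)


@dataclass(frozen=True)
class Subject:
    """One simulated participant, with the ground-truth regime sequence."""

    subject_id: str
    timeseries: RegionTimeSeries
    connectome: StructuralConnectome
    condition: str
    condition_rank: int
    states: np.ndarray
    config: SimulationConfig


def _subject_seed(base_seed: int, condition_index: int,
                  subject_index: int) -> int:
    """Deterministic per-subject seed without global state."""
    ss = np.random.SeedSequence((base_seed, condition_index, subject_index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_structural_connectome(n_regions: int, density: float = 0.3,
                                   seed: int = 0) -> StructuralConnectome:
    """Random connectome with exactly round(density * R(R-1)/2) edges.

    Edge weights are lognormal, echoing the heavy-tailed streamline
    counts of tractography.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n_pairs = n_regions * (n_regions - 1) // 2
    n_edges = int(round(density * n_pairs))
    if n_edges < 1:
        raise ValueError("empty connectome")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    iu = np.triu_indices(n_regions, k=1)
    w = np.zeros((n_regions, n_regions))
    w[iu[0][chosen], iu[1][chosen]] = rng.lognormal(0.0, 0.5, size=n_edges)
    return StructuralConnectome(weights=w + w.T)


def generate_regime_sequence(n_timepoints: int, n_states: int,
                             mean_dwell: float, seed: int = 0) -> np.ndarray:
    """First-order Markov state labels with self-transition probability
    1 - 1/mean_dwell and uniform switch targets (geometric dwell times
    with the requested mean)."""
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if mean_dwell < 1:
        raise ValueError("mean_dwell must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_timepoints, dtype=np.int64)
    labels[0] = rng.integers(n_states)
    if n_states == 1:
        labels[:] = labels[0]
        return labels
    p_stay = 1.0 - 1.0 / mean_dwell
    for t in range(1, n_timepoints):
        if rng.random() < p_stay:
            labels[t] = labels[t - 1]
        else:
            others = [s for s in range(n_states) if s != labels[t - 1]]
            labels[t] = others[rng.integers(n_states - 1)]
    return labels


def _state_covariances(config: SimulationConfig,
                       structural: StructuralConnectome,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-state covariances: convex blend of an SC-derived covariance and
    a random positive-definite factor model, both on correlation scale."""
    r = config.n_regions
    sc = structural.weights
    # SC-derived covariance via communicability: expm of the spectrally
    # normalised connectome, standardised to unit diagonal. PD by
    # construction, with off-diagonal strength comparable to the factor
    # component (a plain scaled-SC-plus-identity covariance is too weak
    # off-diagonal for coupling to matter, and is not even PD in general).
    if sc.any():
        rho = np.abs(np.linalg.eigvalsh(sc)).max()
        comm = expm(SC_COMM_BETA * sc / rho)
        d = np.sqrt(np.diag(comm))
        c_sc = comm / np.outer(d, d)
    else:
        c_sc = np.eye(r)
    # per-state coupling: fixed relative spread around the configured mean,
    # so states differ in how tightly they track the structural backbone
    # (sc_coupling is the state-average coupling)
    if config.n_states == 1:
        spread = np.array([1.0])
    else:
        spread = np.linspace(0.25, 1.75, config.n_states)
    covs = np.empty((config.n_states, r, r))
    for s in range(config.n_states):
        loadings = rng.standard_normal((r, N_FACTORS))
        fac = loadings @ loadings.T + DIAG_FLOOR * np.eye(r)
        d = np.sqrt(np.diag(fac))
        fac = fac / np.outer(d, d)  # unit diagonal: comparable scale to c_sc
        c_s = float(np.clip(config.sc_coupling * spread[s], 0.0, 1.0))
        covs[s] = c_s * c_sc + (1 - c_s) * fac
    return covs


def _blend_weights(labels: np.ndarray, n_states: int,
                   width: int) -> np.ndarray:
    """Per-timepoint convex state weights: one-hot labels linearly blended
    with a moving average of length width + 1 around switches."""
    onehot = np.zeros((labels.size, n_states))
    onehot[np.arange(labels.size), labels] = 1.0
    if width == 0:
        return onehot
    kernel = np.ones(width + 1) / (width + 1)
    smooth = np.empty_like(onehot)
    for s in range(n_states):
        smooth[:, s] = np.convolve(onehot[:, s], kernel, mode="same")
    return smooth / smooth.sum(axis=1, keepdims=True)


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky with jitter repair for marginally non-PD blends."""
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            if jitter > 0.0:
                log.warning("covariance repaired with jitter %g", jitter)
    raise RuntimeError("covariance not positive definite after jitter repair")


def generate_bold(config: SimulationConfig, structural: StructuralConnectome,
                  return_states: bool = False):
    """Simulate a T x R BOLD-like series.

    Each timepoint is drawn from a zero-mean multivariate normal whose
    covariance is the active state's (states blended linearly over
    ``transition_width`` timepoints around switches), then AR(1)-smoothed
    with coefficient ``ar_coefficient`` and perturbed with iid Gaussian
    noise of sd ``noise_sd``.
    """
    if structural.n_regions != config.n_regions:
        raise ValueError("structural connectome size does not match config")
    ss = np.random.SeedSequence(config.seed)
    seed_states, seed_cov, seed_noise = (int(c.generate_state(1)[0] % (2 ** 31))
                                         for c in ss.spawn(3))
    labels = generate_regime_sequence(config.n_timepoints, config.n_states,
                                      config.mean_dwell, seed=seed_states)
    rng_cov = np.random.default_rng(seed_cov)
    covs = _state_covariances(config, structural, rng_cov)
    weights = _blend_weights(labels, config.n_states, config.transition_width)

    rng = np.random.default_rng(seed_noise)
    t_pts, r = config.n_timepoints, config.n_regions
    innovations = rng.standard_normal((t_pts, r))
    jit = config.state_jitter
    if jit > 0:
        # transient co-activation events: an independent random rank-1
        # pattern each timepoint, i.e. fast stochastic reconfiguration
        # superimposed on the slow regime structure
        jit_dirs = rng.standard_normal((t_pts, r))
        jit_amps = rng.standard_normal(t_pts)
    out = np.empty((t_pts, r))
    chol_cache: dict[tuple, np.ndarray] = {}
    prev = np.zeros(r)
    for t in range(t_pts):
        key = tuple(np.round(weights[t], 9))
        chol = chol_cache.get(key)
        if chol is None:
            cov_t = np.tensordot(weights[t], covs, axes=1)
            chol = _safe_cholesky(cov_t)
            chol_cache[key] = chol
        x = chol @ innovations[t]
        if jit > 0:
            x = np.sqrt(1 - jit) * x + np.sqrt(jit) * jit_amps[t] * jit_dirs[t]
        prev = config.ar_coefficient * prev + x
        out[t] = prev
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, size=out.shape)
    ts = RegionTimeSeries(values=out, tr_seconds=config.tr_seconds)
    return (ts, labels) if return_states else ts


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Simulate the full cohort: per-subject seeds derive deterministically
    from the base seed; conditions keep the spec's least-to-most-aware
    order and carry the planted arousal mapping."""
    subjects: list[Subject] = []
    for rank, label in enumerate(spec.conditions):
        cfg_cond = spec.condition_config(rank)
        for si in range(spec.n_subjects_per_condition[rank]):
            seed = _subject_seed(spec.base_seed, rank, si)
            cfg = replace(cfg_cond, seed=seed)
            sc = generate_structural_connectome(
                cfg.n_regions, density=spec.sc_density,
                seed=_subject_seed(spec.base_seed, rank, si + 10 ** 6))
            ts, labels = generate_bold(cfg, sc, return_states=True)
            subjects.append(Subject(
                subject_id=f"{label}-{si:02d}", timeseries=ts, connectome=sc,
                condition=label, condition_rank=rank, states=labels,
                config=cfg))
    return subjects
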