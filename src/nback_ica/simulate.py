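"""Synthetic n-back fMRI and behavior with known ground truth.

The generator produces everything the analysis consumes — 4D BOLD
volumes, motion tables, event timing and a trial-level behavior table —
with the statistical structure the pipeline assumes:

* spatially sparse, super-Gaussian component maps (Gaussian blobs at
  disjoint centers) mixed linearly into voxel time series;
* per-subject condition amplitudes, so each source carries its own task
  modulation profile (the "working-memory" source increases with load);
* per-subject hemodynamic responses whose gamma delays are jittered,
  more so in the old group — the variability the derivative basis set is
  meant to absorb;
* slow cosine drift plus white Gaussian noise, and smooth random-walk
  motion nuisance series;
* behavioral trials (lognormal RTs, Bernoulli correctness) matched to
  published young/old group means and SDs, with a tunable coupling
  between a designated source's 2-back amplitude and accuracy in the
  old group.

All randomness flows from one master seed through named substreams, so
identical configs give bit-identical data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import DURATION, PEAK_DELAY, UNDERSHOOT_DELAY
from .task import CONDITIONS, TaskSchedule, build_schedule, condition_onsets

GROUPS = ("young", "old")

#: published group-level behavior: {group: {condition: (RT mean ms, RT SD ms,
#: accuracy mean, accuracy SD)}} — between-subject moments.
DEFAULT_BEHAVIOR_PARAMS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "young": {"0back": (473.0, 51.0, 0.93, 0.03),
              "1back": (511.0, 59.0, 0.90, 0.05),
              "2back": (617.0, 98.0, 0.86, 0.04)},
    "old": {"0back": (589.0, 50.0, 0.94, 0.03),
            "1back": (668.0, 84.0, 0.90, 0.04),
            "2back": (866.0, 125.0, 0.73, 0.12)},
}

#: condition modulation profiles cycled over sources; the designated
#: working-memory source always takes the load-increasing profile.
_LOAD_PROFILES = (
    (0.5, 1.0, 1.5),   # load-increasing (fronto-parietal-like)
    (1.0, 1.0, 1.0),   # load-flat (sensorimotor-like)
    (1.2, 1.0, 0.6),   # load-decreasing (default-mode-like)
    (0.8, 1.2, 1.0),   # mid-load peak
)


@dataclass(frozen=True)
class SimulationConfig:
    grid_dims: tuple[int, int, int] = (16, 16, 12)
    n_sources: int = 8
    n_subjects_per_group: int = 6
    tr_seconds: float = 2.0
    scans_per_condition: int = 200
    trials_per_block: int = 100
    rest_duration: float = 20.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    spontaneous_sd: float = 1.0             # ongoing network fluctuation,
                                            # relative to task modulation
    hrf_delay_jitter_sd: float = 0.3        # seconds, young group
    old_jitter_multiplier: float = 2.0      # old group jitter scale
    coupling_strength: float = 0.0          # accuracy <-> activation, old group
    designated_source: int = 0
    amplitude_subject_sd: float = 0.3
    rt_within_cv: float = 0.2               # within-subject lognormal CV
    rt_outlier_fraction: float = 0.02       # out-of-range RTs (<200 / >1500 ms)
    blob_sigma: float = 1.5                 # voxels
    behavior_params: dict = field(
        default_factory=lambda: {g: dict(c) for g, c in
                                 DEFAULT_BEHAVIOR_PARAMS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be 3 positive integers")
        if self.n_sources <= 0:
            raise ValueError("n_sources must be positive")
        if int(np.prod(self.grid_dims)) < self.n_sources * 20:
            raise ValueError("grid volume must be >= 20 voxels per source")
        if self.n_subjects_per_group < 0:
            raise ValueError("n_subjects_per_group must be >= 0")
        if self.tr_seconds <= 0 or self.scans_per_condition <= 0:
            raise ValueError("tr_seconds and scans_per_condition must be > 0")
        for name in ("noise_sd", "drift_amplitude", "hrf_delay_jitter_sd",
                     "spontaneous_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for group, conds in self.behavior_params.items():
            for cond, (rt_m, rt_s, acc_m, acc_s) in conds.items():
                if rt_m <= 0 or rt_s <= 0 or acc_s < 0:
                    raise ValueError(f"non-positive RT parameters for "
                                     f"{group}/{cond}")
                if not 0 < acc_m < 1:
                    raise ValueError(f"accuracy mean for {group}/{cond} "
                                     "must lie in (0, 1)")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_subjects_per_group

    @property
    def subject_groups(self) -> tuple[str, ...]:
        return tuple(["young"] * self.n_subjects_per_group
                     + ["old"] * self.n_subjects_per_group)


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Named child generator of the master seed (stable across runs)."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def subseed(seed: int, *names: str | int) -> int:
    """Deterministic 31-bit integer child seed of the master seed."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    state = np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def build_schedule_for(config: SimulationConfig) -> TaskSchedule:
    """Task schedule consistent with the simulation config.

    Verifies that the schedule's task-scan budget agrees with
    ``scans_per_condition`` (each block of N trials spans roughly
    N * (stimulus + mean ITI) seconds, i.e. ~1 scan per trial at TR 2).
    """
    schedule = build_schedule(subseed(config.seed, "schedule"),
                              trials_per_block=config.trials_per_block,
                              rest_duration=config.rest_duration,
                              tr_seconds=config.tr_seconds)
    task_seconds = sum(
        b.trials[-1].onset + b.trials[-1].duration - b.onset
        for b in schedule.blocks)
    task_scans = task_seconds / config.tr_seconds
    expected = 3 * config.scans_per_condition
    if not 0.6 * expected <= task_scans <= 1.4 * expected:
        raise ValueError(
            f"schedule spans ~{task_scans:.0f} task scans but config expects "
            f"{expected}; adjust trials_per_block or scans_per_condition")
    return schedule


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score recovery: the generating parameters."""
    source_maps: np.ndarray          # n_sources x n_voxels (unit norm)
    grid_dims: tuple[int, int, int]
    amplitudes: np.ndarray           # n_subjects x n_sources x 3 conditions
    hrf_delays: np.ndarray           # n_subjects x 2 (response, undershoot)
    subject_groups: tuple[str, ...]
    behavior_params: dict
    seed: int

    @property
    def n_sources(self) -> int:
        return self.source_maps.shape[0]

    def map_volume(self, source: int) -> np.ndarray:
        return self.source_maps[source].reshape(self.grid_dims)


# ---------------------------------------------------------------------------
# sources

def generate_source_maps(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """n_sources sparse Gaussian-blob maps, unit-normalized, n_sources x voxels.

    Each map is a dominant positive Gaussian blob with a weaker negative
    satellite blob nearby — a signed, super-Gaussian spatial source like
    the z-maps real decompositions produce (networks have both engaged
    and suppressed territory).  Centers are placed by rejection sampling
    with a minimum separation of ~3 blob sigmas so that maps are nearly
    uncorrelated (pairwise |spatial r| <= 0.3 is enforced).  Raises when
    the grid cannot hold the requested number of sources.
    """
    rng = rng if rng is not None else substream(config.seed, "sources")
    dims = np.asarray(config.grid_dims, dtype=float)
    sigma = config.blob_sigma
    # 3 sigma separation keeps pairwise blob correlation ~exp(-9/4) < 0.3
    min_sep = 3.0 * sigma

    xx, yy, zz = np.meshgrid(*[np.arange(d) for d in config.grid_dims],
                             indexing="ij")
    coords = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)

    packed = False
    best_maps = None
    best_off = np.inf
    for _restart in range(300):
        # place positive cores and negative satellites jointly so that no
        # lobe of one source intrudes on another source's territory
        centers: list[np.ndarray] = []
        satellites: list[np.ndarray] = []
        tries = 0
        while (len(centers) < config.n_sources
               and tries < 200 * config.n_sources):
            tries += 1
            c = rng.uniform(0.1, 0.9, size=3) * (dims - 1)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            c_neg = np.clip(c + 2.5 * sigma * direction, 0, dims - 1)
            others = centers + satellites
            if all(np.linalg.norm(p - q) >= min_sep
                   for p in (c, c_neg) for q in others):
                centers.append(c)
                satellites.append(c_neg)
        if len(centers) < config.n_sources:
            continue
        packed = True

        maps = np.empty((config.n_sources, coords.shape[0]))
        for s, (c, c_neg) in enumerate(zip(centers, satellites)):
            d2 = ((coords - c) ** 2).sum(axis=1)
            d2_neg = ((coords - c_neg) ** 2).sum(axis=1)
            m = (np.exp(-d2 / (2 * sigma ** 2))
                 - 0.6 * np.exp(-d2_neg / (2 * sigma ** 2)))
            maps[s] = m / np.linalg.norm(m)

        corr = np.atleast_2d(np.corrcoef(maps))
        off = np.abs(corr[~np.eye(config.n_sources, dtype=bool)])
        worst = float(off.max()) if off.size else 0.0
        if worst <= 0.15:
            return maps
        if worst < best_off:
            best_off, best_maps = worst, maps

    if not packed and best_maps is None:
        raise ValueError(
            f"cannot pack {config.n_sources} sources of sigma {sigma} "
            f"into grid {config.grid_dims}")
    if best_off <= 0.3:   # acceptable, if not ideal, spatial independence
        return best_maps
    raise RuntimeError("source maps exceed the 0.3 spatial-correlation "
                       "bound; increase grid size or reduce blob_sigma")


def generate_amplitudes(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Subject x source x condition amplitudes around per-source profiles."""
    rng = rng if rng is not None else substream(config.seed, "amplitudes")
    n_sub, n_src = config.n_subjects, config.n_sources
    profiles = np.empty((n_src, 3))
    for s in range(n_src):
        if s == config.designated_source:
            profiles[s] = _LOAD_PROFILES[0]
        else:
            # base profile plus a fixed per-source perturbation so that no
            # two networks share an identical task-modulation signature
            base = np.asarray(_LOAD_PROFILES[(s + 1) % len(_LOAD_PROFILES)])
            profiles[s] = base + rng.uniform(-0.3, 0.3, size=3)
    amp = profiles[None] + rng.normal(0, config.amplitude_subject_sd,
                                      size=(n_sub, n_src, 3))
    return amp


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    maps = generate_source_maps(config)
    amplitudes = generate_amplitudes(config)
    rng = substream(config.seed, "hrf")
    n_sub = config.n_subjects
    jitter_sd = np.where(np.asarray(config.subject_groups) == "old",
                         config.hrf_delay_jitter_sd * config.old_jitter_multiplier,
                         config.hrf_delay_jitter_sd)
    delays = np.column_stack([
        PEAK_DELAY + rng.normal(0, 1, n_sub) * jitter_sd,
        UNDERSHOOT_DELAY + rng.normal(0, 1, n_sub) * jitter_sd,
    ])
    delays[:, 0] = np.clip(delays[:, 0], 3.0, 9.0)
    delays[:, 1] = np.clip(delays[:, 1], 12.0, 20.0)
    return GroundTruth(source_maps=maps, grid_dims=tuple(config.grid_dims),
                       amplitudes=amplitudes, hrf_delays=delays,
                       subject_groups=config.subject_groups,
                       behavior_params={g: dict(c) for g, c in
                                        config.behavior_params.items()},
                       seed=config.seed)


# ---------------------------------------------------------------------------
# BOLD

def _subject_hrf(delays: tuple[float, float], step: float) -> np.ndarray:
    """Peak-normalized double-gamma with subject-specific delays."""
    from scipy.stats import gamma as gamma_dist
    t = np.arange(0.0, DURATION + step / 2, step)
    resp = gamma_dist.pdf(t, delays[0], scale=1.0)
    under = gamma_dist.pdf(t, delays[1], scale=1.0)
    h = resp - under / 6.0
    return h / h.max()


def condition_regressors(schedule: TaskSchedule, hrf_curve: np.ndarray,
                         step: float, event_duration: float = 0.5) -> np.ndarray:
    """3 x n_scans condition regressors: boxcars convolved with ``hrf_curve``."""
    tr = schedule.tr_seconds
    n_scans = schedule.n_scans
    n_fine = int(np.ceil(n_scans * tr / step)) + 1
    onsets = condition_onsets(schedule)
    scan_idx = np.round(np.arange(n_scans) * tr / step).astype(int)
    out = np.empty((3, n_scans))
    for ci, cond in enumerate(CONDITIONS):
        stim = np.zeros(n_fine)
        for onset in onsets[cond]:
            i0 = int(round(onset / step))
            i1 = max(i0 + 1, int(round((onset + event_duration) / step)))
            stim[i0:min(i1, n_fine)] = 1.0
        out[ci] = np.convolve(stim, hrf_curve)[:n_fine][scan_idx]
    return out


def generate_motion(n_scans: int, rng: np.random.Generator,
                    step_sd: float = 0.02, smooth: int = 5) -> np.ndarray:
    """Six smooth random-walk nuisance series (3 translations, 3 rotations)."""
    walk = np.cumsum(rng.normal(0, step_sd, size=(n_scans + smooth, 6)), axis=0)
    kernel = np.ones(smooth) / smooth
    smoothed = np.column_stack([np.convolve(walk[:, j], kernel, mode="valid")
                                for j in range(6)])
    return smoothed[:n_scans]


def source_timecourses(truth: GroundTruth, schedule: TaskSchedule,
                       subject_index: int, config: SimulationConfig,
                       hrf_step: float = 0.1) -> np.ndarray:
    """Ground-truth neural time courses (n_sources x n_scans).

    Task modulation (the amplitude-weighted condition regressors,
    convolved with the subject's jittered HRF) plus, when
    ``spontaneous_sd > 0``, ongoing task-independent network activity:
    hemodynamically smoothed white noise per source, scaled relative to
    the mean task-regressor amplitude.  This spontaneous covariation is
    what makes distinct networks separable by ICA even when their task
    profiles are similar.  Deterministic given the master seed.
    """
    n_scans = schedule.n_scans
    hrf_curve = _subject_hrf(tuple(truth.hrf_delays[subject_index]), hrf_step)
    regs = condition_regressors(schedule, hrf_curve, hrf_step)  # 3 x T
    amp = truth.amplitudes[subject_index]                       # S x 3
    neural = amp @ regs                                         # S x T
    if config.spontaneous_sd > 0:
        rng = substream(truth.seed, "neural", subject_index)
        n_src = neural.shape[0]
        kernel = hrf_curve[::max(1, int(round(schedule.tr_seconds
                                              / hrf_step)))]
        white = rng.normal(size=(n_src, n_scans + len(kernel)))
        fluct = np.stack([np.convolve(w, kernel)[len(kernel):
                                                 len(kernel) + n_scans]
                          for w in white])
        fluct /= fluct.std(axis=1, keepdims=True)
        task_scale = regs.std(axis=1).mean()
        neural = neural + config.spontaneous_sd * task_scale * fluct
    return neural


def generate_subject_bold(
    truth: GroundTruth, schedule: TaskSchedule, subject_index: int,
    config: SimulationConfig, hrf_step: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """4D BOLD volume (grid + time) and 6-column motion table for one subject.

    Voxel time series are the exact linear mixture of the ground-truth
    source maps with the subject's neural time courses (task modulation
    plus spontaneous network activity; see :func:`source_timecourses`),
    plus low-order cosine drift and white noise.
    """
    if not 0 <= subject_index < truth.amplitudes.shape[0]:
        raise IndexError(f"subject_index {subject_index} out of range")
    n_scans = schedule.n_scans
    rng = substream(truth.seed, "bold", subject_index)

    neural = source_timecourses(truth, schedule, subject_index, config,
                                hrf_step=hrf_step)
    data = truth.source_maps.T @ neural                         # V x T

    if config.drift_amplitude > 0:
        t = np.arange(n_scans) / n_scans
        drift = np.zeros(n_scans)
        for order in (1, 2, 3):
            drift += (rng.normal(0, 1)
                      * np.cos(np.pi * order * t))
        drift *= config.drift_amplitude
        data = data + drift[None, :]
    if config.noise_sd > 0:
        data = data + rng.normal(0, config.noise_sd, size=data.shape)

    motion = generate_motion(n_scans, rng)
    volume = data.reshape(*truth.grid_dims, n_scans)
    return volume, motion


# ---------------------------------------------------------------------------
# behavior

def generate_behavior(config: SimulationConfig, truth: GroundTruth,
                      trials_per_condition: int | None = None) -> pd.DataFrame:
    """Trial table: subject, group, condition, trial, rt_ms, correct.

    Per subject and condition a mean RT and an accuracy level are drawn
    from the group's between-subject distribution; trial RTs are
    lognormal around the subject mean (so the subject's median RT is the
    drawn level) and correctness is Bernoulli at the subject's accuracy.
    In the old group ``coupling_strength`` times the within-group
    z-score of the designated source's 2-back amplitude is added to the
    subject's 2-back accuracy.  A configurable fraction of
    RTs is replaced by out-of-range values (<200 or >1500 ms) to
    exercise downstream filtering.
    """
    n_trials = (trials_per_condition if trials_per_condition is not None
                else 2 * config.trials_per_block)
    columns = ["subject", "group", "condition", "trial", "rt_ms", "correct"]
    if config.n_subjects == 0:
        return pd.DataFrame(columns=columns)

    rng = substream(config.seed, "behavior")
    groups = np.asarray(truth.subject_groups)
    old_idx = np.where(groups == "old")[0]

    # accuracy-coupling offsets for old subjects
    offsets = np.zeros(len(groups))
    if config.coupling_strength != 0 and len(old_idx) > 1:
        amp2 = truth.amplitudes[old_idx, config.designated_source, 2]
        z = (amp2 - amp2.mean()) / amp2.std(ddof=0)
        offsets[old_idx] = config.coupling_strength * z

    rows = []
    sigma_ln = np.sqrt(np.log(1 + config.rt_within_cv ** 2))
    for subj in range(config.n_subjects):
        group = groups[subj]
        for cond in CONDITIONS:
            rt_m, rt_s, acc_m, acc_s = config.behavior_params[group][cond]
            subj_rt = max(250.0, rng.normal(rt_m, rt_s))
            subj_acc = float(np.clip(rng.normal(acc_m, acc_s), 0.02, 0.995))
            if cond == "2back":   # coupling acts on the load condition
                subj_acc += offsets[subj]
            if not 0 < subj_acc < 1:
                raise ValueError(
                    f"coupling pushed accuracy to {subj_acc:.3f} for subject "
                    f"{subj} ({cond}); reduce coupling_strength")
            rts = np.exp(rng.normal(np.log(subj_rt), sigma_ln, n_trials))
            rts = np.clip(rts, 201.0, 1499.0)
            if config.rt_outlier_fraction > 0:
                out_mask = rng.random(n_trials) < config.rt_outlier_fraction
                n_out = int(out_mask.sum())
                fast = rng.random(n_out) < 0.5
                out_vals = np.where(fast, rng.uniform(50, 199, n_out),
                                    rng.uniform(1501, 2500, n_out))
                rts[out_mask] = out_vals
            correct = rng.random(n_trials) < subj_acc
            for trial in range(n_trials):
                rows.append((subj, group, cond, trial,
                             float(rts[trial]), bool(correct[trial])))
    return pd.DataFrame(rows, columns=columns)
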