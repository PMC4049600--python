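"""Temporal-concatenation group spatial ICA.

The decomposition follows the standard group-ICA recipe for task fMRI:

1. per-subject temporal PCA (scans -> k_subject), whitened;
2. concatenation of the reduced data across subjects and a second,
   group-level PCA (-> k_group), whitened;
3. infomax ICA (natural gradient, logistic nonlinearity) on the reduced
   group data, giving spatially independent component maps;
4. stability analysis by re-running infomax with different seeds and
   clustering the pooled components (ICASSO-style): each cluster's
   centrotype is kept and its tightness indexes component reliability;
5. back-reconstruction of subject-specific maps and time courses by
   inverting the composed reduction pipeline on each subject's block.

Model order can be chosen with a minimum-description-length criterion
on the eigenvalue spectrum of the temporal covariance.

Conventions: each component's map is sign-flipped so its largest-|value|
voxel is positive, components are ordered by explained variance
(descending), and stored maps/time courses are z-scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .simulate import subseed

logger = logging.getLogger(__name__)


def zscore(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """(x - mean) / SD along ``axis`` (population SD)."""
    a = np.asarray(a, dtype=float)
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mean) / sd


# ---------------------------------------------------------------------------
# dataset container

@dataclass(frozen=True)
class GroupDataset:
    """Masked per-subject voxel x scan matrices sharing one mask."""
    data: tuple[np.ndarray, ...]         # each voxels x scans
    mask: np.ndarray                     # boolean volume
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        shapes = {d.shape for d in self.data}
        if len({s[0] for s in shapes}) != 1 or len({s[1] for s in shapes}) != 1:
            raise ValueError("all subjects must share voxel and scan counts")
        if self.data[0].shape[0] != int(self.mask.sum()):
            raise ValueError("data rows must match mask voxel count")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_voxels(self) -> int:
        return self.data[0].shape[0]

    @property
    def n_scans(self) -> int:
        return self.data[0].shape[1]

    @classmethod
    def from_volumes(cls, volumes: list[np.ndarray],
                     mask: np.ndarray | None = None,
                     subject_ids: list[str] | None = None) -> "GroupDataset":
        """Mask 4D volumes and remove each voxel's temporal mean."""
        if mask is None:
            mask = np.ones(volumes[0].shape[:3], dtype=bool)
        mask = mask.astype(bool)
        mats = []
        for vol in volumes:
            if vol.shape[:3] != mask.shape:
                raise ValueError("volume/mask shape mismatch")
            x = vol[mask].astype(float)
            mats.append(x - x.mean(axis=1, keepdims=True))
        ids = (tuple(subject_ids) if subject_ids is not None
               else tuple(f"sub-{i:03d}" for i in range(len(mats))))
        return cls(data=tuple(mats), mask=mask, subject_ids=ids)


# ---------------------------------------------------------------------------
# model order (MDL)

def mdl_spectrum(eigenvalues: np.ndarray, n_samples: int) -> np.ndarray:
    """Gaussian-source MDL cost for k = 0..p-1 retained components."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    lam = np.maximum(lam, 1e-12 * lam.max())  # ridge floor for exact-rank data
    p = len(lam)
    costs = np.empty(p)
    log_lam = np.log(lam)
    for k in range(p):
        tail = lam[k:]
        geo = np.exp(log_lam[k:].mean())
        arith = tail.mean()
        costs[k] = (-n_samples * (p - k) * np.log(geo / arith)
                    + 0.5 * k * (2 * p - k + 1) * np.log(n_samples))
    return costs


def estimate_order(dataset: GroupDataset) -> int:
    """MDL estimate of the number of components.

    Uses the eigenvalue spectrum of the temporal (scan x scan)
    covariance averaged over subjects, with the number of scans as the
    i.i.d. sample count in the MDL penalty.
    """
    if dataset.n_subjects < 1:
        raise ValueError("need at least one subject")
    T = dataset.n_scans
    cov = np.zeros((T, T))
    for x in dataset.data:
        cov += x.T @ x / x.shape[0]
    cov /= dataset.n_subjects
    lam = np.linalg.eigvalsh(cov)[::-1]
    if lam.max() <= 0:
        raise ValueError("rank-deficient input: no positive eigenvalues")
    costs = mdl_spectrum(lam, n_samples=T)
    return int(np.argmin(costs))


# ---------------------------------------------------------------------------
# two-stage PCA reduction

@dataclass(frozen=True)
class ReductionOperators:
    """Whitening operators retained for back-reconstruction."""
    subject_bases: tuple[np.ndarray, ...]   # E_i: scans x k_subject
    subject_eigs: tuple[np.ndarray, ...]    # top k_subject eigenvalues
    group_basis: np.ndarray                 # F: (M * k_subject) x k_group
    group_eigs: np.ndarray                  # top k_group eigenvalues
    k_subject: int
    k_group: int


def _top_eig(sym: np.ndarray, k: int, what: str) -> tuple[np.ndarray, np.ndarray]:
    lam, vec = np.linalg.eigh(sym)
    lam, vec = lam[::-1], vec[:, ::-1]
    rank = int((lam > max(1e-10 * lam[0], 0.0)).sum())
    if k > rank:
        raise ValueError(f"{what}: requested {k} components but rank is {rank}")
    return lam[:k], vec[:, :k]


def reduce(dataset: GroupDataset, k_subject: int,
           k_group: int) -> tuple[np.ndarray, ReductionOperators]:
    """Two-stage PCA: subject temporal reduction, concatenation, group PCA.

    Returns the whitened reduced group matrix (k_group x voxels) ready
    for spatial ICA, plus the operators needed to reconstruct
    subject-level maps and time courses.
    """
    if k_subject > dataset.n_scans:
        raise ValueError("k_subject cannot exceed the scan count")
    if k_group > dataset.n_subjects * k_subject:
        raise ValueError("k_group cannot exceed total reduced dimensions")
    bases, eigs, reduced = [], [], []
    for x in dataset.data:
        lam, E = _top_eig(x.T @ x, k_subject, "subject reduction")
        bases.append(E)
        eigs.append(lam)
        reduced.append(x @ E)   # voxels x k_subject, variance-preserving
    Y = np.hstack(reduced)      # voxels x (M * k_subject)
    glam, F = _top_eig(Y.T @ Y, k_group, "group reduction")
    # whiten only at the group stage (unit sample variance across voxels)
    Z = Y @ F / np.sqrt(glam) * np.sqrt(dataset.n_voxels)
    ops = ReductionOperators(subject_bases=tuple(bases),
                             subject_eigs=tuple(eigs),
                             group_basis=F, group_eigs=glam,
                             k_subject=k_subject, k_group=k_group)
    return Z.T, ops                               # k_group x voxels


def reduction_errors(dataset: GroupDataset,
                     ops: ReductionOperators) -> dict[str, float]:
    """Squared Frobenius reconstruction errors of the two PCA stages.

    The group-stage error equals the sum of the eigenvalues of the
    concatenated-data Gram matrix discarded at ``k_group``.
    """
    Y = np.hstack([x @ E for x, E in zip(dataset.data, ops.subject_bases)])
    F = ops.group_basis
    group_err = float(((Y - Y @ F @ F.T) ** 2).sum())
    subj_err = 0.0
    for x, E in zip(dataset.data, ops.subject_bases):
        subj_err += float(((x - x @ E @ E.T) ** 2).sum())
    return {"subject": subj_err, "group": group_err}


# ---------------------------------------------------------------------------
# infomax

class InfomaxNonConvergence(RuntimeError):
    """Raised when infomax fails to converge; carries the partial result."""

    def __init__(self, message: str, partial: np.ndarray):
        super().__init__(message)
        self.partial = partial


def infomax(reduced: np.ndarray, n_components: int, seed: int, *,
            learning_rate: float | None = None, max_sweeps: int = 512,
            tol: float = 1e-6, anneal: float = 0.9,
            block_size: int | None = None,
            burn_in_sweeps: int = 64, sweep_decay: float = 0.97,
            ) -> np.ndarray:
    """Natural-gradient infomax with logistic nonlinearity and bias.

    ``reduced`` is the whitened k x N matrix (components along rows
    after unmixing).  The learning rate is annealed by ``anneal``
    whenever the update direction oscillates (angle to the previous
    sweep's update > 60 degrees); after ``burn_in_sweeps`` sweeps of
    full-rate learning it is additionally decayed geometrically by
    ``sweep_decay`` per sweep so the stochastic block updates settle
    onto a fixed point.  Converges when the relative weight-change
    norm drops below ``tol``; raises :class:`InfomaxNonConvergence`
    (with the partial unmixing retrievable) after ``max_sweeps``
    sweeps.
    """
    X = np.asarray(reduced, dtype=float)
    k, n = X.shape
    if n_components != k:
        raise ValueError("n_components must equal the reduced row count")
    rng = np.random.default_rng(seed)
    lr = learning_rate if learning_rate is not None else 0.005 / np.log(k)
    block = block_size if block_size is not None else int(
        np.ceil(min(5 * np.log(n), 0.3 * n)))

    W = np.eye(k)
    bias = np.zeros((k, 1))
    I = np.eye(k)
    prev_delta = None
    wchange = np.inf
    for sweep in range(max_sweeps):
        perm = rng.permutation(n)
        W_old = W.copy()
        for start in range(0, n - block + 1, block):
            xb = X[:, perm[start:start + block]]
            u = W @ xb + bias
            y = 1.0 / (1.0 + np.exp(-u))
            q = 1.0 - 2.0 * y
            W = W + lr * (I + q @ u.T / block) @ W
            bias = bias + lr * q.mean(axis=1, keepdims=True)
            if not np.isfinite(W).all():
                raise InfomaxNonConvergence(
                    f"weights blew up at sweep {sweep}; lower the learning "
                    "rate", W_old)
        delta = W - W_old
        wchange = np.linalg.norm(delta) / np.linalg.norm(W_old)
        if prev_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(prev_delta)
            if denom > 0 and (delta * prev_delta).sum() / denom < 0.5:
                lr *= anneal  # oscillation (> 60 degrees)
        if sweep >= burn_in_sweeps:
            lr *= sweep_decay
        prev_delta = delta
        if wchange < tol:
            logger.debug("infomax converged after %d sweeps (lr=%.2e)",
                         sweep + 1, lr)
            return W
    raise InfomaxNonConvergence(
        f"infomax did not converge in {max_sweeps} sweeps "
        f"(last weight change {wchange:.2e})", W)


# ---------------------------------------------------------------------------
# ICASSO stability

@dataclass(frozen=True)
class IcassoResult:
    unmixing: np.ndarray          # k x k centrotype unmixing rows
    stability: np.ndarray         # k: mean within-|corr| - mean between-|corr|
    within_similarity: np.ndarray # k: mean within-cluster |corr|
    n_runs_succeeded: int


def icasso(reduced: np.ndarray, n_components: int, n_runs: int = 10,
           seed: int = 0, seeds: list[int] | None = None,
           **infomax_kwargs) -> IcassoResult:
    """Run infomax ``n_runs`` times, cluster pooled components, keep
    centrotypes.

    Components are pooled across runs and clustered by 1 - |correlation|
    (average-linkage agglomerative, ``n_components`` clusters).  Each
    cluster is represented by its centrotype — the member with maximal
    summed within-cluster similarity — and scored by the ICASSO quality
    index: mean within-cluster |corr| minus mean between-cluster |corr|.
    """
    if n_runs < 2:
        raise ValueError("icasso needs at least two runs")
    run_seeds = (list(seeds) if seeds is not None
                 else [subseed(seed, "icasso", r) for r in range(n_runs)])
    if len(run_seeds) != n_runs:
        raise ValueError("seeds must have length n_runs")

    unmixings, failures = [], []
    for s in run_seeds:
        try:
            unmixings.append(infomax(reduced, n_components, s,
                                     **infomax_kwargs))
        except InfomaxNonConvergence as exc:   # noqa: PERF203
            failures.append(exc)
    if len(unmixings) < (n_runs + 1) // 2:
        raise RuntimeError(
            f"only {len(unmixings)}/{n_runs} infomax runs converged") \
            from (failures[0] if failures else None)

    comps = np.vstack([W @ reduced for W in unmixings])   # (runs*k) x N
    sim = np.abs(np.corrcoef(comps))
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    labels = fcluster(linkage(dist, method="average"),
                      t=n_components, criterion="maxclust")

    k = n_components
    rows, stability, within_sim, order_keys = [], [], [], []
    for cl in range(1, k + 1):
        members = np.where(labels == cl)[0]
        sub = sim[np.ix_(members, members)]
        # centrotype: member with the largest summed within-cluster similarity
        centro = members[np.argmax(sub.sum(axis=1))]
        if len(members) > 1:
            within = sub[~np.eye(len(members), dtype=bool)].mean()
        else:
            within = 1.0
        outside = np.setdiff1d(np.arange(sim.shape[0]), members)
        between = sim[np.ix_(members, outside)].mean() if outside.size else 0.0
        run_idx, row_idx = divmod(centro, k)
        rows.append(unmixings[run_idx][row_idx])
        stability.append(within - between)
        within_sim.append(within)
        order_keys.append(centro)

    order = np.argsort(order_keys)  # deterministic cluster ordering
    W_sel = np.vstack([rows[i] for i in order])
    return IcassoResult(unmixing=W_sel,
                        stability=np.array([stability[i] for i in order]),
                        within_similarity=np.array([within_sim[i]
                                                    for i in order]),
                        n_runs_succeeded=len(unmixings))


# ---------------------------------------------------------------------------
# back-reconstruction and decomposition assembly

@dataclass(frozen=True)
class ICADecomposition:
    maps: np.ndarray                 # k x voxels, z-scored
    timecourses: np.ndarray          # k x (subjects * scans), z-scored
    subject_maps: np.ndarray         # M x k x voxels, z-scored
    subject_timecourses: np.ndarray  # M x k x scans, z-scored
    stability: np.ndarray | None
    n_components: int
    subject_ids: tuple[str, ...]


def back_project(unmixing: np.ndarray, ops: ReductionOperators,
                 dataset: GroupDataset) -> tuple[np.ndarray, np.ndarray]:
    """GICA back-reconstruction: raw subject maps and time courses.

    Applies the (pseudo-)inverse of the composed pipeline
    ``group unmixing o group whitening o subject whitening`` to each
    subject's partition.  Returns (subject_maps M x k x V,
    subject_timecourses M x k x T), unscaled.  The subject maps sum to
    the group maps, so their mean matches the group map up to scale.
    """
    M = dataset.n_subjects
    if len(ops.subject_bases) != M:
        raise ValueError("reduction operators do not match this dataset")
    k = unmixing.shape[0]
    A_group = np.linalg.pinv(unmixing)                 # k_group x k
    sqrt_glam = np.sqrt(ops.group_eigs)
    sqrt_v = np.sqrt(dataset.n_voxels)
    maps = np.empty((M, k, dataset.n_voxels))
    tcs = np.empty((M, k, dataset.n_scans))
    for i, x in enumerate(dataset.data):
        E = ops.subject_bases[i]
        F_i = ops.group_basis[i * ops.k_subject:(i + 1) * ops.k_subject]
        # time courses: forward mixing chain applied to the subject block
        tcs[i] = (A_group.T * sqrt_glam) @ F_i.T @ E.T / sqrt_v
        # maps: inverse (unmixing) chain applied to the subject data
        maps[i] = (unmixing / sqrt_glam) @ F_i.T @ (x @ E).T * sqrt_v
    return maps, tcs


def run_group_ica(dataset: GroupDataset, n_components: int, *,
                  k_subject: int | None = None, n_runs: int = 10,
                  seed: int = 0, use_icasso: bool = True,
                  **infomax_kwargs) -> ICADecomposition:
    """Full decomposition: reduce -> (icasso | infomax) -> back-project.

    Applies the package conventions: sign flip so each map's
    largest-|value| voxel is positive, ordering by explained variance,
    and z-scoring of all stored maps and time courses (applied after
    back-projection, at both group and subject level).
    """
    if k_subject is not None:
        ks = k_subject
    else:
        # default 1.5 x n_components, capped by scans and by the actual
        # temporal rank (noiseless task data can be very low-rank)
        ranks = []
        for x in dataset.data:
            lam = np.linalg.eigvalsh(x.T @ x)
            ranks.append(int((lam > 1e-10 * lam.max()).sum()))
        ks = min(int(np.ceil(1.5 * n_components)), dataset.n_scans,
                 min(ranks))
    reduced, ops = reduce(dataset, ks, n_components)

    if use_icasso:
        result = icasso(reduced, n_components, n_runs=n_runs, seed=seed,
                        **infomax_kwargs)
        W, stability = result.unmixing, result.stability
    else:
        W = infomax(reduced, n_components, subseed(seed, "infomax"),
                    **infomax_kwargs)
        stability = None

    raw_maps = W @ reduced                              # k x voxels
    sub_maps, sub_tcs = back_project(W, ops, dataset)

    # sign convention: largest-|value| voxel of each group map is positive
    flip = np.sign(raw_maps[np.arange(len(raw_maps)),
                            np.argmax(np.abs(raw_maps), axis=1)])
    flip[flip == 0] = 1.0
    raw_maps *= flip[:, None]
    sub_maps *= flip[None, :, None]
    sub_tcs *= flip[None, :, None]

    # order by explained variance: variance of back-projected time courses
    group_tc = np.concatenate([sub_tcs[i] for i in range(dataset.n_subjects)],
                              axis=1)                   # k x (M*T)
    order = np.argsort(group_tc.var(axis=1))[::-1]
    raw_maps = raw_maps[order]
    group_tc = group_tc[order]
    sub_maps = sub_maps[:, order]
    sub_tcs = sub_tcs[:, order]
    stability = stability[order] if stability is not None else None

    return ICADecomposition(
        maps=zscore(raw_maps),
        timecourses=zscore(group_tc),
        subject_maps=zscore(sub_maps),
        subject_timecourses=zscore(sub_tcs),
        stability=stability,
        n_components=n_components,
        subject_ids=dataset.subject_ids,
    )


# ---------------------------------------------------------------------------
# component selection by template matching

def select_components(decomposition: ICADecomposition,
                      templates: dict[str, np.ndarray], *,
                      threshold: float = 0.3,
                      override: dict[str, int] | None = None,
                      strict: bool = True,
                      ) -> dict[str, tuple[int | None, float]]:
    """Programmatic stand-in for visual component selection.

    For each named template map, returns the component index maximizing
    |spatial correlation| with the template (with the correlation), or
    ``None`` when no component reaches ``threshold``.  Raises if two
    templates pick the same component unless an ``override`` mapping
    resolves them (``strict=False`` keeps the better-correlated
    template instead and leaves the other unmatched).
    """
    override = override or {}
    out: dict[str, tuple[int | None, float]] = {}
    taken: dict[int, str] = {}
    for name, tmpl in templates.items():
        tmpl = np.asarray(tmpl, dtype=float).ravel()
        if tmpl.size != decomposition.maps.shape[1]:
            raise ValueError(f"template {name!r} does not share the voxel "
                             "mask")
        if name in override:
            idx = override[name]
            r = float(np.corrcoef(tmpl, decomposition.maps[idx])[0, 1])
            out[name] = (idx, r)
            taken[idx] = name
            continue
        corrs = np.array([np.corrcoef(tmpl, m)[0, 1]
                          for m in decomposition.maps])
        idx = int(np.argmax(np.abs(corrs)))
        best = float(corrs[idx])
        if abs(best) < threshold:
            out[name] = (None, best)
            continue
        if idx in taken:
            if strict:
                raise ValueError(
                    f"templates {taken[idx]!r} and {name!r} both select "
                    f"component {idx}; provide an override")
            prev = taken[idx]
            if abs(best) > abs(out[prev][1]):
                out[prev] = (None, out[prev][1])
                taken[idx] = name
                out[name] = (idx, best)
            else:
                out[name] = (None, best)
            continue
        taken[idx] = name
        out[name] = (idx, best)
    return out


def amari_distance(W: np.ndarray, A: np.ndarray) -> float:
    """Amari index between unmixing W and true mixing A (0 = perfect)."""
    P = np.abs(W @ A)
    m = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((rows.sum() + cols.sum()) / (2 * m * (m - 1)))
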