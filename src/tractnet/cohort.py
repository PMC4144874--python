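"""Synthetic two-group tractography cohorts with known injected effects.

No imaging data ships with this package; instead this module generates
cohorts at the count-matrix level that emulate the structure of a
probabilistic-tractography study: two groups of subjects (default 16 per
group, e.g. musicians vs. controls), 90 network nodes, one to three
repeated scans per subject, overdispersed non-negative streamline counts,
per-region seed-voxel counts, per-volume head-motion logs, and training
onset ages for the second group.

Counts are negative-binomial around an expected-count matrix. Expected
counts decay with the Euclidean distance between node positions drawn in a
unit cube; this spatial embedding gives the strongest connections the
short-range, locally clustered layout real white-matter networks show, so
that extracted backbones exhibit small-world organisation. Group effects
are injected multiplicatively: every edge incident to a chosen node has its
expected count scaled by ``effect_multiplier`` in the second group.

All randomness flows from one integer seed; per-subject and per-scan
streams are derived from stable (seed, group, subject, scan) keys so any
subset of the cohort is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .network import WeightedNetwork, average_networks, build_weight_matrix, extract_backbone
from .nodes import default_node_table

__all__ = [
    "GROUPS",
    "CohortSpec",
    "TractCountSet",
    "MotionLog",
    "SubjectData",
    "Cohort",
    "generate_cohort",
    "expected_weight_matrix",
    "calibrate_effect_multiplier",
]

#: group labels in order; the second group carries the injected effect.
GROUPS: tuple[str, str] = ("control", "musician")

# stream tags keeping independent random streams apart
_MASK, _POSITIONS, _SUBJECT, _SCAN = 0xA1, 0xA2, 0xB0, 0xC0


@dataclass(frozen=True)
class TractCountSet:
    """Directed streamline counts of one scan.

    ``counts[i, j]`` is the number of sampled pathways seeded in region i
    that reached region j; ``voxels[i]`` the number of seed voxels of
    region i.
    """

    counts: np.ndarray
    voxels: np.ndarray
    subject_id: str
    scan_id: str
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        voxels = np.asarray(self.voxels)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(np.diagonal(counts) != 0):
            raise ValueError("self-connections must be zero on the counts diagonal")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if voxels.shape != (counts.shape[0],) or np.any(voxels <= 0):
            raise ValueError("voxels must be strictly positive, one per region")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "voxels", voxels)


@dataclass(frozen=True)
class MotionLog:
    """Per-volume rigid-body motion parameters of one scan.

    ``params`` has one row per volume and six columns: three translations
    (mm) followed by three rotations (degrees).
    """

    params: np.ndarray
    subject_id: str
    scan_id: str

    def __post_init__(self) -> None:
        params = np.asarray(self.params, dtype=float)
        if params.ndim != 2 or params.shape[1] != 6 or params.shape[0] < 1:
            raise ValueError("params must be a non-empty (n_volumes, 6) array")
        if not np.all(np.isfinite(params)):
            raise ValueError("motion parameters must be finite")
        object.__setattr__(self, "params", params)


def _positive(name, value):
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults follow the emulated study design: 16 subjects per group, the
    90-node AAL parcellation, three repeated scans per subject, 21 volumes
    per scan (one b=0 plus 20 diffusion directions).
    """

    n_per_group: int = 16
    n_nodes: int = 90
    n_scans: int = 3
    base_density: float = 0.3
    mean_count: float = 50.0
    dispersion: float = 5.0
    voxel_range: tuple[int, int] = (150, 1500)
    effect_nodes: tuple[str, ...] = ()
    effect_multiplier: float = 1.0
    spatial_decay: float | None = 0.25
    motion_sd: float = 0.05
    n_volumes: int = 21
    qc_violation_fraction: float = 0.0
    onset_age_range: tuple[float, float] = (4.0, 16.0)
    connection_mask: np.ndarray | None = None
    labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if self.n_nodes < 3:
            raise ValueError(f"n_nodes must be >= 3, got {self.n_nodes}")
        if self.n_scans not in (1, 2, 3):
            raise ValueError(f"n_scans must be 1, 2 or 3, got {self.n_scans}")
        if not 0.0 <= self.base_density <= 1.0:
            raise ValueError(f"base_density must lie in [0, 1], got {self.base_density}")
        _positive("mean_count", self.mean_count)
        _positive("dispersion", self.dispersion)
        lo, hi = self.voxel_range
        if not (0 < lo <= hi):
            raise ValueError(f"voxel_range must satisfy 0 < low <= high, got {self.voxel_range}")
        _positive("effect_multiplier", self.effect_multiplier)
        if self.spatial_decay is not None:
            _positive("spatial_decay", self.spatial_decay)
        if self.motion_sd < 0:
            raise ValueError(f"motion_sd must be non-negative, got {self.motion_sd}")
        if self.n_volumes < 1:
            raise ValueError(f"n_volumes must be >= 1, got {self.n_volumes}")
        if not 0.0 <= self.qc_violation_fraction <= 1.0:
            raise ValueError(
                f"qc_violation_fraction must lie in [0, 1], got {self.qc_violation_fraction}"
            )
        if self.onset_age_range[0] > self.onset_age_range[1]:
            raise ValueError(f"onset_age_range is empty: {self.onset_age_range}")
        labels = self.node_labels()
        unknown = set(self.effect_nodes) - set(labels)
        if unknown:
            raise ValueError(f"effect_nodes not among node labels: {sorted(unknown)}")
        if self.connection_mask is not None:
            m = np.asarray(self.connection_mask, dtype=bool)
            if m.shape != (self.n_nodes, self.n_nodes):
                raise ValueError("connection_mask must be an (n_nodes, n_nodes) matrix")
            if np.any(m != m.T) or np.any(np.diagonal(m)):
                raise ValueError("connection_mask must be symmetric with a false diagonal")
            m = m.copy()
            m.flags.writeable = False
            object.__setattr__(self, "connection_mask", m)
        object.__setattr__(self, "effect_nodes", tuple(self.effect_nodes))
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))

    def node_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            if len(self.labels) != self.n_nodes:
                raise ValueError(
                    f"labels has {len(self.labels)} entries for n_nodes={self.n_nodes}"
                )
            return tuple(self.labels)
        if self.n_nodes == 90:
            return tuple(default_node_table()["abbreviation"])
        width = max(3, len(str(self.n_nodes)))
        return tuple(f"n{i:0{width}d}" for i in range(1, self.n_nodes + 1))


@dataclass(frozen=True)
class SubjectData:
    subject_id: str
    group: str
    onset_age: float | None
    scans: tuple[tuple[TractCountSet, MotionLog], ...]


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    subjects: tuple[SubjectData, ...]
    node_labels: tuple[str, ...]

    def group(self, label: str) -> tuple[SubjectData, ...]:
        if label not in GROUPS:
            raise ValueError(f"unknown group {label!r}; expected one of {GROUPS}")
        return tuple(s for s in self.subjects if s.group == label)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _mask_and_mu(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cohort-level anatomy: connection mask and baseline expected counts."""
    n = spec.n_nodes
    if spec.connection_mask is not None:
        mask = np.asarray(spec.connection_mask, dtype=bool)
    else:
        rng = _rng(spec.seed, _MASK)
        upper = rng.random((n, n)) < spec.base_density
        mask = np.triu(upper, 1)
        mask = mask | mask.T
    mu = np.zeros((n, n))
    if not mask.any():
        return mask, mu
    if spec.spatial_decay is None or not np.isfinite(spec.spatial_decay):
        mu[mask] = spec.mean_count
        return mask, mu
    pos = _rng(spec.seed, _POSITIONS).random((n, 3))
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    decay = np.exp(-dist / spec.spatial_decay)
    # scale so the mean expected count over present connections is mean_count
    scale = spec.mean_count / decay[mask].mean()
    mu[mask] = scale * decay[mask]
    return mask, mu


def _effect_scaling(spec: CohortSpec) -> np.ndarray:
    labels = spec.node_labels()
    idx = [labels.index(v) for v in spec.effect_nodes]
    scale = np.ones((spec.n_nodes, spec.n_nodes))
    if idx:
        scale[idx, :] = spec.effect_multiplier
        scale[:, idx] = spec.effect_multiplier
        # edges between two effect nodes get the multiplier once, not squared
        scale[np.ix_(idx, idx)] = spec.effect_multiplier
    return scale


def _group_mu(spec: CohortSpec, group: str, mu: np.ndarray) -> np.ndarray:
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if group == GROUPS[1]:
        return mu * _effect_scaling(spec)
    return mu


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Elementwise negative binomial with mean mu and NB2 variance mu + mu^2/r."""
    counts = np.zeros(mu.shape, dtype=np.int64)
    present = mu > 0
    if present.any():
        r = dispersion
        p = r / (r + mu[present])
        counts[present] = rng.negative_binomial(r, p)
    np.fill_diagonal(counts, 0)
    return counts


def _motion_walk(rng: np.random.Generator, spec: CohortSpec, violate: bool) -> np.ndarray:
    steps = rng.normal(0.0, spec.motion_sd, size=(spec.n_volumes, 6))
    params = np.cumsum(steps, axis=0)
    if violate:
        # force a clear QC failure: a sudden >1 mm translation jump
        axis = int(rng.integers(0, 3))
        start = int(rng.integers(0, spec.n_volumes))
        params[start:, axis] += 1.5
    return params


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort, deterministically from ``spec.seed``."""
    labels = spec.node_labels()
    mask, mu_base = _mask_and_mu(spec)
    subjects: list[SubjectData] = []
    for g_idx, group in enumerate(GROUPS):
        mu = _group_mu(spec, group, mu_base)
        for s_idx in range(spec.n_per_group):
            subject_id = f"{'con' if g_idx == 0 else 'mus'}{s_idx + 1:02d}"
            rng_subj = _rng(spec.seed, _SUBJECT, g_idx, s_idx)
            voxels = rng_subj.integers(spec.voxel_range[0], spec.voxel_range[1] + 1,
                                       size=spec.n_nodes)
            onset: float | None = None
            if group == GROUPS[1]:
                lo, hi = spec.onset_age_range
                onset = float(rng_subj.uniform(lo, hi))
            scans = []
            for scan_idx in range(spec.n_scans):
                scan_id = f"scan{scan_idx + 1}"
                rng_scan = _rng(spec.seed, _SCAN, g_idx, s_idx, scan_idx)
                counts = _draw_counts(rng_scan, mu, spec.dispersion)
                violate = bool(rng_scan.random() < spec.qc_violation_fraction)
                motion = _motion_walk(rng_scan, spec, violate)
                scans.append(
                    (
                        TractCountSet(counts, voxels, subject_id, scan_id, labels),
                        MotionLog(motion, subject_id, scan_id),
                    )
                )
            subjects.append(SubjectData(subject_id, group, onset, tuple(scans)))
    return Cohort(spec, tuple(subjects), labels)


def expected_weight_matrix(
    spec: CohortSpec, group: str, voxels: Sequence[float] | None = None
) -> np.ndarray:
    """Analytic expectation of a group's symmetric weight matrix.

    The weight of edge (i, j) is ``counts[i, j]/voxels[i] +
    counts[j, i]/voxels[j]``, so its expectation is ``mu_ij * (1/v_i +
    1/v_j)``. When ``voxels`` is omitted the expectation is also taken over
    the uniform voxel-count distribution, replacing ``1/v`` with its exact
    mean over the integer range.
    """
    _, mu_base = _mask_and_mu(spec)
    mu = _group_mu(spec, group, mu_base)
    if voxels is None:
        lo, hi = spec.voxel_range
        inv_v = np.full(spec.n_nodes, np.mean(1.0 / np.arange(lo, hi + 1)))
    else:
        inv_v = 1.0 / np.asarray(voxels, dtype=float)
        if inv_v.shape != (spec.n_nodes,):
            raise ValueError("voxels must have one entry per node")
    expected = mu * inv_v[:, None] + mu.T * inv_v[None, :]
    np.fill_diagonal(expected, 0.0)
    return expected


def subject_backbone(subject: SubjectData, target_avg_degree: float = 4.0) -> WeightedNetwork:
    """Average a subject's scans into one network and extract its backbone."""
    from .network import BackboneConfig

    nets = [build_weight_matrix(tc) for tc, _ in subject.scans]
    return extract_backbone(average_networks(nets), BackboneConfig(target_avg_degree))


def calibrate_effect_multiplier(
    spec: CohortSpec,
    target_d: float = 1.0,
    n_pilot: int = 10,
    n_iter: int = 3,
) -> float:
    """Choose ``effect_multiplier`` so the injected backbone-strength effect
    has a given standardised size (Cohen's d, pooled SD) at the effect nodes.

    Runs small pilot ensembles of cohorts, measures the mean empirical d of
    nodal strength at ``spec.effect_nodes`` on per-subject backbones, and
    updates the multiplier by fixed-point iteration on the (approximately
    linear) relation between ``effect_multiplier - 1`` and d.
    """
    if not spec.effect_nodes:
        raise ValueError("spec.effect_nodes is empty; nothing to calibrate")

    labels = spec.node_labels()
    idx = [labels.index(v) for v in spec.effect_nodes]

    def measure(mult: float) -> float:
        ds = []
        for rep in range(n_pilot):
            s = replace(spec, effect_multiplier=mult, seed=spec.seed + 7919 * (rep + 1))
            cohort = generate_cohort(s)
            strengths = {g: [] for g in GROUPS}
            for subj in cohort.subjects:
                net = subject_backbone(subj)
                strengths[subj.group].append(net.weights.sum(axis=1)[idx])
            a = np.asarray(strengths[GROUPS[0]])
            b = np.asarray(strengths[GROUPS[1]])
            pooled = np.sqrt((a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)) / 2.0)
            ds.append(np.mean((b.mean(axis=0) - a.mean(axis=0)) / pooled))
        return float(np.mean(ds))

    mult = spec.effect_multiplier if spec.effect_multiplier != 1.0 else 1.5
    for _ in range(n_iter):
        d = measure(mult)
        if d <= 0:
            mult = 1.0 + 2.0 * (mult - 1.0)
            continue
        mult = 1.0 + (mult - 1.0) * target_d / d
    return float(mult)
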