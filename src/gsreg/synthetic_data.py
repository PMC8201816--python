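"""Ground-truth generators for the structuring and graph-learning experiments.

Three generators, each mirroring the statistical structure of one
experiment:

* :func:`generate_module_data` — n independent binary "feature modules":
  the 2^n binary codes replicated with Gaussian noise, so a learned feature
  graph should fragment into exactly n connected components.
* :func:`generate_hierarchy_data` — clusters within clusters: n_super
  well-separated super-clusters each containing n_sub Gaussian sub-clusters
  in a 15-dimensional ambient space.
* :func:`generate_trajectory_data` — a bifurcating progression: cells
  sampled along a Y-shaped piecewise-linear backbone with noise, standing in
  for differentiating cell populations (e.g. T cells diverging into two
  lineages), with branch labels and a scalar pseudotime.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModuleDataSpec",
    "HierarchyDataSpec",
    "TrajectoryDataSpec",
    "generate_module_data",
    "generate_hierarchy_data",
    "generate_trajectory_data",
]

TRUNK = "trunk"
BRANCH_PREFIX = "branch"


@dataclass(frozen=True)
class ModuleDataSpec:
    """Binary-pattern data with ``n_modules`` independent feature modules.

    The base patterns are the binary representations of 0 .. 2^n - 1 (one
    bit per feature), cycled until ``n_samples`` rows exist, each corrupted
    with fresh N(0, noise_sd^2) noise.  noise_sd defaults to 0.1.
    """

    n_modules: int
    n_samples: int | None = None
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples is not None and self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def resolved_n_samples(self) -> int:
        # default: 64 noisy replicates of each binary code
        return self.n_samples if self.n_samples is not None else 64 * 2**self.n_modules


@dataclass(frozen=True)
class HierarchyDataSpec:
    """3 super-clusters x 2 Gaussian sub-clusters in 15 dimensions (defaults).

    ``super_sep`` and ``sub_sep`` are the center spacings of the two levels;
    the hierarchy is realizable when super_sep > sub_sep > noise_sd.
    """

    n_super: int = 3
    n_sub: int = 2
    dim: int = 15
    per_cluster: int = 100
    super_sep: float = 10.0
    sub_sep: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_super", "n_sub", "dim", "per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (self.super_sep > self.sub_sep > self.noise_sd > 0):
            warnings.warn(
                "hierarchy may not be realizable: expected "
                "super_sep > sub_sep > noise_sd > 0",
                UserWarning,
                stacklevel=2,
            )
        if self.n_super > self.dim:
            raise ValueError("need dim >= n_super for orthogonal super-centers")


@dataclass(frozen=True)
class TrajectoryDataSpec:
    """Cells along a Y-shaped (bifurcating) piecewise-linear backbone.

    The trunk runs from the origin to the branch point at half the total
    arc length; ``n_branches`` branches then diverge symmetrically.  Cells
    are placed uniformly along arc length and jittered with isotropic
    Gaussian noise.  Pseudotime is the normalized arc-length position in
    [0, 1].
    """

    n_branches: int = 2
    dim: int = 10
    n_cells: int = 1000
    noise_sd: float = 0.05
    seed: int = 0
    backbone_length: float = 2.0  # total arc length trunk + one branch

    def __post_init__(self) -> None:
        if self.n_branches < 2:
            raise ValueError("n_branches must be >= 2 to produce a bifurcation")
        if self.dim < 3:
            raise ValueError("dim must be >= 3")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def generate_module_data(
    spec: ModuleDataSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate binary-module data.

    Returns
    -------
    data : ndarray of shape (n_samples, n_modules)
        Noisy binary patterns; feature j carries bit j.
    module_ids : ndarray of shape (n_modules,)
        Ground-truth module id per feature (bit index; each feature is its
        own singleton module).
    base_patterns : ndarray of shape (n_samples, n_modules)
        The noiseless binary code underlying each row.
    """
    n = spec.n_modules
    n_samples = spec.resolved_n_samples
    if n_samples < 2**n:
        warnings.warn(
            f"n_samples={n_samples} < 2^{n}: not every binary pattern is "
            "represented",
            UserWarning,
            stacklevel=2,
        )
    codes = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
    reps = -(-n_samples // 2**n)  # ceil
    base = np.tile(codes, (reps, 1))[:n_samples]
    rng = np.random.default_rng(spec.seed)
    data = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
    return data, np.arange(n), base


def generate_hierarchy_data(
    spec: HierarchyDataSpec = HierarchyDataSpec(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate clusters-within-clusters data.

    Super-centers sit on orthogonal coordinate axes at distance
    ``super_sep / sqrt(2)`` from the origin (so super-centers are exactly
    ``super_sep`` apart); each spawns ``n_sub`` sub-centers at distance
    ``sub_sep`` in random directions; rows are isotropic Gaussian noise
    around the sub-centers.

    Returns ``(data, super_labels, sub_labels)`` where data has
    ``n_super * n_sub * per_cluster`` rows.
    """
    rng = np.random.default_rng(spec.seed)
    radius = spec.super_sep / np.sqrt(2.0)
    super_centers = np.zeros((spec.n_super, spec.dim))
    for s in range(spec.n_super):
        super_centers[s, s] = radius

    rows, sup_lab, sub_lab = [], [], []
    for s in range(spec.n_super):
        for b in range(spec.n_sub):
            direction = rng.normal(size=spec.dim)
            direction /= np.linalg.norm(direction)
            center = super_centers[s] + spec.sub_sep * direction
            pts = center + rng.normal(0.0, spec.noise_sd, size=(spec.per_cluster, spec.dim))
            rows.append(pts)
            sup_lab.extend([s] * spec.per_cluster)
            sub_lab.extend([b] * spec.per_cluster)
    return np.vstack(rows), np.asarray(sup_lab), np.asarray(sub_lab)


def _backbone_points(spec: TrajectoryDataSpec, t: np.ndarray, branch: np.ndarray) -> np.ndarray:
    """Noiseless backbone position for pseudotime t in [0,1] and branch id.

    branch id 0 = trunk is ignored for t <= 0.5; for t > 0.5, branch id
    b in {1..n_branches} selects the diverging segment.
    """
    L = spec.backbone_length
    half = 0.5 * L
    trunk_dir = np.zeros(spec.dim)
    trunk_dir[0] = 1.0
    branch_point = half * trunk_dir

    pts = np.empty((len(t), spec.dim))
    on_trunk = t <= 0.5
    pts[on_trunk] = np.outer(t[on_trunk] * L, trunk_dir)
    for b in range(1, spec.n_branches + 1):
        # branch b leaves at 45 degrees within the (axis 0, axis b) plane,
        # alternating sign so two branches form a symmetric Y
        sign = 1.0 if b % 2 == 1 else -1.0
        d = np.zeros(spec.dim)
        d[0] = 1.0 / np.sqrt(2.0)
        d[min(b, spec.dim - 1)] = sign / np.sqrt(2.0)
        sel = (~on_trunk) & (branch == b)
        arc = (t[sel] - 0.5) * L
        pts[sel] = branch_point + np.outer(arc, d)
    return pts


def generate_trajectory_data(
    spec: TrajectoryDataSpec = TrajectoryDataSpec(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate bifurcating-trajectory data.

    Returns
    -------
    data : ndarray of shape (n_cells, dim)
    branch_labels : ndarray of str
        ``"trunk"`` for pseudotime <= 0.5, else ``"branch1"`` ...
        ``"branch<n_branches>"``.
    pseudotime : ndarray of shape (n_cells,)
        Normalized arc-length position in [0, 1]; the branch point sits at
        0.5.
    """
    rng = np.random.default_rng(spec.seed)
    t = rng.uniform(0.0, 1.0, size=spec.n_cells)
    branch = np.where(
        t <= 0.5, 0, rng.integers(1, spec.n_branches + 1, size=spec.n_cells)
    )
    pts = _backbone_points(spec, t, branch)
    data = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    labels = np.where(
        branch == 0, TRUNK, np.char.add(BRANCH_PREFIX, branch.astype(str))
    )
    return data, labels, t
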