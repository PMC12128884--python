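"""Synthetic multi-crystal studies with planted group structure.

The generator emulates the situation the clustering method targets:
several groups of isomorphous data sets whose true merged intensities
differ only by a small multiplicative perturbation on a minority of
reflections, observed partially (each data set sees a random subset, or a
contiguous wedge, of the unique reflections), with heteroscedastic
counting-statistics noise, optional sigma-inflated low-quality data sets
and planted outlier data sets drawn from unrelated intensities.

The intensity model per unique reflection h:

* base true intensity J_h ~ Exponential(1) (acentric Wilson statistics);
* group g truth J_h^(g) = J_h * exp(delta * z_hg) for a seeded fraction
  ``perturbed_fraction`` of reflections, z standard normal and
  independent per group, J_h elsewhere;
* each observation I = J^(g) + eps with eps ~ N(0, sigma_h^2) and
  sigma_h = noise_scale * sqrt(J^(g) + 1), replicated with Poisson
  multiplicity (minimum 1);
* a ``hetero_fraction`` of data sets have sigma (and the noise actually
  drawn) inflated threefold on a random half of their observations —
  per-observation quality loss of the kind produced by partiality errors
  or beam-centring drift, which uncertainty-aware correlation weighting
  can down-weight (a uniform inflation of a whole data set would leave
  the relative weights, and hence the weighted correlation, unchanged);
* each planted outlier data set perturbs the shared base intensities with
  a strong global log-normal factor built from a *shared* aberration mode
  plus an individual component, with per-outlier severity:
  J -> J * exp(outlier_delta * u_i * (z_shared + z_i) / sqrt(2)),
  u_i ~ U(0.7, 1.3).  This mimics how real aberrant data sets arise from
  a common failure mechanism (mis-centring, scale drift) of varying
  severity: they are far from every group yet correlated with the groups
  and partially with each other, occupying roughly one extra direction of
  the embedding.  Fully unrelated intensity realizations would instead be
  mutually orthogonal and inflate the apparent dimensionality of the
  study by one dimension per outlier, which is not how degraded data sets
  of the same crystal form behave.

Indices live on a cubic grid (identity-only symmetry, Friedel mates
merged) so d-spacings span a real range and the resolution filter has
something to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reflections import CrystalMetadata, ReflectionTable, write_study

__all__ = [
    "ScenarioConfig",
    "TruthLabels",
    "generate_study",
    "preset_scenarios",
    "write_truth",
    "read_truth",
]

HETERO_SIGMA_FACTOR = 3.0
DEFAULT_CELL_EDGE = 78.0  # angstrom, cubic — like the insulin test systems


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study; see the module docstring."""

    group_sizes: tuple[int, ...]
    n_unique: int = 3000
    coverage: float = 0.7
    delta: float = 0.3
    perturbed_fraction: float = 0.05
    noise_scale: float = 0.3
    hetero_fraction: float = 0.0
    n_outliers: int = 0
    outlier_delta: float = 0.3
    multiplicity_mean: float = 3.0
    wedge_mode: bool = False
    cell_edge: float = DEFAULT_CELL_EDGE
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        if not self.group_sizes or any(s < 1 for s in self.group_sizes):
            raise ValueError("group_sizes must be positive integers")
        if self.n_unique < 10:
            raise ValueError("n_unique too small")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        for name in ("perturbed_fraction", "hetero_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.delta < 0 or self.n_outliers < 0:
            raise ValueError("delta and n_outliers must be non-negative")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive (sigmas must be > 0)")
        if self.multiplicity_mean <= 0:
            raise ValueError("multiplicity_mean must be positive")

    @property
    def n_datasets(self) -> int:
        return sum(self.group_sizes) + self.n_outliers

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


@dataclass
class TruthLabels:
    """Planted group index per dataset_id; -1 marks planted outliers."""

    labels: dict[str, int] = field(default_factory=dict)

    def as_array(self, dataset_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in dataset_ids], dtype=np.int64)


def _cubic_grid_indices(n_unique: int) -> np.ndarray:
    """First n_unique Friedel-canonical cubic-grid indices by resolution."""
    limit = int(np.ceil((2.0 * n_unique) ** (1.0 / 3.0))) + 2
    rng_axis = np.arange(-limit, limit + 1)
    h, k, l = np.meshgrid(rng_axis, rng_axis, rng_axis, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    s2 = (hkl**2).sum(axis=1)
    hkl = hkl[s2 > 0]
    s2 = s2[s2 > 0]
    # keep the lexicographically greater of (v, -v): Friedel-canonical form
    neg = -hkl
    keep = (hkl[:, 0] > neg[:, 0]) | (
        (hkl[:, 0] == neg[:, 0])
        & ((hkl[:, 1] > neg[:, 1]) | ((hkl[:, 1] == neg[:, 1]) & (hkl[:, 2] > neg[:, 2])))
    )
    hkl, s2 = hkl[keep], s2[keep]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    hkl, s2 = hkl[order], s2[order]
    order = np.argsort(s2, kind="stable")
    if len(order) < n_unique:
        raise RuntimeError("index grid too small")  # pragma: no cover
    return hkl[order[:n_unique]]


def generate_study(
    cfg: ScenarioConfig,
) -> tuple[list[ReflectionTable], CrystalMetadata, TruthLabels]:
    """Simulate one study: reflection tables, metadata and truth labels.

    Deterministic in ``cfg.seed``; data sets are named ``dataset_###`` in
    group order with outliers last, so lexicographic file order preserves
    the generation order.
    """
    rng = np.random.default_rng(cfg.seed)
    hkl = _cubic_grid_indices(cfg.n_unique)
    base_j = rng.exponential(1.0, cfg.n_unique)

    group_j = []
    for _ in range(cfg.n_groups):
        mask = rng.random(cfg.n_unique) < cfg.perturbed_fraction
        z = rng.standard_normal(cfg.n_unique)
        jg = base_j.copy()
        jg[mask] *= np.exp(cfg.delta * z[mask])
        group_j.append(jg)

    outlier_shared_z = rng.standard_normal(cfg.n_unique)

    n = cfg.n_datasets
    n_hetero = int(round(cfg.hetero_fraction * n))
    hetero = np.zeros(n, dtype=bool)
    hetero[rng.choice(n, size=n_hetero, replace=False)] = True

    truth = TruthLabels()
    tables = []
    idx = 0
    membership = [(g, None) for g, size in enumerate(cfg.group_sizes) for _ in range(size)]
    membership += [(-1, None)] * cfg.n_outliers
    n_obs_per_set = max(1, int(round(cfg.coverage * cfg.n_unique)))
    for group, _ in membership:
        dataset_id = f"dataset_{idx:03d}"
        if group >= 0:
            true_j = group_j[group]
        else:
            # aberrant data set: shared failure mode, individual severity
            severity = cfg.outlier_delta * rng.uniform(0.7, 1.3)
            z = (outlier_shared_z + rng.standard_normal(cfg.n_unique)) / np.sqrt(2)
            true_j = base_j * np.exp(severity * z)
        if cfg.wedge_mode:
            start = rng.integers(0, cfg.n_unique)
            observed = (start + np.arange(n_obs_per_set)) % cfg.n_unique
        else:
            observed = rng.choice(cfg.n_unique, size=n_obs_per_set, replace=False)
        mult = np.maximum(1, rng.poisson(cfg.multiplicity_mean, len(observed)))
        rows = np.repeat(observed, mult)
        sigma = cfg.noise_scale * np.sqrt(np.maximum(true_j[rows], 0.0) + 1.0)
        if hetero[idx]:
            bad = rng.random(len(rows)) < 0.5
            sigma = np.where(bad, sigma * HETERO_SIGMA_FACTOR, sigma)
        intensity = true_j[rows] + rng.normal(0.0, sigma)
        tables.append(
            ReflectionTable(
                dataset_id=dataset_id,
                hkl=hkl[rows],
                intensity=intensity,
                sigma=sigma,
            )
        )
        truth.labels[dataset_id] = group
        idx += 1

    a = cfg.cell_edge
    meta = CrystalMetadata(
        unit_cell=(a, a, a, 90.0, 90.0, 90.0),
        symmetry_ops=[np.eye(3, dtype=np.int64)],
        space_group_name="P1",
        anomalous_flag=False,
    )
    return tables, meta, truth


def preset_scenarios() -> dict[str, ScenarioConfig]:
    """Named study shapes mirroring the experimental scenarios.

    * ``two_group_small`` — two groups of eight high-quality data sets
      (the bovine/human-style pairing).
    * ``three_group_balanced`` — three groups of twelve (the cryogenic
      three-species study).
    * ``three_group_unbalanced_outliers`` — populations 83/85/28 plus 19
      outliers, noisier and partly sigma-inflated (the large
      room-temperature study).
    * ``sparse_overlap`` — two groups of eight with coverage chosen so
      pairs share about 100 unique reflections (the low-common-reflection
      regime).
    """
    return {
        "two_group_small": ScenarioConfig(
            group_sizes=(8, 8),
            n_unique=3000,
            coverage=0.7,
            delta=0.3,
            perturbed_fraction=0.05,
            noise_scale=0.1,
            multiplicity_mean=4.0,
        ),
        "three_group_balanced": ScenarioConfig(
            group_sizes=(12, 12, 12),
            n_unique=3000,
            coverage=0.7,
            delta=0.3,
            perturbed_fraction=0.05,
            noise_scale=0.1,
            multiplicity_mean=3.0,
        ),
        "three_group_unbalanced_outliers": ScenarioConfig(
            group_sizes=(83, 85, 28),
            n_outliers=19,
            n_unique=2500,
            coverage=0.7,
            delta=0.3,
            perturbed_fraction=0.05,
            noise_scale=0.15,
            hetero_fraction=0.2,
            multiplicity_mean=3.0,
        ),
        # the low-common-reflection limit: coverage^2 * n_unique ~ 100
        # shared uniques per pair, clean high-quality noise so the binding
        # constraint is the reflection count.  The group difference is a
        # weak perturbation on every reflection (a real substitution
        # touches all structure factors slightly); a rare-but-strong
        # perturbation would make the ~10 shared perturbed reflections a
        # lottery rather than a systematic signal.
        "sparse_overlap": ScenarioConfig(
            group_sizes=(8, 8),
            n_unique=2500,
            coverage=0.2,
            delta=0.1,
            perturbed_fraction=1.0,
            noise_scale=0.05,
            multiplicity_mean=2.0,
        ),
    }


def write_truth(path, truth: TruthLabels) -> None:
    lines = [f"{k}\t{v}" for k, v in sorted(truth.labels.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path) -> TruthLabels:
    labels = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, value = line.split("\t")
        labels[name] = int(value)
    return TruthLabels(labels=labels)
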