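"""Probability-of-origin surfaces and odds-ratio assignment masks.

For every feather sample, the likelihood that a grid cell is the moult
origin is the multivariate normal density of the sample's isotope vector at
the cell's feather-isoscape means. The covariance is diagonal by default,
with per-isotope variance

    var_i(cell) = isoscape_sd_i(cell)^2 + analytical_sd_i^2

(the calibration residual is already folded into the feather isoscape SD).
Normalizing over valid cells gives a posterior origin surface (no spatial
prior by default); the "upper 50% (1:1 odds)" and "upper 75% (3:1 odds)"
binary maps are the smallest sets of highest-posterior cells accumulating
that much posterior mass — spatial credible regions for the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec
from .isoscape import IsoscapeStack

#: analytical (method) uncertainty per isotope, one SD, per mil
DEFAULT_ANALYTICAL_SD = {"2H": 2.0, "13C": 0.1, "15N": 0.2}

ISOTOPE_SETS = {"HCN": ("2H", "13C", "15N"), "CN": ("13C", "15N")}


@dataclass
class FeatherSample:
    """One individual's feather isotope measurement (per mil).

    delta-2H is on V-SMOW, delta-13C on V-PDB, delta-15N on Air. A missing
    delta-2H restricts the sample to the two-isotope (CN) set.
    """

    id: str
    d13C: float
    d15N: float
    d2H: float | None = None
    analytical_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTICAL_SD)
    )

    def __post_init__(self) -> None:
        if sum(v is not None for v in (self.d2H, self.d13C, self.d15N)) < 2:
            raise ValueError("a sample needs at least two isotope values")
        for iso in self.isotopes():
            if self.analytical_sd.get(iso, 0) <= 0:
                raise ValueError(f"analytical_sd for {iso} must be > 0")

    def isotopes(self) -> tuple[str, ...]:
        out = []
        if self.d2H is not None:
            out.append("2H")
        out.extend(["13C", "15N"])
        return tuple(out)

    def value(self, isotope: str) -> float:
        v = {"2H": self.d2H, "13C": self.d13C, "15N": self.d15N}[isotope]
        if v is None:
            raise KeyError(f"sample {self.id} has no {isotope} value")
        return float(v)

    def vector(self, isotopes: Sequence[str]) -> np.ndarray:
        return np.array([self.value(i) for i in isotopes])


def read_samples(path) -> list[FeatherSample]:
    """Read samples from a CSV with columns id, d2H, d13C, d15N.

    An empty d2H field marks the isotope as missing.
    """
    df = pd.read_csv(path)
    samples = []
    for _, row in df.iterrows():
        d2h = row.get("d2H")
        samples.append(
            FeatherSample(
                id=str(row["id"]),
                d2H=None if pd.isna(d2h) else float(d2h),
                d13C=float(row["d13C"]),
                d15N=float(row["d15N"]),
            )
        )
    return samples


@dataclass
class AssignmentSurface:
    """Per-cell origin likelihood (or posterior, once normalized)."""

    grid: GridSpec
    id: str
    isotope_set: str
    density: np.ndarray
    valid_mask: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.density.shape != self.grid.shape:
            raise ValueError("density shape does not match grid")
        if np.any(self.density[self.valid_mask] < 0):
            raise ValueError("density must be non-negative")
        if np.any(self.density[~self.valid_mask] != 0):
            raise ValueError("invalid cells must carry zero density")


@dataclass
class BinaryMask:
    """Likely (1) / unlikely (0) origin cells at one odds level."""

    grid: GridSpec
    id: str
    q: float
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.shape != self.grid.shape:
            raise ValueError("cells shape does not match grid")

    @property
    def n_assigned(self) -> int:
        return int(self.cells.sum())

    @property
    def odds_label(self) -> str:
        ratio = self.q / (1 - self.q)
        return f"{ratio:g}:1"


@dataclass
class CountRaster:
    """Per-cell count of individuals whose mask includes the cell."""

    grid: GridSpec
    counts: np.ndarray
    n_individuals: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid")
        if self.counts.min() < 0 or self.counts.max() > self.n_individuals:
            raise ValueError("counts must lie in [0, n_individuals]")


def _per_cell_variances(sample: FeatherSample, stack: IsoscapeStack,
                        isotopes: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(means, variances) arrays of shape (k, n_rows, n_cols)."""
    means = np.stack([stack.layer(i).mean for i in isotopes])
    var = np.stack(
        [stack.layer(i).sd_or_zero() ** 2 + sample.analytical_sd[i] ** 2 for i in isotopes]
    )
    return means, var


def likelihood_surface(sample: FeatherSample, stack: IsoscapeStack,
                       isotope_set: str = "HCN",
                       covariance: np.ndarray | None = None) -> AssignmentSurface:
    """Evaluate the origin likelihood of a sample over all valid cells.

    Parameters
    ----------
    sample, stack
        The feather measurement and the feather-equivalent isoscape stack.
    isotope_set
        "HCN" (2H, 13C, 15N) or "CN" (13C, 15N).
    covariance
        Optional k x k matrix added to the per-cell diagonal covariance
        (hook for off-diagonal error structure). Default: none (diagonal).
    """
    isotopes = ISOTOPE_SETS[isotope_set]
    missing = [i for i in isotopes if i not in stack.isotopes]
    if missing:
        raise KeyError(f"stack lacks isotopes {missing}")
    x = sample.vector(isotopes)
    sub = stack.subset(isotopes)
    mask = sub.joint_valid_mask
    means, var = _per_cell_variances(sample, sub, isotopes)
    k = len(isotopes)

    dev = x[:, None, None] - means
    if covariance is None:
        if np.any(var[:, mask] <= 0):
            raise ValueError("singular covariance: zero variance on a valid cell")
        log_d = -0.5 * (
            k * math.log(2 * math.pi)
            + np.sum(np.log(var), axis=0)
            + np.sum(dev**2 / var, axis=0)
        )
    else:
        covariance = np.asarray(covariance, dtype=float)
        if covariance.shape != (k, k):
            raise ValueError(f"covariance must be {k}x{k}")
        n_valid = int(mask.sum())
        log_d = np.full(stack.grid.shape, -np.inf)
        dev_v = dev[:, mask].T  # (n_valid, k)
        var_v = var[:, mask].T
        vals = np.empty(n_valid)
        for j in range(n_valid):
            cov_j = covariance + np.diag(var_v[j])
            sign, logdet = np.linalg.slogdet(cov_j)
            if sign <= 0:
                raise ValueError("singular covariance at a valid cell")
            sol = np.linalg.solve(cov_j, dev_v[j])
            vals[j] = -0.5 * (k * math.log(2 * math.pi) + logdet + dev_v[j] @ sol)
        log_d[mask] = vals

    density = np.zeros(stack.grid.shape)
    density[mask] = np.exp(log_d[mask])
    return AssignmentSurface(grid=stack.grid, id=sample.id, isotope_set=isotope_set,
                             density=density, valid_mask=mask, normalized=False)


def normalize(surface: AssignmentSurface,
              prior: np.ndarray | None = None) -> AssignmentSurface:
    """Convert a likelihood surface to a posterior over valid cells.

    ``prior`` is an optional per-cell prior weight (defaults to uniform over
    valid cells); the posterior is the weighted, renormalized likelihood.
    """
    density = surface.density
    if prior is not None:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != surface.grid.shape:
            raise ValueError("prior shape does not match grid")
        if np.any(prior[surface.valid_mask] < 0):
            raise ValueError("prior must be non-negative")
        density = density * np.where(surface.valid_mask, prior, 0.0)
    total = density[surface.valid_mask].sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero surface")
    out = np.zeros_like(density)
    out[surface.valid_mask] = density[surface.valid_mask] / total
    return replace(surface, density=out, normalized=True)


def _mass_mask(values: np.ndarray, q: float) -> np.ndarray:
    """Boolean mask of the smallest prefix of sorted values with mass >= q.

    ``values`` is a flat array of non-negative masses summing to ~1.
    All entries tying the last included value are included (tie rule);
    within distinct values the order (here: flat row-major index, i.e.
    row then column) is a deterministic total order.
    """
    order = np.argsort(-values, kind="stable")
    csum = np.cumsum(values[order])
    # first index where cumulative mass reaches q
    idx = int(np.searchsorted(csum, q - 1e-12))
    idx = min(idx, len(order) - 1)
    threshold = values[order[idx]]
    return values >= threshold


def odds_mask(surface: AssignmentSurface, q: float,
              method: str = "mass") -> BinaryMask:
    """Binarize a posterior surface at odds level ``q``.

    ``q=0.50`` is the 1:1-odds map, ``q=0.75`` the 3:1-odds map. The default
    ``method="mass"`` marks the smallest set of highest-posterior cells whose
    cumulative posterior mass reaches ``q`` (a credible region, making the
    odds literal). ``method="density_quantile"`` instead keeps cells whose
    posterior exceeds the (1-q) quantile of per-cell posterior values — an
    alternative reading of "upper q% of the probability densities".
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if not surface.normalized:
        raise ValueError("surface must be normalized before odds selection")
    mask = surface.valid_mask
    cells = np.zeros(surface.grid.shape, dtype=bool)
    vals = surface.density[mask]
    if method == "mass":
        sel = _mass_mask(vals, q)
    elif method == "density_quantile":
        thr = np.quantile(vals, 1 - q)
        sel = vals >= thr
    else:
        raise ValueError(f"unknown odds_mask method {method!r}")
    cells[mask] = sel
    return BinaryMask(grid=surface.grid, id=surface.id, q=q, cells=cells)


def stack_masks(masks: Iterable[BinaryMask]) -> CountRaster:
    """Sum individual binary assignment maps into a population count map."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to stack")
    g = masks[0].grid
    q = masks[0].q
    counts = np.zeros(g.shape, dtype=int)
    for m in masks:
        if not m.grid.same_geometry(g):
            raise ValueError("all masks must share one grid")
        if m.q != q:
            raise ValueError("all masks must share one odds level")
        counts += m.cells
    return CountRaster(grid=g, counts=counts, n_individuals=len(masks))
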