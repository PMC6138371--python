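"""Assignment of samples and grid cells to discrete isotopic clusters.

Continental-scale multi-isotope baselines are often summarized as a handful
of isotopically similar regions ("clusters"), each described by per-isotope
mean and SD. A sample is assigned by the Bayes posterior under per-cluster
Gaussians with a pooled (linear-discriminant) covariance:

    P(c | x)  proportional to  prior(c) * N(x; mean_c, Sigma_pooled)

The pooled covariance is diagonal by default — the prior-weighted mean of
per-cluster variances — which is the minimal linear-DFA construction when
only per-cluster means and SDs are available; a full pooled covariance can
be supplied instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import BinaryMask, FeatherSample
from .grid import GridSpec
from .isoscape import IsoscapeStack


@dataclass
class ClusterModel:
    """Per-cluster, per-isotope Gaussian statistics with priors.

    ``means`` and ``sds`` are (k, n_isotopes) arrays ordered like
    ``isotopes``; cluster ids are 1..k. Priors default to equal.
    """

    isotopes: Sequence[str]
    means: np.ndarray
    sds: np.ndarray
    priors: np.ndarray | None = None
    pooled_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = self.means.shape[0]
        if k < 2:
            raise ValueError("need at least two clusters")
        if self.means.shape != (k, len(self.isotopes)) or self.sds.shape != self.means.shape:
            raise ValueError("means/sds must be (k, n_isotopes)")
        if np.any(self.sds <= 0):
            raise ValueError("cluster SDs must be positive")
        if self.priors is None:
            self.priors = np.full(k, 1.0 / k)
        else:
            self.priors = np.asarray(self.priors, dtype=float)
            if self.priors.shape != (k,) or np.any(self.priors < 0):
                raise ValueError("priors must be k non-negative values")
            if not math.isclose(self.priors.sum(), 1.0, abs_tol=1e-6):
                raise ValueError("priors must sum to 1")
        if self.pooled_cov is not None:
            self.pooled_cov = np.asarray(self.pooled_cov, dtype=float)
            if self.pooled_cov.shape != (len(self.isotopes),) * 2:
                raise ValueError("pooled_cov must be n_isotopes x n_isotopes")

    @property
    def k(self) -> int:
        return self.means.shape[0]

    def pooled_covariance(self) -> np.ndarray:
        """Pooled within-cluster covariance (diagonal unless supplied)."""
        if self.pooled_cov is not None:
            return self.pooled_cov
        pooled_var = np.einsum("c,ci->i", self.priors, self.sds**2)
        return np.diag(pooled_var)

    @classmethod
    def from_csv(cls, path, priors: np.ndarray | None = None) -> "ClusterModel":
        """Read a cluster-stats CSV with columns cluster, isotope, mean, sd.

        Extra min/max columns are accepted and ignored with a warning.
        """
        df = pd.read_csv(path)
        extra = {c for c in df.columns} - {"cluster", "isotope", "mean", "sd"}
        if extra:
            warnings.warn(f"ignoring extra cluster-stats columns: {sorted(extra)}")
        clusters = sorted(df["cluster"].unique())
        isotopes = list(dict.fromkeys(df["isotope"]))
        wide_m = df.pivot(index="cluster", columns="isotope", values="mean")
        wide_s = df.pivot(index="cluster", columns="isotope", values="sd")
        return cls(
            isotopes=isotopes,
            means=wide_m.loc[clusters, isotopes].to_numpy(),
            sds=wide_s.loc[clusters, isotopes].to_numpy(),
            priors=priors,
        )

    def to_csv(self, path) -> None:
        rows = [
            {"cluster": c + 1, "isotope": iso, "mean": self.means[c, i], "sd": self.sds[c, i]}
            for c in range(self.k)
            for i, iso in enumerate(self.isotopes)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ClusterPosterior:
    """Posterior cluster membership of one sample (clusters numbered 1..k)."""

    id: str
    probs: np.ndarray
    hard_label: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0) or not math.isclose(self.probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("posterior must be non-negative and sum to 1")

    def percentages(self) -> np.ndarray:
        """Integer-percent rendering (the published-table dialect)."""
        return np.round(self.probs * 100).astype(int)


@dataclass
class ClusterRaster:
    """Per-cell maximum-posterior cluster label (0 = invalid cell)."""

    grid: GridSpec
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        if self.labels.min() < 0 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 0..k")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels > 0


def _log_gauss(x: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Per-cluster log prior * Gaussian density at points x (n, d)."""
    cov = model.pooled_covariance()
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("degenerate pooled covariance")
    prec = np.linalg.inv(cov)
    d = len(model.isotopes)
    dev = x[:, None, :] - model.means[None, :, :]  # (n, k, d)
    maha = np.einsum("nkd,de,nke->nk", dev, prec, dev)
    log_prior = np.log(np.where(model.priors > 0, model.priors, np.finfo(float).tiny))
    return log_prior[None, :] - 0.5 * (d * math.log(2 * math.pi) + logdet + maha)


def _posterior_from_log(logp: np.ndarray) -> np.ndarray:
    m = logp.max(axis=-1, keepdims=True)
    w = np.exp(logp - m)
    return w / w.sum(axis=-1, keepdims=True)


def cluster_posteriors(sample: FeatherSample, model: ClusterModel) -> ClusterPosterior:
    """Posterior probability that a sample originated from each cluster.

    Ties in the maximum posterior break toward the lowest cluster id.
    """
    x = sample.vector(model.isotopes)[None, :]
    probs = _posterior_from_log(_log_gauss(x, model))[0]
    return ClusterPosterior(id=sample.id, probs=probs, hard_label=int(np.argmax(probs)) + 1)


def classify_cells(stack: IsoscapeStack, model: ClusterModel) -> ClusterRaster:
    """Label every valid cell with its maximum-posterior cluster."""
    missing = [i for i in model.isotopes if i not in stack.isotopes]
    if missing:
        raise KeyError(f"stack lacks isotopes {missing}")
    sub = stack.subset(model.isotopes)
    mask = sub.joint_valid_mask
    x = np.stack([sub.layer(i).mean[mask] for i in model.isotopes], axis=1)
    labels = np.zeros(stack.grid.shape, dtype=int)
    if x.size:
        logp = _log_gauss(x, model)
        labels[mask] = np.argmax(logp, axis=1) + 1
    return ClusterRaster(grid=stack.grid, labels=labels, k=model.k)


def cluster_composition(cells: BinaryMask, clusters: ClusterRaster,
                        decimals: int = 0) -> np.ndarray:
    """Percentage of mask cells assigned to each cluster (sums to ~100).

    Mask cells falling on invalid (unlabeled) cluster cells are dropped from
    the denominator. ``decimals`` controls reporting precision (0 = the
    integer dialect of the published tables; raw percentages for decimals<0).
    """
    sel = cells.cells & clusters.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty mask (no labeled cells under the mask)")
    counts = np.bincount(clusters.labels[sel], minlength=clusters.k + 1)[1:]
    pct = counts / n * 100.0
    if decimals >= 0:
        pct = np.round(pct, decimals)
    return pct


def correspondence_count(posteriors: Iterable[ClusterPosterior],
                         compositions: Mapping[str, np.ndarray],
                         threshold: float = 50.0,
                         rule: str = "at_least") -> int:
    """Count individuals whose DFA cluster dominates their KDE composition.

    An individual corresponds when the composition percentage of its
    hard-labeled cluster meets the threshold under ``rule`` ("at_least",
    i.e. >=, the default; or "strict", i.e. >).
    """
    if rule not in ("at_least", "strict"):
        raise ValueError(f"unknown rule {rule!r}")
    posteriors = list(posteriors)
    ids = {p.id for p in posteriors}
    if ids != set(compositions):
        raise ValueError("posterior and composition individuals differ")
    count = 0
    for p in posteriors:
        pct = np.asarray(compositions[p.id], dtype=float)[p.hard_label - 1]
        if pct >= threshold if rule == "at_least" else pct > threshold:
            count += 1
    return count


def posterior_table(posteriors: Sequence[ClusterPosterior]) -> pd.DataFrame:
    """Render posteriors as an id + integer-percentage table (Cn columns)."""
    k = len(posteriors[0].probs)
    rows = [
        {"id": p.id, **{f"C{c + 1}": int(p.percentages()[c]) for c in range(k)}}
        for p in posteriors
    ]
    return pd.DataFrame(rows)
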