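"""Synthetic isoscapes, feather samples and geolocator tracks.

The generator builds a self-consistent world in which every stage of the
pipeline has a known truth:

* each source isoscape is a smooth continental-scale plane (a per-isotope
  gradient in permil per degree) plus a Gaussian random field of chosen
  amplitude and correlation length — emulating large-scale isotopic
  gradients with spatially structured model error;
* feather values are the calibrated feather-isoscape value at a true moult
  site plus independent Gaussian noise;
* geolocator fixes scatter around the true residence site with larger
  latitudinal than longitudinal error, as light-level positions do.

Defaults follow the study conditions: a 0.33 degree grid, analytical SDs of
2.0 / 0.1 / 0.2 permil for 2H / 13C / 15N, and fixes spanning the stationary
non-breeding window (October to March). All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans

from .assignment import DEFAULT_ANALYTICAL_SD, FeatherSample
from .clusters import ClusterModel
from .grid import GridSpec
from .isoscape import CalibrationModel, IsoscapeRaster, IsoscapeStack, feather_stack
from .kde import GeoFix

#: documented placeholder for the precipitation-to-feather 2H transfer
DEFAULT_CALIBRATION = CalibrationModel(
    h_slope=0.95, h_intercept=-25.0, h_residual_sd=12.0,
    c13_offset=2.0, n15_offset=5.0, c13_residual_sd=1.0, n15_residual_sd=1.0,
)

#: per-isotope gradients, permil per degree (continental-scale magnitudes)
DEFAULT_GRADIENTS = {
    "2H": (0.3, 1.2),   # (per degree lon, per degree lat)
    "13C": (0.15, 0.25),
    "15N": (0.1, 0.2),
}
DEFAULT_BASE = {"2H": -40.0, "13C": -22.0, "15N": 6.0}
DEFAULT_NOISE_AMPLITUDE = {"2H": 6.0, "13C": 1.0, "15N": 1.0}


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Parameters of a synthetic study region."""

    grid: GridSpec = GridSpec(lon_min=-20.0, lat_max=20.0, n_rows=100, n_cols=100,
                              resolution=0.33)
    gradients: dict = field(default_factory=lambda: dict(DEFAULT_GRADIENTS))
    base: dict = field(default_factory=lambda: dict(DEFAULT_BASE))
    noise_amplitude: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_AMPLITUDE))
    correlation_length: float = 3.0  # degrees
    land_fraction: float = 0.9
    isoscape_sd: dict = field(default_factory=lambda: {"2H": 8.0, "13C": 1.5, "15N": 1.5})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if not 0 < self.land_fraction <= 1:
            raise ValueError("land_fraction must be in (0, 1]")


@dataclass
class SyntheticWorld:
    """A generated world: source and feather stacks plus known truth."""

    spec: SyntheticWorldSpec
    source_stack: IsoscapeStack   # precipitation 2H + plant 13C/15N
    feather_stack: IsoscapeStack  # calibrated feather-equivalent layers
    calibration: CalibrationModel
    cluster_models: dict[str, ClusterModel]  # isotope_set -> model


def gaussian_random_field(shape: tuple[int, int], correlation_cells: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth field: Gaussian-smoothed white noise, restandardized.

    Smoothing white noise with a Gaussian kernel of scale sigma yields a
    Gaussian autocorrelation exp(-lag^2 / (4 sigma^2)); sigma is chosen as
    half the requested correlation length so the autocorrelation falls to
    1/e exactly at ``correlation_cells``.
    """
    sigma = correlation_cells / 2.0
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def make_world(spec: SyntheticWorldSpec,
               calibration: CalibrationModel | None = None) -> SyntheticWorld:
    """Generate source isoscapes, feather layers, calibration and clusters.

    Deterministic for a given spec (including its seed). The land mask is a
    smooth field thresholded at the requested land fraction, shared by all
    layers. Cluster statistics (4 clusters for HCN, 5 for CN) are fitted by
    k-means on the feather-layer values of land cells. ``calibration``
    overrides the shipped default transfer function.
    """
    g = spec.grid
    rng = np.random.default_rng(spec.seed)
    corr_cells = spec.correlation_length / g.resolution

    lon = g.lon_centers()[None, :]
    lat = g.lat_centers()[:, None]

    if spec.land_fraction >= 1.0:
        mask = np.ones(g.shape, dtype=bool)
    else:
        sea_field = gaussian_random_field(g.shape, corr_cells, rng)
        thr = np.quantile(sea_field, 1.0 - spec.land_fraction)
        mask = sea_field >= thr

    layers = []
    for iso in ("2H", "13C", "15N"):
        glon, glat = spec.gradients[iso]
        mean = spec.base[iso] + glon * (lon - g.lon_min) + glat * (lat - g.lat_min)
        amp = spec.noise_amplitude[iso]
        if amp > 0:
            mean = mean + amp * gaussian_random_field(g.shape, corr_cells, rng)
        sd = np.full(g.shape, spec.isoscape_sd.get(iso, 0.0))
        layers.append(IsoscapeRaster(grid=g, isotope=iso, mean=mean, sd=sd,
                                     valid_mask=mask.copy()))
    source = IsoscapeStack(layers)

    cal = calibration if calibration is not None else DEFAULT_CALIBRATION
    feather = feather_stack(source.layer("2H"), source.layer("13C"),
                            source.layer("15N"), cal)

    cluster_models = {}
    for iso_set, isotopes, k in (("HCN", ("2H", "13C", "15N"), 4), ("CN", ("13C", "15N"), 5)):
        x = np.stack([feather.layer(i).mean[mask] for i in isotopes], axis=1)
        km = KMeans(n_clusters=k, n_init=4, random_state=spec.seed).fit(x)
        order = np.argsort(km.cluster_centers_[:, 0])
        means = np.empty((k, len(isotopes)))
        sds = np.empty((k, len(isotopes)))
        for rank, c in enumerate(order):
            sel = km.labels_ == c
            means[rank] = x[sel].mean(axis=0)
            sds[rank] = np.maximum(x[sel].std(axis=0), 0.5)
        cluster_models[iso_set] = ClusterModel(isotopes=isotopes, means=means, sds=sds)

    return SyntheticWorld(spec=spec, source_stack=source, feather_stack=feather,
                          calibration=cal, cluster_models=cluster_models)


@dataclass(frozen=True)
class IndividualParams:
    """Noise and sampling parameters for one simulated individual."""

    feather_noise_sd: dict | None = None  # None = matched to assignment model
    fix_sd_lon_km: float = 60.0
    fix_sd_lat_km: float = 150.0
    n_fixes: int = 50

    def __post_init__(self) -> None:
        if self.fix_sd_lat_km < self.fix_sd_lon_km:
            raise ValueError("latitudinal fix error must be >= longitudinal error")
        if self.n_fixes < 1:
            raise ValueError("need at least one fix")


@dataclass
class SyntheticIndividual:
    id: str
    true_site: tuple[float, float]  # (lon, lat)
    feather: FeatherSample
    fixes: list[GeoFix]
    params: IndividualParams
    seed: int


def _nonbreeding_dates(n: int, rng: np.random.Generator, year: int = 2010) -> list[date]:
    """n dates drawn from the stationary window Oct 1 .. Mar 1, sorted."""
    start = date(year, 10, 1)
    span = (date(year + 1, 3, 1) - start).days
    offsets = np.sort(rng.choice(span, size=n, replace=n > span))
    return [start + timedelta(days=int(o)) for o in offsets]


def simulate_individual(world: SyntheticWorld, true_site: tuple[float, float],
                        params: IndividualParams | None = None, seed: int = 0,
                        id: str | None = None) -> SyntheticIndividual:
    """Simulate one bird: a feather sample and a cloud of geolocator fixes.

    The feather value per isotope is the feather-layer mean at the true
    site's cell plus Gaussian noise. By default the noise SD is *matched* to
    the assignment model — sqrt(layer sd^2 + analytical sd^2) — so that
    credible-region coverage is calibrated by construction; explicit
    per-isotope SDs can be supplied instead (e.g. to study misspecification).
    """
    params = params or IndividualParams()
    rng = np.random.default_rng(seed)
    g = world.feather_stack.grid
    lon, lat = true_site
    row, col = g.cell_of(lon, lat)
    if not world.feather_stack.joint_valid_mask[row, col]:
        raise ValueError(f"true site {true_site} is not on a valid land cell")

    values = {}
    for iso in ("2H", "13C", "15N"):
        layer = world.feather_stack.layer(iso)
        if params.feather_noise_sd is None:
            noise_sd = float(np.sqrt(layer.sd_or_zero()[row, col] ** 2
                                     + DEFAULT_ANALYTICAL_SD[iso] ** 2))
        else:
            noise_sd = float(params.feather_noise_sd.get(iso, 0.0))
        values[iso] = float(layer.mean[row, col]) + rng.normal(0.0, noise_sd)

    label = id if id is not None else f"SYN{seed:04d}"
    feather = FeatherSample(id=label, d2H=values["2H"], d13C=values["13C"],
                            d15N=values["15N"])

    km_per_deg_lat = 111.320
    km_per_deg_lon = 111.320 * np.cos(np.radians(lat))
    dlon = rng.normal(0.0, params.fix_sd_lon_km / km_per_deg_lon, params.n_fixes)
    dlat = rng.normal(0.0, params.fix_sd_lat_km / km_per_deg_lat, params.n_fixes)
    dates = _nonbreeding_dates(params.n_fixes, rng)
    fixes = [
        GeoFix(id=label, date=d,
               lon=float(np.clip(lon + dx, -180, 180)),
               lat=float(np.clip(lat + dy, -90, 90)))
        for d, dx, dy in zip(dates, dlon, dlat)
    ]
    return SyntheticIndividual(id=label, true_site=true_site, feather=feather,
                               fixes=fixes, params=params, seed=seed)


def coverage_experiment(n: int = 500, seed: int = 0,
                        q_levels: tuple[float, ...] = (0.50, 0.75),
                        spec: SyntheticWorldSpec | None = None,
                        isotope_set: str = "HCN") -> dict[float, float]:
    """Credible-region coverage of the assignment under a matched model.

    Simulates ``n`` individuals with true sites drawn uniformly from the
    valid cells (the same prior the assignment uses), assigns each feather
    with the generating isoscapes and noise model, and returns the fraction
    of replicates whose true cell falls inside each odds mask. With the
    model correctly specified this is calibrated: coverage tracks q.
    """
    from .assignment import likelihood_surface, normalize, odds_mask

    spec = spec or SyntheticWorldSpec(
        grid=GridSpec(lon_min=-10.0, lat_max=10.0, n_rows=60, n_cols=60,
                      resolution=0.33),
        seed=seed,
    )
    world = make_world(spec)
    g = world.feather_stack.grid
    # collision-free per-replicate seeds derived from the experiment seed
    sub_seeds = np.random.SeedSequence([seed, 202]).generate_state(n + 1) & 0x7FFFFFFF
    sites = sample_land_sites(world, n, seed=int(sub_seeds[0]), margin_cells=0)
    hits = {q: 0 for q in q_levels}
    for i, site in enumerate(sites):
        ind = simulate_individual(world, site, seed=int(sub_seeds[i + 1]))
        surf = normalize(likelihood_surface(ind.feather, world.feather_stack,
                                            isotope_set))
        r, c = g.cell_of(*site)
        for q in q_levels:
            hits[q] += bool(odds_mask(surf, q).cells[r, c])
    return {q: hits[q] / n for q in q_levels}


def sample_land_sites(world: SyntheticWorld, n: int, seed: int,
                      margin_cells: int = 2) -> list[tuple[float, float]]:
    """n cell-center sites drawn uniformly from valid land cells.

    ``margin_cells`` keeps sites away from the grid edge so that KDE and
    assignment windows remain inside the domain.
    """
    g = world.feather_stack.grid
    rng = np.random.default_rng(seed)
    mask = world.feather_stack.joint_valid_mask.copy()
    m = margin_cells
    if m > 0:
        interior = np.zeros_like(mask)
        interior[m:-m, m:-m] = True
        mask &= interior
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no valid interior land cells to sample")
    idx = rng.choice(rows.size, size=n, replace=True)
    return [g.center_of(int(r), int(c)) for r, c in zip(rows[idx], cols[idx])]
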