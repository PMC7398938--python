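"""Virtual-species simulation.

Generates the fixtures the pipeline is validated on: spatially
autocorrelated standardized covariates (with deliberately collinear
copies to exercise collinearity filtering), a categorical land-cover
layer, a logistic true-suitability surface, presence points sampled in
proportion to that surface, and "future" covariate stacks produced by
additive climate shifts.  Because the true response is known, downstream
predictions can be scored against ground truth — the standard
virtual-species benchmarking approach for distribution models.

Spatial autocorrelation is induced by Gaussian-kernel smoothing of white
noise; all generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import CapacityError, ConfigError
from .grids import Grid


@dataclass
class VirtualSpeciesConfig:
    """Parameters of one simulated species and its landscape.

    The defaults describe the reference study system used throughout the
    test-suite: a 64x64 window of 0.05-degree cells over an arid-lowland
    extent, three informative climate covariates with mixed-sign effects,
    two nearly-collinear copies (correlation ~0.995 with their parents),
    and presence/background sample sizes typical of a national-scale
    invasive-species dataset.
    """

    grid_rows: int = 64
    grid_cols: int = 64
    cell_size_deg: float = 0.05
    origin_lon: float = 39.0
    origin_lat: float = 12.0
    autocorr_range: float = 6.0
    n_informative: int = 3
    n_collinear: int = 2
    collinear_noise_sd: float = 0.1
    coefficients: list = field(default_factory=lambda: [2.5, -2.0, 1.5])
    intercept: float = -1.0
    n_presences: int = 662
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ConfigError("grid must be at least 8x8")
        if self.n_informative < 2:
            raise ConfigError("need at least 2 informative covariates")
        if self.n_collinear < 0 or self.n_collinear > self.n_informative:
            raise ConfigError(
                "n_collinear must be between 0 and n_informative")
        if len(self.coefficients) not in (self.n_informative,
                                          2 * self.n_informative):
            raise ConfigError(
                "coefficients must cover the linear terms (one per "
                "informative covariate) or linear + quadratic terms")
        if self.n_presences < 1:
            raise ConfigError("n_presences must be positive")
        if self.collinear_noise_sd <= 0:
            raise ConfigError("collinear_noise_sd must be positive")


def generate_covariate_grid(rows: int, cols: int, autocorr_range: float,
                            seed: int, origin_lon: float = 0.0,
                            origin_lat: float = 0.0,
                            cell_size: float = 1.0) -> Grid:
    """Spatially autocorrelated covariate, standardized to mean 0 / sd 1.

    White noise is smoothed with a Gaussian kernel of scale
    ``autocorr_range`` (in cells) and re-standardized, giving a smooth
    random field whose correlation length is set by the kernel scale —
    a lightweight stand-in for a gridded climate layer.
    """
    if rows < 8 or cols < 8:
        raise ConfigError("rows and cols must each be >= 8")
    if autocorr_range <= 0:
        raise ConfigError("autocorr_range must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((rows, cols))
    smooth = gaussian_filter(noise, sigma=autocorr_range, mode="reflect")
    smooth = (smooth - smooth.mean()) / smooth.std()
    return Grid(smooth, origin_lon, origin_lat, cell_size)


def add_collinear_covariate(base: Grid, noise_sd: float, seed: int) -> Grid:
    """Near-copy of ``base``: base plus iid Gaussian noise of sd ``noise_sd``.

    For a standardized base the expected Pearson correlation with the copy
    is 1/sqrt(1 + noise_sd^2), so small ``noise_sd`` yields the strong
    collinearity that VIF screening is meant to catch.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = base.values + rng.normal(0.0, noise_sd, size=base.shape)
    return base.with_values(np.where(base.mask, noisy, np.nan))


def make_true_suitability(covariates: list[Grid], coefficients: list[float],
                          intercept: float) -> Grid:
    """Logistic true-suitability surface.

    suitability = 1 / (1 + exp(-(intercept + sum coef_j * term_j)))

    Terms are the covariates in order; if ``coefficients`` is twice as
    long as ``covariates`` the second half weights the squared covariates
    (quadratic niche response).  Nodata in any covariate propagates.
    """
    if not covariates:
        raise ConfigError("need at least one covariate")
    ncov = len(covariates)
    if len(coefficients) not in (ncov, 2 * ncov):
        raise ConfigError(
            f"got {len(coefficients)} coefficients for {ncov} covariates; "
            "expected one per covariate (linear) or two per covariate "
            "(linear + quadratic)")
    ref = covariates[0]
    for g in covariates[1:]:
        ref.require_same_geometry(g)
    eta = np.full(ref.shape, float(intercept))
    for j, g in enumerate(covariates):
        eta = eta + coefficients[j] * g.values
    if len(coefficients) == 2 * ncov:
        for j, g in enumerate(covariates):
            eta = eta + coefficients[ncov + j] * g.values ** 2
    suit = 1.0 / (1.0 + np.exp(-eta))
    return ref.with_values(suit)


def sample_presences(suitability: Grid, n: int, seed: int):
    """Draw ``n`` presence points at distinct cell centres, with selection
    probability proportional to suitability.

    Returns a pandas DataFrame with columns id, lon, lat, label (=1),
    partition (="unassigned") — the package's occurrence-table schema.
    """
    import pandas as pd

    if n < 1:
        raise ConfigError("n must be >= 1")
    valid = suitability.mask & (np.nan_to_num(suitability.values) > 0)
    idx = np.flatnonzero(valid.ravel())
    if idx.size < n:
        raise CapacityError(
            f"requested {n} presences but only {idx.size} cells have "
            "positive suitability", eligible=int(idx.size))
    weights = suitability.values.ravel()[idx]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False, p=weights / weights.sum())
    rows, cols = np.unravel_index(chosen, suitability.shape)
    lon, lat = suitability.cell_center(rows, cols)
    return pd.DataFrame({
        "id": [f"p{i}" for i in range(n)],
        "lon": lon,
        "lat": lat,
        "label": 1,
        "partition": "unassigned",
    })


def make_future_scenario(covariates: list[Grid],
                         shifts: list[float]) -> list[Grid]:
    """Additively shifted covariate stack (simple climate-change emulation)."""
    if len(shifts) != len(covariates):
        raise ConfigError(
            f"{len(shifts)} shifts for {len(covariates)} covariates")
    return [g.with_values(np.where(g.mask, g.values + s, np.nan))
            for g, s in zip(covariates, shifts)]


def make_landcover(rows: int, cols: int, autocorr_range: float, seed: int,
                   n_classes: int = 4, origin_lon: float = 0.0,
                   origin_lat: float = 0.0, cell_size: float = 1.0) -> Grid:
    """Categorical land-cover layer: a smoothed field cut into
    ``n_classes`` integer classes at its quantiles."""
    base = generate_covariate_grid(rows, cols, autocorr_range, seed,
                                   origin_lon, origin_lat, cell_size)
    qs = np.quantile(base.values, np.linspace(0, 1, n_classes + 1)[1:-1])
    classes = np.digitize(base.values, qs).astype(float)
    return base.with_values(classes)


def simulate_virtual_species(config: VirtualSpeciesConfig):
    """Build the full fixture for one virtual species.

    Returns a dict with: ``covariates`` (informative + collinear, in
    order), ``names``, ``kinds``, ``landcover``, ``truth`` (suitability
    grid), ``presences`` (occurrence table) and ``future`` — a mapping of
    scenario tag to the shifted covariate list.  Future scenarios shift
    the informative covariates by scenario-scaled amounts (collinear
    copies shift with their parents), emulating a stabilisation pathway
    and a high-emission pathway at two horizons.
    """
    cfg = config
    geo = dict(origin_lon=cfg.origin_lon, origin_lat=cfg.origin_lat,
               cell_size=cfg.cell_size_deg)
    covs = [generate_covariate_grid(cfg.grid_rows, cfg.grid_cols,
                                    cfg.autocorr_range, cfg.seed + 11 * j,
                                    **geo)
            for j in range(cfg.n_informative)]
    names = [f"bio{j + 1}" for j in range(cfg.n_informative)]
    for j in range(cfg.n_collinear):
        covs.append(add_collinear_covariate(covs[j], cfg.collinear_noise_sd,
                                            cfg.seed + 1000 + j))
        names.append(f"bio{j + 1}_dup")
    kinds = ["continuous"] * len(covs)
    landcover = make_landcover(cfg.grid_rows, cfg.grid_cols,
                               cfg.autocorr_range, cfg.seed + 5000, **geo)
    truth = make_true_suitability(covs[:cfg.n_informative], cfg.coefficients,
                                  cfg.intercept)
    presences = sample_presences(truth, cfg.n_presences, cfg.seed + 7000)

    # Future stacks: shift each informative covariate toward higher
    # suitability (sign of its linear coefficient), scaled by scenario
    # severity; collinear duplicates inherit their parent's shift.
    base_shift = [0.25 * np.sign(c) if c != 0 else 0.0
                  for c in cfg.coefficients[:cfg.n_informative]]
    scenario_scale = {"RCP4.5-2050": 1.0, "RCP8.5-2050": 1.6,
                      "RCP4.5-2070": 2.2, "RCP8.5-2070": 3.0}
    future = {}
    for tag, scale in scenario_scale.items():
        shifts = [s * scale for s in base_shift]
        shifts += [shifts[j] for j in range(cfg.n_collinear)]
        future[tag] = make_future_scenario(covs, shifts)
    return {"covariates": covs, "names": names, "kinds": kinds,
            "landcover": landcover, "truth": truth, "presences": presences,
            "future": future}
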