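"""Virtual-species worlds: correlated bioclim-like raster stacks with a known
truth surface, presence samples drawn from it, and shifted "future" stacks.

The generator builds each layer as a linear combination of smooth latent
fields (seeded white noise convolved with a Gaussian kernel, standardized)
plus independent cell noise, then maps it affinely onto a plausible bioclim
range.  The loading matrix controls the pairwise Pearson correlations between
layers, so worlds can be built that contain |r| > 0.8 pairs for exercising
collinearity screening.  True suitability is a product of response terms
(Gaussian or logistic in a layer's value), each rescaled to [0, 1], so the
species' niche is known exactly and parameter recovery can be measured.

Presences are sampled proportionally to true suitability (not thresholded),
which leaves a meaningful ceiling below 1 on achievable discrimination (AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geo import GeoPoint, LatLonGrid, RasterLayer, RasterStack
from .occurrences import OccurrenceRecord, OccurrenceSet

__all__ = ["ResponseTerm", "VirtualSpeciesConfig", "TruthRecord",
           "generate_stack", "sample_presences", "shift_scenario",
           "default_config", "implied_correlations", "BIOCLIM_RANGES"]


#: Plausible value ranges for the 19 bioclimatic summaries, used to map the
#: dimensionless latent combinations onto realistic units (°C, mm, etc.).
BIOCLIM_RANGES: dict[str, tuple[float, float]] = {
    "bio1": (8.0, 28.0), "bio2": (6.0, 14.0), "bio3": (20.0, 60.0),
    "bio4": (300.0, 900.0), "bio5": (22.0, 38.0), "bio6": (-8.0, 15.0),
    "bio7": (15.0, 40.0), "bio8": (10.0, 28.0), "bio9": (0.0, 25.0),
    "bio10": (18.0, 30.0), "bio11": (-2.0, 18.0), "bio12": (400.0, 2200.0),
    "bio13": (100.0, 400.0), "bio14": (5.0, 80.0), "bio15": (30.0, 110.0),
    "bio16": (300.0, 1000.0), "bio17": (20.0, 250.0), "bio18": (200.0, 700.0),
    "bio19": (30.0, 300.0),
}


#: Default future-scenario perturbations for the reference world: progressive
#: warming of the causal temperature layer with mild precipitation scaling,
#: enough to genuinely gain and lose suitable cells between scenarios.
DEFAULT_SCENARIO_DELTAS: dict[str, dict[str, float]] = {
    "2050s_SSP1-2.6": {"bio1": 1.0, "bio12": 1.03},
    "2050s_SSP2-4.5": {"bio1": 1.6, "bio12": 1.05},
    "2050s_SSP5-8.5": {"bio1": 2.6, "bio12": 1.08},
}
#: Layers in DEFAULT_SCENARIO_DELTAS treated multiplicatively (precipitation-like).
DEFAULT_MULTIPLICATIVE = {"bio12"}


@dataclass(frozen=True)
class ResponseTerm:
    """One multiplicative term of the true suitability function.

    ``gaussian``: exp(−(v − a)² / (2 b²)) with a = optimum, b = niche breadth.
    ``logistic``: 1 / (1 + exp(−a (v − b))) with a = slope, b = midpoint.
    """

    layer: str
    form: str  # "gaussian" | "logistic"
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.form not in ("gaussian", "logistic"):
            raise ValueError(f"unknown response form {self.form!r}")
        if self.form == "gaussian" and self.b <= 0:
            raise ValueError("gaussian breadth must be positive")

    def evaluate(self, v: np.ndarray) -> np.ndarray:
        if self.form == "gaussian":
            return np.exp(-0.5 * ((v - self.a) / self.b) ** 2)
        return 1.0 / (1.0 + np.exp(-self.a * (v - self.b)))


@dataclass
class VirtualSpeciesConfig:
    grid: LatLonGrid
    layer_names: list[str]
    n_latent: int
    loading: np.ndarray                      # (n_layers, n_latent)
    noise_sd: float = 0.1
    length_scale_cells: float = 8.0
    responses: list[ResponseTerm] = field(default_factory=list)
    n_presence: int = 374
    jitter_sd_deg: float = 0.02
    seed: int = 0
    layer_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loading = np.asarray(self.loading, dtype=float)
        if self.loading.shape != (len(self.layer_names), self.n_latent):
            raise ValueError("loading matrix must be (n_layers, n_latent)")
        if not self.responses:
            raise ValueError("at least one response term is required")
        for term in self.responses:
            if term.layer not in self.layer_names:
                raise ValueError(f"response references unknown layer {term.layer!r}")
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")

    @property
    def causal_layers(self) -> list[str]:
        return [t.layer for t in self.responses]


@dataclass
class TruthRecord:
    """Ground truth for a generated world: the suitability surface and the
    response function that produced it."""

    suitability: RasterLayer
    responses: list[ResponseTerm]
    causal_layers: list[str]


def _smooth_standard_field(rng: np.ndarray, shape: tuple[int, int],
                           length_scale: float) -> np.ndarray:
    raw = rng.standard_normal(shape)
    if length_scale > 0:
        raw = gaussian_filter(raw, sigma=length_scale, mode="reflect")
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate latent field (zero variance)")
    return (raw - raw.mean()) / sd


def generate_stack(config: VirtualSpeciesConfig) -> tuple[RasterStack, TruthRecord]:
    """Generate the world's raster stack and its truth record (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    shape = (config.grid.n_rows, config.grid.n_cols)

    latents = np.stack([
        _smooth_standard_field(rng, shape, config.length_scale_cells)
        for _ in range(config.n_latent)
    ])
    layers = []
    ranges = {**BIOCLIM_RANGES, **config.layer_ranges}
    for i, name in enumerate(config.layer_names):
        combo = np.tensordot(config.loading[i], latents, axes=(0, 0))
        if config.noise_sd > 0:
            combo = combo + config.noise_sd * rng.standard_normal(shape)
        lo_v, hi_v = combo.min(), combo.max()
        if hi_v - lo_v <= 0:
            raise ValueError(f"layer {name!r} is constant; check the loading matrix")
        lo, hi = ranges.get(name, (0.0, 1.0))
        values = lo + (hi - lo) * (combo - lo_v) / (hi_v - lo_v)
        layers.append(RasterLayer(grid=config.grid, name=name, values=values))
    stack = RasterStack(layers)

    truth = compute_truth(stack, config.responses)
    return stack, truth


def compute_truth(stack: RasterStack, responses: list[ResponseTerm]) -> TruthRecord:
    """Evaluate the response product on a stack and rescale each term to [0, 1]."""
    suit = np.ones((stack.grid.n_rows, stack.grid.n_cols))
    for term in responses:
        vals = term.evaluate(stack[term.layer].values)
        peak = np.nanmax(vals)
        if peak > 0:
            vals = vals / peak
        suit = suit * vals
    suit = np.where(stack.valid_mask(), np.clip(suit, 0.0, 1.0), np.nan)
    layer = RasterLayer(grid=stack.grid, name="true_suitability", values=suit)
    return TruthRecord(suitability=layer, responses=list(responses),
                       causal_layers=[t.layer for t in responses])


def sample_presences(stack: RasterStack, truth: TruthRecord, n: int, seed: int = 0,
                     jitter_sd_deg: float = 0.02,
                     species: str = "virtual_species") -> OccurrenceSet:
    """Draw ``n`` presence cells without replacement, P(cell) ∝ true suitability.

    Each record is the cell center plus seeded Gaussian jitter clipped inside
    the cell, so records do not sit suspiciously on exact centers but still
    resolve to the sampled cell.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    suit = truth.suitability.values
    valid = stack.valid_mask() & np.isfinite(suit)
    flat_idx = np.flatnonzero(valid & (np.nan_to_num(suit) > 0))
    if n > flat_idx.size:
        raise ValueError(
            f"n={n} exceeds the {flat_idx.size} valid cells with positive suitability")
    weights = suit.ravel()[flat_idx]
    chosen = rng.choice(flat_idx, size=n, replace=False, p=weights / weights.sum())

    half = grid.cell_deg / 2.0
    clip = half * 0.999  # keep the jittered point strictly inside the cell
    records = []
    for k in chosen:
        r, c = divmod(int(k), grid.n_cols)
        center = grid.cell_center(r, c)
        dx, dy = rng.normal(0.0, jitter_sd_deg, size=2)
        lon = center.lon_deg + float(np.clip(dx, -clip, clip))
        lat = center.lat_deg + float(np.clip(dy, -clip, clip))
        records.append(OccurrenceRecord(species=species, location=GeoPoint(lon, lat)))
    return OccurrenceSet(records=records, seed=seed)


def shift_scenario(stack: RasterStack, deltas: dict[str, float],
                   multiplicative: set[str] | None = None) -> RasterStack:
    """Perturb layers to make a "future scenario" stack on the same grid.

    ``deltas[name]`` is added to the layer (or, for names in ``multiplicative``,
    the layer is scaled by that factor — natural for precipitation-like
    quantities).  Layers not mentioned are passed through unchanged.
    """
    multiplicative = multiplicative or set()
    unknown = set(deltas) - set(stack.names)
    if unknown:
        raise ValueError(f"deltas reference unknown layers: {sorted(unknown)}")
    layers = []
    for lyr in stack.layers:
        if lyr.name in deltas:
            if lyr.name in multiplicative:
                vals = lyr.values * deltas[lyr.name]
            else:
                vals = lyr.values + deltas[lyr.name]
            layers.append(RasterLayer(grid=lyr.grid, name=lyr.name, values=vals))
        else:
            layers.append(lyr)
    return RasterStack(layers)


def implied_correlations(config: VirtualSpeciesConfig) -> np.ndarray:
    """Pairwise layer correlations implied by the loading matrix and noise sd.

    corr(i, j) = (L Lᵀ)_ij / sqrt(((L Lᵀ)_ii + σ²)((L Lᵀ)_jj + σ²)); the affine
    range mapping does not change correlations.
    """
    gram = config.loading @ config.loading.T
    var = np.diag(gram) + config.noise_sd ** 2
    denom = np.sqrt(np.outer(var, var))
    corr = gram / denom
    np.fill_diagonal(corr, 1.0)
    return corr


def default_config(seed: int = 0, n_rows: int = 200, n_cols: int = 200,
                   n_presence: int = 374) -> VirtualSpeciesConfig:
    """The package's reference virtual world.

    200×200 cells over lon 100–115°E, lat 20–35°N at 0.075° (the scale of a
    subtropical study region).  19 layers named bio1…bio19; each has its own
    primary latent field plus a 0.3 cross-loading five latents over, giving
    moderate realistic collinearity; bio18 and bio19 share one latent with
    loadings (1.0, 0.95), an engineered |r| > 0.8 pair for screening tests.
    The species responds to bio1 alone with a narrow Gaussian niche (optimum
    25 °C, breadth 1.2 °C — a warm-climate specialist occupying roughly 6% of
    the region), so the causal signal is strong and its recovery measurable.
    """
    cell = 15.0 / n_cols
    grid = LatLonGrid(n_rows=n_rows, n_cols=n_cols, west_deg=100.0,
                      south_deg=20.0, cell_deg=cell)
    names = [f"bio{i}" for i in range(1, 20)]
    n_latent = 18
    loading = np.zeros((19, n_latent))
    for i in range(18):
        loading[i, i] = 1.0
        loading[i, (i + 5) % 18] += 0.3
    loading[18, 17] = 0.95  # bio19 rides bio18's latent -> |r| ~ 0.95
    return VirtualSpeciesConfig(
        grid=grid,
        layer_names=names,
        n_latent=n_latent,
        loading=loading,
        noise_sd=0.1,
        length_scale_cells=8.0,
        responses=[ResponseTerm(layer="bio1", form="gaussian", a=25.0, b=1.2)],
        n_presence=n_presence,
        jitter_sd_deg=0.02,
        seed=seed,
    )
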