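"""Synthetic feeding-trial generator.

Real calibration data for milk-MIR nitrogen phenotyping (per-cow feed
intakes, milk analyses and spectra) are rarely public, so this module
generates trial-like datasets whose marginal means, dispersions, correlation
structure and spectral physics match what the downstream analysis assumes:

* a **calibration trial** ("T1-like"): one diet, ~600 cow-day records;
* an **external trial** ("T2-like"): three diet subgroups with shifted
  concentrate:roughage ratios and production levels, ~104 records.

Production traits come from a latent Gaussian model (per-cow effect plus
day-to-day noise under a common correlation matrix).  Spectra follow a linear
Beer-Lambert-style forward model: each milk component (lactose, protein, fat,
urea, water) contributes Gaussian absorption bands at literature wavenumbers,
plus a smooth polynomial baseline, per-sample multiplicative scatter and
offset, white noise, and high-variance water signal in the excluded regions
(so region masking is consequential).

Everything is a pure function of the config, including its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import Dataset, DietSpec, SpectrumGrid

__all__ = [
    "ComponentBand",
    "GroupTargets",
    "GeneratorConfig",
    "DEFAULT_BANDS",
    "DEFAULT_TRAIT_SDS",
    "DEFAULT_TRAIT_CORRELATION",
    "make_default_grid",
    "simulate_cows",
    "simulate_production",
    "simulate_spectra",
    "generate_trial",
    "t1_like_config",
    "t2_like_config",
    "band_profiles",
]

#: grid spacing in cm^-1; reproduces the documented 215 retained channels
GRID_STEP = 3.78

#: retained spectral segments, anchored at their lower bounds
_RETAINED_SEGMENTS = ((968.1, 1577.5), (1731.8, 1762.6), (1781.9, 1808.9), (2831.0, 2966.0))


@dataclasses.dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band tied to a milk component."""

    center_cm1: float
    width_cm1: float  # Gaussian SD
    component: str  # lactose | protein | fat | urea | water
    unit_absorbance: float  # peak height per unit concentration

    def __post_init__(self) -> None:
        if self.width_cm1 <= 0 or self.unit_absorbance <= 0:
            raise ValueError("band width and height must be positive")


#: default band library.  Fingerprint assignments: ~973-989 cm^-1 C-O/C-H of
#: lactose, ~1354 cm^-1 C-N of protein, amide II ~1548 cm^-1, ester carbonyl
#: ~1745 cm^-1 and C-H stretch 2850/2920 cm^-1 for fat, urea ~1160/1460
#: cm^-1; broad water bands sit in the excluded regions.
DEFAULT_BANDS: tuple[ComponentBand, ...] = (
    ComponentBand(980.0, 6.0, "lactose", 0.060),
    ComponentBand(1040.0, 12.0, "lactose", 0.045),
    ComponentBand(1076.0, 10.0, "lactose", 0.040),
    ComponentBand(1242.0, 12.0, "protein", 0.030),
    ComponentBand(1354.0, 10.0, "protein", 0.045),
    ComponentBand(1548.0, 14.0, "protein", 0.060),
    ComponentBand(1160.0, 10.0, "urea", 0.040),
    ComponentBand(1460.0, 12.0, "urea", 0.060),
    ComponentBand(1745.0, 8.0, "fat", 0.070),
    ComponentBand(1796.0, 6.0, "fat", 0.020),
    ComponentBand(2852.0, 12.0, "fat", 0.050),
    ComponentBand(2922.0, 14.0, "fat", 0.065),
    ComponentBand(940.0, 30.0, "water", 0.40),
    ComponentBand(1640.0, 45.0, "water", 1.20),
    ComponentBand(3020.0, 80.0, "water", 0.80),
)

_TRAIT_ORDER = ("my_kg", "protein_pct", "fat_pct", "lactose_pct", "mun_mg_dl", "dmi_kg")

#: day-level dispersions (total SD across cows and days)
DEFAULT_TRAIT_SDS: dict[str, float] = {
    "my_kg": 4.5,
    "protein_pct": 0.20,
    "fat_pct": 0.35,
    "lactose_pct": 0.15,
    "mun_mg_dl": 2.0,
    "dmi_kg": 2.5,
}

#: latent correlation among (MY, protein, fat, lactose, MUN, DMI).  Chosen on
#: plausibility: yield dilutes protein, fat tracks protein, lactose rises
#: with yield, MUN reflects N (hence feed) intake, intake drives yield.
DEFAULT_TRAIT_CORRELATION = np.array(
    [
        [1.00, 0.00, -0.10, 0.30, 0.10, 0.40],
        [0.00, 1.00, 0.35, -0.10, 0.10, -0.10],
        [-0.10, 0.35, 1.00, 0.00, 0.00, 0.00],
        [0.30, -0.10, 0.00, 1.00, 0.00, 0.10],
        [0.10, 0.10, 0.00, 0.00, 1.00, 0.50],
        [0.40, -0.10, 0.00, 0.10, 0.50, 1.00],
    ]
)


@dataclasses.dataclass(frozen=True)
class GroupTargets:
    """Per-diet-group mean targets for the production model."""

    my_kg: float
    protein_pct: float
    fat_pct: float
    lactose_pct: float
    mun_mg_dl: float
    dmi_kg: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _TRAIT_ORDER])


@dataclasses.dataclass
class GeneratorConfig:
    """Full specification of one synthetic trial."""

    seed: int
    trial_id: str
    n_cows: int
    n_days_per_cow: int
    diets: list[DietSpec]
    group_weights: list[float]
    group_targets: list[GroupTargets]
    trait_sds: dict[str, float] = dataclasses.field(default_factory=lambda: dict(DEFAULT_TRAIT_SDS))
    trait_correlation: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_TRAIT_CORRELATION.copy()
    )
    cow_effect_share: float = 0.6  # fraction of trait variance between cows
    dim_range: tuple[int, int] = (154, 452)
    parity_range: tuple[int, int] = (1, 4)
    bands: tuple[ComponentBand, ...] = DEFAULT_BANDS
    additive_noise_sd: float = 0.003
    scatter_sd: float = 0.02
    offset_sd: float = 0.005
    baseline_amplitude: float = 0.005
    water_amp_sd: float = 0.08
    start_date: str = "2020-01-01"
    cow_id_prefix: str = "C"

    def __post_init__(self) -> None:
        if self.n_cows < 0:
            raise ValueError("n_cows must be >= 0")
        if self.n_days_per_cow < 1:
            raise ValueError("n_days_per_cow must be >= 1")
        if len(self.group_weights) != len(self.diets) or len(self.group_targets) != len(self.diets):
            raise ValueError("diets, group_weights and group_targets must align")
        if abs(sum(self.group_weights) - 1.0) > 1e-9:
            raise ValueError("group weights must sum to 1")
        if any(sd < 0 for sd in self.trait_sds.values()):
            raise ValueError("trait SDs must be >= 0")
        if not 0 <= self.cow_effect_share <= 1:
            raise ValueError("cow_effect_share must be in [0, 1]")


def make_default_grid(
    step: float = GRID_STEP,
    n_head: int = 12,
    n_tail: int = 24,
) -> SpectrumGrid:
    """Instrument wavenumber grid: retained segments plus excluded filler.

    Each retained segment runs from its anchor at spacing ``step`` up to its
    upper bound; filler channels continue at the same spacing through the
    water/noise gaps, below the first segment and above the last, so masking
    with the default regions is a real subset operation.  With the default
    step the four retained segments hold 162 + 9 + 8 + 36 = 215 channels.
    """
    channels: list[float] = []
    # head filler below the first retained anchor
    first = _RETAINED_SEGMENTS[0][0]
    channels.extend(first - k * step for k in range(n_head, 0, -1))
    for i, (lo, hi) in enumerate(_RETAINED_SEGMENTS):
        n_in = int(np.floor((hi - lo) / step)) + 1
        seg = [lo + k * step for k in range(n_in)]
        channels.extend(seg)
        last = seg[-1]
        next_anchor = (
            _RETAINED_SEGMENTS[i + 1][0] if i + 1 < len(_RETAINED_SEGMENTS) else last + (n_tail + 0.5) * step
        )
        w = last + step
        while w < next_anchor - 1e-9:
            channels.append(w)
            w += step
    return SpectrumGrid(np.round(np.array(channels), 6))


def _allocate_groups(n_cows: int, weights: list[float], rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder allocation, then a seeded shuffle."""
    raw = np.array(weights) * n_cows
    counts = np.floor(raw).astype(int)
    frac_order = np.argsort(-(raw - counts), kind="stable")
    for j in range(n_cows - counts.sum()):
        counts[frac_order[j % len(counts)]] += 1
    assignment = np.repeat(np.arange(len(weights)), counts)
    return rng.permutation(assignment)


def simulate_cows(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-cow table: diet group, parity, DIM, DIP, BCS.

    DIM is uniform on the configured mid/late-lactation range; DIP is derived
    from DIM minus a uniform open period, floored at 0; BCS is a per-cow
    score on the 1-5 scale in 0.25 steps.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_cows
    if n == 0:
        return pd.DataFrame(
            columns=["cow_id", "group", "diet_id", "parity", "dim_d", "dip_d", "bcs"]
        )
    group = _allocate_groups(n, cfg.group_weights, rng)
    dim = rng.integers(cfg.dim_range[0], cfg.dim_range[1] + 1, size=n)
    open_period = rng.uniform(100.0, 220.0, size=n)
    dip = np.maximum(0.0, np.round(dim - open_period)).astype(int)
    # stratified parity enrolment (trials recruit both parity groups on
    # purpose): cycle the support, then shuffle
    support = np.arange(cfg.parity_range[0], cfg.parity_range[1] + 1)
    parity = rng.permutation(np.resize(support, n))
    bcs = np.clip(np.round(rng.normal(3.25, 0.35, size=n) * 4) / 4, 1.0, 5.0)
    return pd.DataFrame(
        {
            "cow_id": [f"{cfg.cow_id_prefix}{i:03d}" for i in range(n)],
            "group": group,
            "diet_id": [cfg.diets[g].diet_id for g in group],
            "parity": parity,
            "dim_d": dim,
            "dip_d": dip,
            "bcs": bcs,
        }
    )


def simulate_production(
    cows: pd.DataFrame, cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-cow-day production traits from the latent Gaussian model.

    Each trait value is group mean + SD x (sqrt(w) z_cow + sqrt(1-w) z_day)
    with both latent vectors drawn from the configured correlation matrix, so
    sample means converge to the targets and cross-trait correlations to the
    configured matrix as n grows.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    sds = np.array([cfg.trait_sds[k] for k in _TRAIT_ORDER])
    C = np.asarray(cfg.trait_correlation, dtype=float)
    # tiny jitter guards Cholesky against a semidefinite user matrix
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    w_cow = np.sqrt(cfg.cow_effect_share)
    w_day = np.sqrt(1.0 - cfg.cow_effect_share)
    start = pd.Timestamp(cfg.start_date)

    rows = []
    for cow in cows.itertuples():
        mu = cfg.group_targets[cow.group].as_vector()
        z_cow = L @ rng.standard_normal(len(C))
        for d in range(cfg.n_days_per_cow):
            z_day = L @ rng.standard_normal(len(C))
            vals = mu + sds * (w_cow * z_cow + w_day * z_day)
            rows.append(
                {
                    "cow_id": cow.cow_id,
                    "date": start + pd.Timedelta(days=d),
                    "group": cow.group,
                    "diet_id": cow.diet_id,
                    **dict(zip(_TRAIT_ORDER, vals)),
                }
            )
    prod = pd.DataFrame(rows)
    if len(prod):
        prod["dmi_kg"] = prod["dmi_kg"].clip(lower=0.1)
        for col in ("my_kg", "protein_pct", "fat_pct", "lactose_pct", "mun_mg_dl"):
            prod[col] = prod[col].clip(lower=0.01)
    return prod


def band_profiles(grid: SpectrumGrid, bands: tuple[ComponentBand, ...] = DEFAULT_BANDS) -> dict[str, np.ndarray]:
    """Per-component absorbance profile at unit concentration on ``grid``."""
    wn = grid.wavenumbers
    profiles: dict[str, np.ndarray] = {}
    for band in bands:
        prof = band.unit_absorbance * np.exp(-0.5 * ((wn - band.center_cm1) / band.width_cm1) ** 2)
        profiles[band.component] = profiles.get(band.component, 0.0) + prof
    return profiles


def simulate_spectra(
    production: pd.DataFrame,
    cfg: GeneratorConfig,
    grid: SpectrumGrid,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Forward-model MIR spectra for each production record.

    spectrum = sum_c conc_c x profile_c + baseline + scatter + white noise,
    with the water amplitude drawn per sample (high-variance nuisance in the
    excluded regions).  ``noise=False`` turns off baseline, scatter, additive
    noise and water-amplitude variation, leaving the pure linear mixture.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n = len(production)
    wn = grid.wavenumbers
    profiles = band_profiles(grid, cfg.bands)

    conc = {
        "lactose": production["lactose_pct"].to_numpy(dtype=float),
        "protein": production["protein_pct"].to_numpy(dtype=float),
        "fat": production["fat_pct"].to_numpy(dtype=float),
        "urea": production["mun_mg_dl"].to_numpy(dtype=float) / 10.0,
    }
    water_amp = np.ones(n)
    if noise:
        water_amp = water_amp + cfg.water_amp_sd * rng.standard_normal(n)
    X = water_amp[:, None] * profiles.get("water", np.zeros_like(wn))[None, :]
    for comp, c in conc.items():
        if comp in profiles:
            X = X + np.outer(c, profiles[comp])

    if noise:
        # smooth quadratic baseline with per-sample random coefficients
        u = (wn - wn.mean()) / (wn.max() - wn.min())
        coefs = cfg.baseline_amplitude * rng.standard_normal((n, 3))
        baseline = coefs @ np.vstack([np.ones_like(u), u, u**2])
        mult = 1.0 + cfg.scatter_sd * rng.standard_normal(n)
        offset = cfg.offset_sd * rng.standard_normal(n)
        X = mult[:, None] * (X + baseline) + offset[:, None]
        X = X + cfg.additive_noise_sd * rng.standard_normal((n, len(wn)))
    return X


def generate_trial(cfg: GeneratorConfig, grid: SpectrumGrid | None = None) -> Dataset:
    """Compose cows, production and spectra into a :class:`Dataset`."""
    grid = make_default_grid() if grid is None else grid
    rng = np.random.default_rng(cfg.seed)
    cows = simulate_cows(cfg, rng)
    prod = simulate_production(cows, cfg, rng)
    spectra = simulate_spectra(prod, cfg, grid, rng)

    if len(prod):
        meta = cows.set_index("cow_id")
        table = pd.DataFrame(
            {
                "cow_id": prod["cow_id"],
                "date": prod["date"],
                "trial_id": cfg.trial_id,
                "diet_id": prod["diet_id"],
                "dmi_kg": prod["dmi_kg"],
                "my_kg": prod["my_kg"],
                "fat_pct": prod["fat_pct"],
                "protein_pct": prod["protein_pct"],
                "lactose_pct": prod["lactose_pct"],
                "mun_mg_dl": prod["mun_mg_dl"],
                "parity": meta.loc[prod["cow_id"], "parity"].to_numpy(),
                "dim_d": meta.loc[prod["cow_id"], "dim_d"].to_numpy(),
                "dip_d": meta.loc[prod["cow_id"], "dip_d"].to_numpy(),
                "bcs": meta.loc[prod["cow_id"], "bcs"].to_numpy(),
            }
        )
    else:
        from .data import RECORD_COLUMNS

        table = pd.DataFrame(columns=RECORD_COLUMNS)
        table["date"] = pd.to_datetime(table["date"])
    diets = {d.diet_id: d for d in cfg.diets}
    return Dataset(table, spectra, grid, diets).canonicalize()


# ---------------------------------------------------------------------------
# Bundled trial configurations
# ---------------------------------------------------------------------------


def t1_like_config(seed: int = 0, n_cows: int = 60, n_days_per_cow: int = 10) -> GeneratorConfig:
    """Calibration-trial config: one diet (CP 17.0% of DM, C:R 56:44),
    600 cow-day records by default."""
    diet = DietSpec("T1", dm_pct=58.8, cp_pct=17.0, cr_concentrate=56.0, cr_roughage=44.0)
    targets = GroupTargets(
        my_kg=32.5, protein_pct=3.4, fat_pct=3.9, lactose_pct=5.0, mun_mg_dl=12.0, dmi_kg=25.2
    )
    return GeneratorConfig(
        seed=seed,
        trial_id="T1",
        n_cows=n_cows,
        n_days_per_cow=n_days_per_cow,
        diets=[diet],
        group_weights=[1.0],
        group_targets=[targets],
        cow_id_prefix="T1C",
    )


def t2_like_config(seed: int = 1, n_cows: int = 52, n_days_per_cow: int = 2) -> GeneratorConfig:
    """External-trial config: three roughage-level groups, 104 records.

    Group C:R ratios 61:39 / 59:41 / 56:44 and production targets follow the
    shifted-diet design: less roughage depresses milk fat and raises MUN, and
    group 3's diet matches the calibration trial most closely.
    """
    diets = [
        DietSpec("T2G1", dm_pct=61.5, cp_pct=17.0, cr_concentrate=61.0, cr_roughage=39.0),
        DietSpec("T2G2", dm_pct=55.7, cp_pct=17.0, cr_concentrate=59.0, cr_roughage=41.0),
        DietSpec("T2G3", dm_pct=51.0, cp_pct=17.2, cr_concentrate=56.0, cr_roughage=44.0),
    ]
    targets = [
        GroupTargets(my_kg=24.1, protein_pct=3.7, fat_pct=3.45, lactose_pct=4.80, mun_mg_dl=14.5, dmi_kg=24.8),
        GroupTargets(my_kg=24.0, protein_pct=3.7, fat_pct=3.70, lactose_pct=4.95, mun_mg_dl=13.2, dmi_kg=21.7),
        GroupTargets(my_kg=27.1, protein_pct=3.6, fat_pct=3.90, lactose_pct=5.00, mun_mg_dl=12.5, dmi_kg=22.1),
    ]
    return GeneratorConfig(
        seed=seed,
        trial_id="T2",
        n_cows=n_cows,
        n_days_per_cow=n_days_per_cow,
        diets=diets,
        group_weights=[17 / 52, 17 / 52, 18 / 52],
        group_targets=targets,
        dim_range=(200, 452),
        start_date="2021-12-01",
        cow_id_prefix="T2C",
    )
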