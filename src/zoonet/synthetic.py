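"""Synthetic multi-class zooplankton communities with known interactions.

A latent-factor lognormal model: each class has a set of guilds (groups of
taxa sharing resources).  The log-biomass of taxon *j* in sample *s* is

    log b_js = mu_j + a_j * F_g(j)(s) + eps_js,

with F_g independent standard-normal guild factors per sample, a_j the
taxon's loading (``guild_loading`` for guild members, ``-antagonist_loading``
for antagonists attached to the same factor) and eps ~ N(0, noise_sd²).
Biomass is exp(log b), rescaled so the mean per-sample total biomass equals
``biomass_scale``.  Every pair of taxa loading on the same factor is a
ground-truth interaction with population (log-scale) correlation

    rho_ij = a_i a_j / sqrt((a_i² + sd²)(a_j² + sd²)),

positive for shared-guild pairs, negative for antagonist–member pairs.
The closed form makes edge-recovery tests exact on the log scale; on the
observed (lognormal) scale correlations are attenuated, which downstream
tolerances absorb.

Environmental tables carry an annual temperature sinusoid (minimum at the
class's winter mean, annual mean matched), dissolved oxygen negatively
coupled to temperature, and the remaining physico-chemical variables drawn
from per-class mean/SD profiles truncated at zero where physically
non-negative.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, EnvironmentalTable

__all__ = [
    "ClassSpec",
    "ScenarioConfig",
    "GroundTruthInteractions",
    "generate_class",
    "generate_environment",
    "generate_scenario",
    "default_class_specs",
    "cw_like_spec",
    "ww_like_spec",
    "monthly_sampling_dates",
    "ENV_PROFILES",
]

# Per-class environmental profiles: variable -> (mean, sd).  Temperature is
# generated from the seasonal sinusoid and is not part of the profile.
ENV_PROFILES = {
    "CW": {
        "DO": (9.36, 1.35), "pH": (7.80, 0.39), "Chl_a": (5.10, 2.86),
        "TOC": (3.85, 3.37), "PO4_P": (0.020, 0.010), "TP": (0.125, 0.175),
        "NO3_N": (0.160, 0.053), "NH4_N": (0.080, 0.053), "TN": (0.299, 0.124),
        "Turbidity": (17.30, 7.08), "SD": (0.756, 0.168), "Color": (15.00, 7.09),
        "SSmin": (2.95, 2.79), "SSorg": (3.09, 3.05), "SStot": (6.05, 4.28),
        "Fe": (0.165, 0.098),
    },
    "MW": {
        "DO": (9.33, 1.33), "pH": (7.80, 0.24), "Chl_a": (4.32, 3.74),
        "TOC": (1.98, 0.71), "PO4_P": (0.024, 0.014), "TP": (0.109, 0.048),
        "NO3_N": (0.143, 0.063), "NH4_N": (0.083, 0.059), "TN": (0.238, 0.077),
        "Turbidity": (12.56, 7.53), "SD": (0.919, 0.166), "Color": (10.04, 3.91),
        "SSmin": (0.975, 0.868), "SSorg": (3.00, 2.64), "SStot": (3.98, 3.04),
        "Fe": (0.255, 0.204),
    },
    "WW": {
        "DO": (7.59, 0.97), "pH": (7.69, 0.29), "Chl_a": (1.99, 4.42),
        "TOC": (1.63, 0.62), "PO4_P": (0.025, 0.012), "TP": (0.122, 0.068),
        "NO3_N": (0.118, 0.045), "NH4_N": (0.098, 0.098), "TN": (0.220, 0.126),
        "Turbidity": (9.74, 5.14), "SD": (1.46, 0.32), "Color": (7.39, 2.71),
        "SSmin": (1.46, 1.42), "SSorg": (2.76, 2.19), "SStot": (4.28, 2.88),
        "Fe": (0.138, 0.062),
    },
}

#: only pH may meaningfully stay unclipped; everything else is a
#: concentration/length and is truncated at 0.
_NONNEGATIVE_VARS = set().union(*(set(p) for p in ENV_PROFILES.values())) - {"pH"}

#: target Gaussian coupling between temperature and dissolved oxygen
#: (yields a rank correlation of about −0.5).
DO_TEMP_COUPLING = 0.555


@dataclass(frozen=True)
class ClassSpec:
    """Generator parameters for one thermal class.

    The loading/noise defaults give guild-mate pairs a log-scale population
    correlation of exactly 0.5 (a_i a_j / (a² + sd²) with a = sd = 0.35) and
    a total log-SD of about 0.5 — moderate overdispersion typical of
    plankton biomass.  ``guild_coverage`` is the fraction of taxa assigned
    to a guild factor at all; the rest fluctuate independently.
    """

    name: str
    n_taxa: int
    n_guilds: int = 3
    guild_loading: float = 0.35
    antagonist_fraction: float = 0.2
    antagonist_loading: float = 0.35
    noise_sd: float = 0.35
    guild_coverage: float = 0.6
    biomass_scale: float = 1.0          # mean total biomass, mg l-1
    winter_temp_mean: float = 5.63      # deg C
    winter_temp_sd: float = 2.19
    annual_temp_mean: float = 13.61
    seasonal_sensitivity_sd: float = 0.0  # per-taxon thermal weight (0 = off)
    env_profile: dict = field(default_factory=lambda: dict(ENV_PROFILES["CW"]))

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_guilds < 1:
            raise ValueError("n_guilds must be >= 1")
        for name in ("guild_loading", "antagonist_fraction", "antagonist_loading",
                     "guild_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Multi-class scenario: class specs, samples per class, taxon sharing.

    ``shared_fraction`` is the target fraction of the taxon-pool union that
    is common to every class (the default 0.26 matches communities in which
    roughly a quarter of all recorded taxa occur everywhere).
    """

    classes: tuple = ()
    n_samples_per_class: int = 84
    shared_fraction: float = 0.26
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 8:
            raise ValueError("n_samples_per_class must be >= 8")
        names = [c.name for c in self.classes]
        if len(names) != len(set(names)):
            raise ValueError("class names must be unique")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")


@dataclass
class GroundTruthInteractions:
    """True interacting taxon pairs with their population correlations."""

    positive_pairs: set
    negative_pairs: set
    population_r: dict  # frozenset pair -> signed population correlation

    def __post_init__(self) -> None:
        if self.positive_pairs & self.negative_pairs:
            raise ValueError("a pair cannot be both positive and negative")
        for r in self.population_r.values():
            if abs(r) > 1:
                raise ValueError("population correlations must lie in [-1, 1]")

    @property
    def pairs(self) -> set:
        return self.positive_pairs | self.negative_pairs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair in sorted(self.pairs, key=lambda p: tuple(sorted(p))):
            a, b = sorted(pair)
            r = self.population_r[pair]
            rows.append({"taxonA": a, "taxonB": b,
                         "sign": "positive" if r > 0 else "negative",
                         "population_r": r})
        return pd.DataFrame(rows, columns=["taxonA", "taxonB", "sign", "population_r"])


def _stable_hash(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")


def _loadings(spec: ClassSpec, rng: np.random.Generator):
    """Assign guild membership and signed loadings.

    Returns (guild index per taxon with −1 for unguilded, loading per taxon).
    Antagonists are the tail of each guild's member list and load negatively.
    """
    if spec.n_taxa < 2 * spec.n_guilds:
        raise ValueError("guilds must be non-degenerate: need n_taxa >= 2 * n_guilds")
    n_member = int(round(spec.guild_coverage * spec.n_taxa))
    n_member = max(n_member, 2 * spec.n_guilds) if spec.guild_coverage > 0 else 0
    guild = np.full(spec.n_taxa, -1, dtype=int)
    loading = np.zeros(spec.n_taxa)
    if n_member:
        guild[:n_member] = np.arange(n_member) % spec.n_guilds
        for g in range(spec.n_guilds):
            members = np.flatnonzero(guild == g)
            n_ant = int(round(spec.antagonist_fraction * members.size))
            loading[members] = spec.guild_loading
            if n_ant:
                loading[members[-n_ant:]] = -spec.antagonist_loading
    return guild, loading


def _ground_truth(taxa, guild, loading, noise_sd) -> GroundTruthInteractions:
    pos, neg, pop = set(), set(), {}
    for g in np.unique(guild[guild >= 0]):
        members = np.flatnonzero(guild == g)
        for ii, i in enumerate(members):
            for j in members[ii + 1:]:
                prod = loading[i] * loading[j]
                if prod == 0:
                    continue
                denom = np.sqrt((loading[i] ** 2 + noise_sd**2) * (loading[j] ** 2 + noise_sd**2))
                r = float(prod / denom) if denom > 0 else float(np.sign(prod))
                pair = frozenset((taxa[i], taxa[j]))
                (pos if r > 0 else neg).add(pair)
                pop[pair] = r
    return GroundTruthInteractions(pos, neg, pop)


def generate_class(
    spec: ClassSpec,
    n_samples: int,
    seed: int,
    taxon_names=None,
    sample_names=None,
    temperature=None,
):
    """Generate one class's community matrix and its ground-truth pairs.

    ``temperature`` (optional, one value per sample) drives per-taxon
    seasonal responses when ``spec.seasonal_sensitivity_sd`` > 0; by default
    seasonality is off so network structure reflects guilds only.
    """
    rng = np.random.default_rng(seed)
    if taxon_names is None:
        taxon_names = [f"{spec.name}_taxon{i + 1:03d}" for i in range(spec.n_taxa)]
    if len(taxon_names) != spec.n_taxa:
        raise ValueError("taxon_names length must equal n_taxa")
    if sample_names is None:
        sample_names = [f"{spec.name}_s{i + 1:03d}" for i in range(n_samples)]
    guild, loading = _loadings(spec, rng)
    mu = rng.normal(0.0, 1.0, size=spec.n_taxa)
    factors = rng.standard_normal((n_samples, spec.n_guilds))
    eps = rng.standard_normal((n_samples, spec.n_taxa)) * spec.noise_sd
    log_b = mu[None, :] + eps
    guilded = guild >= 0
    log_b[:, guilded] += factors[:, guild[guilded]] * loading[guilded]
    if spec.seasonal_sensitivity_sd > 0 and temperature is not None:
        t = np.asarray(temperature, dtype=float)
        t_std = (t - t.mean()) / (t.std() or 1.0)
        sens = rng.normal(0.0, spec.seasonal_sensitivity_sd, size=spec.n_taxa)
        log_b += np.outer(t_std, sens)
    biomass = np.exp(log_b)
    biomass *= spec.biomass_scale / biomass.sum(axis=1).mean()
    cm = CommunityMatrix(pd.DataFrame(biomass, index=sample_names, columns=taxon_names))
    truth = _ground_truth(list(taxon_names), guild, loading, spec.noise_sd)
    return cm, truth


def monthly_sampling_dates(n_samples: int):
    """Default sampling calendar: monthly Jan 2014 – Dec 2015 plus
    Jun–Sep 2016 (28 months), cycled/replicated to cover ``n_samples``
    (84 samples = 28 months × 3 stations)."""
    months = [dt.date(2014 + y, m, 15) for y in (0, 1) for m in range(1, 13)]
    months += [dt.date(2016, m, 15) for m in (6, 7, 8, 9)]
    reps = -(-n_samples // len(months))
    dates = sorted(months * reps)[:n_samples]
    return dates


def _seasonal_temperature(spec: ClassSpec, dates) -> np.ndarray:
    """Annual cosine with minimum ``winter_temp_mean`` in mid-January and
    annual mean ``annual_temp_mean``."""
    month = np.array([d.month for d in dates], dtype=float)
    amplitude = spec.annual_temp_mean - spec.winter_temp_mean
    return spec.annual_temp_mean - amplitude * np.cos(2.0 * np.pi * (month - 1.0) / 12.0)


def generate_environment(spec: ClassSpec, n_samples: int, seed: int, dates=None) -> EnvironmentalTable:
    """Environmental table for one class.

    Temperature = seasonal sinusoid + N(0, winter_temp_sd) noise; DO is
    coupled negatively to temperature; the remaining variables are drawn
    from the class profile and truncated at 0 where physically non-negative.
    """
    rng = np.random.default_rng(seed)
    if dates is None:
        dates = monthly_sampling_dates(n_samples)
    if len(dates) < n_samples:
        reps = -(-n_samples // len(dates))
        dates = (list(dates) * reps)[:n_samples]  # cycle, preserving order
    dates = list(dates)[:n_samples]
    temp = _seasonal_temperature(spec, dates) + rng.normal(0.0, spec.winter_temp_sd, n_samples)
    out = {"Temperature": temp}
    if temp.std() > 0:
        z_t = (temp - temp.mean()) / temp.std()
    else:
        z_t = np.zeros(n_samples)
    rho = DO_TEMP_COUPLING
    for var, (mean, sd) in spec.env_profile.items():
        z = rng.standard_normal(n_samples)
        if var == "DO":
            z = -rho * z_t + np.sqrt(1.0 - rho**2) * z
        vals = mean + sd * z
        if var in _NONNEGATIVE_VARS:
            vals = np.clip(vals, 0.0, None)
        out[var] = vals
    index = [f"{spec.name}_s{i + 1:03d}" for i in range(n_samples)]
    return EnvironmentalTable(pd.DataFrame(out, index=index))


def default_class_specs() -> tuple:
    """The three thermal-class presets (CW/MW/WW defaults).

    Taxon counts, biomass scales and temperature parameters follow the
    study conditions; guild counts and antagonist fractions encode the
    qualitative gradient from a cohesive, antagonist-balanced cold-winter
    community to a fragmented warm-winter one.
    """
    return (
        ClassSpec(name="CW", n_taxa=61, n_guilds=2, antagonist_fraction=0.5,
                  biomass_scale=28.25, winter_temp_mean=5.63, winter_temp_sd=2.19,
                  annual_temp_mean=13.61, env_profile=dict(ENV_PROFILES["CW"])),
        ClassSpec(name="MW", n_taxa=74, n_guilds=4, antagonist_fraction=0.3,
                  biomass_scale=0.730, winter_temp_mean=8.60, winter_temp_sd=0.76,
                  annual_temp_mean=14.69, env_profile=dict(ENV_PROFILES["MW"])),
        ClassSpec(name="WW", n_taxa=89, n_guilds=8, antagonist_fraction=0.1,
                  biomass_scale=0.094, winter_temp_mean=15.35, winter_temp_sd=1.41,
                  annual_temp_mean=18.49, env_profile=dict(ENV_PROFILES["WW"])),
    )


def cw_like_spec() -> ClassSpec:
    """Cohesive cold-winter-like preset: one large, strongly loaded guild
    with balanced antagonists."""
    return ClassSpec(name="CW_like", n_taxa=61, n_guilds=1, guild_loading=0.8,
                     antagonist_fraction=0.5, antagonist_loading=0.8, noise_sd=0.5,
                     biomass_scale=28.25, winter_temp_mean=5.63, winter_temp_sd=2.19,
                     annual_temp_mean=13.61, env_profile=dict(ENV_PROFILES["CW"]))


def ww_like_spec() -> ClassSpec:
    """Fragmented warm-winter-like preset: many small, weakly loaded guilds
    with few antagonists."""
    return ClassSpec(name="WW_like", n_taxa=89, n_guilds=12, guild_loading=0.35,
                     antagonist_fraction=0.1, antagonist_loading=0.35, noise_sd=0.5,
                     biomass_scale=0.094, winter_temp_mean=15.35, winter_temp_sd=1.41,
                     annual_temp_mean=18.49, env_profile=dict(ENV_PROFILES["WW"]))


def default_scenario(seed: int = 0) -> ScenarioConfig:
    return ScenarioConfig(classes=default_class_specs(), n_samples_per_class=84,
                          shared_fraction=0.26, rng_seed=seed)


def _taxon_pools(config: ScenarioConfig):
    """Split each class's taxon list into a core shared by all classes and
    class-specific taxa, targeting ``shared_fraction`` of the union."""
    sizes = [c.n_taxa for c in config.classes]
    f = config.shared_fraction
    if f >= 1.0:
        core_size = min(sizes)
    else:
        # union = sum(sizes) - (k-1)*core; core = f*union
        k = len(sizes)
        core_size = int(round(f * sum(sizes) / (1.0 + (k - 1) * f)))
        core_size = min(core_size, min(sizes))
    core = [f"taxon_core{i + 1:03d}" for i in range(core_size)]
    pools = {}
    for c in config.classes:
        specific = [f"taxon_{c.name}{i + 1:03d}" for i in range(c.n_taxa - core_size)]
        pools[c.name] = core + specific
    return pools


def generate_scenario(config: ScenarioConfig):
    """Generate the full multi-class scenario.

    Returns ``(community, environment, ground_truth)`` where the community
    holds all classes' samples over the union of taxa (zero biomass for
    taxa absent from a class), the environmental table is row-aligned with
    it, and ``ground_truth`` maps class name → its interaction list.
    """
    if not config.classes:
        raise ValueError("scenario needs at least one class")
    pools = _taxon_pools(config)
    union: list = []
    for pool in pools.values():
        union.extend(t for t in pool if t not in union)
    frames, env_frames, labels, dates_all = [], [], {}, {}
    truths = {}
    for spec in config.classes:
        seed_seq = np.random.SeedSequence([config.rng_seed, _stable_hash(spec.name)])
        com_seed, env_seed = (int(s) for s in seed_seq.generate_state(2) % (2**31))
        n = config.n_samples_per_class
        dates = monthly_sampling_dates(n)
        env = generate_environment(spec, n, env_seed, dates)
        cm, truth = generate_class(
            spec, n, com_seed,
            taxon_names=pools[spec.name],
            temperature=env.values["Temperature"].to_numpy(),
        )
        frame = cm.biomass.reindex(columns=union, fill_value=0.0)
        frames.append(frame)
        env_frames.append(env.values)
        truths[spec.name] = truth
        for i, s in enumerate(frame.index):
            labels[s] = spec.name
            dates_all[s] = dates[i]
    biomass = pd.concat(frames, axis=0)
    community = CommunityMatrix(
        biomass,
        class_label=pd.Series(labels),
        sample_date=pd.Series(dates_all),
    )
    environment = EnvironmentalTable(pd.concat(env_frames, axis=0))
    return community, environment, truths
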