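"""Synthetic sputum acquisitions: event-level stand-ins for dissociated
sputum tubes, their unstained/FMO controls, bead calibration runs and whole
labeled cohorts.

The generator emulates the cell populations seen in sputum flow cytometry:
debris, dead squamous epithelial cells (SECs, oral-cavity contaminants with
high side scatter), granulocytes/lymphocytes, CD206-bright autofluorescent
alveolar macrophages, smaller CD206-intermediate interstitial macrophages,
EpCAM+panCK+ epithelial cells, marker-negative epithelial cells, and a
TCPP-dim CD45- remainder.  Marker intensities are log-normal per population
(the standard cytometry stand-in); doublets are injected by summing the
scatter/fluorescence of random event pairs with pulse height near the pair
maximum, so area/height discrimination behaves as on a real instrument.

Every event carries a hidden true-population label in an extra non-analysed
channel (``truth_label``), so gating accuracy can be scored without touching
the analysis path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .fcs_io import EventTable, TRUTH_CHANNEL

__all__ = [
    "PopulationProfile",
    "SampleConfig",
    "CohortConfig",
    "GroupParams",
    "SampleParams",
    "SampleTubes",
    "ControlSet",
    "CohortSample",
    "TRUTH_CODES",
    "TRUTH_DOUBLET",
    "LEUKOCYTE_CHANNELS",
    "EPITHELIAL_CHANNELS",
    "sample_population",
    "generate_sample",
    "generate_controls",
    "generate_bead_run",
    "generate_cohort",
    "default_sample_params",
    "default_cohort_config",
    "null_cohort_config",
    "build_sample_config",
]

POPULATION_NAMES = (
    "debris",
    "sec",
    "granulocyte_lymphocyte",
    "alveolar_macrophage",
    "interstitial_macrophage",
    "epithelial_dp",
    "epithelial_dn",
    "other_cd45neg",
)
TRUTH_CODES = {name: i for i, name in enumerate(POPULATION_NAMES)}
TRUTH_DOUBLET = 8

COCKTAIL = "CD66b_CD3_CD19"  # granulocyte/lymphocyte cocktail on the FITC axis

LEUKOCYTE_CHANNELS = [
    "FSC-A", "FSC-H", "SSC-A", "FVS510", "CD45", "CD206", COCKTAIL, "TCPP",
    TRUTH_CHANNEL,
]
EPITHELIAL_CHANNELS = [
    "FSC-A", "FSC-H", "SSC-A", "FVS510", "CD45", "EpCAM", "panCK", "TCPP",
    TRUTH_CHANNEL,
]

#: stain-dependent markers per tube layout; panCK shares the FITC axis with
#: the cocktail, so constitutive FITC autofluorescence appears on both.
_TUBE_MARKERS = {
    "leukocyte": ("FVS510", "CD45", "CD206", COCKTAIL, "TCPP"),
    "epithelial": ("FVS510", "CD45", "EpCAM", "panCK", "TCPP"),
}
_FITC_AXIS = {COCKTAIL, "panCK"}

# global autofluorescence baselines (log-location, log-scale on raw scale)
_BASELINE = {"default": (math.log(60.0), 0.5), "TCPP": (math.log(80.0), 0.6)}


@dataclass
class PopulationProfile:
    """Parametric description of one synthetic cell population.

    ``stained`` gives the observed log-normal (location, scale) per marker in
    a fully stained tube; ``baseline`` the autofluorescence-only distribution
    used when that marker's stain is omitted (unstained/FMO tubes).  Markers
    absent from either dict fall back to the global autofluorescence
    baseline.  ``fitc_autofluor`` overrides the FITC-axis baseline — alveolar
    macrophages are constitutively bright there.
    """

    name: str
    fraction: float
    scatter_mean: tuple[float, float]  # (FSC-A, SSC-A)
    scatter_sd: tuple[float, float]
    scatter_corr: float = 0.5
    dead: bool = False
    stained: dict[str, tuple[float, float]] = field(default_factory=dict)
    baseline: dict[str, tuple[float, float]] = field(default_factory=dict)
    fitc_autofluor: tuple[float, float] | None = None
    tcpp: tuple[float, float] | None = None  # convenience alias for stained TCPP

    def __post_init__(self) -> None:
        if self.name not in TRUTH_CODES:
            raise ConfigurationError(f"unknown population name {self.name!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ConfigurationError("population fraction must lie in [0, 1]")
        if self.tcpp is not None:
            self.stained.setdefault("TCPP", self.tcpp)
        for loc, scale in list(self.stained.values()) + list(self.baseline.values()):
            if scale <= 0:
                raise ConfigurationError("log-normal scale parameters must be > 0")
        if min(self.scatter_sd) <= 0:
            raise ConfigurationError("scatter SDs must be > 0")

    def _params(self, marker: str, stained: bool) -> tuple[float, float]:
        if marker in _FITC_AXIS and self.fitc_autofluor is not None:
            base = self.fitc_autofluor
        else:
            base = self.baseline.get(marker, _BASELINE.get(marker, _BASELINE["default"]))
        if not stained:
            return base
        return self.stained.get(marker, base)


@dataclass
class SampleConfig:
    """Mixture description of one sample's two stained tubes plus controls."""

    sample_id: str
    populations: list[PopulationProfile]
    n_events: int = 100_000
    control_n_events: int = 20_000
    total_cells_prestain: float = 8.0e6
    doublet_rate: float = 0.03
    singlet_ratio: float = 0.95
    singlet_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"population fractions must sum to 1 (got {total:.12f})"
            )
        if self.n_events < 0 or self.control_n_events < 0:
            raise ConfigurationError("event counts must be >= 0")
        if not (0.0 <= self.doublet_rate <= 1.0):
            raise ConfigurationError("doublet_rate must lie in [0, 1]")


@dataclass
class SampleTubes:
    leukocyte: EventTable
    epithelial: EventTable
    meta: dict


@dataclass
class ControlSet:
    """Unstained and fluorescence-minus-one control tubes for one sample.

    Every FMO tube keeps the viability dye, CD45 and TCPP stains; only the
    omitted marker's channel reverts to its autofluorescence baseline.
    """

    unstained_leukocyte: EventTable
    unstained_epithelial: EventTable
    fmo_cocktail: EventTable
    fmo_cd206: EventTable
    fmo_panck: EventTable
    fmo_epcam: EventTable

    def unstained(self, tube: str) -> EventTable:
        return self.unstained_leukocyte if tube == "leukocyte" else self.unstained_epithelial


# ---------------------------------------------------------------------------
# Event-level sampling
# ---------------------------------------------------------------------------

def _draw_scatter(
    p: PopulationProfile, n: int, rng: np.random.Generator,
    singlet_ratio: float, singlet_noise: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mx, my = p.scatter_mean
    sx, sy = p.scatter_sd
    cov = np.array(
        [[sx**2, p.scatter_corr * sx * sy], [p.scatter_corr * sx * sy, sy**2]]
    )
    xy = rng.multivariate_normal([mx, my], cov, size=n, method="cholesky")
    fsc_a = np.clip(xy[:, 0], 1.0, None)
    ssc_a = np.clip(xy[:, 1], 1.0, None)
    fsc_h = fsc_a * (singlet_ratio + rng.normal(0.0, singlet_noise, size=n))
    return fsc_a, np.clip(fsc_h, 1.0, None), ssc_a


def sample_population(
    p: PopulationProfile,
    n: int,
    rng: np.random.Generator,
    tube: str = "leukocyte",
    omit: Sequence[str] = (),
    unstained: bool = False,
    singlet_ratio: float = 0.95,
    singlet_noise: float = 0.02,
) -> EventTable:
    """Draw ``n`` events from one population for one tube layout.

    ``omit`` lists markers whose stain is left out (FMO tubes);
    ``unstained=True`` reverts every stain-dependent marker to baseline.
    Raw (linear) intensities; the truth channel carries the population code.
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    if tube not in _TUBE_MARKERS:
        raise ConfigurationError(f"unknown tube layout {tube!r}")
    channels = LEUKOCYTE_CHANNELS if tube == "leukocyte" else EPITHELIAL_CHANNELS
    values = np.empty((n, len(channels)))
    fsc_a, fsc_h, ssc_a = _draw_scatter(p, n, rng, singlet_ratio, singlet_noise)
    values[:, 0], values[:, 1], values[:, 2] = fsc_a, fsc_h, ssc_a
    for j, marker in enumerate(_TUBE_MARKERS[tube], start=3):
        stained = not unstained and marker not in omit
        loc, scale = p._params(marker, stained)
        values[:, j] = rng.lognormal(loc, scale, size=n)
    values[:, -1] = TRUTH_CODES[p.name]
    return EventTable(values, list(channels))


def _mix_tube(
    config: SampleConfig, tube: str, rng: np.random.Generator,
    omit: Sequence[str] = (), unstained: bool = False,
    n_events: int | None = None,
) -> EventTable:
    n = config.n_events if n_events is None else n_events
    n_doublets = int(round(n * config.doublet_rate))
    n_singlets = n - n_doublets
    fractions = np.array([p.fraction for p in config.populations])
    counts = rng.multinomial(n_singlets, fractions)
    parts = [
        sample_population(
            p, int(c), rng, tube=tube, omit=omit, unstained=unstained,
            singlet_ratio=config.singlet_ratio, singlet_noise=config.singlet_noise,
        )
        for p, c in zip(config.populations, counts)
    ]
    channels = parts[0].channel_names if parts else (
        LEUKOCYTE_CHANNELS if tube == "leukocyte" else EPITHELIAL_CHANNELS
    )
    singles = np.vstack([t.values for t in parts]) if parts else np.empty((0, len(channels)))

    if n_doublets:
        pair_pops = rng.choice(len(config.populations), size=2 * n_doublets, p=fractions)
        pool = []
        for i, p in enumerate(config.populations):
            k = int(np.sum(pair_pops == i))
            pool.append(
                sample_population(
                    p, k, rng, tube=tube, omit=omit, unstained=unstained,
                    singlet_ratio=config.singlet_ratio,
                    singlet_noise=config.singlet_noise,
                ).values
            )
        pool_arr = np.vstack(pool)
        rng.shuffle(pool_arr, axis=0)
        a, b = pool_arr[:n_doublets], pool_arr[n_doublets:]
        doublets = a + b  # summed area and fluorescence
        doublets[:, 1] = np.maximum(a[:, 1], b[:, 1])  # FSC-H ~ max of the pair
        doublets[:, -1] = TRUTH_DOUBLET
        events = np.vstack([singles, doublets])
    else:
        events = singles
    rng.shuffle(events, axis=0)
    return EventTable(events, list(channels), sample_id=config.sample_id)


def _tube_rng(config: SampleConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


def generate_sample(config: SampleConfig) -> SampleTubes:
    """Generate the two stained acquisition tubes for one sample.

    Both tubes draw from the same population mixture (the cell suspension is
    split, not re-composed); only the antibody panel differs.  Reproducible
    under a fixed seed.
    """
    leuko = _mix_tube(config, "leukocyte", _tube_rng(config, 0))
    epi = _mix_tube(config, "epithelial", _tube_rng(config, 1))
    meta = {
        "sample_id": config.sample_id,
        "total_cells_prestain": config.total_cells_prestain,
        "seed": config.seed,
    }
    return SampleTubes(leuko, epi, meta)


def generate_controls(config: SampleConfig) -> ControlSet:
    """Generate the unstained tube and the four FMO tubes for one sample."""
    n = config.control_n_events
    return ControlSet(
        unstained_leukocyte=_mix_tube(
            config, "leukocyte", _tube_rng(config, 2), unstained=True, n_events=n
        ),
        unstained_epithelial=_mix_tube(
            config, "epithelial", _tube_rng(config, 3), unstained=True, n_events=n
        ),
        fmo_cocktail=_mix_tube(
            config, "leukocyte", _tube_rng(config, 4), omit=(COCKTAIL,), n_events=n
        ),
        fmo_cd206=_mix_tube(
            config, "leukocyte", _tube_rng(config, 5), omit=("CD206",), n_events=n
        ),
        fmo_panck=_mix_tube(
            config, "epithelial", _tube_rng(config, 6), omit=("panCK",), n_events=n
        ),
        fmo_epcam=_mix_tube(
            config, "epithelial", _tube_rng(config, 7), omit=("EpCAM",), n_events=n
        ),
    )


def generate_bead_run(
    diameters_um: Sequence[float],
    rng: np.random.Generator,
    n_per_diameter: int = 2000,
    cv: float = 0.03,
) -> EventTable:
    """Scatter profile of calibration beads, one tight cluster per diameter.

    FSC-A scales linearly with bead diameter under these voltage settings,
    so cluster medians increase strictly with diameter.
    """
    diameters = list(diameters_um)
    if any(d <= 0 for d in diameters) or sorted(diameters) != diameters:
        raise ConfigurationError("diameters must be positive and sorted ascending")
    rows = []
    for d in diameters:
        fsc = rng.normal(6000.0 * d, cv * 6000.0 * d, size=n_per_diameter)
        ssc = rng.normal(2500.0 * d, cv * 2500.0 * d, size=n_per_diameter)
        fsc_h = fsc * (0.98 + rng.normal(0.0, 0.005, size=n_per_diameter))
        rows.append(np.column_stack([fsc, fsc_h, ssc]))
    values = np.clip(np.vstack(rows), 1.0, None)
    rng.shuffle(values, axis=0)
    return EventTable(values, ["FSC-A", "FSC-H", "SSC-A"], sample_id="beads")


# ---------------------------------------------------------------------------
# High-level sample parameterization
# ---------------------------------------------------------------------------

@dataclass
class SampleParams:
    """Realized high-level composition of one sample.

    Fractions are of the compartment named in the comment; intensity
    locations are natural-log raw-scale.  ``ssc_scale_bright`` scales the
    side-scatter of the TCPP-bright populations (alveolar macrophages and
    EpCAM+panCK+ epithelial cells).
    """

    cd45_frac: float = 0.3895          # of live cells
    gate1_frac: float = 0.52           # of CD45+ (granulocytes/lymphocytes)
    gate2_frac: float = 0.37           # of CD45+ (alveolar macrophages)
    gate3_frac: float = 0.11           # of CD45+ (interstitial macrophages)
    dp_frac: float = 0.22              # of CD45- (EpCAM+panCK+)
    dn_frac: float = 0.38              # of CD45- (marker-negative epithelial)
    debris_frac: float = 0.12          # of all events
    sec_frac: float = 0.18             # of all events
    doublet_rate: float = 0.03
    epcam_loc: float = math.log(3000.0)
    ssc_scale_bright: float = 1.0
    dn_tcpp_loc: float = math.log(2500.0)
    dn_tcpp_scale: float = 0.8
    total_cells_prestain: float = 8.0e6

    def normalized(self) -> "SampleParams":
        g = np.array([self.gate1_frac, self.gate2_frac, self.gate3_frac])
        # the CD45- remainder is derived, so it is clipped rather than checked
        e = np.array([
            self.dp_frac, self.dn_frac,
            max(1.0 - self.dp_frac - self.dn_frac, 0.0),
        ])
        if np.any(g < 0) or np.any(e[:2] < 0):
            raise ConfigurationError("compartment fractions must be non-negative")
        g = g / g.sum()
        e = e / e.sum()
        return replace(
            self, gate1_frac=g[0], gate2_frac=g[1], gate3_frac=g[2],
            dp_frac=e[0], dn_frac=e[1],
        )


def default_sample_params(group: str = "high_risk") -> SampleParams:
    """Composition a typical sample of the given group is generated from."""
    if group in ("high_risk", "hr"):
        return SampleParams()
    if group in ("cancer", "ca"):
        return SampleParams(
            cd45_frac=0.4964,
            gate1_frac=0.62, gate2_frac=0.18, gate3_frac=0.20,
            dp_frac=0.38, dn_frac=0.28,
            epcam_loc=math.log(3000.0) + 0.5,
            ssc_scale_bright=0.72,
        )
    raise ConfigurationError(f"unknown group {group!r}")


def build_sample_config(
    params: SampleParams,
    sample_id: str = "S0",
    n_events: int = 100_000,
    control_n_events: int = 20_000,
    seed: int = 0,
) -> SampleConfig:
    """Expand high-level composition into per-population profiles."""
    p = params.normalized()
    live = 1.0 - p.debris_frac - p.sec_frac
    if live <= 0:
        raise ConfigurationError("debris + SEC fractions must leave live cells")
    cd45 = live * p.cd45_frac
    cd45n = live * (1.0 - p.cd45_frac)
    s = p.ssc_scale_bright
    ln = math.log

    cd45_hi = (ln(5000.0), 0.4)
    dead_fvs = (ln(20000.0), 0.35)

    profiles = [
        PopulationProfile(
            "debris", p.debris_frac, (12_000, 8_000), (4_200, 2_800), 0.3,
            stained={"TCPP": (ln(100.0), 0.6)},
        ),
        PopulationProfile(
            "sec", p.sec_frac, (130_000, 140_000), (15_600, 16_800), 0.5,
            dead=True,
            stained={"FVS510": dead_fvs, "TCPP": (ln(1500.0), 0.6)},
            baseline={"TCPP": (ln(200.0), 0.6)},
        ),
        PopulationProfile(
            "granulocyte_lymphocyte", cd45 * p.gate1_frac,
            (45_000, 30_000), (5_400, 3_600), 0.5,
            stained={
                "CD45": cd45_hi, COCKTAIL: (ln(8000.0), 0.5),
                "TCPP": (ln(800.0), 0.5),
            },
        ),
        PopulationProfile(
            "alveolar_macrophage", cd45 * p.gate2_frac,
            (110_000, 90_000 * s), (13_200, 10_800 * s), 0.5,
            stained={
                "CD45": cd45_hi, "CD206": (ln(20_000.0), 0.4),
                "TCPP": (ln(20_000.0), 0.4),
            },
            fitc_autofluor=(ln(3000.0), 0.5),
        ),
        PopulationProfile(
            "interstitial_macrophage", cd45 * p.gate3_frac,
            (55_000, 35_000), (6_600, 4_200), 0.5,
            stained={
                "CD45": cd45_hi, "CD206": (ln(1500.0), 0.4),
                "TCPP": (ln(800.0), 0.5),
            },
        ),
        PopulationProfile(
            "epithelial_dp", cd45n * p.dp_frac,
            (90_000, 50_000 * s), (10_800, 6_000 * s), 0.5,
            stained={
                "EpCAM": (p.epcam_loc, 0.5), "panCK": (ln(3000.0), 0.5),
                "TCPP": (ln(15_000.0), 0.5),
            },
        ),
        PopulationProfile(
            "epithelial_dn", cd45n * p.dn_frac,
            (80_000, 45_000), (9_600, 5_400), 0.5,
            stained={"TCPP": (p.dn_tcpp_loc, p.dn_tcpp_scale)},
        ),
        PopulationProfile(
            "other_cd45neg", cd45n * max(1.0 - p.dp_frac - p.dn_frac, 0.0),
            (70_000, 40_000), (8_400, 4_800), 0.5,
            stained={"TCPP": (ln(120.0), 0.6)},
        ),
    ]
    return SampleConfig(
        sample_id=sample_id,
        populations=profiles,
        n_events=n_events,
        control_n_events=control_n_events,
        total_cells_prestain=p.total_cells_prestain,
        doublet_rate=p.doublet_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Between-sample distribution of composition for one study group.

    Fractions vary between samples on the logit scale with SD ``frac_sigma``;
    intensity locations with SD ``loc_sigma``; the bright-population SSC
    scale multiplicatively with log-SD ``ssc_sigma``.  ``smoking_effects``
    applies the current-smoker logit shifts (alveolar/interstitial/EpCAM+
    panCK+ excess seen in current smokers); ``stage_epcam_shift`` moves the
    EpCAM location up for Stage I/II and down for Stage III/IV.
    """

    base: SampleParams
    frac_sigma: float = 0.30
    loc_sigma: float = 0.12
    ssc_sigma: float = 0.06
    smoking_current_prob: float = 0.447
    smoking_effects: bool = False
    smoking_logit_alveolar: float = 0.8
    smoking_logit_interstitial: float = 0.7
    smoking_logit_dp: float = 0.8
    stage_probs: tuple[float, float, float] | None = None  # (I/II, III/IV, unknown)
    stage_epcam_shift: float = 0.0


def default_cohort_config(
    n_cancer: int = 32,
    n_highrisk: int = 132,
    seed: int = 0,
    n_events: int = 100_000,
    control_n_events: int = 20_000,
) -> "CohortConfig":
    """Study conditions: group composition means and effect directions.

    High-risk samples average 38.95% CD45+ cells, cancer samples 49.64%,
    with more granulocytes/lymphocytes and interstitial macrophages, a
    larger and brighter EpCAM+panCK+ compartment, and lower side scatter in
    the TCPP-bright populations in the cancer group.  Current high-risk
    smokers carry more macrophages and EpCAM+panCK+ cells than former
    smokers; within cancer, Stage I/II samples have brighter EpCAM than
    Stage III/IV.
    """
    return CohortConfig(
        n_cancer=n_cancer,
        n_highrisk=n_highrisk,
        groups={
            "high_risk": GroupParams(
                base=default_sample_params("high_risk"),
                smoking_effects=True,
            ),
            "cancer": GroupParams(
                base=default_sample_params("cancer"),
                smoking_current_prob=0.406,
                stage_probs=(14 / 32, 14 / 32, 4 / 32),
                stage_epcam_shift=0.3,
            ),
        },
        seed=seed,
        n_events=n_events,
        control_n_events=control_n_events,
    )


def null_cohort_config(
    n_cancer: int = 32,
    n_highrisk: int = 132,
    seed: int = 0,
    n_events: int = 100_000,
    control_n_events: int = 20_000,
) -> "CohortConfig":
    """Both groups and all covariates share the high-risk composition."""
    base = GroupParams(base=default_sample_params("high_risk"))
    cancer = replace(
        base, smoking_current_prob=0.406, stage_probs=(14 / 32, 14 / 32, 4 / 32)
    )
    return CohortConfig(
        n_cancer=n_cancer,
        n_highrisk=n_highrisk,
        groups={"high_risk": base, "cancer": cancer},
        seed=seed,
        n_events=n_events,
        control_n_events=control_n_events,
    )


@dataclass
class CohortConfig:
    n_cancer: int
    n_highrisk: int
    groups: dict[str, GroupParams]
    seed: int = 0
    n_events: int = 100_000
    control_n_events: int = 20_000

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.n_highrisk < 0:
            raise ConfigurationError("group sizes must be >= 0")
        for g in ("high_risk", "cancer"):
            if g not in self.groups:
                raise ConfigurationError(f"groups must define {g!r}")


@dataclass
class CohortSample:
    sample_id: str
    group: str
    smoking: str  # current | former
    stage: str    # I/II | III/IV | unknown | n/a
    tubes: SampleTubes
    controls: ControlSet
    params: SampleParams
    seed: int


# ---------------------------------------------------------------------------
# On-disk cohort layout: one directory per sample with the two stained tubes
# and all control tubes as FCS files, plus a tab-separated metadata sidecar.
# ---------------------------------------------------------------------------

_TUBE_FILES = {
    "leukocyte": "leukocyte.fcs",
    "epithelial": "epithelial.fcs",
    "unstained_leukocyte": "unstained_leukocyte.fcs",
    "unstained_epithelial": "unstained_epithelial.fcs",
    "fmo_cocktail": "fmo_cocktail.fcs",
    "fmo_cd206": "fmo_cd206.fcs",
    "fmo_panck": "fmo_panck.fcs",
    "fmo_epcam": "fmo_epcam.fcs",
}


def write_sample_dir(sample: "CohortSample", directory) -> None:
    """Write one sample's tubes and controls as FCS files into a directory."""
    from pathlib import Path

    from .fcs_io import write_fcs

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tables = {
        "leukocyte": sample.tubes.leukocyte,
        "epithelial": sample.tubes.epithelial,
        "unstained_leukocyte": sample.controls.unstained_leukocyte,
        "unstained_epithelial": sample.controls.unstained_epithelial,
        "fmo_cocktail": sample.controls.fmo_cocktail,
        "fmo_cd206": sample.controls.fmo_cd206,
        "fmo_panck": sample.controls.fmo_panck,
        "fmo_epcam": sample.controls.fmo_epcam,
    }
    for key, table in tables.items():
        write_fcs(table, d / _TUBE_FILES[key])


def read_sample_dir(directory) -> tuple[SampleTubes, ControlSet, str]:
    """Read a sample directory written by :func:`write_sample_dir`."""
    from pathlib import Path

    from .fcs_io import read_fcs

    d = Path(directory)
    tables = {key: read_fcs(d / fname) for key, fname in _TUBE_FILES.items()}
    sample_id = tables["leukocyte"].sample_id or d.name
    tubes = SampleTubes(
        tables["leukocyte"], tables["epithelial"], {"sample_id": sample_id}
    )
    controls = ControlSet(
        unstained_leukocyte=tables["unstained_leukocyte"],
        unstained_epithelial=tables["unstained_epithelial"],
        fmo_cocktail=tables["fmo_cocktail"],
        fmo_cd206=tables["fmo_cd206"],
        fmo_panck=tables["fmo_panck"],
        fmo_epcam=tables["fmo_epcam"],
    )
    return tubes, controls, sample_id


def write_cohort(samples: Sequence["CohortSample"], root) -> None:
    """Write a cohort as per-sample directories plus a metadata table."""
    from pathlib import Path

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    lines = ["sample_id\tgroup\tsmoking\tstage\ttotal_cells_prestain\tseed"]
    for s in samples:
        write_sample_dir(s, root / s.sample_id)
        lines.append(
            f"{s.sample_id}\t{s.group}\t{s.smoking}\t{s.stage}\t"
            f"{s.params.total_cells_prestain:.0f}\t{s.seed}"
        )
    (root / "metadata.tsv").write_text("\n".join(lines) + "\n")


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _draw_sample_params(
    gp: GroupParams, rng: np.random.Generator
) -> tuple[SampleParams, str, str]:
    b = gp.base
    smoking = "current" if rng.random() < gp.smoking_current_prob else "former"
    if gp.stage_probs is not None:
        stage = ("I/II", "III/IV", "unknown")[
            rng.choice(3, p=np.asarray(gp.stage_probs) / sum(gp.stage_probs))
        ]
    else:
        stage = "n/a"

    def frac(mean: float, shift: float = 0.0) -> float:
        return _expit(_logit(mean) + shift + rng.normal(0.0, gp.frac_sigma))

    sm = smoking == "current" and gp.smoking_effects
    g1 = frac(b.gate1_frac)
    g2 = frac(b.gate2_frac, gp.smoking_logit_alveolar if sm else 0.0)
    g3 = frac(b.gate3_frac, gp.smoking_logit_interstitial if sm else 0.0)
    dp = frac(b.dp_frac, gp.smoking_logit_dp if sm else 0.0)
    dn = frac(b.dn_frac)

    epcam = b.epcam_loc + rng.normal(0.0, gp.loc_sigma)
    if stage == "I/II":
        epcam += gp.stage_epcam_shift
    elif stage == "III/IV":
        epcam -= gp.stage_epcam_shift

    params = replace(
        b,
        cd45_frac=frac(b.cd45_frac),
        gate1_frac=g1, gate2_frac=g2, gate3_frac=g3,
        dp_frac=dp, dn_frac=dn,
        debris_frac=frac(b.debris_frac),
        sec_frac=frac(b.sec_frac),
        epcam_loc=epcam,
        ssc_scale_bright=b.ssc_scale_bright * math.exp(rng.normal(0.0, gp.ssc_sigma)),
        total_cells_prestain=float(np.exp(rng.uniform(np.log(2e6), np.log(4e7)))),
    ).normalized()
    return params, smoking, stage


def generate_cohort(cc: CohortConfig, with_controls: bool = True) -> list[CohortSample]:
    """Generate a labeled cohort of samples (and their controls).

    Per-sample composition is drawn from the group's between-sample
    distribution; deterministic under the master seed.
    """
    samples: list[CohortSample] = []
    order = [("cancer", i) for i in range(cc.n_cancer)] + [
        ("high_risk", i) for i in range(cc.n_highrisk)
    ]
    for k, (group, i) in enumerate(order):
        param_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cc.seed, spawn_key=(1, k))
        )
        params, smoking, stage = _draw_sample_params(cc.groups[group], param_rng)
        sample_seed = int(
            np.random.SeedSequence(entropy=cc.seed, spawn_key=(2, k)).generate_state(1)[0]
            % (2**31)
        )
        sid = f"{'CA' if group == 'cancer' else 'HR'}{i:03d}"
        config = build_sample_config(
            params, sample_id=sid, n_events=cc.n_events,
            control_n_events=cc.control_n_events, seed=sample_seed,
        )
        tubes = generate_sample(config)
        controls = generate_controls(config) if with_controls else None
        samples.append(
            CohortSample(sid, group, smoking, stage, tubes, controls, params, sample_seed)
        )
    return samples
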