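"""Run configuration for the trade-off pipeline.

Everything that stands in for an external convention — the stem allometry,
the taper rate used to correct non-standard measurement heights, wood
densities by decay class, the diameter bands that define which stems count
towards each service — lives here as configuration with loud defaults, so
that a user with better local information can replace any of them without
touching the analysis code.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: The six provisioning services tracked by the pipeline.
TREE_SERVICES: tuple[str, ...] = (
    "charcoal",
    "firewood",
    "construction",
    "food",
    "medicine",
)
SERVICES: tuple[str, ...] = TREE_SERVICES + ("grass",)

#: How each service is quantified: standing woody biomass (Mg C), stem
#: density (stems), or the grass-potential envelope (Mg dry grass).
SERVICE_METRIC: dict[str, str] = {
    "charcoal": "biomass",
    "firewood": "biomass",
    "construction": "biomass",
    "food": "stem_density",
    "medicine": "stem_density",
    "grass": "grass_potential",
}

#: Chronosequence classes ordering villages by charcoal-production stage.
CHRONO_CLASSES: tuple[str, ...] = ("pre-boom", "boom", "post-boom")


@dataclass(frozen=True)
class AllometryCoeffs:
    """Power-law stem allometry ``agb = a * dbh**b``.

    ``a`` is in Mg C per cm**b, ``b`` dimensionless.  Defaults follow the
    stem-level allometry for southern African dry woodlands of Ryan et al.
    (2011, Biotropica 43:423-432), converted to Mg C.  They are ordinary
    configuration, not a result of this package.
    """

    a: float = 2.65e-5
    b: float = 2.601
    form: str = "power"
    source: str = "Ryan et al. (2011) stem allometry, southern African dry woodland"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometry coefficients must be positive")
        if self.form != "power":
            raise ValueError(f"unsupported allometry form: {self.form!r}")


def _default_decay_density() -> dict[int, float]:
    # Wood density (Mg m^-3) by decay class 1 (sound) .. 5 (rotten);
    # line-intersect necromass defers to these and the carbon fraction.
    return {1: 0.65, 2: 0.55, 3: 0.45, 4: 0.30, 5: 0.20}


def _default_dbh_bands() -> dict[str, tuple[float, float]]:
    # Diameter bands (cm at 1.3 m) defining which stems provide a service.
    # The study's species-use supplement does not print size criteria, so
    # these are explicit package defaults: charcoal takes large stems,
    # firewood and construction poles intermediate ones, food and medicine
    # any inventoried stem.
    return {
        "charcoal": (10.0, math.inf),
        "firewood": (5.0, 20.0),
        "construction": (5.0, 15.0),
        "food": (5.0, math.inf),
        "medicine": (5.0, math.inf),
    }


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run."""

    #: Linear per-metre taper rate used to correct diameters measured away
    #: from 1.3 m: d(1.3) = d(pom) * (1 - taper * (1.3 - pom)).
    taper: float = 0.02
    allometry: AllometryCoeffs = field(default_factory=AllometryCoeffs)
    #: Carbon fraction of dry wood, applied to coarse woody debris.
    carbon_fraction: float = 0.47
    decay_density: dict[int, float] = field(default_factory=_default_decay_density)
    dbh_bands: dict[str, tuple[float, float]] = field(default_factory=_default_dbh_bands)
    #: Upper-envelope quantile for the grass-potential fit.
    grass_quantile: float = 0.9
    envelope_form: str = "linear"
    #: Radius of the village sampling area (the landscape each village's
    #: services are upscaled to).
    village_radius_km: float = 5.0
    #: Candidate cluster counts for woodland-type selection.
    k_min: int = 2
    k_max: int = 8
    kmeans_restarts: int = 25
    #: Standard errors are suppressed for cells with fewer plots than this.
    min_n_for_se: int = 4
    #: |percent change| above which a modelled change counts as material
    #: when checked against perceived trends.
    concordance_threshold: float = 10.0
    #: Use Monte-Carlo resampling instead of the delta method for scenario
    #: confidence intervals.
    use_monte_carlo_ci: bool = False
    mc_draws: int = 100_000
    seed: int = 0

    @property
    def village_area_ha(self) -> float:
        """Area of the circular village sampling landscape in hectares."""
        return village_area_ha(self.village_radius_km)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dbh_bands"] = {
            k: [lo, None if math.isinf(hi) else hi] for k, (lo, hi) in self.dbh_bands.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "allometry" in d and isinstance(d["allometry"], dict):
            d["allometry"] = AllometryCoeffs(**d["allometry"])
        if "dbh_bands" in d:
            d["dbh_bands"] = {
                k: (float(v[0]), math.inf if v[1] is None else float(v[1]))
                for k, v in d["dbh_bands"].items()
            }
        if "decay_density" in d:
            d["decay_density"] = {int(k): float(v) for k, v in d["decay_density"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def village_area_ha(radius_km: float) -> float:
    """Area in ha of a circle of the given radius in km (5 km -> 7854 ha)."""
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    return math.pi * radius_km**2 * 100.0
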