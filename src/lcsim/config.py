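"""Country-level inputs, calibration targets, and calibrated parameter sets.

A :class:`CountryConfig` bundles everything the simulation needs for one
country: the smoking cessation schedule, the six-bin cigarettes-per-day
(CPD) distribution, calibration targets (adult smoking prevalence and
annual lung-cancer death counts by sex), national population projections,
an other-cause mortality schedule, and -- once calibration has run -- the
fitted parameters (initiation curves, natural-history baseline scales, and
the screening-benefit parameters).

Configs are stored as YAML with a flat schema:

.. code-block:: yaml

    schema_version: 1
    country: china
    cessation:               # sex -> [[age_lo, age_hi, annual quit prob]], [lo, hi)
    cpd:                     # sex -> either {bins: [[lo, hi|null, prop]]} or
                             #               {mean_cpd: m, sigma_log: s}
    targets:                 # prevalence_year/prevalence + mortality_year/mortality_deaths
    population:              # anchors {year: total}, median_age, pyramid_seed
    other_cause:             # makeham {sex: [A, B, c]}, ratio {sex: r}
    natural_history:         # fixed structural surrogate parameters
    initiation:              # peak_age {sex}, width
    calibrated: null | {...} # filled by lcsim.calibrate

Ages are integer attained age at the start of each annual cycle and all age
intervals are closed-open ``[lo, hi)``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

SEXES = ("male", "female")
MAX_AGE = 100
SCHEMA_VERSION = 1

#: Canonical six smoking-intensity categories (cigarettes per day), closed
#: integer ranges; the last bin is open-ended.
MODEL_BIN_EDGES: tuple[tuple[int, int | None], ...] = (
    (1, 5), (6, 15), (16, 25), (26, 35), (36, 45), (46, None),
)
MODEL_BIN_LABELS = ("1-5", "6-15", "16-25", "26-35", "36-45", "45+")
#: Representative CPD assigned to a person drawn into each bin.
MODEL_BIN_CPD = np.array([3.0, 10.5, 20.5, 30.5, 40.5, 50.0])
#: Largest integer CPD used when spreading an open-ended survey bin.
OPEN_BIN_MAX_CPD = 50


class ConfigError(ValueError):
    """A country config violates its schema or an invariant."""


class NormalizationError(ConfigError):
    """Proportions that must sum to one do not."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CessationSchedule:
    """Annual quit probabilities by sex and closed-open age interval."""

    entries: tuple[tuple[str, int, int, float], ...]  # (sex, lo, hi, prob)

    def __post_init__(self) -> None:
        for sex in SEXES:
            ivs = sorted((lo, hi, p) for s, lo, hi, p in self.entries if s == sex)
            if not ivs:
                raise ConfigError(f"cessation: no intervals for sex {sex!r}")
            cur = 20
            for lo, hi, p in ivs:
                if lo != cur:
                    raise ConfigError(
                        f"cessation[{sex}]: intervals must be disjoint and cover "
                        f"[20, {MAX_AGE}]; gap/overlap at age {cur}")
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"cessation[{sex}]: probability {p} outside [0, 1]")
                cur = hi
            if cur < MAX_AGE + 1:
                raise ConfigError(f"cessation[{sex}]: coverage ends at {cur}, need {MAX_AGE + 1}")

    def quit_prob_array(self, sex: str) -> np.ndarray:
        """Annual quit probability indexed by age 0..100 (zero before 20)."""
        out = np.zeros(MAX_AGE + 1)
        for s, lo, hi, p in self.entries:
            if s == sex:
                out[lo:min(hi, MAX_AGE + 1)] = p
        return out


def _bin_index_for_cpd(k: np.ndarray) -> np.ndarray:
    """Model-bin index for integer CPD values (k >= 1)."""
    edges = np.array([b[0] for b in MODEL_BIN_EDGES[1:]])  # 6, 16, 26, 36, 46
    return np.searchsorted(edges, np.asarray(k), side="right")


#: printed survey proportions may carry rounding error this large; anything
#: worse is treated as a schema violation rather than renormalized silently
PRINTED_ROUNDING_TOL = 0.005


def survey_integer_pmf(
    survey_bins: Sequence[tuple[int, int | None, float]],
    open_bin_max: int = OPEN_BIN_MAX_CPD,
) -> np.ndarray:
    """Probability mass over integer CPD 1..``open_bin_max`` implied by
    coarse survey bins, spreading each bin's mass uniformly over the
    integers in its range (open-ended top bins run to ``open_bin_max``).

    Inputs off one by no more than printed rounding error are renormalized;
    larger deviations raise :class:`NormalizationError`.
    """
    bins = [(lo, open_bin_max if hi is None else hi, p) for lo, hi, p in survey_bins]
    covered: list[tuple[int, int]] = []
    for lo, hi, p in bins:
        if hi < lo or lo < 1 or hi > open_bin_max:
            raise ConfigError(f"survey bin [{lo}, {hi}] is invalid")
        for lo2, hi2 in covered:
            if lo <= hi2 and lo2 <= hi:
                raise ConfigError(f"survey bins overlap at [{lo}, {hi}]")
        covered.append((lo, hi))
    total = sum(p for _, _, p in bins)
    if not math.isclose(total, 1.0, abs_tol=PRINTED_ROUNDING_TOL):
        raise NormalizationError(f"survey bin proportions sum to {total}, not 1")
    pmf = np.zeros(open_bin_max + 1)  # index = integer CPD; 0 unused
    for lo, hi, p in bins:
        pmf[lo:hi + 1] += p / (hi - lo + 1)
    return pmf / pmf.sum()


def map_survey_to_model_bins(
    survey_bins: Sequence[tuple[int, int | None, float]],
    open_bin_max: int = OPEN_BIN_MAX_CPD,
) -> np.ndarray:
    """Map coarse survey CPD bins onto the six canonical model bins.

    Aggregates the uniform-over-integer-CPD mass of each survey bin into
    the model bins; mass is conserved exactly.
    """
    pmf = survey_integer_pmf(survey_bins, open_bin_max)
    ks = np.arange(1, pmf.size)
    out = np.zeros(6)
    np.add.at(out, _bin_index_for_cpd(ks), pmf[1:])
    return out


def lognormal_integer_pmf(mean_cpd: float, sigma_log: float,
                          max_cpd: int = 80) -> np.ndarray:
    """Integer-CPD mass from a reported mean: lognormal with the given
    arithmetic mean and log-scale spread, discretized onto 1..``max_cpd``.

    Used where a source reports only mean cigarettes per day rather than a
    binned distribution.
    """
    if mean_cpd <= 0 or sigma_log <= 0:
        raise ConfigError("mean_cpd and sigma_log must be positive")
    mu = math.log(mean_cpd) - 0.5 * sigma_log**2
    ks = np.arange(1, max_cpd + 1)
    z_hi = (np.log(ks + 0.5) - mu) / sigma_log
    z_lo = (np.log(np.maximum(ks - 0.5, 1e-9)) - mu) / sigma_log
    cdf = lambda z: 0.5 * (1.0 + np.vectorize(math.erf)(z / math.sqrt(2.0)))
    mass = cdf(z_hi) - cdf(z_lo)
    pmf = np.zeros(max_cpd + 1)
    pmf[1:] = mass / mass.sum()
    return pmf


def lognormal_model_bins(mean_cpd: float, sigma_log: float,
                         max_cpd: int = 80) -> np.ndarray:
    """Six-bin proportions from a reported mean CPD."""
    pmf = lognormal_integer_pmf(mean_cpd, sigma_log, max_cpd)
    out = np.zeros(6)
    np.add.at(out, _bin_index_for_cpd(np.arange(1, pmf.size)), pmf[1:])
    return out


@dataclass(frozen=True)
class CpdDistribution:
    """Survey CPD inputs and their reduction to the six model bins, per sex.

    ``survey`` holds, per sex, either ``{"bins": [(lo, hi|None, prop)]}`` or
    ``{"mean_cpd": m, "sigma_log": s}`` as printed by the source survey.
    """

    survey: Mapping[str, Mapping]

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.survey:
                raise ConfigError(f"cpd: missing sex {sex!r}")
            self.model_bins(sex)  # validates

    def integer_pmf(self, sex: str) -> np.ndarray:
        """Mass over integer CPD (index = CPD, entry 0 unused).

        The same density that defines the six-category reduction also
        supplies the within-category intensity a sampled smoker carries, so
        no distributional information is invented beyond the mapping.
        """
        spec = self.survey[sex]
        if "bins" in spec:
            return survey_integer_pmf(
                [(int(lo), None if hi is None else int(hi), float(p))
                 for lo, hi, p in spec["bins"]])
        if "mean_cpd" in spec:
            return lognormal_integer_pmf(float(spec["mean_cpd"]),
                                         float(spec.get("sigma_log", 0.5)))
        raise ConfigError(f"cpd[{sex}]: need 'bins' or 'mean_cpd'")

    def model_bins(self, sex: str) -> np.ndarray:
        pmf = self.integer_pmf(sex)
        props = np.zeros(6)
        np.add.at(props, _bin_index_for_cpd(np.arange(1, pmf.size)), pmf[1:])
        if not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
            raise NormalizationError(f"cpd[{sex}]: model bins sum to {props.sum()}")
        return props


@dataclass(frozen=True)
class CalibrationTargets:
    prevalence_year: int
    prevalence: Mapping[str, float]        # sex -> adult current-smoking proportion
    mortality_year: int
    mortality_deaths: Mapping[str, int]    # sex -> annual lung-cancer deaths

    def __post_init__(self) -> None:
        for sex in SEXES:
            p = self.prevalence.get(sex)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigError(f"targets.prevalence[{sex}]={p} outside [0, 1]")
            d = self.mortality_deaths.get(sex)
            if d is None or int(d) != d or d <= 0:
                raise ConfigError(f"targets.mortality_deaths[{sex}]={d} must be a positive integer")


@dataclass(frozen=True)
class PopulationProjection:
    """Total-population anchors plus a single-year-of-age pyramid.

    ``age_sex_shares`` has shape (101, 2) -- ages 0..100 by (male, female) --
    and sums to one over all cells.  It is generated deterministically from
    ``median_age`` and ``pyramid_seed`` when read from file (the sources
    publish totals, not age detail), or supplied directly.
    """

    anchors: Mapping[int, int]
    median_age: float
    pyramid_seed: int
    age_sex_shares: np.ndarray = field(compare=False, repr=False, default=None)

    def __post_init__(self) -> None:
        for year in (2020, 2030, 2040):
            if year not in self.anchors:
                raise ConfigError(f"population.anchors missing year {year}")
        for year, count in self.anchors.items():
            if count <= 0:
                raise ConfigError(f"population.anchors[{year}]={count} must be positive")
        if self.age_sex_shares is None:
            from .synth import pyramid_shares  # local import: synth builds on config
            object.__setattr__(self, "age_sex_shares",
                               pyramid_shares(self.median_age, self.pyramid_seed))
        s = np.asarray(self.age_sex_shares, dtype=float)
        if s.shape != (MAX_AGE + 1, 2) or not math.isclose(s.sum(), 1.0, abs_tol=1e-9):
            raise ConfigError("population.age_sex_shares must be (101, 2) summing to 1")
        object.__setattr__(self, "age_sex_shares", s)


@dataclass(frozen=True)
class OtherCauseMortalityTable:
    """Reference Gompertz-Makeham schedule scaled by a per-sex country ratio.

    The reference schedule is synthetic: annual death probability
    ``A + B * c**age``, parameterized per sex.  Country differences enter
    only through the multiplicative ``ratio`` applied to the reference, the
    same mechanism used to transport a U.S.-style schedule to each country.
    """

    makeham: Mapping[str, tuple[float, float, float]]  # sex -> (A, B, c)
    ratio: Mapping[str, float]
    #: all-cause (non-lung-cancer) relative risk of a 20-CPD current smoker
    #: versus a never smoker; scales linearly in CPD.  Applied as a
    #: within-age redistribution: the population-average schedule stays
    #: ``makeham * ratio``, smokers sit above it and never smokers below.
    smoker_rr_20cpd: float = 2.0
    #: half-life (years) of the smoker's excess all-cause risk after quitting
    quit_rr_halflife: float = 7.0

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.makeham or sex not in self.ratio:
                raise ConfigError(f"other_cause: missing sex {sex!r}")
            if self.ratio[sex] < 0:
                raise ConfigError(f"other_cause.ratio[{sex}] must be nonnegative")
        if self.smoker_rr_20cpd < 1.0 or self.quit_rr_halflife <= 0:
            raise ConfigError("smoker_rr_20cpd must be >= 1 and quit_rr_halflife > 0")

    def base_rate_array(self, sex: str) -> np.ndarray:
        a, b, c = (float(x) for x in self.makeham[sex])
        ages = np.arange(MAX_AGE + 1, dtype=float)
        return np.clip(a + b * np.power(c, ages), 0.0, 1.0)

    def rate_array(self, sex: str, warn_clip: bool = True) -> np.ndarray:
        """Country schedule: reference times ratio, clipped into [0, 1]."""
        raw = self.base_rate_array(sex) * float(self.ratio[sex])
        if warn_clip and (raw > 1.0).any():
            import warnings
            warnings.warn(f"other-cause probabilities for {sex} exceed 1 after "
                          "scaling; clipping", RuntimeWarning, stacklevel=2)
        return np.clip(raw, 0.0, 1.0)


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Structural parameters of the lung-cancer natural-history surrogate.

    The surrogate is: an age-increasing baseline onset hazard times an
    excess-relative-risk dose response in effective (post-quit decayed)
    pack-years; a geometric preclinical sojourn; two detection stages
    (early/late) with stage-specific annual cause-specific death
    probabilities.  ``baseline_scale`` (per sex) is fitted to the national
    death-count targets; the rest are fixed design values.
    """

    baseline_age0: float = 35.0      # years; no baseline risk before this age
    baseline_power: float = 2.0      # Weibull-like age exponent
    baseline_plateau_age: float = 80.0  # hazard stops rising here (incidence
                                     # curves flatten at the oldest ages)
    err_per_pack_year: float = 0.40  # excess relative risk per effective pack-year
                                     # (current-smoker RR ~15-20 at a typical career)
    quit_halflife: float = 15.0      # years; decay of excess risk after quitting
    sojourn_mean: float = 4.0        # years; mean preclinical sojourn (geometric)
    early_frac_clinical: float = 0.25  # P(early stage | clinical surfacing)
    cure_early: float = 0.10         # P(cured | early stage): mixture-cure survival
    cure_late: float = 0.01          # P(cured | late stage)
    q_early: float = 0.135           # annual death prob, early stage, uncured
    q_late: float = 0.45             # annual death prob, late stage, uncured

    def __post_init__(self) -> None:
        if self.sojourn_mean <= 0:
            raise ConfigError("sojourn_mean must be positive")
        for name in ("err_per_pack_year", "quit_halflife"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("early_frac_clinical", "cure_early", "cure_late",
                     "q_early", "q_late"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class InitiationModel:
    """Gaussian-bump initiation hazard: shape fixed, height calibrated.

    Annual initiation probability at age ``a`` is
    ``peak_rate * exp(-0.5 ((a - peak_age) / width)^2)`` on ages 10..39 and
    zero elsewhere; ``peak_rate`` per sex lives in :class:`CalibratedParams`.
    """

    peak_age: Mapping[str, float]
    width: float = 4.5
    min_age: int = 10
    max_age: int = 40  # exclusive

    def hazard_array(self, sex: str, peak_rate: float) -> np.ndarray:
        ages = np.arange(MAX_AGE + 1, dtype=float)
        h = peak_rate * np.exp(-0.5 * ((ages - self.peak_age[sex]) / self.width) ** 2)
        h[(ages < self.min_age) | (ages >= self.max_age)] = 0.0
        return np.clip(h, 0.0, 1.0)


@dataclass(frozen=True)
class CalibratedParams:
    """Parameters filled in by the staged calibration."""

    initiation_peak_rate: Mapping[str, float]
    baseline_scale: Mapping[str, float] | None = None
    screen_sensitivity: float | None = None   # per-screen detection prob, preclinical
    early_frac_screen: float | None = None    # P(early stage | screen detection)
    report: Mapping | None = field(default=None, compare=False)

    @property
    def has_natural_history(self) -> bool:
        return self.baseline_scale is not None

    @property
    def has_screening_benefit(self) -> bool:
        return self.screen_sensitivity is not None and self.early_frac_screen is not None


@dataclass(frozen=True)
class CountryConfig:
    country: str
    cessation: CessationSchedule
    cpd: CpdDistribution
    targets: CalibrationTargets
    population: PopulationProjection
    other_cause: OtherCauseMortalityTable
    natural_history: NaturalHistoryParams = field(default_factory=NaturalHistoryParams)
    initiation: InitiationModel = field(
        default_factory=lambda: InitiationModel(peak_age={"male": 19.0, "female": 19.0}))
    calibrated: CalibratedParams | None = None
    schema_version: int = SCHEMA_VERSION

    @property
    def is_calibrated(self) -> bool:
        return self.calibrated is not None

    @property
    def is_fully_calibrated(self) -> bool:
        return (self.calibrated is not None and self.calibrated.has_natural_history
                and self.calibrated.has_screening_benefit)

    def with_calibrated(self, **kwargs) -> "CountryConfig":
        base = dataclasses.asdict(self.calibrated) if self.calibrated else {
            "initiation_peak_rate": {}}
        base.update(kwargs)
        return dataclasses.replace(self, calibrated=CalibratedParams(**base))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _cfg_to_dict(cfg: CountryConfig) -> dict:
    d: dict = {
        "schema_version": cfg.schema_version,
        "country": cfg.country,
        "cessation": {
            sex: [[lo, hi, p] for s, lo, hi, p in cfg.cessation.entries if s == sex]
            for sex in SEXES},
        "cpd": {sex: {k: (v if not isinstance(v, list) else
                          [list(b) for b in v])
                      for k, v in cfg.cpd.survey[sex].items()} for sex in SEXES},
        "targets": {
            "prevalence_year": cfg.targets.prevalence_year,
            "prevalence": {s: float(v) for s, v in cfg.targets.prevalence.items()},
            "mortality_year": cfg.targets.mortality_year,
            "mortality_deaths": {s: int(v) for s, v in cfg.targets.mortality_deaths.items()},
        },
        "population": {
            "anchors": {int(y): int(v) for y, v in cfg.population.anchors.items()},
            "median_age": cfg.population.median_age,
            "pyramid_seed": cfg.population.pyramid_seed,
        },
        "other_cause": {
            "makeham": {s: [float(x) for x in cfg.other_cause.makeham[s]] for s in SEXES},
            "ratio": {s: float(cfg.other_cause.ratio[s]) for s in SEXES},
            "smoker_rr_20cpd": float(cfg.other_cause.smoker_rr_20cpd),
            "quit_rr_halflife": float(cfg.other_cause.quit_rr_halflife),
        },
        "natural_history": dataclasses.asdict(cfg.natural_history),
        "initiation": {
            "peak_age": dict(cfg.initiation.peak_age),
            "width": cfg.initiation.width,
            "min_age": cfg.initiation.min_age,
            "max_age": cfg.initiation.max_age,
        },
        "calibrated": None,
    }
    if cfg.calibrated is not None:
        c = cfg.calibrated
        d["calibrated"] = {
            "initiation_peak_rate": dict(c.initiation_peak_rate),
            "baseline_scale": None if c.baseline_scale is None else dict(c.baseline_scale),
            "screen_sensitivity": c.screen_sensitivity,
            "early_frac_screen": c.early_frac_screen,
            "report": None if c.report is None else dict(c.report),
        }
    return d


def _cfg_from_dict(d: Mapping) -> CountryConfig:
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unrecognized schema_version {version!r}")
    try:
        cess = CessationSchedule(tuple(
            (sex, int(lo), int(hi), float(p))
            for sex in SEXES for lo, hi, p in d["cessation"][sex]))
        cpd = CpdDistribution({sex: d["cpd"][sex] for sex in SEXES})
        t = d["targets"]
        targets = CalibrationTargets(int(t["prevalence_year"]), t["prevalence"],
                                     int(t["mortality_year"]), t["mortality_deaths"])
        p = d["population"]
        pop = PopulationProjection({int(y): int(v) for y, v in p["anchors"].items()},
                                   float(p["median_age"]), int(p["pyramid_seed"]))
        oc = d["other_cause"]
        other = OtherCauseMortalityTable(
            {s: tuple(oc["makeham"][s]) for s in SEXES},
            {s: float(oc["ratio"][s]) for s in SEXES},
            smoker_rr_20cpd=float(oc.get("smoker_rr_20cpd", 2.0)),
            quit_rr_halflife=float(oc.get("quit_rr_halflife", 7.0)))
        nh = NaturalHistoryParams(**d.get("natural_history", {}))
        init_d = d.get("initiation", {})
        init = InitiationModel(
            peak_age=init_d.get("peak_age", {"male": 19.0, "female": 19.0}),
            width=float(init_d.get("width", 4.5)),
            min_age=int(init_d.get("min_age", 10)),
            max_age=int(init_d.get("max_age", 40)))
    except KeyError as exc:
        raise ConfigError(f"missing field {exc.args[0]!r}") from exc
    cal = None
    if d.get("calibrated") is not None:
        c = d["calibrated"]
        cal = CalibratedParams(
            initiation_peak_rate=c["initiation_peak_rate"],
            baseline_scale=c.get("baseline_scale"),
            screen_sensitivity=c.get("screen_sensitivity"),
            early_frac_screen=c.get("early_frac_screen"),
            report=c.get("report"))
    return CountryConfig(country=str(d["country"]), cessation=cess, cpd=cpd,
                         targets=targets, population=pop, other_cause=other,
                         natural_history=nh, initiation=init, calibrated=cal)


def read_country_config(path: str | Path) -> CountryConfig:
    """Read and validate a country config; raises :class:`ConfigError`."""
    with open(path, "r") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: not a mapping")
    return _cfg_from_dict(d)


def write_country_config(cfg: CountryConfig, path: str | Path) -> None:
    """Serialize a config; writes are deterministic (byte-identical reruns)."""
    text = yaml.safe_dump(_cfg_to_dict(cfg), sort_keys=True, default_flow_style=None)
    Path(path).write_text(text)


_DATA_DIR = Path(__file__).parent / "data"
COUNTRIES = ("china", "japan", "singapore", "south_korea")


def packaged_config_path(country: str) -> Path:
    path = _DATA_DIR / f"{country}.yaml"
    if not path.exists():
        raise ConfigError(f"no packaged config for {country!r}; have {COUNTRIES}")
    return path


def load_country(country: str) -> CountryConfig:
    """Load one of the packaged country configs by name."""
    return read_country_config(packaged_config_path(country))
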