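"""Synthetic bioassay and metabolite data with known ground truth.

The generator emulates the statistical structure of a wild-tomato
insect-resistance screen: ~19 accessions scored with no-choice whitefly cage
assays (binomial survival, ~15 insects per cage, 2 cages per plant) and
daily-observed thrips larval survival (right-censored at a 19-day horizon),
plus sparse, zero-inflated replicate-level metabolite tables in which a few
"planted" discriminative features are enriched, in presence and abundance, in
the resistant genotypes.

Randomness: a single NumPy ``SeedSequence`` is spawned into one child stream
per generator (features / whitefly / thrips), each driving a PCG64
``default_rng``; a fixed seed therefore gives bit-identical output, and each
stage can be regenerated independently of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_feature_table",
    "simulate_whitefly_assay",
    "simulate_thrips_assay",
    "simulate_trichome_densities",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation settings."""


@dataclass
class SimConfig:
    """Study-design constants for the synthetic screen.

    Defaults mirror the screen the generator emulates: 19 accessions of which
    8 resist the insect, ~15 adults per clip cage and two cages on each of
    three plants, 30 larvae per accession followed daily for 19 days, and
    sparse log-normal metabolite tables with 6 (acylsugar-like) or 4
    (volatile-like) biological replicates.
    """

    n_accessions: int = 19
    n_resistant: int = 8
    n_features: int = 80
    n_planted: int = 2
    presence_prob_resistant: float = 0.9   # q_r, planted features in resistant lines
    presence_prob_susceptible: float = 0.1  # q_s, planted features elsewhere
    background_presence: float = 0.15       # p_bg, all other features
    planted_presence_level: Literal["replicate", "accession"] = "replicate"
    background_presence_level: Literal["replicate", "accession"] = "accession"
    lognormal_mu: float = 10.0
    lognormal_sigma: float = 1.0
    planted_fold: float = 8.0
    n_replicates: int = 6
    cage_size: int = 15
    cages_per_plant: int = 2
    plants_per_accession: int = 3
    n_larvae: int = 30
    followup_days: int = 19
    baseline_daily_hazard: float = 0.04
    log_hr_resistant: float = math.log(5.0)
    survival_prob_resistant: float = 0.25
    survival_prob_susceptible: float = 0.75
    event_time_model: Literal["exponential", "weibull"] = "exponential"
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "presence_prob_resistant": self.presence_prob_resistant,
            "presence_prob_susceptible": self.presence_prob_susceptible,
            "background_presence": self.background_presence,
            "survival_prob_resistant": self.survival_prob_resistant,
            "survival_prob_susceptible": self.survival_prob_susceptible,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.n_planted > self.n_features:
            raise ConfigurationError(
                f"n_planted={self.n_planted} exceeds n_features={self.n_features}"
            )
        if self.n_planted > 0 and (
            self.presence_prob_resistant < self.presence_prob_susceptible
        ):
            raise ConfigurationError("planted features require q_r >= q_s")
        if not 0 < self.n_resistant < self.n_accessions:
            raise ConfigurationError("need 0 < n_resistant < n_accessions")
        if self.baseline_daily_hazard < 0:
            raise ConfigurationError("baseline_daily_hazard must be >= 0")
        for name in ("cage_size", "cages_per_plant", "plants_per_accession",
                     "n_replicates", "n_larvae", "followup_days"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be > 0")

    # ---- derived per-accession truth -------------------------------------
    @property
    def accessions(self) -> list[str]:
        return [f"ACC{i:02d}" for i in range(1, self.n_accessions + 1)]

    @property
    def classes(self) -> dict[str, str]:
        """First ``n_resistant`` accessions are resistant; the rest susceptible.

        The last accession plays the susceptible baseline (the "Moneymaker"
        role in the emulated design).
        """
        return {
            acc: ("resistant" if i < self.n_resistant else "susceptible")
            for i, acc in enumerate(self.accessions)
        }

    @property
    def baseline_accession(self) -> str:
        return self.accessions[-1]

    def survival_probs(self) -> dict[str, float]:
        return {
            acc: (
                self.survival_prob_resistant
                if cls == "resistant"
                else self.survival_prob_susceptible
            )
            for acc, cls in self.classes.items()
        }

    def log_hazard_ratios(self) -> dict[str, float]:
        """Thrips die faster on resistant plants: positive log HR vs baseline."""
        return {
            acc: (self.log_hr_resistant if cls == "resistant" else 0.0)
            for acc, cls in self.classes.items()
        }

    def _stream(self, name: str) -> np.random.Generator:
        salt = {"features": 1, "whitefly": 2, "thrips": 3, "trichomes": 4}[name]
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth handed back next to each simulated dataset."""

    planted_feature_ids: tuple[str, ...]
    true_class: dict[str, str]
    true_survival_prob: dict[str, float]
    true_log_hr: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "planted_feature_ids": list(self.planted_feature_ids),
            "true_class": self.true_class,
            "true_survival_prob": self.true_survival_prob,
            "true_log_hr": self.true_log_hr,
        }


def _truth(config: SimConfig, planted: tuple[str, ...]) -> SimTruth:
    return SimTruth(
        planted_feature_ids=planted,
        true_class=config.classes,
        true_survival_prob=config.survival_probs(),
        true_log_hr=config.log_hazard_ratios(),
    )


def simulate_feature_table(config: SimConfig):
    """Zero-inflated log-normal replicate-level metabolite table.

    Each table entry is zero with probability (1 - presence probability) and
    otherwise ``LogNormal(mu, sigma)``, multiplied by ``planted_fold`` for
    planted features in resistant accessions.  The presence probability is
    q_r for planted features in resistant accessions, q_s for planted
    features elsewhere, and p_bg for background features.

    The Bernoulli presence draw happens at a configurable level: per
    replicate entry for planted features (discriminative compounds show a
    graded, replicate-to-replicate signal in their producing genotypes) and
    once per (accession, feature) for background features, which reproduces
    the hallmark sparsity of trichome metabolite screens — most metabolites
    detected in only a couple of accessions, with all replicates of a
    non-producer at zero.

    Returns ``(FeatureTable, SimTruth)``.
    """
    from .annotation import FeatureTable  # local import to avoid cycle at init

    rng = config._stream("features")
    accs = config.accessions
    classes = config.classes
    feature_ids = [f"F{j:03d}" for j in range(1, config.n_features + 1)]
    planted = tuple(feature_ids[: config.n_planted])
    planted_set = set(planted)

    rows = []
    for acc in accs:
        resistant = classes[acc] == "resistant"
        for fid in feature_ids:
            if fid in planted_set:
                p = (
                    config.presence_prob_resistant
                    if resistant
                    else config.presence_prob_susceptible
                )
                level = config.planted_presence_level
            else:
                p = config.background_presence
                level = config.background_presence_level
            acc_present = rng.random() < p if level == "accession" else True
            fold = (
                config.planted_fold if (fid in planted_set and resistant) else 1.0
            )
            for rep in range(1, config.n_replicates + 1):
                present = rng.random() < p if level == "replicate" else acc_present
                if present:
                    x = fold * rng.lognormal(config.lognormal_mu, config.lognormal_sigma)
                else:
                    x = 0.0
                rows.append((acc, rep, fid, classes[acc], x))

    data = pd.DataFrame(
        rows, columns=["accession", "replicate", "feature_id", "class", "abundance"]
    )
    meta = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "feature_class": "synthetic",
            "planted": [fid in planted_set for fid in feature_ids],
        }
    ).set_index("feature_id")
    # the class column rides along in the long table for exports
    table = FeatureTable(data, feature_meta=meta)
    return table, _truth(config, planted)


def simulate_whitefly_assay(config: SimConfig):
    """Clip-cage alive/dead counts: ``n_alive ~ Binomial(cage_size, p_accession)``.

    Returns ``(DataFrame[accession, plant_id, cage_id, n_alive, n_dead],
    SimTruth)``.
    """
    rng = config._stream("whitefly")
    probs = config.survival_probs()
    rows = []
    for acc in config.accessions:
        p = probs[acc]
        for plant in range(1, config.plants_per_accession + 1):
            for cage in range(1, config.cages_per_plant + 1):
                alive = int(rng.binomial(config.cage_size, p))
                rows.append(
                    (acc, f"{acc}-P{plant}", f"{acc}-P{plant}-C{cage}",
                     alive, config.cage_size - alive)
                )
    df = pd.DataFrame(
        rows, columns=["accession", "plant_id", "cage_id", "n_alive", "n_dead"]
    )
    return df, _truth(config, ())


def simulate_thrips_assay(config: SimConfig):
    """Daily-observed right-censored larval death times.

    A continuous event time is drawn (exponential by default, Weibull via
    ``event_time_model``) with per-day rate ``baseline_daily_hazard *
    exp(log_hr)`` and rounded **up** to the observation day; larvae alive past
    ``followup_days`` are censored there with status 0.

    Returns ``(DataFrame[accession, individual_id, day, status], SimTruth)``.
    """
    rng = config._stream("thrips")
    log_hrs = config.log_hazard_ratios()
    rows = []
    for acc in config.accessions:
        rate = config.baseline_daily_hazard * math.exp(log_hrs[acc])
        for i in range(1, config.n_larvae + 1):
            if rate <= 0:
                day, status = config.followup_days, 0
            else:
                if config.event_time_model == "weibull":
                    scale = 1.0 / rate
                    t = scale * rng.weibull(config.weibull_shape)
                else:
                    t = rng.exponential(1.0 / rate)
                day = max(1, math.ceil(t))
                if day > config.followup_days:
                    day, status = config.followup_days, 0
                else:
                    status = 1
            rows.append((acc, f"{acc}-L{i:03d}", day, status))
    df = pd.DataFrame(rows, columns=["accession", "individual_id", "day", "status"])
    return df, _truth(config, ())


def simulate_trichome_densities(config: SimConfig):
    """Per-leaf-disc trichome densities (trichomes per mm^2).

    Resistant accessions get denser glandular type-I/IV cover (acylsugar
    producers); type VI and non-glandular densities are class-independent.
    Two discs per surface per plant, both leaf surfaces.
    """
    rng = config._stream("trichomes")
    base = {"NG": 4.0, "I/IV": 1.0, "VI": 2.0}
    rows = []
    for acc in config.accessions:
        resistant = config.classes[acc] == "resistant"
        for plant in range(1, config.plants_per_accession + 1):
            for surface in ("abaxial", "adaxial"):
                for disc in (1, 2):
                    for ttype, mu in base.items():
                        m = mu
                        if ttype == "I/IV" and resistant:
                            m *= 5.0
                        if ttype == "I/IV" and surface == "abaxial":
                            m *= 1.5
                        d = rng.gamma(shape=4.0, scale=m / 4.0)
                        rows.append(
                            (acc, f"{acc}-P{plant}", f"{acc}-P{plant}-{surface}-D{disc}",
                             surface, ttype, d)
                        )
    return (
        pd.DataFrame(
            rows,
            columns=["accession", "plant_id", "leaf_disc_id", "surface",
                     "trichome_type", "density"],
        ),
        _truth(config, ()),
    )
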