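"""Synthetic cohorts of individuals with variable coagulation-protein levels.

Plasma levels of coagulation proteins vary widely between healthy
individuals.  This module draws virtual cohorts in which each protein's
initial level is an independent zero-truncated Gaussian around the
kinetic model's default mean, with literature coefficients of variation
(CVs measured in normal populations).  It also applies the
anticoagulant-treatment transform: a uniform proportional reduction of
the vitamin-K-dependent factors (II, VII/VIIa, IX, X), which scales both
the mean and the spread of those levels.

Factor XI is accepted for completeness but carried as an inert
annotation: the extrinsic-pathway network contains no XI species, so its
level has no kinetic effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .network import ReactionNetwork, load_network

__all__ = [
    "ProteinVariability",
    "PopulationSpec",
    "FactorProfile",
    "TreatmentIntensity",
    "VITAMIN_K_DEPENDENT",
    "default_population_spec",
    "sample_population",
    "apply_treatment",
    "mean_profile",
    "save_population_spec",
    "load_population_spec",
]

#: proteins whose functional levels anticoagulant treatment reduces
#: (VIIa is the activated form of VII and is reduced with it)
VITAMIN_K_DEPENDENT = ("II", "VII", "VIIa", "IX", "X")

#: population coefficients of variation (%) of coagulation-protein levels
#: in normal adults, from published cohort measurements (median where
#: several determinations exist)
DEFAULT_CV_PERCENT = {
    "II": 11.95,
    "V": 31.88,
    "VII": 26.33,
    "VIII": 31.165,
    "IX": 33.11,
    "X": 25.07,
    "XI": 23.42,
    "ATIII": 18.35,
    "TFPI": 35.16,
}

#: sampling rejects non-positive draws; a spec whose truncation would
#: reject more than this fraction is considered degenerate
MAX_REJECTION_PROBABILITY = 0.5


@dataclass(frozen=True)
class ProteinVariability:
    """Interindividual coefficient of variation of one protein's level."""

    protein: str
    cv_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cv_percent < 100.0:
            raise ValueError(
                f"{self.protein}: cv_percent must be in [0, 100), got {self.cv_percent}"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a virtual cohort.

    ``mean_levels`` are nM means per protein (the kinetic model's default
    plasma concentrations); ``variabilities`` carry the per-protein CVs.
    Factor XI, absent from the extrinsic network, uses a nominal mean of
    1.0 and is inert.  Levels are drawn independently; draws at or below
    zero are rejected and redrawn (``truncation = "reject_nonpositive"``).
    """

    variabilities: tuple[ProteinVariability, ...]
    mean_levels: dict[str, float]
    n_individuals: int = 1000
    seed: int = 0
    truncation: str = "reject_nonpositive"

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.truncation != "reject_nonpositive":
            raise ValueError(f"unknown truncation rule {self.truncation!r}")
        missing = [v.protein for v in self.variabilities if v.protein not in self.mean_levels]
        if missing:
            raise ValueError(f"no mean level for: {missing}")

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(v.protein for v in self.variabilities)

    def cv(self, protein: str) -> float:
        for v in self.variabilities:
            if v.protein == protein:
                return v.cv_percent
        raise KeyError(protein)


@dataclass(frozen=True)
class FactorProfile:
    """One simulated individual's initial coagulation-protein levels.

    ``levels_nM`` maps species names (including VIIa) to initial
    concentrations; ``multipliers`` holds the dimensionless draw
    (level / population mean) per sampled protein.  VII and VIIa are the
    same gene product and share one multiplier.
    """

    individual_id: int
    levels_nM: dict[str, float]
    multipliers: dict[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.levels_nM.items() if not v > 0}
        if bad:
            raise ValueError(f"non-positive levels: {bad}")


@dataclass(frozen=True)
class TreatmentIntensity:
    """Anticoagulation intensity as the fraction of vitamin-K-dependent
    factor levels remaining (1.0 = untreated, 0.2 = heavy treatment)."""

    fraction_remaining: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_remaining <= 1.0:
            raise ValueError(
                f"fraction_remaining must be in (0, 1], got {self.fraction_remaining}"
            )


def default_population_spec(
    network: ReactionNetwork | None = None,
    n_individuals: int = 1000,
    seed: int = 0,
) -> PopulationSpec:
    """The default cohort recipe: literature CVs around the kinetic
    model's default plasma concentrations.

    Factor XI is included with a nominal mean of 1.0; it has no species
    in the extrinsic-pathway network and no kinetic effect.
    """
    network = network if network is not None else load_network()
    means = {}
    for protein in DEFAULT_CV_PERCENT:
        if protein in network.index:
            means[protein] = network.species[network.index[protein]].initial_nM
        else:
            means[protein] = 1.0
    variabilities = tuple(
        ProteinVariability(p, cv) for p, cv in DEFAULT_CV_PERCENT.items()
    )
    return PopulationSpec(
        variabilities=variabilities,
        mean_levels=means,
        n_individuals=n_individuals,
        seed=seed,
    )


def _check_rejection_rate(spec: PopulationSpec) -> None:
    for v in spec.variabilities:
        if v.cv_percent == 0.0:
            continue
        p_reject = stats.norm.cdf(-100.0 / v.cv_percent)
        if p_reject > MAX_REJECTION_PROBABILITY:
            raise ValueError(
                f"{v.protein}: cv {v.cv_percent}% would reject "
                f"{p_reject:.0%} of draws; spec is degenerate"
            )


def sample_multipliers(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Dimensionless level multipliers, shape (n_individuals, n_proteins).

    Each entry is ``1 + (cv/100) * z`` with ``z`` standard normal,
    independently per protein and individual; non-positive draws are
    rejected and redrawn (truncation at zero).
    """
    _check_rejection_rate(spec)
    cvs = np.array([v.cv_percent for v in spec.variabilities]) / 100.0
    n = spec.n_individuals
    m = 1.0 + cvs * rng.standard_normal((n, cvs.size))
    bad = m <= 0.0
    while bad.any():
        m[bad] = 1.0 + (np.broadcast_to(cvs, m.shape)[bad]
                        * rng.standard_normal(int(bad.sum())))
        bad = m <= 0.0
    return m


def sample_population(
    spec: PopulationSpec, network: ReactionNetwork | None = None
) -> list[FactorProfile]:
    """Draw a cohort of :class:`FactorProfile` from ``spec``.

    Reproducible from ``spec.seed``.  VIIa's level is its network mean
    scaled by VII's multiplier (same gene product, fixed activation
    ratio).  Proteins without a network species (factor XI) are carried
    as inert levels and trigger a warning once per call.
    """
    network = network if network is not None else load_network()
    rng = np.random.default_rng(spec.seed)
    mult = sample_multipliers(spec, rng)

    inert = [p for p in spec.proteins if p not in network.index]
    if inert:
        warnings.warn(
            f"proteins with no species in the network are inert: {inert}",
            stacklevel=2,
        )

    viia_mean = (
        network.species[network.index["VIIa"]].initial_nM
        if "VIIa" in network.index
        else None
    )
    profiles = []
    for i in range(spec.n_individuals):
        multipliers = dict(zip(spec.proteins, mult[i]))
        levels = {p: spec.mean_levels[p] * multipliers[p] for p in spec.proteins}
        if viia_mean is not None and "VII" in multipliers:
            multipliers["VIIa"] = multipliers["VII"]
            levels["VIIa"] = viia_mean * multipliers["VII"]
        profiles.append(FactorProfile(i, levels, multipliers))
    return profiles


def apply_treatment(
    profile: FactorProfile, intensity: TreatmentIntensity
) -> FactorProfile:
    """Scale the vitamin-K-dependent factor levels of one individual.

    Multiplies II, VII, VIIa, IX and X by ``fraction_remaining``, leaving
    all other proteins untouched.  Returns a new profile; the input is
    not modified.
    """
    levels = dict(profile.levels_nM)
    for p in VITAMIN_K_DEPENDENT:
        if p in levels:
            levels[p] = levels[p] * intensity.fraction_remaining
    return replace(profile, levels_nM=levels)


def mean_profile(
    spec: PopulationSpec, network: ReactionNetwork | None = None
) -> FactorProfile:
    """The cohort-mean individual: every multiplier exactly 1."""
    network = network if network is not None else load_network()
    multipliers = {p: 1.0 for p in spec.proteins}
    levels = dict(spec.mean_levels)
    if "VIIa" in network.index and "VII" in multipliers:
        multipliers["VIIa"] = 1.0
        levels["VIIa"] = network.species[network.index["VIIa"]].initial_nM
    return FactorProfile(-1, levels, multipliers)


def save_population_spec(spec: PopulationSpec, path) -> None:
    """Serialize a :class:`PopulationSpec` to YAML (lossless round trip)."""
    import yaml

    doc = {
        "variabilities": [
            {"protein": v.protein, "cv_percent": v.cv_percent}
            for v in spec.variabilities
        ],
        "mean_levels": dict(spec.mean_levels),
        "n_individuals": spec.n_individuals,
        "seed": spec.seed,
        "truncation": spec.truncation,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_population_spec(path) -> PopulationSpec:
    """Load a :class:`PopulationSpec` from YAML."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PopulationSpec(
        variabilities=tuple(
            ProteinVariability(rec["protein"], float(rec["cv_percent"]))
            for rec in doc["variabilities"]
        ),
        mean_levels={k: float(v) for k, v in doc["mean_levels"].items()},
        n_individuals=int(doc["n_individuals"]),
        seed=int(doc["seed"]),
        truncation=doc.get("truncation", "reject_nonpositive"),
    )
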