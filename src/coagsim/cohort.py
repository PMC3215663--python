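"""Cohort-level INR analysis: canalization and level-INR correlations.

Runs every individual of a virtual cohort through the PT assay at a grid
of anticoagulation intensities, normalises PTs to the cohort's mean
normal prothrombin time (MNPT), and summarises the resulting INR
distributions.  The INR here is the plain ratio PT / MNPT (no
reagent-specific ISI exponent).

The scientific content: in the untreated cohort, wide protein-level
variability produces only a narrow INR spread (canalization); as the
vitamin-K-dependent factors are reduced, the same underlying variability
is unmasked and the INR spread grows.  Correlating each protein's
baseline level with the INR identifies which proteins drive the spread
in each regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assay import CLOT_NOT_REACHED, AssayConditions, IntegrationError, simulate_clotting
from .network import ReactionNetwork, load_network
from .population import (
    FactorProfile,
    PopulationSpec,
    TreatmentIntensity,
    apply_treatment,
    sample_population,
)

__all__ = [
    "CohortResult",
    "compute_mnpt",
    "compute_inr",
    "run_cohort",
    "correlate_levels_vs_inr",
]

logger = logging.getLogger(__name__)

#: standard boxplot outlier rule: beyond 1.5 * IQR from the quartiles
IQR_WHISKER_FACTOR = 1.5


def compute_mnpt(untreated_pts) -> float:
    """Mean normal prothrombin time: the arithmetic mean of the
    untreated cohort's finite PTs.

    Non-clotting entries (:data:`CLOT_NOT_REACHED`) are excluded with a
    logged warning.  Requires at least two finite PTs.
    """
    pts = np.asarray(list(untreated_pts), dtype=float)
    finite = pts[np.isfinite(pts)]
    n_dropped = pts.size - finite.size
    if n_dropped:
        logger.warning(
            "excluding %d non-clotting individual(s) from the MNPT", n_dropped
        )
    if finite.size == 0:
        raise ValueError("no finite prothrombin times; cannot compute MNPT")
    if finite.size < 2:
        raise ValueError("need at least two finite prothrombin times for the MNPT")
    return float(finite.mean())


def compute_inr(pt: float, mnpt: float) -> float:
    """INR of one sample: its PT divided by the MNPT.

    A non-clotting PT propagates the sentinel (infinite INR), which
    summaries exclude.  No ISI exponent is applied.
    """
    if not mnpt > 0:
        raise ValueError(f"MNPT must be > 0, got {mnpt}")
    return pt / mnpt


@dataclass(frozen=True)
class CohortResult:
    """PT/INR of every individual at every treatment intensity.

    ``records`` has one row per individual x intensity with columns
    ``individual_id, intensity, pt_s, inr`` (non-clotting rows carry
    ``inf``).  ``baseline_levels`` holds each individual's pretreatment
    protein levels.  ``diagnostics`` counts non-clotting and failed
    integrations per intensity.
    """

    records: pd.DataFrame
    mnpt: float
    baseline_levels: pd.DataFrame
    profiles: tuple[FactorProfile, ...]
    diagnostics: dict = field(default_factory=dict)

    def intensities(self) -> tuple[float, ...]:
        return tuple(sorted(self.records["intensity"].unique(), reverse=True))

    def inr_values(self, intensity: float) -> np.ndarray:
        """Finite INRs at one intensity."""
        sel = self.records.loc[self.records["intensity"] == intensity, "inr"]
        vals = sel.to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    def summary(self) -> pd.DataFrame:
        """Per-intensity INR summary: moments, quartiles, outlier count.

        Outliers follow the standard boxplot convention (beyond
        1.5 x IQR from the quartiles).  Non-clotting individuals are
        excluded from all statistics and counted in the diagnostics.
        """
        rows = []
        for intensity in self.intensities():
            inr = self.inr_values(intensity)
            q1, med, q3 = np.percentile(inr, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - IQR_WHISKER_FACTOR * iqr, q3 + IQR_WHISKER_FACTOR * iqr
            rows.append(
                {
                    "intensity": intensity,
                    "n": inr.size,
                    "mean_inr": inr.mean(),
                    "sd_inr": inr.std(ddof=1),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "n_outliers": int(((inr < lo) | (inr > hi)).sum()),
                }
            )
        return pd.DataFrame(rows)


def run_cohort(
    spec: PopulationSpec,
    intensities=(1.0, 0.8, 0.6, 0.4, 0.2),
    conditions: AssayConditions | None = None,
    network: ReactionNetwork | None = None,
) -> CohortResult:
    """Simulate the PT assay for a whole cohort across intensities.

    The intensity grid must include 1.0: the untreated arm defines the
    MNPT, which is then reused as a fixed scalar for every treated arm
    of the same cohort.  Individuals whose integration fails are dropped
    and counted in the diagnostics; individuals that do not clot within
    the horizon keep an infinite PT/INR and are excluded from summary
    statistics only.
    """
    network = network if network is not None else load_network()
    conditions = conditions or AssayConditions()
    grid = [
        i.fraction_remaining if isinstance(i, TreatmentIntensity) else float(i)
        for i in intensities
    ]
    if 1.0 not in grid:
        raise ValueError("the intensity grid must include 1.0 (MNPT reference)")
    grid = sorted(set(grid), reverse=True)

    profiles = sample_population(spec, network)
    levels = pd.DataFrame(
        [{"individual_id": p.individual_id, **p.levels_nM} for p in profiles]
    ).set_index("individual_id")

    pt = {}  # (intensity, individual_id) -> PT
    diagnostics: dict = {"n_failed": {}, "n_not_clotted": {}}
    for f in grid:
        intensity = TreatmentIntensity(f)
        n_failed = 0
        for p in profiles:
            treated = apply_treatment(p, intensity) if f != 1.0 else p
            try:
                res = simulate_clotting(network, treated, conditions)
                pt[(f, p.individual_id)] = res.prothrombin_time_s
            except IntegrationError as exc:
                n_failed += 1
                logger.warning(
                    "individual %d at intensity %g: %s", p.individual_id, f, exc
                )
        diagnostics["n_failed"][f] = n_failed
        diagnostics["n_not_clotted"][f] = sum(
            1
            for p in profiles
            if (f, p.individual_id) in pt and math.isinf(pt[(f, p.individual_id)])
        )

    mnpt = compute_mnpt(
        [pt[(1.0, p.individual_id)] for p in profiles if (1.0, p.individual_id) in pt]
    )
    rows = []
    for f in grid:
        for p in profiles:
            key = (f, p.individual_id)
            if key not in pt:
                continue
            rows.append(
                {
                    "individual_id": p.individual_id,
                    "intensity": f,
                    "pt_s": pt[key],
                    "inr": compute_inr(pt[key], mnpt),
                }
            )
    return CohortResult(
        records=pd.DataFrame(rows),
        mnpt=mnpt,
        baseline_levels=levels,
        profiles=tuple(profiles),
        diagnostics=diagnostics,
    )


def correlate_levels_vs_inr(result: CohortResult, intensity: float = 1.0) -> pd.DataFrame:
    """Pearson R between baseline protein levels and INR at one intensity.

    Levels are always the pretreatment (baseline) ones, so treated-arm
    correlations ask how the original interindividual variability shows
    through under treatment.  A protein with zero level variance gets an
    undefined (NaN) R.  Requires at least three finite INRs.
    """
    f = intensity.fraction_remaining if isinstance(intensity, TreatmentIntensity) else float(intensity)
    sub = result.records[result.records["intensity"] == f]
    if sub.empty:
        raise ValueError(f"no records at intensity {f}")
    sub = sub[np.isfinite(sub["inr"])]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 finite INRs at intensity {f}, have {len(sub)}")
    inr = sub.set_index("individual_id")["inr"]
    levels = result.baseline_levels.loc[inr.index]

    rows = []
    for protein in levels.columns:
        if protein == "VIIa":
            continue  # VIIa is tied to VII; one entry per gene product
        x = levels[protein].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            r = math.nan
        else:
            r = stats.pearsonr(x, inr.to_numpy())[0]
        rows.append({"intensity": f, "protein": protein, "pearson_r": r})
    return pd.DataFrame(rows)
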