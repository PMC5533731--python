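"""Synthetic MCI-like cohorts with planted decliner clusters.

Real late-MCI study records of the kind this pipeline analyses are
restricted-access, so this module generates cohorts that reproduce the
statistical structure the analysis assumes: two planted clusters of
"rapid" and "slow" decliners plus a diffuse unclustered remainder, a
baseline descriptor layer and a consistent longitudinal visit series
(so the slope layer is obtained by actually running the slope
estimator), block-structured missingness for CSF and PET descriptors,
and clinician-style diagnosis trajectories with MCI-to-dementia
conversion and MCI-to-normal reversion.

Default group means and SDs are the published per-cluster summary values
for the two decliner clusters; descriptors without a published
per-cluster summary fall back to whole-sample values or realistic
clinic-scale defaults (see the methods note).  The unclustered group is
drawn wide, centred between the two cluster means, so that it resists
confident assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CohortTable, DescriptorSchema, VisitRecord, default_schema
from .errors import ConfigurationError
from .rule_similarity import SimilarityTable

GROUPS = ("rapid", "slow", "unclustered")

#: Default visit grid: 6-month intervals over a 5-year follow-up.
DEFAULT_VISIT_MONTHS = tuple(float(m) for m in range(0, 61, 6))


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything :func:`generate` needs, including the seed.

    ``baseline_params`` and ``slope_params`` map group -> descriptor ->
    (mean, SD).  ``rho_within`` is the plain equicorrelation of the
    descriptors within a group, induced through one shared per-subject
    factor per layer.  ``layer_coupling`` is the correlation between the
    two layers' shared factors, coupling a subject's baseline state to
    their prognosis within a group.
    ``conversion_cumulative`` / ``reversion_cumulative`` are 5-year
    cumulative probabilities converted internally to per-visit hazards.
    ``missingness`` maps block name -> (descriptors, fraction of subjects
    missing the whole block).
    """

    n_rapid: int = 240
    n_slow: int = 184
    n_unclustered: int = 138
    baseline_params: dict = field(default_factory=dict)
    slope_params: dict = field(default_factory=dict)
    apoe4_prevalence: dict = field(default_factory=dict)
    female_fraction: dict = field(default_factory=dict)
    rho_within: dict = field(default_factory=dict)
    layer_coupling: float = 0.4
    visit_months: tuple = DEFAULT_VISIT_MONTHS
    conversion_cumulative: dict = field(default_factory=dict)
    reversion_cumulative: dict = field(default_factory=dict)
    measurement_noise_scale: float = 2.0
    missingness: dict = field(default_factory=dict)
    study1_fraction: float = 378 / 562
    seed: int = 0
    schema: DescriptorSchema = field(default_factory=default_schema)

    def counts(self) -> dict:
        return {"rapid": self.n_rapid, "slow": self.n_slow,
                "unclustered": self.n_unclustered}

    def validate(self) -> None:
        if min(self.counts().values()) < 0:
            raise ConfigurationError("group counts must be non-negative")
        for params in (self.baseline_params, self.slope_params):
            for group, table in params.items():
                for name, (_, sd) in table.items():
                    if sd <= 0:
                        raise ConfigurationError(
                            f"SD for {name!r} in group {group!r} must be positive")
        for group, rho in self.rho_within.items():
            if not 0.0 <= rho < 1.0:
                raise ConfigurationError(
                    f"rho_within for group {group!r} must be in [0, 1)")
        if not 0.0 <= self.layer_coupling <= 1.0:
            raise ConfigurationError("layer_coupling must be in [0, 1]")
        for table in (self.conversion_cumulative, self.reversion_cumulative):
            for group, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError("cumulative probabilities must be in [0, 1]")
        for group in GROUPS:
            total = (self.conversion_cumulative.get(group, 0.0)
                     + self.reversion_cumulative.get(group, 0.0))
            if total > 1.0:
                raise ConfigurationError(
                    f"conversion + reversion exceed 1 for group {group!r}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted group of every subject."""

    cohort: CohortTable
    truth: dict[str, str]


# Published per-cluster summaries (slow, rapid) as (mean, SD); whole-sample or
# clinic-scale defaults fill the descriptors without a per-cluster summary.
_SLOW_RAPID = {
    # descriptor: (slow mean, slow sd, rapid mean, rapid sd)
    "AGE": (73.6, 7.6, 74.9, 7.0),
    "EDUCATION": (16.6, 2.6, 15.4, 3.1),
    "MMSE": (28.1, 1.6, 26.4, 1.7),
    "ADAS11": (9.0, 2.6, 15.8, 3.5),
    "ADAS13": (11.7, 3.3, 24.5, 4.2),
    "MOCA": (24.7, 2.9, 20.6, 2.4),
    "RAVLT_immediate": (35.5, 9.0, 26.8, 7.5),
    "RAVLT_learning": (4.5, 2.5, 2.8, 2.2),
    "RAVLT_forgetting": (4.2, 2.4, 5.0, 2.2),
    "RAVLT_perc_forgetting": (45.8, 30.4, 83.7, 23.7),
    "LDELTOTAL": (5.0, 2.7, 2.5, 2.2),
    "FAQ": (2.2, 3.7, 5.3, 4.9),
    "CDRSB": (1.4, 0.8, 2.0, 1.0),
    "Ventricles": (38809, 21120, 46461, 24608),
    "Hippocampus": (6905, 1055, 6096, 964),
    "WholeBrain": (1018660, 100500, 1000120, 91500),
    "Entorhinal": (3681, 746, 3055, 656),
    "Fusiform": (17600, 1900, 16700, 2100),
    "MidTemp": (19716, 2670, 18348, 2970),
    "ICV": (1530000, 160000, 1530000, 160000),
    "FDG": (1.26, 0.13, 1.16, 0.11),
    "AV45": (1.18, 0.18, 1.38, 0.24),
    "ABETA": (177, 56, 148, 45),
    "TAU": (80, 41, 121, 67),
    "PTAU": (32, 18, 48, 24),
}

_SLOW_RAPID_SLOPES = {
    "SCDRSB": (0.1, 0.4, 0.7, 0.8),
    "SADAS11": (0.5, 1.5, 1.4, 2.0),
    "SADAS13": (0.7, 2.0, 1.9, 2.6),
    "SMMSE": (-0.1, 0.8, -1.0, 1.3),
    "SFAQ": (0.5, 1.3, 1.7, 2.4),
    "SMOCA": (-0.2, 0.9, -0.7, 0.9),
    "SRAVLT_immediate": (-0.7, 2.8, -1.5, 2.6),
    "SRAVLT_learning": (-0.05, 0.8, -0.3, 0.9),
    "SRAVLT_forgetting": (0.05, 0.9, 0.2, 1.0),
    "SRAVLT_perc_forgetting": (1.0, 8.0, 2.5, 9.0),
    "SVentricles": (1128, 1079, 2197, 1801),
    "SHippocampus": (-64, 75, -113, 110),
    "SWholeBrain": (-3600, 6000, -7600, 8100),
    "SEntorhinal": (-33, 176, -71, 187),
    "SFusiform": (-102, 308, -282, 391),
    "SMidTemp": (-138, 287, -344, 449),
    "SICV": (0.0, 3000, 0.0, 3000),
}

#: Width multiplier for the unclustered group's SDs relative to the wider
#: of the two cluster SDs; chosen so the remainder is diffuse enough to
#: resist confident assignment.
_UNCLUSTERED_SD_FACTOR = 1.5


def _three_group_params(table: dict) -> dict:
    slow = {k: (v[0], v[1]) for k, v in table.items()}
    rapid = {k: (v[2], v[3]) for k, v in table.items()}
    unclustered = {
        k: ((v[0] + v[2]) / 2.0, _UNCLUSTERED_SD_FACTOR * max(v[1], v[3]))
        for k, v in table.items()
    }
    return {"slow": slow, "rapid": rapid, "unclustered": unclustered}


def default_config(
    n_rapid: int = 240,
    n_slow: int = 184,
    n_unclustered: int = 138,
    seed: int = 0,
) -> GeneratorConfig:
    """The study-condition configuration: published per-cluster means/SDs,
    cluster sizes 240/184 plus a 138-strong unclustered remainder, 5-year
    cumulative conversion 64%/13% and reversion 0%/10%, and CSF/PET
    availability blocks matching the reported biomarker subsample sizes
    (CSF 302/562, amyloid PET 157/562, FDG-PET 362/562)."""
    schema = default_schema()
    return GeneratorConfig(
        n_rapid=n_rapid,
        n_slow=n_slow,
        n_unclustered=n_unclustered,
        baseline_params=_three_group_params(_SLOW_RAPID),
        slope_params=_three_group_params(_SLOW_RAPID_SLOPES),
        apoe4_prevalence={"slow": 0.49, "rapid": 0.77, "unclustered": 0.60},
        female_fraction={"slow": 77 / 184, "rapid": 90 / 240,
                         "unclustered": 51 / 138},
        rho_within={"slow": 0.2, "rapid": 0.2, "unclustered": 0.0},
        layer_coupling=0.4,
        conversion_cumulative={"rapid": 0.64, "slow": 0.13, "unclustered": 0.424},
        reversion_cumulative={"rapid": 0.0, "slow": 0.10, "unclustered": 0.03},
        missingness={
            "csf": (("ABETA", "TAU", "PTAU"), 1.0 - 302 / 562),
            "amyloid_pet": (("AV45",), 1.0 - 157 / 562),
            "fdg_pet": (("FDG",), 1.0 - 362 / 562),
        },
        seed=seed,
        schema=schema,
    )


def _per_visit_hazard(cumulative: float, n_post_visits: int) -> float:
    if cumulative <= 0.0:
        return 0.0
    if cumulative >= 1.0:
        return 1.0
    return 1.0 - (1.0 - cumulative) ** (1.0 / n_post_visits)


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a cohort from ``config``; fully reproducible under its seed.

    Baseline descriptors come from group-specific equicorrelated normals;
    longitudinal measures are synthesised as visit series around a drawn
    per-subject slope, so the slope layer downstream is produced by the
    real slope estimator.  The drawn slope SD is shrunk to compensate for
    the variance the visit-level measurement noise adds to the fitted
    slope, keeping the realized slope distribution close to the
    configured (mean, SD).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    months = np.asarray(config.visit_months, dtype=float)
    if months.size < 2 or months[0] != 0.0:
        raise ConfigurationError("visit grid must start at month 0 with >=2 visits")
    n_post = months.size - 1
    mc = months - months.mean()
    sxx = float(mc @ mc)

    longit = set(schema.longitudinal)
    subjects: list[str] = []
    truth: dict[str, str] = {}
    baseline: dict[str, dict[str, float]] = {}
    visits: dict[str, list[VisitRecord]] = {}
    cohort_label: dict[str, str] = {}
    sex: dict[str, str] = {}

    counter = 0
    for group in GROUPS:
        n_g = config.counts()[group]
        if n_g == 0:
            continue
        bparams = config.baseline_params.get(group, {})
        sparams = config.slope_params.get(group, {})
        rho = float(config.rho_within.get(group, 0.0))
        coupling = config.layer_coupling
        p_dem = _per_visit_hazard(config.conversion_cumulative.get(group, 0.0), n_post)
        p_cn = _per_visit_hazard(config.reversion_cumulative.get(group, 0.0), n_post)
        prev = config.apoe4_prevalence.get(group, 0.5)
        p_allele = 1.0 - math.sqrt(max(1.0 - prev, 0.0))
        f_frac = config.female_fraction.get(group, 0.4)

        # one shared factor per layer (plain equicorrelation rho within each
        # layer); the two factors are correlated by `layer_coupling`
        factor_base = rng.standard_normal(n_g)
        factor_slope = (coupling * factor_base
                        + math.sqrt(max(1.0 - coupling**2, 0.0))
                        * rng.standard_normal(n_g))

        base_values: dict[str, np.ndarray] = {}
        for name, (mean, sd) in bparams.items():
            if name == "APOE4":
                continue
            if rho > 0.0:
                z = (math.sqrt(rho) * factor_base
                     + math.sqrt(1.0 - rho) * rng.standard_normal(n_g))
            else:
                z = rng.standard_normal(n_g)
            base_values[name] = mean + sd * z
        if "APOE4" in bparams or prev is not None:
            base_values["APOE4"] = rng.binomial(2, p_allele, size=n_g).astype(float)

        slope_values: dict[str, np.ndarray] = {}
        noise_sd: dict[str, float] = {}
        for name, (mean, sd) in sparams.items():
            sigma = config.measurement_noise_scale * sd  # per-visit noise, measure units
            # realized OLS slope variance = drawn variance + 36*sigma^2/Sxx
            extra = 36.0 * sigma * sigma / sxx
            sd_draw = math.sqrt(max(sd * sd - extra, (0.35 * sd) ** 2))
            if rho > 0.0:
                z = (math.sqrt(rho) * factor_slope
                     + math.sqrt(1.0 - rho) * rng.standard_normal(n_g))
            else:
                z = rng.standard_normal(n_g)
            slope_values[name] = mean + sd_draw * z
            noise_sd[name] = sigma

        block_missing: dict[str, np.ndarray] = {}
        for block, (descs, frac) in config.missingness.items():
            block_missing[block] = rng.random(n_g) < frac

        female = rng.random(n_g) < f_frac
        study1 = rng.random(n_g) < config.study1_fraction

        for k in range(n_g):
            sid = f"S{counter:04d}"
            counter += 1
            subjects.append(sid)
            truth[sid] = group
            sex[sid] = "F" if female[k] else "M"
            cohort_label[sid] = "study-1" if study1[k] else "study-2"

            values = {name: float(col[k]) for name, col in base_values.items()}
            for block, (descs, _) in config.missingness.items():
                if block_missing[block][k]:
                    for d in descs:
                        values.pop(d, None)
            baseline[sid] = dict(values)

            series: dict[str, np.ndarray] = {}
            for name, col in slope_values.items():
                base = name[1:]
                b0 = values.get(base)
                if b0 is None:
                    b0 = float(bparams.get(base, (0.0, 1.0))[0])
                eps = rng.normal(0.0, noise_sd[name], size=months.size)
                eps[0] = 0.0  # entry measurement defines the baseline value
                series[base] = b0 + (col[k] / 6.0) * months + eps

            diagnosis = ["MCI"]
            state = "MCI"
            for _ in range(n_post):
                if state == "MCI":
                    u = rng.random()
                    if u < p_dem:
                        state = "Dementia"
                    elif u < p_dem + p_cn:
                        state = "CN"
                diagnosis.append(state)

            recs = []
            for t, m in enumerate(months):
                measures = {base: float(series[base][t]) for base in series
                            if base in longit}
                if t == 0:
                    for name, val in values.items():
                        measures.setdefault(name, val)
                recs.append(VisitRecord(sid, float(m), diagnosis[t], measures))
            visits[sid] = recs
            # baseline map reflects the month-0 record for longitudinal measures
            for base in series:
                baseline[sid][base] = float(series[base][0])

    order = rng.permutation(len(subjects))
    subjects = [subjects[i] for i in order]

    cohort = CohortTable(subjects=subjects, cohort_label=cohort_label, sex=sex,
                         baseline=baseline, visits=visits, schema=schema)
    return SyntheticCohort(cohort=cohort, truth=truth)


def write_truth(truth: dict[str, str], path) -> None:
    """Persist the planted-group assignment as a two-column CSV."""
    import pandas as pd

    pd.DataFrame(
        {"subject_id": list(truth), "group": [truth[s] for s in truth]}
    ).to_csv(path, index=False)


def generate_two_block_est(n1: int, n2: int, within: float,
                           between: float) -> SimilarityTable:
    """Block-structured similarity table used as a clustering fixture.

    Off-diagonal entries are ``within`` inside each block and ``between``
    across blocks; the diagonal is 1.  Requires
    ``0 <= between < within <= 1``.
    """
    if not (0.0 <= between < within <= 1.0):
        raise ConfigurationError("need 0 <= between < within <= 1")
    if n1 < 1 or n2 < 1:
        raise ConfigurationError("block sizes must be >= 1")
    n = n1 + n2
    x = np.full((n, n), between, dtype=float)
    x[:n1, :n1] = within
    x[n1:, n1:] = within
    np.fill_diagonal(x, 1.0)
    subjects = [f"S{i:04d}" for i in range(n)]
    return SimilarityTable(x=x, subjects=subjects, layer_id="two-block")
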