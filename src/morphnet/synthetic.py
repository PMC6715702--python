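"""Synthetic cohort generation with planted structure, plus recovery metrics.

Cohorts are drawn from a configurable generative model that mirrors the
statistical assumptions of the analysis pipeline:

* each breed carries a body-weight (lognormal) and craniofacial-ratio
  (normal) distribution plus a mixture over morphometric *archetypes*;
* an archetype is a mean profile in normalized-measurement space (base
  value x (1 + deviation)) with multiplicative Gaussian noise, including an
  "aged-brain" motif (small normalized brain width/volume, enlarged
  ventricles);
* total brain volume follows an allometric power law of body weight so the
  per-weight and per-brain-volume denominators are genuinely distinct;
* raw measurements are emitted by *inverting* the normalization rules
  (multiplying by the drawn denominators), so preprocessing is exercised
  end to end;
* the tumour outcome is drawn from a logistic model with configurable
  baseline, per-archetype and per-sex/neuter-status log-odds increments
  (a programmable neuter-status x tumour association).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb, log
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, ScanRecord
from .enrichment import ContingencyTable2x2
from .errors import ConfigError

__all__ = [
    "Archetype",
    "BreedSpec",
    "OutcomeModel",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_config",
    "null_config",
    "generate_cohort",
    "adjusted_rand_index",
    "exposure_outcome_table",
    "recovery_experiment",
]

#: Plausible base magnitudes of each networked parameter in normalized space
#: (value after division by its denominator). Arbitrary but fixed; the
#: pipeline median-centers them away.
BASE_PROFILE: dict[str, float] = {
    "brain_length": 8.0e-4,
    "brain_width": 2.75,
    "cerebellar_compression_index": 0.01,
    "cerebellar_compression_length": 0.3,
    "cerebellar_diameter": 4.0e-4,
    "cerebellar_volume": 0.10,
    "corpus_callosum_angle": 25.0,
    "corpus_callosum_thickness": 3.0e-5,
    "cranial_length": 5.0,
    "interthalamic_adhesion_height": 6.0e-5,
    "obex_position": 0.10,
    "sulcus_depth": 0.25,
    "total_brain_volume": 5000.0,
    "ventricular_volume": 0.05,
}

PARAMETERS: tuple[str, ...] = tuple(sorted(BASE_PROFILE))

_NON_TUMOUR_CLASSES: tuple[tuple[str, float], ...] = (
    ("idiopathic", 0.30),
    ("anomalous", 0.15),
    ("inflammatory", 0.15),
    ("normal", 0.15),
    ("vascular", 0.10),
    ("degenerative", 0.05),
    ("trauma", 0.05),
    ("metabolic", 0.05),
)


@dataclass(frozen=True)
class Archetype:
    """A morphometric mean profile with demographic and clinical hooks."""

    name: str
    deviations: Mapping[str, float]  # parameter -> relative mean shift
    age_log_mean: Optional[float] = None  # overrides the cohort age law
    age_log_sd: Optional[float] = None
    ventricle_zero_prob: float = 0.85
    ventricle_scale_mm: float = 2.0

    def mean_profile(self, parameters: Sequence[str]) -> np.ndarray:
        return np.array(
            [1.0 + float(self.deviations.get(p, 0.0)) for p in parameters]
        )


@dataclass(frozen=True)
class BreedSpec:
    name: str
    weight_median_kg: float
    weight_sdlog: float
    cfr_mean: float
    cfr_sd: float
    breed_group: str
    clade: Optional[str]
    archetype_weights: Mapping[str, float]
    sampling_weight: float = 1.0
    purebred: bool = True


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic tumour model: baseline + archetype + sex/neuter increments."""

    baseline_log_odds: float = -3.03  # ~4.6% baseline prevalence
    archetype_log_odds: Mapping[str, float] = field(default_factory=dict)
    sex_neuter_log_odds: Mapping[str, float] = field(default_factory=dict)

    def tumour_probability(self, archetype: str, sex_neuter: str) -> float:
        eta = (
            self.baseline_log_odds
            + float(self.archetype_log_odds.get(archetype, 0.0))
            + float(self.sex_neuter_log_odds.get(sex_neuter, 0.0))
        )
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class SyntheticConfig:
    n_scans: int
    archetypes: tuple[Archetype, ...]
    breeds: tuple[BreedSpec, ...]
    outcome_model: OutcomeModel
    noise_sd: float = 0.07
    female_prob: float = 0.47
    neutered_prob: float = 0.65
    allometric_exponent: float = 0.9
    allometric_sdlog: float = 0.03
    weight_ref_kg: float = 18.0
    cfr_missing_prob: float = 0.5
    head_angle_mean_deg: float = 35.0
    head_angle_sd_deg: float = 3.0
    age_log_mean: float = log(6.0)
    age_log_sd: float = 0.5
    planted_category: str = "breed"
    planted_descriptor: str = "Boxer"
    exposure_label: str = "FN"  # sex_neuter exposure for the risk contrast
    reference_label: str = "FE"
    parameters: tuple[str, ...] = PARAMETERS

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ConfigError("n_scans must be >= 1")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        if len(self.parameters) < 3:
            raise ConfigError("need at least 3 parameters")
        names = {a.name for a in self.archetypes}
        if len(names) != len(self.archetypes):
            raise ConfigError("duplicate archetype names")
        for breed in self.breeds:
            total = sum(breed.archetype_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"breed {breed.name!r}: archetype weights sum to {total}, not 1"
                )
            unknown = set(breed.archetype_weights) - names
            if unknown:
                raise ConfigError(f"breed {breed.name!r}: unknown archetypes {unknown}")

    @property
    def exposure_log_or(self) -> float:
        """Programmed log odds ratio of exposure vs reference label."""
        m = self.outcome_model.sex_neuter_log_odds
        return float(m.get(self.exposure_label, 0.0)) - float(
            m.get(self.reference_label, 0.0)
        )


@dataclass
class SyntheticTruth:
    """Row-for-row generating labels for an emitted cohort."""

    table: pd.DataFrame  # index scan_id: archetype, breed, sex_neuter, outcome...
    profiles: pd.DataFrame  # drawn normalized profiles (scans x parameters)
    config: SyntheticConfig

    def archetype_labels(self) -> dict[str, str]:
        return self.table["archetype"].to_dict()


def _default_archetypes() -> tuple[Archetype, ...]:
    # rms deviation ~0.3; motif directions chosen to be close to mutually
    # orthogonal so between-archetype profile correlations stay low
    s = 0.3
    return (
        Archetype(
            "aged_brain",
            {
                "brain_length": -0.5 * s,
                "brain_width": -1.0 * s,
                "ventricular_volume": +1.0 * s,
                "sulcus_depth": +0.7 * s,
                "total_brain_volume": -1.0 * s,
                "corpus_callosum_thickness": -0.5 * s,
                "interthalamic_adhesion_height": -0.3 * s,
            },
            age_log_mean=log(10.5),
            age_log_sd=0.25,
            ventricle_zero_prob=0.35,
            ventricle_scale_mm=4.0,
        ),
        Archetype(
            "brachy_ventriculomegaly",
            {
                "brain_width": +1.0 * s,
                "ventricular_volume": +0.8 * s,
                "brain_length": -0.8 * s,
                "cranial_length": -0.8 * s,
                "corpus_callosum_angle": +0.8 * s,
                "cerebellar_diameter": +0.3 * s,
            },
            ventricle_zero_prob=0.45,
            ventricle_scale_mm=3.5,
        ),
        Archetype(
            "cerebellar_compression",
            {
                "cerebellar_compression_index": +1.0 * s,
                "cerebellar_compression_length": +1.0 * s,
                "obex_position": +1.0 * s,
                "cerebellar_volume": -0.6 * s,
                "ventricular_volume": +0.6 * s,
                "interthalamic_adhesion_height": +0.3 * s,
            },
        ),
        Archetype(
            "dolicho_narrow",
            {
                "brain_width": -0.8 * s,
                "brain_length": +1.0 * s,
                "cranial_length": +1.0 * s,
                "ventricular_volume": -0.3 * s,
                "cerebellar_diameter": +0.3 * s,
            },
        ),
        Archetype(
            "immature",
            {
                "total_brain_volume": +1.0 * s,
                "brain_width": +0.5 * s,
                "ventricular_volume": -0.8 * s,
                "sulcus_depth": -0.8 * s,
                "corpus_callosum_thickness": +0.4 * s,
            },
            age_log_mean=log(1.2),
            age_log_sd=0.35,
        ),
        Archetype(
            "mesocephalic_baseline",
            {
                "cerebellar_volume": +0.6 * s,
                "obex_position": -0.5 * s,
                "corpus_callosum_angle": -0.7 * s,
                "interthalamic_adhesion_height": +0.6 * s,
                "cerebellar_compression_length": -0.4 * s,
            },
        ),
    )


def _default_breeds() -> tuple[BreedSpec, ...]:
    return (
        BreedSpec("Boxer", 30.0, 0.12, 0.45, 0.03, "Working", "European Mastiff",
                  {"aged_brain": 0.92, "brachy_ventriculomegaly": 0.08}, 0.10),
        BreedSpec("Labrador Retriever", 30.0, 0.15, 0.60, 0.04, "Gundog", "Retriever",
                  {"mesocephalic_baseline": 0.80, "immature": 0.20}, 0.15),
        BreedSpec("CKCS", 8.0, 0.12, 0.48, 0.04, "Toy", "Spaniel",
                  {"cerebellar_compression": 0.85, "brachy_ventriculomegaly": 0.15}, 0.10),
        BreedSpec("Chihuahua", 3.0, 0.20, 0.42, 0.05, "Toy", "New World",
                  {"brachy_ventriculomegaly": 0.70, "immature": 0.30}, 0.07),
        BreedSpec("French Bulldog", 12.0, 0.15, 0.40, 0.04, "Utility", "European Mastiff",
                  {"brachy_ventriculomegaly": 0.90, "aged_brain": 0.10}, 0.08),
        BreedSpec("Greyhound", 30.0, 0.10, 0.73, 0.03, "Hound", "UK Rural",
                  {"dolicho_narrow": 0.90, "mesocephalic_baseline": 0.10}, 0.08),
        BreedSpec("German Shepherd Dog", 35.0, 0.12, 0.66, 0.04, "Pastoral", "Continental Herder",
                  {"mesocephalic_baseline": 0.60, "dolicho_narrow": 0.40}, 0.10),
        BreedSpec("Whippet", 13.0, 0.12, 0.72, 0.03, "Hound", "UK Rural",
                  {"dolicho_narrow": 0.80, "immature": 0.20}, 0.07),
        BreedSpec("Crossbreed", 18.0, 0.30, 0.58, 0.06, "Crossbreed", None,
                  {"mesocephalic_baseline": 0.40, "immature": 0.20,
                   "dolicho_narrow": 0.20, "brachy_ventriculomegaly": 0.20},
                  0.15, purebred=False),
        BreedSpec("Weimaraner", 28.0, 0.10, 0.68, 0.03, "Gundog", "Pointer Setter",
                  {"mesocephalic_baseline": 0.50, "aged_brain": 0.50}, 0.10),
    )


def default_config(
    n_scans: int = 286,
    noise_sd: float = 0.07,
    exposure_or: float = 13.5,
    archetype_tumour_boost: float = 0.8,
) -> SyntheticConfig:
    """Cohort-scale default: 6 archetypes, 10 breeds, a planted Boxer ->
    aged-brain association and a programmed neutered-female tumour odds
    ratio (default 13.5). Simulation defaults, not claims about any real
    cohort."""
    outcome = OutcomeModel(
        baseline_log_odds=-3.03,
        archetype_log_odds={"aged_brain": archetype_tumour_boost},
        sex_neuter_log_odds={
            "FN": log(exposure_or) if exposure_or > 0 else 0.0,
            "ME": log(7.5),
            "MN": log(7.5),
        },
    )
    return SyntheticConfig(
        n_scans=n_scans,
        archetypes=_default_archetypes(),
        breeds=_default_breeds(),
        outcome_model=outcome,
        noise_sd=noise_sd,
    )


def null_config(n_scans: int = 250) -> SyntheticConfig:
    """No planted structure: one flat archetype, no outcome effects.

    Used for false-positive-rate calibration of the enrichment stage and
    for the programmed-OR=1 contrast. The allometric exponent is set to 1
    so body weight carries no morphometric signal either — any detected
    enrichment is a genuine false positive."""
    flat = Archetype("baseline", {}, ventricle_zero_prob=0.85)
    breeds = tuple(
        replace(b, archetype_weights={"baseline": 1.0}) for b in _default_breeds()
    )
    return SyntheticConfig(
        n_scans=n_scans,
        archetypes=(flat,),
        breeds=breeds,
        outcome_model=OutcomeModel(baseline_log_odds=-2.0),
        noise_sd=0.07,
        allometric_exponent=1.0,
        allometric_sdlog=1e-9,
    )


def generate_cohort(
    config: SyntheticConfig, seed: int
) -> tuple[CohortTable, SyntheticTruth]:
    """Draw a full raw cohort and its generating truth from a seed."""
    rng = np.random.default_rng(seed)
    arch_by_name = {a.name: a for a in config.archetypes}
    breed_probs = np.array([b.sampling_weight for b in config.breeds], dtype=float)
    breed_probs /= breed_probs.sum()
    params = list(config.parameters)
    base = np.array([BASE_PROFILE.get(p, 1.0) for p in params])
    p_index = {p: i for i, p in enumerate(params)}

    records: list[ScanRecord] = []
    truth_rows: dict[str, dict] = {}
    profile_rows: dict[str, np.ndarray] = {}
    width = len(str(config.n_scans))
    for i in range(config.n_scans):
        scan_id = f"scan_{i + 1:0{width}d}"
        breed = config.breeds[rng.choice(len(config.breeds), p=breed_probs)]
        weight = float(
            breed.weight_median_kg * np.exp(rng.normal(0.0, breed.weight_sdlog))
        )
        arch_names = sorted(breed.archetype_weights)
        arch_p = np.array([breed.archetype_weights[a] for a in arch_names])
        archetype = arch_by_name[arch_names[rng.choice(len(arch_names), p=arch_p)]]

        sex = "female" if rng.random() < config.female_prob else "male"
        neutered = bool(rng.random() < config.neutered_prob)
        sex_neuter = ("F" if sex == "female" else "M") + ("N" if neutered else "E")

        mu = archetype.age_log_mean if archetype.age_log_mean is not None else config.age_log_mean
        sdl = archetype.age_log_sd if archetype.age_log_sd is not None else config.age_log_sd
        age = float(np.exp(rng.normal(mu, sdl)))

        # normalized profile: archetype mean x multiplicative noise; total
        # brain volume additionally scales allometrically with body weight
        profile = (
            base
            * archetype.mean_profile(params)
            * (1.0 + rng.normal(0.0, config.noise_sd, size=len(params)))
        )
        tbv_i = p_index.get("total_brain_volume")
        if tbv_i is not None:
            allo = (weight / config.weight_ref_kg) ** (config.allometric_exponent - 1.0)
            profile[tbv_i] *= allo * float(np.exp(rng.normal(0.0, config.allometric_sdlog)))
        profile = np.abs(profile)  # physical measurements are non-negative

        head_angle = float(
            max(5.0, rng.normal(config.head_angle_mean_deg, config.head_angle_sd_deg))
        )
        tbv_raw = float(profile[tbv_i] * weight) if tbv_i is not None else 1.0

        from .preprocess import DEFAULT_REGISTRY, NormalizationClass

        measurements: dict[str, float] = {"head_angle": head_angle}
        for p, norm_value in zip(params, profile):
            cls = DEFAULT_REGISTRY.get(p, NormalizationClass.NONE)
            if cls is NormalizationClass.BRAIN_VOLUME_NORM:
                measurements[p] = float(norm_value * tbv_raw)
            elif cls is NormalizationClass.BODY_WEIGHT_NORM:
                measurements[p] = float(norm_value * weight)
            elif cls is NormalizationClass.HEAD_ANGLE_NORM:
                measurements[p] = float(norm_value * head_angle)
            else:
                measurements[p] = float(norm_value)

        if rng.random() < archetype.ventricle_zero_prob:
            measurements["ventricle_height"] = 0.0
        else:
            measurements["ventricle_height"] = float(
                rng.exponential(archetype.ventricle_scale_mm)
            )

        cfr = float(np.clip(rng.normal(breed.cfr_mean, breed.cfr_sd), 0.2, 1.2))
        if rng.random() >= config.cfr_missing_prob:
            measurements["muzzle_length"] = float(cfr * measurements["cranial_length"])

        p_tumour = config.outcome_model.tumour_probability(archetype.name, sex_neuter)
        if rng.random() < p_tumour:
            outcome = "tumour"
        else:
            labels, probs = zip(*_NON_TUMOUR_CLASSES)
            outcome = str(labels[rng.choice(len(labels), p=np.array(probs))])

        records.append(
            ScanRecord(
                scan_id=scan_id,
                patient_id=f"patient_{i + 1:0{width}d}",
                measurements=measurements,
                body_weight=weight,
                age=age,
                sex=sex,
                neutered=neutered,
                breed=breed.name,
                breed_group=breed.breed_group,
                diagnostic_class=outcome,
                purebred=breed.purebred,
                clade=breed.clade,
            )
        )
        truth_rows[scan_id] = {
            "archetype": archetype.name,
            "breed": breed.name,
            "breed_group": breed.breed_group,
            "sex_neuter": sex_neuter,
            "outcome": outcome,
            "body_weight": weight,
            "age": age,
            "cfr": cfr,
        }
        profile_rows[scan_id] = profile

    truth_table = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth_table.index.name = "scan_id"
    profiles = pd.DataFrame.from_dict(profile_rows, orient="index", columns=params)
    profiles.index.name = "scan_id"
    cohort = CohortTable(records=records)
    return cohort, SyntheticTruth(table=truth_table, profiles=profiles, config=config)


# --------------------------------------------------------------------------
# recovery metrics
# --------------------------------------------------------------------------

def _as_membership(partition) -> dict[str, int]:
    if hasattr(partition, "membership"):
        return partition.membership()
    labels = dict(partition)
    codes: dict[object, int] = {}
    return {k: codes.setdefault(v, len(codes)) for k, v in labels.items()}


def adjusted_rand_index(partition_a, partition_b) -> float:
    """Pair-counting adjusted Rand index between two partitions.

    Accepts ClusterPartition objects (unclustered nodes count as
    singletons) or plain id -> label mappings; both must cover the same
    IDs.
    """
    ma, mb = _as_membership(partition_a), _as_membership(partition_b)
    if set(ma) != set(mb):
        raise ConfigError("partitions cover different ID sets")
    ids = sorted(ma)
    n = len(ids)
    if n < 2:
        return 1.0
    contingency: dict[tuple[int, int], int] = {}
    row_totals: dict[int, int] = {}
    col_totals: dict[int, int] = {}
    for x in ids:
        key = (ma[x], mb[x])
        contingency[key] = contingency.get(key, 0) + 1
        row_totals[ma[x]] = row_totals.get(ma[x], 0) + 1
        col_totals[mb[x]] = col_totals.get(mb[x], 0) + 1
    index = sum(comb(v, 2) for v in contingency.values())
    sum_a = sum(comb(v, 2) for v in row_totals.values())
    sum_b = sum(comb(v, 2) for v in col_totals.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:  # both partitions trivial (all-singletons etc.)
        return 1.0 if index == expected else 0.0
    return float((index - expected) / (maximum - expected))


def exposure_outcome_table(
    truth: SyntheticTruth,
    exposure: Optional[str] = None,
    reference: Optional[str] = None,
    outcome: str = "tumour",
) -> ContingencyTable2x2:
    """2x2 exposure x outcome counts from a truth table (e.g. FN vs FE)."""
    cfg = truth.config
    exposure = exposure or cfg.exposure_label
    reference = reference or cfg.reference_label
    t = truth.table
    exposed = t[t["sex_neuter"] == exposure]
    unexposed = t[t["sex_neuter"] == reference]
    a = int((exposed["outcome"] == outcome).sum())
    b = int((exposed["outcome"] != outcome).sum())
    c = int((unexposed["outcome"] == outcome).sum())
    d = int((unexposed["outcome"] != outcome).sum())
    return ContingencyTable2x2(a, b, c, d)


def recovery_experiment(
    config: SyntheticConfig,
    n_seeds: int,
    base_seed: int = 0,
    pipeline_config=None,
    alpha: float = 0.05,
) -> dict:
    """Run the full pipeline over seeds and summarize recovery.

    Reports the ARI between the MCL partition and the archetype truth, the
    per-seed odds-ratio estimate for the programmed exposure contrast with
    CI coverage of the true OR, and the detection rate of the planted
    demographic enrichment at adjusted p < alpha.
    """
    from .enrichment import odds_ratio
    from .errors import StatsError
    from .pipeline import PipelineConfig, run_pipeline

    pconf = pipeline_config or PipelineConfig()
    true_or = float(np.exp(config.exposure_log_or))
    aris, ors, covered, detected = [], [], [], []
    or_p_values: list[float] = []
    false_positive = []
    for s in range(n_seeds):
        seed = base_seed + s
        cohort, truth = generate_cohort(config, seed)
        result = run_pipeline(cohort, pconf)
        part = result.partition
        truth_labels = {
            sid: truth.table.loc[sid, "archetype"]
            for sid in part.membership()
        }
        aris.append(adjusted_rand_index(part, truth_labels))
        enr = result.enrichment
        planted = enr[
            (enr["category"] == config.planted_category)
            & (enr["descriptor"] == config.planted_descriptor)
            & enr["reported"]
        ]
        detected.append(bool((planted["adjusted_p"] < alpha).any()))
        # per-seed rejection within the planted category's adjustment
        # family (the unit at which BH controls error under the null)
        family = enr[(enr["category"] == config.planted_category) & enr["reported"]]
        false_positive.append(bool((family["adjusted_p"] < alpha).any()))
        try:
            table = exposure_outcome_table(truth)
            res = odds_ratio(table, ci_method="woolf", alpha=alpha)
            ors.append(res.odds_ratio)
            or_p_values.append(res.p_value)
            covered.append(bool(res.ci_low <= true_or <= res.ci_high))
        except StatsError:
            pass  # degenerate margins at this seed; excluded from OR metrics
    aris_arr = np.array(aris)
    return {
        "n_seeds": n_seeds,
        "true_or": true_or,
        "ari": aris,
        "ari_mean": float(aris_arr.mean()) if len(aris_arr) else float("nan"),
        "ari_q10": float(np.quantile(aris_arr, 0.1)) if len(aris_arr) else float("nan"),
        "or_estimates": ors,
        "or_p_values": or_p_values,
        "or_detection_rate": (
            float(np.mean([p < alpha for p in or_p_values]))
            if or_p_values
            else float("nan")
        ),
        "or_ci_coverage": float(np.mean(covered)) if covered else float("nan"),
        "n_or_evaluable": len(ors),
        "enrichment_detection_rate": float(np.mean(detected)),
        "family_rejection_rate": float(np.mean(false_positive)),
    }
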