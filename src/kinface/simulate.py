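"""Synthetic colony and rater-response generator.

This module replaces the free-ranging study population and its human
raters with a generative stand-in that has the statistical structure the
downstream stages assume:

* a multi-generation pedigree with polygynous reproductive skew
  (gamma-distributed male "quality" weights, i.e. Dirichlet paternity
  shares), inbreeding avoidance by hard rejection of matings at or above
  a relatedness threshold, and census presence intervals;
* ~21 STR loci with ~7 alleles each, Mendelian transmission, a
  per-allele typing-error process and per-locus missingness averaging
  ~14.6 typed loci per individual;
* 8-point forced-choice similarity scores generated from fixed effects
  plus crossed random intercepts (participant, triad, target/left/right
  image) and Gaussian residual noise, discretized to the response grid.

Each generator consumes a single documented stream of randomness per
seed: identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinship import KinshipCalculator
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "ResponseSimConfig",
    "SimulationError",
    "SimulatedGenotypes",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_inventory",
    "simulate_responses",
    "discretize_score",
    "SCORE_GRID",
]

#: gestation-scale lead between conception and birth, in years.  Matches the
#: 200-day presence rule used in paternity screening so that every simulated
#: true sire is by construction a demographic candidate.
CONCEPTION_LEAD_YEARS = 200.0 / 365.25

#: the 8-point response grid
SCORE_GRID = np.arange(-3.5, 4.0, 1.0)


class SimulationError(RuntimeError):
    """Raised when a configuration is demographically infeasible."""


@dataclass
class SimConfig:
    """Colony-simulation settings.

    Defaults emulate the study colony: roughly 850 individuals, 21 STR
    loci with 7 alleles each, individuals typed at ~14.6 loci on
    average, and a 1% per-allele typing-error rate.
    """

    n_founders: int = 150
    n_years: int = 18
    births_per_year: int = 40
    male_skew: float = 0.5  # gamma shape of male quality; smaller = more skew
    reproductive_age_male: float = 5.0
    reproductive_age_female: float = 4.0
    inbreeding_avoidance_r: float = 0.25
    n_loci: int = 21
    alleles_per_locus: int = 7
    allele_freq_concentration: float = 1.0
    typing_error_rate: float = 0.01
    mean_typed_loci: float = 14.6
    seed: int = 0

    # founder demography (years relative to simulation start) and lifespan
    founder_birth_range: tuple[float, float] = (-12.0, -4.0)
    lifespan_range: tuple[float, float] = (18.0, 28.0)

    def validate(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_years": self.n_years + 1,  # n_years = 0 is legal (founders only)
            "births_per_year": self.births_per_year,
            "n_loci": self.n_loci,
            "alleles_per_locus": self.alleles_per_locus,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        for name, value in {
            "typing_error_rate": self.typing_error_rate,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.mean_typed_loci <= self.n_loci:
            raise ValueError("mean_typed_loci must be in (0, n_loci]")
        if self.male_skew <= 0:
            raise ValueError("male_skew must be positive")
        if self.allele_freq_concentration <= 0:
            raise ValueError("allele_freq_concentration must be positive")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        kwargs: dict[str, object] = {}
        defaults = cls()
        for key, value in raw.items():
            if not hasattr(defaults, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(defaults, key)
            if isinstance(default, tuple):
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif isinstance(default, bool):
                kwargs[key] = value.lower() in {"1", "true", "yes"}
            elif isinstance(default, int):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def simulate_pedigree(config: SimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Grow a pedigree year by year and return it with its census table.

    Every non-founder has a dam and sire that were alive and of
    reproductive age at conception (birth minus the 200-day lead); sires
    are drawn with gamma-skewed weights; proposed matings with pedigree
    relatedness >= ``inbreeding_avoidance_r`` are rejected and redrawn.
    Census rows give the presence interval (birth to death) of every
    individual.

    Raises
    ------
    SimulationError
        Naming the year in which no eligible dam or sire exists.
    """
    config.validate()
    rng = np.random.default_rng((int(config.seed), 0))

    ids: list[str] = []
    sex: dict[str, str] = {}
    birth: dict[str, float] = {}
    death: dict[str, float] = {}
    dam: dict[str, str | None] = {}
    sire: dict[str, str | None] = {}
    quality: dict[str, float] = {}

    lo, hi = config.founder_birth_range
    ls_lo, ls_hi = config.lifespan_range
    for i in range(config.n_founders):
        ind = f"F{i:04d}"
        ids.append(ind)
        sex[ind] = "F" if i < (config.n_founders + 1) // 2 else "M"
        birth[ind] = float(rng.uniform(lo, hi))
        death[ind] = birth[ind] + float(rng.uniform(ls_lo, ls_hi))
        dam[ind] = None
        sire[ind] = None
        if sex[ind] == "M":
            quality[ind] = float(rng.gamma(config.male_skew))

    kin = KinshipCalculator(dam, sire)
    serial = 0
    for year in range(1, config.n_years + 1):
        mothers_this_year: set[str] = set()
        for _ in range(config.births_per_year):
            t_birth = year + float(rng.uniform(0.0, 1.0))
            t_conc = t_birth - CONCEPTION_LEAD_YEARS
            eligible_dams = [
                i
                for i in ids
                if sex[i] == "F"
                and i not in mothers_this_year
                and t_conc - birth[i] >= config.reproductive_age_female
                and birth[i] <= t_conc
                and death[i] >= t_birth
            ]
            if not eligible_dams:
                raise SimulationError(
                    f"no eligible dam in year {year}; config infeasible"
                )
            mother = eligible_dams[int(rng.integers(len(eligible_dams)))]
            eligible_sires = [
                i
                for i in ids
                if sex[i] == "M"
                and t_conc - birth[i] >= config.reproductive_age_male
                and birth[i] <= t_conc
                and death[i] >= t_conc
            ]
            if not eligible_sires:
                raise SimulationError(
                    f"no eligible sire in year {year}; config infeasible"
                )
            pool = list(eligible_sires)
            father = None
            while pool:
                weights = np.array([quality[m] for m in pool])
                total = weights.sum()
                probs = weights / total if total > 0 else None
                pick = pool[int(rng.choice(len(pool), p=probs))]
                if kin.r(mother, pick) < config.inbreeding_avoidance_r:
                    father = pick
                    break
                pool.remove(pick)  # rejected mating: redraw from the rest
            if father is None:
                raise SimulationError(
                    f"all eligible sires related to dam above threshold "
                    f"in year {year}; config infeasible"
                )
            child = f"I{serial:05d}"
            serial += 1
            ids.append(child)
            sex[child] = "F" if rng.random() < 0.5 else "M"
            birth[child] = t_birth
            death[child] = t_birth + float(rng.uniform(ls_lo, ls_hi))
            dam[child] = mother
            sire[child] = father
            mothers_this_year.add(mother)
            if sex[child] == "M":
                quality[child] = float(rng.gamma(config.male_skew))

    table = pd.DataFrame(
        {
            "id": ids,
            "sex": [sex[i] for i in ids],
            "birth": [birth[i] for i in ids],
            "dam": [dam[i] for i in ids],
            "sire": [sire[i] for i in ids],
        }
    )
    census = pd.DataFrame(
        {
            "id": ids,
            "start": [birth[i] for i in ids],
            "end": [death[i] for i in ids],
        }
    )
    return Pedigree(table), census


@dataclass
class SimulatedGenotypes:
    true: "GenotypeTable"
    observed: "GenotypeTable"
    allele_freqs: list[np.ndarray]


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> SimulatedGenotypes:
    """Drop alleles down the pedigree and overlay typing error + missingness.

    Founder alleles are drawn from per-locus Dirichlet frequencies;
    every non-founder inherits one allele per parent uniformly.  Each
    recorded allele is independently replaced by a uniformly random
    *different* allele with probability ``typing_error_rate``, and each
    (individual, locus) is typed independently with probability
    ``mean_typed_loci / n_loci``.
    """
    from .genotypes import GenotypeTable, MISSING

    config.validate()
    rng = np.random.default_rng((int(config.seed), 1))
    L, k = config.n_loci, config.alleles_per_locus
    loci = [f"L{j + 1:02d}" for j in range(L)]
    freqs = [
        rng.dirichlet(np.full(k, config.allele_freq_concentration)) for _ in range(L)
    ]

    order = sorted(pedigree.ids, key=pedigree.depth)
    row = {ind: i for i, ind in enumerate(pedigree.ids)}
    true = np.empty((len(pedigree.ids), L, 2), dtype=np.int32)
    for ind in order:
        i = row[ind]
        dam_id, sire_id = pedigree.parents(ind)
        for j in range(L):
            if dam_id is None:
                a = int(rng.choice(k, p=freqs[j]))
            else:
                a = int(true[row[dam_id], j, int(rng.integers(2))])
            if sire_id is None:
                b = int(rng.choice(k, p=freqs[j]))
            else:
                b = int(true[row[sire_id], j, int(rng.integers(2))])
            true[i, j] = (a, b)

    observed = true.copy()
    if config.typing_error_rate > 0:
        err = rng.random(observed.shape) < config.typing_error_rate
        shift = rng.integers(1, k, size=observed.shape)
        observed = np.where(err, (observed + shift) % k, observed).astype(np.int32)
    typed = rng.random((len(pedigree.ids), L)) < (config.mean_typed_loci / L)
    observed[~typed] = MISSING

    return SimulatedGenotypes(
        true=GenotypeTable(pedigree.ids, loci, true),
        observed=GenotypeTable(pedigree.ids, loci, observed),
        allele_freqs=freqs,
    )


def simulate_inventory(
    pedigree: Pedigree,
    census: pd.DataFrame,
    photo_year: float,
    seed: int = 0,
    lighting_classes: Sequence[str] = ("A", "B"),
    min_age: float = 0.0,
) -> pd.DataFrame:
    """Photograph inventory for individuals alive at ``photo_year``.

    Each individual receives one frontal and two three-quarter images
    (facing left and right), all sharing one lighting class — the
    masking and standardization pipeline of the real study is out of
    scope, so images carry only the metadata the design constraints
    consume (individual, orientation, lighting class, photo date).
    """
    rng = np.random.default_rng((int(seed), 3))
    present = census[(census["start"] <= photo_year) & (census["end"] >= photo_year)]
    rows = []
    for ind in present["id"]:
        ind = str(ind)
        if photo_year - pedigree.birth(ind) < min_age:
            continue
        lighting = lighting_classes[int(rng.integers(len(lighting_classes)))]
        for suffix, orientation in (
            ("fr", "frontal"),
            ("tql", "three_quarter_left"),
            ("tqr", "three_quarter_right"),
        ):
            rows.append(
                {
                    "image_id": f"{ind}_{suffix}",
                    "individual_id": ind,
                    "orientation": orientation,
                    "lighting_class": lighting,
                    "photo_date": photo_year,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rater responses
# ---------------------------------------------------------------------------


def _default_betas() -> dict[str, float]:
    # Generative mirror of the kin-discrimination fixed-effect table:
    # treatment coding with maternal / mixed-sex / inexperienced / trial
    # midpoint as reference.
    return {
        "intercept": 0.169,
        "line": 0.471,
        "triad_type": 0.340,
        "experience": 0.334,
        "trial_position": 0.247,
        "line_x_experience": -0.304,
        "trial_position_x_experience": -0.192,
        "id_intercept": 2.141,
        "triad_sex": 0.0,
    }


@dataclass
class ResponseSimConfig:
    """Settings for the forced-choice score generator.

    ``beta`` entries are on the score scale; sigmas are the standard
    deviations of the crossed random intercepts and the residual.
    """

    n_participants: int = 59
    p_expert: float = 0.593
    beta: dict[str, float] = field(default_factory=_default_betas)
    sigma_participant: float = 0.30
    sigma_triad: float = 0.30
    sigma_target: float = 0.20
    sigma_left: float = 0.20
    sigma_right: float = 0.20
    sigma_resid: float = 1.50
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.p_expert <= 1.0:
            raise ValueError("p_expert must be in [0, 1]")
        for name in (
            "sigma_participant",
            "sigma_triad",
            "sigma_target",
            "sigma_left",
            "sigma_right",
            "sigma_resid",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def discretize_score(latent: np.ndarray) -> np.ndarray:
    """Snap latent values to the 8-point grid.

    Nearest grid point, clamped at +/-3.5; exact ties (including a
    latent value of 0, which is equidistant from -0.5 and +0.5) break
    upward, so 0 maps to +0.5.
    """
    latent = np.asarray(latent, dtype=float)
    snapped = np.floor(latent) + 0.5
    return np.clip(snapped, SCORE_GRID[0], SCORE_GRID[-1])


def _condition_codes(triad) -> tuple[float, float]:
    """(line, triad_type) treatment codes for a KD triad.

    line: maternal = 0, paternal = 1; triad type: mixed sex = 0, same
    sex = 1 (mother-daughter and father-son are same-sex triads).
    """
    condition = triad.condition
    line = 1.0 if condition.startswith("father") else 0.0
    same = 1.0 if condition in ("mother-daughter", "father-son") else 0.0
    return line, same


def simulate_responses(
    triads: Sequence,
    schedules: Mapping[str, "SessionSchedule"],
    config: ResponseSimConfig,
) -> pd.DataFrame:
    """Generate trial-level 8-point scores for every scheduled session.

    The latent score is the fixed-effect linear predictor (trial
    position entered z-transformed) plus the five crossed random
    intercepts and a Gaussian residual, then discretized to the grid.
    Random-effect values are drawn once per level and shared across all
    trials in which the level appears.  ID trials use the separate
    ``id_intercept`` and ``triad_sex`` coefficients and the same random
    structure.
    """
    config.validate()
    rng = np.random.default_rng((int(config.seed), 5))
    beta = dict(_default_betas(), **config.beta)

    by_id = {t.triad_id: t for t in triads}
    participants = sorted(schedules)
    expert = {p: bool(rng.random() < config.p_expert) for p in participants}
    gender = {p: ("F" if rng.random() < 0.5 else "M") for p in participants}

    u_participant = {p: float(rng.normal(0.0, config.sigma_participant)) for p in participants}
    u_triad: dict[str, float] = {}
    u_target: dict[str, float] = {}
    u_left: dict[str, float] = {}
    u_right: dict[str, float] = {}

    def effect(store: dict[str, float], key: str, sigma: float) -> float:
        if key not in store:
            store[key] = float(rng.normal(0.0, sigma))
        return store[key]

    rows = []
    for participant in participants:
        schedule = schedules[participant]
        trials = schedule.trials
        n_trials = len(trials)
        positions = np.arange(1, n_trials + 1, dtype=float)
        tz = (positions - positions.mean()) / positions.std(ddof=1)
        exp_code = 1.0 if expert[participant] else 0.0
        for k, trial in enumerate(trials.itertuples(index=False)):
            triad = by_id[trial.triad_id]
            side = trial.side_correct
            left_img = triad.match_image if side == "left" else triad.decoy_image
            right_img = triad.decoy_image if side == "left" else triad.match_image
            if triad.kind == "KD":
                line, same = _condition_codes(triad)
                fixed = (
                    beta["intercept"]
                    + beta["line"] * line
                    + beta["triad_type"] * same
                    + beta["experience"] * exp_code
                    + beta["trial_position"] * tz[k]
                    + beta["line_x_experience"] * line * exp_code
                    + beta["trial_position_x_experience"] * tz[k] * exp_code
                )
                triad_sex = None
            else:
                male = 1.0 if triad.condition.startswith("male") else 0.0
                fixed = beta["id_intercept"] + beta["triad_sex"] * male
                line = same = None
                triad_sex = "male" if male else "female"
            latent = (
                fixed
                + u_participant[participant]
                + effect(u_triad, triad.triad_id, config.sigma_triad)
                + effect(u_target, triad.target_image, config.sigma_target)
                + effect(u_left, left_img, config.sigma_left)
                + effect(u_right, right_img, config.sigma_right)
                + float(rng.normal(0.0, config.sigma_resid))
            )
            rows.append(
                {
                    "participant": participant,
                    "trial_position": k + 1,
                    "trial_position_z": tz[k],
                    "triad_id": triad.triad_id,
                    "kind": triad.kind,
                    "condition": triad.condition,
                    "line": (
                        None
                        if line is None
                        else ("paternal" if line else "maternal")
                    ),
                    "triad_type": (
                        None if same is None else ("same" if same else "mixed")
                    ),
                    "triad_sex": triad_sex,
                    "side_correct": side,
                    "experience": "expert" if expert[participant] else "inexperienced",
                    "participant_gender": gender[participant],
                    "target_image": triad.target_image,
                    "left_image": left_img,
                    "right_image": right_img,
                    "latent": latent,
                    "score": float(discretize_score(latent)),
                }
            )
    return pd.DataFrame(rows)
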