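"""Synthetic mouth-rinse metabolomics studies.

The generator emulates a two-group (control vs. high-stress), four-time-point
repeated-measures design with the statistical structure that motivates a
ratiometric biomarker search:

* log-normal concentrations with additive random effects on the log scale,
* a dominant participant-level random effect (individual metabolic
  signatures swamp group differences),
* a per-sample multiplicative dilution factor shared by every feature of a
  sample (rinse-volume variation) that two-feature ratios cancel exactly,
* planted group effects (by default an opposed pair whose ratio is a strong
  chronic-stress marker), planted acute time-course effects, and
* below-LOD censoring plus optional decoy features that violate the QC
  inclusion criteria.

The log-concentration model for sample s (participant p) and feature f is::

    log value[s, f] = mu_f + b[p, f] + d_s + group + time + sex + age + eps

with ``b[p, f] = sigma_participant * (sqrt(w) * g_p + sqrt(1 - w) * e_pf)``
so each participant has both a global intensity signature (``g_p``, weight
``w = participant_shared_frac``) and feature-specific individuality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .tables import (
    CLASS_METABOLITE,
    CLASS_PROTEIN,
    CLASS_STEROID,
    GROUP_CONTROL,
    GROUP_STRESS,
    TIME_POINTS,
    FeatureTable,
    ValidationError,
)

__all__ = [
    "PlantedEffect",
    "GeneratorConfig",
    "generate_study",
    "attach_qc_metadata",
    "simulate_study",
]

#: default planted marker pair: opposed group effects so the met001/met002
#: ratio separates groups with a log-fold difference of 2 * delta
DEFAULT_GROUP_DELTA = 1.2

#: default SD of the participant-level latent shared by the marker pair
#: (same-pathway covariation): the pair's ratio cancels it, a ratio of one
#: pair member against any other feature keeps its variance
DEFAULT_PAIR_LATENT_SD = 1.2


@dataclass(frozen=True)
class PlantedEffect:
    """A deliberate signal planted into one feature.

    ``group_log_fc`` shifts the high-stress group's log concentration;
    ``time_offsets`` adds per-time-point log offsets (both groups).
    """

    feature: str
    group_log_fc: float = 0.0
    time_offsets: dict = field(default_factory=dict)
    #: restrict the group effect to these time points (None = chronic,
    #: present at every collection point)
    group_time_points: tuple | None = None


def default_planted_effects() -> list[PlantedEffect]:
    return [
        # chronic marker pair with opposed shifts: the ratio doubles the
        # effect while participant/dilution common factors cancel
        PlantedEffect("met001", group_log_fc=+DEFAULT_GROUP_DELTA),
        PlantedEffect("met002", group_log_fc=-DEFAULT_GROUP_DELTA),
        # acute task responses (both groups)
        PlantedEffect("met003", time_offsets={"Post-UK": 0.4, "Post-WM": 0.4}),
        PlantedEffect("prot_sIgA", time_offsets={"Post-UK": 0.3}),
    ]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    Variance components are log-scale SDs. ``qc_violation_fractions`` maps
    criterion name (``recovery``, ``rsd``, ``detection``) to the fraction of
    ``n_metabolites`` added as decoy features violating exactly that
    criterion. ``seed`` fixes the whole output bit-for-bit; sub-streams are
    split per stage so adding decoys never perturbs the core draws.
    """

    n_per_group: int = 16
    time_points: tuple = TIME_POINTS
    n_metabolites: int = 100
    n_steroids: int = 25
    n_proteins: int = 2
    mu: np.ndarray | None = None  # baseline log concentration per core feature
    mu_loc: float = 2.0
    mu_scale: float = 1.0
    sigma_participant: float = 0.8
    participant_shared_frac: float = 0.6
    sigma_dilution: float = 0.5
    sigma_noise: float = 0.3
    planted_effects: list = field(default_factory=default_planted_effects)
    #: (feature_a, feature_b, sd): per-participant latent added to both
    #: features' log concentrations, modelling same-pathway covariation
    latent_pairs: list = field(
        default_factory=lambda: [("met001", "met002", DEFAULT_PAIR_LATENT_SD)]
    )
    sex_effects: dict | None = None  # feature -> log offset added for males
    age_effects: dict | None = None  # feature -> per-decade log slope
    covariate_effect_frac: float = 0.1
    covariate_effect_size: float = 0.2
    lod_quantile: float = 0.02
    qc_violation_fractions: dict = field(
        default_factory=lambda: {"recovery": 0.10, "rsd": 0.05, "detection": 0.05}
    )
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if len(self.time_points) == 0:
            raise ValidationError("time_points must be non-empty")
        if len(set(self.time_points)) != len(self.time_points):
            raise ValidationError("time_points must be unique")
        for name in ("sigma_participant", "sigma_dilution", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.participant_shared_frac <= 1:
            raise ValidationError("participant_shared_frac must be in [0, 1]")
        if not 0 < self.lod_quantile < 1:
            raise ValidationError("lod_quantile must be in (0, 1)")
        for a, b, sd in self.latent_pairs:
            if a == b:
                raise ValidationError("latent_pairs entries must name two distinct features")
            if sd < 0:
                raise ValidationError("latent_pairs sd must be >= 0")
        for k in self.qc_violation_fractions:
            if k not in ("recovery", "rsd", "detection"):
                raise ValidationError(f"unknown qc_violation_fractions key: {k!r}")
            if self.qc_violation_fractions[k] < 0:
                raise ValidationError(f"qc_violation_fractions[{k!r}] must be >= 0")
        n_core = self.n_metabolites + self.n_steroids + self.n_proteins
        if self.mu is not None and len(np.atleast_1d(self.mu)) != n_core:
            raise ValidationError("mu must have one entry per core feature")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    @property
    def n_core_features(self) -> int:
        return self.n_metabolites + self.n_steroids + self.n_proteins

    def feature_ids(self) -> list[str]:
        mets = [f"met{i + 1:03d}" for i in range(self.n_metabolites)]
        sters = [f"ster{i + 1:02d}" for i in range(self.n_steroids)]
        prots = ["prot_sIgA", "prot_CgA"][: self.n_proteins]
        prots += [f"prot{i + 1:02d}" for i in range(len(prots), self.n_proteins)]
        return mets + sters + prots

    def decoy_ids(self) -> dict:
        out = {}
        for crit in ("recovery", "rsd", "detection"):
            n = int(round(self.qc_violation_fractions.get(crit, 0.0) * self.n_metabolites))
            out[crit] = [f"decoy_{crit[:3]}{i + 1:02d}" for i in range(n)]
        return out


def _streams(seed: int) -> dict:
    """Named per-stage RNGs split from one seed (stable spawn order)."""
    children = np.random.SeedSequence(seed).spawn(8)
    names = ("mu", "participant", "dilution", "noise", "covariates", "decoys", "qc", "latent")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _design(config: GeneratorConfig) -> pd.DataFrame:
    """Sample metadata: participants x time points, long format."""
    n = config.n_per_group
    n_male = int(round(n * 7 / 16))  # cohort sex split: 7 male / 9 female per 16
    rows = []
    pid = 0
    for group in (GROUP_CONTROL, GROUP_STRESS):
        for i in range(n):
            pid += 1
            participant = f"P{pid:02d}"
            sex = "M" if i < n_male else "F"
            age_group = ("20s", "30s", "40s")[i % 3]
            for t in config.time_points:
                rows.append(
                    {
                        "sample": f"{participant}_{t}",
                        "participant": participant,
                        "group": group,
                        "time_point": t,
                        "sex": sex,
                        "age_group": age_group,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def generate_study(config: GeneratorConfig) -> FeatureTable:
    """Draw one synthetic study from the generative model.

    Returns a :class:`FeatureTable` with ``2 * n_per_group * len(time_points)``
    samples and all core features plus any configured decoys (flagged in
    ``features['is_decoy']``). Identical config + seed gives identical output.
    """
    config.validate()
    rng = _streams(config.seed)
    samples = _design(config)
    n_samples = len(samples)
    tps = list(config.time_points)

    core_ids = config.feature_ids()
    decoy_map = config.decoy_ids()
    decoy_ids = [d for ids in decoy_map.values() for d in ids]
    n_core, n_decoy = len(core_ids), len(decoy_ids)

    if config.mu is None:
        mu_core = rng["mu"].normal(config.mu_loc, config.mu_scale, n_core)
    else:
        mu_core = np.asarray(config.mu, dtype=float)
    mu_decoy = rng["decoys"].normal(config.mu_loc, config.mu_scale, n_decoy)

    participants = samples["participant"].unique()
    n_part = len(participants)
    w = config.participant_shared_frac
    g = rng["participant"].normal(size=n_part)  # shared intensity signature
    e_core = rng["participant"].normal(size=(n_part, n_core))
    e_decoy = rng["decoys"].normal(size=(n_part, n_decoy))
    b_core = config.sigma_participant * (np.sqrt(w) * g[:, None] + np.sqrt(1 - w) * e_core)
    b_decoy = config.sigma_participant * (np.sqrt(w) * g[:, None] + np.sqrt(1 - w) * e_decoy)

    d = rng["dilution"].normal(0.0, config.sigma_dilution, n_samples)
    eps_core = rng["noise"].normal(0.0, config.sigma_noise, (n_samples, n_core))
    eps_decoy = rng["decoys"].normal(0.0, config.sigma_noise, (n_samples, n_decoy))

    # covariate offsets on a random core-feature subset unless given
    sex_effects = config.sex_effects
    age_effects = config.age_effects
    if sex_effects is None:
        k = int(round(config.covariate_effect_frac * n_core))
        idx = rng["covariates"].choice(n_core, size=k, replace=False)
        signs = rng["covariates"].choice([-1.0, 1.0], size=k)
        sex_effects = {core_ids[i]: s * config.covariate_effect_size for i, s in zip(idx, signs)}
    if age_effects is None:
        k = int(round(config.covariate_effect_frac * n_core))
        idx = rng["covariates"].choice(n_core, size=k, replace=False)
        signs = rng["covariates"].choice([-1.0, 1.0], size=k)
        age_effects = {core_ids[i]: s * config.covariate_effect_size / 2 for i, s in zip(idx, signs)}

    all_ids = core_ids + decoy_ids
    col = {f: j for j, f in enumerate(all_ids)}
    mu = np.concatenate([mu_core, mu_decoy])
    b = np.hstack([b_core, b_decoy])
    eps = np.hstack([eps_core, eps_decoy])

    part_idx = pd.Categorical(samples["participant"], categories=participants).codes
    log_v = mu[None, :] + b[part_idx, :] + d[:, None] + eps

    is_stress = (samples["group"] == GROUP_STRESS).to_numpy()
    tp_idx = {t: (samples["time_point"] == t).to_numpy() for t in tps}
    for eff in config.planted_effects:
        if eff.feature not in col:
            raise ValidationError(f"planted effect names unknown feature {eff.feature!r}")
        j = col[eff.feature]
        if eff.group_log_fc:
            if eff.group_time_points is None:
                log_v[is_stress, j] += eff.group_log_fc
            else:
                for t in eff.group_time_points:
                    if t not in tp_idx:
                        raise ValidationError(f"planted effect names unknown time point {t!r}")
                    log_v[is_stress & tp_idx[t], j] += eff.group_log_fc
        for t, off in eff.time_offsets.items():
            if t not in tp_idx:
                raise ValidationError(f"planted effect names unknown time point {t!r}")
            log_v[tp_idx[t], j] += off

    for a, bfeat, sd in config.latent_pairs:
        for f in (a, bfeat):
            if f not in col:
                raise ValidationError(f"latent_pairs names unknown feature {f!r}")
        u = rng["latent"].normal(0.0, sd, n_part)
        log_v[:, col[a]] += u[part_idx]
        log_v[:, col[bfeat]] += u[part_idx]

    is_male = (samples["sex"] == "M").to_numpy()
    age_idx = samples["age_group"].map({"20s": 0, "30s": 1, "40s": 2}).to_numpy(float)
    for f, off in sex_effects.items():
        log_v[is_male, col[f]] += off
    for f, slope in age_effects.items():
        log_v[:, col[f]] += slope * (age_idx - 1.0)

    values = np.exp(log_v)

    # censoring: per-feature LOD at the lod_quantile of the marginal
    # log-concentration distribution; detection decoys are censored at a
    # high quantile so they fail the >=50 % detection criterion everywhere
    s_marg = np.sqrt(
        config.sigma_participant**2 + config.sigma_dilution**2 + config.sigma_noise**2
    )
    lod = np.exp(mu + norm.ppf(config.lod_quantile) * s_marg)
    for f in decoy_map["detection"]:
        lod[col[f]] = np.exp(mu[col[f]] + norm.ppf(0.75) * s_marg)
    below = values < lod[None, :]

    classes = (
        [CLASS_METABOLITE] * config.n_metabolites
        + [CLASS_STEROID] * config.n_steroids
        + [CLASS_PROTEIN] * config.n_proteins
        + [CLASS_METABOLITE] * n_decoy
    )
    violation = [""] * n_core + [
        crit for crit in ("recovery", "rsd", "detection") for _ in decoy_map[crit]
    ]
    features = pd.DataFrame(
        {
            "feature_class": classes,
            "is_decoy": [False] * n_core + [True] * n_decoy,
            "decoy_violation": violation,
            "min_quantifiable": lod,
            "recovery": np.nan,
            "rsd": np.nan,
        },
        index=pd.Index(all_ids, name="feature"),
    )

    return FeatureTable(
        values=pd.DataFrame(values, index=samples.index, columns=all_ids),
        below_lod=pd.DataFrame(below, index=samples.index, columns=all_ids),
        samples=samples,
        features=features,
    )


def attach_qc_metadata(table: FeatureTable, config: GeneratorConfig) -> FeatureTable:
    """Fill per-feature QC fields (recovery %, RSD %, minimum quantifiable).

    Non-decoy features receive QC values inside the inclusion window
    (recovery in [70, 130], RSD <= 20); each decoy violates exactly the
    criterion it was configured for. Draws come from the dedicated ``qc``
    sub-stream, so the concentration matrix is untouched.
    """
    rng = _streams(config.seed)["qc"]
    out = table.copy()
    rec = np.empty(out.n_features)
    rsd = np.empty(out.n_features)
    for j, f in enumerate(out.features.index):
        violation = out.features.at[f, "decoy_violation"]
        if violation == "recovery":
            # alternate high/low violations around the [70, 130] window
            rec[j] = rng.uniform(131.0, 160.0) if j % 2 == 0 else rng.uniform(40.0, 69.0)
            rsd[j] = rng.uniform(2.0, 15.0)
        elif violation == "rsd":
            rec[j] = rng.uniform(85.0, 115.0)
            rsd[j] = rng.uniform(20.5, 40.0)
        else:
            rec[j] = rng.uniform(85.0, 115.0)
            rsd[j] = rng.uniform(2.0, 15.0)
    out.features["recovery"] = rec
    out.features["rsd"] = rsd
    return out


def simulate_study(config: GeneratorConfig | None = None) -> FeatureTable:
    """Generate a study and attach its QC metadata (the common entry point)."""
    config = config or GeneratorConfig()
    return attach_qc_metadata(generate_study(config), config)
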