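"""Synthetic expression and survival generator with planted lncRNA modules.

The generator plants co-regulated modules with a single-latent-factor model:
each module m draws one Gaussian factor per tumour sample; member lncRNAs
and the module's positive mRNA block load on it with ``+latent_loading``,
the negative mRNA block with ``-latent_loading``, plus iid Gaussian noise.
Background genes are pure noise around the same baseline.  Adjacent-normal
samples carry no module factors, and planted lncRNAs are shifted down by
``tumour_shift`` relative to tumour tissue.  Survival times follow an
exponential proportional-hazards model whose log-hazard is a linear
function of standardized module scores, age and stage, with independent
exponential censoring calibrated to a target censoring fraction.

Every quantity is reproducible from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .io import ClinicalTable, ExpressionMatrix, write_clinical, write_expression

BASELINE_EXPRESSION = 5.0  # log2-scale mean for every gene
AGE_RANGE = (45.0, 85.0)
# roughly the stage mix seen in resected lung adenocarcinoma cohorts
STAGE_PROBS = (0.55, 0.25, 0.14, 0.06)


@dataclass
class PlantedModule:
    """One planted co-regulated module.

    latent_loading is the standard-deviation scale of the shared factor in
    every member gene; survival_beta the log-hazard per unit (standardized)
    module score; tumour_shift the log2 mean drop of member lncRNAs in
    normal relative to tumour tissue.
    """

    n_lnc_members: int
    n_mrna_pos: int
    n_mrna_neg: int
    latent_loading: float = 0.9
    survival_beta: float = 0.0
    tumour_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lnc_members < 2:
            raise ConfigurationError("planted module needs >= 2 lncRNA members")
        if not 0.0 < self.latent_loading <= 1.0:
            raise ConfigurationError("latent_loading must lie in (0, 1]")
        if min(self.n_mrna_pos, self.n_mrna_neg) < 0:
            raise ConfigurationError("mRNA block sizes must be non-negative")


@dataclass
class SyntheticConfig:
    """Full description of one synthetic dataset."""

    n_tumour_samples: int = 400
    n_normal_samples: int = 100
    n_lnc: int = 200
    n_mrna: int = 800
    modules: list[PlantedModule] = field(default_factory=list)
    noise_sd: float = 0.3
    baseline_hazard_scale: float = 1500.0  # days
    censoring_rate: float = 0.3
    age_beta: float = 0.02
    stage_beta: float = 0.4
    stage_coupling: float = 0.0  # pulls stage towards high module score
    pfs_factor: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.baseline_hazard_scale <= 0:
            raise ConfigurationError("baseline_hazard_scale must be positive")
        if sum(m.n_lnc_members for m in self.modules) > self.n_lnc:
            raise ConfigurationError("planted lncRNAs exceed n_lnc")
        if sum(m.n_mrna_pos + m.n_mrna_neg for m in self.modules) > self.n_mrna:
            raise ConfigurationError("planted mRNA blocks exceed n_mrna")


@dataclass
class GroundTruth:
    """Planted structure: who belongs where, and with what hazard effect."""

    module_membership: dict[str, str]
    correlated_mrna_sets: dict[str, tuple[list[str], list[str]]]
    survival_betas: dict[str, float]

    def module_members(self, module_id: str) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == module_id]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_membership": self.module_membership,
            "correlated_mrna_sets": {
                k: {"positive": v[0], "negative": v[1]}
                for k, v in self.correlated_mrna_sets.items()
            },
            "survival_betas": self.survival_betas,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["module_membership"],
            {
                k: (v["positive"], v["negative"])
                for k, v in payload["correlated_mrna_sets"].items()
            },
            payload["survival_betas"],
        )


def suggested_mr_fraction(config: SyntheticConfig, margin: float = 1.07) -> float:
    """MR selection fraction that lets the cutoff span the planted blocks.

    A planted block of B mRNAs shared by M member lncRNAs occupies mutual
    ranks up to sqrt(B * M), so the cutoff sqrt(n_lnc * n_mrna) * fraction
    must reach that far (with a small margin) for the correlated sets to
    capture whole blocks.  At the published data scale the analogous choice
    is the conventional 0.001.
    """
    if not config.modules:
        return 0.001
    need = max(
        np.sqrt(max(m.n_mrna_pos, m.n_mrna_neg) * m.n_lnc_members)
        for m in config.modules
    )
    frac = margin * need / np.sqrt(config.n_lnc * config.n_mrna)
    return float(min(frac, 0.5))


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Three planted prognostic modules at the scale used throughout the docs."""
    modules = [
        PlantedModule(15, 60, 60, latent_loading=0.9, survival_beta=-0.8, tumour_shift=1.5),
        PlantedModule(15, 60, 60, latent_loading=0.9, survival_beta=-0.6, tumour_shift=1.5),
        PlantedModule(15, 60, 60, latent_loading=0.9, survival_beta=0.7, tumour_shift=1.5),
    ]
    return SyntheticConfig(modules=modules, stage_coupling=0.8, seed=seed, **overrides)


def _gene_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:04d}" for i in range(config.n_lnc)]
    mrna = [f"MRNA{i:04d}" for i in range(config.n_mrna)]
    return lnc, mrna


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate tumour and normal expression plus the planted ground truth.

    Tumour values for a member gene g of module m with factor f_m are
    ``baseline + s * loading * f_m + N(0, noise_sd)`` (s = +1 for lncRNAs and
    the positive mRNA block, -1 for the negative block), floored at 0 on the
    log2-like scale.  Background genes are baseline plus noise only.
    """
    rng = np.random.default_rng(config.seed)
    lnc_ids, mrna_ids = _gene_ids(config)
    tumour_samples = [f"T{i:04d}" for i in range(config.n_tumour_samples)]
    normal_samples = [f"N{i:04d}" for i in range(config.n_normal_samples)]

    n_t, n_n = config.n_tumour_samples, config.n_normal_samples
    tum = np.full((config.n_lnc + config.n_mrna, n_t), BASELINE_EXPRESSION)
    nor = np.full((config.n_lnc + config.n_mrna, n_n), BASELINE_EXPRESSION)

    membership: dict[str, str] = {}
    mrna_sets: dict[str, tuple[list[str], list[str]]] = {}
    betas: dict[str, float] = {}

    lnc_cursor, mrna_cursor = 0, 0
    for idx, mod in enumerate(config.modules, start=1):
        mod_id = f"m{idx}"
        factor = rng.standard_normal(n_t)
        members = lnc_ids[lnc_cursor : lnc_cursor + mod.n_lnc_members]
        lnc_rows = slice(lnc_cursor, lnc_cursor + mod.n_lnc_members)
        lnc_cursor += mod.n_lnc_members
        pos = mrna_ids[mrna_cursor : mrna_cursor + mod.n_mrna_pos]
        pos_rows = slice(
            config.n_lnc + mrna_cursor, config.n_lnc + mrna_cursor + mod.n_mrna_pos
        )
        mrna_cursor += mod.n_mrna_pos
        neg = mrna_ids[mrna_cursor : mrna_cursor + mod.n_mrna_neg]
        neg_rows = slice(
            config.n_lnc + mrna_cursor, config.n_lnc + mrna_cursor + mod.n_mrna_neg
        )
        mrna_cursor += mod.n_mrna_neg

        tum[lnc_rows] += mod.latent_loading * factor
        tum[pos_rows] += mod.latent_loading * factor
        tum[neg_rows] -= mod.latent_loading * factor
        nor[lnc_rows] -= mod.tumour_shift

        membership.update({g: mod_id for g in members})
        mrna_sets[mod_id] = (list(pos), list(neg))
        betas[mod_id] = mod.survival_beta

    tum += rng.normal(0.0, config.noise_sd, tum.shape)
    nor += rng.normal(0.0, config.noise_sd, nor.shape)
    np.clip(tum, 0.0, None, out=tum)
    np.clip(nor, 0.0, None, out=nor)

    index = pd.Index(lnc_ids + mrna_ids, name="gene_id")
    types = pd.Series(
        ["lncRNA"] * config.n_lnc + ["mRNA"] * config.n_mrna, index=index
    )
    tumour = ExpressionMatrix(pd.DataFrame(tum, index=index, columns=tumour_samples), types)
    normal = ExpressionMatrix(
        pd.DataFrame(nor, index=index, columns=normal_samples), types.copy()
    )
    return tumour, normal, GroundTruth(membership, mrna_sets, betas)


def module_scores(tumour: ExpressionMatrix, truth: GroundTruth) -> pd.DataFrame:
    """Standardized mean member-lncRNA expression per planted module (samples x modules)."""
    scores = {}
    for mod_id in sorted(truth.survival_betas):
        members = truth.module_members(mod_id)
        mean = tumour.values.loc[members].mean(axis=0)
        sd = mean.std(ddof=0)
        scores[mod_id] = (mean - mean.mean()) / sd if sd > 0 else mean * 0.0
    return pd.DataFrame(scores)


def _censoring_rate_for(lam: float, hazards: np.ndarray) -> float:
    # P(C < T) for independent exponentials with rates lam and h_i
    return float(np.mean(lam / (lam + hazards)))


def _solve_censoring_rate(target: float, hazards: np.ndarray) -> float:
    lo, hi = 1e-12, float(hazards.max()) * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _censoring_rate_for(mid, hazards) < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def generate_clinical(
    config: SyntheticConfig, tumour: ExpressionMatrix, truth: GroundTruth
) -> ClinicalTable:
    """Draw ages, stages and censored survival for the tumour samples.

    The hazard is ``exp(sum_m beta_m * score_m + age_beta*(age-65) +
    stage_beta*(stage-1)) / baseline_hazard_scale`` with standardized module
    scores.  Stage is cut from a latent Gaussian at the quantiles of the
    target stage mix; ``stage_coupling`` tilts that latent towards the total
    hazard-weighted module score (0 = stage independent of expression).
    Censoring is an independent exponential whose rate is solved so the
    expected censored fraction matches ``censoring_rate``.
    """
    if set(tumour.sample_ids) != set(tumour.values.columns):  # defensive
        raise InputError("tumour sample ids inconsistent")
    rng = np.random.default_rng(config.seed + 1)
    samples = tumour.sample_ids
    n = len(samples)

    scores = module_scores(tumour, truth)
    betas = pd.Series(truth.survival_betas)
    lp_modules = scores.to_numpy() @ betas.reindex(scores.columns).to_numpy() if len(
        betas
    ) else np.zeros(n)

    age = rng.uniform(*AGE_RANGE, size=n)

    # stage: latent Gaussian tilted by the signed module burden, cut at the
    # empirical quantiles of the target stage mix so the mix is preserved
    burden = lp_modules / (np.std(lp_modules) + 1e-12) if np.std(lp_modules) > 0 else np.zeros(n)
    latent = config.stage_coupling * burden + rng.standard_normal(n)
    cum = np.cumsum(STAGE_PROBS)[:-1]
    cuts = np.quantile(latent, cum)
    stage = 1 + np.searchsorted(cuts, latent, side="left")

    lp = lp_modules + config.age_beta * (age - 65.0) + config.stage_beta * (stage - 1)
    hazard = np.exp(lp) / config.baseline_hazard_scale
    t_event = rng.exponential(1.0, size=n) / hazard

    if config.censoring_rate <= 0.0:
        os_time, os_event = t_event, np.ones(n, dtype=int)
    elif config.censoring_rate >= 1.0:
        os_time = rng.exponential(config.baseline_hazard_scale, size=n)
        os_time = np.minimum(os_time, t_event * (1 - 1e-9))
        os_event = np.zeros(n, dtype=int)
    else:
        lam = _solve_censoring_rate(config.censoring_rate, hazard)
        c = rng.exponential(1.0 / lam, size=n)
        os_time = np.minimum(t_event, c)
        os_event = (t_event <= c).astype(int)

    df = pd.DataFrame(
        {
            "os_time": np.maximum(os_time, 1e-6),
            "os_event": os_event,
            "pfs_time": np.maximum(os_time * config.pfs_factor, 1e-6),
            "pfs_event": os_event,
            "age": age,
            "stage": stage.astype(float),
            "tissue": "tumour",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ClinicalTable(df)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Expression (tumour + normal), clinical table and ground truth in one call."""
    tumour, normal, truth = generate_expression(config)
    clinical = generate_clinical(config, tumour, truth)
    return tumour, normal, clinical, truth


def write_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> dict[str, str]:
    """Write the TSV/JSON fixture files; returns name -> path written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tumour, normal, clinical, truth = generate_dataset(config)
    paths = {
        "expression_tumour": out / "expression_tumour.tsv",
        "expression_normal": out / "expression_normal.tsv",
        "clinical": out / "clinical.tsv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "synthetic_config.json",
    }
    write_expression(tumour, paths["expression_tumour"])
    write_expression(normal, paths["expression_normal"])
    write_clinical(clinical, paths["clinical"])
    truth.to_json(paths["ground_truth"])
    paths["config"].write_text(json.dumps(asdict(config), indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
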