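"""Synthetic CBMN experiment generator.

Emulates the statistical structure the analysis pipeline assumes so that
every stage — scoring aggregation, indices, tests, verdicts — can be
exercised and calibrated without laboratory data:

* triplicate inserts per dose group, ~500 cells classified per insert;
* a low binucleation fraction (a few percent: organotypic airway tissue
  divides slowly even under cytochalasin-B block with EGF stimulation);
* dose-dependent suppression of binucleation (cytotoxicity), modelled as
  a log-logistic curve on the binucleated-class probability with the
  lost mass reallocated to mononucleated cells;
* micronucleus events among BNCs with a logit-linear dose-response and
  optional beta-binomial between-insert overdispersion (``rho`` is the
  intra-insert correlation; ``rho = 0`` recovers the binomial exactly);
* MN scoring limited by BNC availability: the classification-sample BNC
  fraction is scaled to a slide-level cell pool and capped at the
  per-insert scoring target, reproducing the BNC shortfalls real slides
  show at cytotoxic doses.

Default parameter values mirror the mitomycin-C validation condition of
the airway-model assay (control binucleation ~8.5%, control MN rate
~0.28%, doses 1.25–20 ug/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .data_model import (
    CellClassCounts,
    DoseGroup,
    Experiment,
    InsertRecord,
    MnCounts,
)
from .errors import ConfigError
from .stats import FisherSidedness, TrendSpec, genotoxic_call

__all__ = [
    "SimulationConfig",
    "OperatingCharacteristics",
    "simulate_insert",
    "simulate_experiment",
    "operating_characteristics",
    "mmc_like_config",
    "null_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic experiment.

    ``bnc_suppression_ec50`` / ``bnc_suppression_hill`` parameterize the
    log-logistic relative binucleation curve 1 / (1 + (dose/EC50)^hill);
    ``mn_dose_slope`` is the logit-scale MN-rate increase per unit dose;
    ``overdispersion_rho`` the beta-binomial intra-insert correlation.
    ``slide_cell_pool`` is the effective number of cells available on a
    slide for MN scoring, a free parameter of the availability model.
    """

    n_inserts_per_group: int = 3
    cells_classified_per_insert: int = 500
    target_bnc_per_insert: int = 667
    slide_cell_pool: int = 20_000
    baseline_class_probs: tuple[float, float, float] = (0.913, 0.085, 0.002)
    bnc_suppression_ec50: float = 9.0
    bnc_suppression_hill: float = 2.3
    mn_baseline_rate: float = 0.0028
    mn_dose_slope: float = 0.43
    overdispersion_rho: float = 0.0
    doses: tuple[float, ...] = (1.25, 2.5, 5.0, 10.0, 20.0)
    chemical: str = "SIM"
    teer_mean_ohm: Optional[float] = None
    teer_sd_ohm: float = 0.0
    ak_mean_rlu: Optional[float] = None
    ak_sd_rlu: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = self.baseline_class_probs
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1) > 1e-9:
            raise ConfigError(
                f"baseline_class_probs must be 3 non-negative values "
                f"summing to 1, got {p}"
            )
        if not (0 <= self.mn_baseline_rate < 1):
            raise ConfigError("mn_baseline_rate must be in [0, 1)")
        if not (0 <= self.overdispersion_rho < 1):
            raise ConfigError("overdispersion_rho must be in [0, 1)")
        if any(d < 0 for d in self.doses):
            raise ConfigError("doses must be non-negative")
        if list(self.doses) != sorted(self.doses):
            raise ConfigError("doses must be sorted ascending")
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(
            self, "baseline_class_probs", tuple(float(x) for x in p)
        )

    def bnc_suppression(self, dose: float) -> float:
        """Relative binucleation at ``dose`` (1 at dose 0, log-logistic)."""
        if dose <= 0:
            return 1.0
        return 1.0 / (1.0 + (dose / self.bnc_suppression_ec50) ** self.bnc_suppression_hill)

    def mn_rate(self, dose: float) -> float:
        """Expected micronucleated-BNC probability at ``dose``."""
        if self.mn_baseline_rate == 0.0:
            return 0.0
        return float(
            expit(logit(self.mn_baseline_rate) + self.mn_dose_slope * dose)
        )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo performance of the conjunction decision rule."""

    rejection_rate: float
    trend_rejection_rate: float
    per_dose_rates: dict[float, float]
    mc_se: float
    n_reps: int
    alpha: float


def _insert_rng(seed: int, group_idx: int, insert_idx: int) -> np.random.Generator:
    # Counter-based derivation: each insert's stream depends only on its
    # (group, insert) coordinates, so adding inserts or doses never shifts
    # the draws of existing ones.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(group_idx, insert_idx))
    )


def simulate_insert(
    config: SimulationConfig,
    dose: float,
    rng: np.random.Generator,
    insert_id: str = "sim",
) -> InsertRecord:
    """Draw one insert's scoring record at the given dose.

    Class counts are multinomial over (mono, bi, multi) with the
    binucleated probability scaled by the suppression curve; the MN count
    is beta-binomial over the BNCs actually scored.
    """
    p_mono0, p_bi0, p_multi0 = config.baseline_class_probs
    p_bi = p_bi0 * config.bnc_suppression(dose)
    probs = (p_mono0 + (p_bi0 - p_bi), p_bi, p_multi0)
    n_mono, n_bi, n_multi = rng.multinomial(
        config.cells_classified_per_insert, probs
    )
    counts = CellClassCounts(
        int(n_mono), int(n_bi), int(n_multi),
        config.cells_classified_per_insert,
    )

    # BNC availability: the classification sample's BNC fraction scaled to
    # the slide-level cell pool, capped at the scoring target.
    available = int(
        config.slide_cell_pool * n_bi / config.cells_classified_per_insert
    )
    n_scored = min(config.target_bnc_per_insert, available)

    rate = config.mn_rate(dose)
    rho = config.overdispersion_rho
    if n_scored == 0 or rate == 0.0:
        n_mn = 0
    else:
        if rho > 0:
            a = rate * (1 - rho) / rho
            b = (1 - rate) * (1 - rho) / rho
            p = rng.beta(a, b)
        else:
            p = rate
        n_mn = int(rng.binomial(n_scored, p))

    teer = (
        float(rng.normal(config.teer_mean_ohm, config.teer_sd_ohm))
        if config.teer_mean_ohm is not None
        else None
    )
    ak = (
        float(rng.normal(config.ak_mean_rlu, config.ak_sd_rlu))
        if config.ak_mean_rlu is not None
        else None
    )
    return InsertRecord(
        insert_id=insert_id,
        class_counts=counts,
        mn_counts=MnCounts(n_scored, n_mn),
        teer_ohm=teer,
        ak_rlu=ak,
    )


def simulate_experiment(config: SimulationConfig) -> Experiment:
    """Control group (dose 0) plus one dose group per configured dose."""
    groups = []
    for g_idx, dose in enumerate((0.0,) + config.doses):
        inserts = tuple(
            simulate_insert(
                config,
                dose,
                _insert_rng(config.seed, g_idx, i_idx),
                insert_id=f"{config.chemical}-{dose:g}-{i_idx + 1}",
            )
            for i_idx in range(config.n_inserts_per_group)
        )
        groups.append(
            DoseGroup(
                chemical=config.chemical,
                concentration=dose,
                inserts=inserts,
                is_control=dose == 0,
            )
        )
    return Experiment(control=groups[0], treated=tuple(groups[1:]))


def operating_characteristics(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    fisher_sidedness: FisherSidedness = "two_sided",
    trend_spec: Optional[TrendSpec] = None,
) -> OperatingCharacteristics:
    """Rejection rate of the conjunction rule over simulated experiments.

    Each replicate gets an independent seed derived from the master seed
    by replicate index.  The Monte-Carlo standard error is the binomial
    SE of the overall rejection rate.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    n_reject = 0
    n_trend = 0
    dose_hits = {d: 0 for d in config.doses}
    for rep in range(n_reps):
        rep_seed = int(
            np.random.SeedSequence(
                entropy=config.seed, spawn_key=(rep,)
            ).generate_state(1)[0] & 0x7FFFFFFF
        )
        exp = simulate_experiment(replace(config, seed=rep_seed))
        call = genotoxic_call(
            exp, alpha=alpha, spec=trend_spec, fisher_sidedness=fisher_sidedness
        )
        n_reject += call.verdict
        n_trend += call.trend_p < alpha
        for d in call.significant_doses:
            dose_hits[d] += 1
    rate = n_reject / n_reps
    return OperatingCharacteristics(
        rejection_rate=rate,
        trend_rejection_rate=n_trend / n_reps,
        per_dose_rates={d: h / n_reps for d, h in dose_hits.items()},
        mc_se=math.sqrt(max(rate * (1 - rate), 1e-12) / n_reps),
        n_reps=n_reps,
        alpha=alpha,
    )


def mmc_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Preset mimicking the mitomycin-C validation pattern: falling %BNC
    with dose, %MN rising until BNC availability collapses at the top."""
    base = dict(
        baseline_class_probs=(0.913, 0.085, 0.002),
        bnc_suppression_ec50=9.0,
        bnc_suppression_hill=2.3,
        mn_baseline_rate=0.0028,
        mn_dose_slope=0.43,
        doses=(1.25, 2.5, 5.0, 10.0, 20.0),
        chemical="MMC-like",
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """No dose effect anywhere: flat binucleation, flat MN rate, rho 0."""
    base = dict(
        bnc_suppression_ec50=math.inf,
        mn_dose_slope=0.0,
        overdispersion_rho=0.0,
        chemical="NULL",
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)
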