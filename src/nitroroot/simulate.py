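"""Synthetic-data generators with known ground truth.

Three generators emulate the study's inputs:

* ``simulate_expression`` — a balanced 2 genotypes x 2 nitrate x r replicates
  factorial of log2 intensities with per-gene baselines, additive genotype /
  nitrate / interaction effects planted on random gene subsets and i.i.d.
  Gaussian noise.
* ``simulate_growth`` — destructively sampled plants over successive sampling
  days; total dry weight grows exponentially, a fixed fraction is allocated to
  roots, root surface area is proportional to root mass, and whole-plant N
  accumulates at a known specific uptake rate per unit root area.
* ``simulate_qpcr`` — qPCR plates with per-gene amplification efficiencies,
  planted condition fold changes, serial-dilution standard curves, reference
  genes at fold change 1, and technical CT noise.

Every generator is deterministic given its seed: one global seed per call,
sub-streams spawned from it deterministically.

Effect coding in ``simulate_expression``: a genotype effect e is split -e/2 on
WT and +e/2 on MUT (so the genotype marginal-mean difference equals e),
likewise nitrate (-e/2 HN, +e/2 LN); an interaction i is planted as
(+i/4, -i/4, -i/4, +i/4) on the (WT-HN, WT-LN, MUT-HN, MUT-LN) cells so the
classical interaction contrast (cell[1,1] - cell[1,0] - cell[0,1] + cell[0,0])
equals i. This makes the ground truth directly comparable to the ANOVA
estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ecophysiology import PlantRecord
from .errors import ConfigurationError
from .expression import ExpressionMatrix, GENOTYPES, NITRATES


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

EffectSize = float | tuple[float, float]


@dataclass
class ExpressionSimConfig:
    """Configuration for the factorial expression simulator.

    Effect sizes are log2 units and may be a fixed value or a (low, high)
    sampling interval; fractions give the proportion of genes carrying each
    effect (subsets are drawn independently, so they may overlap, mirroring
    genes responsive to several effects at once).
    """

    n_genes: int = 2000
    n_replicates: int = 3
    prop_G: float = 0.0
    prop_N: float = 0.0
    prop_GxN: float = 0.0
    effect_size_G: EffectSize = 2.0
    effect_size_N: EffectSize = 2.0
    effect_size_GxN: EffectSize = 2.0
    baseline_range: tuple[float, float] = (2.0, 14.0)
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("prop_G", "prop_N", "prop_GxN"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if not (self.noise_sd > 0):
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise ConfigurationError("baseline_range must be (low, high) with low <= high")


@dataclass
class ExpressionGroundTruth:
    """Planted per-gene effect labels and signed log2 effect sizes.

    Effect size is 0 wherever the corresponding flag is False.
    """

    has_G: np.ndarray
    has_N: np.ndarray
    has_GxN: np.ndarray
    effect_G: np.ndarray
    effect_N: np.ndarray
    effect_GxN: np.ndarray
    baseline: np.ndarray

    def to_json(self, path) -> None:
        payload = {k: np.asarray(v).tolist() for k, v in vars(self).items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def _draw_effect(rng: np.random.Generator, size_spec: EffectSize, n: int) -> np.ndarray:
    if isinstance(size_spec, (tuple, list)):
        lo, hi = size_spec
        return rng.uniform(lo, hi, size=n)
    return np.full(n, float(size_spec))


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, ExpressionGroundTruth]:
    """Simulate a balanced factorial log2 expression matrix with ground truth.

    Samples are named ``<genotype>_<nitrate>_<replicate>`` and ordered by
    genotype, nitrate, then replicate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, r = config.n_genes, config.n_replicates

    baseline = rng.uniform(*config.baseline_range, size=n)
    has = {}
    eff = {}
    for key, prop, spec in (
        ("G", config.prop_G, config.effect_size_G),
        ("N", config.prop_N, config.effect_size_N),
        ("GxN", config.prop_GxN, config.effect_size_GxN),
    ):
        has[key] = rng.random(n) < prop
        eff[key] = np.where(has[key], _draw_effect(rng, spec, n), 0.0)

    # cell means, order (genotype, nitrate) = (WT/MUT, HN/LN)
    g_sign = np.array([-0.5, 0.5])              # WT, MUT
    n_sign = np.array([-0.5, 0.5])              # HN, LN
    i_sign = np.array([[0.25, -0.25], [-0.25, 0.25]])  # (WT-HN, WT-LN; MUT-HN, MUT-LN)
    cell_means = (
        baseline[:, None, None]
        + eff["G"][:, None, None] * g_sign[None, :, None]
        + eff["N"][:, None, None] * n_sign[None, None, :]
        + eff["GxN"][:, None, None] * i_sign[None, :, :]
    )
    noise = rng.normal(0.0, config.noise_sd, size=(n, 2, 2, r))
    cells = cell_means[:, :, :, None] + noise

    sample_ids = []
    design_rows = []
    columns = []
    for i, g in enumerate(GENOTYPES):
        for j, nit in enumerate(NITRATES):
            for k in range(r):
                sid = f"{g}_{nit}_{k + 1}"
                sample_ids.append(sid)
                design_rows.append({"genotype": g, "nitrate": nit, "replicate": k + 1})
                columns.append(cells[:, i, j, k])
    probe_ids = [f"gene_{i + 1:05d}" for i in range(n)]
    values = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )
    design = pd.DataFrame(design_rows, index=pd.Index(sample_ids, name="sample_id"))
    truth = ExpressionGroundTruth(
        has_G=has["G"], has_N=has["N"], has_GxN=has["GxN"],
        effect_G=eff["G"], effect_N=eff["N"], effect_GxN=eff["GxN"],
        baseline=baseline,
    )
    return ExpressionMatrix(values=values, design=design), truth


def simulate_null_cells(
    n_genes: int, n_replicates: int, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Fast path for null simulations: a (n_genes, 2, 2, r) noise-only array.

    Baselines are irrelevant to the SS decomposition under the null, so pure
    noise around zero is generated; used by the FWER study where thousands of
    datasets are needed.
    """
    return rng.normal(0.0, noise_sd, size=(n_genes, 2, 2, n_replicates))


# --------------------------------------------------------------------------
# growth
# --------------------------------------------------------------------------


@dataclass
class GrowthScenario:
    """Deterministic growth-core parameters for one genotype x nitrate group.

    Rates are per day; masses in g, areas in cm^2, the specific uptake rate
    ``uptake_rate`` in g N per cm^2 root area per day.
    """

    relative_growth_rate: float = 0.12
    root_allocation: float = 0.30
    uptake_rate: float = 5.0e-5
    specific_root_area: float = 250.0   # cm^2 root area per g root dry weight
    leaf_area_per_shoot_mass: float = 180.0  # cm^2 per g shoot dry weight
    initial_tdw: float = 0.005
    initial_totn: float = 2.0e-4
    prl0: float = 3.0                   # primary root length at transfer, cm
    prl_rate: float = 1.1               # cm per day
    lrn_rate: float = 2.0               # lateral roots initiated per day
    mean_lrl: float = 3.0               # cm per lateral root

    def validate(self) -> None:
        if not (0 < self.root_allocation < 1):
            raise ConfigurationError(
                f"root_allocation must be in (0, 1), got {self.root_allocation}"
            )
        for name in (
            "relative_growth_rate", "uptake_rate", "specific_root_area",
            "leaf_area_per_shoot_mass", "initial_tdw", "initial_totn",
        ):
            if not (getattr(self, name) > 0):
                raise ConfigurationError(f"{name} must be > 0")


def default_growth_scenarios() -> dict[tuple[str, str], GrowthScenario]:
    """Study-like defaults: the mutant is depressed in growth and N uptake and
    allocates more dry weight to its (highly branched, short-lateral) roots;
    low nitrate lowers uptake in both genotypes."""
    return {
        ("WT", "HN"): GrowthScenario(
            relative_growth_rate=0.13, root_allocation=0.30, uptake_rate=6.0e-5,
            lrn_rate=2.2, mean_lrl=3.0,
        ),
        ("WT", "LN"): GrowthScenario(
            relative_growth_rate=0.11, root_allocation=0.33, uptake_rate=4.5e-5,
            lrn_rate=1.8, mean_lrl=3.4,
        ),
        ("MUT", "HN"): GrowthScenario(
            relative_growth_rate=0.10, root_allocation=0.40, uptake_rate=3.5e-5,
            lrn_rate=6.5, mean_lrl=1.0,
        ),
        ("MUT", "LN"): GrowthScenario(
            relative_growth_rate=0.09, root_allocation=0.42, uptake_rate=2.5e-5,
            lrn_rate=6.5, mean_lrl=1.0,
        ),
    }


@dataclass
class GrowthSimConfig:
    """Configuration for the longitudinal phenotype simulator.

    Two noise CVs are exposed: ``cv_between_plants`` (a lognormal size factor
    shared by all of one plant's measures — biological variability) and
    ``cv_measurement`` (independent lognormal noise per measured variable).
    """

    sampling_days: tuple[float, ...] = (7, 10, 14, 21, 28)
    scenarios: dict[tuple[str, str], GrowthScenario] = field(
        default_factory=default_growth_scenarios
    )
    plants_per_group: int = 6
    cv_between_plants: float = 0.10
    cv_measurement: float = 0.02
    root_n_fraction: float = 0.25   # share of whole-plant N residing in roots
    n_integration_grid: int = 64    # sub-steps per sampling interval for N uptake
    seed: int = 0

    def validate(self) -> None:
        days = tuple(self.sampling_days)
        if len(days) == 0:
            raise ConfigurationError("sampling_days must not be empty")
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ConfigurationError("sampling_days must be strictly increasing")
        if days[0] <= 0:
            raise ConfigurationError("sampling days are days after transfer and must be > 0")
        if not (0 < self.root_n_fraction < 1):
            raise ConfigurationError("root_n_fraction must be in (0, 1)")
        if self.cv_between_plants < 0 or self.cv_measurement < 0:
            raise ConfigurationError("noise CVs must be >= 0")
        if self.plants_per_group < 1:
            raise ConfigurationError("plants_per_group must be >= 1")
        for sc in self.scenarios.values():
            sc.validate()


@dataclass
class GrowthGroundTruth:
    """True (noise-free) group trajectories and the generating parameters."""

    scenarios: dict[tuple[str, str], GrowthScenario]
    trajectories: pd.DataFrame  # genotype, nitrate, day, tdw, rdw, sdw, area, leaf_area, totn

    def uptake_rate(self, genotype: str, nitrate: str) -> float:
        return self.scenarios[(genotype, nitrate)].uptake_rate

    def to_json(self, path) -> None:
        payload = {
            "scenarios": {
                f"{g}_{n}": asdict(sc) for (g, n), sc in self.scenarios.items()
            },
            "trajectories": self.trajectories.to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1 + cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def simulate_growth(
    config: GrowthSimConfig,
) -> tuple[list[PlantRecord], GrowthGroundTruth]:
    """Simulate destructively sampled plants over the sampling days.

    Deterministic core per group: TDW(t) = TDW0 * exp(rgr * t), RDW =
    allocation * TDW, root area = specific root area * RDW, LeafA = leaf-area
    coefficient * SDW. Root area is taken linear in time between sampling days
    (plants are only observed then); whole-plant N accumulates as
    u * integral(area dt), evaluated by the trapezoid rule on a fine internal
    grid over each interval — exact for the piecewise-linear area. Tissue N
    concentrations are back-computed from the simulated shoot/root N pools.
    Multiplicative lognormal noise (per-plant factor plus per-variable
    measurement noise) is applied on top of the group trajectory.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.sampling_days, dtype=float)
    records: list[PlantRecord] = []
    truth_rows = []

    for (genotype, nitrate) in sorted(config.scenarios):
        sc = config.scenarios[(genotype, nitrate)]
        grid_days = np.concatenate([[0.0], days])
        tdw = sc.initial_tdw * np.exp(sc.relative_growth_rate * grid_days)
        rdw = sc.root_allocation * tdw
        sdw = tdw - rdw
        area = sc.specific_root_area * rdw
        leaf = sc.leaf_area_per_shoot_mass * sdw
        totn = np.empty_like(grid_days)
        totn[0] = sc.initial_totn
        for k in range(len(grid_days) - 1):
            tt = np.linspace(grid_days[k], grid_days[k + 1], config.n_integration_grid + 1)
            aa = np.interp(tt, [grid_days[k], grid_days[k + 1]], [area[k], area[k + 1]])
            totn[k + 1] = totn[k] + sc.uptake_rate * np.trapezoid(aa, tt)
        for idx, day in enumerate(days, start=1):
            truth_rows.append(
                {
                    "genotype": genotype, "nitrate": nitrate, "day": day,
                    "tdw": tdw[idx], "rdw": rdw[idx], "sdw": sdw[idx],
                    "root_area": area[idx], "leaf_area": leaf[idx], "totn": totn[idx],
                }
            )
            root_n = config.root_n_fraction * totn[idx]
            shoot_n = totn[idx] - root_n
            prl = sc.prl0 + sc.prl_rate * day
            lrn = sc.lrn_rate * day
            for p in range(config.plants_per_group):
                plant_factor = float(_lognormal_factor(rng, config.cv_between_plants, ()))
                meas = _lognormal_factor(rng, config.cv_measurement, 9)
                sdw_p = sdw[idx] * plant_factor * meas[0]
                rdw_p = rdw[idx] * plant_factor * meas[1]
                area_p = area[idx] * plant_factor * meas[2]
                leaf_p = leaf[idx] * plant_factor * meas[3]
                shoot_n_p = shoot_n * plant_factor * meas[4]
                root_n_p = root_n * plant_factor * meas[5]
                prl_p = prl * meas[6]
                lrn_p = lrn * plant_factor * meas[7]
                lrl_p = sc.mean_lrl * meas[8]
                if config.cv_between_plants > 0 or config.cv_measurement > 0:
                    lrn_p = float(max(0, round(lrn_p)))
                records.append(
                    PlantRecord(
                        genotype=genotype,
                        nitrate=nitrate,
                        day=float(day),
                        plant_id=f"{genotype}_{nitrate}_d{day:g}_p{p + 1}",
                        prl=prl_p,
                        lrn=lrn_p,
                        trl=prl_p + lrn_p * lrl_p,
                        root_area=area_p,
                        leaf_area=leaf_p,
                        sdw=sdw_p,
                        rdw=rdw_p,
                        pct_shoot_n=100.0 * shoot_n_p / sdw_p,
                        pct_root_n=100.0 * root_n_p / rdw_p,
                    )
                )
    truth = GrowthGroundTruth(
        scenarios=dict(config.scenarios), trajectories=pd.DataFrame(truth_rows)
    )
    return records, truth


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------


@dataclass
class QPCRDataset:
    """Simulated qPCR wells plus the planted truth.

    ``wells`` columns: gene, sample_id, biological_replicate,
    technical_replicate, ct, role, standard_quantity. Unknown samples span two
    conditions ('control', 'treated'); the planted fold change is
    treated/control. Reference genes carry fold change 1.
    """

    wells: pd.DataFrame
    fold_changes: dict[str, float]
    efficiencies: dict[str, float]
    ref_genes: tuple[str, ...]


def simulate_qpcr(
    n_genes: int,
    fold_changes,
    efficiencies=2.0,
    seed: int = 0,
    ct_noise_sd: float = 0.1,
    n_bio: int = 3,
    n_tech: int = 3,
    intercept: float = 35.0,
    ref_genes: tuple[str, ...] = ("EF1", "UBQ"),
    n_dilutions: int = 5,
    dilution_base: float = 10.0,
) -> QPCRDataset:
    """Simulate qPCR plates for ``n_genes`` target genes plus reference genes.

    CT values follow the standard-curve model CT = intercept + slope *
    log10(quantity) with slope = -1/log10(E); ``ct_noise_sd`` is Gaussian
    technical noise on the CT scale. Each gene gets an ``n_dilutions``-point
    serial dilution standard series (noise-free quantities, noisy CTs) and
    3 technical x ``n_bio`` biological replicate unknowns per condition.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    fold = np.broadcast_to(np.asarray(fold_changes, dtype=float), (n_genes,)).copy()
    eff = np.broadcast_to(np.asarray(efficiencies, dtype=float), (n_genes,)).copy()
    if (fold <= 0).any():
        raise ConfigurationError("fold changes must be > 0")
    if ((eff <= 1) | (eff > 2)).any():
        raise ConfigurationError("amplification efficiencies must satisfy 1 < E <= 2")
    if ct_noise_sd < 0:
        raise ConfigurationError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    genes = [f"target_{i + 1}" for i in range(n_genes)] + list(ref_genes)
    gene_fold = {g: float(f) for g, f in zip(genes, fold)} | {g: 1.0 for g in ref_genes}
    gene_eff = {g: float(e) for g, e in zip(genes, eff)} | {g: 2.0 for g in ref_genes}

    rows = []
    for gene in genes:
        slope = -1.0 / math.log10(gene_eff[gene])
        # standards: serial dilution from dilution_base**2 downwards
        for d in range(n_dilutions):
            q = dilution_base ** (2 - d)
            ct = intercept + slope * math.log10(q) + rng.normal(0, ct_noise_sd)
            rows.append(
                {
                    "gene": gene, "sample_id": f"std_{d + 1}", "biological_replicate": 0,
                    "technical_replicate": 1, "ct": ct, "role": "standard",
                    "standard_quantity": q,
                }
            )
        for condition, q_cond in (("control", 1.0), ("treated", gene_fold[gene])):
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    ct = intercept + slope * math.log10(q_cond) + rng.normal(0, ct_noise_sd)
                    rows.append(
                        {
                            "gene": gene, "sample_id": condition,
                            "biological_replicate": b, "technical_replicate": t,
                            "ct": ct, "role": "unknown", "standard_quantity": math.nan,
                        }
                    )
    wells = pd.DataFrame(rows)
    return QPCRDataset(
        wells=wells,
        fold_changes=gene_fold,
        efficiencies=gene_eff,
        ref_genes=tuple(ref_genes),
    )
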