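"""Structural-equation phenotype simulation for trio studies.

Generates a continuous primary phenotype Y (FEV1-like), a secondary
phenotype K (weight-like) and two measured covariates L1 (height-like,
possibly genotype-dependent) and L2 (age-like, never genotype-dependent)
from a linear structural model driven by the offspring genotype X of a
causal marker and an unmeasured standard-normal confounder U:

    L1 = c·X + δ·U + e_L          (X→L edge optional)
    L2 = e_age
    K  = a·X + b1·L1 + b2·L2 + η·U + e_K      (X→K edge optional)
    Y  = d·X + γ1·K + f1·L1 + f2·L2 + ζ·U + e_Y

Effect sizes are specified as variance fractions (locus-specific
heritabilities for the genetic edges; the fraction of Var(Y) explained by K
for the mediated path) and converted to slopes using Var(X) = 2p(1-p).
Noise variances are solved so that L1, K and Y each have unit total
variance, so fractions are interpretable and additive effects are in SD
units.  Four canonical causal scenarios toggle the X→K, X→L and K→Y edges;
an optional two-population stratification design gives the two populations
different allele frequencies and shifts population 2's phenotype means,
which acts as the unmeasured confounder U inducing spurious X-Y
association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trio_genetics import MarkerPanel, as_rng, draw_trio_marker

__all__ = [
    "ScenarioConfig",
    "StratificationConfig",
    "PhenotypeTable",
    "ConfigurationError",
    "effect_size_to_coefficient",
    "correlation_to_coefficient",
    "simulate_phenotypes",
    "simulate_null_markers",
    "simulate_stratified",
    "simulate_study",
    "write_ped_map",
    "write_phenotypes",
    "write_manifest",
]


class ConfigurationError(ValueError):
    """Raised when a scenario's variance budget is infeasible."""


def effect_size_to_coefficient(
    variance_fraction: float, var_outcome: float, var_predictor: float
) -> float:
    """Slope giving the predictor the stated fraction of outcome variance.

    Returns ``sqrt(variance_fraction * var_outcome / var_predictor)``
    (positive sign); e.g. a locus-specific heritability of 1% on a
    unit-variance phenotype maps to a per-genotype slope of
    ``sqrt(0.01 / (2p(1-p)))``.
    """
    if var_predictor <= 0:
        raise ValueError("var_predictor must be positive")
    if variance_fraction < 0:
        raise ValueError("variance_fraction must be nonnegative")
    return math.sqrt(variance_fraction * var_outcome / var_predictor)


def correlation_to_coefficient(r: float, var_outcome: float, var_predictor: float) -> float:
    """Slope giving the stated marginal correlation: r·sqrt(Vout/Vpred)."""
    if var_predictor <= 0:
        raise ValueError("var_predictor must be positive")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    return r * math.sqrt(var_outcome / var_predictor)


# ---------------------------------------------------------------------------
# configuration

_SCENARIO_EDGES = {
    # scenario -> (x_to_k, x_to_l, k_to_y)
    1: (True, True, True),
    2: (True, False, True),
    3: (True, True, False),
    4: (False, False, True),
}


@dataclass(frozen=True)
class StratificationConfig:
    """Two-population admixture design.

    Population 2's phenotype means are shifted (in outcome SD units), which
    combined with different allele frequencies creates confounding of the
    genotype-phenotype association.
    """

    maf_pop1: float
    maf_pop2: float
    proportion_pop1: float = 0.5
    mean_shift_y: float = 0.5
    mean_shift_k: float = 0.5

    def __post_init__(self) -> None:
        for name in ("maf_pop1", "maf_pop2"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 < self.proportion_pop1 < 1.0:
            raise ValueError("proportion_pop1 must be in (0, 1)")


@dataclass(frozen=True)
class ScenarioConfig:
    """Causal-diagram switches and effect sizes for one simulation scenario.

    Variance fractions: ``h2_k`` / ``h2_l`` are the locus heritabilities of
    K and L1; ``var_y_k`` the fraction of Var(Y) explained by K;
    ``var_y_direct`` the direct X→Y fraction (0 under the null). Covariate
    slopes and confounder loadings are in SD units of the unit-variance
    outcomes.

    The L1–Y association is confounded through U (``u_to_l``, ``u_to_y``)
    rather than causal: ``l1_to_y`` defaults to 0 because a causal L→Y
    arrow combined with the X→L edge would constitute a genuine unmediated
    X→Y path — the direct-effect null would no longer hold in scenarios
    1 and 3. L2 ("age") is never genotype-dependent, so its causal slope
    on Y is harmless.
    """

    scenario_id: int = 1
    x_to_k: bool = True
    x_to_l: bool = True
    k_to_y: bool = True
    x_to_y_direct: bool = False
    h2_k: float = 0.01
    h2_l: float = 0.01
    var_y_k: float = 0.01
    var_y_direct: float = 0.0
    direct_slope: float | None = None
    l1_to_k: float = 0.5
    l2_to_k: float = 0.2
    l1_to_y: float = 0.0
    l2_to_y: float = 0.2
    u_to_l: float = 0.5
    u_to_k: float = 0.0
    u_to_y: float = 0.3
    stratification: StratificationConfig | None = None

    def __post_init__(self) -> None:
        if self.scenario_id not in _SCENARIO_EDGES:
            raise ValueError("scenario_id must be in {1, 2, 3, 4}")
        for name in ("h2_k", "h2_l", "var_y_k", "var_y_direct"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be a variance fraction in [0, 1)")

    @classmethod
    def for_scenario(
        cls,
        scenario_id: int,
        direct_effect: float = 0.0,
        direct_slope: float | None = None,
        **overrides,
    ) -> "ScenarioConfig":
        """Scenario presets: 1 = X→K, X→L, K→Y; 2 = no X→L; 3 = no K→Y;
        4 = neither X→K nor X→L.

        The direct X→Y effect for power simulations is either
        ``direct_effect`` (a variance fraction / locus heritability, so the
        noncentrality is flat in allele frequency) or ``direct_slope`` (a
        fixed per-allele effect in Y-SD units, so power rises with allele
        frequency). Both zero/None keeps the null of no direct effect.
        """
        if scenario_id not in _SCENARIO_EDGES:
            raise ValueError("scenario_id must be in {1, 2, 3, 4}")
        x_to_k, x_to_l, k_to_y = _SCENARIO_EDGES[scenario_id]
        base = dict(
            scenario_id=scenario_id,
            x_to_k=x_to_k,
            x_to_l=x_to_l,
            k_to_y=k_to_y,
            x_to_y_direct=direct_effect > 0 or direct_slope is not None,
            var_y_direct=direct_effect,
            direct_slope=direct_slope,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PhenotypeTable:
    """Per-offspring phenotypes, row-aligned with a panel's trios."""

    y: np.ndarray
    k: np.ndarray
    covariates: np.ndarray  # (n, n_covariates)
    covariate_names: list[str] = field(default_factory=lambda: ["L1", "L2"])
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.y.shape[0]:
            self.covariates = self.covariates.T
        if not (self.y.shape[0] == self.k.shape[0] == self.covariates.shape[0]):
            raise ValueError("phenotype columns must share a length")
        if self.ids is None:
            self.ids = [f"trio{i + 1}_o" for i in range(len(self.y))]

    @property
    def n(self) -> int:
        return int(self.y.shape[0])

    @property
    def y_mean(self) -> float:
        return float(np.mean(self.y))

    @property
    def k_mean(self) -> float:
        return float(np.mean(self.k))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"iid": self.ids, "Y": self.y, "K": self.k})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df


# ---------------------------------------------------------------------------
# structural-equation simulation


def _slopes(config: ScenarioConfig, var_x: float) -> dict[str, float]:
    c = effect_size_to_coefficient(config.h2_l, 1.0, var_x) if config.x_to_l else 0.0
    a = effect_size_to_coefficient(config.h2_k, 1.0, var_x) if config.x_to_k else 0.0
    # K and L1 are built to unit variance, so these are direct fractions
    gamma1 = effect_size_to_coefficient(config.var_y_k, 1.0, 1.0) if config.k_to_y else 0.0
    if not config.x_to_y_direct:
        d = 0.0
    elif config.direct_slope is not None:
        d = float(config.direct_slope)
    else:
        d = effect_size_to_coefficient(config.var_y_direct, 1.0, var_x)
    return {"a": a, "c": c, "d": d, "gamma1": gamma1}


def _noise_sd(total: float, deterministic_var: float, outcome: str) -> float:
    resid = total - deterministic_var
    if resid <= 0.0:
        raise ConfigurationError(
            f"variance fractions for {outcome} leave no room for noise "
            f"(deterministic variance {deterministic_var:.4f} >= {total})"
        )
    return math.sqrt(resid)


def _generate_phenotypes(
    rng: np.random.Generator,
    x: np.ndarray,
    var_x: float,
    config: ScenarioConfig,
    ids: list[str] | None = None,
) -> PhenotypeTable:
    """Evaluate the structural equations in topological order.

    Exact population variances of the deterministic parts are tracked via
    loadings on the independent sources (X, U and the upstream noises), and
    each outcome's noise SD is solved so its total variance is 1.
    """
    n = x.shape[0]
    s = _slopes(config, var_x)
    a, c, d, gamma1 = s["a"], s["c"], s["d"], s["gamma1"]
    b1, b2 = config.l1_to_k, config.l2_to_k
    f1, f2 = config.l1_to_y, config.l2_to_y
    eta, zeta, delta = config.u_to_k, config.u_to_y, config.u_to_l

    # fixed draw order so that zeroing a coefficient leaves the stream intact
    u = rng.standard_normal(n)
    e_l1 = rng.standard_normal(n)
    l2 = rng.standard_normal(n)
    e_k = rng.standard_normal(n)
    e_y = rng.standard_normal(n)

    xc = x.astype(float)

    sd_l1 = _noise_sd(1.0, c * c * var_x + delta * delta, "L1")
    l1 = c * xc + delta * u + sd_l1 * e_l1

    # loadings of K's deterministic part on (X, U, e_L1, L2)
    k_x = a + b1 * c
    k_u = eta + b1 * delta
    k_el = b1 * sd_l1
    var_k_det = k_x * k_x * var_x + k_u * k_u + k_el * k_el + b2 * b2
    sd_k = _noise_sd(1.0, var_k_det, "K")
    k = a * xc + b1 * l1 + b2 * l2 + eta * u + sd_k * e_k

    y_x = d + gamma1 * k_x + f1 * c
    y_u = zeta + gamma1 * k_u + f1 * delta
    y_el = gamma1 * k_el + f1 * sd_l1
    y_ea = gamma1 * b2 + f2
    y_ek = gamma1 * sd_k
    var_y_det = y_x * y_x * var_x + y_u * y_u + y_el * y_el + y_ea * y_ea + y_ek * y_ek
    sd_y = _noise_sd(1.0, var_y_det, "Y")
    y = d * xc + gamma1 * k + f1 * l1 + f2 * l2 + zeta * u + sd_y * e_y

    return PhenotypeTable(y=y, k=k, covariates=np.column_stack([l1, l2]), ids=ids)


def simulate_phenotypes(
    panel: MarkerPanel,
    config: ScenarioConfig,
    seed,
    causal_marker: int = 0,
    var_x: float | None = None,
) -> PhenotypeTable:
    """Generate (Y, K, L1, L2) from the causal marker's offspring genotypes.

    ``var_x`` defaults to the HWE genotype variance 2p(1-p) from the panel's
    recorded minor-allele frequency; stratified designs pass the exact
    mixture variance instead.
    """
    rng = as_rng(seed)
    x = panel.offspring[causal_marker]
    if var_x is None:
        p = float(panel.maf[causal_marker])
        var_x = 2.0 * p * (1.0 - p)
        if var_x <= 0.0:
            raise ConfigurationError("causal marker is monomorphic (maf 0 or 1)")
    return _generate_phenotypes(rng, x, var_x, config, ids=panel.trio_ids)


def simulate_null_markers(n_trios: int, n_markers: int, mafs, seed) -> MarkerPanel:
    """Markers simulated independently of all phenotypes and of each other."""
    mafs = np.atleast_1d(np.asarray(mafs, dtype=float))
    if mafs.shape[0] != n_markers:
        raise ValueError("need one maf per marker")
    rng = as_rng(seed)
    fathers, mothers, offsprings = [], [], []
    for p in mafs:
        f, m, o = draw_trio_marker(rng, float(p), n_trios)
        fathers.append(f)
        mothers.append(m)
        offsprings.append(o)
    shape = (max(n_markers, 0), n_trios)
    return MarkerPanel(
        father=np.array(fathers, dtype=np.int8).reshape(shape),
        mother=np.array(mothers, dtype=np.int8).reshape(shape),
        offspring=np.array(offsprings, dtype=np.int8).reshape(shape),
        maf=mafs,
    )


def mixture_genotype_variance(strat: StratificationConfig) -> float:
    """Exact Var(X) of the two-population offspring genotype mixture."""
    w1 = strat.proportion_pop1
    w2 = 1.0 - w1
    p1, p2 = strat.maf_pop1, strat.maf_pop2
    within = w1 * 2.0 * p1 * (1.0 - p1) + w2 * 2.0 * p2 * (1.0 - p2)
    between = w1 * w2 * (2.0 * p1 - 2.0 * p2) ** 2
    return within + between


def _per_trio_maf(strat: StratificationConfig, n_trios: int) -> tuple[np.ndarray, np.ndarray]:
    n1 = int(round(strat.proportion_pop1 * n_trios))
    pop = np.zeros(n_trios, dtype=np.int8)
    pop[n1:] = 1
    maf = np.where(pop == 0, strat.maf_pop1, strat.maf_pop2)
    return maf, pop


def simulate_stratified(
    n_trios: int,
    strat: StratificationConfig,
    config: ScenarioConfig,
    seed,
    n_null_markers: int = 0,
) -> tuple[MarkerPanel, PhenotypeTable]:
    """Two-population design: population-specific allele frequencies for
    every marker plus phenotype mean shifts for population 2.

    With equal frequencies and zero shifts this reduces exactly (same seed,
    same draw path) to the unstratified :func:`simulate_study`.
    """
    rng = as_rng(seed)
    per_trio, pop = _per_trio_maf(strat, n_trios)
    pooled = float(np.mean(per_trio))

    fathers, mothers, offsprings = [], [], []
    for _ in range(1 + n_null_markers):
        f, m, o = draw_trio_marker(rng, per_trio, n_trios)
        fathers.append(f)
        mothers.append(m)
        offsprings.append(o)
    panel = MarkerPanel(
        father=np.array(fathers),
        mother=np.array(mothers),
        offspring=np.array(offsprings),
        maf=np.full(1 + n_null_markers, pooled),
        populations=pop,
    )
    phen = _generate_phenotypes(
        rng, panel.offspring[0], mixture_genotype_variance(strat), config, ids=panel.trio_ids
    )
    phen.y = phen.y + strat.mean_shift_y * (pop == 1)
    phen.k = phen.k + strat.mean_shift_k * (pop == 1)
    return panel, phen


def simulate_study(
    n_trios: int,
    maf: float,
    config: ScenarioConfig,
    seed,
    n_null_markers: int = 0,
) -> tuple[MarkerPanel, PhenotypeTable]:
    """One replicate: causal marker first, then null markers, then phenotypes,
    all from a single seeded stream."""
    rng = as_rng(seed)
    fathers, mothers, offsprings = [], [], []
    for _ in range(1 + n_null_markers):
        f, m, o = draw_trio_marker(rng, maf, n_trios)
        fathers.append(f)
        mothers.append(m)
        offsprings.append(o)
    panel = MarkerPanel(
        father=np.array(fathers),
        mother=np.array(mothers),
        offspring=np.array(offsprings),
        maf=np.full(1 + n_null_markers, float(maf)),
    )
    phen = simulate_phenotypes(panel, config, rng)
    return panel, phen


# ---------------------------------------------------------------------------
# plain-text writers (PED/MAP + phenotype table + manifest)

_MAJOR, _MINOR = "1", "2"


def _genotype_to_alleles(g: int) -> str:
    if g < 0:
        return "0 0"
    return " ".join([_MINOR] * int(g) + [_MAJOR] * (2 - int(g)))


def write_ped_map(panel: MarkerPanel, prefix: str | Path) -> tuple[Path, Path]:
    """Write a panel as PLINK-style PED/MAP text files (alleles 1=major,
    2=minor). Each trio becomes one family of three individuals."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    trio_ids = panel.trio_ids or [f"trio{i + 1}_o" for i in range(panel.n_trios)]
    with open(map_path, "w") as fh:
        for j, mid in enumerate(panel.marker_ids):
            fh.write(f"1 {mid} 0 {j + 1}\n")
    with open(ped_path, "w") as fh:
        for i in range(panel.n_trios):
            fam = f"fam{i + 1}"
            oid = trio_ids[i]
            fid_, mid_ = f"{fam}_f", f"{fam}_m"
            rows = [
                (fid_, "0", "0", "1", panel.father[:, i]),
                (mid_, "0", "0", "2", panel.mother[:, i]),
                (oid, fid_, mid_, "0", panel.offspring[:, i]),
            ]
            for iid, pat, mat, sex, geno in rows:
                alleles = " ".join(_genotype_to_alleles(int(g)) for g in geno)
                fh.write(f"{fam} {iid} {pat} {mat} {sex} -9 {alleles}\n")
    return ped_path, map_path


def write_phenotypes(phen: PhenotypeTable, path: str | Path) -> Path:
    """Tab-delimited phenotype table keyed by offspring ID."""
    path = Path(path)
    phen.to_dataframe().to_csv(path, sep="\t", index=False)
    return path


def write_manifest(path: str | Path, seed, config: ScenarioConfig, **extra) -> Path:
    """Plain-text run manifest echoing the seed and configuration."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"seed\t{seed}\n")
        for key, val in vars(config).items():
            fh.write(f"{key}\t{val}\n")
        for key, val in extra.items():
            fh.write(f"{key}\t{val}\n")
    return path
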