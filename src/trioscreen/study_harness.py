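"""Monte Carlo reproduction of the method's operating characteristics.

Runs the type-I-error and power study for the direct-effect FBAT and its
screening companion: single-SNP calibration/power tables over the four
causal scenarios and a grid of allele frequencies, multi-SNP tables (one
causal SNP plus 49 or 99 unassociated SNPs) comparing the two-stage
procedure against single-stage Sidak testing, and the same comparison under
two-population stratification designs.  Also provides plain-text I/O for
real trio data (PED/MAP plus a delimited phenotype table).

Replicate-level seeds are derived deterministically from
(master seed, scenario, allele frequency, replicate index) so any single
replicate can be replayed in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_core import direct_test, screen_statistic
from .pheno_sim import (
    PhenotypeTable,
    ScenarioConfig,
    StratificationConfig,
    simulate_stratified,
    simulate_study,
)
from .trio_genetics import MarkerPanel, TrioGenotypeRecord, mendel_check
from .two_stage import ProcedureConfig, sidak_threshold, two_stage_procedure

__all__ = [
    "SimulationDesign",
    "replicate_rng",
    "run_single_snp_table",
    "run_multi_snp_table",
    "run_stratification_table",
    "read_trio_ped",
    "read_phenotypes",
    "align_phenotypes",
    "write_result_table",
]

logger = logging.getLogger("trioscreen")

MAF_GRID = tuple(round(0.05 * i, 2) for i in range(1, 10))
STRAT_PAIRS = ((0.05, 0.10), (0.05, 0.45), (0.20, 0.25), (0.40, 0.45))

# Default per-allele direct-effect slope for power runs, in Y-SD units.
# A fixed allelic slope makes the test's noncentrality n·d²·p(1−p) grow with
# allele frequency; d² = 0.025 puts single-SNP power near 0.18 at MAF 5% and
# 0.7 at MAF 45% for n = 1000 trios at α = 0.05 (≈1% locus heritability at
# mid-grid frequencies).
DIRECT_EFFECT_SLOPE = 0.025**0.5


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one Monte Carlo study.

    Defaults mirror the study conditions: 1000 trios, 5000 replications,
    allele frequencies 5-45% in 5% steps, α = 0.05, and the four
    stratification frequency pairs. Power runs give the causal SNP a fixed
    per-allele direct effect ``direct_slope`` (set it to None to use the
    ``direct_effect`` variance fraction instead). ``n_reps`` is configurable
    so reduced-replication runs stay cheap.
    """

    scenarios: tuple[int, ...] = (1, 2, 3, 4)
    mafs: tuple[float, ...] = MAF_GRID
    n_trios: int = 1000
    n_reps: int = 5000
    n_null_markers: int = 0
    alpha: float = 0.05
    direct_slope: float | None = DIRECT_EFFECT_SLOPE
    direct_effect: float = 0.01
    strat_pairs: tuple[tuple[float, float], ...] = STRAT_PAIRS
    strat_shift: float = 0.5
    seed: int = 0
    config_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(not 0.0 < m < 1.0 for m in self.mafs):
            raise ValueError("allele frequencies must lie in (0, 1)")


def replicate_rng(master_seed: int, scenario: int, maf: float, rep: int) -> np.random.Generator:
    """Deterministic per-replicate generator from the design coordinates."""
    return np.random.default_rng(
        [int(master_seed) % (2**31), int(scenario), int(round(maf * 10000)), int(rep)]
    )


def _scenario_config(design: SimulationDesign, scenario: int, with_direct_effect: bool) -> ScenarioConfig:
    if not with_direct_effect:
        return ScenarioConfig.for_scenario(scenario, **design.config_overrides)
    return ScenarioConfig.for_scenario(
        scenario,
        direct_effect=design.direct_effect if design.direct_slope is None else 0.0,
        direct_slope=design.direct_slope,
        **design.config_overrides,
    )


def _rate_row(scenario, method, maf, hits: int, n_reps: int) -> dict:
    rate = hits / n_reps
    return {
        "scenario": scenario,
        "method": method,
        "maf": maf,
        "rate": rate,
        "n_reps": n_reps,
        "mc_se": float(np.sqrt(rate * (1.0 - rate) / n_reps)),
    }


def run_single_snp_table(design: SimulationDesign, with_direct_effect: bool) -> pd.DataFrame:
    """Single-SNP rejection rates of the two statistics at level α.

    ``model1_test`` is the direct-effect FBAT (model (1));
    ``model2_test`` uses the screening statistic itself as a chi-square(1)
    test (model (2)). ``with_direct_effect`` toggles the X→Y edge, so rates
    are power when True and type-I error when False.
    """
    crit = stats.chi2.isf(design.alpha, df=1)
    rows = []
    for scenario in design.scenarios:
        config = _scenario_config(design, scenario, with_direct_effect)
        for maf in design.mafs:
            hits1 = hits2 = 0
            undefined = 0
            for rep in range(design.n_reps):
                rng = replicate_rng(design.seed, scenario, maf, rep)
                panel, phen = simulate_study(design.n_trios, maf, config, rng)
                res1 = direct_test(phen.y, phen.k, phen.covariates, panel.marker(0))
                if res1.defined and res1.p_value < design.alpha:
                    hits1 += 1
                elif not res1.defined:
                    undefined += 1
                res2 = screen_statistic(phen.y, phen.k, phen.covariates, panel.marker(0))
                if res2.defined and res2.value > crit:
                    hits2 += 1
            if undefined:
                logger.info(
                    "scenario %s maf %.2f: %d undefined replicates counted as non-rejections",
                    scenario, maf, undefined,
                )
            rows.append(_rate_row(scenario, "model1_test", maf, hits1, design.n_reps))
            rows.append(_rate_row(scenario, "model2_test", maf, hits2, design.n_reps))
    return pd.DataFrame(rows)


def _multi_snp_cell(
    design: SimulationDesign,
    scenario: int,
    maf_key: float,
    config: ScenarioConfig,
    simulate_rep,
) -> tuple[dict, dict]:
    """Shared multi-SNP loop: causal-SNP rejection rates for the two-stage
    procedure and for the causal SNP's FBAT at the Sidak single-stage level
    (equivalent to running every marker for this metric)."""
    M = 1 + design.n_null_markers
    proc_cfg = ProcedureConfig(alpha=design.alpha, top_fraction=0.05)
    sidak = sidak_threshold(design.alpha, M)
    hits_two = hits_one = 0
    for rep in range(design.n_reps):
        rng = replicate_rng(design.seed, scenario, maf_key, rep)
        panel, phen = simulate_rep(rng)
        result = two_stage_procedure(panel, phen, proc_cfg)
        if 0 in result.rejected:
            hits_two += 1
        res1 = result.tests.get(0)
        if res1 is None:
            res1 = direct_test(phen.y, phen.k, phen.covariates, panel.marker(0))
        if res1.defined and res1.p_value < sidak:
            hits_one += 1
    return (
        _rate_row(scenario, "two_stage_screen", maf_key, hits_two, design.n_reps),
        _rate_row(scenario, "single_stage_sidak", maf_key, hits_one, design.n_reps),
    )


def run_multi_snp_table(design: SimulationDesign, with_direct_effect: bool = True) -> pd.DataFrame:
    """Causal-SNP rejection rates with M = 1 + n_null_markers SNPs tested.

    Power when the causal SNP has a direct effect; the type-I analog keeps
    only the indirect causal structure (no X→Y edge).
    """
    if design.n_null_markers < 1:
        raise ValueError("run_multi_snp_table needs n_null_markers >= 1")
    rows = []
    for scenario in design.scenarios:
        config = _scenario_config(design, scenario, with_direct_effect)
        for maf in design.mafs:

            def simulate_rep(rng, maf=maf, config=config):
                return simulate_study(
                    design.n_trios, maf, config, rng, n_null_markers=design.n_null_markers
                )

            two, one = _multi_snp_cell(design, scenario, maf, config, simulate_rep)
            rows.extend([two, one])
    return pd.DataFrame(rows)


def run_stratification_table(design: SimulationDesign, with_direct_effect: bool = True) -> pd.DataFrame:
    """Multi-SNP comparison under two-population stratification.

    Each frequency pair gives population 1 and 2 different allele
    frequencies at every marker; population 2's phenotype means are shifted
    by ``design.strat_shift`` SD. The ``maf`` column holds the pair's mean
    frequency; a ``freq_pair`` column labels the design.
    """
    if design.n_null_markers < 1:
        raise ValueError("run_stratification_table needs n_null_markers >= 1")
    rows = []
    for scenario in design.scenarios:
        config = _scenario_config(design, scenario, with_direct_effect)
        for p1, p2 in design.strat_pairs:
            strat = StratificationConfig(
                maf_pop1=p1,
                maf_pop2=p2,
                mean_shift_y=design.strat_shift,
                mean_shift_k=design.strat_shift,
            )
            maf_key = round((p1 + p2) / 2.0, 4)

            def simulate_rep(rng, strat=strat, config=config):
                return simulate_stratified(
                    design.n_trios, strat, config, rng, n_null_markers=design.n_null_markers
                )

            two, one = _multi_snp_cell(design, scenario, maf_key, config, simulate_rep)
            for row in (two, one):
                row["freq_pair"] = f"{int(p1 * 100)}% and {int(p2 * 100)}%"
            rows.extend([two, one])
    return pd.DataFrame(rows)


def write_result_table(table: pd.DataFrame, path: str | Path, design: SimulationDesign | None = None) -> Path:
    """Tab-delimited result table with a header echoing the design."""
    path = Path(path)
    with open(path, "w") as fh:
        if design is not None:
            fh.write(
                f"# n_trios={design.n_trios} n_reps={design.n_reps} alpha={design.alpha} "
                f"n_null_markers={design.n_null_markers} seed={design.seed}\n"
            )
        table.to_csv(fh, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# plain-text readers


class PedigreeError(ValueError):
    """Malformed or unresolvable PED/MAP input."""


def _parse_ped_line(line: str, lineno: int, n_markers: int):
    parts = line.split()
    if len(parts) != 6 + 2 * n_markers:
        raise PedigreeError(
            f"PED line {lineno}: expected {6 + 2 * n_markers} fields "
            f"({n_markers} markers), got {len(parts)}"
        )
    fam, iid, pat, mat = parts[0], parts[1], parts[2], parts[3]
    alleles = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_markers)]
    return fam, iid, pat, mat, alleles


def read_trio_ped(ped_path: str | Path, map_path: str | Path) -> MarkerPanel:
    """Read complete trios from PED/MAP text files.

    Each offspring whose father and mother are genotyped in the same family
    yields one trio. Per marker the minor allele is the one with the lower
    parental allele frequency (ties break to the lexicographically smaller
    allele); genotypes are coded as minor-allele counts, missing ('0') as
    -1. Trios that are Mendelian-inconsistent at any marker are excluded
    with a logged count.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    marker_ids = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PedigreeError(f"MAP line {lineno}: expected 4 fields, got {len(parts)}")
        marker_ids.append(parts[1])
    n_markers = len(marker_ids)

    individuals: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fam, iid, pat, mat, alleles = _parse_ped_line(line, lineno, n_markers)
        individuals[(fam, iid)] = [pat, mat, alleles]
        order.append((fam, iid))

    trios = []  # (offspring key, father key, mother key)
    for key in order:
        fam, iid = key
        pat, mat, _ = individuals[key]
        if pat in ("0", "") or mat in ("0", ""):
            continue
        fkey, mkey = (fam, pat), (fam, mat)
        if fkey not in individuals or mkey not in individuals:
            raise PedigreeError(
                f"family {fam}: offspring {iid} references ungenotyped parent(s)"
            )
        trios.append((key, fkey, mkey))
    if not trios:
        raise PedigreeError("no complete trios found in PED file")

    # minor allele per marker from parental allele frequencies
    minor_alleles = []
    for j in range(n_markers):
        counts: dict[str, int] = {}
        for _, fkey, mkey in trios:
            for pk in (fkey, mkey):
                for allele in individuals[pk][2][j]:
                    if allele != "0":
                        counts[allele] = counts.get(allele, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise PedigreeError(
                f"marker {marker_ids[j]} has {len(alleles)} alleles; only biallelic "
                "markers are supported"
            )
        if not alleles:
            raise PedigreeError(f"marker {marker_ids[j]} has no observed alleles")
        if len(alleles) == 1:
            minor_alleles.append(alleles[0])  # monomorphic: count the only allele
        else:
            a, b = alleles
            # ties break to the lexicographically smaller allele
            minor_alleles.append(a if counts[a] <= counts[b] else b)

    def code(pair: tuple[str, str], j: int) -> int:
        if "0" in pair:
            return -1
        return sum(1 for al in pair if al == minor_alleles[j])

    father = np.zeros((n_markers, len(trios)), dtype=np.int8)
    mother = np.zeros_like(father)
    offspring = np.zeros_like(father)
    trio_ids = []
    for i, (okey, fkey, mkey) in enumerate(trios):
        trio_ids.append(okey[1])
        for j in range(n_markers):
            father[j, i] = code(individuals[fkey][2][j], j)
            mother[j, i] = code(individuals[mkey][2][j], j)
            offspring[j, i] = code(individuals[okey][2][j], j)

    consistent = np.ones(len(trios), dtype=bool)
    for i in range(len(trios)):
        for j in range(n_markers):
            f, m, o = int(father[j, i]), int(mother[j, i]), int(offspring[j, i])
            if f < 0 or m < 0 or o < 0:
                continue
            if not mendel_check(TrioGenotypeRecord(f, m, o)):
                consistent[i] = False
                logger.warning(
                    "trio %s is Mendelian-inconsistent at marker %s; excluded",
                    trio_ids[i], marker_ids[j],
                )
                break
    if not consistent.any():
        raise PedigreeError("all trios are Mendelian-inconsistent")
    n_excluded = int((~consistent).sum())
    if n_excluded:
        logger.info("excluded %d Mendelian-inconsistent trios", n_excluded)

    maf = np.full(n_markers, np.nan)
    for j in range(n_markers):
        parental = np.concatenate([father[j, consistent], mother[j, consistent]])
        parental = parental[parental >= 0]
        if parental.size:
            maf[j] = parental.sum() / (2.0 * parental.size)

    return MarkerPanel(
        father=father[:, consistent],
        mother=mother[:, consistent],
        offspring=offspring[:, consistent],
        maf=maf,
        marker_ids=marker_ids,
        trio_ids=[t for t, keep in zip(trio_ids, consistent) if keep],
    )


def read_phenotypes(
    path: str | Path,
    y_column: str = "Y",
    k_column: str = "K",
    l_columns: tuple[str, ...] = ("L1", "L2"),
    id_column: str = "iid",
) -> PhenotypeTable:
    """Read a delimited phenotype table (header required, any whitespace or
    tab/comma separator pandas can sniff)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (id_column, y_column, k_column, *l_columns):
        if col not in df.columns:
            raise KeyError(f"phenotype file {path} has no column {col!r}")
    for col in (y_column, k_column, *l_columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row + 2} of {path}"
            )
        df[col] = numeric
    return PhenotypeTable(
        y=df[y_column].to_numpy(float),
        k=df[k_column].to_numpy(float),
        covariates=df[list(l_columns)].to_numpy(float),
        covariate_names=list(l_columns),
        ids=df[id_column].astype(str).tolist(),
    )


def align_phenotypes(panel: MarkerPanel, phen: PhenotypeTable) -> PhenotypeTable:
    """Reorder phenotype rows to the panel's trios; unmatched IDs on either
    side are dropped (missing phenotypes become NaN and fall to the
    per-marker complete-case handling)."""
    if panel.trio_ids is None:
        if phen.n != panel.n_trios:
            raise ValueError("panel has no trio IDs and sizes differ")
        return phen
    index = {iid: i for i, iid in enumerate(phen.ids)}
    unmatched = [t for t in panel.trio_ids if t not in index]
    if unmatched:
        logger.info("%d panel trios have no phenotype row (NaN-filled)", len(unmatched))
    n = panel.n_trios
    y = np.full(n, np.nan)
    k = np.full(n, np.nan)
    cov = np.full((n, phen.covariates.shape[1]), np.nan)
    for i, tid in enumerate(panel.trio_ids):
        j = index.get(tid)
        if j is not None:
            y[i], k[i], cov[i] = phen.y[j], phen.k[j], phen.covariates[j]
    return PhenotypeTable(
        y=y, k=k, covariates=cov, covariate_names=phen.covariate_names, ids=list(panel.trio_ids)
    )
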