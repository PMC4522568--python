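"""Design grid construction, cell execution and result aggregation.

The full design crosses two population families with sample size (250,
1000), nine consistency levels (0.1..0.9) and three reliability bases
(0.6, 0.7, 0.8); CMm1 populations additionally vary the method-factor
correlation (0.2, 0.5, 0.8).  That yields 54 + 162 = 216 population cells,
each fit by all four model families: 864 grid entries, 864 000 fits at the
full 1000-replication profile.

Within a replication one dataset is drawn and every requested family is fit
to that same dataset.  Per-replication seeds derive deterministically from
(master seed, cell key, replication index), so results are identical
regardless of scheduling order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model_space import Family, build_model
from .population import (
    PopulationCell,
    CONSISTENCY_LEVELS,
    RELIABILITY_LEVELS,
    METHOD_CORRELATION_LEVELS,
    SAMPLE_SIZES,
    cell_reliabilities,
    derive_population_point,
    population_covariance,
    sample_dataset,
)
from .estimator import fit_ml
from .fit_evaluation import compute_indices, classify_fit
from .collapse import loading_profile

ALL_FAMILIES = (
    Family.UM_CONSTRAINED,
    Family.CMM1,
    Family.UM_UNCONSTRAINED,
    Family.CM,
)

FULL_REPLICATIONS = 1000
DEFAULT_REPLICATIONS = 100
CRITERIA = ("chi2", "rmsea", "cfi", "srmr")


def _cell_key(cell: PopulationCell) -> int:
    """Stable integer key of a cell (independent of jitter seed)."""
    return zlib.crc32(cell.cell_id.encode())


def _jitter_seed(master_seed: int, key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(key), 0x9E37])
    return int(ss.generate_state(1)[0] % (2**31))


def population_cells(master_seed: int = 0) -> list:
    """The 216 population cells in deterministic order."""
    cells = []

    def _make(fam, n, con, rel, corr):
        probe = PopulationCell(fam, n, con, rel, corr, jitter_seed=0)
        seed = _jitter_seed(master_seed, _cell_key(probe))
        return PopulationCell(fam, n, con, rel, corr, jitter_seed=seed)

    for n in SAMPLE_SIZES:
        for con in CONSISTENCY_LEVELS:
            for rel in RELIABILITY_LEVELS:
                cells.append(_make(Family.UM_CONSTRAINED, n, con, rel, 0.0))
    for n in SAMPLE_SIZES:
        for con in CONSISTENCY_LEVELS:
            for rel in RELIABILITY_LEVELS:
                for corr in METHOD_CORRELATION_LEVELS:
                    cells.append(_make(Family.CMM1, n, con, rel, corr))
    return cells


def build_grid(master_seed: int = 0) -> list:
    """All (population cell, fitted family) pairs — 864 entries."""
    return [(cell, fam) for cell in population_cells(master_seed) for fam in ALL_FAMILIES]


def total_fits(n_replications: int = FULL_REPLICATIONS, master_seed: int = 0) -> int:
    """Number of fits the grid implies at a replication count (counted, not run)."""
    return len(build_grid(master_seed)) * n_replications


@dataclass
class CellSummary:
    """Aggregated outcomes for one (population cell x fitted family)."""

    cell_id: str
    fitted_family: str
    population_family: str
    sample_size: int
    consistency: float
    reliability_base: float
    method_correlation: float
    master_seed: int
    n_requested: int
    n_converged: int
    n_theta_npd: int
    n_psi_npd: int
    reject_counts: dict = field(default_factory=dict)  # criterion -> count among converged
    nonsig_dist: dict = field(default_factory=dict)  # set -> [n0, n1, n2, n3]
    collapse_counts: dict = field(default_factory=dict)  # method -> count
    collapse_eligible: dict = field(default_factory=dict)  # method -> converged fits counted
    n_any_collapse: int = 0  # converged fits with >= 1 collapsed method factor

    @property
    def pct_convergence(self) -> float:
        return 100.0 * self.n_converged / self.n_requested

    @property
    def pct_theta_npd(self) -> float:
        return 100.0 * self.n_theta_npd / self.n_requested

    @property
    def pct_psi_npd(self) -> float:
        return 100.0 * self.n_psi_npd / self.n_requested

    def rejection_rate(self, criterion: str, denominator: str = "converged") -> float:
        """Percent rejected; denominator 'converged' (default) or 'requested'."""
        count = self.reject_counts.get(criterion, 0)
        denom = self.n_converged if denominator == "converged" else self.n_requested
        return 100.0 * count / denom if denom else float("nan")

    def collapse_rate(self, method: int) -> float:
        eligible = self.collapse_eligible.get(method, 0)
        return 100.0 * self.collapse_counts.get(method, 0) / eligible if eligible else float("nan")

    def to_record(self) -> dict:
        rec = asdict(self)
        rec["pct_convergence"] = self.pct_convergence
        rec["pct_theta_npd"] = self.pct_theta_npd
        rec["pct_psi_npd"] = self.pct_psi_npd
        return rec


def run_cell(
    cell: PopulationCell,
    fitted_families: Sequence[Family] = ALL_FAMILIES,
    n_replications: int = DEFAULT_REPLICATIONS,
    master_seed: int = 0,
    dialect: str = "wishart",
    record_sink: Optional[Callable[[dict], None]] = None,
    compute_fit_indices: bool = True,
    compute_se: bool = True,
) -> dict:
    """Run one population cell; returns {family: CellSummary}.

    ``compute_se=False`` skips standard errors and therefore the loading
    significance/collapse outcomes (useful when only convergence and
    improper-solution rates are required).

    One dataset is drawn per replication and every requested family is fit
    to it.  A fit that raises is contained: logged to the record sink and
    counted as non-converged.
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    fitted_families = [Family(f) for f in fitted_families]
    rel = cell_reliabilities(cell)
    point = derive_population_point(cell, rel)
    sigma_pop = population_covariance(cell)
    key = _cell_key(cell)

    specs = {
        fam: build_model(fam, 1 if fam is Family.CMM1 else None) for fam in fitted_families
    }
    summaries = {
        fam: CellSummary(
            cell_id=cell.cell_id,
            fitted_family=fam.value,
            population_family=cell.population_family.value,
            sample_size=cell.sample_size,
            consistency=cell.consistency,
            reliability_base=cell.reliability_base,
            method_correlation=cell.method_correlation,
            master_seed=master_seed,
            n_requested=n_replications,
            n_converged=0,
            n_theta_npd=0,
            n_psi_npd=0,
            reject_counts={c: 0 for c in CRITERIA},
            nonsig_dist={k: [0, 0, 0, 0] for k in range(1, 7)},
            collapse_counts={m: 0 for m in (1, 2, 3)},
            collapse_eligible={m: 0 for m in (1, 2, 3)},
        )
        for fam in fitted_families
    }

    for rep in range(n_replications):
        ss = np.random.SeedSequence([int(master_seed), int(key), int(rep)])
        rng = np.random.default_rng(ss)
        _, s = sample_dataset(sigma_pop, cell.sample_size, rng)
        for fam in fitted_families:
            summary = summaries[fam]
            record = {
                "cell_id": cell.cell_id,
                "replication": rep,
                "family": fam.value,
                "master_seed": master_seed,
            }
            try:
                fit = fit_ml(specs[fam], s, cell.sample_size, compute_se=compute_se)
            except Exception as exc:  # contained: counted as non-converged
                record.update({"converged": False, "error": repr(exc)})
                if record_sink is not None:
                    record_sink(record)
                continue
            record.update(
                {
                    "converged": fit.converged,
                    "iterations": fit.iterations,
                    "discrepancy": fit.discrepancy,
                    "theta_npd": fit.theta_npd,
                    "psi_npd": fit.psi_npd,
                }
            )
            if fit.converged:
                summary.n_converged += 1
                summary.n_theta_npd += int(fit.theta_npd)
                summary.n_psi_npd += int(fit.psi_npd)
                if compute_fit_indices:
                    idx = compute_indices(fit, specs[fam], s, cell.sample_size, dialect)
                    flags = classify_fit(idx)
                    for crit in CRITERIA:
                        summary.reject_counts[crit] += int(getattr(flags, f"reject_{crit}"))
                    record["indices"] = {
                        "chi_square": idx.chi_square,
                        "df": idx.df,
                        "p_value": idx.p_value,
                        "rmsea": idx.rmsea,
                        "cfi": idx.cfi,
                        "srmr": idx.srmr,
                    }
                if not compute_se:
                    if record_sink is not None:
                        record_sink(record)
                    continue
                profile = loading_profile(fit)
                for k, c in profile.nonsig_counts.items():
                    if c is not None:
                        summary.nonsig_dist[k][c] += 1
                for m, flag in profile.collapse.items():
                    if flag is not None:
                        summary.collapse_eligible[m] += 1
                        summary.collapse_counts[m] += int(flag)
                summary.n_any_collapse += int(
                    any(flag is True for flag in profile.collapse.values())
                )
                record["estimates"] = {k: float(v) for k, v in fit.point.values.items()}
                record["standard_errors"] = {
                    k: float(v) for k, v in fit.standard_errors.items()
                }
            if record_sink is not None:
                record_sink(record)

    # population manifest piggybacks on the first record sink call if wanted
    if record_sink is not None:
        record_sink(
            {
                "cell_id": cell.cell_id,
                "manifest": True,
                "reliabilities": rel.tolist(),
                "population_point": {k: float(v) for k, v in point.values.items()},
                "jitter_seed": cell.jitter_seed,
            }
        )
    return summaries


def run_grid(
    cells: Optional[Iterable[PopulationCell]] = None,
    fitted_families: Sequence[Family] = ALL_FAMILIES,
    n_replications: int = DEFAULT_REPLICATIONS,
    master_seed: int = 0,
    dialect: str = "wishart",
    record_sink: Optional[Callable[[dict], None]] = None,
    compute_fit_indices: bool = True,
    progress: Optional[Callable[[str], None]] = None,
) -> list:
    """Run many cells serially; returns a flat list of CellSummary."""
    if cells is None:
        cells = population_cells(master_seed)
    out: list = []
    for cell in cells:
        summaries = run_cell(
            cell,
            fitted_families,
            n_replications,
            master_seed,
            dialect,
            record_sink,
            compute_fit_indices,
        )
        out.extend(summaries.values())
        if progress is not None:
            progress(cell.cell_id)
    return out


def _pool(summaries: Iterable[CellSummary], numer, denom) -> pd.DataFrame:
    rows: dict = {}
    for s in summaries:
        k = (s.population_family, s.fitted_family)
        a, b = rows.get(k, (0, 0))
        rows[k] = (a + numer(s), b + denom(s))
    return rows


def aggregate_table2(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    """Pool convergence and improper-solution rates by (population, fitted).

    Mirrors the study's summary table: for each criterion block the count of
    problematic replications, the total requested, and the percentage to two
    decimals, with a grand-total row per block.
    """
    blocks = {
        "non_convergence": (lambda s: s.n_requested - s.n_converged, lambda s: s.n_requested),
        "theta_npd": (lambda s: s.n_theta_npd, lambda s: s.n_requested),
        "psi_npd": (lambda s: s.n_psi_npd, lambda s: s.n_requested),
    }
    records = []
    for crit, (numer, denom) in blocks.items():
        pooled = _pool(summaries, numer, denom)
        tot_a = tot_b = 0
        for (pop, fam), (a, b) in pooled.items():
            records.append(
                {
                    "criterion": crit,
                    "population_model": pop,
                    "fitted_model": fam,
                    "problematic": a,
                    "total": b,
                    "percent": round(100.0 * a / b, 2) if b else float("nan"),
                }
            )
            tot_a += a
            tot_b += b
        records.append(
            {
                "criterion": crit,
                "population_model": "all",
                "fitted_model": "all",
                "problematic": tot_a,
                "total": tot_b,
                "percent": round(100.0 * tot_a / tot_b, 2) if tot_b else float("nan"),
            }
        )
    return pd.DataFrame.from_records(records)


def rejection_rate_table(
    summaries: Sequence[CellSummary], denominator: str = "converged"
) -> pd.DataFrame:
    """Cell-level per-criterion rejection rates (fit-index outcomes)."""
    records = []
    for s in summaries:
        base = {
            "cell_id": s.cell_id,
            "population_model": s.population_family,
            "fitted_model": s.fitted_family,
            "sample_size": s.sample_size,
            "consistency": s.consistency,
            "reliability_base": s.reliability_base,
            "method_correlation": s.method_correlation,
            "n_requested": s.n_requested,
            "n_converged": s.n_converged,
        }
        for crit in CRITERIA:
            base[f"reject_{crit}_pct"] = s.rejection_rate(crit, denominator)
        records.append(base)
    return pd.DataFrame.from_records(records)


def loading_significance_table(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    """Cell-level distribution of non-significant loading counts per set."""
    records = []
    for s in summaries:
        for set_number in range(1, 7):
            dist = s.nonsig_dist[set_number]
            records.append(
                {
                    "cell_id": s.cell_id,
                    "population_model": s.population_family,
                    "fitted_model": s.fitted_family,
                    "sample_size": s.sample_size,
                    "consistency": s.consistency,
                    "method_correlation": s.method_correlation,
                    "set": set_number,
                    "n0": dist[0],
                    "n1": dist[1],
                    "n2": dist[2],
                    "n3": dist[3],
                }
            )
    return pd.DataFrame.from_records(records)


def summaries_to_json(summaries: Sequence[CellSummary]) -> str:
    return json.dumps([s.to_record() for s in summaries], indent=1)
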