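"""End-to-end analyses: from vial CSVs to structured, serializable reports.

Each ``run_*`` function chains the library modules for one named analysis
(half-sib variance components, two-group contrast, trait correlations,
power) and returns an :class:`AnalysisReport` carrying the results, an input
digest (file hashes and row counts), every seed used, and all data warnings.
Excluded records are always accounted for: input rows = used + excluded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .core_data_io import (LineTraitTable, MassRecord, VialCount,
                           read_line_traits, read_masses, read_vials)
from .mortality_index import compute_mi_pooled, paired_mi_records
from .power_sim import PowerConfig, simulate_power
from .resampling_stats import (bootstrap_correlation, cv_randomization_test,
                               levene_test, one_sample_t, student_t_test,
                               welch_t_test)
from .varcomp import anova_varcomp, fit_sire_model_records


class AnalysisError(ValueError):
    """The requested analysis cannot be run on these inputs."""


@dataclass
class AnalysisReport:
    analysis: str
    inputs: dict[str, Any] = field(default_factory=dict)
    results: dict[str, Any] = field(default_factory=dict)
    seeds: dict[str, int | None] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    n_input_rows: int = 0
    n_used: int = 0
    n_excluded: int = 0
    version: str = __version__

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _plain(obj):
    """Recursively convert numpy scalars/arrays and dataclasses to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _digest(path: str | Path | None, n_rows: int) -> dict:
    if path is None:
        return {"source": "<memory>", "n_rows": n_rows}
    data = Path(path).read_bytes()
    return {"source": str(path), "sha256": hashlib.sha256(data).hexdigest(),
            "n_rows": n_rows}


def _as_vials(vials: str | Path | Sequence[VialCount]
              ) -> tuple[list[VialCount], str | Path | None]:
    if isinstance(vials, (str, Path)):
        return read_vials(vials), vials
    return list(vials), None


# ---------------------------------------------------------------------------
# half-sib pipeline
# ---------------------------------------------------------------------------

def run_halfsib(vials: str | Path | Sequence[VialCount],
                include_block: bool = True, cva_weighted: bool = False,
                strict: bool = False) -> AnalysisReport:
    """Half-sib analysis: dam-level MI -> REML sire variance -> LRT -> VA/h2/CVA.

    Dams lacking a usable hit/sham pair are excluded with a logged warning
    (mirroring dams that produced no offspring); ``strict=True`` raises on
    any such dam.  The expected-mean-squares (ANOVA) estimate is reported
    alongside the REML fit as an independent cross-check.
    """
    records, path = _as_vials(vials)
    mi_records, warnings = paired_mi_records(records, strict=strict)
    if not mi_records:
        raise AnalysisError("no complete hit/sham pairs in input")
    fit = fit_sire_model_records(mi_records, include_block=include_block,
                                 cva_weighted=cva_weighted)
    mom = anova_varcomp([r.mi for r in mi_records],
                        [r.group_id for r in mi_records])
    n_units = len({(v.group_id, v.unit_id) for v in records})
    report = AnalysisReport(analysis="halfsib")
    report.inputs["vials"] = _digest(path, len(records))
    report.results["varcomp"] = fit
    report.results["anova_oracle"] = mom
    report.results["mi_records"] = mi_records
    report.warnings = warnings
    report.n_input_rows = n_units
    report.n_used = len(mi_records)
    report.n_excluded = n_units - len(mi_records)
    return report


# ---------------------------------------------------------------------------
# two-group pipeline
# ---------------------------------------------------------------------------

def run_group_comparison(vials: str | Path | Sequence[VialCount],
                         masses: str | Path | Sequence[MassRecord] | None = None,
                         design: str = "paired", n_reps: int = 10_000,
                         seed: int | None = None, strict: bool = False,
                         cv_test: bool = True) -> AnalysisReport:
    """Two-group MI contrast with optional body-mass comparison.

    MI per unit (paired design) or per hit vial against the group's pooled
    sham baseline (pooled design); Student t on MI between groups, one-sample
    t of all MI against 0 (overall trauma-induced mortality), fold change of
    group means, CV randomization test, and — when masses are provided — a
    Levene-gated t-test on mass (Welch when Levene rejects at 0.05).
    """
    if design not in ("paired", "pooled"):
        raise AnalysisError("design must be 'paired' or 'pooled'")
    records, path = _as_vials(vials)
    groups = sorted({v.group_id for v in records})
    if len(groups) != 2:
        raise AnalysisError(
            f"exactly two groups required, got {len(groups)}: {groups}; "
            "run pairwise comparisons for more groups")
    warnings: list[str] = []
    if design == "paired":
        mi_records, warnings = paired_mi_records(records, strict=strict)
        n_units = len({(v.group_id, v.unit_id) for v in records})
    else:
        mi_records = []
        for g in groups:
            hit = [v for v in records if v.group_id == g and v.treatment == "hit"]
            sham = [v for v in records if v.group_id == g and v.treatment == "sham"]
            mi_records.extend(compute_mi_pooled(hit, sham))
        n_units = sum(1 for v in records if v.treatment == "hit")
    by_group = {g: np.array([r.mi for r in mi_records if r.group_id == g])
                for g in groups}
    a, b = groups
    if len(by_group[a]) < 2 or len(by_group[b]) < 2:
        raise AnalysisError("each group needs at least two MI values")

    report = AnalysisReport(analysis=f"group_comparison[{design}]")
    report.inputs["vials"] = _digest(path, len(records))
    report.seeds["cv_randomization"] = seed
    t_mi = student_t_test(by_group[a], by_group[b])
    report.results["mi_t_test"] = t_mi
    all_mi = np.concatenate([by_group[a], by_group[b]])
    report.results["overall_mi_t_vs_zero"] = one_sample_t(all_mi, 0.0)
    report.results["mean_mi_overall"] = float(all_mi.mean())
    mean_a, mean_b = float(by_group[a].mean()), float(by_group[b].mean())
    report.results["group_means"] = {a: mean_a, b: mean_b}
    if mean_a != 0:
        report.results["fold_change_b_over_a"] = mean_b / mean_a
    if cv_test:
        report.results["cv_comparison"] = cv_randomization_test(
            by_group[a], by_group[b], n_reps=n_reps, seed=seed)
    if masses is not None:
        if isinstance(masses, (str, Path)):
            mass_records, mass_path = read_masses(masses), masses
        else:
            mass_records, mass_path = list(masses), None
        report.inputs["masses"] = _digest(mass_path, len(mass_records))
        by_sex: dict[str, dict[str, np.ndarray]] = {}
        for sex in sorted({m.sex for m in mass_records}):
            by_sex[sex] = {g: np.array([m.dry_mass for m in mass_records
                                        if m.sex == sex and m.group_id == g])
                           for g in groups}
        mass_results = {}
        for sex, vals in by_sex.items():
            if len(vals[a]) < 2 or len(vals[b]) < 2:
                warnings.append(f"mass comparison skipped for sex={sex}: too few records")
                continue
            lev = levene_test(vals[a], vals[b])
            t_fn = welch_t_test if lev.p < 0.05 else student_t_test
            mass_results[sex] = {"levene": lev, "t_test": t_fn(vals[a], vals[b]),
                                 "mean_reduction_fraction":
                                     1.0 - vals[b].mean() / vals[a].mean()}
        report.results["mass_comparison"] = mass_results
    report.warnings = warnings
    report.n_input_rows = n_units
    report.n_used = len(mi_records)
    report.n_excluded = n_units - len(mi_records)
    return report


# ---------------------------------------------------------------------------
# correlations and power
# ---------------------------------------------------------------------------

def run_correlations(table: str | Path | LineTraitTable,
                     pairs: Sequence[tuple[str, str]],
                     n_reps: int = 10_000, seed: int | None = None) -> AnalysisReport:
    """Bootstrap Pearson correlation for each named trait pair (complete pairs)."""
    if isinstance(table, (str, Path)):
        tab, path = read_line_traits(table), table
    else:
        tab, path = table, None
    report = AnalysisReport(analysis="correlations")
    report.inputs["line_traits"] = _digest(path, len(tab))
    report.n_input_rows = len(tab)
    used = 0
    for k, (tx, ty) in enumerate(pairs):
        for t in (tx, ty):
            if t not in tab.traits:
                raise AnalysisError(f"unknown trait {t!r}; available: {tab.traits}")
        x, y = tab.complete_pairs(tx, ty)
        pair_seed = None if seed is None else seed + k
        est = bootstrap_correlation(x, y, n_reps=n_reps, seed=pair_seed)
        report.results[f"{tx}~{ty}"] = est
        report.seeds[f"{tx}~{ty}"] = pair_seed
        used = max(used, est.n)
    report.n_used = used
    report.n_excluded = report.n_input_rows - used
    return report


def run_power(config: PowerConfig) -> AnalysisReport:
    report = AnalysisReport(analysis="power")
    report.seeds["power"] = config.seed
    report.n_input_rows = (len(config.empirical_sample)
                           if config.empirical_sample is not None else 0)
    report.n_used = report.n_input_rows
    report.results["power"] = simulate_power(config)
    return report
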