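"""End-to-end orchestration: simulate -> fit -> LPA -> cutoffs -> classify -> stats.

``run_pipeline`` executes the whole workflow on synthetic cohorts and
writes every intermediate artifact plus a manifest (seed, parameters,
sha256 checksums), so a fixed (config, seed) pair yields byte-identical
numeric outputs.  The top-level seed is fanned out to per-stage child
seeds through ``numpy.random.SeedSequence``, so stages are reproducible
in isolation.

``fixture_mode`` bypasses simulation entirely and runs the contingency
statistics directly on the published count tables (transcribed in
:mod:`phenocut.defaults`), reproducing the published chi-square
statistics exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .classifier import build_cutoffs, classify_cohort, classify_recovery, reference_cutoffs
from .cohort_io import write_cohort
from .contingency_stats import chi_square, incidence_table, recovery_table
from .dist_fit import compare_fits, describe
from .lpa import fit_lpa, select_model
from .synthetic_cohorts import (
    all_stress_scenarios,
    naive_mixture_spec,
    simulate_naive_mixture,
    simulate_stressed_cohort,
    simulate_treatment_response,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "fixture_mode"]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort run.

    Defaults encode the modelled study design: a naive reference cohort
    of 309 drawn from the four-class profile, stress groups of
    120/111/122/99, percentile cutoff levels 5/10 (mirrored 95/85), and
    LPA over K = 1..5.
    """

    seed: int = 0
    naive_n: int = defaults.NAIVE_N
    group_sizes: dict = field(default_factory=lambda: dict(defaults.GROUP_SIZES))
    percentile_method: str = "weibull"
    cutoff_levels: tuple = (0.05, 0.10)
    k_range: tuple = (1, 5)
    lpa_restarts: int = 30
    lpa_max_iter: int = 500
    lpa_tol: float = 1e-8
    variance_structure: str = "shared"
    output_dir: str = "phenocut_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        cfg.cutoff_levels = tuple(cfg.cutoff_levels)
        cfg.k_range = tuple(cfg.k_range)
        return cfg


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 8)
    artifacts: dict[str, str] = {}
    cutoffs_published = reference_cutoffs()

    def register(name: str, path: Path) -> None:
        artifacts[name] = str(path)
        logger.info("stage artifact %s -> %s", name, path)

    # ---- stage 1: simulate cohorts -------------------------------------
    naive, labels = simulate_naive_mixture(
        config.naive_n, naive_mixture_spec(), seed=seeds[0]
    )
    naive_path = out / "naive_cohort.csv"
    write_cohort(naive, naive_path)
    register("naive_cohort", naive_path)

    scenarios = all_stress_scenarios(cutoffs=cutoffs_published)
    stress_seeds = _child_seeds(seeds[1], len(scenarios))
    stressed = {}
    for s, (group, scenario) in zip(stress_seeds, scenarios.items()):
        scenario.n = config.group_sizes.get(group, scenario.n)
        cohort = simulate_stressed_cohort(scenario, seed=s)
        stressed[group] = cohort
        path = out / f"stressed_{group.replace('+', 'plus')}.csv"
        write_cohort(cohort, path)
        register(f"stressed_{group}", path)

    # ---- stage 2: descriptives and distribution fits -------------------
    spt = naive.values("spt_rate")
    fst = naive.values("fst_immobility_s")
    dist_report = {
        "spt_rate": {
            "describe": asdict(describe(spt)),
            "fits": compare_fits(spt, ["beta", "normal"]).to_dict("records"),
        },
        "fst_immobility_s": {
            "describe": asdict(describe(fst)),
            "fits": compare_fits(fst, ["gamma", "normal"]).to_dict("records"),
        },
    }
    dist_path = out / "dist_fits.json"
    _write_json(dist_path, dist_report)
    register("dist_fits", dist_path)

    # ---- stage 3: latent profile analysis ------------------------------
    data = np.column_stack([spt, fst])
    k_lo, k_hi = config.k_range
    lpa_seeds = _child_seeds(seeds[2], k_hi - k_lo + 1)
    fits = [
        fit_lpa(
            data, K, restarts=config.lpa_restarts, max_iter=config.lpa_max_iter,
            tol=config.lpa_tol, variance_structure=config.variance_structure,
            seed=s,
        )
        for K, s in zip(range(k_lo, k_hi + 1), lpa_seeds)
    ]
    selection = select_model(fits)
    sel_path = out / "selection_table.csv"
    selection.to_dataframe().to_csv(sel_path, index=False)
    register("selection_table", sel_path)
    best_fit = fits[selection.chosen_K - k_lo]
    post_path = out / "posteriors.csv"
    pd.DataFrame(
        best_fit.posteriors,
        columns=[f"class_{k + 1}" for k in range(best_fit.K)],
    ).assign(assigned=best_fit.assignments + 1).to_csv(post_path, index=False)
    register("posteriors", post_path)

    # ---- stage 4: percentile cutoffs -----------------------------------
    built_cutoffs = build_cutoffs(
        naive, method=config.percentile_method, levels=config.cutoff_levels
    )
    cut_path = out / "cutoffs.json"
    cut_path.write_text(built_cutoffs.to_json())
    register("cutoffs", cut_path)

    # ---- stage 5: classification + treatment ---------------------------
    call_rows = []
    stats_report: dict = {"incidence": {}, "recovery": {}}
    classified_all = {}
    treat_seeds = dict(zip(stressed, _child_seeds(seeds[3], len(stressed))))
    for group, cohort in stressed.items():
        classified = classify_cohort(cohort, cutoffs_published)
        treated = simulate_treatment_response(
            cohort, classified.calls, scenarios[group], seed=treat_seeds[group],
        )
        for rec, call in zip(treated, classified.calls):
            if rec.arm == "escitalopram":
                call.recovery = classify_recovery(
                    call, rec.post_spt_rate, rec.post_fst_immobility_s,
                    cutoffs_published,
                )
        classified_all[group] = classified
        for call in classified.calls:
            call_rows.append(
                {
                    "animal_id": call.animal_id,
                    "group": call.group,
                    "anhedonia": call.categories["spt_rate"],
                    "despair": call.categories["fst_immobility_s"],
                    "stress_resilient": call.joint_stress_resilient,
                    "anhedonia_recovery": call.recovery.get("spt_rate", ""),
                    "despair_recovery": call.recovery.get("fst_immobility_s", ""),
                }
            )
    calls_path = out / "phenotype_calls.csv"
    pd.DataFrame(call_rows).to_csv(calls_path, index=False)
    register("phenotype_calls", calls_path)

    # ---- stage 6: contingency statistics -------------------------------
    merged = ClassifiedMerge(classified_all)
    for index, axis in (("spt_rate", "anhedonia"), ("fst_immobility_s", "despair")):
        for category in ("affected", "sub", "resilient"):
            table = incidence_table(merged, index, category)
            res = chi_square(table)
            stats_report["incidence"][f"{axis}_{category}"] = {
                "observed": table.to_dict(),
                "chi2": res.chi2, "df": res.df, "p": res.p,
            }
        for category in ("affected", "sub"):
            try:
                table = recovery_table(merged, index, category)
                res = chi_square(table)
                stats_report["recovery"][f"{axis}_{category}"] = {
                    "observed": table.to_dict(),
                    "chi2": res.chi2, "df": res.df, "p": res.p,
                }
            except ValueError as exc:
                stats_report["recovery"][f"{axis}_{category}"] = {"note": str(exc)}
    stats_path = out / "stats.json"
    _write_json(stats_path, stats_report)
    register("stats", stats_path)

    manifest = {
        "seed": config.seed,
        "config": {**asdict(config)},
        "chosen_K": selection.chosen_K,
        "selection_rationale": selection.rationale,
        "artifacts": artifacts,
        "checksums": {name: _sha256(Path(p)) for name, p in artifacts.items()},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


class ClassifiedMerge:
    """Duck-typed merge of per-group :class:`ClassifiedCohort` objects so
    the tabulation helpers see one cohort spanning all groups."""

    def __init__(self, by_group: dict):
        self.calls = [c for cc in by_group.values() for c in cc.calls]
        self.excluded = [e for cc in by_group.values() for e in cc.excluded]

    def category_counts(self, index: str):
        from .classifier import ClassifiedCohort

        return ClassifiedCohort(calls=self.calls).category_counts(index)


def fixture_mode(fixtures: Optional[dict] = None) -> dict:
    """Contingency statistics straight from published count tables.

    ``fixtures`` maps a label to {"group": (in_category, total)} pairs;
    when omitted, the transcribed incidence and recovery tables of the
    modelled study are used, reproducing its ten chi-square statistics.
    An empty fixture dict yields an explicit nothing-to-compute report.
    """
    if fixtures is None:
        fixtures = builtin_fixtures()
    if not fixtures:
        return {"note": "nothing to compute: empty fixture set"}
    report = {}
    for label, counts in fixtures.items():
        try:
            table = pd.DataFrame.from_dict(
                {
                    g: (int(k), int(n) - int(k))
                    for g, (k, n) in counts.items()
                },
                orient="index",
                columns=["in_category", "rest"],
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed fixture {label!r}: {exc}") from exc
        res = chi_square(table)
        report[label] = {
            "observed": table.to_dict(),
            "chi2": res.chi2,
            "chi2_2dp": round(res.chi2, 2),
            "df": res.df,
            "p": res.p,
            "warnings": res.warnings,
        }
    return report


def builtin_fixtures() -> dict:
    """The ten published category-vs-rest tables as (count, total) pairs."""
    out: dict = {}
    for axis, counts in (
        ("anhedonia", defaults.ANHEDONIA_COUNTS),
        ("despair", defaults.DESPAIR_COUNTS),
    ):
        for j, cat in enumerate(("affected", "sub", "resilient")):
            out[f"{axis}_{cat}"] = {
                g: (counts[g][j], defaults.GROUP_SIZES[g]) for g in counts
            }
    for kind, table in defaults.RECOVERY_COUNTS.items():
        out[f"recovery_{kind}"] = dict(table)
    return out
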