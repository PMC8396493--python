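"""End-to-end analysis: records → life tables → parameters → comparisons.

:func:`run_pipeline` ties the package together: it takes either observed
records or generative configurations (in which case the cohorts are
simulated first), builds one life table per diet, computes Birch's
parameters with jackknife standard errors, performs all unadjusted pairwise
diet comparisons per parameter, assigns compact letter groups, and emits the
descriptive stage/reproduction summaries — optionally writing CSVs, lx/mx
plots and a machine-readable ``results.json`` to an output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import DEFAULT_TOL, PARAMETERS
from .errors import InputError
from .io import write_records
from .jackknife_inference import compare_diets, jackknife_all, letter_groups
from .life_table import build_life_table
from .records import split_by_diet
from .stage_summaries import summarize_reproduction, summarize_stages
from .synthetic_cohort import generate_cohort

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _meanse_dict(v):
    if v is None:
        return None
    return {"mean": v.mean, "se": v.se, "n": v.n}


def run_pipeline(
    records=None,
    *,
    configs=None,
    seed: int | None = None,
    out_dir=None,
    progeny_female_fraction: float | None = None,
    alpha: float = 0.05,
    tol: float = DEFAULT_TOL,
    pivotal_age: bool = False,
    make_plots: bool = True,
) -> dict:
    """Run the full analysis and return the results dictionary.

    Exactly one of ``records`` (individual records, possibly several diets)
    or ``configs`` (list of :class:`CohortConfig` to simulate) must be given.
    ``seed``, when provided with ``configs``, reseeds the per-diet streams
    deterministically.  ``progeny_female_fraction`` defaults to each config's
    own value when simulating, and to 0.67 for observed records.
    """
    if (records is None) == (configs is None):
        raise InputError("pass exactly one of records= or configs=")

    pff_by_diet: dict[str, float] = {}
    if configs is not None:
        all_records = []
        for k, cfg in enumerate(configs):
            if seed is not None:
                cfg = cfg.with_seed(int(seed) + k)
            cfg.validate()
            logger.info("simulating %d eggs on diet %r (seed %d)",
                        cfg.n_eggs, cfg.diet_label, cfg.seed)
            all_records.extend(generate_cohort(cfg))
            pff_by_diet[cfg.diet_label] = cfg.progeny_female_fraction
        records = all_records

    cohorts = split_by_diet(records)
    if not cohorts:
        raise InputError("no records to analyze")

    results: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "options": {
            "alpha": alpha,
            "tol": tol,
            "pivotal_age": pivotal_age,
            "progeny_female_fraction": progeny_female_fraction,
        },
        "diets": {},
        "comparisons": {},
        "letters": {},
    }

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_records(records, out / "records.csv")

    tables, estimates = {}, {}
    for diet, recs in cohorts.items():
        pff = (progeny_female_fraction
               if progeny_female_fraction is not None
               else pff_by_diet.get(diet, 0.67))
        lt = build_life_table(recs, pff)
        tables[diet] = lt
        estimates[diet] = jackknife_all(recs, pff, tol, pivotal_age=pivotal_age)
        stages = summarize_stages(recs)
        repro = summarize_reproduction(recs)
        results["diets"][diet] = {
            "n_initial": lt.n_initial,
            "n_females": lt.n_females,
            "progeny_female_fraction": pff,
            "params": {
                name: {
                    "theta_all": est.theta_all,
                    "estimate": est.estimate,
                    "se": est.se,
                    "n": est.n,
                    "n_effective": est.n_effective,
                }
                for name, est in estimates[diet].items()
            },
            "stage_summary": {
                "stage_durations": {
                    s: _meanse_dict(v) for s, v in stages.stage_durations.items()
                },
                "egg_to_female": _meanse_dict(stages.egg_to_female),
                "egg_to_male": _meanse_dict(stages.egg_to_male),
                "egg_to_adult": _meanse_dict(stages.egg_to_adult),
                "stage_survival_pct": stages.stage_survival_pct,
                "maturity_pct": stages.maturity_pct,
            },
            "reproduction": {
                "n_females": repro.n_females,
                "n_ovipositing": repro.n_ovipositing,
                **{
                    q: _meanse_dict(getattr(repro, q))
                    for q in ("total_fecundity", "oviposition_rate", "longevity",
                              "preoviposition", "oviposition", "postoviposition")
                },
            },
        }
        if out is not None:
            lt.to_csv(out / f"life_table_{diet.replace(' ', '_')}.csv")
            stages.to_frame().to_csv(
                out / f"stage_summary_{diet.replace(' ', '_')}.csv", index=False)
            repro.to_frame().to_csv(
                out / f"reproduction_{diet.replace(' ', '_')}.csv", index=False)

    diets = list(cohorts)
    if len(diets) >= 2:
        for name in PARAMETERS:
            comps = [
                compare_diets(estimates[a][name], estimates[b][name])
                for i, a in enumerate(diets) for b in diets[i + 1:]
            ]
            results["comparisons"][name] = [
                {"diet_a": c.diet_a, "diet_b": c.diet_b,
                 "difference": c.difference, "t": c.t_statistic,
                 "df": c.df, "p": c.p_value}
                for c in comps
            ]
            results["letters"][name] = letter_groups(
                comps, {d: estimates[d][name].estimate for d in diets}, alpha)

    if out is not None:
        parameter_table(results).to_csv(out / "demographic_parameters.csv")
        if results["comparisons"]:
            pd.concat({
                name: pd.DataFrame(rows)
                for name, rows in results["comparisons"].items()
            }, names=["parameter", ""]).to_csv(out / "comparisons.csv")
        if make_plots:
            plot_life_tables(list(tables.values()), out / "lx_mx.png")
        (out / "results.json").write_text(
            json.dumps(_jsonify(results), indent=2))
        logger.info("pipeline outputs written to %s", out)
    return results


def parameter_table(results: dict) -> pd.DataFrame:
    """Demographic parameters as one row per parameter, one column per diet,
    formatted ``estimate ± SE letter`` (letters only when comparisons exist)."""
    diets = list(results["diets"])
    rows = {}
    for name in PARAMETERS:
        row = {}
        for d in diets:
            p = results["diets"][d]["params"][name]
            cell = f"{p['estimate']:.3f} ± {p['se']:.3f}"
            letter = results.get("letters", {}).get(name, {}).get(d)
            row[d] = cell + (f" {letter}" if letter else "")
        rows[name] = row
    return pd.DataFrame(rows).T.rename_axis("parameter")


def plot_life_tables(tables, path) -> None:
    """Paired lx (solid, left axis) and mx (dashed, right axis) curves,
    one panel per diet."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(tables)
    fig, axes = plt.subplots(n, 1, figsize=(7, 2.6 * n), squeeze=False, sharex=True)
    for ax, lt in zip(axes.ravel(), tables):
        ax.plot(lt.ages, lt.lx, "-", color="tab:blue", label="$l_x$")
        ax.set_ylabel("$l_x$", color="tab:blue")
        ax.set_ylim(0, 1.05)
        ax2 = ax.twinx()
        ax2.plot(lt.ages, lt.mx, "--", color="tab:red", label="$m_x$")
        ax2.set_ylabel("$m_x$", color="tab:red")
        ax2.set_ylim(bottom=0)
        ax.set_title(lt.diet_label, fontsize=10)
    axes.ravel()[-1].set_xlabel("age (days since egg deposition)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
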