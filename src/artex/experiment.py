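"""Run an artificial-extinction plan end to end and summarize trends.

Each job: fossilize the subjects, run the implied-weights parsimony
search, take the strict consensus of the optimal trees, and score it
against the well-corroborated reference (shared splits, shared quartets,
per-subject placement accuracy in both strict and lenient modes).  Rows
are logged incrementally to a TSV so long runs are resumable; per-job
seeds make the result independent of execution order.

Aggregation weights templates equally (the published per-template means
are the quantity of interest, not per-job means) and fits ordinary
least-squares slopes of mean congruence on template completeness per
(group size, state mode) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .congruence import ReferenceTreeConfig, collapse_low_support, subject_accuracy
from .fossilize import ExperimentPlan, fossilize_matrix
from .matrix import CharacterMatrix
from .parsimony import SearchConfig, search, strict_consensus, tied_leaf_placements
from .treeutils import PhyloTree

__all__ = ["run_experiment", "aggregate", "TrendSummary", "CONGRUENCE_INDICES"]

CONGRUENCE_INDICES = (
    "shared_splits",
    "shared_quartets",
    "accuracy_strict",
    "accuracy_lenient",
)

_COLUMNS = [
    "job_id", "template", "completeness", "group_size", "mode", "subjects",
    "shared_splits", "shared_quartets", "accuracy_strict", "accuracy_lenient",
    "best_fit", "n_trees", "error",
]


def _run_job(matrix, job, templates, reference, root_taxon, search_config):
    fossilized = fossilize_matrix(matrix, job, templates)
    cfg = SearchConfig(
        k=search_config.k,
        n_addition_replicates=search_config.n_addition_replicates,
        swap=search_config.swap,
        max_trees_held=search_config.max_trees_held,
        seed=job.seed,
    )
    result = search(fossilized, cfg)
    # subject placements are the dominant source of equally optimal trees;
    # enumerate each subject's tied reattachment positions explicitly so the
    # strict consensus reflects genuine placement ambiguity
    trees = list(result.trees)
    trees += tied_leaf_placements(
        fossilized, result.trees[0], job.subjects, k=cfg.k
    )
    consensus = strict_consensus(list({t: None for t in trees}))
    res_strict = subject_accuracy(
        consensus, reference, job.subjects, root_taxon, "strict"
    )
    res_lenient = subject_accuracy(
        consensus, reference, job.subjects, root_taxon, "lenient"
    )
    return {
        "shared_splits": res_strict.shared_splits,
        "shared_quartets": res_strict.shared_quartets,
        "accuracy_strict": res_strict.accuracy,
        "accuracy_lenient": res_lenient.accuracy,
        "best_fit": result.best_fit,
        "n_trees": len(result.trees),
    }


def run_experiment(
    matrix: CharacterMatrix,
    templates,
    reference: PhyloTree,
    plan: ExperimentPlan,
    search_config: SearchConfig | None = None,
    *,
    root_taxon: str | None = None,
    reference_config: ReferenceTreeConfig | None = None,
    out_path=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute every job of *plan*; returns one row per job.

    If *out_path* exists, previously completed job ids are skipped and new
    rows appended (resumable runs).  Job failures are recorded in the
    ``error`` column and do not stop the run.
    """
    if search_config is None:
        search_config = SearchConfig()
    if root_taxon is None:
        root_taxon = sorted(set(matrix.taxa) - {s for j in plan for s in j.subjects})[0]
    tdict = {t.name: t for t in templates}
    ref = collapse_low_support(reference, reference_config or ReferenceTreeConfig())

    done: dict[str, dict] = {}
    fh = None
    if out_path is not None:
        out_path = Path(out_path)
        if out_path.exists():
            prev = pd.read_csv(out_path, sep="\t", dtype={"error": str})
            done = {r["job_id"]: r.to_dict() for _, r in prev.iterrows()}
        else:
            out_path.parent.mkdir(parents=True, exist_ok=True)
            out_path.write_text("\t".join(_COLUMNS) + "\n")
        fh = open(out_path, "a")

    rows = []
    n_failed = 0
    try:
        for i, job in enumerate(plan):
            if job.job_id in done:
                rows.append(done[job.job_id])
                continue
            row = {
                "job_id": job.job_id,
                "template": job.template,
                "completeness": tdict[job.template].completeness,
                "group_size": job.group_size,
                "mode": job.mode,
                "subjects": ";".join(job.subjects),
                "error": "",
            }
            try:
                row.update(
                    _run_job(matrix, job, tdict, ref, root_taxon, search_config)
                )
            except Exception as exc:  # pragma: no cover - defensive per-row capture
                row["error"] = f"{type(exc).__name__}: {exc}"
                n_failed += 1
            rows.append(row)
            if fh is not None:
                fh.write(
                    "\t".join(str(row.get(c, "")) for c in _COLUMNS) + "\n"
                )
                fh.flush()
            if progress and (i + 1) % 20 == 0:
                print(f"  {i + 1}/{len(plan)} jobs done", flush=True)
    finally:
        if fh is not None:
            fh.close()
    if n_failed == len(plan) and len(plan) > 0:
        raise RuntimeError("every job in the experiment failed")
    df = pd.DataFrame(rows)
    return df.reindex(columns=_COLUMNS)


# ----------------------------------------------------------------------
# aggregation


@dataclass
class TrendSummary:
    """Per-stratum congruence means and congruence-vs-completeness slopes."""

    group_stats: pd.DataFrame  # indexed (template, group_size, mode)
    slopes: pd.DataFrame       # rows (group_size, mode, index)
    n_excluded: int            # failed/missing rows left out

    def slope(self, index: str, group_size: int, mode: str = "real") -> float:
        s = self.slopes
        row = s[
            (s["group_size"] == group_size)
            & (s["mode"] == mode)
            & (s["index"] == index)
        ]
        return float(row["slope"].iloc[0]) if len(row) else float("nan")


def aggregate(table: pd.DataFrame) -> TrendSummary:
    """Template-weighted means and OLS congruence-on-completeness slopes."""
    import statsmodels.api as sm

    if table.empty:
        raise ValueError("empty result table")
    ok = table[(table["error"].isna()) | (table["error"] == "")].copy()
    n_excluded = len(table) - len(ok)
    for col in CONGRUENCE_INDICES + ("completeness",):
        ok[col] = pd.to_numeric(ok[col])

    group_stats = (
        ok.groupby(["template", "group_size", "mode"])
        .agg(
            completeness=("completeness", "first"),
            n_jobs=("job_id", "count"),
            **{
                f"{ix}_{stat}": (ix, stat)
                for ix in CONGRUENCE_INDICES
                for stat in ("mean", "std")
            },
        )
    )

    rows = []
    means = group_stats.reset_index()
    for (g, mode), sub in means.groupby(["group_size", "mode"]):
        x = sub["completeness"].to_numpy(dtype=float)
        for ix in CONGRUENCE_INDICES:
            y = sub[f"{ix}_mean"].to_numpy(dtype=float)
            keep = ~np.isnan(y)
            n_levels = len(np.unique(x[keep]))
            if n_levels < 3:
                slope = se = pval = r2 = float("nan")
            else:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    fit = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
                    slope, se = fit.params[1], fit.bse[1]
                    pval, r2 = fit.pvalues[1], fit.rsquared
            rows.append(
                {
                    "group_size": g,
                    "mode": mode,
                    "index": ix,
                    "slope": slope,
                    "stderr": se,
                    "pvalue": pval,
                    "r_squared": r2,
                    "n_levels": n_levels,
                }
            )
    return TrendSummary(
        group_stats=group_stats,
        slopes=pd.DataFrame(rows),
        n_excluded=n_excluded,
    )
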