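"""Model-style front end: build an artificial-extinction experiment from
data, fit it, and inspect results.

``ArtificialExtinction`` holds the design (matrix, templates, reference,
subject pool, group sizes, state modes); ``fit()`` executes the plan and
returns an ``ArtificialExtinctionResults`` carrying the per-job table,
per-template congruence means with dispersions, congruence-vs-completeness
OLS slopes with standard errors, a text ``summary()``, and plotting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .congruence import ReferenceTreeConfig
from .experiment import CONGRUENCE_INDICES, TrendSummary, aggregate, run_experiment
from .fossilize import ExperimentPlan, enumerate_plan
from .matrix import CharacterMatrix
from .parsimony import SearchConfig
from .treeutils import PhyloTree

__all__ = ["ArtificialExtinction", "ArtificialExtinctionResults"]


class ArtificialExtinction:
    """Artificial-extinction experiment over a combined character matrix.

    Parameters
    ----------
    matrix : CharacterMatrix
        Extant taxa only (fossil rows removed beforehand).
    templates : list of Template
        Fossil character-coverage masks over the morphology partition.
    reference : PhyloTree
        Well-corroborated reference with support values; weakly supported
        nodes are collapsed per *reference_config* before scoring.
    root_taxon : str, optional
        Outgroup used for rooting in accuracy scoring; excluded from the
        subject pool.  Defaults to the alphabetically first taxon.
    group_sizes, modes, replicates_per_template
        Design axes passed to :func:`artex.fossilize.enumerate_plan`.
    """

    def __init__(
        self,
        matrix: CharacterMatrix,
        templates,
        reference: PhyloTree,
        *,
        root_taxon: str | None = None,
        subject_pool=None,
        group_sizes=(1, 2, 4, 8, 16, 32),
        modes=("real", "random"),
        replicates_per_template: int | None = None,
        reference_config: ReferenceTreeConfig | None = None,
    ):
        self.matrix = matrix
        self.templates = list(templates)
        self.reference = reference
        self.root_taxon = root_taxon or sorted(matrix.taxa)[0]
        self.subject_pool = [
            t for t in (subject_pool or matrix.taxa) if t != self.root_taxon
        ]
        self.group_sizes = tuple(group_sizes)
        self.modes = tuple(modes)
        self.replicates_per_template = replicates_per_template
        self.reference_config = reference_config or ReferenceTreeConfig()

    @classmethod
    def from_study(cls, study, **kwargs):
        """Build from a :class:`artex.simulate.SyntheticStudy`."""
        kwargs.setdefault("root_taxon", study.root_taxon)
        return cls(study.matrix, study.templates, study.reference, **kwargs)

    def plan(self, seed: int = 0) -> ExperimentPlan:
        return enumerate_plan(
            self.subject_pool,
            self.templates,
            group_sizes=self.group_sizes,
            modes=self.modes,
            master_seed=seed,
            replicates_per_template=self.replicates_per_template,
            root_taxon=self.root_taxon,
        )

    def fit(
        self,
        seed: int = 0,
        search_config: SearchConfig | None = None,
        out_path=None,
        progress: bool = False,
    ) -> "ArtificialExtinctionResults":
        plan = self.plan(seed)
        table = run_experiment(
            self.matrix,
            self.templates,
            self.reference,
            plan,
            search_config,
            root_taxon=self.root_taxon,
            reference_config=self.reference_config,
            out_path=out_path,
            progress=progress,
        )
        return ArtificialExtinctionResults(self, plan, table)


class ArtificialExtinctionResults:
    """Fitted artificial-extinction experiment."""

    def __init__(self, model: ArtificialExtinction, plan: ExperimentPlan, table):
        self.model = model
        self.plan = plan
        self.table = table
        self._trends: TrendSummary | None = None

    @property
    def trends(self) -> TrendSummary:
        if self._trends is None:
            self._trends = aggregate(self.table)
        return self._trends

    @property
    def group_stats(self):
        return self.trends.group_stats

    @property
    def slopes(self):
        return self.trends.slopes

    def mean_accuracy(
        self, group_size: int, mode: str = "real", template: str | None = None,
        index: str = "accuracy_strict",
    ) -> float:
        """Template-weighted mean accuracy for one design cell."""
        gs = self.group_stats.reset_index()
        sel = (gs["group_size"] == group_size) & (gs["mode"] == mode)
        if template is not None:
            sel &= gs["template"] == template
        vals = gs.loc[sel, f"{index}_mean"]
        return float(vals.mean()) if len(vals) else float("nan")

    def summary(self) -> str:
        t = self.table
        ok = t[(t["error"].isna()) | (t["error"] == "")]
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("Artificial-Extinction Experiment Results".center(w))
        lines.append("=" * w)
        lines.append(
            f"Taxa: {self.model.matrix.n_taxa:<6} Characters: "
            f"{self.model.matrix.n_char:<8} Templates: {len(self.model.templates)}"
        )
        lines.append(
            f"Jobs: {len(t):<6} completed: {len(ok):<6} "
            f"group sizes: {list(self.model.group_sizes)} modes: {list(self.model.modes)}"
        )
        lines.append("-" * w)
        lines.append("Mean congruence by group size and state mode")
        lines.append(
            f"{'size':>5} {'mode':>7} {'splits':>8} {'quartets':>9} "
            f"{'acc(strict)':>12} {'acc(lenient)':>13}"
        )
        gs = self.group_stats.reset_index()
        for (g, mode), sub in gs.groupby(["group_size", "mode"]):
            lines.append(
                f"{g:>5} {mode:>7} "
                f"{sub['shared_splits_mean'].mean():>8.3f} "
                f"{sub['shared_quartets_mean'].mean():>9.3f} "
                f"{sub['accuracy_strict_mean'].mean():>12.3f} "
                f"{sub['accuracy_lenient_mean'].mean():>13.3f}"
            )
        lines.append("-" * w)
        lines.append("OLS slope of mean congruence on template completeness")
        lines.append(
            f"{'size':>5} {'mode':>7} {'index':>17} {'slope':>8} {'se':>7} {'p':>8}"
        )
        for _, r in self.slopes.iterrows():
            lines.append(
                f"{r['group_size']:>5} {r['mode']:>7} {r['index']:>17} "
                f"{r['slope']:>8.3f} {r['stderr']:>7.3f} {r['pvalue']:>8.2g}"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_congruence(self, index: str = "shared_quartets", ax=None):
        """Mean congruence vs template completeness, one line per (size, mode)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        gs = self.group_stats.reset_index()
        for (g, mode), sub in gs.groupby(["group_size", "mode"]):
            sub = sub.sort_values("completeness")
            ax.plot(
                sub["completeness"],
                sub[f"{index}_mean"],
                marker="o",
                linestyle="-" if mode == "real" else "--",
                label=f"n={g} ({mode})",
            )
        ax.set_xlabel("template completeness")
        ax.set_ylabel(f"mean {index.replace('_', ' ')}")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=8)
        return ax
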