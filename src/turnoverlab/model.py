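"""Model/Results interface over the turnover pipeline.

``ProteinTurnoverModel`` wraps a validated observation table plus a run
configuration; ``fit()`` performs the per-animal kinetic inversion and group
statistics and returns a ``ProteinTurnoverResults`` carrying the per-animal
estimates, the comparison table, the run report, and presentation helpers
(``summary()``, ``save()``, ``plot_rates()``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .io import RunConfig, read_study_csv, run_pipeline

__all__ = ["ProteinTurnoverModel", "ProteinTurnoverResults"]


class ProteinTurnoverModel:
    """Non-steady-state protein turnover model for a heavy-water labelling study.

    Parameters
    ----------
    data : pandas.DataFrame
        Observation table with columns ``subject_id, group, pool, P0, P_t,
        E_t, body_water, t`` (see :mod:`turnoverlab.io`).
    config : RunConfig, optional
        Analysis configuration; defaults are the conventional unilateral
        design (paired sham P0 proxy, both comparators, ROUT Q=1 % on
        collagen rates).

    Examples
    --------
    >>> from turnoverlab import ProteinTurnoverModel, simulate_study
    >>> study = simulate_study()
    >>> res = ProteinTurnoverModel(study.observations).fit()
    >>> res.per_animal[["subject_id", "group", "k_deg", "k_syn"]].head()  # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, config: Optional[RunConfig] = None):
        missing = [c for c in
                   ("subject_id", "group", "pool", "P0", "P_t", "E_t", "body_water", "t")
                   if c not in data.columns]
        if missing:
            raise ValueError(f"observation table missing column(s): {', '.join(missing)}")
        self.data = data.reset_index(drop=True)
        self.config = config or RunConfig()

    @classmethod
    def from_csv(cls, path, config: Optional[RunConfig] = None) -> "ProteinTurnoverModel":
        """Build a model from an observation CSV (schema-validated)."""
        return cls(read_study_csv(path), config=config)

    def fit(self) -> "ProteinTurnoverResults":
        """Run the per-animal inversion and group statistics."""
        per_animal, comparisons, report = run_pipeline(self.data, self.config)
        return ProteinTurnoverResults(self, per_animal, comparisons, report)


class ProteinTurnoverResults:
    """Fitted per-animal turnover estimates plus group comparisons.

    Attributes
    ----------
    per_animal : pandas.DataFrame
        One row per (subject, group, pool): f, FSR (steady and non-steady),
        k_deg, FBR, P_eq, k_syn and validity flags.
    comparisons : pandas.DataFrame
        One row per pool x metric x comparator: group mean +/- SEM, t, p,
        percent deficit, outliers removed.
    report : dict
        Run metadata: software version, config echo + hash, flags raised,
        comparator caveat.
    """

    def __init__(self, model, per_animal, comparisons, report):
        self.model = model
        self.per_animal = per_animal
        self.comparisons = comparisons
        self.report = report

    def group_means(self, metric: str, pool: str = "myofibrillar") -> pd.DataFrame:
        """Mean +/- SEM of one metric per group within a pool."""
        sub = self.per_animal[self.per_animal["pool"] == pool]
        g = sub.groupby("group")[metric]
        out = g.agg(["mean", "sem", "count"]).rename(columns={"count": "n"})
        return out

    def summary(self) -> str:
        """Human-readable run summary: per-group means and the comparison table."""
        lines = [
            f"{self.report['software']}  (config {self.report['config_hash']})",
            f"observations: {self.report['n_observations']} "
            f"({self.report['n_subjects']} subjects; pools: "
            f"{', '.join(self.report['pools'])})",
            "",
        ]
        for pool in self.report["pools"]:
            lines.append(f"[{pool}] group means +/- SEM")
            sub = self.per_animal[self.per_animal["pool"] == pool]
            tab = (
                sub.groupby("group")[["fsr_ss", "fsr_nss", "k_deg", "k_syn"]]
                .agg(["mean", "sem"])
            )
            lines.append(tab.round(4).to_string())
            lines.append("")
        if len(self.comparisons):
            lines.append("group comparisons (denervated vs comparator)")
            cols = ["pool", "metric", "comparator", "mean_denervated",
                    "mean_comparator", "pct_deficit", "t", "p"]
            lines.append(self.comparisons[cols].round(4).to_string(index=False))
        if self.report["flags_raised"]:
            lines.append("")
            lines.append("flags raised:")
            for fl in self.report["flags_raised"]:
                lines.append(
                    f"  {fl['subject_id']} {fl['group']}/{fl['pool']}: {fl['flags']}")
        lines.append("")
        lines.append("note: " + self.report["comparator_caveat"])
        return "\n".join(lines)

    def save(self, outdir, round_digits: Optional[int] = None) -> dict:
        """Write per-animal TSV, comparisons TSV and report JSON; returns the paths.

        Output is deterministic for identical inputs and configuration
        (no timestamps); ``round_digits`` optionally rounds for display,
        default is full precision.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_animal, comparisons = self.per_animal, self.comparisons
        if round_digits is not None:
            per_animal = per_animal.round(round_digits)
            comparisons = comparisons.round(round_digits)
        paths = {
            "per_animal": outdir / "per_animal.tsv",
            "comparisons": outdir / "comparisons.tsv",
            "report": outdir / "report.json",
        }
        per_animal.to_csv(paths["per_animal"], sep="\t", index=False)
        comparisons.to_csv(paths["comparisons"], sep="\t", index=False)
        with open(paths["report"], "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}

    def plot_rates(self, pool: str = "myofibrillar", ax=None):
        """Diagnostic strip plot of k_syn and k_deg per group (matplotlib axes)."""
        import matplotlib.pyplot as plt

        sub = self.per_animal[self.per_animal["pool"] == pool]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        groups = [g for g in ("denervated", "sham", "nonsurgical")
                  if g in set(sub["group"])]
        for k, g in enumerate(groups):
            y = sub.loc[sub["group"] == g, "k_deg"]
            ax.plot([k] * len(y), y, "o", alpha=0.6, label=g)
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(groups)
        ax.set_ylabel("k_deg (1/day)")
        ax.set_title(f"{pool}: degradation constants per group")
        return ax
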