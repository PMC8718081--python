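"""Study-table I/O, run configuration, and the end-to-end pipeline.

The observation CSV has one row per (subject, group, pool):

    subject_id, group, pool, P0, P_t, E_t, body_water, t [, hydroxyproline]

with masses in mg (collagen in ug-equivalents), enrichments as excess mole
fractions, and ``t`` in days.  ``run_pipeline`` converts body water to
precursor enrichment (MIDA), resolves each denervated limb's initial-mass
proxy, inverts the kinetic model per row, and builds group comparisons with
mean +/- SEM, paired/unpaired t tests, and optional ROUT outlier screening.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import GROUPS, POOLS, PoolObservation, analyze_pool
from .precursor import DEFAULT_N_SITES, fraction_new, mida_precursor_enrichment
from .stats import compare_groups

__all__ = ["SchemaError", "RunConfig", "read_study_csv", "run_pipeline"]

REQUIRED_COLUMNS = ["subject_id", "group", "pool", "P0", "P_t", "E_t", "body_water", "t"]
OPTIONAL_COLUMNS = ["hydroxyproline"]
NUMERIC_COLUMNS = ["P0", "P_t", "E_t", "body_water", "t"]

#: which precursor analyte each pool's enrichment is read from
POOL_ANALYTE = {
    "myofibrillar": "alanine",
    "collagen": "alanine",
    "RNA": "ribose",
    "DNA": "deoxyribose",
}

#: metrics carried into the group-comparison table
COMPARISON_METRICS = ["fsr_ss", "fsr_nss", "k_deg", "fbr", "k_syn", "P_t"]

CROSSOVER_CAVEAT = (
    "Contralateral (sham) limbs of a unilateral intervention are not pristine "
    "controls: a crossover effect can alter their turnover, so denervation "
    "effect sizes depend on the comparator. Interpret sham-referenced and "
    "non-surgical-referenced contrasts together."
)


class SchemaError(ValueError):
    """Raised when an observation table fails validation; carries row-level errors."""

    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("invalid study table:\n  " + "\n  ".join(errors))


def _default_modes() -> Dict[str, str]:
    # nucleic-acid pools default to steady (their content is typically stable)
    return {"myofibrillar": "nonsteady", "collagen": "nonsteady",
            "RNA": "steady", "DNA": "steady"}


@dataclass(frozen=True)
class RunConfig:
    """Validated analysis configuration, echoed verbatim into the run report."""

    comparator: str = "both"             # sham | nonsurgical | both
    p0_policy: str = "paired_sham"       # paired_sham | nonsurgical_mean | table
    mode: Dict[str, str] = field(default_factory=_default_modes)
    n_sites: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_SITES))
    plateau_method: str = "last"
    rout_q: Optional[float] = 1.0
    rout_pools: Tuple[str, ...] = ("collagen",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.comparator not in ("sham", "nonsurgical", "both"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.p0_policy not in ("paired_sham", "nonsurgical_mean", "table"):
            raise ValueError(f"unknown p0_policy {self.p0_policy!r}")
        modes = dict(_default_modes(), **self.mode)
        for pool, mode in modes.items():
            if pool not in POOLS or mode not in ("steady", "nonsteady"):
                raise ValueError(f"invalid mode entry {pool!r}: {mode!r}")
        object.__setattr__(self, "mode", modes)
        sites = dict(DEFAULT_N_SITES, **self.n_sites)
        for analyte, n in sites.items():
            if not (1 <= n <= 10):
                raise ValueError(f"n_sites for {analyte!r} must be in [1, 10]")
        object.__setattr__(self, "n_sites", sites)
        if self.rout_q is not None and not (0 < self.rout_q <= 10):
            raise ValueError("rout_q must be in (0, 10] percent")
        object.__setattr__(self, "rout_pools", tuple(self.rout_pools))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        precursor = d.pop("precursor", {})
        if "n_sites" in precursor:
            d["n_sites"] = dict(precursor["n_sites"])
        if "plateau_method" in precursor:
            d["plateau_method"] = precursor["plateau_method"]
        rout = d.pop("rout", {})
        if "q" in rout:
            d["rout_q"] = rout["q"]
        if "pools" in rout:
            d["rout_pools"] = tuple(rout["pools"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rout_pools"] = list(self.rout_pools)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_study_csv(path) -> pd.DataFrame:
    """Read and validate an observation CSV.

    Row-level problems are collected (with CSV line numbers, header = line 1)
    and raised together as a :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    errors: List[str] = []

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing required column(s): {', '.join(missing)}"])

    for col in NUMERIC_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            errors.append(f"line {i + 2}: non-numeric {col}={df.at[i, col]!r}")
        df[col] = coerced

    for i, row in df.iterrows():
        line = i + 2
        if row["group"] not in GROUPS:
            errors.append(f"line {line}: unknown group {row['group']!r}")
        if row["pool"] not in POOLS:
            errors.append(f"line {line}: unknown pool {row['pool']!r}")
        for col in ("P0", "P_t", "t"):
            if pd.notna(row[col]) and row[col] <= 0:
                errors.append(f"line {line}: {col} must be positive")
        if pd.notna(row["E_t"]) and row["E_t"] < 0:
            errors.append(f"line {line}: E_t must be non-negative")
        if pd.notna(row["body_water"]) and not (0 <= row["body_water"] <= 0.2):
            errors.append(f"line {line}: body_water outside [0, 0.2]")

    dup = df.duplicated(subset=["subject_id", "group", "pool"], keep=False)
    for i in df.index[dup]:
        errors.append(
            f"line {i + 2}: duplicate key "
            f"({df.at[i, 'subject_id']}, {df.at[i, 'group']}, {df.at[i, 'pool']})"
        )
    if errors:
        raise SchemaError(errors)
    return df


def _resolve_p0(table: pd.DataFrame, policy: str) -> pd.Series:
    """Initial-mass proxy per row under the configured convention.

    ``paired_sham``: a denervated limb's P0 is its animal's sham terminal
    mass (falling back to the table value when no sham row exists);
    ``nonsurgical_mean``: the non-surgical group's mean terminal mass per
    pool; ``table``: the P0 column as given.
    """
    p0 = table["P0"].astype(float).copy()
    if policy == "table":
        return p0
    den = table["group"] == "denervated"
    if policy == "paired_sham":
        sham = table[table["group"] == "sham"].set_index(["subject_id", "pool"])["P_t"]
        for i in table.index[den]:
            key = (table.at[i, "subject_id"], table.at[i, "pool"])
            if key in sham.index:
                p0.at[i] = float(sham.loc[key])
    else:  # nonsurgical_mean
        ns = table[table["group"] == "nonsurgical"].groupby("pool")["P_t"].mean()
        for i in table.index[den]:
            pool = table.at[i, "pool"]
            if pool in ns.index:
                p0.at[i] = float(ns.loc[pool])
    return p0


def run_pipeline(
    table: pd.DataFrame, config: Optional[RunConfig] = None
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Observation table -> (per-animal results, group comparisons, run report).

    Deterministic given table + config; the report echoes the configuration,
    its hash, and every estimator flag raised, once per (subject, pool).
    """
    config = config or RunConfig()
    if len(table) == 0:
        raise ValueError("empty study table: nothing to analyze")
    table = table.reset_index(drop=True)

    p0 = _resolve_p0(table, config.p0_policy)
    rows = []
    for i, row in table.iterrows():
        analyte = POOL_ANALYTE[row["pool"]]
        e_star = mida_precursor_enrichment(config.n_sites[analyte], row["body_water"])
        with warnings.catch_warnings():
            # f > 1 is surfaced through result flags, not repeated warnings
            warnings.simplefilter("ignore")
            f = fraction_new(row["E_t"], e_star)
        obs = PoolObservation(
            subject_id=str(row["subject_id"]), group=row["group"], pool=row["pool"],
            p0=float(p0.at[i]), p_t=float(row["P_t"]), f=f, t=float(row["t"]),
        )
        res = analyze_pool(obs, mode=config.mode[row["pool"]])
        rows.append({
            "subject_id": res.subject_id, "group": res.group, "pool": res.pool,
            "mode": res.mode, "P0": obs.p0, "P_t": obs.p_t, "f": f,
            "E_star": e_star, "t": obs.t,
            "fsr_ss": res.fsr_ss, "fsr_nss": res.fsr_nss, "k_deg": res.k_deg,
            "fbr": res.fbr, "p_eq": res.p_eq, "k_syn": res.k_syn,
            "flags": ";".join(sorted(res.flags)),
        })
    results = pd.DataFrame(rows)

    comparisons = _build_comparisons(results, config)

    flags_raised = [
        {"subject_id": r["subject_id"], "group": r["group"], "pool": r["pool"],
         "flags": r["flags"]}
        for r in rows if r["flags"]
    ]
    report = {
        "software": f"turnoverlab {__version__}",
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "n_observations": int(len(table)),
        "n_subjects": int(table["subject_id"].nunique()),
        "pools": sorted(table["pool"].unique().tolist()),
        "flags_raised": flags_raised,
        "comparator_caveat": CROSSOVER_CAVEAT,
    }
    return results, comparisons, report


def _build_comparisons(results: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    comparators = {"sham": ["sham"], "nonsurgical": ["nonsurgical"],
                   "both": ["sham", "nonsurgical"]}[config.comparator]
    rows = []
    for pool, sub in results.groupby("pool", sort=False):
        den = sub[sub["group"] == "denervated"]
        if den.empty:
            continue
        rout_q = config.rout_q if pool in config.rout_pools else None
        for comp in comparators:
            ref = sub[sub["group"] == comp]
            if ref.empty:
                continue
            paired = comp == "sham"
            for metric in COMPARISON_METRICS:
                if paired:
                    merged = den.merge(ref, on="subject_id", suffixes=("_den", "_ref"))
                    a = merged[f"{metric}_den"].to_numpy(float)
                    b = merged[f"{metric}_ref"].to_numpy(float)
                    ids = merged["subject_id"].tolist()
                else:
                    a = den[metric].to_numpy(float)
                    b = ref[metric].to_numpy(float)
                    ids = den["subject_id"].tolist()
                ok_a, ok_b = np.isfinite(a), np.isfinite(b)
                if paired:
                    ok = ok_a & ok_b
                    a, b = a[ok], b[ok]
                    ids = [s for s, k in zip(ids, ok) if k]
                else:
                    a, b = a[ok_a], b[ok_b]
                    ids = [s for s, k in zip(ids, ok_a) if k]
                if a.size == 0 or b.size == 0:
                    continue
                gc = compare_groups(
                    metric, pool, "denervated", a, comp, b,
                    paired=paired, subject_ids_a=ids, rout_q=rout_q,
                )
                rows.append({
                    "pool": pool, "metric": metric, "comparator": comp,
                    "paired": paired, "n_denervated": gc.n_a, "n_comparator": gc.n_b,
                    "mean_denervated": gc.mean_a, "sem_denervated": gc.sem_a,
                    "mean_comparator": gc.mean_b, "sem_comparator": gc.sem_b,
                    "t": gc.t, "p": gc.p, "pct_deficit": gc.pct_difference,
                    "outliers_removed": ";".join(gc.outliers_removed),
                })
    return pd.DataFrame(rows)
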