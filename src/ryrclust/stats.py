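"""Hierarchical aggregation, blinded group comparison, and study reporting.

Imaging metrics are nested: clusters within images within patients within
clinical groups.  The patient is the unit of analysis — per-cluster metrics
are averaged per image, per-image values per patient, and group tests run on
the per-patient values — so pseudo-replication at the cluster level never
inflates the n of a test.

Group comparison follows a standard decision tree: Shapiro–Wilk normality in
each group (α = 0.05), then Brown–Forsythe–Levene variance homogeneity
(α = 0.05); non-normal data go to Kruskal–Wallis with Dunn post hoc tests,
normal data with unequal variances to Welch ANOVA with Games–Howell, and
fully well-behaved data to one-way ANOVA with Tukey HSD.  The path taken is
logged in the result so every reported p-value is auditable.

Blinding replaces group labels with opaque codes keyed separately, mirroring
how the imaging analysis is run without knowledge of clinical group.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "aggregate",
    "compare_groups",
    "blind",
    "unblind",
    "report_tables",
    "provenance_counts",
]

LONG_COLUMNS = ["patient", "group", "image", "metric", "value"]


def _check_long(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns {missing}")
    return table


def aggregate(table: pd.DataFrame, level: str = "patient") -> pd.DataFrame:
    """Aggregate a long-format study table to image or patient level.

    ``level="image"`` returns per-image means of the per-cluster (or
    per-row) values; ``level="patient"`` additionally averages images within
    each patient, unweighted by how many clusters an image contributed.
    Patients with no rows for a metric are dropped with a warning.
    """
    table = _check_long(table)
    if level not in ("image", "patient"):
        raise ValueError("level must be 'image' or 'patient'")
    per_image = (table.groupby(["patient", "group", "image", "metric"],
                               as_index=False, sort=True)["value"].mean())
    if level == "image":
        return per_image
    per_patient = (per_image.groupby(["patient", "group", "metric"],
                                     as_index=False, sort=True)["value"].mean())
    all_patients = set(table["patient"].unique())
    kept = set(per_patient["patient"].unique())
    dropped = all_patients - kept
    if dropped:
        warnings.warn(f"patients dropped (no images): {sorted(dropped)}")
    return per_patient


@dataclass
class GroupComparison:
    """Result of one metric's group comparison, with the decision path."""

    metric: str
    groups: list[str]
    means: dict[str, float]
    sems: dict[str, float]
    ns: dict[str, int]
    test: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None
    decision_path: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)


def _dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal–Wallis (Holm adjusted).

    z-statistics from the pooled-rank mean differences with the standard
    tie correction; two-sided p-values adjusted by the Holm step-down
    procedure.
    """
    names = list(samples)
    all_vals = np.concatenate([samples[g] for g in names])
    n_total = len(all_vals)
    ranks = sps.rankdata(all_vals)
    offsets = np.cumsum([0] + [len(samples[g]) for g in names])
    mean_ranks = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                  for i, g in enumerate(names)}
    # tie correction
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(samples[a]), len(samples[b])
        se = np.sqrt((n_total * (n_total + 1) / 12.0
                      - tie_term / (12.0 * (n_total - 1))) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"A": a, "B": b, "z": z, "p_unc": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_unc"], method="holm")[1]
    return out


def compare_groups(values: dict[str, np.ndarray] | pd.DataFrame,
                   metric: str = "", alpha: float = 0.05) -> GroupComparison:
    """Compare >= 2 groups of per-patient values via the decision tree.

    ``values`` is either ``{group: 1-D array}`` or a per-patient long table
    (columns ``group`` and ``value``; one row per patient).  Each group
    needs n >= 3.  See the module docstring for the branch logic.
    """
    if isinstance(values, pd.DataFrame):
        sub = values if metric == "" or "metric" not in values.columns else \
            values[values["metric"] == metric]
        samples = {str(g): grp["value"].to_numpy(float)
                   for g, grp in sub.groupby("group", sort=True)}
    else:
        samples = {str(g): np.asarray(v, dtype=float) for g, v in values.items()}
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for g, v in samples.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n={len(v)} < 3")
    names = list(samples)
    path: list[str] = []
    means = {g: float(v.mean()) for g, v in samples.items()}
    sems = {g: float(sps.sem(v)) if len(v) > 1 else float("nan")
            for g, v in samples.items()}
    ns = {g: int(len(v)) for g, v in samples.items()}

    arrays = [samples[g] for g in names]
    if all(np.ptp(v) == 0 for v in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        path.append("degenerate: all values identical; reported p = 1")
        return GroupComparison(metric, names, means, sems, ns,
                               test="one-way ANOVA", statistic=0.0, p=1.0,
                               posthoc=None, decision_path=path)

    # gate 1: Shapiro–Wilk normality per group
    normal = True
    for g in names:
        v = samples[g]
        if np.ptp(v) == 0:
            path.append(f"Shapiro-Wilk {g}: constant values, treated as non-normal")
            normal = False
            continue
        p_sw = float(sps.shapiro(v).pvalue)
        path.append(f"Shapiro-Wilk {g}: p={p_sw:.4f} "
                    f"({'pass' if p_sw >= alpha else 'fail'})")
        normal &= p_sw >= alpha

    if not normal:
        path.append("-> non-normal: Kruskal-Wallis + Dunn post hoc")
        stat, p = sps.kruskal(*arrays)
        posthoc = _dunn_posthoc(samples)
        return GroupComparison(metric, names, means, sems, ns,
                               test="Kruskal-Wallis", statistic=float(stat),
                               p=float(p), posthoc=posthoc, decision_path=path)

    # gate 2: Brown–Forsythe–Levene variance homogeneity
    stat_lev, p_lev = sps.levene(*arrays, center="median")
    path.append(f"Brown-Forsythe-Levene: p={p_lev:.4f} "
                f"({'pass' if p_lev >= alpha else 'fail'})")
    long = pd.DataFrame({
        "value": np.concatenate(arrays),
        "group": np.repeat(names, [len(v) for v in arrays]),
    })
    if p_lev < alpha:
        path.append("-> unequal variance: Welch ANOVA + Games-Howell post hoc")
        aov = pg.welch_anova(data=long, dv="value", between="group")
        posthoc = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        return GroupComparison(metric, names, means, sems, ns,
                               test="Welch ANOVA",
                               statistic=float(aov["F"].iloc[0]),
                               p=float(aov["p_unc"].iloc[0]),
                               posthoc=posthoc, decision_path=path)

    path.append("-> one-way ANOVA + Tukey HSD post hoc")
    stat, p = sps.f_oneway(*arrays)
    tukey = pairwise_tukeyhsd(long["value"], long["group"], alpha=alpha)
    posthoc = pd.DataFrame(tukey.summary().data[1:],
                           columns=tukey.summary().data[0])
    return GroupComparison(metric, names, means, sems, ns,
                           test="one-way ANOVA", statistic=float(stat),
                           p=float(p), posthoc=posthoc, decision_path=path)


# -- blinding --------------------------------------------------------------

def blind(table: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, dict[str, str]]:
    """Replace group labels with opaque codes; return (blinded table, key).

    The key maps code -> original group and is the only way back; the
    blinded table carries no original group strings.
    """
    if "group" not in table.columns:
        raise ValueError("table has no 'group' column to blind")
    rng = np.random.default_rng(seed)
    groups = sorted(map(str, table["group"].unique()))
    codes = [f"G{rng.integers(10**6, 10**7)}" for _ in groups]
    while len(set(codes)) < len(codes):  # pragma: no cover - rare collision
        codes = [f"G{rng.integers(10**6, 10**7)}" for _ in groups]
    order = rng.permutation(len(groups))
    mapping = {groups[i]: codes[order[i]] for i in range(len(groups))}
    key = {v: k for k, v in mapping.items()}
    blinded = table.copy()
    blinded["group"] = blinded["group"].astype(str).map(mapping)
    return blinded, key


def unblind(table: pd.DataFrame, key: dict[str, str]) -> pd.DataFrame:
    """Restore original group labels; errors on any unknown code."""
    if "group" not in table.columns:
        raise ValueError("table has no 'group' column to unblind")
    codes = set(map(str, table["group"].unique()))
    unknown = codes - set(key)
    if unknown:
        raise ValueError(f"codes not in key (wrong key?): {sorted(unknown)}")
    out = table.copy()
    out["group"] = out["group"].astype(str).map(key)
    return out


# -- reporting -------------------------------------------------------------

def provenance_counts(cluster_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group provenance: # clusters, # images, # patients.

    ``cluster_table`` is a cluster-level long table (one row per cluster per
    metric, or per cluster); counts are over unique rows/ids.
    """
    _check_long(cluster_table)
    rows = []
    for g, grp in cluster_table.groupby("group", sort=True):
        one_metric = grp[grp["metric"] == grp["metric"].iloc[0]]
        rows.append({
            "group": g,
            "n_clusters": int(len(one_metric)),
            "n_images": int(grp["image"].nunique()),
            "n_patients": int(grp["patient"].nunique()),
        })
    return pd.DataFrame(rows)


def report_tables(per_patient: pd.DataFrame,
                  comparisons: list[GroupComparison],
                  provenance: pd.DataFrame | None = None
                  ) -> tuple[pd.DataFrame, str]:
    """Study-style summary: mean ± SEM per group per metric + p-value column.

    Returns the machine-readable DataFrame and an aligned plain-text
    rendering.  Metrics present in ``per_patient`` but lacking a comparison
    are emitted with blanks and a warning.  A provenance table (from
    :func:`provenance_counts`) appends the footer rows.
    """
    groups = sorted(map(str, per_patient["group"].unique())) \
        if len(per_patient) else []
    comp_by_metric = {c.metric: c for c in comparisons}
    rows = []
    for metric in sorted(per_patient["metric"].unique()) if len(per_patient) else []:
        row: dict[str, Any] = {"metric": metric}
        comp = comp_by_metric.get(metric)
        sub = per_patient[per_patient["metric"] == metric]
        for g in groups:
            v = sub.loc[sub["group"].astype(str) == g, "value"].to_numpy(float)
            if v.size:
                sem = sps.sem(v) if v.size > 1 else float("nan")
                row[g] = f"{v.mean():.4g} ± {sem:.3g}"
            else:
                row[g] = ""
        if comp is None:
            warnings.warn(f"no comparison supplied for metric {metric!r}")
            row["test"] = ""
            row["p"] = ""
        else:
            row["test"] = comp.test
            row["p"] = f"{comp.p:.4f}"
        rows.append(row)
    table = pd.DataFrame(rows, columns=["metric", *groups, "test", "p"])

    if provenance is not None and len(provenance):
        prov = provenance.set_index("group")
        footer_rows = []
        for label, fmt in (("# clusters analyzed",
                            lambda r: str(r["n_clusters"])),
                           ("# images(# patients)",
                            lambda r: f"{r['n_images']}({r['n_patients']})")):
            row = {"metric": label, "test": "", "p": ""}
            for g in groups:
                row[g] = fmt(prov.loc[g]) if g in prov.index else ""
            footer_rows.append(row)
        table = pd.concat([table, pd.DataFrame(footer_rows)], ignore_index=True)

    text = table.to_string(index=False)
    return table, text


def write_report(table: pd.DataFrame, text: str, directory: str | Path,
                 stem: str = "report") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.to_csv(directory / f"{stem}.csv", index=False)
    (directory / f"{stem}.txt").write_text(text + "\n")
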