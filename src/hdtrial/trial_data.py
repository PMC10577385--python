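"""Trial data structures, CSV I/O, survival filtering, and descriptive summaries.

A provenance trial is a randomized complete block design (RCBD) with
single-tree plots: at each site, each block holds one planted position per
genetic entry.  The unit of analysis is the individual tree, carried here as
one row of a :class:`TrialTable` with columns

    site, provenance, block, tree, dbh_cm, height_m, alive

Dead or missing trees keep their rows (with blank measurements) so that
block-level survival can be computed against the planted design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .selection import tree_volume

COLUMNS = ["site", "provenance", "block", "tree", "dbh_cm", "height_m", "alive"]


class SchemaError(ValueError):
    """The input table does not have the required columns."""


class ValidationError(ValueError):
    """A row violates the per-tree measurement invariants."""


class EmptyTrialWarning(UserWarning):
    """All blocks were discarded by the survival filter."""


@dataclass
class TrialTable:
    """Per-tree measurements plus trial design metadata.

    Parameters
    ----------
    data
        One row per planted position. ``dbh_cm``/``height_m`` may be NaN for
        dead trees; ``alive`` is 0/1.
    planned_per_block
        Planted positions per block — a single int applying to every site, a
        mapping ``site -> int``, or None, in which case the maximum observed
        row count over blocks within each site is used (an RCBD with
        single-tree plots implies a fixed planted count per block).
    site_metadata
        Optional ``site -> {"age": years, ...}`` descriptive metadata.
    """

    data: pd.DataFrame
    planned_per_block: int | Mapping[str, int] | None = None
    site_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        self.data = self.data[COLUMNS].copy()
        self.data["alive"] = self.data["alive"].astype(int)
        alive = self.data["alive"] == 1
        for col in ("dbh_cm", "height_m"):
            vals = pd.to_numeric(self.data[col], errors="coerce")
            bad = alive & (~np.isfinite(vals) | (vals <= 0))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {row}: alive tree with non-positive or non-numeric {col}"
                )
            self.data[col] = vals

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if len(a) != len(b):
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, check_like=True)
        except AssertionError:
            return False
        return True

    # -- design metadata ----------------------------------------------------

    def planned_for(self, site: str) -> int:
        if isinstance(self.planned_per_block, Mapping):
            return int(self.planned_per_block[site])
        if self.planned_per_block is not None:
            return int(self.planned_per_block)
        per_block = self.data[self.data["site"] == site].groupby("block").size()
        return int(per_block.max())

    def survival(self) -> pd.DataFrame:
        """Block survival: alive trees / planted positions, per (site, block)."""
        g = self.data.groupby(["site", "block"], sort=False, observed=True)
        out = g["alive"].sum().reset_index(name="n_alive")
        out["planned"] = [self.planned_for(s) for s in out["site"]]
        out["survival"] = out["n_alive"] / out["planned"]
        return out

    def alive(self) -> pd.DataFrame:
        """Rows for live, measured trees only."""
        return self.data[self.data["alive"] == 1]


def read_trial(
    path,
    planned_per_block: int | Mapping[str, int] | None = None,
    site_metadata: dict | None = None,
) -> TrialTable:
    """Read a trial CSV (UTF-8, header required) into a validated TrialTable.

    Row order is preserved.  Raises :class:`SchemaError` for missing columns
    and :class:`ValidationError` for invalid measurements on live trees.
    """
    df = pd.read_csv(path)
    return TrialTable(df, planned_per_block=planned_per_block,
                      site_metadata=site_metadata or {})


def write_trial(table: TrialTable, path) -> None:
    """Write a trial CSV, preserving one decimal for dbh (cm) and height (m)."""
    df = table.data.copy()
    df["dbh_cm"] = df["dbh_cm"].round(1)
    df["height_m"] = df["height_m"].round(1)
    df.to_csv(path, index=False, float_format="%.1f")


def filter_blocks(table: TrialTable, min_survival: float = 0.60) -> TrialTable:
    """Discard (site, block) groups whose survival rate is below ``min_survival``.

    Survival is alive trees divided by planted positions per block.  Records
    within retained blocks are unchanged.  Idempotent.  Emits
    :class:`EmptyTrialWarning` if every block is discarded.
    """
    surv = table.survival()
    keep = surv[surv["survival"] >= min_survival]
    keys = set(zip(keep["site"], keep["block"]))
    mask = [
        (s, b) in keys for s, b in zip(table.data["site"], table.data["block"])
    ]
    out = table.data[mask]
    if out.empty:
        warnings.warn(
            f"all blocks fall below the {min_survival:.0%} survival threshold",
            EmptyTrialWarning,
        )
    return TrialTable(out.reset_index(drop=True),
                      planned_per_block=table.planned_per_block,
                      site_metadata=table.site_metadata)


def summarize(table: TrialTable, include_site_totals: bool = True) -> pd.DataFrame:
    """Per-(site, provenance) growth summaries over live trees.

    Returns one row per provenance present at each site with columns ``n``,
    ``mean_dbh``, ``se_dbh``, ``mean_height``, ``se_height``,
    ``mean_hd_ratio`` and ``mean_volume``, plus (optionally) a per-site
    totals row with provenance label ``"(all)"``.

    The height-diameter ratio is height in m divided by DBH in cm — the
    slenderness convention used throughout this package (values near 1 for
    mature broadleaf trees).  Volume is the mean of per-tree volumes, not
    the volume of the mean tree.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty trial")
    live = table.alive().copy()
    live["hd_ratio"] = live["height_m"] / live["dbh_cm"]
    live["volume"] = tree_volume(live["dbh_cm"], live["height_m"])

    def _agg(df: pd.DataFrame) -> pd.Series:
        n = len(df)
        se = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return pd.Series({
            "n": n,
            "mean_dbh": df["dbh_cm"].mean(),
            "se_dbh": se(df["dbh_cm"]),
            "mean_height": df["height_m"].mean(),
            "se_height": se(df["height_m"]),
            "mean_hd_ratio": df["hd_ratio"].mean(),
            "mean_volume": df["volume"].mean(),
        })

    rows = []
    for (site, prov), df in live.groupby(["site", "provenance"], sort=False,
                                         observed=True):
        rows.append(pd.concat([pd.Series({"site": site, "provenance": prov}),
                               _agg(df)]))
    if include_site_totals:
        for site, df in live.groupby("site", sort=False, observed=True):
            rows.append(pd.concat([pd.Series({"site": site, "provenance": "(all)"}),
                                   _agg(df)]))
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["n"] = out["n"].astype(int)
    return out


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    trait: str
    f_statistic: float
    p_value: float
    #: DataFrame with columns group1, group2, meandiff, p_adj
    tukey: pd.DataFrame


def anova_tukey(
    table: TrialTable,
    trait: str = "dbh",
    by: str = "site",
    site: str | None = None,
) -> AnovaTukeyResult:
    """One-way ANOVA and Tukey honest-significant-difference tests.

    ``by="site"`` compares sites on all live trees; ``by="provenance"``
    compares provenances within the single site given by ``site``.
    Each group needs at least two observations.
    """
    col = {"dbh": "dbh_cm", "height": "height_m"}[trait]
    live = table.alive()
    if by == "site":
        group_col = "site"
    elif by == "provenance":
        if site is None:
            raise ValueError("by='provenance' requires a site")
        live = live[live["site"] == site]
        group_col = "provenance"
    else:
        raise ValueError(f"unknown grouping {by!r}")

    groups = {g: df[col].to_numpy() for g, df in
              live.groupby(group_col, sort=False, observed=True)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    f, p = stats.f_oneway(*groups.values())
    hsd = pairwise_tukeyhsd(live[col].to_numpy(),
                            live[group_col].astype(str).to_numpy())
    tk = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    tk = tk.rename(columns={"p-adj": "p_adj"})[
        ["group1", "group2", "meandiff", "p_adj"]
    ]
    return AnovaTukeyResult(trait=trait, f_statistic=float(f), p_value=float(p),
                            tukey=tk)
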