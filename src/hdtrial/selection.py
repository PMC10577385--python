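"""Provenance clustering by asymptote offset and superior-provenance selection.

Large-timber breeding of broadleaf species favours genetic entries that put
growth into diameter rather than height: at a given DBH a *lower* asymptote
of the height-diameter curve means a stockier, more stable stem.  The
selection rule implemented here therefore screens provenances with
above-average DBH and ranks them by their asymptote offset ``k`` (ascending),
keeping the lowest fraction ``rate``.

Gains are reported as (selected mean − total mean) / total mean × 100 %.
For traits whose total mean can be negative (the offsets themselves) an
absolute-denominator variant is reported alongside.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


def tree_volume(dbh_cm, height_m):
    """Individual stem volume in m³ from DBH (cm) and height (m).

    volume = 0.45/4 · π · DBH² · H with DBH in metres — a conical form
    factor of 0.45 applied to the breast-height basal-area cylinder.
    Vectorized over array inputs.
    """
    d_m = np.asarray(dbh_cm, dtype=float) / 100.0
    v = 0.45 / 4.0 * np.pi * d_m**2 * np.asarray(height_m, dtype=float)
    return v if v.ndim else float(v)


def selection_gain(selected_mean: float, total_mean: float,
                   absolute_base: bool = False) -> float:
    """Selection gain in percent: (selected − total) / total × 100.

    With ``absolute_base=True`` the denominator is |total|, which keeps the
    sign of the improvement interpretable when the total mean is negative
    (as for asymptote offsets).
    """
    if total_mean == 0:
        raise ZeroDivisionError("selection gain undefined for a zero total mean")
    base = abs(total_mean) if absolute_base else total_mean
    return (selected_mean - total_mean) / base * 100.0


@dataclass
class ProvenanceGroupSet:
    """Ordered partition of provenances by asymptote offset at one site.

    Groups are ordered by descending group-mean offset (conventionally
    labelled I, II, ... from tallest to flattest curves), and members within
    a group by descending offset.
    """

    site_id: str
    groups: list[list[str]]
    group_means: list[float]
    linkage_method: str

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def labels(self) -> dict[str, int]:
        """Map provenance -> 1-based group index."""
        return {p: i + 1 for i, grp in enumerate(self.groups) for p in grp}


def cluster_provenances(
    k_values: Mapping[str, float],
    n_groups: int,
    linkage_method: str = "average",
    site_id: str = "",
) -> ProvenanceGroupSet:
    """Agglomerative clustering of 1-D asymptote offsets into ``n_groups``.

    Hierarchical clustering on the scalar offsets with Euclidean distance;
    the tree is cut to exactly ``n_groups`` clusters.  Deterministic for
    given inputs: ties across a cut boundary are resolved by stable label
    order (and logged).  Default linkage is between-groups average (UPGMA),
    the common default of classical "system clustering" routines; ward,
    complete and single are accepted too — on scalars every one of these
    yields groups that are contiguous intervals of the sorted offsets.
    """
    labels = list(k_values)
    if len(labels) < n_groups:
        raise ValueError("need at least as many provenances as groups")
    vals = np.array([[k_values[p]] for p in labels], dtype=float)
    if len(np.unique(vals)) < len(vals):
        logger.info("duplicate offset values present; stable label order breaks ties")
    Z = linkage(vals, method=linkage_method)
    assign = fcluster(Z, n_groups, criterion="maxclust")
    by_cluster: dict[int, list[str]] = {}
    for lab, c in zip(labels, assign):
        by_cluster.setdefault(int(c), []).append(lab)
    groups = sorted(by_cluster.values(),
                    key=lambda g: -float(np.mean([k_values[p] for p in g])))
    groups = [sorted(g, key=lambda p: (-k_values[p], p)) for g in groups]
    means = [float(np.mean([k_values[p] for p in g])) for g in groups]
    return ProvenanceGroupSet(site_id=site_id, groups=groups, group_means=means,
                              linkage_method=linkage_method)


@dataclass
class SelectionReport:
    """Outcome of the asymptote-based provenance selection at one site."""

    site_id: str
    selected: list[str]
    rate: float
    criterion: str
    #: trait -> mean over selected provenances' means
    selected_means: dict[str, float]
    #: trait -> mean over all provenances' means
    total_means: dict[str, float]
    #: trait -> gain % with the signed total-mean denominator
    gains: dict[str, float]
    #: trait -> gain % with |total mean| denominator
    gains_absolute_base: dict[str, float]
    eligible: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        traits = list(self.total_means)
        return pd.DataFrame({
            "trait": traits,
            "selected_mean": [self.selected_means[t] for t in traits],
            "total_mean": [self.total_means[t] for t in traits],
            "gain_pct": [self.gains[t] for t in traits],
            "gain_pct_abs_base": [self.gains_absolute_base[t] for t in traits],
        })


def select(
    summaries: pd.DataFrame,
    k_values: Mapping[str, float],
    rate: float = 0.20,
    criterion: str = "dbh_above_mean",
    include_reference: bool = True,
    reference: str = "Y",
    site_mean_dbh: float | None = None,
    site_mean_height: float | None = None,
    site_id: str = "",
) -> SelectionReport:
    """Apply the above-average-DBH / lowest-asymptote selection rule.

    Parameters
    ----------
    summaries
        Per-provenance summary rows for one site with columns ``provenance``,
        ``n``, ``mean_dbh``, ``mean_height`` and optionally
        ``mean_hd_ratio`` / ``mean_volume`` (reconstructed from means if
        absent — an approximation flagged in the report only through its
        docstring; pass per-tree summaries for exact volumes).
    k_values
        Provenance -> asymptote offset at this site.
    rate
        Selection rate; the number kept is ``ceil(rate × provenances present)``.
    criterion
        ``"dbh_above_mean"`` (default) or ``"dbh_and_height_above_mean"``.
    include_reference
        Whether the reference provenance (offset fixed at 0) competes.
    site_mean_dbh, site_mean_height
        Overall per-tree site means used for the eligibility screen; when
        None they are computed from the summaries weighted by ``n``.

    Notes
    -----
    Eligibility uses the *tree-weighted* site mean (strictly above), while
    the reported total means average the per-provenance means unweighted —
    the convention that reproduces published gain tables.
    """
    df = summaries[summaries["provenance"] != "(all)"].copy()
    present = list(df["provenance"])
    missing = [p for p in present if p not in k_values]
    if missing:
        raise KeyError(f"no asymptote offset for provenances {missing}")

    if site_mean_dbh is None:
        site_mean_dbh = float(np.average(df["mean_dbh"], weights=df["n"]))
    if site_mean_height is None:
        site_mean_height = float(np.average(df["mean_height"], weights=df["n"]))

    eligible = df[df["mean_dbh"] > site_mean_dbh]
    if criterion == "dbh_and_height_above_mean":
        eligible = eligible[eligible["mean_height"] > site_mean_height]
    elif criterion != "dbh_above_mean":
        raise ValueError(f"unknown criterion {criterion!r}")
    if not include_reference:
        eligible = eligible[eligible["provenance"] != reference]

    n_select = math.ceil(rate * len(present))
    ranked = sorted(eligible["provenance"], key=lambda p: (k_values[p], p))
    if len(ranked) < n_select:
        warnings.warn(
            f"only {len(ranked)} provenances eligible at {site_id or 'site'}; "
            f"selecting all of them instead of {n_select}"
        )
    selected = ranked[:n_select]

    df = df.set_index("provenance")
    if "mean_hd_ratio" not in df.columns:
        df["mean_hd_ratio"] = df["mean_height"] / df["mean_dbh"]
    if "mean_volume" not in df.columns:
        df["mean_volume"] = tree_volume(df["mean_dbh"], df["mean_height"])

    traits = {
        "height": df["mean_height"],
        "dbh": df["mean_dbh"],
        "hd_ratio": df["mean_hd_ratio"],
        "volume": df["mean_volume"],
        "k": pd.Series({p: k_values[p] for p in present}),
    }
    total_means = {t: float(v.loc[present].mean()) for t, v in traits.items()}
    selected_means = {
        t: float(v.loc[selected].mean()) if selected else float("nan")
        for t, v in traits.items()
    }
    gains, gains_abs = {}, {}
    for t in traits:
        if selected and total_means[t] != 0:
            gains[t] = selection_gain(selected_means[t], total_means[t])
            gains_abs[t] = selection_gain(selected_means[t], total_means[t],
                                          absolute_base=True)
        else:
            gains[t] = gains_abs[t] = float("nan")
    return SelectionReport(
        site_id=site_id, selected=selected, rate=rate, criterion=criterion,
        selected_means=selected_means, total_means=total_means,
        gains=gains, gains_absolute_base=gains_abs,
        eligible=list(eligible["provenance"]),
    )
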