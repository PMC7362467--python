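"""Cathartic-activity bioassay statistics.

The laxative (cathartic) potency of a rhubarb extract is assayed in mice
through two experiments: a defecation test (incubation period until the
first charcoal-containing faeces, number and weight of charcoal faeces,
diarrhea incidence over 5 h) and a charcoal-meal small-intestine propulsion
test (fraction of the small intestine traversed by the marker in 20 min).

Group comparisons follow the conventional scheme for such designs: one-way
ANOVA across treatment groups, with post hoc pairwise comparisons by LSD
(pooled-variance t tests) when a homogeneity-of-variance test accepts, and
by Tamhane's T2 (Welch statistics with Sidak-adjusted levels) when it
rejects.  Diarrhea incidence is compared by an overall Pearson chi-square
test followed by pairwise two-sided Fisher exact tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DefecationRecord",
    "PropulsionRecord",
    "diarrhea_rate",
    "propelling_ratio",
    "anova_oneway",
    "posthoc",
    "diarrhea_tests",
    "read_defecation_csv",
    "read_propulsion_csv",
    "group_summary",
]


@dataclass(frozen=True)
class DefecationRecord:
    """Per-mouse defecation-test record.

    ``incubation_min`` is None for a mouse that never passed charcoal faeces
    within the 5-h observation window (treated as missing downstream).
    """

    mouse_id: str
    group: str
    dose: float  # g crude rhubarb / kg body weight; 0 for control
    incubation_min: float | None
    n_charcoal_feces: int
    feces_weight_mg: float
    loose_stools: bool

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.incubation_min is not None and self.incubation_min <= 0:
            raise ValueError("incubation_min must be positive when recorded")
        if self.n_charcoal_feces < 0 or self.feces_weight_mg < 0:
            raise ValueError("counts and weights must be non-negative")
        if self.n_charcoal_feces == 0 and self.incubation_min is not None:
            raise ValueError("incubation recorded although no charcoal feces appeared")


@dataclass(frozen=True)
class PropulsionRecord:
    """Per-mouse small-intestine propulsion record (distances in cm)."""

    mouse_id: str
    group: str
    dose: float
    charcoal_distance_cm: float
    intestine_length_cm: float

    def __post_init__(self) -> None:
        if self.charcoal_distance_cm <= 0 or self.intestine_length_cm <= 0:
            raise ValueError("distances must be positive")
        if self.charcoal_distance_cm > self.intestine_length_cm:
            raise ValueError("charcoal distance cannot exceed intestine length")

    @property
    def propelling_ratio(self) -> float:
        return propelling_ratio(self.charcoal_distance_cm, self.intestine_length_cm)


def diarrhea_rate(n_loose: int, n_total: int) -> float:
    """Diarrhea incidence in percent: 100 * n_loose / n_total, to 1 decimal."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_loose <= n_total:
        raise ValueError("need 0 <= n_loose <= n_total")
    return round(100.0 * n_loose / n_total, 1)


def propelling_ratio(distance_cm: float, total_cm: float) -> float:
    """Charcoal propelling ratio in percent: 100 * distance / total length."""
    if distance_cm <= 0 or total_cm <= 0:
        raise ValueError("distances must be positive")
    if distance_cm > total_cm:
        raise ValueError("distance cannot exceed total intestine length")
    return 100.0 * distance_cm / total_cm


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, df_b, df_w, 1.0
        return math.inf, df_b, df_w, 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def _levene_bf(groups: Sequence[np.ndarray]) -> float:
    """Brown–Forsythe (median-centered Levene) homogeneity-of-variance p."""
    return float(stats.levene(*groups, center="median").pvalue)


def posthoc(
    groups: Sequence[Sequence[float]],
    group_names: Sequence[str] | None = None,
    method: Literal["auto", "lsd", "tamhane_t2"] = "auto",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise post hoc comparisons after one-way ANOVA.

    ``auto`` selects LSD when the Brown–Forsythe homogeneity test accepts at
    ``alpha`` and Tamhane's T2 otherwise.  LSD performs pooled-variance t
    tests on the within-group mean square; Tamhane's T2 uses Welch t
    statistics with Sidak-adjusted per-comparison significance (the reported
    p is the Sidak-adjusted value 1-(1-p_welch)^m, capped at 1).

    Returns a table with columns group_1, group_2, mean_diff, p, significant
    and a ``method`` attribute recording the choice.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    k = len(arrays)
    if group_names is None:
        group_names = [f"group{i+1}" for i in range(k)]
    if method == "auto":
        p_lev = _levene_bf(arrays)
        method = "lsd" if p_lev >= alpha else "tamhane_t2"

    df_w = sum(a.size for a in arrays) - k
    ms_within = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_w
    m = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        diff = a.mean() - b.mean()
        if method == "lsd":
            if ms_within == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                se = math.sqrt(ms_within * (1 / a.size + 1 / b.size))
                t = diff / se
                p = float(2 * stats.t.sf(abs(t), df_w))
        else:  # tamhane_t2
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            if va + vb == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                t = diff / math.sqrt(va + vb)
                df = (va + vb) ** 2 / (
                    va**2 / (a.size - 1) + vb**2 / (b.size - 1)
                )
                p_raw = float(2 * stats.t.sf(abs(t), df))
                p = float(min(1.0, 1.0 - (1.0 - p_raw) ** m))  # Sidak adjustment
        rows.append(
            {
                "group_1": group_names[i],
                "group_2": group_names[j],
                "mean_diff": diff,
                "p": p,
                "significant": p < alpha,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["method"] = method
    return table


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×2 table (probability-mass definition)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def diarrhea_tests(
    counts: pd.DataFrame | np.ndarray,
    group_names: Sequence[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Overall chi-square and pairwise Fisher exact tests on diarrhea counts.

    ``counts`` is a groups × 2 table of (loose, not-loose) mouse counts.
    Returns (overall chi-square p, pairwise table with columns group_1,
    group_2 and fisher_p).
    """
    if isinstance(counts, pd.DataFrame):
        if group_names is None:
            group_names = [str(i) for i in counts.index]
        counts = counts.to_numpy()
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
        raise ValueError("counts must be a (>=2 groups) x 2 table")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("every group needs at least one mouse")
    if group_names is None:
        group_names = [f"group{i+1}" for i in range(counts.shape[0])]

    col_tot = counts.sum(axis=0)
    if np.any(col_tot == 0):
        # degenerate margin (e.g. no diarrhea anywhere): no association testable
        overall_p = 1.0
    else:
        overall_p = float(stats.chi2_contingency(counts, correction=False).pvalue)
    rows = [
        {
            "group_1": group_names[i],
            "group_2": group_names[j],
            "fisher_p": fisher_exact_2x2(counts[[i, j]]),
        }
        for i, j in combinations(range(counts.shape[0]), 2)
    ]
    return overall_p, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O and summaries


def read_defecation_csv(path) -> list[DefecationRecord]:
    """Columns: mouse_id,group,dose_g_per_kg,incubation_min,n_feces,feces_mg,loose."""
    df = pd.read_csv(path)
    recs = []
    for r in df.itertuples():
        inc = None if pd.isna(r.incubation_min) else float(r.incubation_min)
        recs.append(
            DefecationRecord(
                mouse_id=str(r.mouse_id),
                group=str(r.group),
                dose=float(r.dose_g_per_kg),
                incubation_min=inc,
                n_charcoal_feces=int(r.n_feces),
                feces_weight_mg=float(r.feces_mg),
                loose_stools=bool(r.loose),
            )
        )
    return recs


def read_propulsion_csv(path) -> list[PropulsionRecord]:
    """Columns: mouse_id,group,dose_g_per_kg,distance_cm,length_cm."""
    df = pd.read_csv(path)
    return [
        PropulsionRecord(
            mouse_id=str(r.mouse_id),
            group=str(r.group),
            dose=float(r.dose_g_per_kg),
            charcoal_distance_cm=float(r.distance_cm),
            intestine_length_cm=float(r.length_cm),
        )
        for r in df.itertuples()
    ]


def group_summary(records: Sequence[DefecationRecord]) -> pd.DataFrame:
    """Per-group mean ± sd of the defecation endpoints plus diarrhea rate.

    Mice that never passed charcoal faeces are excluded from the incubation
    mean (their count is reported in ``n_no_defecation``).
    """
    rows = []
    df = pd.DataFrame(
        [
            {
                "group": r.group,
                "dose": r.dose,
                "incubation_min": r.incubation_min,
                "n_feces": r.n_charcoal_feces,
                "feces_mg": r.feces_weight_mg,
                "loose": r.loose_stools,
            }
            for r in records
        ]
    )
    for (group, dose), grp in df.groupby(["group", "dose"], sort=False):
        inc = grp["incubation_min"].dropna()
        n_missing = int(grp["incubation_min"].isna().sum())
        if n_missing:
            warnings.warn(
                f"group {group}: {n_missing} mouse/mice never defecated; "
                "excluded from incubation mean",
                stacklevel=2,
            )
        rows.append(
            {
                "group": group,
                "dose": dose,
                "n": len(grp),
                "incubation_mean": inc.mean() if len(inc) else math.nan,
                "incubation_sd": inc.std(ddof=1) if len(inc) > 1 else math.nan,
                "n_feces_mean": grp["n_feces"].mean(),
                "n_feces_sd": grp["n_feces"].std(ddof=1),
                "feces_mg_mean": grp["feces_mg"].mean(),
                "feces_mg_sd": grp["feces_mg"].std(ddof=1),
                "n_loose": int(grp["loose"].sum()),
                "diarrhea_rate": diarrhea_rate(int(grp["loose"].sum()), len(grp)),
                "n_no_defecation": n_missing,
            }
        )
    return pd.DataFrame(rows)
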