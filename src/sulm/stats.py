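"""Group-level statistics for per-lesion glomerular densities and sULM metrics.

The clinical comparison is a one-way ANOVA across three independent groups —
tumors (n=6 lesions), pseudotumors (n=6 lesions) and the adjacent normal
cortex (n=12, one cortex measurement per lesion) — followed by Tukey-Kramer
post-hoc pairwise tests (studentized range, valid for unequal group sizes),
with a Shapiro-Wilk normality check reported alongside. Descriptive summaries
use the sample (n-1) standard deviation and render as ``mean ± SD [min-max]``
rounded half away from zero, matching the published presentation.

The per-lesion clinical tables ship as packaged CSV fixtures (patients,
lesions, acquisition settings, and glomerular densities per cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyResult",
    "summarize_group",
    "shapiro_wilk",
    "one_way_anova",
    "tukey_posthoc",
    "load_table",
    "density_groups",
    "clinical_aggregates",
    "run_clinical_fixture",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the published tables)."""
    factor = 10.0**decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    min: float
    max: float

    def display(self, decimals: int = 0) -> str:
        """Render as ``mean ± SD [min-max]`` at the printed precision."""
        fmt = f"{{:.{decimals}f}}"
        parts = [round_half_away(v, decimals) for v in (self.mean, self.sd, self.min, self.max)]
        m, s, lo, hi = (fmt.format(v) for v in parts)
        return f"{m} ± {s} [{lo}-{hi}]"


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class TukeyResult:
    """Pairwise Tukey-Kramer comparisons keyed by unordered label pairs."""

    mean_diff: dict[frozenset, float]
    p_adj: dict[frozenset, float]

    def p(self, a: str, b: str) -> float:
        return self.p_adj[frozenset((a, b))]

    def diff(self, a: str, b: str) -> float:
        return self.mean_diff[frozenset((a, b))]


def summarize_group(values, label: str = "") -> GroupSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else 0.0
    return GroupSummary(label, int(v.size), float(v.mean()), sd, float(v.min()), float(v.max()))


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p. Reported as a gate; never blocks the pipeline."""
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical between/within sums-of-squares decomposition.

    F = MS_between / MS_within with df (k-1, N-k). Raises when the
    within-group variance is zero (F undefined).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    if ss_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p)


def tukey_posthoc(groups: dict[str, np.ndarray]) -> TukeyResult:
    """Tukey-Kramer adjusted pairwise comparisons (studentized range, unequal n)."""
    one_way_anova(groups)  # validates the same preconditions
    labels = list(groups.keys())
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    res = sps.tukey_hsd(*arrays)
    mean_diff, p_adj = {}, {}
    for i, j in combinations(range(len(labels)), 2):
        key = frozenset((labels[i], labels[j]))
        mean_diff[key] = float(arrays[i].mean() - arrays[j].mean())
        p_adj[key] = float(res.pvalue[i, j])
    return TukeyResult(mean_diff, p_adj)


# ---------------------------------------------------------------------------
# Packaged clinical tables


def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged per-lesion clinical tables.

    ``name`` is one of ``patients``, ``lesions``, ``ceus``, ``densities``
    (patient demographics; lesion characteristics; CEUS acquisition settings;
    per-lesion glomerular densities with the adjacent-cortex control).
    """
    fname = {
        "patients": "table_patients.csv",
        "lesions": "table_lesions.csv",
        "ceus": "table_ceus.csv",
        "densities": "table_densities.csv",
    }[name]
    with resources.files("sulm.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def density_groups() -> dict[str, np.ndarray]:
    """The three density groups: per-lesion tumor and pseudotumor values and
    the pooled 12 adjacent-cortex values."""
    dens = load_table("densities")
    tumor = dens.loc[dens["group"] == "tumor", "lesion_density_per_cm2"].to_numpy(float)
    pseudo = dens.loc[dens["group"] == "pseudotumor", "lesion_density_per_cm2"].to_numpy(float)
    cortex = dens["cortex_density_per_cm2"].to_numpy(float)
    return {"tumor": tumor, "pseudotumor": pseudo, "cortex": cortex}


def clinical_aggregates() -> dict[str, float]:
    """Recomputed aggregate rows of the clinical tables (before rounding)."""
    ceus = load_table("ceus")
    lesions = load_table("lesions")
    out = {}
    for grp in ("tumor", "pseudotumor"):
        c = ceus[ceus["group"] == grp]
        out[f"{grp}_frame_rate_hz"] = float(c["frame_rate_hz"].mean())
        out[f"{grp}_depth_mm"] = float(c["depth_mm"].mean())
        out[f"{grp}_loop_duration_s"] = float(c["loop_duration_s"].mean())
        le = lesions[lesions["group"] == grp]
        out[f"{grp}_diameter_mm"] = float(le["max_diameter_mm"].mean())
    return out


def run_clinical_fixture() -> dict:
    """Full statistical report on the packaged per-lesion density table.

    Returns per-group summaries (with display strings), the omnibus ANOVA,
    Tukey-Kramer pairwise p-values, and Shapiro-Wilk per group.
    """
    groups = density_groups()
    summaries = {k: summarize_group(v, k) for k, v in groups.items()}
    anova = one_way_anova(groups)
    tukey = tukey_posthoc(groups)
    shapiro = {k: shapiro_wilk(v) for k, v in groups.items()}
    return {
        "groups": groups,
        "summaries": summaries,
        "display": {k: s.display(0) for k, s in summaries.items()},
        "anova": anova,
        "tukey": tukey,
        "shapiro": shapiro,
    }


def format_report(report: dict) -> str:
    lines = ["Glomerular density (per cm^2) by group:"]
    for k, disp in report["display"].items():
        lines.append(f"  {k:12s} n={report['summaries'][k].n:2d}  {disp}")
    a = report["anova"]
    lines.append(
        f"One-way ANOVA: F({a.df_between}, {a.df_within}) = {a.F:.2f}, p = {a.p_value:.2e}"
    )
    tk = report["tukey"]
    for pair in tk.p_adj:
        a_, b_ = sorted(pair)
        lines.append(f"Tukey {a_} vs {b_}: p = {tk.p_adj[pair]:.4g}")
    return "\n".join(lines)
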