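"""Colony productivity index, effect-size sensitivity analysis and statistics.

The productivity index combines three tray-level life-history traits into a
single number approximating population growth potential:

    PI = ln(100 · F · S) / D

with F the tray's mean first-clutch fecundity (eggs/female), S the
larva-to-adult survival proportion, D the mean development time (days), and
the factor 100 an assumed 100% egg hatch expressed as a percentage.  An
alternative variant ln(F · S) / D is available behind a switch.

The sensitivity analysis recomputes PI after freezing chosen traits at their
grand mean ("holding D/S/F constant"), fits a fixed-effects two-way ANOVA
(container size × treatment) to each simulated PI, and reports η² effect
sizes — the share of the total sum of squares explained by each term.

Also provided: one-way ANOVA intra-class correlation (repeatability) with a
seeded percentile bootstrap, and a tie-corrected Kruskal–Wallis test with
Dunn pairwise post-hoc comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


class LifeHistoryError(ValueError):
    """Invalid life-history input."""


PI_FORMULAS = ("ln100fs", "lnfs")

#: Hold-constant scenarios of the sensitivity analysis: frozen variables per name.
SENSITIVITY_SCENARIOS: dict[str, tuple[str, ...]] = {
    "none": (),
    "D": ("D",),
    "S": ("S",),
    "F": ("F",),
    "SF": ("S", "F"),
}


def productivity(F: float, S: float, D: float, formula: str = "ln100fs") -> float:
    """Productivity index of one tray.

    Parameters
    ----------
    F : mean fecundity (eggs per female).
    S : larva-to-adult survival proportion in [0, 1].
    D : mean development time in days (> 0).
    formula : ``"ln100fs"`` for ln(100·F·S)/D (default) or ``"lnfs"`` for
        ln(F·S)/D.

    A non-positive log argument is a domain error; arguments in (0, 1)
    (negative PI) are allowed with a warning, since they indicate a tray
    producing less than one expected adult-equivalent.
    """
    if formula not in PI_FORMULAS:
        raise LifeHistoryError(f"unknown PI formula {formula!r}")
    if D <= 0:
        raise LifeHistoryError("development time D must be positive")
    if not 0 <= S <= 1:
        raise LifeHistoryError("survival S must lie in [0, 1]")
    arg = F * S * (100.0 if formula == "ln100fs" else 1.0)
    if arg <= 0:
        raise LifeHistoryError("F*S must be positive for the log")
    if arg < 1 and not math.isclose(arg, 1.0, rel_tol=1e-12):
        warnings.warn("productivity log argument < 1; PI is negative", stacklevel=2)
    return math.log(arg) / D


def productivity_table(
    table: pd.DataFrame,
    formula: str = "ln100fs",
    fecundity_col: str = "Fecundity",
    survival_col: str = "Survival",
    development_col: str = "Development",
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-tray PI column for a tidy life-history table.

    Returns a copy of the table with a ``PI`` column and a list of per-row
    error reports for rows with missing or invalid fields (those rows get
    NaN PI and are otherwise skipped, not silently zeroed).
    """
    out = table.copy()
    pi = np.full(len(out), np.nan)
    errors: list[dict] = []
    for i, (_, row) in enumerate(out.iterrows()):
        try:
            f, s, d = (float(row[c]) for c in (fecundity_col, survival_col, development_col))
            if any(math.isnan(v) for v in (f, s, d)):
                raise LifeHistoryError("missing value")
            pi[i] = productivity(f, s, d, formula=formula)
        except (KeyError, TypeError, ValueError) as exc:
            errors.append({"row": i, "error": str(exc)})
    out["PI"] = pi
    return out, errors


def eta_squared(ss_effect: float, ss_total: float) -> float:
    """Effect size η²: the share of the total sum of squares of one term."""
    if ss_total <= 0:
        raise LifeHistoryError("total sum of squares must be positive")
    if not 0 <= ss_effect <= ss_total:
        raise LifeHistoryError("need 0 <= ss_effect <= ss_total")
    return ss_effect / ss_total


def _anova_eta(table: pd.DataFrame, size_col: str, treatment_col: str) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA on PI with η² per term.

    Uses a sequential (Type I) decomposition in the fixed order
    size → treatment → interaction so that the term and residual sums of
    squares tile the total exactly; for balanced designs this coincides with
    the Type II/III decomposition.
    """
    data = table.rename(columns={size_col: "size_", treatment_col: "treat_"})
    if data["PI"].std(ddof=0) < 1e-12:
        # degenerate: simulated PI constant (e.g. every trait frozen)
        terms = [f"C(size_)", f"C(treat_)", "C(size_):C(treat_)", "Residual"]
        n_size = data["size_"].nunique()
        n_tr = data["treat_"].nunique()
        dfs = [n_size - 1, n_tr - 1, (n_size - 1) * (n_tr - 1)]
        dfs.append(len(data) - 1 - sum(dfs))
        out = pd.DataFrame(
            {
                "term": ["size", "treatment", "size:treatment", "Residual"],
                "df": dfs,
                "sum_sq": 0.0,
                "F": np.nan,
                "p": np.nan,
                "eta_sq": 0.0,
            }
        )
        return out
    model = smf.ols("PI ~ C(size_) * C(treat_)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    ss_total = float(aov["sum_sq"].sum())
    aov = aov.reset_index().rename(
        columns={"index": "term", "PR(>F)": "p", "df": "df", "sum_sq": "sum_sq"}
    )
    names = {
        "C(size_)": "size",
        "C(treat_)": "treatment",
        "C(size_):C(treat_)": "size:treatment",
        "Residual": "Residual",
    }
    aov["term"] = aov["term"].map(names)
    aov["eta_sq"] = aov["sum_sq"] / ss_total
    return aov[["term", "df", "sum_sq", "F", "p", "eta_sq"]]


def simulated_productivity(
    table: pd.DataFrame,
    hold: tuple[str, ...] = (),
    formula: str = "ln100fs",
) -> pd.Series:
    """Per-tray PI after freezing the given traits at their grand mean.

    ``hold`` is a subset of {"D", "S", "F"} referring to the Development,
    Survival and Fecundity columns; grand means are unweighted means over
    trays.
    """
    cols = {"D": "Development", "S": "Survival", "F": "Fecundity"}
    bad = set(hold) - set(cols)
    if bad:
        raise LifeHistoryError(f"unknown hold variables: {sorted(bad)}")
    work = table.copy()
    for var in hold:
        col = cols[var]
        work[col] = work[col].astype(float).mean()
    with_pi, errors = productivity_table(work, formula=formula)
    if errors:
        raise LifeHistoryError(f"invalid rows in life-history table: {errors}")
    return with_pi["PI"]


@dataclass
class SensitivityReport:
    """η² effect sizes for each hold-constant scenario.

    ``table`` has one row per scenario × ANOVA term with columns
    ``scenario, held, term, df, sum_sq, F, p, eta_sq``.
    """

    table: pd.DataFrame
    scenarios: dict[str, tuple[str, ...]] = field(default_factory=dict)
    formula: str = "ln100fs"

    def eta(self, scenario: str, term: str) -> float:
        sel = self.table[(self.table["scenario"] == scenario) & (self.table["term"] == term)]
        if sel.empty:
            raise KeyError((scenario, term))
        return float(sel["eta_sq"].iloc[0])

    def summary(self) -> str:
        lines = ["Productivity sensitivity analysis (two-way fixed-effects ANOVA)"]
        lines.append(f"PI formula: {self.formula}")
        for scen, held in self.scenarios.items():
            held_txt = ", ".join(held) if held else "none"
            lines.append(f"\nscenario {scen!r} (held constant: {held_txt})")
            sub = self.table[self.table["scenario"] == scen]
            lines.append(
                sub[["term", "df", "F", "p", "eta_sq"]].to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                )
            )
        return "\n".join(lines)


def sensitivity_analysis(
    table: pd.DataFrame,
    scenarios: dict[str, tuple[str, ...]] | None = None,
    size_col: str = "Size",
    treatment_col: str | None = None,
    formula: str = "ln100fs",
) -> SensitivityReport:
    """Hold-one-factor-constant productivity sensitivity analysis.

    For each scenario, PI is recomputed with the scenario's traits frozen at
    their grand mean and a two-way ANOVA (container size × treatment) is
    fitted; η² per term quantifies how much variance each design factor
    explains.  Requires at least two trays per size × treatment cell.
    """
    if scenarios is None:
        scenarios = dict(SENSITIVITY_SCENARIOS)
    if treatment_col is None:
        for cand in ("Diet", "Density", "Treatment"):
            if cand in table.columns:
                treatment_col = cand
                break
        else:
            raise LifeHistoryError("no treatment column (Diet/Density/Treatment) found")
    cells = table.groupby([size_col, treatment_col]).size()
    full = (
        table[size_col].nunique() * table[treatment_col].nunique()
    )
    if len(cells) < full:
        have = set(cells.index)
        missing = [
            c
            for c in itertools.product(
                table[size_col].unique(), table[treatment_col].unique()
            )
            if c not in have
        ]
        raise LifeHistoryError(f"empty design cells: {missing}")
    if (cells < 2).any():
        thin = list(cells[cells < 2].index)
        raise LifeHistoryError(f"cells with fewer than 2 trays: {thin}")
    rows = []
    for name, held in scenarios.items():
        work = table.copy()
        work["PI"] = simulated_productivity(table, hold=held, formula=formula).to_numpy()
        aov = _anova_eta(work, size_col, treatment_col)
        aov.insert(0, "held", "+".join(held) if held else "")
        aov.insert(0, "scenario", name)
        rows.append(aov)
    return SensitivityReport(
        table=pd.concat(rows, ignore_index=True), scenarios=dict(scenarios), formula=formula
    )


@dataclass(frozen=True)
class ICCResult:
    """One-way ANOVA intra-class correlation with bootstrap CI."""

    r: float
    ci_low: float
    ci_high: float
    ms_between: float
    ms_within: float
    k: float
    clamped: bool

    def __iter__(self):
        yield self.r
        yield (self.ci_low, self.ci_high)


def _icc_point(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, float, float, bool]:
    uniq, inv = np.unique(groups, return_inverse=True)
    g = len(uniq)
    sizes = np.bincount(inv).astype(float)
    grand = values.mean()
    means = np.array([values[inv == i].mean() for i in range(g)])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(np.sum((values - means[inv]) ** 2))
    n = float(len(values))
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    k = g / np.sum(1.0 / sizes)  # harmonic-mean group size
    r = (msb - msw) / (msb + (k - 1) * msw)
    clamped = False
    if r < 0:
        r, clamped = 0.0, True
    return r, msb, msw, k, clamped


def repeatability_icc(
    values,
    group_ids,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> ICCResult:
    """Repeatability (one-way random-effects ICC) of grouped measurements.

    ``R = (MSB − MSW) / (MSB + (k − 1)·MSW)`` with MSB/MSW the between- and
    within-group mean squares and k the harmonic-mean group size; the share
    of measurement variance attributable to differences among groups (e.g.
    containers photographed repeatedly).  The CI is a seeded percentile
    bootstrap resampling whole groups.  Negative estimates are clamped to 0
    and flagged.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_ids)
    if values.shape != groups.shape:
        raise LifeHistoryError("values and group_ids must have equal length")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise LifeHistoryError("need at least two groups")
    if min(np.sum(groups == u) for u in uniq) < 2:
        raise LifeHistoryError("need at least two values per group")
    r, msb, msw, k, clamped = _icc_point(values, groups)
    rng = np.random.default_rng(seed)
    by_group = {u: values[groups == u] for u in uniq}
    boots = np.empty(n_boot)
    for b in range(n_boot):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        v = np.concatenate([by_group[u] for u in chosen])
        gid = np.concatenate(
            [np.full(len(by_group[u]), i) for i, u in enumerate(chosen)]
        )
        boots[b], *_ = _icc_point(v, gid)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ICCResult(
        r=float(r), ci_low=float(lo), ci_high=float(hi),
        ms_between=msb, ms_within=msw, k=float(k), clamped=clamped,
    )


@dataclass(frozen=True)
class KruskalDunnResult:
    """Kruskal–Wallis H with Dunn pairwise z statistics."""

    h: float
    p: float
    dunn: pd.DataFrame

    def summary(self) -> str:
        head = f"Kruskal-Wallis H = {self.h:.4f}, p = {self.p:.4g}\n"
        return head + self.dunn.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def kruskal_dunn(samples, labels=None, adjust: str = "none") -> KruskalDunnResult:
    """Tie-corrected Kruskal–Wallis test with Dunn pairwise comparisons.

    Parameters
    ----------
    samples : sequence of 1-D arrays, one per group (e.g. per region).
    labels : optional group names (defaults to 0..g-1).
    adjust : multiplicity adjustment for the Dunn p-values: ``"none"``
        (default, unadjusted pairwise p) or ``"holm"``.

    With all values identical across groups the test is degenerate and
    H = 0, p = 1 is returned.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) < 1 for s in samples):
        raise LifeHistoryError("need >= 2 groups with >= 1 observation each")
    if labels is None:
        labels = list(range(len(samples)))
    if adjust not in ("none", "holm"):
        raise LifeHistoryError(f"unknown adjustment {adjust!r}")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    # Dunn: pairwise z from pooled mean ranks with tie correction
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    sizes = [len(s) for s in samples]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(samples))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var) if var > 0 else 0.0
        p_ij = 2.0 * stats.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, p_ij))
    dunn = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    if adjust == "holm" and len(dunn):
        dunn["p_adj"] = multipletests(dunn["p"], method="holm")[1]
    else:
        dunn["p_adj"] = dunn["p"]
    return KruskalDunnResult(h=float(h), p=float(p), dunn=dunn)


def diet_concentration(mg_per_larva_day: float, n_larvae: int, water_volume_ml: float) -> float:
    """Diet concentration (mg/ml/day) implied by a treatment row."""
    if water_volume_ml <= 0:
        raise LifeHistoryError("water volume must be positive")
    return mg_per_larva_day * n_larvae / water_volume_ml


def stocking_density(n_larvae: int, water_volume_ml: float) -> float:
    """Stocking density (larva/ml) of a treatment row."""
    if water_volume_ml <= 0:
        raise LifeHistoryError("water volume must be positive")
    return n_larvae / water_volume_ml
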