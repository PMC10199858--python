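"""Group summaries, dose-arm statistics, and saturation metrics.

The study convention: organ and plasma measures are summarized as
mean ± SD and compared with one-way ANOVA followed by Tukey's HSD; tumor
measures are non-parametric, summarized as median (IQR) and compared with
Kruskal–Wallis followed by pairwise two-sided Wilcoxon rank-sum tests with
Bonferroni correction. Saturation of target-specific uptake is expressed
as the fraction of the specific (above-floor) signal blocked at each mass
dose.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DoseGroupSummary",
    "ComparisonResult",
    "SaturationReport",
    "summarize_group",
    "compare_parametric",
    "compare_nonparametric",
    "saturation_report",
]


@dataclass(frozen=True)
class DoseGroupSummary:
    mass_dose_mg: float
    time_h: float
    n: int
    central: float                       # median or mean
    spread: tuple[float, float]          # (q1, q3) or (sd, sd)
    style: str                           # nonparametric | parametric
    measure_kind: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.style == "nonparametric":
            q1, q3 = self.spread
            if not q1 <= self.central <= q3:
                raise ValueError("need q1 <= median <= q3")


@dataclass(frozen=True)
class PairwiseTest:
    pair: tuple[float, float]
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonResult:
    test: str                            # anova_tukey | kw_wilcoxon_bonferroni
    global_stat: float                   # F or H
    df: int
    pairwise: tuple[PairwiseTest, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for pw in self.pairwise:
            if pw.p_adjusted < pw.p_raw - 1e-12:
                raise ValueError("adjusted p cannot be below raw p")


@dataclass(frozen=True)
class SaturationReport:
    """Fraction of the target-specific signal blocked at each mass dose.

    ``specific_fraction_blocked[d] = 1 − (Ki_d − Ki_floor)/(Ki_ref − Ki_floor)``
    with the reference (unblocked) and floor (fully blocked) doses given.
    Classification: full if ≥ ``full_threshold``, partial if ≥
    ``partial_threshold``, none below.
    """

    region: str
    ki_by_dose: dict[float, float]
    ref_dose: float
    floor_dose: float
    specific_fraction_blocked: dict[float, float] = field(default_factory=dict)
    classification: dict[float, str] = field(default_factory=dict)


def summarize_group(values, style: str = "nonparametric",
                    mass_dose_mg: float = float("nan"),
                    time_h: float = float("nan"),
                    measure_kind: str = "") -> DoseGroupSummary:
    """Median (IQR, linear-interpolation quantiles) or mean (SD, n−1)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    if style == "nonparametric":
        central = float(np.median(v))
        spread = (float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75)))
    elif style == "parametric":
        central = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        spread = (sd, sd)
    else:
        raise ValueError(f"unknown style {style!r}")
    return DoseGroupSummary(mass_dose_mg=mass_dose_mg, time_h=time_h,
                            n=int(v.size), central=central, spread=spread,
                            style=style, measure_kind=measure_kind)


def _validated_groups(groups: dict) -> dict[float, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    out = {}
    for dose, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size < 1:
            raise ValueError(f"group {dose} is empty")
        out[float(dose)] = v
    return out


def compare_parametric(groups: dict, alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Supports unbalanced groups. All-identical data leave F undefined and
    raise.
    """
    g = _validated_groups(groups)
    allv = np.concatenate(list(g.values()))
    if allv.size <= len(g):
        raise ValueError("total n must exceed the number of groups")
    if np.ptp(allv) == 0:
        raise ValueError("all values identical: F is undefined")
    doses = sorted(g)
    f_stat, _ = stats.f_oneway(*(g[d] for d in doses))
    tukey = stats.tukey_hsd(*(g[d] for d in doses))
    pairwise = []
    for i, j in itertools.combinations(range(len(doses)), 2):
        p = float(tukey.pvalue[i, j])
        pairwise.append(PairwiseTest(
            pair=(doses[i], doses[j]), statistic=float(tukey.statistic[i, j]),
            p_raw=p, p_adjusted=p))  # HSD p-values are already family-adjusted
    return ComparisonResult(test="anova_tukey", global_stat=float(f_stat),
                            df=len(doses) - 1, pairwise=tuple(pairwise),
                            alpha=alpha)


def compare_nonparametric(groups: dict, alpha: float = 0.05
                          ) -> ComparisonResult:
    """Kruskal–Wallis plus pairwise two-sided rank-sum tests (Bonferroni).

    Pairwise tests use the exact rank-sum distribution when the smaller
    group has ≤ 10 observations and there are no ties, and the mid-rank
    normal approximation otherwise. Bonferroni multiplies by the number of
    pairwise tests, capped at 1.
    """
    g = _validated_groups(groups)
    doses = sorted(g)
    allv = np.concatenate(list(g.values()))
    if np.ptp(allv) == 0:
        h = 0.0
    else:
        h, _ = stats.kruskal(*(g[d] for d in doses))
    pairs = list(itertools.combinations(doses, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        x, y = g[a], g[b]
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) \
            else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        p_raw = float(res.pvalue)
        pairwise.append(PairwiseTest(pair=(a, b), statistic=float(res.statistic),
                                     p_raw=p_raw,
                                     p_adjusted=min(1.0, m * p_raw)))
    return ComparisonResult(test="kw_wilcoxon_bonferroni",
                            global_stat=float(h), df=len(doses) - 1,
                            pairwise=tuple(pairwise), alpha=alpha)


def saturation_report(ki_by_dose: dict, ref_dose: float, floor_dose: float,
                      region: str = "", full_threshold: float = 0.95,
                      partial_threshold: float = 0.5) -> SaturationReport:
    """Classify target saturation per mass dose from Ki (or ratio) values."""
    ki = {float(d): float(v) for d, v in ki_by_dose.items()}
    if ref_dose not in ki or floor_dose not in ki:
        raise ValueError("reference and floor doses must be present")
    ki_ref, ki_floor = ki[ref_dose], ki[floor_dose]
    if ki_ref <= ki_floor:
        raise ValueError("degenerate: reference Ki must exceed the floor Ki")
    fractions, classes = {}, {}
    for d, v in ki.items():
        frac = 1.0 - (v - ki_floor) / (ki_ref - ki_floor)
        fractions[d] = frac
        if frac >= full_threshold:
            classes[d] = "full"
        elif frac >= partial_threshold:
            classes[d] = "partial"
        else:
            classes[d] = "none"
    return SaturationReport(region=region, ki_by_dose=ki, ref_dose=ref_dose,
                            floor_dose=floor_dose,
                            specific_fraction_blocked=fractions,
                            classification=classes)
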