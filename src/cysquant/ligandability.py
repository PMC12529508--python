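"""Ligandability calling and screen-level analytics.

Implements the two-clause calling rule (mean log2(H/L) >= threshold,
with a both-replicates requirement when the replicate SD exceeds the
gate), the anti-ligandable mirror rule, per-compound reactivity
summaries, screen totals with promiscuous-compound exclusion,
reference-database categorization, hit-rate analysis and
stereoselectivity comparisons.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cysquant.io_formats import ReferenceSiteDB
from cysquant.quantification import SiteConditionResult, UNQUANTIFIED
from cysquant.site_mapping import CysteineSiteID

__all__ = [
    "CallConfig",
    "CompoundSummary",
    "HitRateResult",
    "ScreenTotals",
    "StereoComparison",
    "call_all",
    "call_antiligandable",
    "call_site",
    "categorize_vs_reference",
    "dose_response_table",
    "hit_rate_analysis",
    "parse_dose_condition",
    "screen_totals",
    "stereo_compare",
    "summarize_compound",
]

LIGANDED = "liganded"
NOT_LIGANDED = "not-liganded"
ANTI_LIGANDED = "anti-liganded"

KNOWN_LIGANDABLE = "known-ligandable"
KNOWN_IDENTIFIED_ONLY = "known-identified-only"
NOVEL = "novel"


@dataclass(frozen=True)
class CallConfig:
    """Thresholds and filters for ligandability calling.

    ``threshold`` and ``sd_gate`` default to 2.0 on the log2(H/L) scale;
    ``excluded_compounds`` lists promiscuously reactive conditions left
    out of screen totals.
    """

    threshold: float = 2.0
    sd_gate: float = 2.0
    anti_threshold: float = -2.0
    excluded_compounds: tuple[str, ...] = ()
    required_replicates: int = 2

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.sd_gate <= 0:
            raise ValueError("sd_gate must be positive")
        if self.anti_threshold >= 0:
            raise ValueError("anti_threshold must be negative")


def call_site(result: SiteConditionResult, cfg: CallConfig = CallConfig()) -> str:
    """Apply the two-clause calling rule to one site x condition result.

    Liganded when the replicate mean meets the threshold and either the
    replicate SD is within the gate or every individual replicate meets
    the threshold on its own.  The anti-liganded rule is the mirror image
    at ``anti_threshold``.
    """
    if result.call == UNQUANTIFIED or result.n_replicates_quantified < cfg.required_replicates:
        return UNQUANTIFIED
    mean = result.mean_log2
    sd = result.sd_log2 if result.sd_log2 is not None else 0.0
    ratios = result.ratios
    if mean >= cfg.threshold and (
        sd <= cfg.sd_gate or all(r >= cfg.threshold for r in ratios)
    ):
        return LIGANDED
    if mean <= cfg.anti_threshold and (
        sd <= cfg.sd_gate or all(r <= cfg.anti_threshold for r in ratios)
    ):
        return ANTI_LIGANDED
    return NOT_LIGANDED


def call_antiligandable(
    result: SiteConditionResult, cfg: CallConfig = CallConfig()
) -> bool:
    """True when the site shows compound-induced increased probe labeling
    (mirror of the liganded rule at the negative threshold)."""
    return call_site(result, cfg) == ANTI_LIGANDED


def call_all(
    results: Iterable[SiteConditionResult], cfg: CallConfig = CallConfig()
) -> list[SiteConditionResult]:
    """Finalize the ``call`` field of every result in place."""
    out = []
    for r in results:
        r.call = call_site(r, cfg)
        out.append(r)
    return out


@dataclass(frozen=True)
class CompoundSummary:
    condition: str
    n_identified: int
    n_liganded: int
    fraction_liganded: float
    excluded_from_totals: bool


def summarize_compound(
    results: Sequence[SiteConditionResult],
    cfg: CallConfig = CallConfig(),
    condition: Optional[str] = None,
) -> CompoundSummary:
    """Reactivity summary for one condition: the fraction of identified
    cysteines it ligands."""
    conditions = {r.condition for r in results}
    if condition is None:
        if len(conditions) != 1:
            raise ValueError(f"results span multiple conditions: {sorted(conditions)}")
        condition = next(iter(conditions))
    elif conditions - {condition}:
        raise ValueError("results do not all belong to the stated condition")
    identified = [r for r in results if r.call != UNQUANTIFIED]
    n_liganded = sum(1 for r in identified if r.call == LIGANDED)
    n_identified = len(identified)
    return CompoundSummary(
        condition=condition,
        n_identified=n_identified,
        n_liganded=n_liganded,
        fraction_liganded=(n_liganded / n_identified) if n_identified else 0.0,
        excluded_from_totals=condition in cfg.excluded_compounds,
    )


@dataclass(frozen=True)
class ScreenTotals:
    n_unique_sites: int
    n_unique_proteins: int
    n_liganded_total: int


def screen_totals(
    results: Iterable[SiteConditionResult], cfg: CallConfig = CallConfig()
) -> ScreenTotals:
    """Screen-wide unique quantified sites/proteins, and the number of
    sites liganded by at least one non-excluded condition."""
    sites: set[str] = set()
    proteins: set[str] = set()
    liganded: set[str] = set()
    for r in results:
        if r.call == UNQUANTIFIED:
            continue
        key = r.site.render()
        sites.add(key)
        proteins.add(r.site.accession)
        if r.call == LIGANDED and r.condition not in cfg.excluded_compounds:
            liganded.add(key)
    return ScreenTotals(
        n_unique_sites=len(sites),
        n_unique_proteins=len(proteins),
        n_liganded_total=len(liganded),
    )


def categorize_vs_reference(
    results: Iterable[SiteConditionResult],
    refdb: ReferenceSiteDB,
) -> tuple[dict[str, str], dict[str, int]]:
    """Label each quantified site against the reference database.

    Categories partition the quantified site set into known-ligandable,
    known-identified-only and novel; the summary additionally counts the
    liganded-and-novel subset.
    """
    categories: dict[str, str] = {}
    liganded_sites: set[str] = set()
    for r in results:
        if r.call == UNQUANTIFIED:
            continue
        key = r.site.render()
        if r.call == LIGANDED:
            liganded_sites.add(key)
        if key in categories:
            continue
        if refdb.is_ligandable(key):
            categories[key] = KNOWN_LIGANDABLE
        elif refdb.is_identified(key):
            categories[key] = KNOWN_IDENTIFIED_ONLY
        else:
            categories[key] = NOVEL
    counts = {KNOWN_LIGANDABLE: 0, KNOWN_IDENTIFIED_ONLY: 0, NOVEL: 0}
    for cat in categories.values():
        counts[cat] += 1
    counts["liganded-novel"] = sum(
        1 for s in liganded_sites if categories[s] == NOVEL
    )
    return categories, counts


@dataclass
class HitRateResult:
    """Per-condition reference hit rates and per-site liganding counts.

    ``per_condition`` maps condition -> fraction of its liganded sites
    that are reference-ligandable (``None`` when it liganded nothing).
    ``per_site`` maps site -> (n_conditions_liganding, total_conditions).
    """

    per_condition: dict[str, Optional[float]]
    per_site: dict[str, tuple[int, int]]
    total_conditions: int


def hit_rate_analysis(
    results: Iterable[SiteConditionResult],
    refdb: ReferenceSiteDB,
) -> HitRateResult:
    """Hit-rate analysis across all conditions (dose points count as
    separate conditions)."""
    liganded_by_condition: dict[str, set[str]] = {}
    conditions: set[str] = set()
    for r in results:
        conditions.add(r.condition)
        if r.call == LIGANDED:
            liganded_by_condition.setdefault(r.condition, set()).add(r.site.render())
    total = len(conditions)
    per_condition: dict[str, Optional[float]] = {}
    for cond in sorted(conditions):
        liganded = liganded_by_condition.get(cond, set())
        if not liganded:
            per_condition[cond] = None
            continue
        n_ref = sum(1 for s in liganded if refdb.is_ligandable(s))
        per_condition[cond] = n_ref / len(liganded)
    site_counts: dict[str, int] = {}
    for liganded in liganded_by_condition.values():
        for s in liganded:
            site_counts[s] = site_counts.get(s, 0) + 1
    per_site = {s: (n, total) for s, n in sorted(site_counts.items())}
    return HitRateResult(
        per_condition=per_condition, per_site=per_site, total_conditions=total
    )


@dataclass(frozen=True)
class StereoComparison:
    site: CysteineSiteID
    mean_a: float
    mean_b: float
    delta: float
    p_value: float
    selective_for: str  # "A", "B" or "none"


def _welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sample unequal-variance (Welch) t-test p-value; degenerate
    zero-variance identical samples yield 1.0."""
    import warnings

    with warnings.catch_warnings():
        # identical degenerate samples trigger a precision warning; they
        # are mapped to p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):
        return 1.0
    return max(p, np.nextafter(0.0, 1.0))


def stereo_compare(
    results_a: Iterable[SiteConditionResult],
    results_b: Iterable[SiteConditionResult],
    min_delta: float = 1.0,
    alpha: float = 0.05,
    adjust: Optional[str] = None,
) -> tuple[list[StereoComparison], dict[str, int]]:
    """Compare per-site engagement between two conditions (for example a
    pair of atropisomers at matched concentration).

    For each site quantified with >= 2 replicates under both conditions,
    computes ``delta = mean_a - mean_b`` and a Welch t-test p-value on
    the replicate log2 ratios; a site is selective for A when
    ``delta >= min_delta`` and ``p < alpha`` (B symmetric).  Sites
    missing on either side are skipped and tallied.  ``adjust="bh"``
    applies Benjamini-Hochberg adjustment before the significance test.
    """
    a_by_site = {r.site.render(): r for r in results_a}
    b_by_site = {r.site.render(): r for r in results_b}
    skipped = {"missing-in-a": 0, "missing-in-b": 0, "insufficient-replicates": 0}
    raw: list[tuple[SiteConditionResult, SiteConditionResult]] = []
    for key in sorted(set(a_by_site) | set(b_by_site)):
        ra, rb = a_by_site.get(key), b_by_site.get(key)
        if ra is None:
            skipped["missing-in-a"] += 1
            continue
        if rb is None:
            skipped["missing-in-b"] += 1
            continue
        if ra.n_replicates_quantified < 2 or rb.n_replicates_quantified < 2:
            skipped["insufficient-replicates"] += 1
            continue
        raw.append((ra, rb))

    p_values = [ _welch_p(ra.ratios, rb.ratios) for ra, rb in raw ]
    if adjust == "bh":
        p_values = list(stats.false_discovery_control(p_values, method="bh"))
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    comparisons = []
    for (ra, rb), p in zip(raw, p_values):
        delta = ra.mean_log2 - rb.mean_log2
        if delta >= min_delta and p < alpha:
            selective = "A"
        elif -delta >= min_delta and p < alpha:
            selective = "B"
        else:
            selective = "none"
        comparisons.append(
            StereoComparison(
                site=ra.site,
                mean_a=ra.mean_log2,
                mean_b=rb.mean_log2,
                delta=delta,
                p_value=min(p, 1.0),
                selective_for=selective,
            )
        )
    return comparisons, skipped


_DOSE_RE = re.compile(r"^(?P<name>.+)@(?P<conc>\d+(?:\.\d+)?)(?P<unit>\D*)$")


def parse_dose_condition(condition: str) -> tuple[str, float, str]:
    """Split a ``name@<conc><unit>`` condition into its parts."""
    m = _DOSE_RE.match(condition)
    if not m:
        raise ValueError(f"condition {condition!r} has no parseable concentration")
    return m.group("name"), float(m.group("conc")), m.group("unit")


def dose_response_table(results: Iterable[SiteConditionResult]) -> pd.DataFrame:
    """Site x condition matrix of mean log2 ratios across a dose range.

    Columns are ordered by compound name then numeric concentration;
    rows sorted by descending max ``|mean|``; unquantified cells are NaN
    (rendered ``N.D.`` on write).
    """
    cells: dict[str, dict[str, float]] = {}
    order: dict[str, tuple[str, float]] = {}
    for r in results:
        name, conc, _ = parse_dose_condition(r.condition)
        order[r.condition] = (name, conc)
        if r.call == UNQUANTIFIED or r.mean_log2 is None:
            continue
        cells.setdefault(r.site.render(), {})[r.condition] = r.mean_log2
    columns = sorted(order, key=lambda c: order[c])
    df = pd.DataFrame.from_dict(cells, orient="index", columns=columns)
    df = df.reindex(columns=columns)
    df.index.name = "site"
    if len(df):
        strength = df.abs().max(axis=1, skipna=True).fillna(0.0)
        df = df.loc[strength.sort_values(ascending=False, kind="stable").index]
    return df
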