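"""Per-site log2(H/L) competition ratios and replicate merging.

Heavy is the vehicle (DMSO) channel, light the compound channel, so high
log2(H/L) indicates the compound blocked probe labeling.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from statistics import mean as _mean, stdev as _stdev
from typing import Iterable, Optional, Sequence

from cysquant.io_formats import PsmRecord
from cysquant.site_mapping import CysteineSiteID, MappedPsm

__all__ = [
    "DEFAULT_RATIO_CAP",
    "SiteConditionResult",
    "SiteReplicateQuant",
    "aggregate_site_replicate",
    "group_and_quantify",
    "merge_replicates",
    "psm_log2_ratio",
]

#: default cap on the raw H/L ratio before log2 (complete competition
#: zeroes the light channel; the uncapped ratio would be infinite)
DEFAULT_RATIO_CAP = 20.0

UNQUANTIFIED = "unquantified"
PENDING = "pending"


@dataclass(frozen=True)
class SiteReplicateQuant:
    site: CysteineSiteID
    condition: str
    replicate: int
    log2_ratio: float
    n_psms: int
    capped: bool


@dataclass
class SiteConditionResult:
    """Replicate-merged quantification for one site under one condition.

    ``call`` starts as ``"pending"`` (or ``"unquantified"`` when the
    replicate-presence requirement fails) and is finalized by the
    ligandability module.
    """

    site: CysteineSiteID
    condition: str
    replicate_ratios: tuple[tuple[int, float], ...]
    mean_log2: Optional[float]
    sd_log2: Optional[float]
    n_replicates_quantified: int
    n_psms: int
    call: str = PENDING

    @property
    def ratios(self) -> list[float]:
        return [r for _, r in self.replicate_ratios]


def psm_log2_ratio(
    light: float, heavy: float, cap: float = DEFAULT_RATIO_CAP
) -> tuple[float, bool]:
    """log2 of heavy/light with the raw ratio clamped into ``[1/cap, cap]``.

    A zero light intensity yields ``+log2(cap)`` (capped); zero heavy
    yields ``-log2(cap)``.
    """
    if cap <= 1:
        raise ValueError("cap must exceed 1")
    if light == 0 and heavy == 0:
        raise ValueError("both intensities zero (unquantified PSM)")
    if light < 0 or heavy < 0:
        raise ValueError("negative intensity")
    if light == 0:
        return math.log2(cap), True
    if heavy == 0:
        return -math.log2(cap), True
    ratio = heavy / light
    if ratio > cap:
        return math.log2(cap), True
    if ratio < 1 / cap:
        return -math.log2(cap), True
    return math.log2(ratio), False


def aggregate_site_replicate(
    group: Sequence[MappedPsm],
    cap: float = DEFAULT_RATIO_CAP,
    method: str = "median",
) -> SiteReplicateQuant:
    """Collapse the PSMs of one site x condition x replicate group.

    The summary is the median of PSM-level log2 ratios by default
    (robust to outlier PSMs); ``method="mean"`` is available.  ``capped``
    is true when the median-selecting value(s) were capped.
    """
    if not group:
        raise ValueError("empty PSM group")
    first = group[0]
    pairs = sorted(
        psm_log2_ratio(m.psm.light_intensity, m.psm.heavy_intensity, cap)
        for m in group
    )
    n = len(pairs)
    if method == "median":
        if n % 2:
            mid = pairs[n // 2]
            value, capped = mid
        else:
            lo, hi = pairs[n // 2 - 1], pairs[n // 2]
            value = (lo[0] + hi[0]) / 2
            capped = lo[1] or hi[1]
    elif method == "mean":
        value = _mean(v for v, _ in pairs)
        capped = any(c for _, c in pairs)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return SiteReplicateQuant(
        site=first.site,
        condition=first.psm.condition,
        replicate=first.psm.replicate,
        log2_ratio=value,
        n_psms=n,
        capped=capped,
    )


def merge_replicates(
    quants: Sequence[SiteReplicateQuant],
    required_replicates: int = 2,
) -> SiteConditionResult:
    """Merge the replicate-level quants of one site x condition.

    Sites quantified in fewer than ``required_replicates`` replicates are
    marked unquantified.  SD uses the n-1 sample estimator.
    """
    if not quants:
        raise ValueError("empty quant group")
    reps = [q.replicate for q in quants]
    if len(set(reps)) != len(reps):
        raise ValueError(f"duplicate replicate index in {sorted(reps)}")
    quants = sorted(quants, key=lambda q: q.replicate)
    ratios = [q.log2_ratio for q in quants]
    n = len(quants)
    mean_log2 = _mean(ratios) if n >= 1 else None
    sd_log2 = _stdev(ratios) if n >= 2 else None
    call = PENDING if n >= required_replicates else UNQUANTIFIED
    return SiteConditionResult(
        site=quants[0].site,
        condition=quants[0].condition,
        replicate_ratios=tuple((q.replicate, q.log2_ratio) for q in quants),
        mean_log2=mean_log2,
        sd_log2=sd_log2,
        n_replicates_quantified=n,
        n_psms=sum(q.n_psms for q in quants),
        call=call,
    )


def group_and_quantify(
    mapped: Iterable[MappedPsm],
    cap: float = DEFAULT_RATIO_CAP,
    method: str = "median",
    required_replicates: int = 2,
) -> tuple[list[SiteReplicateQuant], list[SiteConditionResult]]:
    """Full quantification stage: group mapped PSMs by
    (site, condition, replicate), aggregate, then merge replicates per
    (site, condition).  Every mapped PSM contributes to exactly one
    replicate quant."""
    groups: dict[tuple[str, str, int], list[MappedPsm]] = defaultdict(list)
    for m in mapped:
        groups[(m.site.render(), m.psm.condition, m.psm.replicate)].append(m)
    quants = [
        aggregate_site_replicate(group, cap=cap, method=method)
        for group in groups.values()
    ]
    by_condition: dict[tuple[str, str], list[SiteReplicateQuant]] = defaultdict(list)
    for q in quants:
        by_condition[(q.site.render(), q.condition)].append(q)
    results = [
        merge_replicates(group, required_replicates=required_replicates)
        for group in by_condition.values()
    ]
    quants.sort(key=lambda q: (q.site.render(), q.condition, q.replicate))
    results.sort(key=lambda r: (r.site.render(), r.condition))
    return quants, results
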