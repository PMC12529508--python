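"""Peptide-to-residue mapping and isotope-channel classification.

Converts probe-labeled peptides into cysteine residue identifiers on the
protein coordinate frame (1-based, UniProt convention) and classifies
each PSM's modification state from its modification masses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from cysquant.io_formats import ProteinEntry, PsmRecord

__all__ = [
    "BUILTIN_SCHEMES",
    "CARBAMIDOMETHYL_DELTA",
    "CysteineSiteID",
    "LabelScheme",
    "MappedPsm",
    "MappingReport",
    "assign_channel",
    "cysteine_site",
    "locate_peptide",
    "map_psms",
]

log = logging.getLogger(__name__)

CARBAMIDOMETHYL_DELTA = 57.02146

PROBE_LABELED = "probe-labeled"
CARBAMIDOMETHYL_ONLY = "carbamidomethyl-only"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class LabelScheme:
    """Isotopic labeling chemistry: MS1 modification masses for the light
    (compound-treated) and heavy (vehicle-treated) capture reagents."""

    name: str
    light_delta: float
    heavy_delta: float
    carbamidomethyl_delta: float = CARBAMIDOMETHYL_DELTA
    match_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.light_delta <= 0 or self.heavy_delta <= 0:
            raise ValueError("label deltas must be positive")
        if self.heavy_delta <= self.light_delta:
            raise ValueError("heavy_delta must exceed light_delta")
        gap = self.heavy_delta - self.light_delta
        if not 0 < self.match_tolerance < gap / 2:
            raise ValueError(
                "match_tolerance must be positive and below half the "
                "heavy-light mass gap"
            )


BUILTIN_SCHEMES: dict[str, LabelScheme] = {
    "biotin-azide": LabelScheme("biotin-azide", 463.2366, 469.2742),
    "isoTOP-TEV": LabelScheme("isoTOP-TEV", 521.3074, 527.3213),
    "sCIP": LabelScheme("sCIP", 493.3007, 499.3145),
}


_SITE_RE = re.compile(r"^(?P<acc>.+?)(?P<pos>(?:_C\d+)+)$")


@dataclass(frozen=True)
class CysteineSiteID:
    """Protein accession plus ordered 1-based cysteine positions.

    Rendered as ``ACC_C<p1>`` or ``ACC_C<p1>_C<p2>...`` for peptides
    bearing several cysteines without modification localization.
    """

    accession: str
    positions: tuple[int, ...]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("positions must be non-empty")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        if any(p < 1 for p in self.positions):
            raise ValueError("positions are 1-based")

    def render(self) -> str:
        return self.accession + "".join(f"_C{p}" for p in self.positions)

    @classmethod
    def parse(cls, text: str) -> "CysteineSiteID":
        m = _SITE_RE.match(text)
        if not m:
            raise ValueError(f"malformed site identifier {text!r}")
        # the pos group looks like "_C3_C6"
        positions = tuple(
            int(t[1:]) for t in m.group("pos").split("_") if t.startswith("C")
        )
        return cls(
            accession=m.group("acc"),
            positions=positions,
            ambiguous=len(positions) > 1,
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def locate_peptide(peptide: str, protein: ProteinEntry) -> list[int]:
    """Return every 1-based start offset of ``peptide`` in the protein
    sequence (exact matching, ascending; empty when absent)."""
    if not peptide:
        raise ValueError("empty peptide")
    seq = protein.sequence
    hits: list[int] = []
    start = seq.find(peptide)
    while start != -1:
        hits.append(start + 1)
        start = seq.find(peptide, start + 1)
    return hits


def cysteine_site(
    peptide: str,
    start: int,
    accession: str,
    localized: Optional[Sequence[int]] = None,
) -> CysteineSiteID:
    """Build the residue identifier for a probe-labeled peptide placed at
    1-based protein offset ``start``.

    With upstream localization, only the localized Cys positions are
    reported (unambiguous).  Otherwise every Cys in the peptide is
    reported and the site is flagged ambiguous when there is more than
    one.
    """
    cys_idx = [i + 1 for i, aa in enumerate(peptide) if aa == "C"]
    if not cys_idx:
        raise ValueError(f"peptide {peptide!r} contains no cysteine")
    if localized:
        bad = set(localized) - set(cys_idx)
        if bad:
            raise ValueError(f"localized positions {sorted(bad)} are not Cys")
        chosen = sorted(set(localized))
        ambiguous = False
    else:
        chosen = cys_idx
        ambiguous = len(cys_idx) > 1
    positions = tuple(start + i - 1 for i in chosen)
    return CysteineSiteID(accession=accession, positions=positions, ambiguous=ambiguous)


def assign_channel(psm: PsmRecord, scheme: LabelScheme) -> str:
    """Classify a PSM as ``probe-labeled``, ``carbamidomethyl-only`` or
    ``unlabeled`` from its cysteine modification masses.

    A PSM is probe-labeled when at least one Cys modification matches the
    scheme's light or heavy delta within tolerance; the isotope channel
    itself is carried by the two intensity columns (both channels of a
    pair share one peptide row in MS1 label quantification).
    """
    tol = scheme.match_tolerance
    cys_mods = psm.cys_modifications()
    if not cys_mods:
        return UNLABELED
    matched_probe = False
    all_carb = True
    for _, delta in cys_mods:
        is_probe = (
            abs(delta - scheme.light_delta) <= tol
            or abs(delta - scheme.heavy_delta) <= tol
        )
        is_carb = abs(delta - scheme.carbamidomethyl_delta) <= tol
        if is_probe:
            matched_probe = True
        if not is_carb:
            all_carb = False
        if not is_probe and not is_carb:
            log.warning(
                "Cys modification delta %.4f on %s matches neither the %s "
                "labels nor carbamidomethyl",
                delta,
                psm.peptide,
                scheme.name,
            )
    if matched_probe:
        return PROBE_LABELED
    if all_carb:
        return CARBAMIDOMETHYL_ONLY
    return UNLABELED


@dataclass(frozen=True)
class MappedPsm:
    psm: PsmRecord
    site: CysteineSiteID


@dataclass
class MappingReport:
    """Per-reason exclusion tallies from :func:`map_psms`."""

    n_input: int = 0
    n_mapped: int = 0
    excluded: dict[str, int] = field(default_factory=dict)

    def tally(self, reason: str) -> None:
        self.excluded[reason] = self.excluded.get(reason, 0) + 1

    @property
    def n_probe_labeled(self) -> int:
        non_probe = self.excluded.get(CARBAMIDOMETHYL_ONLY, 0) + self.excluded.get(
            UNLABELED, 0
        )
        return self.n_input - non_probe


REASON_MISSING_PROTEIN = "missing-protein"
REASON_PEPTIDE_NOT_FOUND = "peptide-not-found"
REASON_MULTI_LOCUS = "multi-locus"


def map_psms(
    psms: Iterable[PsmRecord],
    proteome: Sequence[ProteinEntry],
    scheme: LabelScheme,
) -> tuple[list[MappedPsm], MappingReport]:
    """Map probe-labeled PSMs to cysteine site identifiers.

    PSMs that are not probe-labeled, reference an accession absent from
    the proteome, whose peptide is not found in the assigned protein, or
    whose peptide occurs at more than one offset, are excluded and
    tallied by reason.
    """
    index = {p.accession: p for p in proteome}
    report = MappingReport()
    mapped: list[MappedPsm] = []
    for psm in psms:
        report.n_input += 1
        channel = assign_channel(psm, scheme)
        if channel != PROBE_LABELED:
            report.tally(channel)
            continue
        protein = index.get(psm.accession)
        if protein is None:
            report.tally(REASON_MISSING_PROTEIN)
            continue
        offsets = locate_peptide(psm.peptide, protein)
        if not offsets:
            report.tally(REASON_PEPTIDE_NOT_FOUND)
            continue
        if len(offsets) > 1:
            report.tally(REASON_MULTI_LOCUS)
            continue
        site = cysteine_site(
            psm.peptide, offsets[0], psm.accession, psm.localized_positions
        )
        mapped.append(MappedPsm(psm=psm, site=site))
    report.n_mapped = len(mapped)
    return mapped, report
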