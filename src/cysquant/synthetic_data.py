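"""Synthetic competitive-screen generator with planted ground truth.

Produces a random proteome FASTA, in-silico tryptic digests, and
labeled-PSM tables with the statistical structure the analysis assumes:
log-normal abundances, per-site true log2(H/L) effects (zero-centred
background, positive planted effects), replicate noise, PSM multiplicity
and missingness.  All randomness is keyed hierarchically by seed so that
adding conditions does not perturb existing draws.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from cysquant.io_formats import ProteinEntry
from cysquant.site_mapping import BUILTIN_SCHEMES, LabelScheme, cysteine_site

__all__ = [
    "DigestRules",
    "GroundTruth",
    "MONOISOTOPIC_MASS",
    "SimConfig",
    "WATER_MONO",
    "digest",
    "enumerate_sites",
    "generate_proteome",
    "generate_screen",
    "peptide_mass",
    "write_fasta",
]

log = logging.getLogger(__name__)

#: monoisotopic residue masses (Da) for the 20 standard amino acids
MONOISOTOPIC_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONO = 18.010565

#: background residue frequencies (approximate vertebrate proteome
#: composition); Cys is overridden by ``SimConfig.cys_frequency``
_BASE_FREQ: dict[str, float] = {
    "A": 0.074, "R": 0.042, "N": 0.044, "D": 0.059, "C": 0.033,
    "E": 0.058, "Q": 0.037, "G": 0.074, "H": 0.029, "I": 0.038,
    "L": 0.076, "K": 0.072, "M": 0.018, "F": 0.040, "P": 0.050,
    "S": 0.081, "T": 0.062, "W": 0.013, "Y": 0.033, "V": 0.068,
}


def peptide_mass(peptide: str) -> float:
    """Monoisotopic mass of an unmodified peptide (residues + water)."""
    return sum(MONOISOTOPIC_MASS[aa] for aa in peptide) + WATER_MONO


@dataclass(frozen=True)
class DigestRules:
    """Strict-trypsin digestion parameters: cleave after K or R unless
    followed by P, with missed-cleavage, length and mass windows."""

    max_missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 50
    min_mass: float = 500.0
    max_mass: float = 5000.0

    def __post_init__(self) -> None:
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be below max_length")
        if self.min_mass >= self.max_mass:
            raise ValueError("min_mass must be below max_mass")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be non-negative")


def digest(
    protein: ProteinEntry, rules: DigestRules = DigestRules()
) -> list[tuple[str, int]]:
    """In-silico tryptic digest: ``(peptide, 1-based start offset)`` pairs.

    Peptides span up to ``max_missed_cleavages`` internal cleavage sites
    and must satisfy the length and monoisotopic-mass windows.
    """
    seq = protein.sequence
    n = len(seq)
    # boundary i sits between residues i-1 and i (0-based string indexing)
    boundaries = [0]
    for i in range(1, n):
        if seq[i - 1] in "KR" and seq[i] != "P":
            boundaries.append(i)
    boundaries.append(n)

    peptides: list[tuple[str, int]] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + rules.max_missed_cleavages + 2, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            length = end - start
            if length < rules.min_length or length > rules.max_length:
                continue
            pep = seq[start:end]
            if not rules.min_mass <= peptide_mass(pep) <= rules.max_mass:
                continue
            peptides.append((pep, start + 1))
    return peptides


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic screen.

    ``planted_effects`` maps rendered site identifier -> condition ->
    true log2(H/L) effect; every other site x condition draws a
    background effect from Normal(0, sigma_bg).  ``seed`` is mandatory.
    """

    seed: int
    n_proteins: int = 100
    min_length: int = 100
    max_length: int = 600
    cys_frequency: float = 0.033
    conditions: tuple[str, ...] = ("KB2", "KB7")
    n_replicates: int = 2
    planted_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sigma_bg: float = 0.25
    sigma_rep: float = 0.30
    abundance_mu: float = math.log(1e6)
    abundance_sigma: float = 1.0
    psm_multiplicity: tuple[int, ...] = (1, 2, 3)
    missingness: float = 0.10
    p_localized: float = 0.8
    scheme: str = "biotin-azide"
    digest_rules: DigestRules = DigestRules()
    call_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must be in [0, 1]")
        if not 0 <= self.p_localized <= 1:
            raise ValueError("p_localized must be in [0, 1]")
        if not 0 <= self.cys_frequency < 1:
            raise ValueError("cys_frequency must be in [0, 1)")
        if self.sigma_bg < 0 or self.sigma_rep < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")
        if self.scheme not in BUILTIN_SCHEMES:
            raise ValueError(f"unknown label scheme {self.scheme!r}")

    @property
    def label_scheme(self) -> LabelScheme:
        return BUILTIN_SCHEMES[self.scheme]


@dataclass
class GroundTruth:
    """Planted/background true effects realized by the simulator; the
    oracle for recovery tests."""

    effects: dict[tuple[str, str], float]
    threshold: float

    def true_effect(self, site: str, condition: str) -> float:
        return self.effects[(site, condition)]

    def liganded(self, site: str, condition: str) -> bool:
        return self.effects[(site, condition)] >= self.threshold

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": site,
                "condition": cond,
                "true_effect": effect,
                "liganded_flag": int(effect >= self.threshold),
            }
            for (site, cond), effect in sorted(self.effects.items())
        ]
        return pd.DataFrame(
            rows, columns=["site", "condition", "true_effect", "liganded_flag"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, threshold: float = 2.0) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        effects = {
            (row.site, row.condition): float(row.true_effect)
            for row in df.itertuples(index=False)
        }
        return cls(effects=effects, threshold=threshold)


def _key(*parts) -> list[int]:
    """Stable integer key list for seeding a numpy Generator."""
    out = []
    for p in parts:
        if isinstance(p, int):
            out.append(p & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(p).encode()))
    return out


def _rng(*parts) -> np.random.Generator:
    return np.random.default_rng(_key(*parts))


def generate_proteome(cfg: SimConfig) -> list[ProteinEntry]:
    """Random proteome with accessions ``SYN%04d``; deterministic for a
    fixed seed."""
    alphabet = sorted(_BASE_FREQ)
    base_no_c = {aa: f for aa, f in _BASE_FREQ.items() if aa != "C"}
    scale = (1.0 - cfg.cys_frequency) / sum(base_no_c.values())
    probs = np.array(
        [
            cfg.cys_frequency if aa == "C" else base_no_c[aa] * scale
            for aa in alphabet
        ]
    )
    probs /= probs.sum()
    entries = []
    for i in range(cfg.n_proteins):
        rng = _rng(cfg.seed, "proteome", i)
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        seq = "".join(np.asarray(alphabet)[rng.choice(len(alphabet), size=length, p=probs)])
        accession = f"SYN{i + 1:04d}"
        entries.append(
            ProteinEntry(
                accession=accession,
                description=f"{accession} synthetic protein {i + 1}",
                sequence=seq,
            )
        )
    return entries


def write_fasta(entries: Sequence[ProteinEntry], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f">{e.accession} {e.description}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


@dataclass(frozen=True)
class _PeptideSlot:
    accession: str
    peptide: str
    start: int
    probe_cys: int  # 1-based peptide index of the probe-modified Cys
    localized: bool
    site_id: str


def _peptide_layout(proteome: Sequence[ProteinEntry], cfg: SimConfig) -> list[_PeptideSlot]:
    """Deterministic per-peptide layout: probe position, localization and
    resulting site identifier.

    Peptides occurring at more than one offset in their protein are
    skipped (the mapper would exclude them as multi-locus anyway).
    """
    slots: list[_PeptideSlot] = []
    for protein in proteome:
        for pep, start in digest(protein, cfg.digest_rules):
            cys_idx = [i + 1 for i, aa in enumerate(pep) if aa == "C"]
            if not cys_idx:
                continue
            if protein.sequence.count(pep) > 1:
                continue
            rng = _rng(cfg.seed, "layout", protein.accession, pep)
            probe_cys = int(cys_idx[rng.integers(len(cys_idx))])
            localized = len(cys_idx) == 1 or bool(rng.random() < cfg.p_localized)
            site = cysteine_site(
                pep,
                start,
                protein.accession,
                localized=[probe_cys] if localized else None,
            )
            slots.append(
                _PeptideSlot(
                    accession=protein.accession,
                    peptide=pep,
                    start=start,
                    probe_cys=probe_cys,
                    localized=localized,
                    site_id=site.render(),
                )
            )
    return slots


def enumerate_sites(proteome: Sequence[ProteinEntry], cfg: SimConfig) -> list[str]:
    """Sorted unique site identifiers the screen can realize; use this to
    choose sites for planting effects."""
    return sorted({slot.site_id for slot in _peptide_layout(proteome, cfg)})


def plant_random_effects(
    proteome: Sequence[ProteinEntry],
    cfg: SimConfig,
    fraction: float,
    effect: float,
    conditions: Optional[Sequence[str]] = None,
) -> SimConfig:
    """Return a copy of ``cfg`` with ``effect`` planted on a random
    ``fraction`` of realizable sites (for every listed condition;
    defaults to all).  Site choice is deterministic in the seed."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    sites = enumerate_sites(proteome, cfg)
    n_plant = int(round(fraction * len(sites)))
    rng = _rng(cfg.seed, "plant")
    chosen = sorted(rng.choice(len(sites), size=n_plant, replace=False).tolist())
    conds = tuple(conditions) if conditions is not None else cfg.conditions
    planted = dict(cfg.planted_effects)
    for i in chosen:
        per_cond = dict(planted.get(sites[i], {}))
        for cond in conds:
            per_cond[cond] = effect
        planted[sites[i]] = per_cond
    return replace(cfg, planted_effects=planted)


def _mod_string(slot: _PeptideSlot, light_delta: float, carb_delta: float) -> str:
    """Assigned-modification string: probe mass on the probe Cys,
    carbamidomethyl on every other Cys."""
    tokens = []
    for i, aa in enumerate(slot.peptide):
        if aa != "C":
            continue
        pos = i + 1
        delta = light_delta if pos == slot.probe_cys else carb_delta
        tokens.append(f"{pos}C({delta:.5f})")
    return "; ".join(tokens)


def generate_screen(
    proteome: Sequence[ProteinEntry],
    cfg: SimConfig,
    outdir: Optional[str | Path] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the labeled-PSM table and ground truth for a full screen.

    For every Cys peptide x condition x replicate the true site effect is
    either planted or drawn from Normal(0, sigma_bg); each PSM observes
    the effect plus Normal(0, sigma_rep) noise on a log-normal abundance,
    and survives with probability ``1 - missingness``.  When ``outdir``
    is given, writes ``proteome.fasta``, ``psms.tsv`` and
    ``ground_truth.tsv`` there.
    """
    slots = _peptide_layout(proteome, cfg)
    site_ids = {s.site_id for s in slots}
    orphans = sorted(set(cfg.planted_effects) - site_ids)
    if orphans:
        raise ValueError(
            "planted sites not realizable from the digestible peptides: "
            + ", ".join(orphans)
        )

    scheme = cfg.label_scheme
    effects: dict[tuple[str, str], float] = {}

    def site_effect(site: str, condition: str) -> float:
        key = (site, condition)
        if key not in effects:
            planted = cfg.planted_effects.get(site, {})
            if condition in planted:
                effects[key] = float(planted[condition])
            else:
                rng = _rng(cfg.seed, "effect", site, condition)
                effects[key] = float(cfg.sigma_bg * rng.standard_normal())
        return effects[key]

    rows = []
    for slot in slots:
        mods = _mod_string(slot, scheme.light_delta, scheme.carbamidomethyl_delta)
        loc_text = str(slot.probe_cys) if slot.localized else ""
        for condition in cfg.conditions:
            r = site_effect(slot.site_id, condition)
            for replicate in range(1, cfg.n_replicates + 1):
                rng = _rng(
                    cfg.seed, "psm", slot.accession, slot.peptide, condition, replicate
                )
                n_psms = int(
                    np.asarray(cfg.psm_multiplicity)[
                        rng.integers(len(cfg.psm_multiplicity))
                    ]
                )
                for _ in range(n_psms):
                    observed = r + cfg.sigma_rep * float(rng.standard_normal())
                    abundance = float(
                        np.exp(cfg.abundance_mu + cfg.abundance_sigma * rng.standard_normal())
                    )
                    dropped = bool(rng.random() < cfg.missingness)
                    if dropped:
                        continue
                    heavy = abundance
                    light = abundance * 2.0 ** (-observed)
                    rows.append(
                        {
                            "peptide": slot.peptide,
                            "assigned_modifications": mods,
                            "protein": slot.accession,
                            "intensity_l": repr(light),
                            "intensity_h": repr(heavy),
                            "condition": condition,
                            "replicate": replicate,
                            "localized_positions": loc_text,
                        }
                    )

    columns = [
        "peptide",
        "assigned_modifications",
        "protein",
        "intensity_l",
        "intensity_h",
        "condition",
        "replicate",
        "localized_positions",
    ]
    psms = pd.DataFrame(rows, columns=columns)
    if psms.empty:
        log.warning("generated screen is empty (missingness too high?)")
    truth = GroundTruth(effects=effects, threshold=cfg.call_threshold)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(proteome, outdir / "proteome.fasta")
        psms.to_csv(outdir / "psms.tsv", sep="\t", index=False)
        truth.write(outdir / "ground_truth.tsv")
    return psms, truth
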