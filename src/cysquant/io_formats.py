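"""Readers and writers for every external artifact of the pipeline.

Handles proteome FASTA files, labeled-PSM TSV tables, reference site
databases and all result reports.  All tables are UTF-8, tab-delimited
with a header row; missing ratio cells render as ``N.D.``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ColumnMap",
    "FormatError",
    "ProteinEntry",
    "PsmLoadReport",
    "PsmRecord",
    "ReferenceSiteDB",
    "read_fasta",
    "read_psm_table",
    "read_reference_db",
    "read_site_table",
    "write_reports",
]

#: sentinel rendered for missing ratio cells in every report table
ND = "N.D."

#: decimals used when rendering log2 ratios
LOG2_DECIMALS = 4

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_SITE_ID_RE = re.compile(r"^(?P<acc>\S+?)(?P<pos>(?:_C\d+)+)$")


class FormatError(ValueError):
    """Raised on malformed input artifacts."""


@dataclass(frozen=True)
class ProteinEntry:
    """One proteome entry; the coordinate frame for residue numbering."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.accession!r}")


@dataclass(frozen=True)
class PsmRecord:
    """One quantified labeled PSM.

    ``modifications`` holds ``(position, delta_mass)`` pairs with 1-based
    positions into ``peptide``.  ``localized_positions``, when present,
    lists the peptide Cys indices the upstream search localized the probe
    modification to.
    """

    peptide: str
    modifications: tuple[tuple[int, float], ...]
    accession: str
    light_intensity: float
    heavy_intensity: float
    condition: str
    replicate: int
    localized_positions: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        n = len(self.peptide)
        for pos, _ in self.modifications:
            if not 1 <= pos <= n:
                raise FormatError(
                    f"modification position {pos} outside peptide {self.peptide!r}"
                )
        if self.light_intensity < 0 or self.heavy_intensity < 0:
            raise FormatError("negative intensity")
        if self.light_intensity == 0 and self.heavy_intensity == 0:
            raise FormatError("unquantified PSM (both intensities zero)")
        if self.localized_positions is not None:
            cys = {i + 1 for i, aa in enumerate(self.peptide) if aa == "C"}
            bad = set(self.localized_positions) - cys
            if bad:
                raise FormatError(
                    f"localized positions {sorted(bad)} are not Cys in {self.peptide!r}"
                )
        if self.replicate < 1:
            raise FormatError("replicate must be a positive integer")

    def cys_modifications(self) -> list[tuple[int, float]]:
        """Modifications sitting on cysteine residues."""
        return [(p, d) for p, d in self.modifications if self.peptide[p - 1] == "C"]


@dataclass
class ColumnMap:
    """Maps canonical field names to input-table column headers.

    Defaults follow the pipeline's canonical dialect; remap to adapt
    search-engine exports without hard-coding a vendor schema.
    """

    peptide: str = "peptide"
    assigned_modifications: str = "assigned_modifications"
    protein: str = "protein"
    intensity_l: str = "intensity_l"
    intensity_h: str = "intensity_h"
    condition: str = "condition"
    replicate: str = "replicate"
    localized_positions: Optional[str] = "localized_positions"

    MANDATORY = (
        "peptide",
        "assigned_modifications",
        "protein",
        "intensity_l",
        "intensity_h",
        "condition",
        "replicate",
    )


@dataclass
class PsmLoadReport:
    """Bookkeeping from :func:`read_psm_table`."""

    n_rows: int = 0
    n_loaded: int = 0
    n_dropped_unquantified: int = 0


class ReferenceSiteDB:
    """Reference cysteine-site database: site id -> (identified, ligandable)."""

    def __init__(self, flags: Mapping[str, tuple[bool, bool]] | None = None):
        self._flags: dict[str, tuple[bool, bool]] = {}
        if flags:
            for key, (ident, lig) in flags.items():
                self.add(key, ident, lig)

    def add(self, site_id: str, identified: bool, ligandable: bool) -> None:
        if not _SITE_ID_RE.match(site_id):
            raise FormatError(f"malformed site identifier {site_id!r}")
        if ligandable and not identified:
            raise FormatError(
                f"{site_id}: ligandable implies identified (invariant violated)"
            )
        self._flags[site_id] = (identified, ligandable)

    def __contains__(self, site_id: str) -> bool:
        return site_id in self._flags

    def __len__(self) -> int:
        return len(self._flags)

    def is_identified(self, site_id: str) -> bool:
        return self._flags.get(site_id, (False, False))[0]

    def is_ligandable(self, site_id: str) -> bool:
        return self._flags.get(site_id, (False, False))[1]

    def keys(self):
        return self._flags.keys()


# ---------------------------------------------------------------------------
# readers


def _parse_fasta_accession(header: str) -> str:
    """UniProt-style ``sp|ACC|NAME`` headers yield ACC; otherwise the first
    whitespace-delimited token."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def read_fasta(path: str | Path, on_nonstandard: str = "error") -> list[ProteinEntry]:
    """Read a proteome FASTA into :class:`ProteinEntry` records.

    Parameters
    ----------
    path:
        FASTA file with ``>`` headers.
    on_nonstandard:
        ``"error"`` (default) rejects records whose sequence contains a
        code outside the 20 standard amino acids; ``"skip"`` drops them.
    """
    if on_nonstandard not in ("error", "skip"):
        raise ValueError("on_nonstandard must be 'error' or 'skip'")
    path = Path(path)
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = _parse_fasta_accession(record.description or record.id)
        sequence = "".join(str(record.seq).split()).upper()
        bad = set(sequence) - _STANDARD_AA
        if bad:
            if on_nonstandard == "skip":
                continue
            raise FormatError(
                f"{accession}: nonstandard residue codes {sorted(bad)}"
            )
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r}")
        seen.add(accession)
        entries.append(
            ProteinEntry(
                accession=accession,
                description=record.description,
                sequence=sequence,
            )
        )
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")
    return entries


_MOD_RE = re.compile(r"^(\d+)([A-Z])\((-?\d+(?:\.\d+)?)\)$")


def parse_modifications(text: str) -> tuple[tuple[int, float], ...]:
    """Parse a ``"<pos><AA>(<delta>)"`` semicolon-separated modification string."""
    text = (text or "").strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        m = _MOD_RE.match(token)
        if not m:
            raise FormatError(f"unparseable modification token {token!r}")
        mods.append((int(m.group(1)), float(m.group(3))))
    return tuple(mods)


def _parse_intensity(value, line_no: int, column: str) -> float:
    if value is None:
        return 0.0
    if isinstance(value, float) and math.isnan(value):
        return 0.0
    text = str(value).strip()
    if text == "":
        return 0.0
    try:
        out = float(text)
    except ValueError:
        raise FormatError(
            f"line {line_no}: non-numeric intensity {text!r} in column {column!r}"
        ) from None
    if out < 0:
        raise FormatError(f"line {line_no}: negative intensity in column {column!r}")
    return out


def read_psm_table(
    path: str | Path,
    colmap: ColumnMap | None = None,
) -> tuple[list[PsmRecord], PsmLoadReport]:
    """Read a labeled-PSM TSV table.

    Rows with both intensities missing or zero are unquantified: they are
    dropped and counted in the returned :class:`PsmLoadReport`.  Channel
    membership is NOT decided here (see ``site_mapping.assign_channel``).
    """
    colmap = colmap or ColumnMap()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [
        getattr(colmap, name)
        for name in ColumnMap.MANDATORY
        if getattr(colmap, name) not in df.columns
    ]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    has_loc = (
        colmap.localized_positions is not None
        and colmap.localized_positions in df.columns
    )

    report = PsmLoadReport(n_rows=len(df))
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        line_no = i + 2  # 1-based, after the header line
        light = _parse_intensity(row[colmap.intensity_l], line_no, colmap.intensity_l)
        heavy = _parse_intensity(row[colmap.intensity_h], line_no, colmap.intensity_h)
        if light == 0 and heavy == 0:
            report.n_dropped_unquantified += 1
            continue
        localized: Optional[tuple[int, ...]] = None
        if has_loc:
            loc_text = str(row[colmap.localized_positions]).strip()
            if loc_text:
                localized = tuple(
                    sorted(int(t) for t in loc_text.split(";") if t.strip())
                )
        try:
            replicate = int(str(row[colmap.replicate]).strip())
        except ValueError:
            raise FormatError(
                f"line {line_no}: non-integer replicate "
                f"{row[colmap.replicate]!r}"
            ) from None
        try:
            records.append(
                PsmRecord(
                    peptide=str(row[colmap.peptide]).strip().upper(),
                    modifications=parse_modifications(
                        row[colmap.assigned_modifications]
                    ),
                    accession=str(row[colmap.protein]).strip(),
                    light_intensity=light,
                    heavy_intensity=heavy,
                    condition=str(row[colmap.condition]).strip(),
                    replicate=replicate,
                    localized_positions=localized,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path} line {line_no}: {exc}") from None
    report.n_loaded = len(records)
    return records, report


_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", ""}


def _parse_bool(value, line_no: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    raise FormatError(f"line {line_no}: unparseable boolean {value!r}")


def read_reference_db(path: str | Path) -> ReferenceSiteDB:
    """Read a reference site table (CSV or TSV) with columns
    ``cysteineid``, ``identified``, ``ligandable``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["cysteineid", "identified", "ligandable"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    db = ReferenceSiteDB()
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        line_no = i + 2
        try:
            db.add(
                str(row["cysteineid"]).strip(),
                _parse_bool(row["identified"], line_no),
                _parse_bool(row["ligandable"], line_no),
            )
        except FormatError as exc:
            raise FormatError(f"{path} line {line_no}: {exc}") from None
    return db


# ---------------------------------------------------------------------------
# report writing


def _fmt_ratio(value: Optional[float]) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ND
    return f"{value:.{LOG2_DECIMALS}f}"


def write_reports(
    results: Sequence,
    outdir: str | Path,
    compound_summaries: Sequence | None = None,
    stereo_comparisons: Sequence | None = None,
    reference_categories: Mapping[str, str] | None = None,
    dose_matrix: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write all result tables under ``outdir`` and return their paths.

    ``results`` is a collection of ``quantification.SiteConditionResult``.
    Optional summary collections produce their corresponding tables.
    Unquantified replicate cells render as ``N.D.``.
    """
    if not results:
        raise ValueError("write_reports called with empty results")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    all_reps = sorted(
        {rep for r in results for rep, _ in r.replicate_ratios}
    )
    rows = []
    for r in sorted(results, key=lambda r: (r.site.render(), r.condition)):
        ratios = dict(r.replicate_ratios)
        row = {
            "site": r.site.render(),
            "accession": r.site.accession,
            "condition": r.condition,
        }
        for rep in all_reps:
            row[f"log2_hl_rep{rep}"] = _fmt_ratio(ratios.get(rep))
        row["mean_log2_hl"] = _fmt_ratio(r.mean_log2)
        row["sd_log2_hl"] = _fmt_ratio(r.sd_log2)
        row["n_replicates_quantified"] = r.n_replicates_quantified
        row["n_psms"] = r.n_psms
        row["ambiguous"] = int(r.site.ambiguous)
        row["call"] = r.call
        rows.append(row)
    site_path = outdir / "site_table.tsv"
    pd.DataFrame(rows).to_csv(site_path, sep="\t", index=False)
    written["site_table"] = site_path

    if compound_summaries is not None:
        rows = [
            {
                "condition": s.condition,
                "n_identified": s.n_identified,
                "n_liganded": s.n_liganded,
                "fraction_liganded": f"{s.fraction_liganded:.{LOG2_DECIMALS}f}",
                "excluded_from_totals": int(s.excluded_from_totals),
            }
            for s in sorted(compound_summaries, key=lambda s: s.condition)
        ]
        path = outdir / "compound_summary.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["compound_summary"] = path

    if stereo_comparisons is not None:
        rows = [
            {
                "site": c.site.render(),
                "mean_a": _fmt_ratio(c.mean_a),
                "mean_b": _fmt_ratio(c.mean_b),
                "delta": _fmt_ratio(c.delta),
                "p_value": f"{c.p_value:.6g}",
                "selective_for": c.selective_for,
            }
            for c in sorted(stereo_comparisons, key=lambda c: c.site.render())
        ]
        path = outdir / "stereo_comparison.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["stereo_comparison"] = path

    if reference_categories is not None:
        rows = [
            {"site": site, "category": cat}
            for site, cat in sorted(reference_categories.items())
        ]
        path = outdir / "reference_categories.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["reference_categories"] = path

    if dose_matrix is not None:
        path = outdir / "dose_matrix.tsv"
        dose_matrix.to_csv(path, sep="\t", index=True, na_rep=ND)
        written["dose_matrix"] = path

    return written


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Re-read a written ``site_table.tsv`` with ``N.D.`` as missing."""
    return pd.read_csv(path, sep="\t", na_values=[ND], keep_default_na=False)
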