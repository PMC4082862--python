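"""Readers and writers for PSM tables, spectral-count matrices and the
packaged protein catalog.

All tabular formats are plain TSV with a mandatory header; column order is
irrelevant.  The PSM table schema is an artifact convention for the tabular
export of a database-search engine (one row per peptide-spectrum match);
this package consumes such exports, it does not search spectra.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .matrix import GROUPS, SPLITS, SpectralCountMatrix

logger = logging.getLogger("spcregress")

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """A file-level format problem (missing column, duplicate key...)."""


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from a database-search export.

    ``b_ions`` / ``y_ions`` hold the ordinal indices (1-based, at most
    ``len(peptide) - 1``) of the matched N-terminal (b) and C-terminal (y)
    fragment ions; consecutive matched ions support the correctness of the
    peptide assignment.  ``modifications`` is informational only.
    """

    sample_id: str
    accession: str
    peptide: str
    charge: int
    xcorr: float
    b_ions: frozenset = frozenset()
    y_ions: frozenset = frozenset()
    modifications: Tuple[Tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise ValueError("peptide must be nonempty")
        bad = set(self.peptide) - _VALID_AA
        if bad:
            raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.xcorr < 0:
            raise ValueError(f"xcorr must be >= 0, got {self.xcorr}")
        nmax = len(self.peptide) - 1
        for name, ions in (("b", self.b_ions), ("y", self.y_ions)):
            out = [i for i in ions if not (1 <= i <= nmax)]
            if out:
                raise ValueError(
                    f"{name}-ion indices {sorted(out)} outside [1, {nmax}] "
                    f"for peptide of length {len(self.peptide)}"
                )


@dataclass(frozen=True)
class ProteinCatalogEntry:
    """One row of the identified-protein catalog (accession, size, coverage)."""

    accession: str
    n_aa: int
    mw_da: float
    description: str
    coverage_pct: float

    def __post_init__(self) -> None:
        if self.n_aa < 0:
            raise ValueError("n_aa must be >= 0")
        if self.mw_da < 0:
            raise ValueError("mw_da must be >= 0")
        if not (0 <= self.coverage_pct <= 100):
            raise ValueError(f"coverage_pct outside [0, 100]: {self.coverage_pct}")


@dataclass
class PSMReadReport:
    """Audit of one PSM-table read: nothing is dropped silently."""

    n_rows: int = 0
    rejections: List[Tuple[int, str]] = field(default_factory=list)  # (line no, reason)

    @property
    def n_accepted(self) -> int:
        return self.n_rows - len(self.rejections)


_PSM_REQUIRED = ("sample_id", "accession", "peptide", "charge", "xcorr", "b_ions", "y_ions")


def _parse_ion_list(cell: object) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    try:
        return frozenset(int(tok) for tok in text.split(","))
    except ValueError as exc:
        raise ValueError(f"unparsable fragment-ion list {text!r}") from exc


def read_psm_table(
    path: str | Path,
    dialect: Optional[dict] = None,
    *,
    return_report: bool = False,
):
    """Read a TSV of peptide-spectrum matches into :class:`PSMRecord` objects.

    Rows that violate record invariants (charge < 1, negative Xcorr,
    out-of-range fragment indices, non-standard residues) are rejected and
    reported with their line number; well-formed rows are returned in file
    order.  ``dialect`` may override ``sep`` (default tab).

    Returns the record list, or ``(records, report)`` when
    ``return_report=True``.
    """
    sep = (dialect or {}).get("sep", "\t")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _PSM_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"PSM table {path} missing required column(s): {missing}")

    records: List[PSMRecord] = []
    report = PSMReadReport(n_rows=len(df))
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # 1-based, after the header line
        try:
            rec = PSMRecord(
                sample_id=str(getattr(row, "sample_id")),
                accession=str(getattr(row, "accession")),
                peptide=str(getattr(row, "peptide")).strip().upper(),
                charge=int(getattr(row, "charge")),
                xcorr=float(getattr(row, "xcorr")),
                b_ions=_parse_ion_list(getattr(row, "b_ions")),
                y_ions=_parse_ion_list(getattr(row, "y_ions")),
            )
        except (ValueError, TypeError) as exc:
            report.rejections.append((line_no, str(exc)))
            continue
        records.append(rec)
    for line_no, reason in report.rejections:
        logger.warning("PSM row rejected (line %d): %s", line_no, reason)
    if return_report:
        return records, report
    return records


def write_psm_table(records: Sequence[PSMRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "accession": r.accession,
            "peptide": r.peptide,
            "charge": r.charge,
            "xcorr": r.xcorr,
            "b_ions": ",".join(str(i) for i in sorted(r.b_ions)),
            "y_ions": ",".join(str(i) for i in sorted(r.y_ions)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_PSM_REQUIRED)).to_csv(path, sep="\t", index=False)


_CATALOG_COLUMNS = ("accession", "n_aa", "mw_da", "description", "coverage_pct")


def _decimal(text: str) -> float:
    """Parse a number that may use a decimal comma (as in the printed table)."""
    return float(str(text).strip().replace(",", "."))


def read_protein_catalog(path: str | Path) -> List[ProteinCatalogEntry]:
    """Read a five-column protein catalog TSV.

    Decimal commas in numeric cells (a European-typesetting artifact of the
    transcribed table) are normalized to decimal points.  Duplicate
    accessions are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"protein catalog {path} missing column(s): {missing}")
    entries: List[ProteinCatalogEntry] = []
    seen: Set[str] = set()
    for row in df.itertuples(index=False):
        acc = str(row.accession).strip()
        if acc in seen:
            raise FormatError(f"duplicate accession in catalog: {acc}")
        seen.add(acc)
        entries.append(
            ProteinCatalogEntry(
                accession=acc,
                n_aa=int(row.n_aa),
                mw_da=_decimal(row.mw_da),
                description=str(row.description).strip(),
                coverage_pct=_decimal(row.coverage_pct),
            )
        )
    return entries


def load_packaged_catalog() -> List[ProteinCatalogEntry]:
    """The packaged 165-protein catalog of high-significance identifications."""
    ref = resources.files("spcregress").joinpath("data/table1_proteins.tsv")
    with resources.as_file(ref) as p:
        return read_protein_catalog(p)


def read_spc_matrix(path: str | Path, labels: str | Path) -> SpectralCountMatrix:
    """Read a spectral-count matrix TSV plus its sample-labels TSV.

    The counts file has an ``accession`` column and one integer column per
    sample; the labels file has columns ``sample_id``, ``group``
    (regression/persistence) and optionally ``split`` (learning/validation).
    Every sample column must be labelled.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "accession" not in df.columns:
        raise FormatError(f"counts file {path} missing 'accession' column")
    sample_ids = [c for c in df.columns if c != "accession"]
    protein_ids = [str(a) for a in df["accession"]]
    counts = np.zeros((len(protein_ids), len(sample_ids)), dtype=int)
    for j, s in enumerate(sample_ids):
        for i, cell in enumerate(df[s]):
            text = str(cell).strip()
            if not re.fullmatch(r"\d+", text):
                raise FormatError(
                    f"non-integer count {text!r} at protein {protein_ids[i]!r}, sample {s!r}"
                )
            counts[i, j] = int(text)

    lab = pd.read_csv(labels, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "group"):
        if col not in lab.columns:
            raise FormatError(f"labels file {labels} missing column {col!r}")
    group_of: Dict[str, str] = {}
    split_of: Dict[str, str] = {}
    for row in lab.itertuples(index=False):
        sid = str(row.sample_id)
        g = str(row.group)
        if g not in GROUPS:
            raise FormatError(f"unknown group {g!r} for sample {sid!r}")
        group_of[sid] = g
        if "split" in lab.columns:
            sp = str(getattr(row, "split")).strip()
            if sp:
                if sp not in SPLITS:
                    raise FormatError(f"unknown split {sp!r} for sample {sid!r}")
                split_of[sid] = sp
    unlabelled = [s for s in sample_ids if s not in group_of]
    if unlabelled:
        raise FormatError(f"samples missing from labels file: {unlabelled}")

    m = SpectralCountMatrix(
        counts=counts,
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        group_of={s: group_of[s] for s in sample_ids},
        split_of={s: split_of[s] for s in sample_ids if s in split_of},
    )
    sizes = {g: len(m.samples_in_group(g)) for g in GROUPS}
    logger.info("read %dx%d SPC matrix; group sizes %s", m.n_proteins, m.n_samples, sizes)
    return m


def write_spc_matrix(
    m: SpectralCountMatrix, path: str | Path, labels: str | Path
) -> None:
    """Write a matrix and its labels so that :func:`read_spc_matrix` round-trips."""
    df = pd.DataFrame(m.counts, columns=m.sample_ids)
    df.insert(0, "accession", m.protein_ids)
    df.to_csv(path, sep="\t", index=False)
    lab = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "group": [m.group_of[s] for s in m.sample_ids],
            "split": [m.split_of.get(s, "") for s in m.sample_ids],
        }
    )
    lab.to_csv(labels, sep="\t", index=False)
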