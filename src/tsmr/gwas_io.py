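"""Reading, writing and packaged fixtures for GWAS summary-statistic tables.

The canonical on-disk format is tab-separated text with a header row and
columns ``SNP  EA  NEA  EAF  BETA  SE  P`` plus optional ``CHR``/``POS``
(1-based) and ``N``.  Other headers are accommodated through a *dialect*
mapping of external column names onto the canonical ones.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "SummaryStatRecord",
    "StudyMeta",
    "SummaryStatError",
    "read_summary_stats",
    "write_summary_stats",
    "load_fixture",
    "FIXTURE_NAMES",
]

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")

#: smallest positive double; zero p-values are clamped here with a warning
_TINY_P = sys.float_info.min

CANONICAL_COLUMNS = ("SNP", "EA", "NEA", "EAF", "BETA", "SE", "P")
OPTIONAL_COLUMNS = ("CHR", "POS", "N")


class SummaryStatError(ValueError):
    """Raised for malformed summary-statistic input (file or row level)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association statistics in one study.

    Attributes
    ----------
    snp_id : str
        rsID (or any nonempty variant identifier).
    effect_allele, other_allele : str
        Single-base alleles, one of A/C/G/T, distinct.
    eaf : float
        Effect-allele frequency in [0, 1].
    beta : float
        Additive per-allele effect (log-odds or linear scale).
    se : float
        Standard error of ``beta``; strictly positive.
    pvalue : float
        Two-sided p-value in (0, 1].
    chrom, pos : optional
        1-based genomic coordinate, used only for clumping windows.
    n : optional per-row sample-size override.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise SummaryStatError("snp_id must be nonempty")
        ea, nea = self.effect_allele.upper(), self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", nea)
        if ea not in _VALID_ALLELES or nea not in _VALID_ALLELES:
            raise SummaryStatError(
                f"{self.snp_id}: alleles must be A/C/G/T, got {ea}/{nea}"
            )
        if ea == nea:
            raise SummaryStatError(f"{self.snp_id}: effect and other allele are equal")
        if not (0.0 <= self.eaf <= 1.0):
            raise SummaryStatError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if not (self.se > 0.0) or not math.isfinite(self.se):
            raise SummaryStatError(f"{self.snp_id}: se must be finite and > 0")
        if not math.isfinite(self.beta):
            raise SummaryStatError(f"{self.snp_id}: beta must be finite")
        if self.pvalue == 0.0:
            logger.warning("%s: p-value 0 clamped to %.3e", self.snp_id, _TINY_P)
            object.__setattr__(self, "pvalue", _TINY_P)
        if not (0.0 < self.pvalue <= 1.0):
            raise SummaryStatError(f"{self.snp_id}: p-value {self.pvalue} outside (0, 1]")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata: one GWAS cohort."""

    trait_label: str
    n: int
    population: str = ""
    year: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SummaryStatError(f"{self.trait_label}: sample size must be > 0")


_DEFAULT_DIALECT = {c: c for c in CANONICAL_COLUMNS + OPTIONAL_COLUMNS}

_MANDATORY = ("SNP", "EA", "NEA", "EAF", "BETA", "SE", "P")


def _normalise_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical field -> external header name (case preserved)."""
    if dialect is None:
        return dict(_DEFAULT_DIALECT)
    out = dict(_DEFAULT_DIALECT)
    for canonical, external in dialect.items():
        key = canonical.upper()
        if key not in out:
            raise SummaryStatError(f"unknown canonical column {canonical!r} in dialect")
        out[key] = external
    return out


def read_summary_stats(
    source: str | Path | IO[str],
    dialect: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read a delimited summary-statistic table into records.

    Rows failing the record invariants are rejected collectively with
    row-numbered diagnostics (a :class:`SummaryStatError` listing every bad
    row), never silently dropped.  Row order is preserved.

    Parameters
    ----------
    source:
        Path or open text stream.  Tab-separated with a header row.
    dialect:
        Optional mapping of canonical column names (``SNP``, ``EA``, ...)
        to the external header names used in the file.
    """
    if hasattr(source, "read"):
        return _read_stream(source, dialect)  # type: ignore[arg-type]
    with open(source, "r", encoding="utf-8") as fh:
        return _read_stream(fh, dialect)


def _read_stream(fh: IO[str], dialect: Mapping[str, str] | None) -> list[SummaryStatRecord]:
    cols = _normalise_dialect(dialect)
    header_line = fh.readline()
    if not header_line:
        raise SummaryStatError("empty input: no header row")
    header = header_line.rstrip("\n").split("\t")
    index: dict[str, int] = {}
    for canonical, external in cols.items():
        try:
            index[canonical] = header.index(external)
        except ValueError:
            if canonical in _MANDATORY:
                raise SummaryStatError(
                    f"missing mandatory column {external!r} (for {canonical})"
                ) from None

    records: list[SummaryStatRecord] = []
    errors: list[str] = []
    for lineno, line in enumerate(fh, start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            records.append(_parse_row(parts, index))
        except (SummaryStatError, ValueError, IndexError) as exc:
            errors.append(f"row {lineno}: {exc}")
    if errors:
        raise SummaryStatError(
            "rejected {} row(s):\n  {}".format(len(errors), "\n  ".join(errors))
        )
    return records


def _parse_row(parts: Sequence[str], index: Mapping[str, int]) -> SummaryStatRecord:
    def get(col: str) -> str:
        return parts[index[col]].strip()

    chrom = get("CHR") if "CHR" in index else None
    pos = int(get("POS")) if "POS" in index and get("POS") else None
    n = int(float(get("N"))) if "N" in index and get("N") else None
    return SummaryStatRecord(
        snp_id=get("SNP"),
        effect_allele=get("EA"),
        other_allele=get("NEA"),
        eaf=float(get("EAF")),
        beta=float(get("BETA")),
        se=float(get("SE")),
        pvalue=float(get("P")),
        chrom=chrom or None,
        pos=pos,
        n=n,
    )


def _fmt(x: float) -> str:
    return repr(float(x))


def write_summary_stats(
    records: Iterable[SummaryStatRecord],
    sink: str | Path | IO[str],
) -> None:
    """Write records as canonical TSV; ``read(write(x)) == x`` field-for-field."""
    records = list(records)
    with_coords = any(r.chrom is not None or r.pos is not None for r in records)
    with_n = any(r.n is not None for r in records)
    header = list(CANONICAL_COLUMNS)
    if with_coords:
        header += ["CHR", "POS"]
    if with_n:
        header += ["N"]

    def emit(fh: IO[str]) -> None:
        fh.write("\t".join(header) + "\n")
        for r in records:
            row = [
                r.snp_id,
                r.effect_allele,
                r.other_allele,
                _fmt(r.eaf),
                _fmt(r.beta),
                _fmt(r.se),
                _fmt(r.pvalue),
            ]
            if with_coords:
                row += [r.chrom or "", "" if r.pos is None else str(r.pos)]
            if with_n:
                row += ["" if r.n is None else str(r.n)]
            fh.write("\t".join(row) + "\n")

    if hasattr(sink, "write"):
        emit(sink)  # type: ignore[arg-type]
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            emit(fh)


FIXTURE_NAMES = ("bph_instruments", "prostatitis_instruments", "study_meta")


def load_fixture(name: str):
    """Load a packaged fixture table.

    ``bph_instruments`` (23 records) and ``prostatitis_instruments``
    (10 records) return summary-stat records; ``study_meta`` returns the
    three cohort descriptions.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    ref = resources.files("tsmr.data").joinpath(f"{name}.tsv")
    if name == "study_meta":
        metas: list[StudyMeta] = []
        lines = ref.read_text(encoding="utf-8").splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            trait, n, pop, consortium, year, source = line.split("\t")
            metas.append(
                StudyMeta(
                    trait_label=trait,
                    n=int(n),
                    population=pop,
                    year=int(year),
                    source=f"{source} ({consortium})",
                )
            )
        return metas
    with ref.open("r", encoding="utf-8") as fh:
        return read_summary_stats(fh)
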