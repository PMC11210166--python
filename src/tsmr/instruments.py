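"""Instrument selection and vetting.

Pipeline stages: p-value thresholding, greedy LD clumping against a
user-supplied r-squared lookup, confounder screening against a local
annotation table, and instrument-strength metrics (variance explained and
F statistics under three conventions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from scipy.stats import norm

from .gwas_io import SummaryStatRecord

__all__ = [
    "InstrumentSet",
    "StrengthStats",
    "LDTable",
    "NoInstrumentsError",
    "select_instruments",
    "clump",
    "screen_confounders",
    "instrument_strength",
    "strength_summary",
]

logger = logging.getLogger(__name__)


class NoInstrumentsError(ValueError):
    """Raised when a filter stage leaves no instruments for estimation."""


@dataclass(frozen=True)
class FilterEvent:
    """One applied filter: its name, parameters and removal bookkeeping."""

    name: str
    n_in: int
    n_removed: int
    detail: tuple = ()

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass(frozen=True)
class InstrumentSet:
    """Vetted instruments plus an ordered provenance log of applied filters."""

    records: tuple[SummaryStatRecord, ...]
    provenance: tuple[FilterEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def k(self) -> int:
        return len(self.records)

    def _extend(self, event: FilterEvent) -> "InstrumentSet":
        return InstrumentSet(self.records, self.provenance + (event,))


@dataclass(frozen=True)
class StrengthStats:
    """Instrument-strength metrics for one SNP.

    ``r2_paper``/``f_paper`` follow the R-squared route
    (``R² = 2·MAF·(1−MAF)·(β/(SE·√N))²``, ``F = (N−k−1)/k · R²/(1−R²)``);
    ``f_persnp`` is the same with k = 1; ``f_from_p`` is the squared
    standard-normal two-sided tail quantile of the p-value, the convention
    used for filtering and reporting.
    """

    snp_id: str
    r2_paper: float
    f_paper: float
    f_persnp: float
    f_from_p: float


def select_instruments(
    records: Sequence[SummaryStatRecord],
    p_threshold: float = 5e-6,
    provenance: Sequence[FilterEvent] = (),
) -> InstrumentSet:
    """Keep exactly the records with ``pvalue < p_threshold``."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold {p_threshold} outside (0, 1]")
    kept = tuple(r for r in records if r.pvalue < p_threshold)
    event = FilterEvent("p_threshold", len(records), len(records) - len(kept),
                        detail=(("p_threshold", p_threshold),))
    if not kept:
        raise NoInstrumentsError(
            f"no instruments: all {len(records)} records have p >= {p_threshold}"
        )
    return InstrumentSet(kept, tuple(provenance) + (event,))


class LDTable:
    """Pairwise LD r-squared lookup.

    Symmetric by construction; self-pairs return 1.  Unknown pairs follow
    the *policy*: ``"permissive"`` treats them as r² = 0 with a warning,
    ``"strict"`` raises.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None,
                 policy: str = "permissive") -> None:
        if policy not in ("permissive", "strict"):
            raise ValueError("policy must be 'permissive' or 'strict'")
        self.policy = policy
        self._r2: dict[frozenset, float] = {}
        for (a, b), v in (pairs or {}).items():
            self.set(a, b, v)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 {r2} outside [0, 1] for pair ({a}, {b})")
        self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = frozenset((a, b))
        if key in self._r2:
            return self._r2[key]
        if self.policy == "strict":
            raise KeyError(f"no LD value for pair ({a}, {b})")
        logger.warning("LD pair (%s, %s) unknown; treating r2 as 0", a, b)
        return 0.0

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str], policy: str = "permissive") -> "LDTable":
        """Read either 3-column pairs (snp_a, snp_b, r2) or a square matrix
        with a SNP-id header row and first column."""
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            lines = Path(source).read_text(encoding="utf-8").splitlines()
        lines = [ln for ln in lines if ln.strip()]
        if not lines:
            return cls(policy=policy)
        header = lines[0].split("\t")
        table = cls(policy=policy)
        if len(header) == 3 and header[0].lower() in ("snp_a", "snp1", "snp_id_a"):
            for ln in lines[1:]:
                a, b, v = ln.split("\t")
                table.set(a.strip(), b.strip(), float(v))
        elif len(header) >= 2 and not _is_float(header[1]):
            ids = [h.strip() for h in header[1:]]
            for ln in lines[1:]:
                parts = ln.split("\t")
                row_id = parts[0].strip()
                for col_id, v in zip(ids, parts[1:]):
                    table.set(row_id, col_id, float(v))
        else:  # headerless 3-column pairs
            for ln in lines:
                a, b, v = ln.split("\t")
                table.set(a.strip(), b.strip(), float(v))
        return table


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def clump(
    records: Sequence[SummaryStatRecord] | InstrumentSet,
    ld: LDTable,
    r2_threshold: float = 0.001,
    window_bp: float = 10_000_000,
) -> InstrumentSet:
    """Greedy LD clumping.

    Sort by ascending p-value (ties broken by lexicographic snp_id, making
    the result invariant to input order); accept each SNP unless its r²
    with an already-accepted SNP within ``window_bp`` reaches
    ``r2_threshold``.  Output order is acceptance order.  When either SNP
    of a pair lacks coordinates the pair is always considered in-window.
    """
    provenance: tuple[FilterEvent, ...] = ()
    if isinstance(records, InstrumentSet):
        provenance = records.provenance
        records = records.records
    ranked = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    accepted: list[SummaryStatRecord] = []
    removed: list[tuple[str, str]] = []
    for cand in ranked:
        conflict = None
        for kept in accepted:
            if not _in_window(cand, kept, window_bp):
                continue
            if ld.r2(cand.snp_id, kept.snp_id) >= r2_threshold:
                conflict = kept.snp_id
                break
        if conflict is None:
            accepted.append(cand)
        else:
            removed.append((cand.snp_id, conflict))
    event = FilterEvent("ld_clump", len(ranked), len(removed),
                        detail=tuple(removed))
    return InstrumentSet(tuple(accepted), provenance + (event,))


def _in_window(a: SummaryStatRecord, b: SummaryStatRecord, window_bp: float) -> bool:
    if not math.isfinite(window_bp):
        return True
    if a.pos is None or b.pos is None:
        return True
    if a.chrom is not None and b.chrom is not None and a.chrom != b.chrom:
        return False
    return abs(a.pos - b.pos) <= window_bp


def screen_confounders(
    records: Sequence[SummaryStatRecord] | InstrumentSet,
    annotations: Iterable[tuple[str, str]],
    blocklist: Sequence[str],
) -> InstrumentSet:
    """Remove SNPs annotated with a blocklisted trait.

    Matching is case-insensitive substring: a SNP is removed when any of
    its annotated traits contains any blocklist pattern.  The provenance
    event lists the removed (snp_id, trait) pairs.
    """
    provenance: tuple[FilterEvent, ...] = ()
    if isinstance(records, InstrumentSet):
        provenance = records.provenance
        records = records.records
    patterns = [p.lower() for p in blocklist]
    traits_by_snp: dict[str, list[str]] = {}
    for snp_id, trait in annotations:
        traits_by_snp.setdefault(snp_id, []).append(trait)

    kept: list[SummaryStatRecord] = []
    removed: list[tuple[str, str]] = []
    for r in records:
        hit = next(
            (
                trait
                for trait in traits_by_snp.get(r.snp_id, [])
                if any(p in trait.lower() for p in patterns)
            ),
            None,
        )
        if hit is None:
            kept.append(r)
        else:
            removed.append((r.snp_id, hit))
    event = FilterEvent("confounder_screen", len(records), len(removed),
                        detail=tuple(removed))
    return InstrumentSet(tuple(kept), provenance + (event,))


def read_annotations(source: str | Path | IO[str]) -> list[tuple[str, str]]:
    """Read a 2-column (snp_id, trait) TSV annotation table; header optional."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    out = []
    for i, ln in enumerate(lines):
        if not ln.strip():
            continue
        snp, trait = ln.split("\t", 1)
        if i == 0 and snp.strip().lower() in ("snp", "snp_id", "rsid"):
            continue
        out.append((snp.strip(), trait.strip()))
    return out


def f_from_pvalue(pvalue: float) -> float:
    """Squared standard-normal two-sided tail quantile of a p-value.

    Computed through the upper-tail quantile (``isf``), never ``1 - p``,
    so it is accurate for p-values as small as ~1e-300.
    """
    z = norm.isf(pvalue / 2.0)
    return float(z * z)


def instrument_strength(record: SummaryStatRecord, n: int, k: int = 1) -> StrengthStats:
    """Strength metrics for one instrument given study size *n* and
    instrument count *k* (used only by the R²-route F)."""
    if n <= k + 1:
        raise ValueError(f"need n > k + 1; got n={n}, k={k}")
    maf = record.maf
    r2 = 2.0 * (1.0 - maf) * maf * (record.beta / (record.se * math.sqrt(n))) ** 2
    f_paper = (n - k - 1) / k * r2 / (1.0 - r2)
    f_persnp = (n - 2) * r2 / (1.0 - r2)
    return StrengthStats(
        snp_id=record.snp_id,
        r2_paper=r2,
        f_paper=f_paper,
        f_persnp=f_persnp,
        f_from_p=f_from_pvalue(record.pvalue),
    )


def strength_summary(
    instrument_set: InstrumentSet | Sequence[SummaryStatRecord],
    n: int | None = None,
) -> tuple[float, float, int]:
    """(min F, max F, count with F > 10) across a set, f_from_p convention."""
    records = (
        instrument_set.records
        if isinstance(instrument_set, InstrumentSet)
        else tuple(instrument_set)
    )
    if not records:
        raise NoInstrumentsError("strength_summary needs a nonempty set")
    fs = [f_from_pvalue(r.pvalue) for r in records]
    return min(fs), max(fs), sum(1 for f in fs if f > 10.0)
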