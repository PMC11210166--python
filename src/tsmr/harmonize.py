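"""Align exposure and outcome summary statistics to a shared effect allele.

Resolves allele swaps, strand flips, and palindromic (A/T, C/G) variants,
producing estimation-ready pairs plus an auditable record of everything
dropped and why.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import IO, Sequence

from .gwas_io import SummaryStatRecord

__all__ = [
    "HarmonizedPair",
    "DroppedSnp",
    "HarmonizedSet",
    "harmonize",
    "is_palindromic",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = (
    "unchanged",
    "outcome_beta_flipped",
    "strand_flipped",
    "strand_flipped_and_beta_flipped",
    "dropped_palindromic",
    "dropped_incompatible",
)


def is_palindromic(allele1: str, allele2: str) -> bool:
    """True for A/T and C/G variants (strand-ambiguous)."""
    return _COMPLEMENT[allele1.upper()] == allele2.upper()


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome associations for one SNP on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float
    eaf_y: float
    action: str


@dataclass(frozen=True)
class DroppedSnp:
    snp_id: str
    action: str
    reason: str


@dataclass(frozen=True)
class HarmonizedSet:
    """Retained pairs plus the audit trail of exclusions."""

    pairs: tuple[HarmonizedPair, ...]
    dropped: tuple[DroppedSnp, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        object.__setattr__(self, "dropped", tuple(self.dropped))
        retained = {p.snp_id for p in self.pairs}
        gone = {d.snp_id for d in self.dropped}
        if retained & gone:
            raise ValueError(f"SNPs both retained and dropped: {retained & gone}")

    @property
    def nsnp(self) -> int:
        return len(self.pairs)

    def aligned_records(self) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord]]:
        """Retained pairs re-expressed as (exposure, outcome) record lists,
        both on the harmonized effect allele (useful for re-harmonization
        and round-trip checks)."""
        xs, ys = [], []
        for p in self.pairs:
            common = dict(
                snp_id=p.snp_id,
                effect_allele=p.effect_allele,
                other_allele=p.other_allele,
            )
            xs.append(SummaryStatRecord(eaf=p.eaf_x, beta=p.beta_x, se=p.se_x,
                                        pvalue=1.0, **common))
            ys.append(SummaryStatRecord(eaf=p.eaf_y, beta=p.beta_y, se=p.se_y,
                                        pvalue=1.0, **common))
        return xs, ys

    def report_tsv(self, sink: IO[str]) -> None:
        """Emit the harmonization report (snp_id, action, reason) as TSV."""
        sink.write("snp_id\taction\treason\n")
        for p in self.pairs:
            sink.write(f"{p.snp_id}\t{p.action}\tretained\n")
        for d in self.dropped:
            sink.write(f"{d.snp_id}\t{d.action}\t{d.reason}\n")


def _index_unique(records: Sequence[SummaryStatRecord], label: str):
    out: dict[str, SummaryStatRecord] = {}
    for r in records:
        if r.snp_id in out:
            raise ValueError(f"duplicate snp_id {r.snp_id!r} in {label} study")
        out[r.snp_id] = r
    return out


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Harmonize outcome records onto the exposure's effect alleles.

    Rules, applied per SNP present in both studies:

    * alleles identical -> ``unchanged``;
    * alleles swapped (EA <-> NEA) -> outcome beta negated and
      ``eaf_y := 1 - eaf_y`` (``outcome_beta_flipped``);
    * complementary-strand match -> outcome alleles relabelled to the
      exposure strand, then the swap rule applies
      (``strand_flipped`` / ``strand_flipped_and_beta_flipped``);
    * palindromic variants (A/T, C/G), for which direct and flipped-strand
      matches are indistinguishable, are oriented by allele frequency when
      both eafs lie outside ``0.5 ± palindromic_eaf_window``, otherwise
      ``dropped_palindromic``;
    * anything else -> ``dropped_incompatible``.

    SNPs absent from the outcome study appear in ``dropped`` with reason
    ``absent_in_outcome`` (proxy-variant search is out of scope).
    """
    w = palindromic_eaf_window
    x_by_id = _index_unique(exposure, "exposure")
    y_by_id = _index_unique(outcome, "outcome")

    pairs: list[HarmonizedPair] = []
    dropped: list[DroppedSnp] = []
    for snp_id, x in x_by_id.items():
        y = y_by_id.get(snp_id)
        if y is None:
            dropped.append(DroppedSnp(snp_id, "dropped_incompatible", "absent_in_outcome"))
            continue

        if is_palindromic(x.effect_allele, x.other_allele):
            result = _harmonize_palindromic(x, y, w)
        else:
            result = _harmonize_plain(x, y)

        if isinstance(result, DroppedSnp):
            dropped.append(result)
        else:
            pairs.append(result)
    return HarmonizedSet(tuple(pairs), tuple(dropped))


def _pair(x: SummaryStatRecord, beta_y: float, se_y: float, eaf_y: float,
          action: str) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=x.snp_id,
        effect_allele=x.effect_allele,
        other_allele=x.other_allele,
        beta_x=x.beta,
        se_x=x.se,
        beta_y=beta_y,
        se_y=se_y,
        eaf_x=x.eaf,
        eaf_y=eaf_y,
        action=action,
    )


def _harmonize_plain(x: SummaryStatRecord, y: SummaryStatRecord):
    ea_x, nea_x = x.effect_allele, x.other_allele
    ea_y, nea_y = y.effect_allele, y.other_allele
    if (ea_y, nea_y) == (ea_x, nea_x):
        return _pair(x, y.beta, y.se, y.eaf, "unchanged")
    if (ea_y, nea_y) == (nea_x, ea_x):
        return _pair(x, -y.beta, y.se, 1.0 - y.eaf, "outcome_beta_flipped")
    cea, cnea = _COMPLEMENT[ea_y], _COMPLEMENT[nea_y]
    if (cea, cnea) == (ea_x, nea_x):
        return _pair(x, y.beta, y.se, y.eaf, "strand_flipped")
    if (cea, cnea) == (nea_x, ea_x):
        return _pair(x, -y.beta, y.se, 1.0 - y.eaf, "strand_flipped_and_beta_flipped")
    return DroppedSnp(
        x.snp_id, "dropped_incompatible",
        f"allele sets irreconcilable: {ea_x}/{nea_x} vs {ea_y}/{nea_y}",
    )


def _harmonize_palindromic(x: SummaryStatRecord, y: SummaryStatRecord, w: float):
    ea_x, nea_x = x.effect_allele, x.other_allele
    alleles_y = {y.effect_allele, y.other_allele}
    if alleles_y != {ea_x, nea_x}:
        return DroppedSnp(
            x.snp_id, "dropped_incompatible",
            f"palindromic exposure {ea_x}/{nea_x} vs outcome "
            f"{y.effect_allele}/{y.other_allele}",
        )
    ambiguous = abs(x.eaf - 0.5) <= w or abs(y.eaf - 0.5) <= w
    if ambiguous:
        return DroppedSnp(
            x.snp_id, "dropped_palindromic",
            f"eaf within 0.5±{w} (eaf_x={x.eaf}, eaf_y={y.eaf})",
        )
    # Orient by frequency: the outcome row labels refer to the same
    # physical allele iff the minor allele agrees across studies.
    same_orientation = (x.eaf < 0.5) == (
        (y.eaf < 0.5) if y.effect_allele == ea_x else (y.eaf > 0.5)
    )
    if y.effect_allele == ea_x:
        if same_orientation:
            return _pair(x, y.beta, y.se, y.eaf, "unchanged")
        return _pair(x, -y.beta, y.se, 1.0 - y.eaf, "strand_flipped_and_beta_flipped")
    # labels swapped relative to exposure
    if same_orientation:
        return _pair(x, -y.beta, y.se, 1.0 - y.eaf, "outcome_beta_flipped")
    return _pair(x, y.beta, y.se, y.eaf, "strand_flipped")
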