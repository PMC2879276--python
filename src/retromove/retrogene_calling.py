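"""Screening ortholog families for retrogenes whose parental copy was lost.

A family is a retroposition candidate when at least one species carries an
intronless copy and at least one species an intron-bearing copy (the
intronless copy is the retroposed, derived one).  Candidates pass to a
parental-loss check (no species may carry both copy types intact) and a
flanking-gene check that the relocated copy really sits in a new scaffold
context rather than reflecting an assembly artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .types import (
    GeneModel,
    OrthologCohort,
    OrthologSet,
    RetroCall,
    RetromoveError,
)


class InsufficientFlankingData(RetromoveError):
    """No relocated copy has any flanking-gene information."""


def _is_intronless(model: GeneModel, utr_introns_ok: bool = True) -> bool:
    if not utr_introns_ok:
        return model.cds_introns == 0 and model.utr_introns == 0
    return model.cds_introns == 0


def call_retro_candidate(
    fam: OrthologSet, utr_introns_ok: bool = True
) -> RetroCall:
    """Apply the intron presence/absence criteria to one family.

    Candidate iff some species has a copy with zero CDS introns and some
    species has a copy with at least one (CDS) intron.  With
    ``utr_introns_ok`` (default) UTR-only introns do not disqualify
    intronless status, but such candidates are flagged as needing external
    evidence.
    """
    if not fam.all_models():
        raise RetromoveError(f"family {fam.family_id} is empty")
    intronless = {
        sp: sum(1 for m in ms if _is_intronless(m, utr_introns_ok))
        for sp, ms in fam.members.items()
    }
    intron_bearing = {
        sp: sum(1 for m in ms if not _is_intronless(m, utr_introns_ok))
        for sp, ms in fam.members.items()
    }
    candidate = any(v > 0 for v in intronless.values()) and any(
        v > 0 for v in intron_bearing.values()
    )
    utr_flag = candidate and all(
        m.utr_introns > 0
        for ms in fam.members.values()
        for m in ms
        if _is_intronless(m, utr_introns_ok)
    )
    return RetroCall(
        family_id=fam.family_id,
        candidate=candidate,
        intronless_census=intronless,
        intron_bearing_census=intron_bearing,
        exclusion_reason="none" if candidate else "not-retro",
        utr_intron_flag=utr_flag,
    )


def parental_lost(
    fam: OrthologSet,
    utr_introns_ok: bool = True,
    count_degraded_remnants: bool = False,
) -> bool:
    """True iff no species retains both copy types.

    A species carrying an intronless copy next to an intact intron-bearing
    copy shows a retro *duplication*, not a substitution; such families are
    excluded (the second-origin situation).  Degraded parental remnants do
    not count as a retained copy unless ``count_degraded_remnants``.
    """
    call = call_retro_candidate(fam, utr_introns_ok)
    if not call.candidate:
        raise RetromoveError(
            f"parental_lost() called on non-candidate {fam.family_id}"
        )
    for sp, ms in fam.members.items():
        considered = [
            m for m in ms if count_degraded_remnants or not m.degraded
        ]
        has_retro = any(_is_intronless(m, utr_introns_ok) for m in considered)
        has_parental = any(
            not _is_intronless(m, utr_introns_ok) for m in considered
        )
        if has_retro and has_parental:
            return False
    return True


def _flank_families(
    model: GeneModel, cohort: Optional[OrthologCohort], k: int
) -> frozenset[str]:
    ids = tuple(model.flank_left[:k]) + tuple(model.flank_right[:k])
    if cohort is None:
        return frozenset(ids)
    return frozenset(cohort.family_of_gene(g) or g for g in ids)


def confirm_relocation(
    fam: OrthologSet,
    cohort: Optional[OrthologCohort] = None,
    k: int = 2,
    utr_introns_ok: bool = True,
) -> bool:
    """Flanking-gene confirmation that the intronless copy changed context.

    Confirmed iff (a) at least one relocated (intronless-copy) species has
    flanking orthologs fully disjoint from the flanking orthologs observed
    around the intron-bearing copies, and (b) at least one flanking ortholog
    supports the new context consistently across all relocated species with
    flanking data.  Raises :class:`InsufficientFlankingData` when no
    relocated copy has any flanking information.
    """
    relocated = [
        m
        for ms in fam.members.values()
        for m in ms
        if _is_intronless(m, utr_introns_ok)
    ]
    ancestral = [
        m
        for ms in fam.members.values()
        for m in ms
        if not _is_intronless(m, utr_introns_ok)
    ]
    if not relocated or not ancestral:
        raise RetromoveError(
            f"confirm_relocation() needs both copy types ({fam.family_id})"
        )
    ancestral_flanks = frozenset().union(
        *(_flank_families(m, cohort, k) for m in ancestral)
    )
    with_data = [
        (m, _flank_families(m, cohort, k))
        for m in relocated
        if _flank_families(m, cohort, k)
    ]
    if not with_data:
        raise InsufficientFlankingData(fam.family_id)
    any_disjoint = any(not (fl & ancestral_flanks) for _, fl in with_data)
    shared = frozenset.intersection(*(fl for _, fl in with_data))
    return any_disjoint and bool(shared - ancestral_flanks)


@dataclass
class ScreenSummary:
    total: int = 0
    candidates: int = 0
    parental_lost: int = 0
    flanking_confirmed: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "candidates": self.candidates,
            "parental_lost": self.parental_lost,
            "flanking_confirmed": self.flanking_confirmed,
            "retained": self.retained,
        }


def screen(
    cohort: OrthologCohort,
    overrides: Optional[Mapping[str, Iterable[str]]] = None,
    blacklist: Iterable[str] = (),
    k: int = 2,
    utr_introns_ok: bool = True,
) -> tuple[list[RetroCall], ScreenSummary]:
    """Run the full candidate -> parental-lost -> flanking screen.

    ``overrides`` may contain ``include`` (families retained on external
    evidence, e.g. a UTR-intron-only retrogene backed by expression data)
    and ``exclude`` lists; ``blacklist`` names families from low-coverage
    genomes removed as low-quality.  Returns per-family calls plus stage
    counts; the retained set shrinks (weakly) at every stage before the
    include overrides are applied.
    """
    include = set((overrides or {}).get("include", ()))
    exclude = set((overrides or {}).get("exclude", ()))
    black = set(blacklist)
    calls: list[RetroCall] = []
    summary = ScreenSummary(total=len(cohort.families))
    for fam in cohort.families:
        call = call_retro_candidate(fam, utr_introns_ok)
        if not call.candidate:
            calls.append(call)
            continue
        summary.candidates += 1
        lost = parental_lost(fam, utr_introns_ok)
        reason = "none"
        confirmed: Optional[bool] = None
        if lost:
            summary.parental_lost += 1
            try:
                confirmed = confirm_relocation(fam, cohort, k, utr_introns_ok)
            except InsufficientFlankingData:
                confirmed = False
                reason = "no-flanking-support"
            if confirmed:
                summary.flanking_confirmed += 1
        else:
            reason = "not-retro"
        if fam.family_id in black:
            reason = "low-quality"
        elif call.utr_intron_flag and fam.family_id not in include:
            reason = "utr-intron-only"
        calls.append(
            RetroCall(
                family_id=fam.family_id,
                candidate=True,
                intronless_census=call.intronless_census,
                intron_bearing_census=call.intron_bearing_census,
                parental_lost=lost,
                relocation_confirmed=confirmed,
                exclusion_reason=reason,
                utr_intron_flag=call.utr_intron_flag,
            )
        )
    retained = retained_families(calls, include, exclude)
    summary.retained = len(retained)
    return calls, summary


def retained_families(
    calls: Iterable[RetroCall],
    include: Iterable[str] = (),
    exclude: Iterable[str] = (),
) -> list[str]:
    """Family IDs surviving the screen after include/exclude overrides."""
    inc, exc = set(include), set(exclude)
    kept = []
    for call in calls:
        if call.family_id in exc:
            continue
        if call.family_id in inc or call.retained:
            kept.append(call.family_id)
    return kept
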