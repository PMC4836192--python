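"""Trio Mendelian-consistency checks and FAP/IAP call reconciliation.

STR side: a trio is consistent at a locus when the child's unordered
genotype can be assembled from one transmissible maternal and one
transmissible paternal allele; the amelogenin sex marker gets its own
X/Y-aware check.

Alu side: observations arrive as band patterns from the two amplification
strategies (flanking primers, FAP; internal subfamily primer, IAP).
:func:`reconcile_fap_iap` maps every band combination to a genotype call,
applying the dropout-aware convention for ancient samples (single-band
results stay "+"/"-", never definite homozygotes).  A call is interpreted
as a *compatibility set* -- the biallelic genotypes it could represent --
and a trio is congruent when some choice from the three sets obeys
Mendelian segregation.  ``strict`` mode reads an absence-only ancient
result as {AA}; ``dropout_tolerant`` mode additionally allows a dropped
presence allele, reading it as {AA, PA}.

Classification mirrors the field's "definite result" notion: a locus is
definite when all three trio members yield a call and the trio is
congruent; a missing member makes it incomplete (or not_investigated when
the extract was depleted before the internal-primer retest could run).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import pandas as pd

from aluktrio.core_io import (
    AluCall,
    Call,
    Dataset,
    FapObservation,
    IapObservation,
    StrGenotype,
    is_sex_marker,
)
from aluktrio.kinship import trio_transmission_probability

__all__ = [
    "Genotype",
    "InterpretationMode",
    "CompatibilitySet",
    "LocusClassification",
    "ClassificationSummary",
    "str_trio_consistent",
    "sex_marker_consistent",
    "alu_compatibility_set",
    "alu_trio_congruent",
    "reconcile_fap_iap",
    "reconcile_call",
    "classify_locus",
    "count_consistent_autosomal",
    "classify_dataset",
    "summarize",
    "str_trio_report",
    "mask_iap",
]


class Genotype(str, enum.Enum):
    """Definite biallelic genotype at an insertion locus."""

    PP = "PP"
    PA = "PA"
    AA = "AA"

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.value[0], self.value[1])


class InterpretationMode(str, enum.Enum):
    """How an absence-only ancient result is read.

    ``strict``: at face value, {AA} -- the short absence fragment is
    trusted.  ``dropout_tolerant``: {AA, PA}, admitting dropout of the
    long presence fragment; useful for exploratory QC, not classification.
    """

    STRICT = "strict"
    DROPOUT_TOLERANT = "dropout_tolerant"


@dataclass(frozen=True)
class CompatibilitySet:
    """Genotypes an observation could represent, for one sample/locus."""

    locus_id: str
    sample_id: str
    genotypes: frozenset[Genotype]

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("compatibility set may not be empty")


@dataclass(frozen=True)
class LocusClassification:
    """Definite / incongruent / incomplete / not_investigated status."""

    locus_id: str
    status: str  # {definite, incongruent, incomplete, not_investigated}
    resolved_by: str  # {FAP, FAP+IAP, none}
    child_cr: bool = False  # child call is a combined (FAP+IAP) heterozygote


@dataclass
class ClassificationSummary:
    definite: int = 0
    incongruent: int = 0
    incomplete: int = 0
    not_investigated: int = 0
    definite_fap_only: int = 0
    definite_fap_iap: int = 0

    @property
    def total(self) -> int:
        return (
            self.definite + self.incongruent + self.incomplete + self.not_investigated
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "status": [
                    "definite",
                    "incongruent",
                    "incomplete",
                    "not_investigated",
                ],
                "count": [
                    self.definite,
                    self.incongruent,
                    self.incomplete,
                    self.not_investigated,
                ],
            }
        )


# ---------------------------------------------------------------------------
# STR trio checks


def str_trio_consistent(
    mother: StrGenotype | None,
    father: StrGenotype | None,
    child: StrGenotype | None,
) -> bool | None:
    """True iff the child genotype is producible from the parents.

    Equivalent to ``trio_transmission_probability > 0``.  Returns ``None``
    (indeterminate, distinct from inconsistent) when any genotype is
    missing.
    """
    if mother is None or father is None or child is None:
        return None
    return trio_transmission_probability(mother, father, child) > 0.0


def sex_marker_consistent(
    father_amel: StrGenotype,
    mother_amel: StrGenotype,
    child_amel: StrGenotype,
) -> bool:
    """Amelogenin X/Y transmission check for a trio.

    The mother must be X/X (anything else is malformed input, not mere
    inconsistency).  A daughter (X/X) needs an X from the father -- always
    available; a son (X/Y) needs the father to carry Y.
    """
    for g in (father_amel, mother_amel, child_amel):
        if g is None:
            raise ValueError("amelogenin genotype is missing")
        if not set(g.alleles) <= {"X", "Y"}:
            raise ValueError(f"malformed sex genotype {g}")
    if mother_amel.alleles != ("X", "X"):
        raise ValueError(f"invalid mother amelogenin genotype {mother_amel}")
    if "X" not in father_amel.alleles:
        return False  # no X to give a daughter, no X in any child
    if child_amel.alleles == ("X", "X"):
        return True
    if set(child_amel.alleles) == {"X", "Y"}:
        return "Y" in father_amel.alleles
    # child Y/Y: impossible with an X/X mother
    return False


# ---------------------------------------------------------------------------
# Alu compatibility sets and congruence


def alu_compatibility_set(
    call: AluCall, mode: InterpretationMode = InterpretationMode.STRICT
) -> CompatibilitySet:
    """Genotypes compatible with a (non-missing) reconciled call."""
    if call.call is None:
        raise ValueError(
            f"{call.sample_id}/{call.locus_id}: call not reconciled yet"
        )
    if call.call is Call.MISSING:
        raise ValueError(
            f"{call.sample_id}/{call.locus_id}: missing call has no "
            "compatibility set; filter missing calls first"
        )
    mapping: dict[Call, frozenset[Genotype]] = {
        Call.PP: frozenset({Genotype.PP}),
        Call.PA: frozenset({Genotype.PA}),
        Call.AA: frozenset({Genotype.AA}),
        Call.P_ANY: frozenset({Genotype.PP, Genotype.PA}),
        Call.A_ONLY: (
            frozenset({Genotype.AA})
            if mode is InterpretationMode.STRICT
            else frozenset({Genotype.AA, Genotype.PA})
        ),
    }
    return CompatibilitySet(
        locus_id=call.locus_id,
        sample_id=call.sample_id,
        genotypes=mapping[call.call],
    )


def _mendel_ok(g_m: Genotype, g_f: Genotype, g_c: Genotype) -> bool:
    """Can g_c arise from g_m x g_f under biallelic segregation?"""
    child = tuple(sorted(g_c.alleles))
    return any(
        tuple(sorted((am, af))) == child
        for am in g_m.alleles
        for af in g_f.alleles
    )


def alu_trio_congruent(
    mother_set: CompatibilitySet,
    father_set: CompatibilitySet,
    child_set: CompatibilitySet,
) -> bool:
    """True iff some genotype choice from the three sets is Mendelian.

    Brute force over at most 3**3 combinations; congruence is therefore
    monotone in set inclusion (enlarging a set never removes a witness).
    """
    return any(
        _mendel_ok(g_m, g_f, g_c)
        for g_m, g_f, g_c in product(
            mother_set.genotypes, father_set.genotypes, child_set.genotypes
        )
    )


# ---------------------------------------------------------------------------
# FAP + IAP reconciliation


_REASON_DEPLETED = "extract_depleted"


def reconcile_fap_iap(
    fap: FapObservation, iap: IapObservation, ancient: bool
) -> tuple[Call, str | None]:
    """Map a band pattern to a genotype call; returns (call, reason).

    Truth table (total over all inputs):

    ==============  ==========  =======================================
    FAP bands       IAP         call
    ==============  ==========  =======================================
    presence+absence  any       PA
    presence only     any       P_any (ancient) / PP (modern)
    absence only      band      PA  -- the combined-result heterozygote
    absence only      other     A_only (ancient) / AA (modern)
    no band           band      P_any (presence proved, zygosity unknown)
    no band           other     missing
    ==============  ==========  =======================================

    A depleted extract behaves like an untested IAP, but when the outcome
    is missing the depletion is recorded as the reason so classification
    can mark the locus not_investigated rather than merely incomplete.
    """
    depleted = iap is IapObservation.EXTRACT_DEPLETED
    iap_band = iap is IapObservation.BAND
    if fap.presence_band and fap.absence_band:
        return Call.PA, None
    if fap.presence_band:
        return (Call.P_ANY if ancient else Call.PP), None
    if fap.absence_band:
        if iap_band:
            return Call.PA, None  # combined result ("CR")
        return (Call.A_ONLY if ancient else Call.AA), None
    # no FAP band at all
    if iap_band:
        return Call.P_ANY, None
    return Call.MISSING, (_REASON_DEPLETED if depleted else None)


def reconcile_call(call: AluCall) -> AluCall:
    """Attach the reconciled genotype call to an observation record."""
    reconciled, reason = reconcile_fap_iap(call.fap, call.iap, call.ancient)
    return call.with_call(reconciled, reason)


def mask_iap(call: AluCall) -> AluCall:
    """Copy of an observation with the IAP result hidden (FAP-only pass)."""
    return AluCall(
        sample_id=call.sample_id,
        locus_id=call.locus_id,
        fap=call.fap,
        iap=IapObservation.NOT_TESTED,
        ancient=call.ancient,
    )


# ---------------------------------------------------------------------------
# Locus classification


def classify_locus(
    mother: AluCall,
    father: AluCall,
    child: AluCall,
    mode: InterpretationMode = InterpretationMode.STRICT,
) -> LocusClassification:
    """Classify one locus from the trio's reconciled calls.

    Precedence: a depleted-extract missing call makes the locus
    not_investigated; any other missing call makes it incomplete (even if
    the remaining members conflict); otherwise congruence decides between
    definite and incongruent.
    """
    calls = (mother, father, child)
    locus_id = child.locus_id
    for c in calls:
        if c.call is None:
            raise ValueError(f"{c.sample_id}/{c.locus_id}: call not reconciled")
    missing = [c for c in calls if c.call is Call.MISSING]
    if missing:
        status = (
            "not_investigated"
            if any(c.reason == _REASON_DEPLETED for c in missing)
            else "incomplete"
        )
        return LocusClassification(locus_id, status, resolved_by="none")
    sets = [alu_compatibility_set(c, mode) for c in calls]
    congruent = alu_trio_congruent(*sets)
    iap_used = any(
        c.iap is IapObservation.BAND and not c.fap.presence_band for c in calls
    )
    child_cr = (
        child.call is Call.PA
        and child.iap is IapObservation.BAND
        and not child.fap.presence_band
    )
    return LocusClassification(
        locus_id,
        "definite" if congruent else "incongruent",
        resolved_by="FAP+IAP" if iap_used else "FAP",
        child_cr=child_cr,
    )


def classify_dataset(
    dataset: Dataset,
    mode: InterpretationMode = InterpretationMode.STRICT,
    use_iap: bool = True,
) -> list[LocusClassification]:
    """Reconcile and classify every Alu locus of a dataset's trio.

    ``use_iap=False`` runs the flanking-primer-only pass: every IAP
    observation is masked to not_tested before reconciliation.
    """
    if dataset.pedigree is None:
        raise ValueError("dataset has no pedigree")
    ped = dataset.pedigree
    out: list[LocusClassification] = []
    for locus in dataset.alu_loci():
        members = {}
        for role, sid in (
            ("mother", ped.mother_id),
            ("father", ped.father_id),
            ("child", ped.child_id),
        ):
            obs = dataset.alu_call(sid, locus)
            if obs is None:
                obs = AluCall(
                    sid,
                    locus,
                    FapObservation(False, False),
                    IapObservation.NOT_TESTED,
                )
            if not use_iap:
                obs = mask_iap(obs)
            members[role] = reconcile_call(obs)
        out.append(
            classify_locus(members["mother"], members["father"], members["child"], mode)
        )
    return out


def summarize(classifications: Iterable[LocusClassification]) -> ClassificationSummary:
    """Count classifications by status, splitting definite results by
    whether the internal-primer approach was needed."""
    summary = ClassificationSummary()
    for c in classifications:
        if c.status == "definite":
            summary.definite += 1
            if c.resolved_by == "FAP+IAP":
                summary.definite_fap_iap += 1
            else:
                summary.definite_fap_only += 1
        elif c.status == "incongruent":
            summary.incongruent += 1
        elif c.status == "incomplete":
            summary.incomplete += 1
        elif c.status == "not_investigated":
            summary.not_investigated += 1
        else:  # pragma: no cover - statuses are produced by classify_locus
            raise ValueError(f"unknown status {c.status!r}")
    return summary


def str_trio_report(dataset: Dataset) -> pd.DataFrame:
    """Per-locus STR trio consistency table.

    One row per locus with columns ``locus``, ``marker_type``
    (autosomal/sex), the three genotypes, and ``consistent`` (pandas
    nullable boolean; <NA> when a genotype is missing).  Autosomal systems
    use the Mendelian check, amelogenin the X/Y-aware sex check.
    """
    if dataset.pedigree is None:
        raise ValueError("dataset has no pedigree")
    rows = []
    for locus in dataset.str_loci():
        mother, father, child = dataset.trio_genotypes(locus)
        if is_sex_marker(locus):
            marker = "sex"
            if None in (mother, father, child):
                consistent = None
            else:
                consistent = sex_marker_consistent(father, mother, child)
        else:
            marker = "autosomal"
            consistent = str_trio_consistent(mother, father, child)
        rows.append(
            {
                "locus": locus,
                "marker_type": marker,
                "mother": str(mother) if mother else "",
                "father": str(father) if father else "",
                "child": str(child) if child else "",
                "consistent": consistent,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["consistent"] = frame["consistent"].astype("boolean")
    return frame


def count_consistent_autosomal(report: pd.DataFrame) -> int:
    """Number of autosomal STR systems whose trio check passed."""
    if report.empty:
        return 0
    auto = report[report["marker_type"] == "autosomal"]
    return int((auto["consistent"] == True).sum())  # noqa: E712 - nullable bool
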