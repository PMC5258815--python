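"""Functional phenotyping of IFN-γ ELISPOT depletion assays.

The assay measures indirect antidonor CD4⁺ reactivity in CD8-depleted PBMC
and then crosses CD19 (B cell) and CD25 (regulatory/activated T cell)
depletion to reveal whether the response depends on B cells and whether it
is actively regulated.  Two readouts are computed for every sample:

* a **positivity quadruple** — one thresholded call per depletion condition
  in the order (CD8-dep, CD8+CD19-dep, CD8+CD25-dep, CD8+CD25+CD19-dep) —
  which is looked up in the nine-row decision table of observed patterns;
* **depletion-effect flags** (Bdep/Breg/Treg) based on a ≥20 % relative
  change in spot count between paired conditions.

Both are stored on the call so that disagreements between the two
definitions remain visible.  Donor-specific reactivity (DSR) is positivity
of the CD8-depleted well; its absence is NDSR.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .errors import NotInterpretableError
from .records import (
    AntigenClass,
    CoarseCategory,
    CohortTables,
    DepletionFlag,
    ElispotSample,
    FinePattern,
    PhenotypeCall,
    PositivityRule,
)

#: Default relative-change threshold for depletion-effect flags (≥20 %).
DEFAULT_DELTA = 0.20

#: Tolerance making the boundary of the ≥20 % rule robust to float round-off.
_BOUNDARY_EPS = 1e-12

#: The nine observed positivity quadruples.  Key order is
#: (cd8dep, cd8cd19dep, cd8cd25dep, cd8cd25cd19dep); True means reactive.
FINE_PATTERN_TABLE: dict[tuple[bool, bool, bool, bool], FinePattern] = {
    (False, False, False, False): FinePattern.NO_RESPONSE,
    (False, True, False, False): FinePattern.BREG_CD25_PRESENT,
    (False, True, False, True): FinePattern.BREG_PRESENT_AND_ABSENT,
    (False, False, False, True): FinePattern.BREG_CD25_ABSENT,
    (False, True, True, False): FinePattern.BREG_PRESENT_BDEP_ABSENT,
    (False, False, True, False): FinePattern.BDEP_CD25_ABSENT,
    (True, False, False, True): FinePattern.BDEP_PRESENT_BREG_ABSENT,
    (True, False, True, False): FinePattern.BDEP_PRESENT_AND_ABSENT,
    (True, False, False, False): FinePattern.BDEP_CD25_PRESENT,
}

#: Four-way functional grouping of the nine named patterns.
COARSE_TABLE: dict[FinePattern, CoarseCategory] = {
    FinePattern.NO_RESPONSE: CoarseCategory.NO_RESPONSE_NO_REG,
    FinePattern.BREG_CD25_PRESENT: CoarseCategory.REGULATED_NO_BDEP,
    FinePattern.BREG_PRESENT_AND_ABSENT: CoarseCategory.REGULATED_NO_BDEP,
    FinePattern.BREG_CD25_ABSENT: CoarseCategory.REGULATED_NO_BDEP,
    FinePattern.BREG_PRESENT_BDEP_ABSENT: CoarseCategory.BDEP_REGULATED,
    FinePattern.BDEP_CD25_ABSENT: CoarseCategory.BDEP_REGULATED,
    FinePattern.BDEP_PRESENT_BREG_ABSENT: CoarseCategory.BDEP_REGULATED,
    FinePattern.BDEP_PRESENT_AND_ABSENT: CoarseCategory.BDEP_UNREGULATED,
    FinePattern.BDEP_CD25_PRESENT: CoarseCategory.BDEP_UNREGULATED,
}

_BDEP_FLAGS = {DepletionFlag.BDEP_CD25_PRESENT, DepletionFlag.BDEP_CD25_ABSENT}
_REG_FLAGS = {
    DepletionFlag.BREG_CD25_PRESENT,
    DepletionFlag.BREG_CD25_ABSENT,
    DepletionFlag.TREG,
}


def call_positivity(count: int, background: int, rule: PositivityRule) -> bool:
    """True iff ``count`` clears both the absolute and background thresholds."""
    if count < 0 or background < 0:
        raise ValueError("counts must be nonnegative")
    return count >= rule.min_spots and count >= rule.background_multiplier * background


def relative_change(reference: int, depleted: int) -> Optional[float]:
    """Signed fractional change (depleted − reference) / reference.

    Returns None when ``reference`` is zero: no ≥20 % change of zero exists,
    so flag logic falls back to treating the comparison as no effect.
    """
    if reference < 0 or depleted < 0:
        raise ValueError("counts must be nonnegative")
    if reference == 0:
        return None
    return (depleted - reference) / reference


def flag_depletion_effects(
    sample: ElispotSample, delta: float = DEFAULT_DELTA
) -> frozenset[DepletionFlag]:
    """Bdep/Breg/Treg flags from ≥``delta`` relative changes between wells.

    Bdep: spot count falls ≥20 % on CD19 depletion (with CD25 present or
    absent, judged separately); Breg: rises ≥20 % on CD19 depletion;
    Treg: rises ≥20 % on CD25 depletion.  Boundary changes of exactly
    ``delta`` count as meeting the criterion.
    """
    if not sample.viable or any(c is None for c in sample.counts()):
        raise NotInterpretableError(
            f"sample {sample.patient_id}/{sample.time_point.value} not interpretable"
        )
    flags = set()
    lo, hi = -delta + _BOUNDARY_EPS, delta - _BOUNDARY_EPS

    rc = relative_change(sample.c_cd8dep, sample.c_cd8cd19dep)
    if rc is not None:
        if rc <= lo:
            flags.add(DepletionFlag.BDEP_CD25_PRESENT)
        elif rc >= hi:
            flags.add(DepletionFlag.BREG_CD25_PRESENT)

    rc = relative_change(sample.c_cd8cd25dep, sample.c_cd8cd25cd19dep)
    if rc is not None:
        if rc <= lo:
            flags.add(DepletionFlag.BDEP_CD25_ABSENT)
        elif rc >= hi:
            flags.add(DepletionFlag.BREG_CD25_ABSENT)

    rc = relative_change(sample.c_cd8dep, sample.c_cd8cd25dep)
    if rc is not None and rc >= hi:
        flags.add(DepletionFlag.TREG)

    return frozenset(flags)


def positivity_quadruple(
    sample: ElispotSample, rule: PositivityRule
) -> tuple[bool, bool, bool, bool]:
    """Per-condition positivity calls in canonical condition order."""
    if not sample.viable or any(c is None for c in sample.counts()):
        raise NotInterpretableError(
            f"sample {sample.patient_id}/{sample.time_point.value} not interpretable"
        )
    return tuple(
        call_positivity(c, sample.background, rule) for c in sample.counts()
    )  # type: ignore[return-value]


def classify_fine(sample: ElispotSample, rule: PositivityRule) -> FinePattern:
    """Look the positivity quadruple up in the nine-row decision table.

    Total over all 16 quadruples: the seven unobserved combinations map to
    :attr:`FinePattern.OTHER` and are resolved to a coarse category by the
    flag fallback in :func:`to_coarse`.
    """
    quad = positivity_quadruple(sample, rule)
    return FINE_PATTERN_TABLE.get(quad, FinePattern.OTHER)


def to_coarse(
    fine_pattern: FinePattern,
    flags: frozenset[DepletionFlag] = frozenset(),
    dsr: bool = False,
) -> CoarseCategory:
    """Map a fine pattern to its four-way functional category.

    Named patterns map exactly per the decision table.  OTHER falls back to
    the flags: a DSR sample with a Bdep flag is B-dependent (regulated if
    any Breg/Treg flag also fires, unregulated otherwise); an NDSR sample
    with regulation flags is regulated without B-dependence; anything else
    shows neither response nor regulation.
    """
    if fine_pattern is not FinePattern.OTHER:
        return COARSE_TABLE[fine_pattern]
    has_bdep = bool(flags & _BDEP_FLAGS)
    has_reg = bool(flags & _REG_FLAGS)
    if dsr and has_bdep and not has_reg:
        return CoarseCategory.BDEP_UNREGULATED
    if dsr and has_bdep and has_reg:
        return CoarseCategory.BDEP_REGULATED
    if not dsr and has_reg:
        return CoarseCategory.REGULATED_NO_BDEP
    return CoarseCategory.NO_RESPONSE_NO_REG


def classify_sample(
    sample: ElispotSample,
    rule: PositivityRule | None = None,
    delta: float = DEFAULT_DELTA,
) -> PhenotypeCall:
    """Full phenotype call for one sample; nonviable → interpretable=False."""
    rule = rule or PositivityRule()
    if not sample.viable or any(c is None for c in sample.counts()):
        return PhenotypeCall(
            patient_id=sample.patient_id,
            time_point=sample.time_point,
            antigen_class=sample.antigen_class,
            interpretable=False,
        )
    quad = positivity_quadruple(sample, rule)
    flags = flag_depletion_effects(sample, delta)
    fine = FINE_PATTERN_TABLE.get(quad, FinePattern.OTHER)
    coarse = to_coarse(fine, flags, dsr=quad[0])
    return PhenotypeCall(
        patient_id=sample.patient_id,
        time_point=sample.time_point,
        antigen_class=sample.antigen_class,
        interpretable=True,
        dsr=quad[0],
        positivity=quad,
        flags=flags,
        fine_pattern=fine,
        coarse_category=coarse,
        b_dependent=coarse
        in (CoarseCategory.BDEP_REGULATED, CoarseCategory.BDEP_UNREGULATED),
    )


def classify_cohort(
    cohort: CohortTables,
    rule: PositivityRule | None = None,
    delta: float = DEFAULT_DELTA,
    antigen_classes: Iterable[AntigenClass] | None = None,
) -> dict[tuple, PhenotypeCall]:
    """One call per sample, keyed by (patient_id, time_point, antigen_class).

    Donor and viral antigen classes are classified by identical rules;
    nonviable samples are carried with ``interpretable=False``.
    """
    rule = rule or PositivityRule()
    wanted = set(antigen_classes) if antigen_classes is not None else None
    calls: dict[tuple, PhenotypeCall] = {}
    for sample in cohort.elispot:
        if wanted is not None and sample.antigen_class not in wanted:
            continue
        call = classify_sample(sample, rule, delta)
        calls[(sample.patient_id, sample.time_point, sample.antigen_class)] = call
    return calls


def calls_to_frame(calls: dict[tuple, PhenotypeCall]) -> pd.DataFrame:
    """Tabulate phenotype calls as one row per sample."""
    rows = []
    for (pid, tp, ag), call in sorted(
        calls.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
    ):
        rows.append(
            {
                "patient_id": pid,
                "time_point": tp.value,
                "antigen_class": ag.value,
                "interpretable": call.interpretable,
                "dsr": call.dsr,
                "pos_cd8dep": call.positivity[0] if call.positivity else None,
                "pos_cd8cd19dep": call.positivity[1] if call.positivity else None,
                "pos_cd8cd25dep": call.positivity[2] if call.positivity else None,
                "pos_cd8cd25cd19dep": call.positivity[3] if call.positivity else None,
                "flags": ";".join(sorted(f.value for f in call.flags)),
                "fine_pattern": call.fine_pattern.value if call.fine_pattern else None,
                "coarse_category": call.coarse_category.value
                if call.coarse_category
                else None,
                "b_dependent": call.b_dependent,
            }
        )
    return pd.DataFrame(rows)
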