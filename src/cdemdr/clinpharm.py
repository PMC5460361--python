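"""Packaged "clinical pharmaceutical" worked-example fixture.

A small, fully in-memory reconstruction of the drug-therapy slice of a
cancer-study data dictionary and its registry metadata: seven drug-therapy
CDEs sharing the object class "Pharmacologic Substance" (NCIt C1909) across
the properties "Begin Occurrence" (post-coordinated "C25431:C25275"), "End
Occurrence" and "Continue Occurrence" and four value domains; seven further
dictionary-asserted medication CDEs; and fourteen enriched registry CDEs
that share object classes with the asserted ones but are absent from the
dictionary.  A twenty-row medication-template alignment spec completes the
evaluation inputs.

Public identifiers are synthetic; display names are the published strings.
Concept codes other than C1909 and C25431:C25275 are synthetic placeholders
in NCI Thesaurus format.
"""

from __future__ import annotations

from dataclasses import dataclass

from .analytics import AlignmentRow, AlignmentSpec
from .model import (
    ClinicalDomain,
    ConceptRef,
    DataElement,
    DomainVariable,
    ObjectClass,
    PermissibleValue,
    PropertyDef,
    Registry,
    ValueDomain,
    build_registry,
)

__all__ = [
    "ClinpharmFixture",
    "load_clinpharm_fixture",
    "clinpharm_table2_extract",
    "DOMAIN_NAME",
]

DOMAIN_NAME = "clinical pharmaceutical"

# --- shared components -----------------------------------------------------

_OC_PHARM = ObjectClass(
    "Pharmacologic Substance", public_id="OC2178", concepts=(ConceptRef("C1909"),)
)
_OC_PRESCRIBED = ObjectClass(
    "Prescribed Agent", public_id="OC2186", concepts=(ConceptRef("C71104"),)
)
_OC_CUMULATIVE = ObjectClass(
    "Cumulative Agent", public_id="OC2187", concepts=(ConceptRef("C25424"),)
)
_OC_REGIMEN = ObjectClass(
    "Therapy Regimen", public_id="OC2188", concepts=(ConceptRef("C12218"),)
)
_OC_ADMIN = ObjectClass(
    "Agent Administration", public_id="OC2189", concepts=(ConceptRef("C25409"),)
)

_P_BEGIN = PropertyDef("Begin Occurrence", concepts=(ConceptRef("C25431:C25275"),))
_P_END = PropertyDef("End Occurrence", concepts=(ConceptRef("C25512:C25275"),))
_P_CONTINUE = PropertyDef("Continue Occurrence", concepts=(ConceptRef("C25574:C25275"),))

_VD_YEAR = ValueDomain("Event Year Number", public_id="VD3101", datatype="number")
_VD_MONTH = ValueDomain("Event Month Number", public_id="VD3102", datatype="number")
_VD_DAY = ValueDomain("Event Day Number", public_id="VD3103", datatype="number")
_VD_YESNO = ValueDomain(
    "Yes No Character Indicator",
    public_id="VD3104",
    datatype="string",
    permissible_values=(
        PermissibleValue("YES", "Yes", ConceptRef("C49488")),
        PermissibleValue("NO", "No", ConceptRef("C49487")),
    ),
)
_VD_TEXT = ValueDomain("Text Name", public_id="VD3105", datatype="string")
_VD_DECIMAL = ValueDomain("Decimal Measurement", public_id="VD3106", datatype="number")
_VD_UNITS = ValueDomain("Unit of Measure Name", public_id="VD3107", datatype="string")
_VD_COUNT = ValueDomain("Integer Count", public_id="VD3108", datatype="number")
_VD_ROUTE = ValueDomain("Route Name", public_id="VD3109", datatype="string")
_VD_CODE = ValueDomain("Code Identifier", public_id="VD3110", datatype="string")
_VD_TIME = ValueDomain("Time Value", public_id="VD3111", datatype="string")


def _de(public_id, long_name, oc, prop, vd, definition=""):
    return DataElement(
        public_id=public_id,
        version="1.0",
        long_name=long_name,
        definition=definition,
        workflow_status="RELEASED",
        object_class=oc,
        property=prop,
        value_domain=vd,
    )


# Drug-therapy CDEs of the Pattern 1 worked example, in dictionary order.
# (variable name, CDE)
_DRUG_THERAPY: tuple[tuple[str, DataElement], ...] = (
    (
        "Year Of Drug Therapy Start",
        _de("10001", "Pharmacologic Substance Begin Occurrence Year Number",
            _OC_PHARM, _P_BEGIN, _VD_YEAR,
            "Year the pharmacologic substance administration began."),
    ),
    (
        "Month Of Drug Therapy Start",
        _de("10002", "Pharmacologic Substance Begin Occurrence Month Number",
            _OC_PHARM, _P_BEGIN, _VD_MONTH,
            "Month the pharmacologic substance administration began."),
    ),
    (
        "Day Of Drug Therapy Start",
        _de("10003", "Pharmacologic Substance Begin Occurrence Day Number",
            _OC_PHARM, _P_BEGIN, _VD_DAY,
            "Day the pharmacologic substance administration began."),
    ),
    (
        "Year Of Drug Therapy End",
        _de("10004", "Pharmacologic Substance End Occurrence Year Number",
            _OC_PHARM, _P_END, _VD_YEAR,
            "Year the pharmacologic substance administration ended."),
    ),
    (
        "Month Of Drug Therapy End",
        _de("10005", "Pharmacologic Substance End Occurrence Month Number",
            _OC_PHARM, _P_END, _VD_MONTH,
            "Month the pharmacologic substance administration ended."),
    ),
    (
        "Day Of Drug Therapy End",
        _de("10006", "Pharmacologic Substance End Occurrence Day Number",
            _OC_PHARM, _P_END, _VD_DAY,
            "Day the pharmacologic substance administration ended."),
    ),
    (
        "Therapy Ongoing",
        _de("10007",
            "Pharmacologic Substance Continue Occurrence Yes No Indicator",
            _OC_PHARM, _P_CONTINUE, _VD_YESNO,
            "Whether the pharmacologic substance administration is ongoing."),
    ),
)

# Further dictionary-asserted medication CDEs (plain-font template targets).
_OTHER_ASSERTED: tuple[tuple[str, DataElement], ...] = (
    (
        "Drug Name",
        _de("10008", "Pharmacologic Substance Name Text",
            _OC_PHARM, PropertyDef("Name", concepts=(ConceptRef("C42614"),)),
            _VD_TEXT, "Name of the pharmacologic substance administered."),
    ),
    (
        "Prescribed Dose",
        _de("10009", "Prescribed Agent Dose Measurement",
            _OC_PRESCRIBED, PropertyDef("Dose"), _VD_DECIMAL),
    ),
    (
        "Cumulative Agent Total Dose",
        _de("10010", "Cumulative Agent Total Dose Measurement",
            _OC_CUMULATIVE, PropertyDef("Total Dose"), _VD_DECIMAL),
    ),
    (
        "Total Dose Units",
        _de("10011", "Cumulative Agent Total Dose Unit of Measure Name",
            _OC_CUMULATIVE, PropertyDef("Total Dose Unit of Measure"), _VD_UNITS),
    ),
    (
        "Prescribed Dose Units",
        _de("10012", "Prescribed Agent Dose Unit of Measure Name",
            _OC_PRESCRIBED, PropertyDef("Dose Unit of Measure"), _VD_UNITS),
    ),
    (
        "Number Cycles",
        _de("10013", "Therapy Regimen Cycle Count",
            _OC_REGIMEN, PropertyDef("Cycle Count"), _VD_COUNT),
    ),
    (
        "Route Of Administration",
        _de("10014", "Agent Administration Route Name",
            _OC_ADMIN, PropertyDef("Route"), _VD_ROUTE),
    ),
)

# Enriched registry CDEs: share object classes with asserted elements but
# are not asserted in the dictionary (bold-italic template targets).
_ENRICHED: tuple[DataElement, ...] = (
    _de("11001", "Administered",
        _OC_PHARM, PropertyDef("Administered Occurrence"), _VD_YESNO),
    _de("11002", "Identifier",
        _OC_PHARM, PropertyDef("Identifier"), _VD_CODE),
    _de("11003", "Unique Identifier",
        _OC_PHARM, PropertyDef("Unique Identifier"), _VD_CODE),
    _de("11004", "Cytokine Administered",
        _OC_PHARM, PropertyDef("Cytokine Administered Occurrence"), _VD_YESNO),
    _de("11005", "Placebo Bevacizumab Administered",
        _OC_PHARM, PropertyDef("Placebo Administered Occurrence"), _VD_YESNO),
    _de("11006", "HER2/neu Administered",
        _OC_PHARM, PropertyDef("HER2 Neu Administered Occurrence"), _VD_YESNO),
    _de("11007", "PubChem Compound Identifier",
        _OC_PHARM, PropertyDef("PubChem Compound Identifier"), _VD_CODE),
    _de("11008", "Indication",
        _OC_REGIMEN, PropertyDef("Indication"), _VD_TEXT),
    _de("11009", "Toxicity Description",
        _OC_ADMIN, PropertyDef("Toxicity Description"), _VD_TEXT),
    _de("11010", "Toxicity Grade",
        _OC_ADMIN, PropertyDef("Toxicity Grade"), _VD_COUNT),
    _de("11011", "Pharmaceutical Dosage Form Code",
        _OC_PRESCRIBED, PropertyDef("Dosage Form Code"), _VD_CODE),
    _de("11012", "Agent Administered Begin Time",
        _OC_ADMIN, PropertyDef("Administered Begin Time"), _VD_TIME),
    _de("11013", "Prior Therapy Treatment Regimen",
        _OC_REGIMEN, PropertyDef("Prior Treatment"), _VD_TEXT),
    _de("11014", "Agent Administered End Time",
        _OC_ADMIN, PropertyDef("Administered End Time"), _VD_TIME),
)

# Twenty medication-template rows: question, prompt, mapped element names.
_TEMPLATE_ROWS: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("Were any medications taken?", "Any meds", ("Administered",)),
    ("What is the medication/treatment identifier?", "CM number",
     ("Identifier", "Unique Identifier")),
    ("What was the term for the medication/therapy taken?",
     "Medication or Therapy", ("Drug Name",)),
    ("Did the subject take <specific medication/treatment>?",
     "<specific medication/treatment>",
     ("Cytokine Administered", "Placebo Bevacizumab Administered",
      "HER2/neu Administered")),
    ("What were the active ingredients?", "Active Ingredients",
     ("PubChem Compound Identifier",)),
    ("For what indication was the medication/therapy taken?", "Indication",
     ("Indication",)),
    ("What was the ID for the adverse events(s) for which the medication "
     "was taken?", "AE ID", ("Toxicity Description", "Toxicity Grade")),
    ("What was the ID of the medical history condition(s) for which the "
     "medication was taken?", "MH ID", ()),
    ("What was the individual dose of the medical/therapy?", "Dose",
     ("Prescribed Dose",)),
    ("What was the total daily dose of the medication therapy?",
     "Total Daily Dose", ("Cumulative Agent Total Dose",)),
    ("What was the unit of the medical/therapy?", "Dose Unit",
     ("Total Dose Units", "Prescribed Dose Units")),
    ("What was the dose form of the medication/therapy?", "Dose Form",
     ("Pharmaceutical Dosage Form Code",)),
    ("What was the frequency of the medication/therapy?", "Frequency",
     ("Number Cycles",)),
    ("What was the route of administration of the medication/therapy?",
     "Route", ("Route Of Administration",)),
    ("What was the start date of the medication/therapy?", "Start Date",
     ("Year Of Drug Therapy Start", "Month Of Drug Therapy Start",
      "Day Of Drug Therapy Start")),
    ("What was the start time of the medication/therapy?", "Start Time",
     ("Agent Administered Begin Time",)),
    ("Was the medication/therapy taken prior to the study?",
     "Taken Prior to Study?", ("Prior Therapy Treatment Regimen",)),
    ("What was the end date of the medication/therapy?", "End Date",
     ("Year Of Drug Therapy End", "Month Of Drug Therapy End",
      "Day Of Drug Therapy End")),
    ("What was the end time of the medication/therapy?", "End Time",
     ("Agent Administered End Time",)),
    ("Is the medication/therapy still ongoing?", "Ongoing",
     ("Therapy Ongoing",)),
)


@dataclass(frozen=True)
class ClinpharmFixture:
    registry: Registry
    domains: tuple[ClinicalDomain, ...]
    alignment_spec: AlignmentSpec

    @property
    def domain(self) -> ClinicalDomain:
        return self.domains[0]


def clinpharm_table2_extract() -> ClinicalDomain:
    """The drug-therapy extract of the domain: exactly the seven start/end/
    ongoing variables of the two-pattern worked example, in printed order."""
    return ClinicalDomain(
        name=DOMAIN_NAME,
        variables=tuple(
            DomainVariable(variable_name=name, cde_ref=de.public_id, position=i)
            for i, (name, de) in enumerate(_DRUG_THERAPY)
        ),
    )


def load_clinpharm_fixture() -> ClinpharmFixture:
    """Build the packaged fixture: registry, dictionary domain and
    twenty-row medication-template alignment spec."""
    asserted = _DRUG_THERAPY + _OTHER_ASSERTED
    registry = build_registry(
        [de for _, de in asserted] + list(_ENRICHED)
    )
    domain = ClinicalDomain(
        name=DOMAIN_NAME,
        variables=tuple(
            DomainVariable(variable_name=name, cde_ref=de.public_id, position=i)
            for i, (name, de) in enumerate(asserted)
        ),
    )
    spec = AlignmentSpec(
        rows=tuple(
            AlignmentRow(question_text=q, prompt=p, mapped_names=m)
            for q, p, m in _TEMPLATE_ROWS
        )
    )
    return ClinpharmFixture(
        registry=registry, domains=(domain,), alignment_spec=spec
    )
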