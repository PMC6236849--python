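"""Treatment schedule model: per-fraction status machine and XML persistence.

Each fraction moves through four successive statuses — CBCT ready, pseudo-CT
ready, treatment-dose ready, cumulative-dose ready — starting from PENDING,
strictly in order and never backwards.  The whole course (patient, plan
chain, fractions with dates, CBCT paths and couch corrections) round-trips
losslessly through a small XML schema.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from lxml import etree

STATUSES = (
    "PENDING",
    "CBCT_READY",
    "PSEUDO_CT_READY",
    "TXDOSE_READY",
    "CUMULATIVE_READY",
)

EVENTS = {
    "cbct_arrived": "CBCT_READY",
    "pseudo_ct_done": "PSEUDO_CT_READY",
    "txdose_done": "TXDOSE_READY",
    "cumulative_done": "CUMULATIVE_READY",
}


class StatusError(ValueError):
    """An event that does not match the next legal status transition."""


@dataclass
class FractionRecord:
    index: int
    date: datetime.date
    cbct_paths: tuple[str, ...] = ()
    couch_correction_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    status: str = "PENDING"
    note: str = ""

    def __post_init__(self):
        self.cbct_paths = tuple(self.cbct_paths)
        self.couch_correction_mm = tuple(float(v) for v in self.couch_correction_mm)
        if self.status not in STATUSES:
            raise ValueError(
                f"illegal fraction status {self.status!r}; expected one of {STATUSES}"
            )


@dataclass
class TreatmentRecord:
    patient_id: str
    plan_chain: list[tuple[str, datetime.date]]
    fractions: list[FractionRecord] = dc_field(default_factory=list)

    def __post_init__(self):
        for k, fr in enumerate(self.fractions, start=1):
            if fr.index != k:
                raise ValueError(
                    f"fraction indices must be contiguous from 1; "
                    f"position {k} has index {fr.index}"
                )
        dates = [fr.date for fr in self.fractions]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError("fraction dates must be non-decreasing")

    def fraction(self, index: int) -> FractionRecord:
        try:
            return self.fractions[index - 1]
        except IndexError:
            raise KeyError(f"no fraction with index {index}") from None


def advance_status(record: TreatmentRecord, fraction_index: int,
                   event: str) -> TreatmentRecord:
    """Advance one fraction's status by an event; out-of-order events raise.

    The record is modified in place and returned.  Statuses only ever move
    forward through the declared order; skipping is rejected.
    """
    if event not in EVENTS:
        raise StatusError(f"unknown event {event!r}; expected one of {sorted(EVENTS)}")
    fr = record.fraction(fraction_index)
    target = EVENTS[event]
    cur_i = STATUSES.index(fr.status)
    tgt_i = STATUSES.index(target)
    if tgt_i != cur_i + 1:
        raise StatusError(
            f"fraction {fraction_index}: event {event!r} would move status "
            f"{fr.status} -> {target}, but the next legal status is "
            f"{STATUSES[min(cur_i + 1, len(STATUSES) - 1)]}"
        )
    fr.status = target
    return record


# ---------------------------------------------------------------------------
# XML persistence
# ---------------------------------------------------------------------------

def record_to_xml(record: TreatmentRecord) -> etree._Element:
    root = etree.Element("treatment-course", patient_id=record.patient_id)
    chain = etree.SubElement(root, "plan-chain")
    for plan_id, start in record.plan_chain:
        etree.SubElement(chain, "plan", id=plan_id, start_date=start.isoformat())
    fracs = etree.SubElement(root, "fractions")
    for fr in record.fractions:
        el = etree.SubElement(
            fracs, "fraction",
            index=str(fr.index), date=fr.date.isoformat(), status=fr.status,
        )
        if fr.note:
            el.set("note", fr.note)
        cc = fr.couch_correction_mm
        etree.SubElement(el, "couch-correction",
                         x=repr(cc[0]), y=repr(cc[1]), z=repr(cc[2]))
        for p in fr.cbct_paths:
            etree.SubElement(el, "cbct", path=p)
    return root


def write_schedule_xml(record: TreatmentRecord, path: str | Path) -> None:
    tree = etree.ElementTree(record_to_xml(record))
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")


def _require(el: etree._Element, attr: str) -> str:
    v = el.get(attr)
    if v is None:
        raise ValueError(
            f"schedule XML: element <{el.tag}> at {el.getroottree().getpath(el)} "
            f"is missing attribute {attr!r}"
        )
    return v


def record_from_xml(root: etree._Element) -> TreatmentRecord:
    if root.tag != "treatment-course":
        raise ValueError(f"schedule XML: expected <treatment-course>, got <{root.tag}>")
    plans = []
    for plan in root.findall("plan-chain/plan"):
        plans.append((
            _require(plan, "id"),
            datetime.date.fromisoformat(_require(plan, "start_date")),
        ))
    fractions = []
    for el in root.findall("fractions/fraction"):
        status = _require(el, "status")
        if status not in STATUSES:
            raise ValueError(
                f"schedule XML: illegal status {status!r} at "
                f"{el.getroottree().getpath(el)}; expected one of {STATUSES}"
            )
        cc_el = el.find("couch-correction")
        cc = (0.0, 0.0, 0.0)
        if cc_el is not None:
            cc = tuple(float(_require(cc_el, a)) for a in ("x", "y", "z"))
        fractions.append(FractionRecord(
            index=int(_require(el, "index")),
            date=datetime.date.fromisoformat(_require(el, "date")),
            cbct_paths=tuple(_require(c, "path") for c in el.findall("cbct")),
            couch_correction_mm=cc,
            status=status,
            note=el.get("note", ""),
        ))
    return TreatmentRecord(
        patient_id=_require(root, "patient_id"),
        plan_chain=plans,
        fractions=fractions,
    )


def read_schedule_xml(path: str | Path) -> TreatmentRecord:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"schedule XML: malformed document {path}: {exc}") from exc
    return record_from_xml(tree.getroot())
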