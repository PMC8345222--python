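"""Endpoint construction and first-line therapy response classification.

Three survival endpoints are analyzed: overall survival from metastatic
diagnosis (OS) and overall survival re-anchored at the first receipt of
immunotherapy (OS-IT) or targeted therapy (OS-TT).  Response to first-line
therapy is classified from progression-free survival: responder if PFS
exceeds 9 months, resistant if progression occurred before 6 months, and
indeterminate in between.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

from .types import ClinicalRecord

log = logging.getLogger(__name__)

ENDPOINTS = ("OS", "OS-IT", "OS-TT")

#: PFS thresholds in months for response classification.
RESPONDER_PFS_GT = 9.0
RESISTANT_PFS_LT = 6.0


def build_endpoints(rec: ClinicalRecord) -> dict[str, tuple[float, int]]:
    """Derive the (time, event) pair for each endpoint a patient contributes to.

    OS is always present.  OS-IT / OS-TT are present only when the therapy
    was received, and are the OS time minus the therapy-start offset with
    the event indicator passed through unchanged.
    """
    out = {"OS": (rec.os_months, rec.os_event)}
    for key, offset in (("OS-IT", rec.it_start_offset_months),
                        ("OS-TT", rec.tt_start_offset_months)):
        if offset is None:
            continue
        t = rec.os_months - offset
        if t < 0:
            raise ValueError(
                f"patient {rec.patient_id}: therapy start offset {offset} months "
                f"exceeds OS time {rec.os_months} months ({key})")
        out[key] = (t, rec.os_event)
    return out


def classify_response(pfs_months: Optional[float], received: bool) -> str:
    """Classify first-line therapy outcome from PFS.

    Returns 'responder' (PFS > 9 mo), 'resistant' (PFS < 6 mo),
    'indeterminate' (6-9 mo, or PFS missing for a treated patient), or
    'not_treated'.
    """
    if not received:
        return "not_treated"
    if pfs_months is None or (isinstance(pfs_months, float) and math.isnan(pfs_months)):
        log.warning("treated patient with missing PFS classified as indeterminate")
        return "indeterminate"
    if pfs_months < 0:
        raise ValueError("pfs_months must be >= 0")
    if pfs_months > RESPONDER_PFS_GT:
        return "responder"
    if pfs_months < RESISTANT_PFS_LT:
        return "resistant"
    return "indeterminate"


def response_by_therapy(rec: ClinicalRecord) -> dict[str, str]:
    """Response class per therapy line ('IT', 'TT') for one patient."""
    out = {}
    for therapy, offset in (("IT", rec.it_start_offset_months),
                            ("TT", rec.tt_start_offset_months)):
        received = offset is not None
        # PFS applies to the first-line agent only
        first_line_matches = received and rec.first_line in (therapy, "both")
        pfs = rec.pfs_first_line_months if first_line_matches else None
        out[therapy] = classify_response(pfs, received=first_line_matches)
    return out
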