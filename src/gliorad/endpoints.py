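"""Endpoint containers shared by screening and modelling."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ClinicalRecord


@dataclass(frozen=True)
class BinaryEndpoint:
    """A binary outcome (e.g. methylation status) aligned to patient ids."""

    name: str
    labels: pd.Series  # bool/0-1, index = patient_id

    def subset(self, ids) -> "BinaryEndpoint":
        return BinaryEndpoint(self.name, self.labels.loc[list(ids)])


@dataclass(frozen=True)
class SurvivalEndpoint:
    """A right-censored time-to-event outcome aligned to patient ids."""

    name: str
    times: pd.Series  # months, index = patient_id
    events: pd.Series  # bool, index = patient_id

    def subset(self, ids) -> "SurvivalEndpoint":
        ids = list(ids)
        return SurvivalEndpoint(self.name, self.times.loc[ids], self.events.loc[ids])


def endpoints_from_clinical(records: list[ClinicalRecord]):
    """Build the three study endpoints from clinical records.

    Patients without a methylation label are excluded from the binary
    endpoint only; they keep their survival endpoints.
    """
    ids = [r.patient_id for r in records]
    mgmt = pd.Series(
        {r.patient_id: 1.0 if r.mgmt == "methylated" else 0.0 for r in records if r.mgmt != "missing"}
    )
    pfs2 = SurvivalEndpoint(
        "pfs2",
        pd.Series({r.patient_id: r.pfs2_months for r in records}),
        pd.Series({r.patient_id: bool(r.pfs2_event) for r in records}),
    )
    os_ = SurvivalEndpoint(
        "os",
        pd.Series({r.patient_id: r.os_months for r in records}),
        pd.Series({r.patient_id: bool(r.os_event) for r in records}),
    )
    return {
        "mgmt": BinaryEndpoint("mgmt", mgmt.reindex([i for i in ids if i in mgmt.index])),
        "pfs2": pfs2,
        "os": os_,
    }
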