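"""Patients-by-features tables with VOI and normalization provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class FeatureTable:
    """A patients x named-features matrix plus its extraction provenance."""

    data: pd.DataFrame  # index: patient_id, columns: feature names
    voi: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate patient ids in feature table")
        self.data = self.data.astype(float)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, patient_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(patient_ids)], self.voi, dict(self.provenance))

    def write_csv(self, path: str | Path) -> None:
        """CSV with a ``#``-prefixed metadata header block."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# voi: {self.voi}\n")
            fh.write(f"# provenance: {json.dumps(self.provenance, sort_keys=True)}\n")
            self.data.to_csv(fh, index_label="patient_id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        voi, prov = "", {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("# voi:"):
                voi = line.split(":", 1)[1].strip()
            elif line.startswith("# provenance:"):
                prov = json.loads(line.split(":", 1)[1].strip())
            elif not line.startswith("#"):
                body_start = i
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), index_col="patient_id")
        return cls(df, voi, prov)
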