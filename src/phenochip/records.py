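"""Per-bioreactor feature records and their tabular assembly.

One bioreactor chamber is one analysis unit: its record carries the sample
metadata (line, genotype, genetic background, treatment, timepoint) and the
scalar features extracted by the assay pipeline.  Records concatenate into
the feature table the statistics and classification layers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["bioreactor_id", "assay", "line", "genotype", "background", "treatment", "timepoint"]


@dataclass
class FeatureRecord:
    bioreactor_id: str
    assay: str
    features: dict[str, float] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"bioreactor_id": self.bioreactor_id, "assay": self.assay}
        for key in ("line", "genotype", "background", "treatment", "timepoint"):
            row[key] = self.metadata.get(key, "")
        row.update(self.features)
        return row


def feature_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    """Stack records into a feature table; missing features become NaN."""
    df = pd.DataFrame([r.to_row() for r in records])
    if df["bioreactor_id"].duplicated().any():
        dupes = df.loc[df["bioreactor_id"].duplicated(), "bioreactor_id"].tolist()
        raise ValueError(f"duplicated bioreactor ids: {dupes}")
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in METADATA_COLUMNS and np.issubdtype(df[c].dtype, np.number)]
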