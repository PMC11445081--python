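"""Community-state assignments shared by the PAM and DMM typing routes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["StateAssignment", "state_proportions", "match_labels"]


@dataclass
class StateAssignment:
    """Per-sample community-state labels with provenance.

    ``labels`` holds one state name per sample (initially raw cluster names
    like ``C0``; :meth:`rename` substitutes driver-derived names such as BB /
    EF / BL). ``medoid_ids`` is populated for PAM only.
    """

    sample_ids: list
    labels: list
    method: str  # "PAM" or "DMM"
    k: int
    medoid_ids: list | None = None
    state_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("one label per sample required")
        if len(set(self.labels)) != self.k:
            raise ValueError(f"expected exactly {self.k} distinct labels")

    @property
    def series(self) -> pd.Series:
        return pd.Series(list(self.labels), index=list(self.sample_ids), name="state")

    def rename(self, mapping: dict) -> "StateAssignment":
        """Return a copy with cluster names substituted (e.g. C0 -> BB)."""
        new_labels = [mapping.get(l, l) for l in self.labels]
        return StateAssignment(
            sample_ids=list(self.sample_ids),
            labels=new_labels,
            method=self.method,
            k=self.k,
            medoid_ids=self.medoid_ids,
            state_names={**self.state_names, **mapping},
        )

    def to_tsv(self, path) -> None:
        self.series.rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


def state_proportions(assignment: StateAssignment) -> pd.DataFrame:
    """Per-state counts and percentages (one decimal place).

    Percentages are rounded for reporting; the ``count`` column stays exact so
    the percentages are always re-derivable.
    """
    counts = assignment.series.value_counts().sort_index()
    pct = (100.0 * counts / counts.sum()).round(1)
    return pd.DataFrame({"count": counts, "percentage": pct}).rename_axis("state")


def match_labels(reference, candidate) -> dict:
    """Best one-to-one relabelling of ``candidate`` onto ``reference``.

    Solves the maximum-agreement matching on the contingency table (Hungarian
    algorithm). Returns a mapping from candidate label to reference label;
    surplus candidate labels map to themselves.
    """
    ct = pd.crosstab(pd.Series(list(reference)), pd.Series(list(candidate)))
    rows, cols = linear_sum_assignment(-ct.to_numpy())
    mapping = {ct.columns[c]: ct.index[r] for r, c in zip(rows, cols)}
    for label in ct.columns:
        mapping.setdefault(label, label)
    return mapping
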