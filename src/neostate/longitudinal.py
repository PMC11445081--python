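"""Longitudinal dynamics of community states and their driver species.

Participants are represented as timelines of (timepoint, sample, state)
observations. The week-1 state is the earliest available week-1 sample (day 4
preferred over day 7). Transitions between timepoints are exact
cross-tabulations, optionally stratified by birth mode; per-state retention is
the diagonal over the row sum. Carriage of a species is detection at or above
0.1% relative abundance (inclusive boundary). Group comparisons use paired
t-tests, Wilcoxon signed-rank tests (exact for n <= 25) and 2x2 chi-square
tests without continuity correction, all two-sided with Benjamini-Hochberg
correction across each reported family.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TIMEPOINT_ORDER",
    "ParticipantTimeline",
    "build_timelines",
    "assign_week1_state",
    "TransitionTable",
    "transition_table",
    "retention_test",
    "carriage",
    "strain_retention_summary",
    "paired_group_tests",
]

TIMEPOINT_ORDER = ("day4", "day7", "day21", "infancy")
CARRIAGE_THRESHOLD = 0.001  # 0.1% relative abundance, inclusive


@dataclass
class ParticipantTimeline:
    """Ordered per-participant observations, at most one sample per timepoint."""

    participant_id: str
    birth_mode: str
    observations: dict = field(default_factory=dict)
    # observations: timepoint_label -> {"sample_id": ..., "state": ...,
    #                                   "driver_abundances": {species: fraction}}

    def __post_init__(self) -> None:
        unknown = set(self.observations) - set(TIMEPOINT_ORDER)
        if unknown:
            raise ValueError(f"unknown timepoints: {sorted(unknown)}")

    def state_at(self, timepoint: str):
        obs = self.observations.get(timepoint)
        return obs["state"] if obs else None


def build_timelines(metadata: pd.DataFrame, states: pd.Series,
                    driver_abundances: pd.DataFrame | None = None) -> list[ParticipantTimeline]:
    """Assemble participant timelines from sample metadata and state labels.

    ``states`` is indexed by sample id. When a participant has several samples
    in one timepoint window, the earliest day of life wins. Samples without a
    state label are skipped.
    """
    timelines = []
    for pid, grp in metadata.groupby("participant_id"):
        grp = grp.sort_values("day_of_life", kind="mergesort")
        obs = {}
        for _, row in grp.iterrows():
            tp = row["timepoint_label"]
            if tp not in TIMEPOINT_ORDER or tp in obs:
                continue
            sid = row["sample_id"]
            if sid not in states.index:
                continue
            entry = {"sample_id": sid, "state": states.loc[sid]}
            if driver_abundances is not None and sid in driver_abundances.index:
                entry["driver_abundances"] = driver_abundances.loc[sid].to_dict()
            obs[tp] = entry
        if obs:
            timelines.append(ParticipantTimeline(
                participant_id=str(pid),
                birth_mode=str(grp["birth_mode"].iloc[0]),
                observations=obs,
            ))
    return timelines


def assign_week1_state(timeline: ParticipantTimeline):
    """Week-1 state: the day-4 state if sampled, else day 7, else None."""
    for tp in ("day4", "day7"):
        state = timeline.state_at(tp)
        if state is not None:
            return state
    return None


@dataclass
class TransitionTable:
    """State x state transition counts between two timepoints for one stratum."""

    stratum: str  # "VD", "CS" or "pooled"
    counts: pd.DataFrame  # from-states (rows) x to-states (columns)
    from_timepoint: str
    to_timepoint: str
    n_excluded: int = 0

    def retention(self) -> pd.Series:
        """Per-state proportion remaining in the same state (diagonal/row sum)."""
        shared = self.counts.index.intersection(self.counts.columns)
        diag = pd.Series(
            {s: self.counts.loc[s, s] if s in shared else 0 for s in self.counts.index}
        )
        return (diag / self.counts.sum(axis=1)).rename("retention")


def _resolve_state(timeline: ParticipantTimeline, timepoint: str):
    if timepoint == "week1":
        return assign_week1_state(timeline)
    return timeline.state_at(timepoint)


def transition_table(timelines, from_tp: str, to_tp: str,
                     stratify: bool = False) -> list[TransitionTable]:
    """Cross-tabulate state transitions between two timepoints.

    ``from_tp`` may be ``"week1"`` (earliest day-4/day-7 sample) or any
    timepoint label. Participants missing either timepoint are excluded, with
    the exclusion count recorded on each table. With ``stratify=True`` the
    pooled table is followed by per-birth-mode tables.
    """
    pairs, modes = [], []
    n_excluded = 0
    for tl in timelines:
        a, b = _resolve_state(tl, from_tp), _resolve_state(tl, to_tp)
        if a is None or b is None:
            n_excluded += 1
            continue
        pairs.append((a, b))
        modes.append(tl.birth_mode)
    if not pairs:
        raise ValueError("no participant has both timepoints")
    if n_excluded:
        logger.info("transition_table: excluded %d participant(s) lacking a timepoint",
                    n_excluded)
    df = pd.DataFrame(pairs, columns=["from_state", "to_state"])
    df["birth_mode"] = modes
    all_from = sorted(df["from_state"].unique())
    all_to = sorted(df["to_state"].unique())

    def _table(sub: pd.DataFrame, stratum: str) -> TransitionTable:
        ct = pd.crosstab(sub["from_state"], sub["to_state"])
        ct = ct.reindex(index=all_from, columns=all_to, fill_value=0)
        return TransitionTable(stratum=stratum, counts=ct, from_timepoint=from_tp,
                               to_timepoint=to_tp, n_excluded=n_excluded)

    tables = [_table(df, "pooled")]
    if stratify:
        for mode in sorted(df["birth_mode"].unique()):
            tables.append(_table(df[df["birth_mode"] == mode], mode))
    return tables


def retention_test(table: TransitionTable) -> pd.DataFrame:
    """Pairwise 2x2 chi-square tests of state retention with BH correction.

    For each pair of from-states, retained vs switched counts are compared
    (two-sided, no continuity correction). Expected cells below 1 are flagged
    but still tested.
    """
    counts = table.counts
    states = [s for s in counts.index if counts.loc[s].sum() > 0]
    if len(states) < 2:
        raise ValueError("need at least 2 states with participants")
    retained = {
        s: int(counts.loc[s, s]) if s in counts.columns else 0 for s in states
    }
    total = {s: int(counts.loc[s].sum()) for s in states}
    rows = []
    for a, b in itertools.combinations(states, 2):
        t2 = np.array([
            [retained[a], total[a] - retained[a]],
            [retained[b], total[b] - retained[b]],
        ])
        expected = stats.contingency.expected_freq(t2)
        flagged = bool((expected < 1).any())
        if flagged:
            warnings.warn(
                f"retention test {a} vs {b}: expected cell below 1", stacklevel=2
            )
        if t2.sum(axis=0).min() == 0:  # a column of zeros: no information
            chi2, p = 0.0, 1.0
        else:
            chi2, p = stats.chi2_contingency(t2, correction=False)[:2]
        rows.append({"state_a": a, "state_b": b, "chi2": float(chi2),
                     "p": float(p), "low_expected_cell": flagged})
    out = pd.DataFrame(rows)
    out["q_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def carriage(abundance: float, threshold: float = CARRIAGE_THRESHOLD) -> bool:
    """Species carriage: relative abundance at or above the threshold (0.1%)."""
    if not 0 <= abundance <= 1:
        raise ValueError("abundance must be a fraction in [0, 1]")
    return bool(abundance >= threshold)


def strain_retention_summary(retained) -> dict:
    """Fraction of participants retaining their initial strain, as a percentage.

    ``retained`` is a boolean sequence, one entry per evaluable participant;
    the percentage is reported to one decimal place.
    """
    retained = list(retained)
    n = len(retained)
    if n == 0:
        raise ValueError("no evaluable participants")
    k = int(sum(bool(r) for r in retained))
    return {"retained": k, "n": n, "fraction": k / n,
            "percentage": round(100.0 * k / n, 1)}


def _wilcoxon_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test by sign-flip enumeration.

    Handles ties via midranks: the null distribution of W+ over all 2^n
    equiprobable sign assignments is built by dynamic programming on doubled
    midranks (integers). Zeros are dropped beforehand.
    """
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return 0.0, 1.0
    ranks2 = np.rint(2 * stats.rankdata(np.abs(diffs))).astype(int)
    w_plus2 = int(ranks2[diffs > 0].sum())
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:-r] if r > 0 else dist
        dist = 0.5 * (dist + shifted)
    cdf = float(dist[: w_plus2 + 1].sum())
    sf = float(dist[w_plus2:].sum())
    p = min(1.0, 2.0 * min(cdf, sf))
    return float(w_plus2 / 2.0), p


def paired_group_tests(comparisons: dict, design: str) -> pd.DataFrame:
    """A family of two-sided paired/group tests with BH correction.

    ``comparisons`` maps a comparison name to its data: for ``paired_t`` and
    ``wilcoxon`` a tuple of two aligned equal-length vectors; for ``chisq`` a
    2x2 count array (e.g. retained/switched by group). Wilcoxon is exact for
    n <= 25 pairs and a tie-corrected normal approximation above that.
    Degenerate all-zero paired differences give p = 1 with a warning.
    """
    if design not in ("paired_t", "wilcoxon", "chisq"):
        raise ValueError(f"unknown design {design!r}")
    rows = []
    for name, data in comparisons.items():
        if design == "chisq":
            t2 = np.asarray(data)
            if t2.sum(axis=0).min() == 0 or t2.sum(axis=1).min() == 0:
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.chi2_contingency(t2, correction=False)[:2]
        else:
            x = np.asarray(data[0], dtype=float)
            y = np.asarray(data[1], dtype=float)
            if x.shape != y.shape:
                raise ValueError(f"{name}: paired vectors must have equal length")
            diffs = x - y
            if np.allclose(diffs, 0):
                warnings.warn(f"{name}: all paired differences are zero; p = 1",
                              stacklevel=2)
                stat, p = 0.0, 1.0
            elif design == "paired_t":
                stat, p = stats.ttest_rel(x, y)
            elif len(diffs) <= 25:
                stat, p = _wilcoxon_exact(diffs)
            else:
                stat, p = stats.wilcoxon(x, y, method="approx", correction=False)
        rows.append({"comparison": name, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
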