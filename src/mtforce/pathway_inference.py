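"""Unfolding pathway and direction classification.

Accepted metallothionein events are labelled one-step vs two-step; a
two-step pair of increments summing to ~11 nm is matched to one of four
pathways P1-P4, each defined by an anchoring cysteine that stays bound to
the metal cluster in the intermediate.  Because the C-terminal sub-segment
always carries the larger increment (the Cys51-Cys64 cysteine-free stretch
lies on that side), the order of the two increments identifies the
unfolding direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanics import SegmentTable

__all__ = [
    "PathwayDefinition",
    "PathwayAssignment",
    "PathwayStatistics",
    "build_default_pathways",
    "classify_event",
    "assign_direction",
    "tabulate",
]

#: Measured mean pair increments per pathway (nm), P1..P4, from the
#: alpha-domain two-step statistics; one-step mean 11.3 nm.
MEASURED_PAIRS = [(5.2, 6.1), (4.1, 7.2), (3.2, 8.1), (2.4, 9.3)]
ANCHORS = ["Cys49(51)", "Cys45", "Cys42", "Cys37(38)"]
ONE_STEP_DLC = 11.3


@dataclass(frozen=True)
class PathwayDefinition:
    """One two-step pathway: anchoring cysteine and its increment pair."""

    pathway_id: str  # 'P1'..'P4'
    anchor: str
    small: float
    large: float
    one_step_dlc: float = ONE_STEP_DLC
    sum_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if not self.small < self.large:
            raise ValueError("pair must satisfy small < large")
        if abs(self.small + self.large - self.one_step_dlc) > self.sum_tolerance:
            raise ValueError(
                f"{self.pathway_id}: pair sum {self.small + self.large} not "
                f"within {self.sum_tolerance} nm of {self.one_step_dlc}"
            )


@dataclass
class PathwayAssignment:
    """Classification of one event's increment list."""

    dlc_list: list[float]
    label: str  # 'one-step' | 'P1'..'P4' | 'unassigned'
    direction: str | None = None  # 'N' | 'C' | None; defined iff two-step
    anchor: str | None = None
    match_distance: float | None = None
    tie_broken: bool = False
    note: str = ""


def build_default_pathways(
    segment_table: SegmentTable,
    source: str = "measured",
    one_step_dlc: float = ONE_STEP_DLC,
) -> list[PathwayDefinition]:
    """The four alpha-domain pathway definitions.

    ``source='measured'`` uses the measured average pairs
    (5.2+6.1, 4.1+7.2, 3.2+8.1, 2.4+9.3).  ``source='theoretical'``
    substitutes the theoretical segment pair where the segment table
    provides one (P2: Cys34-Cys45 / Cys45-Cys67 -> 3.6 + 7.5 nm); pathways
    without tabulated theoretical segments keep their measured pair.
    """
    if not segment_table.entries:
        raise ValueError("segment table is empty")
    pairs = [tuple(p) for p in MEASURED_PAIRS]
    if source == "theoretical":
        try:
            small = segment_table.get("alpha:Cys34-Cys45").theoretical_dlc
            large = segment_table.get("alpha:Cys45-Cys67").theoretical_dlc
            pairs[1] = (small, large)
        except KeyError:
            pass
    elif source != "measured":
        raise ValueError("source must be 'measured' or 'theoretical'")
    return [
        PathwayDefinition(f"P{i + 1}", ANCHORS[i], s, l, one_step_dlc)
        for i, (s, l) in enumerate(pairs)
    ]


def assign_direction(
    pair: tuple[float, float],
    observed: tuple[float, float],
    resolution: float = 0.5,
) -> str | None:
    """Unfolding direction from the order of a two-step pair.

    The larger increment belongs to the C-terminal side, so a first-observed
    increment matching the large member means C-terminus-first ('C'), the
    small member N-terminus-first ('N').  If the pair members differ by less
    than ``resolution`` the direction is undecidable (``None``).
    """
    small, large = sorted(pair)
    if large - small < resolution:
        return None
    first = observed[0]
    d_large = abs(first - large)
    d_small = abs(first - small)
    if d_large == d_small:
        return None
    return "C" if d_large < d_small else "N"


def classify_event(
    dlc_list: list[float],
    pathways: list[PathwayDefinition],
    one_step_window: tuple[float, float] = (10.0, 13.0),
    pair_tolerance: float = 0.7,
    direction_resolution: float = 0.5,
) -> PathwayAssignment:
    """Label an event's ordered increment list.

    * one entry inside ``one_step_window`` -> 'one-step';
    * two entries summing to the one-step increment within 1 nm -> nearest
      pathway by Euclidean distance of the sorted pair, if within
      ``pair_tolerance``; distance ties break toward the lower pathway id
      (flagged on the assignment);
    * anything else (including >2 entries, below 1% of events) ->
      'unassigned'.
    """
    if not dlc_list:
        raise ValueError("empty increment list")
    if not pathways:
        raise ValueError("no pathway definitions")
    dlc_list = [float(d) for d in dlc_list]
    if len(dlc_list) == 1:
        lo, hi = one_step_window
        if lo <= dlc_list[0] <= hi:
            return PathwayAssignment(dlc_list, "one-step")
        return PathwayAssignment(dlc_list, "unassigned", note="outside one-step window")
    if len(dlc_list) > 2:
        return PathwayAssignment(dlc_list, "unassigned", note="multi-step")

    one_step_dlc = pathways[0].one_step_dlc
    total = sum(dlc_list)
    if abs(total - one_step_dlc) > 1.0:
        return PathwayAssignment(
            dlc_list, "unassigned", note="pair sum outside conservation window"
        )
    small_obs, large_obs = sorted(dlc_list)
    dists = [
        float(np.hypot(small_obs - p.small, large_obs - p.large)) for p in pathways
    ]
    best = int(np.argmin(dists))
    tie = any(
        abs(d - dists[best]) < 1e-12 for i, d in enumerate(dists) if i != best
    )
    if dists[best] > pair_tolerance:
        return PathwayAssignment(
            dlc_list, "unassigned", match_distance=dists[best],
            note="no pathway within tolerance",
        )
    p = pathways[best]
    direction = assign_direction(
        (p.small, p.large), tuple(dlc_list), direction_resolution
    )
    return PathwayAssignment(
        dlc_list,
        p.pathway_id,
        direction=direction,
        anchor=p.anchor,
        match_distance=dists[best],
        tie_broken=tie,
    )


@dataclass
class PathwayStatistics:
    """Counts, frequencies, direction split and dLc histograms."""

    counts: dict = field(default_factory=dict)  # label -> count
    direction_counts: dict = field(default_factory=dict)  # label -> {'N','C','n/a'}
    frequencies: dict = field(default_factory=dict)  # over assigned events
    n_total: int = 0
    n_assigned: int = 0
    n_two_step: int = 0
    c_terminal_fraction: float | None = None
    two_step_hist: tuple[np.ndarray, np.ndarray] | None = None  # (bin_left, count)
    one_step_hist: tuple[np.ndarray, np.ndarray] | None = None

    def to_table(self, pathways: list[PathwayDefinition]) -> pd.DataFrame:
        rows = []
        for label in ["one-step"] + [p.pathway_id for p in pathways] + ["unassigned"]:
            pdef = next((p for p in pathways if p.pathway_id == label), None)
            d = self.direction_counts.get(label, {})
            rows.append(
                {
                    "path": label,
                    "pair_small_nm": pdef.small if pdef else "",
                    "pair_large_nm": pdef.large if pdef else "",
                    "anchor": pdef.anchor if pdef else "",
                    "count": self.counts.get(label, 0),
                    "n_C_first": d.get("C", 0),
                    "n_N_first": d.get("N", 0),
                    "n_direction_na": d.get("n/a", 0),
                    "frequency": round(self.frequencies.get(label, 0.0), 4),
                }
            )
        return pd.DataFrame(rows)


def tabulate(
    assignments: list[PathwayAssignment],
    two_step_bin: float = 0.4,
    one_step_bin: float = 1.0,
) -> PathwayStatistics:
    """Aggregate assignments into pathway statistics.

    Frequencies are over assigned events (one-step + P1..P4); the two-step
    histogram pools the individual increments of every two-entry event
    whose pair sum passed the conservation window (default bin 0.4 nm, as
    in the published two-step histogram; one-step histogram bin 1 nm).
    """
    if not assignments:
        raise ValueError("no assignments to tabulate")
    stats = PathwayStatistics(n_total=len(assignments))
    two_step_dlcs: list[float] = []
    one_step_dlcs: list[float] = []
    n_c = n_n = 0
    for a in assignments:
        stats.counts[a.label] = stats.counts.get(a.label, 0) + 1
        if a.label == "one-step":
            one_step_dlcs.append(a.dlc_list[0])
        if a.label.startswith("P"):
            stats.n_two_step += 1
            two_step_dlcs.extend(a.dlc_list)
            key = a.direction if a.direction in ("N", "C") else "n/a"
            dc = stats.direction_counts.setdefault(a.label, {})
            dc[key] = dc.get(key, 0) + 1
            if a.direction == "C":
                n_c += 1
            elif a.direction == "N":
                n_n += 1
    assigned = [a for a in assignments if a.label != "unassigned"]
    stats.n_assigned = len(assigned)
    if assigned:
        for label in set(a.label for a in assigned):
            stats.frequencies[label] = stats.counts[label] / len(assigned)
    if n_c + n_n > 0:
        stats.c_terminal_fraction = n_c / (n_c + n_n)
    if two_step_dlcs:
        hi = np.ceil(max(two_step_dlcs) / two_step_bin) * two_step_bin
        edges = np.arange(0.0, hi + two_step_bin, two_step_bin)
        counts, edges = np.histogram(two_step_dlcs, bins=edges)
        stats.two_step_hist = (edges[:-1], counts)
    if one_step_dlcs:
        hi = np.ceil(max(one_step_dlcs) / one_step_bin) * one_step_bin
        edges = np.arange(0.0, hi + one_step_bin, one_step_bin)
        counts, edges = np.histogram(one_step_dlcs, bins=edges)
        stats.one_step_hist = (edges[:-1], counts)
    return stats
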