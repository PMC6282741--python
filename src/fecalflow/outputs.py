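"""Pathway attribution, cross-sectional validation, and network export.

Turns a population of exposure ledgers into the quantities an exposure
assessment reports: per-pathway daily ingestion distributions (log10
scale), the dominant pathway per day, the fraction of ingestion that never
passed over the hands ("direct" exposure), a simulated hand-rinse
cross-section for comparison against membrane-filtration field data, and a
time-binned edge list of the microbe transfer network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .engine import SOURCES, ExposureLedger

__all__ = [
    "PathwaySummary",
    "summarize",
    "fraction_direct",
    "hand_rinse_crosssection",
    "export_network",
]


@dataclass
class PathwaySummary:
    """Population summary of daily ingestion by pathway.

    ``per_source`` has one row per origin source with log10 quantiles
    computed two ways: over exposed days only (zero-exposure days reported
    separately via ``fraction_exposed``) and over all days with zeros kept
    at a log10 of ``-inf`` replaced by ``NaN`` -- zero never masquerades as
    a finite log value.  ``dominant`` gives the fraction of days on which
    each source contributed the most.
    """

    per_source: pd.DataFrame
    dominant: pd.Series
    n_days: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        top = self.dominant.idxmax() if len(self.dominant) else "none"
        return f"<PathwaySummary of {self.n_days} child-days; dominant pathway mode: {top}>"


def _ingestion_matrix(ledgers: Sequence[ExposureLedger]) -> pd.DataFrame:
    rows = [led.ingested_by_source() for led in ledgers]
    return pd.DataFrame(rows, columns=list(SOURCES)).fillna(0).astype(np.int64)


def summarize(ledgers: Sequence[ExposureLedger]) -> PathwaySummary:
    """Per-pathway daily ingestion statistics and dominant-pathway frequencies.

    The dominant pathway of a day is the source with the largest ingested
    count; zero-ingestion days are labeled ``"none"``.
    """
    if not ledgers:
        raise ValueError("need at least one ledger")
    mat = _ingestion_matrix(ledgers)
    n = len(mat)
    records = []
    for source in SOURCES:
        col = mat[source].to_numpy()
        exposed = col[col > 0]
        frac_exposed = len(exposed) / n
        log_exposed = np.log10(exposed) if len(exposed) else np.array([])

        def q(a: np.ndarray, p: float) -> float:
            return float(np.quantile(a, p)) if len(a) else math.nan

        records.append(
            {
                "source": source,
                "fraction_exposed": frac_exposed,
                "median_log10_exposed": q(log_exposed, 0.5),
                "q2.5_log10_exposed": q(log_exposed, 0.025),
                "q97.5_log10_exposed": q(log_exposed, 0.975),
                # all-days convention: zero days enter as count 0 and the
                # quantile is reported on the count scale, then logged when
                # positive (NaN marks "no exposure", never -inf)
                "median_log10_all_days": _log10_or_nan(float(np.quantile(col, 0.5))),
                "q2.5_log10_all_days": _log10_or_nan(float(np.quantile(col, 0.025))),
                "q97.5_log10_all_days": _log10_or_nan(float(np.quantile(col, 0.975))),
            }
        )
    per_source = pd.DataFrame.from_records(records).set_index("source")

    totals = mat.sum(axis=1)
    dominant_labels = mat.idxmax(axis=1).where(totals > 0, "none")
    dominant = dominant_labels.value_counts(normalize=True).reindex(
        list(SOURCES) + ["none"], fill_value=0.0
    )
    return PathwaySummary(per_source=per_source, dominant=dominant, n_days=n)


def _log10_or_nan(x: float) -> float:
    return math.log10(x) if x > 0 else math.nan


def fraction_direct(
    ledgers: Sequence[ExposureLedger],
    grouping: Literal["per-day", "per-child-year"] = "per-day",
) -> pd.Series:
    """Fraction of ingested microbes that never resided on the hands.

    ``per-day`` yields one fraction per child-day; ``per-child-year``
    aggregates consecutive blocks of 365 ledgers into one child-year before
    taking the ratio.  Groups with zero total ingestion are excluded (the
    fraction is undefined there).
    """
    direct = np.array([sum(led.ingested_direct.values()) for led in ledgers], dtype=float)
    total = np.array([led.total_ingested() for led in ledgers], dtype=float)
    if grouping == "per-day":
        mask = total > 0
        return pd.Series(direct[mask] / total[mask], name="fraction_direct")
    if grouping == "per-child-year":
        n_years = len(ledgers) // 365
        if n_years == 0:
            raise ValueError("per-child-year grouping needs at least 365 ledgers")
        fracs = []
        for i in range(n_years):
            sl = slice(i * 365, (i + 1) * 365)
            t = total[sl].sum()
            if t > 0:
                fracs.append(direct[sl].sum() / t)
        return pd.Series(fracs, name="fraction_direct")
    raise ValueError("grouping must be 'per-day' or 'per-child-year'")


def hand_rinse_crosssection(
    ledgers: Sequence[ExposureLedger],
    rng: np.random.Generator,
    *,
    ulod: float = 1e5,
    truncate: bool = False,
) -> pd.DataFrame:
    """Simulate a cross-sectional hand-rinse survey.

    For each child-day a single uniform-random time in the 14-hour window
    is drawn and the total hand load at that moment is read off the
    ledger's hand-load time series.  With ``truncate=True`` observations
    are censored at the assay's upper limit of detection (default 1e5 CFU
    per pair of hands), mimicking membrane filtration.
    """
    rows = []
    for led in ledgers:
        t = float(rng.uniform(0.0, led.horizon_min))
        nh = led.nh_at(t)
        obs = min(float(nh), ulod) if truncate else float(nh)
        rows.append({"child_id": led.child_id, "time_min": t, "hand_load": obs})
    return pd.DataFrame(rows, columns=["child_id", "time_min", "hand_load"])


_NODE_ROLES = {
    "hands": "vehicle",
    "food": "vehicle",
    "mouth": "ingestion",
    "wash_sink": "sink",
    "bath_sink": "sink",
    "surface": "sink",
}


def _node_role(node: str) -> str:
    if node.startswith("source:"):
        return "source"
    return _NODE_ROLES.get(node, "sink")


def export_network(
    ledgers: Sequence[ExposureLedger],
    path,
    *,
    n_bins: int = 14,
    graphml_path=None,
) -> pd.DataFrame:
    """Write the time-binned transfer network as an edge-list CSV.

    Each row is (time_bin, from, to, count, log10_weight, from_role,
    to_role) where ``count`` sums all microbes moved along that edge within
    the bin.  Requires ledgers recorded with ``record_events=True``.  An
    optional GraphML file (aggregated over time) can be written for graph
    tooling.
    """
    frames = [led.events_frame() for led in ledgers]
    events = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time", "from", "to", "count", "source", "direct"]
    )
    horizon = max((led.horizon_min for led in ledgers), default=840.0)
    if len(events):
        events["time_bin"] = np.minimum(
            (events["time"] / horizon * n_bins).astype(int), n_bins - 1
        )
        edges = (
            events.groupby(["time_bin", "from", "to"], as_index=False)["count"].sum()
        )
        edges["log10_weight"] = np.log10(edges["count"])
    else:
        edges = pd.DataFrame(columns=["time_bin", "from", "to", "count", "log10_weight"])
    edges["from_role"] = edges["from"].map(_node_role) if len(edges) else pd.Series(dtype=object)
    edges["to_role"] = edges["to"].map(_node_role) if len(edges) else pd.Series(dtype=object)
    cols = ["time_bin", "from", "to", "count", "log10_weight", "from_role", "to_role"]
    edges = edges.reindex(columns=cols)
    edges.to_csv(path, index=False)

    if graphml_path is not None and len(edges):
        import networkx as nx

        g = nx.DiGraph()
        agg = edges.groupby(["from", "to"], as_index=False)["count"].sum()
        for _, row in agg.iterrows():
            g.add_edge(row["from"], row["to"], count=int(row["count"]),
                       log10_weight=float(np.log10(row["count"])))
        for node in g.nodes:
            g.nodes[node]["role"] = _node_role(node)
        nx.write_graphml(g, graphml_path)
    return edges


def read_network(path) -> pd.DataFrame:
    """Read an edge list written by :func:`export_network`."""
    return pd.read_csv(path)
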