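"""Node centralities, network summaries and topological role labels.

Per node we compute degree, unnormalized shortest-path betweenness (Brandes),
within-component closeness (reachable count / summed distance) and the mean
shortest-path length to reachable nodes (ASPL).  Network-level thresholds
follow the summarization convention of the source workflow: the *mean* for
degree and betweenness, the *median* for closeness and ASPL.  Nodes are then
labelled on two axes:

hub axis (degree vs betweenness thresholds)
    ``hub`` (high/high), ``provincial_hub`` (high degree, low betweenness),
    ``connector_bottleneck`` (low degree, high betweenness), else
    ``peripheral``.

integration axis (closeness vs ASPL thresholds)
    ``integrated`` (high closeness, low ASPL), ``vulnerable`` (low closeness,
    high ASPL), else ``intermediate``.

"High" means >= the threshold ("<=" for ASPL): the taxonomy is stated with
arrows, not strict inequalities, so boundaries count as high.  Singleton nodes
have undefined closeness/ASPL (NaN, excluded from medians) and fall in the
``intermediate`` integration class.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

HUB_AXIS = ("hub", "provincial_hub", "connector_bottleneck", "peripheral")
INTEGRATION_AXIS = ("integrated", "vulnerable", "intermediate")

PROFILE_COLUMNS = ["degree", "betweenness", "closeness", "aspl"]


def compute_centralities(net: nx.Graph, *, normalized_betweenness: bool = False) -> pd.DataFrame:
    """Per-node centrality profiles, indexed by node name (sorted).

    Betweenness is exact (Brandes accumulation over all pairs), undirected and
    by default unnormalized; ``normalized_betweenness`` divides by the number
    of ordered pairs for cross-network comparison plots.
    """
    nodes = sorted(net.nodes, key=str)
    betw = nx.betweenness_centrality(net, normalized=normalized_betweenness)
    degree = {n: net.degree(n) for n in nodes}
    closeness: dict[str, float] = {}
    aspl: dict[str, float] = {}
    for n in nodes:
        dist = nx.single_source_shortest_path_length(net, n)
        dist.pop(n, None)
        if not dist:  # singleton: closeness/ASPL undefined, reported missing
            closeness[n] = np.nan
            aspl[n] = np.nan
        else:
            total = sum(dist.values())
            closeness[n] = len(dist) / total
            aspl[n] = total / len(dist)
    return pd.DataFrame({"degree": pd.Series(degree, dtype=float),
                         "betweenness": pd.Series(betw, dtype=float),
                         "closeness": pd.Series(closeness),
                         "aspl": pd.Series(aspl)}).loc[nodes]


def summarize(profiles: pd.DataFrame, *, medians_everywhere: bool = False) -> pd.Series:
    """Network-level thresholds: mean degree/betweenness, median closeness/ASPL.

    ``medians_everywhere`` switches degree/betweenness to medians as well (an
    outlier-robust alternative to the stated convention).  Undefined
    closeness/ASPL values (singletons) are excluded.
    """
    if len(profiles) == 0:
        raise ValueError("cannot summarize an empty profile table")
    center = pd.Series.median if medians_everywhere else pd.Series.mean
    return pd.Series({
        "mean_degree": center(profiles["degree"].dropna()),
        "mean_betweenness": center(profiles["betweenness"].dropna()),
        "median_closeness": profiles["closeness"].dropna().median(),
        "median_aspl": profiles["aspl"].dropna().median(),
    })


class CentralityRoleClassifier(BaseEstimator):
    """Classify nodes into topological roles from their centrality profiles.

    ``fit`` learns the network-level thresholds (mean degree, mean
    betweenness, median closeness, median ASPL) from a profile table;
    ``predict`` labels profiles on the hub and integration axes against those
    thresholds.  Labels depend only on the profiles and the fitted summary,
    never on node order, and are invariant to any common positive rescaling
    of the betweenness column applied to both fit and predict inputs.

    Parameters
    ----------
    medians_everywhere : bool, default False
        Use medians for all four thresholds instead of the stated mean/median
        convention.
    """

    def __init__(self, medians_everywhere: bool = False):
        self.medians_everywhere = medians_everywhere

    def fit(self, profiles: pd.DataFrame, y=None):
        missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
        if missing:
            raise ValueError(f"profile table missing columns {missing}")
        self.summary_ = summarize(profiles, medians_everywhere=self.medians_everywhere)
        return self

    def predict(self, profiles: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "summary_")
        s = self.summary_
        hi_deg = profiles["degree"] >= s["mean_degree"]
        hi_bet = profiles["betweenness"] >= s["mean_betweenness"]
        hub_axis = np.select(
            [hi_deg & hi_bet, hi_deg & ~hi_bet, ~hi_deg & hi_bet],
            ["hub", "provincial_hub", "connector_bottleneck"],
            default="peripheral")
        defined = profiles["closeness"].notna() & profiles["aspl"].notna()
        hi_clo = profiles["closeness"] >= s["median_closeness"]
        lo_aspl = profiles["aspl"] <= s["median_aspl"]
        integration = np.select(
            [defined & hi_clo & lo_aspl, defined & ~hi_clo & ~lo_aspl],
            ["integrated", "vulnerable"],
            default="intermediate")
        return pd.DataFrame({"hub_axis": hub_axis,
                             "integration_axis": integration,
                             "integration_defined": defined.values},
                            index=profiles.index)

    def fit_predict(self, profiles: pd.DataFrame) -> pd.DataFrame:
        return self.fit(profiles).predict(profiles)


def classify_roles(profiles: pd.DataFrame, summary: pd.Series | None = None) -> pd.DataFrame:
    """Functional wrapper: label profiles against a (possibly precomputed) summary."""
    clf = CentralityRoleClassifier()
    if summary is None:
        return clf.fit_predict(profiles)
    clf.summary_ = summary
    return clf.predict(profiles)
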