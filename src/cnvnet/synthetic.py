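"""Seeded synthetic inputs for the whole pipeline.

Emulates, at desk scale, the statistical structure of a gene-oriented CNV
cohort study: per-sample CNV loss/gain calls with a controlled fraction of
loss/gain overlap, non-overlapping gene models over small chromosomes,
scale-free interaction networks with planted topological roles (hubs,
provincial hubs, connector bottlenecks), an NDD gene panel, and per-gene
dosage-sensitivity scores.

Everything is driven by one global seed; each component draws from its own
independent substream (numpy ``SeedSequence(seed, component_key)``), so adding
or re-running one generator never perturbs another's output, and identical
configs produce byte-identical outputs.

The CNV generator returns its own ground truth, computed by a per-base
brute-force oracle (boolean base masks + run-length extraction) that is
independent of the interval-algebra implementation used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: fixed substream keys — one per generator component
_STREAM = {"genes": 1, "calls": 2, "network": 3, "dosage": 4, "panel": 5}

PLANTED_ROLES = ("hub", "provincial_hub", "bottleneck")


class SizingError(ValueError):
    """Requested structure does not fit the configured sizes."""


def _default_chroms() -> dict[str, int]:
    return {"chr1": 60_000, "chr2": 40_000}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic world.

    The defaults mirror the scale of the emulated cohort: 29 samples passing
    QC, a few CNV calls per sample per type, a few hundred genes on two short
    chromosomes (small enough that every track is verifiable per base), a
    300-node scale-free network with a handful of planted roles, and edge
    confidences from Beta(4, 2) so that a 0.63 medium-confidence filter
    removes a nontrivial minority of edges (P[conf < 0.63] ≈ 0.35).
    """
    seed: int = 0
    n_samples: int = 29
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    n_genes: int = 400
    calls_per_sample: int = 3            # per CNV type
    loss_gain_overlap_frac: float = 0.25
    network_n_nodes: int = 300
    network_attach_m: int = 3
    n_planted_hubs: int = 3
    n_planted_provincial: int = 3
    n_planted_bottlenecks: int = 2
    confidence_beta_params: tuple[float, float] = (4.0, 2.0)
    # construction constants for the planted roles
    hub_attach_frac: float = 0.15        # hub connects to this fraction of all nodes
    provincial_degree: int = 12          # provincial hub degree, confined to one community
    bottleneck_edges_per_side: int = 2   # bottleneck edges into each community

    def __post_init__(self):
        counts = dict(n_samples=self.n_samples, n_genes=self.n_genes,
                      calls_per_sample=self.calls_per_sample,
                      network_n_nodes=self.network_n_nodes,
                      network_attach_m=self.network_attach_m,
                      n_planted_hubs=self.n_planted_hubs,
                      n_planted_provincial=self.n_planted_provincial,
                      n_planted_bottlenecks=self.n_planted_bottlenecks)
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.loss_gain_overlap_frac <= 1.0:
            raise ValueError("loss_gain_overlap_frac must be in [0, 1]")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        a, b = self.confidence_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("confidence_beta_params must be positive")


def _rng(cfg_seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg_seed, _STREAM[component])))


def _allocate_slots(chrom_lengths: dict[str, int], n_slots: int) -> list[tuple[str, int, int]]:
    """Split the genome into n_slots disjoint windows, proportionally per chrom."""
    chroms = sorted(chrom_lengths)
    total = sum(chrom_lengths.values())
    counts = {c: int(round(n_slots * chrom_lengths[c] / total)) for c in chroms}
    # fix rounding drift deterministically on the largest chromosome
    drift = n_slots - sum(counts.values())
    counts[max(chroms, key=lambda c: (chrom_lengths[c], c))] += drift
    slots = []
    for c in chroms:
        k = counts[c]
        if k == 0:
            continue
        width = chrom_lengths[c] // k
        if width < 10:
            raise SizingError(f"chromosome {c} too short for {k} windows")
        for i in range(k):
            slots.append((c, i * width, (i + 1) * width))
    return slots


# ---------------------------------------------------------------------------
# gene models

def gen_gene_models(cfg: SyntheticConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals tiled over the chromosomes.

    One gene per window, with a random sub-interval covering 30–80% of the
    window; symbols are unique (G00001, ...) and gene_type is protein_coding
    with probability 0.8, else lncRNA.
    """
    cols = ["chrom", "start", "end", "symbol", "gene_type"]
    if cfg.n_genes == 0:
        return pd.DataFrame(columns=cols)
    rng = _rng(cfg.seed, "genes")
    slots = _allocate_slots(cfg.chrom_lengths, cfg.n_genes)
    rows = []
    for i, (chrom, lo, hi) in enumerate(slots):
        width = hi - lo
        length = int(rng.integers(max(1, int(0.3 * width)), max(2, int(0.8 * width))))
        start = lo + int(rng.integers(0, width - length + 1))
        gene_type = "protein_coding" if rng.random() < 0.8 else "lncRNA"
        rows.append((chrom, start, start + length, f"G{i + 1:05d}", gene_type))
    return (pd.DataFrame(rows, columns=cols)
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# CNV calls + per-base ground truth

def perbase_tracks(calls: pd.DataFrame, chrom_lengths: dict[str, int]) -> dict[str, pd.DataFrame]:
    """Brute-force per-base oracle for the loss/gain set algebra.

    Builds boolean base masks for the loss and gain tracks on every
    chromosome and run-length-extracts shared (loss AND gain), unique_loss
    (loss AND NOT gain) and unique_gain intervals.  Quadratic in genome size;
    intended for chromosomes up to ~100 kb.
    """
    out: dict[str, list] = {"merged_loss": [], "merged_gain": [],
                            "shared": [], "unique_loss": [], "unique_gain": []}
    for chrom in sorted(chrom_lengths):
        n = chrom_lengths[chrom]
        loss = np.zeros(n, dtype=bool)
        gain = np.zeros(n, dtype=bool)
        sub = calls[calls["chrom"] == chrom]
        for _, row in sub.iterrows():
            mask = loss if row["cnv_type"] == "loss" else gain
            mask[row["start"]:row["end"]] = True
        for label, mask in (("merged_loss", loss), ("merged_gain", gain),
                            ("shared", loss & gain),
                            ("unique_loss", loss & ~gain),
                            ("unique_gain", gain & ~loss)):
            padded = np.concatenate([[False], mask, [False]])
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            for s, e in zip(edges[::2], edges[1::2]):
                out[label].append((chrom, int(s), int(e)))
    return {label: pd.DataFrame({
                "chrom": pd.Series([r[0] for r in rows], dtype=str),
                "start": pd.Series([r[1] for r in rows], dtype="int64"),
                "end": pd.Series([r[2] for r in rows], dtype="int64")})
            for label, rows in out.items()}


def gen_cnv_callset(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-sample CNV calls plus oracle ground truth.

    Each sample receives ``calls_per_sample`` loss calls and the same number
    of gain calls.  Unplanted calls live in their own disjoint genome windows,
    so with ``loss_gain_overlap_frac = 0`` the shared track is exactly empty;
    a fraction ``loss_gain_overlap_frac`` of the gain calls is planted as an
    exact copy of a distinct loss call's interval, so at fraction 1 the loss
    and gain base sets coincide and both unique tracks are empty.

    Returns (calls, truth) where truth holds the five per-base oracle tracks.
    """
    if cfg.calls_per_sample < 1:
        raise SizingError("calls_per_sample must be >= 1")
    rng = _rng(cfg.seed, "calls")
    n_per_type = cfg.n_samples * cfg.calls_per_sample
    slots = _allocate_slots(cfg.chrom_lengths, 2 * n_per_type)
    order = rng.permutation(len(slots))
    rows = []
    for k in range(2 * n_per_type):
        chrom, lo, hi = slots[order[k]]
        width = hi - lo
        length = int(rng.integers(max(1, int(0.2 * width)), max(2, int(0.6 * width))))
        start = lo + int(rng.integers(0, width - length + 1))
        cnv_type = "loss" if k < n_per_type else "gain"
        sample = (k % n_per_type) // cfg.calls_per_sample
        rows.append([chrom, start, start + length, cnv_type, f"S{sample + 1:03d}"])
    calls = pd.DataFrame(rows, columns=["chrom", "start", "end", "cnv_type", "sample_id"])

    n_plant = int(round(cfg.loss_gain_overlap_frac * n_per_type))
    if n_plant:
        loss_idx = calls.index[calls["cnv_type"] == "loss"].to_numpy()
        gain_idx = calls.index[calls["cnv_type"] == "gain"].to_numpy()
        chosen_gain = rng.choice(gain_idx, size=n_plant, replace=False)
        chosen_loss = rng.permutation(loss_idx)[:n_plant]
        for gi, li in zip(chosen_gain, chosen_loss):
            calls.loc[gi, ["chrom", "start", "end"]] = calls.loc[
                li, ["chrom", "start", "end"]].values
    calls = (calls.sort_values(["sample_id", "cnv_type", "chrom", "start"],
                               kind="mergesort").reset_index(drop=True))
    truth = perbase_tracks(calls, cfg.chrom_lengths)
    return calls, truth


# ---------------------------------------------------------------------------
# scored network with planted roles

def gen_network(cfg: SyntheticConfig) -> tuple[nx.Graph, dict[str, str]]:
    """Scale-free network with planted hubs, provincial hubs and bottlenecks.

    Construction: the non-planted nodes form two preferential-attachment
    communities of (near-)equal size, joined only through the planted
    bottlenecks, each of which attaches to the top-degree nodes of both
    communities (few links, all cross-community traffic).  Each provincial
    hub anchors on one community hub and duplicates part of its neighborhood
    (many links, little brokerage, confined to one community).  Each planted
    hub attaches to a uniform fraction of nodes across the whole graph (many
    links everywhere; note these edges may also join the communities).  Edge
    confidences are drawn from Beta(confidence_beta_params); node names come
    from :func:`gen_gene_models`.

    Returns (network, roles) with roles mapping planted symbols to
    hub / provincial_hub / bottleneck.
    """
    n = cfg.network_n_nodes
    m = cfg.network_attach_m
    n_planted = cfg.n_planted_hubs + cfg.n_planted_provincial + cfg.n_planted_bottlenecks
    if n <= m or m < 1:
        raise SizingError("need network_n_nodes > network_attach_m >= 1")
    if n_planted >= n:
        raise SizingError(f"{n_planted} planted roles do not fit in {n} nodes")
    backbone = n - n_planted
    if backbone < 2 * (m + 1):
        raise SizingError("backbone too small for two preferential-attachment communities")
    genes = gen_gene_models(cfg)
    if len(genes) < n:
        raise SizingError(f"need n_genes >= network_n_nodes ({len(genes)} < {n})")
    symbols = genes["symbol"].tolist()[:n]

    rng = _rng(cfg.seed, "network")
    n_a = backbone // 2 + backbone % 2
    n_b = backbone - n_a
    comm_a = symbols[:n_a]
    comm_b = symbols[n_a:backbone]
    planted = symbols[backbone:]
    g = nx.Graph()
    g.graph["provenance"] = f"synthetic:seed={cfg.seed}"
    for names, size in ((comm_a, n_a), (comm_b, n_b)):
        ba = nx.barabasi_albert_graph(size, m, seed=int(rng.integers(2 ** 31)))
        for u, v in ba.edges:
            g.add_edge(names[u], names[v])

    roles: dict[str, str] = {}
    cursor = 0

    def _top_degree(side: list[str], k: int) -> list[str]:
        return sorted(side, key=lambda x: (-g.degree(x), x))[:k]

    for _ in range(cfg.n_planted_bottlenecks):
        name = planted[cursor]; cursor += 1
        roles[name] = "bottleneck"
        for side in (comm_a, comm_b):
            for t in _top_degree(side, cfg.bottleneck_edges_per_side):
                g.add_edge(name, t)
    for i in range(cfg.n_planted_provincial):
        name = planted[cursor]; cursor += 1
        roles[name] = "provincial_hub"
        side = comm_a if i % 2 == 0 else comm_b
        anchor = _top_degree(side, i // 2 + 1)[-1]
        nbrs = sorted(x for x in g.neighbors(anchor) if x in set(side))
        k = min(cfg.provincial_degree - 1, len(nbrs))
        take = list(rng.choice(nbrs, size=k, replace=False)) if k else []
        for t in [anchor] + take:
            g.add_edge(name, t)
    all_backbone = comm_a + comm_b
    for _ in range(cfg.n_planted_hubs):
        name = planted[cursor]; cursor += 1
        roles[name] = "hub"
        k = max(m, int(round(cfg.hub_attach_frac * n)))
        for t in rng.choice(all_backbone, size=min(k, len(all_backbone)), replace=False):
            g.add_edge(name, t)

    a, b = cfg.confidence_beta_params
    for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
        g[u][v]["confidence"] = float(np.round(rng.beta(a, b), 6))
    return g, roles


# ---------------------------------------------------------------------------
# dosage scores and panel

def gen_dosage_table(genes: list[str], seed: int) -> pd.DataFrame:
    """Per-gene constraint and dosage-sensitivity scores, indexed by symbol.

    pLI, pHaplo and pTriplo are Beta-distributed probabilities (U-shaped for
    pLI, mildly so for the dosage scores, mimicking the bimodality of real
    constraint metrics); LOEUF and sHet are log-normal positive scores.
    """
    rng = _rng(seed, "dosage")
    n = len(genes)
    table = pd.DataFrame({
        "pLI": rng.beta(0.3, 0.3, n),
        "LOEUF": rng.lognormal(0.0, 0.45, n),
        "sHet": rng.lognormal(-3.5, 1.0, n),
        "pHaplo": rng.beta(0.7, 0.7, n),
        "pTriplo": rng.beta(0.7, 0.7, n),
    }, index=pd.Index(genes, name="symbol")).round(6)
    return table


def gen_ndd_panel(genes: list[str], seed: int, n_panel: int) -> list[str]:
    """A panel of n_panel distinct gene symbols sampled from the universe."""
    if n_panel > len(genes):
        raise SizingError(f"panel of {n_panel} exceeds {len(genes)} genes")
    rng = _rng(seed, "panel")
    return sorted(rng.choice(genes, size=n_panel, replace=False))
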