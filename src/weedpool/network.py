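"""Co-occurrence network construction and habitat classification.

Habitats are inferred from plot-based survey data alone: species that
co-occur across plots more often than expected by chance form modules of a
co-occurrence network, and modules correspond to habitats. The chain is

1. incidence matrix (plots x species, presence/absence);
2. pairwise null test — exact hypergeometric upper tail on the number of
   shared plots, given each species' occupancy (the probabilistic
   co-occurrence model of Veech 2013);
3. Benjamini–Hochberg FDR filter on the pair p-values;
4. modularity maximization on the significant-edge graph (Newman–Girvan Q,
   greedy agglomeration by default, Louvain optionally);
5. plots labelled by the majority module of their species, and each species
   assigned a *main habitat* — the module label under which it occurs most
   often. A species' occurrences outside its main habitat are what the
   generalism index summarizes.

All stochastic steps take an explicit seed; the default detection method is
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from ._util import logger

UNASSIGNED = "unassigned"


@dataclass
class IncidenceMatrix:
    """Plots x species presence/absence with identifier registries."""

    plots: list[str]
    species: list[str]
    presence: np.ndarray  # bool, shape (n_plots, n_species)

    def __post_init__(self) -> None:
        if len(set(self.plots)) != len(self.plots):
            raise ValueError("duplicate plot identifiers")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species identifiers")
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.plots), len(self.species)):
            raise ValueError("presence shape does not match identifier registries")

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def occupancy(self) -> np.ndarray:
        """Number of plots occupied, per species."""
        return self.presence.sum(axis=0)


@dataclass
class CooccurrenceEdge:
    species_i: str
    species_j: str
    shared: int
    p_null: float
    q_value: float | None = None


@dataclass
class HabitatPartition:
    """Species -> module assignment plus derived plot labels."""

    species_module: dict[str, str]
    modularity_q: float
    plot_habitat: dict[str, str] = field(default_factory=dict)
    module_labels: dict[str, str] = field(default_factory=dict)

    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for m in self.species_module.values():
            if m != UNASSIGNED:
                sizes[m] = sizes.get(m, 0) + 1
        return sizes


def build_incidence(
    records: Iterable[tuple[str, str]], min_occupancy: int = 3
) -> IncidenceMatrix:
    """Build an incidence matrix from (plot_id, species_id) records.

    Duplicate records collapse to a single presence. Species observed in
    fewer than ``min_occupancy`` plots are dropped (and logged), as are
    plots left empty by that filter.
    """
    pairs: set[tuple[str, str]] = set()
    for i, rec in enumerate(records):
        try:
            plot, sp = rec
        except (TypeError, ValueError):
            raise ValueError(f"malformed occurrence record at line {i + 1}: {rec!r}")
        if not str(plot).strip() or not str(sp).strip():
            raise ValueError(f"malformed occurrence record at line {i + 1}: {rec!r}")
        pairs.add((str(plot), str(sp)))
    if not pairs:
        raise ValueError("no occurrence records")
    plots = sorted({p for p, _ in pairs})
    species = sorted({s for _, s in pairs})
    p_idx = {p: i for i, p in enumerate(plots)}
    s_idx = {s: j for j, s in enumerate(species)}
    mat = np.zeros((len(plots), len(species)), dtype=bool)
    for p, s in pairs:
        mat[p_idx[p], s_idx[s]] = True

    occ = mat.sum(axis=0)
    keep = occ >= min_occupancy
    if not keep.all():
        dropped = [s for s, k in zip(species, keep) if not k]
        logger.info(
            "dropped %d/%d species below min_occupancy=%d",
            len(dropped), len(species), min_occupancy,
        )
        species = [s for s, k in zip(species, keep) if k]
        mat = mat[:, keep]
    if not species:
        raise ValueError("min_occupancy filter removed every species")
    nonempty = mat.any(axis=1)
    if not nonempty.all():
        logger.info("dropped %d plots left empty after species filter",
                    int((~nonempty).sum()))
        plots = [p for p, k in zip(plots, nonempty) if k]
        mat = mat[nonempty]
    return IncidenceMatrix(plots=plots, species=species, presence=mat)


def pair_null_test(shared: int, occ_i: int, occ_j: int, n_plots: int) -> float:
    """Upper-tail probability of observing >= ``shared`` joint plots.

    Null model: the ``occ_j`` plots of species j are an equiprobable draw
    from the ``n_plots`` plots, of which ``occ_i`` hold species i; the
    number of shared plots is then hypergeometric. Returns
    P(X >= shared), computed from the exact hypergeometric distribution.
    """
    if not (0 <= shared <= min(occ_i, occ_j) <= max(occ_i, occ_j) <= n_plots):
        raise ValueError(
            f"impossible counts: shared={shared}, occ_i={occ_i}, "
            f"occ_j={occ_j}, n_plots={n_plots}"
        )
    if shared == 0:
        return 1.0
    # sf(k) = P(X > k), so P(X >= shared) = sf(shared - 1)
    return float(stats.hypergeom.sf(shared - 1, n_plots, occ_i, occ_j))


def cooccurrence_edges(incidence: IncidenceMatrix) -> list[CooccurrenceEdge]:
    """All pairwise co-occurrence edges with null p-values (vectorized)."""
    mat = incidence.presence.astype(np.int64)
    shared = mat.T @ mat
    occ = incidence.occupancy.astype(np.int64)
    n = incidence.n_plots
    iu, ju = np.triu_indices(len(incidence.species), k=1)
    sh = shared[iu, ju]
    # P(X >= sh) under hypergeom(n, occ_i, occ_j); sf(sh-1) handles sh=0 too
    p = stats.hypergeom.sf(sh - 1, n, occ[iu], occ[ju])
    sp = incidence.species
    return [
        CooccurrenceEdge(sp[a], sp[b], int(s), float(pv))
        for a, b, s, pv in zip(iu, ju, sh, p)
    ]


def filter_edges(
    edges: Sequence[CooccurrenceEdge], alpha: float = 0.05,
    method: str = "bh_fdr",
) -> list[CooccurrenceEdge]:
    """Retain significant edges; sets ``q_value`` under BH-FDR.

    ``method='none'`` thresholds raw p-values at ``alpha``. Shrinking alpha
    never adds edges. An empty edge list returns an empty list.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if method not in ("none", "bh_fdr"):
        raise ValueError(f"unknown method {method!r}")
    if not edges:
        return []
    p = np.array([e.p_null for e in edges])
    if method == "bh_fdr":
        q = stats.false_discovery_control(p, method="bh")
        kept = []
        for e, qv in zip(edges, q):
            e.q_value = float(qv)
            if qv <= alpha:
                kept.append(e)
    else:
        kept = [e for e in edges if e.p_null <= alpha]
    logger.info("edge filter (%s, alpha=%g): %d/%d retained",
                method, alpha, len(kept), len(edges))
    return kept


def detect_modules(
    graph: nx.Graph, seed: int = 0, method: str = "greedy",
    all_species: Sequence[str] | None = None,
) -> HabitatPartition:
    """Partition species nodes by modularity maximization.

    ``method='greedy'`` (Clauset–Newman–Moore agglomeration) is fully
    deterministic; ``'louvain'`` is deterministic given ``seed``. Species in
    ``all_species`` absent from the graph (no significant edge) are
    assigned the ``unassigned`` module. Raises on an edgeless graph.
    """
    if graph.number_of_edges() == 0:
        raise ValueError(
            "co-occurrence graph has no edges; relax alpha or min_occupancy"
        )
    core = graph.subgraph([n for n in graph if graph.degree(n) > 0])
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(core)
    elif method == "louvain":
        communities = nx.community.louvain_communities(core, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    q = nx.community.modularity(core, communities)
    species_module = {}
    for k, comm in enumerate(communities, start=1):
        for s in comm:
            species_module[s] = str(k)
    for n in graph:
        species_module.setdefault(n, UNASSIGNED)
    if all_species is not None:
        for s in all_species:
            species_module.setdefault(s, UNASSIGNED)
    logger.info("detected %d modules, Q=%.4f", len(communities), q)
    return HabitatPartition(species_module=species_module, modularity_q=float(q))


def assign_plot_habitats(
    incidence: IncidenceMatrix, species_module: Mapping[str, str]
) -> dict[str, str]:
    """Label each plot with the majority module of its species.

    Ties break toward the globally larger module (more species), then the
    lowest module id. Plots whose species are all unassigned get
    ``unassigned``.
    """
    global_sizes: dict[str, int] = {}
    for m in species_module.values():
        if m != UNASSIGNED:
            global_sizes[m] = global_sizes.get(m, 0) + 1
    labels: dict[str, str] = {}
    for i, plot in enumerate(incidence.plots):
        present = [incidence.species[j]
                   for j in np.flatnonzero(incidence.presence[i])]
        votes: dict[str, int] = {}
        for s in present:
            m = species_module.get(s, UNASSIGNED)
            if m != UNASSIGNED:
                votes[m] = votes.get(m, 0) + 1
        if not votes:
            labels[plot] = UNASSIGNED
            logger.info("plot %r has no module-assigned species", plot)
            continue
        labels[plot] = min(
            votes,
            key=lambda m: (-votes[m], -global_sizes.get(m, 0), m),
        )
    return labels


def habitat_occurrence_counts(
    incidence: IncidenceMatrix, plot_habitat: Mapping[str, str]
) -> dict[str, dict[str, int]]:
    """Per-species occurrence counts across plot habitat labels."""
    counts: dict[str, dict[str, int]] = {s: {} for s in incidence.species}
    for i, plot in enumerate(incidence.plots):
        h = plot_habitat.get(plot, UNASSIGNED)
        if h == UNASSIGNED:
            continue
        for j in np.flatnonzero(incidence.presence[i]):
            c = counts[incidence.species[j]]
            c[h] = c.get(h, 0) + 1
    return counts


def assign_main_habitat(
    occurrences: Mapping[str, int], habitat_plot_totals: Mapping[str, int]
) -> str:
    """Main habitat of one species: the label with the most occurrences.

    Ties break toward the habitat with the larger total plot count, then
    the lowest habitat id. No labelled occurrences -> ``unassigned``.
    """
    votes = {h: c for h, c in occurrences.items() if h != UNASSIGNED and c > 0}
    if not votes:
        return UNASSIGNED
    return min(
        votes,
        key=lambda h: (-votes[h], -habitat_plot_totals.get(h, 0), h),
    )
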