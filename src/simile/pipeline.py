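"""End-to-end pair scoring, all-vs-all tables, hit filtering and networks.

``compare_pair`` chains the similarity decomposition, the zero-gap
alignment of the interspectral quadrant and the permutation test into
one :class:`PairScore`.  ``all_vs_all`` drives it over every spectrum
pair; ``filter_hits`` applies the standard similarity cutoffs
(score >= 0.7, p <= 0.05, >= 10 matched ions, all inclusive);
``build_network`` applies the stricter networking cutoffs plus the
usual molecular-networking topology constraints (mutual top-10 edges
per node, components capped at 100 nodes by weakest-edge removal).

The maximum-common-substructure helpers quantify structural similarity
of a molecule pair as the Jaccard coefficient of overlapping bonds,
s = N / (N_A + N_B - N), and bin it into the not/low/medium/high
rubric; the substructure search itself is an optional RDKit-backed
extra.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import similarity
from .alignment import align_dp
from .errors import DegeneracyError, NumericalError, ParameterError
from .significance import DEFAULT_SCHEDULE, monte_carlo_pvalue
from .spectra_io import FragmentationSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SimileParams",
    "PairScore",
    "EdgeTable",
    "Network",
    "compare_pair",
    "all_vs_all",
    "filter_hits",
    "build_network",
    "mcs_jaccard",
    "classify_mcs",
    "McsSimilarity",
]

EDGE_COLUMNS = ("id_a", "id_b", "score", "pvalue", "n_matched", "n_iterations")


@dataclass(frozen=True)
class SimileParams:
    """Scoring parameters and similar-spectra cutoffs.

    tolerance
        m/z window (Th) for difference counting; 0.01 suits
        high-resolution spectra, 0.5 mirrors coarse cosine settings.
    schedule
        Cumulative Monte Carlo stage sizes for the permutation test.
    score_min, p_max, min_matched_ions
        Similar-spectra cutoffs, all boundaries inclusive.
    seed
        Global seed; per-pair streams are derived from it and the pair
        ids so results are independent of comparison order.
    """

    tolerance: float = similarity.DEFAULT_TOLERANCE
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    score_min: float = 0.7
    p_max: float = 0.05
    min_matched_ions: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.score_min < 0:
            raise ParameterError("score_min must be >= 0")
        if not 0 < self.p_max <= 1:
            raise ParameterError("p_max must be in (0, 1]")
        if self.min_matched_ions < 0:
            raise ParameterError("min_matched_ions must be >= 0")
        if self.tolerance < 0:
            raise ParameterError("tolerance must be >= 0")


@dataclass(frozen=True)
class PairScore:
    """Result of comparing one spectrum pair (symmetric in a and b)."""

    id_a: str
    id_b: str
    score: float
    pvalue: float
    n_matched: int
    n_iterations: int

    @property
    def edge_id(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))


@dataclass(frozen=True)
class EdgeTable:
    """A collection of pair scores; the all-vs-all result table."""

    edges: tuple[PairScore, ...]
    nodes: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.nodes:
            seen = dict.fromkeys(
                itertools.chain.from_iterable((e.id_a, e.id_b) for e in self.edges)
            )
            object.__setattr__(self, "nodes", tuple(seen))

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.id_a, e.id_b, e.score, e.pvalue, e.n_matched, e.n_iterations)
                for e in self.edges
            ],
            columns=list(EDGE_COLUMNS),
        )

    def to_tsv(self, sink: str | Path | IO) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, source: str | Path | IO) -> "EdgeTable":
        frame = pd.read_csv(source, sep="\t")
        missing = set(EDGE_COLUMNS) - set(frame.columns)
        if missing:
            raise ParameterError(f"edge table missing columns: {sorted(missing)}")
        edges = tuple(
            PairScore(
                id_a=str(row.id_a),
                id_b=str(row.id_b),
                score=float(row.score),
                pvalue=float(row.pvalue),
                n_matched=int(row.n_matched),
                n_iterations=int(row.n_iterations),
            )
            for row in frame.itertuples()
        )
        return cls(edges=edges)

    def sorted(self) -> "EdgeTable":
        """Canonical view: ids ordered within each row, rows sorted."""
        canonical = tuple(
            e if e.id_a <= e.id_b else replace(e, id_a=e.id_b, id_b=e.id_a)
            for e in self.edges
        )
        return EdgeTable(
            edges=tuple(sorted(canonical, key=lambda e: e.edge_id)),
            nodes=tuple(sorted(self.nodes)),
        )


@dataclass(frozen=True)
class Network:
    """A filtered molecular network."""

    graph: nx.Graph
    components: tuple[frozenset, ...]

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    def to_graphml(self, sink: str | Path) -> None:
        nx.write_graphml(self.graph, sink)

    def to_edge_tsv(self, sink: str | Path | IO) -> None:
        rows = [
            (a, b, d["score"], d["pvalue"], d["n_matched"], d["n_iterations"])
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(sink, sep="\t", index=False)


def _pair_seed(id_a: str, id_b: str, seed: int) -> int:
    """Stable per-pair seed: independent of comparison order, < 2**31."""
    first, second = sorted((id_a, id_b))
    digest = hashlib.sha256(f"{first}\x1f{second}\x1f{seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def compare_pair(
    a: FragmentationSpectrum, b: FragmentationSpectrum, params: SimileParams = SimileParams()
) -> PairScore:
    """Score one spectrum pair: similarity matrix, alignment, p-value.

    Internally the pair is ordered by spectrum id so that
    ``compare_pair(a, b)`` and ``compare_pair(b, a)`` return the same
    result for a fixed seed.
    """
    first, second = sorted((a, b), key=lambda s: s.spectrum_id)
    try:
        decomp = similarity.decompose_pair(first, second, tolerance=params.tolerance)
    except (NumericalError, np.linalg.LinAlgError) as exc:
        raise DegeneracyError(
            f"similarity pipeline failed for pair "
            f"({first.spectrum_id!r}, {second.spectrum_id!r}): {exc}"
        ) from exc
    observed = align_dp(decomp.s_xy)
    concat_mz = np.concatenate([first.mz, second.mz])
    rng = np.random.default_rng(_pair_seed(a.spectrum_id, b.spectrum_id, params.seed))
    pval = monte_carlo_pvalue(
        decomp.S,
        concat_mz,
        decomp.m,
        decomp.n,
        observed.score,
        schedule=params.schedule,
        rng=rng,
    )
    return PairScore(
        id_a=a.spectrum_id,
        id_b=b.spectrum_id,
        score=observed.score,
        pvalue=pval.pvalue,
        n_matched=observed.n_matched,
        n_iterations=pval.iterations,
    )


def all_vs_all(
    spectra: Sequence[FragmentationSpectrum], params: SimileParams = SimileParams()
) -> EdgeTable:
    """Score every unordered spectrum pair; n spectra give n(n-1)/2 rows.

    Per-pair seeds are derived from the sorted id pair and the global
    seed, so the table does not depend on input order (up to row
    ordering; use :meth:`EdgeTable.sorted` for a canonical view).
    """
    if len(spectra) < 2:
        raise ParameterError("all_vs_all needs at least 2 spectra")
    ids = [s.spectrum_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ParameterError("spectrum ids must be unique")
    edges = []
    for a, b in itertools.combinations(spectra, 2):
        edges.append(compare_pair(a, b, params))
    return EdgeTable(edges=tuple(edges), nodes=tuple(ids))


def filter_hits(table: EdgeTable, params: SimileParams = SimileParams()) -> EdgeTable:
    """Keep rows with score >= score_min, p <= p_max and enough matched ions."""
    kept = tuple(
        e
        for e in table.edges
        if e.score >= params.score_min
        and e.pvalue <= params.p_max
        and e.n_matched >= params.min_matched_ions
    )
    return EdgeTable(edges=kept, nodes=table.nodes)


def _mutual_top_k(edges: Sequence[PairScore], top_k: int) -> list[PairScore]:
    # rank each node's incident edges by descending score, ties by edge id
    by_node: dict[str, list[PairScore]] = {}
    for e in edges:
        by_node.setdefault(e.id_a, []).append(e)
        by_node.setdefault(e.id_b, []).append(e)
    allowed: dict[str, set[tuple]] = {}
    for node, incident in by_node.items():
        incident.sort(key=lambda e: (-e.score, e.edge_id))
        allowed[node] = {e.edge_id for e in incident[:top_k]}
    return [
        e for e in edges if e.edge_id in allowed[e.id_a] and e.edge_id in allowed[e.id_b]
    ]


def build_network(
    table: EdgeTable,
    score_min: float = 1.0,
    p_max: float = 0.05,
    top_k: int = 10,
    max_component: int = 100,
) -> Network:
    """Molecular network with the standard topology constraints.

    1. Drop edges with score < ``score_min`` or p > ``p_max`` (a
       stricter cutoff than hit filtering).
    2. Keep an edge only if it ranks in the top ``top_k`` by score at
       *both* endpoints (mutual top-k).
    3. While a connected component exceeds ``max_component`` nodes,
       remove its lowest-scoring edge (ties broken by lexicographic
       edge id).

    Nodes of the input table survive even if all their edges are
    removed; they appear as singletons.
    """
    passing = [e for e in table.edges if e.score >= score_min and e.pvalue <= p_max]
    passing = _mutual_top_k(passing, top_k)

    graph = nx.Graph()
    graph.add_nodes_from(table.nodes)
    for e in passing:
        graph.add_edge(
            *e.edge_id,
            score=e.score,
            pvalue=e.pvalue,
            n_matched=e.n_matched,
            n_iterations=e.n_iterations,
        )

    while True:
        oversized = [
            comp for comp in nx.connected_components(graph) if len(comp) > max_component
        ]
        if not oversized:
            break
        for comp in oversized:
            sub_edges = [
                (d["score"], tuple(sorted((u, v))))
                for u, v, d in graph.subgraph(comp).edges(data=True)
            ]
            _, weakest = min(sub_edges)
            graph.remove_edge(*weakest)

    components = tuple(frozenset(c) for c in nx.connected_components(graph))
    return Network(graph=graph, components=components)


# ---------------------------------------------------------------------------
# Maximum common substructure rubric
# ---------------------------------------------------------------------------

MCS_CATEGORIES = ("not_similar", "low", "medium", "high")


@dataclass(frozen=True)
class McsSimilarity:
    """Bond-overlap Jaccard coefficient with its rubric category."""

    s: float
    category: str


def mcs_jaccard(N: int, N_A: int, N_B: int) -> float:
    """Jaccard coefficient of overlapping bonds: s = N / (N_A + N_B - N)."""
    if N_A < 1 or N_B < 1:
        raise ParameterError("bond counts N_A and N_B must be >= 1")
    if not 0 <= N <= min(N_A, N_B):
        raise ParameterError("N must satisfy 0 <= N <= min(N_A, N_B)")
    return N / ((N_A + N_B) - N)


def classify_mcs(s: float) -> str:
    """Bin a bond-Jaccard value: <0.35 not similar, 0.35–0.45 low,
    0.45–0.7 medium, >0.7 high."""
    if not 0 <= s <= 1:
        raise ParameterError("s must lie in [0, 1]")
    if s < 0.35:
        return "not_similar"
    if s < 0.45:
        return "low"
    if s <= 0.7:
        return "medium"
    return "high"


def mcs_from_structures(smiles_a: str, smiles_b: str, timeout: int = 1800) -> McsSimilarity:
    """Bond-overlap similarity of two structures via an MCS search.

    Optional helper requiring RDKit; the search runs with
    ``ringMatchesRingOnly=False`` and the given timeout (seconds).
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFMCS
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("mcs_from_structures requires the 'rdkit' extra") from exc
    mol_a = Chem.MolFromSmiles(smiles_a)
    mol_b = Chem.MolFromSmiles(smiles_b)
    if mol_a is None or mol_b is None:
        raise ParameterError("could not parse one of the SMILES strings")
    result = rdFMCS.FindMCS(
        [mol_a, mol_b], ringMatchesRingOnly=False, timeout=timeout
    )
    s = mcs_jaccard(
        result.numBonds, mol_a.GetNumBonds(), mol_b.GetNumBonds()
    )
    return McsSimilarity(s=s, category=classify_mcs(s))
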