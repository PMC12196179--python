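"""Seeded generators emulating every input the pipeline consumes.

Each generator emits its ground truth alongside the data (planted hubs,
planted terms, true 4PL parameters, quadrant weights), so downstream
recovery tests are self-contained, and derives its randomness from a
per-generator child stream of one root seed: adding a generator never
perturbs the draws of the others.

What is emulated, and what is not: PPI topology is preferential-attachment
scale-free with uniform edge confidences (real interactome confidence is
evidence-correlated); flow-cytometry clusters are gate-separated log-normal
blobs truncated at the gates (no spectral spillover or debris smear); the
alkane ladder has smoothly widening spacing as in temperature-programmed
elution, but no peak-shape information.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import child_seed
from .enrichment import AnnotationCatalog
from .exceptions import ConfigurationError, ValidationError
from .gcms import AlkaneLadder
from .invitro import CellCycleHistogram, DoseResponse, FlowEventSet

__all__ = [
    "SimulationConfig",
    "gen_ppi_network",
    "gen_target_sets",
    "TargetSets",
    "gen_annotations",
    "gen_dose_response",
    "gen_flow_events",
    "gen_cell_cycle",
    "gen_alkane_ladder",
    "gen_docking_matrix",
    "simulate_study",
    "DEFAULT_CONCENTRATIONS",
]

#: Two-fold serial dilution ladder from a 100 ug/mL stock (9 points).
DEFAULT_CONCENTRATIONS = (100.0, 50.0, 25.0, 12.5, 6.25, 3.13, 1.56, 0.78,
                          0.39)

# fixed child-seed stream indices; append-only so existing draws never move
_STREAMS = {"ppi": 1, "targets": 2, "annotations": 3, "dose": 4, "flow": 5,
            "ladder": 6, "docking": 7, "cycle": 8}


@dataclass
class SimulationConfig:
    """Study-scale simulation settings.

    Defaults mirror the emulated study design: a 19-compound oil, triplicate
    viability readings with a few percentage points of replicate noise, and
    a gene universe large enough for a non-trivial disease overlap.
    """

    seed: int = 0
    n_genes: int = 2000
    n_compounds: int = 19
    n_terms: int = 50
    noise_sd: float = 3.0
    replicate_count: int = 3

    def __post_init__(self):
        for f in ("n_genes", "n_compounds", "n_terms", "replicate_count"):
            if getattr(self, f) < 1:
                raise ConfigurationError(f"{f} must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def gen_ppi_network(n_nodes: int, attach_m: int, seed: int,
                    planted_hubs: int = 0,
                    hub_attach_frac: float = 0.4) -> nx.Graph:
    """Connected preferential-attachment PPI stand-in.

    Nodes are synthetic gene symbols; every edge carries a ``confidence``
    drawn uniformly on [0.15, 1.00] (internal [0, 1] unit; the 0-1000
    STRING dialect is an I/O concern). ``planted_hubs`` optionally wires
    that many randomly chosen nodes to ``hub_attach_frac`` of the network,
    recording them under ``graph.graph["planted_hubs"]`` as screen ground
    truth.
    """
    if not (n_nodes > attach_m >= 1):
        raise ConfigurationError("need n_nodes > attach_m >= 1")
    g = nx.barabasi_albert_graph(int(n_nodes), int(attach_m), seed=int(seed))
    g = nx.relabel_nodes(g, {i: f"G{i + 1:04d}" for i in g.nodes})
    rng = np.random.default_rng(seed)
    for u, v in g.edges:
        g[u][v]["confidence"] = float(rng.uniform(0.15, 1.0))
    hubs: tuple[str, ...] = ()
    if planted_hubs:
        if planted_hubs >= n_nodes:
            raise ConfigurationError("planted_hubs must be < n_nodes")
        nodes = sorted(g.nodes)
        hubs = tuple(sorted(
            str(h) for h in rng.choice(nodes, planted_hubs, replace=False)))
        n_attach = max(1, round(hub_attach_frac * n_nodes))
        for h in hubs:
            partners = rng.choice([v for v in nodes if v != h], n_attach,
                                  replace=False)
            for p in partners:
                p = str(p)
                if not g.has_edge(h, p):
                    g.add_edge(h, p, confidence=float(rng.uniform(0.6, 1.0)))
    g.graph["planted_hubs"] = hubs
    return g


# ---------------------------------------------------------------------------
# compound target sets with a planted disease overlap
# ---------------------------------------------------------------------------

class TargetSets(NamedTuple):
    compound_targets: dict[str, set[str]]
    disease_genes: set[str]
    core_genes: frozenset[str]


def gen_target_sets(n_compounds: int, universe: Sequence[str],
                    core_size: int, per_compound: int, disease_frac: float,
                    seed: int) -> TargetSets:
    """Per-compound target sets sharing a planted core, plus a disease set
    forced to contain the core (guaranteeing a non-trivial Venn overlap).
    """
    universe = [str(g) for g in universe]
    if not (0 < core_size <= per_compound <= len(universe)):
        raise ConfigurationError(
            "need 0 < core_size <= per_compound <= |universe|")
    if not (0.0 < disease_frac <= 1.0):
        raise ConfigurationError("disease_frac must lie in (0, 1]")
    if n_compounds < 1:
        raise ConfigurationError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)
    core = frozenset(str(g) for g in
                     rng.choice(universe, core_size, replace=False))
    rest = sorted(set(universe) - core)
    compounds = {}
    for i in range(n_compounds):
        fill = [str(g) for g in
                rng.choice(rest, per_compound - core_size, replace=False)]
        compounds[f"C{i + 1:02d}"] = set(core) | set(fill)
    disease_size = max(core_size, round(disease_frac * len(universe)))
    extra = [str(g) for g in
             rng.choice(rest, disease_size - core_size, replace=False)]
    disease = set(core) | set(extra)
    return TargetSets(compounds, disease, core)


# ---------------------------------------------------------------------------
# annotation catalogs with planted enrichment
# ---------------------------------------------------------------------------

def gen_annotations(universe: Sequence[str], n_terms: int,
                    planted: Iterable[tuple[str, Iterable[str]]] = (),
                    seed: int = 0,
                    category: str = "GENESET") -> AnnotationCatalog:
    """Annotation catalog: the planted terms verbatim plus ``n_terms``
    random terms with sizes uniform on [10, 200] (capped at the universe).
    """
    universe = [str(g) for g in universe]
    uset = set(universe)
    terms: dict[str, frozenset[str]] = {}
    for name, genes in planted:
        gset = frozenset(str(g) for g in genes)
        if not gset <= uset:
            raise ValidationError(
                f"planted term {name!r} has genes outside the universe")
        terms[str(name)] = gset
    rng = np.random.default_rng(seed)
    for i in range(int(n_terms)):
        size = int(rng.integers(10, 201))
        size = min(size, len(universe))
        terms[f"RND{i + 1:04d}"] = frozenset(
            str(g) for g in rng.choice(universe, size, replace=False))
    return AnnotationCatalog(terms=terms,
                             categories={t: category for t in terms})


# ---------------------------------------------------------------------------
# dose-response curves
# ---------------------------------------------------------------------------

def gen_dose_response(top: float = 100.0, bottom: float = 0.0,
                      hill: float = 1.5, ic50: float = 18.09,
                      concentrations: Sequence[float] | None = None,
                      noise_sd: float = 3.0, reps: int = 3, seed: int = 0,
                      cell_line: str | None = None) -> DoseResponse:
    """Replicate viabilities from a 4PL curve plus Gaussian replicate noise
    truncated at zero.

    The default design mirrors the emulated assay: nine 2-fold dilutions
    from a 100 ug/mL stock, triplicates, a sub-30 ug/mL midpoint and a few
    percentage points of plate noise.
    """
    if ic50 <= 0:
        raise ConfigurationError("ic50 must be positive")
    conc = np.asarray(DEFAULT_CONCENTRATIONS if concentrations is None
                      else concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ConfigurationError("concentrations must be positive")
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    clean = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
    noise = rng.normal(0.0, noise_sd, size=(conc.size, reps)) if noise_sd \
        else np.zeros((conc.size, reps))
    viab = np.clip(clean[:, None] + noise, 0.0, None)
    return DoseResponse(concentrations=conc, viability=viab,
                        cell_line=cell_line,
                        true_params={"top": top, "bottom": bottom,
                                     "hill": hill, "ic50": ic50,
                                     "noise_sd": noise_sd})


# ---------------------------------------------------------------------------
# flow cytometry events
# ---------------------------------------------------------------------------

_QUADRANT_CENTERS = (  # (annexin, pi) log10 cluster centers per quadrant
    (1.2, 1.2),  # viable        A-/P-
    (2.8, 1.2),  # early apopt.  A+/P-
    (2.8, 2.8),  # late apopt.   A+/P+
    (1.2, 2.8),  # necrotic      A-/P+
)


def gen_flow_events(weights: Sequence[float], n_events: int = 50_000,
                    seed: int = 0, annexin_gate: float = 2.0,
                    pi_gate: float = 2.0,
                    cluster_sd: float = 0.25) -> FlowEventSet:
    """Annexin/PI event cloud: four log-normal clusters, one per quadrant.

    ``weights`` are the (viable, early, late, necrotic) fractions and must
    sum to 1. Cluster draws are clipped a small margin inside their quadrant
    so the realized quadrant membership equals the multinomial ground truth
    exactly; quadrant recovery then measures sampling arithmetic, not gate
    placement.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != 4:
        raise ValidationError("need exactly 4 quadrant weights")
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("weights must sum to 1")
    if n_events < 1:
        raise ConfigurationError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, w)
    gates = np.array([annexin_gate, pi_gate])
    margin = 0.02
    chunks = []
    for (cx, cy), m, (a_pos, p_pos) in zip(
            _QUADRANT_CENTERS, counts,
            ((False, False), (True, False), (True, True), (False, True))):
        if m == 0:
            continue
        pts = rng.normal((cx, cy), cluster_sd, size=(m, 2))
        for col, pos in enumerate((a_pos, p_pos)):
            if pos:
                pts[:, col] = np.maximum(pts[:, col], gates[col] + margin)
            else:
                pts[:, col] = np.minimum(pts[:, col], gates[col] - margin)
        chunks.append(pts)
    events = np.concatenate(chunks, axis=0)
    events = events[rng.permutation(events.shape[0])]
    return FlowEventSet(events=events, annexin_gate=annexin_gate,
                        pi_gate=pi_gate, true_weights=tuple(w))


def gen_cell_cycle(weights: Sequence[float], n_events: int = 50_000,
                   seed: int = 0, sub_g1_frac: float = 0.0,
                   gates: tuple[float, float, float, float] = (0.6, 1.4,
                                                               1.7, 2.5),
                   ) -> CellCycleHistogram:
    """DNA-content histogram: G0/G1 (2N) peak near 1.0, an S-phase plateau,
    and a G2/M (4N) peak near 2.0, with an optional sub-G1 debris fraction.

    Draws are clipped inside their gate regions so phase membership matches
    the ground-truth weights exactly.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("need 3 non-negative phase weights summing to 1")
    if not 0.0 <= sub_g1_frac < 1.0:
        raise ValidationError("sub_g1_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3 = gates
    n_sub = int(round(sub_g1_frac * n_events))
    counts = rng.multinomial(n_events - n_sub, w)
    eps = 1e-3
    parts = [
        np.clip(rng.normal(1.0, 0.08, counts[0]), b0, b1 - eps),
        rng.uniform(b1 + eps, b2 - eps, counts[1]),
        np.clip(rng.normal(2.0, 0.08, counts[2]), b2, b3 - eps),
    ]
    if n_sub:
        parts.append(rng.uniform(b0 * 0.2, b0 - eps, n_sub))
    dna = np.concatenate(parts)
    dna = dna[rng.permutation(dna.size)]
    return CellCycleHistogram(dna_content=dna, gates=gates,
                              true_weights=tuple(w))


# ---------------------------------------------------------------------------
# alkane ladder
# ---------------------------------------------------------------------------

def gen_alkane_ladder(c_min: int = 8, c_max: int = 28,
                      seed: int = 0) -> AlkaneLadder:
    """n-alkane retention ladder with strictly increasing retention times
    and monotonically widening spacing, as under a linear temperature ramp.
    """
    if not (8 <= c_min < c_max <= 28):
        raise ConfigurationError("need 8 <= c_min < c_max <= 28")
    rng = np.random.default_rng(seed)
    carbons = list(range(int(c_min), int(c_max) + 1))
    rt = float(rng.uniform(2.0, 4.0))
    gap = float(rng.uniform(0.8, 1.2))
    rts = [rt]
    for _ in carbons[1:]:
        gap += float(rng.uniform(0.01, 0.15))
        rt += gap
        rts.append(rt)
    return AlkaneLadder(tuple(carbons), tuple(rts))


# ---------------------------------------------------------------------------
# docking matrices
# ---------------------------------------------------------------------------

def gen_docking_matrix(compounds: Sequence[str], targets: Sequence[str],
                       score_range: tuple[float, float] = (-6.9, -4.0),
                       seed: int = 0) -> pd.DataFrame:
    """Complete compound x target grid of uniform binding energies within
    ``score_range`` (kcal/mol; both endpoints negative)."""
    lo, hi = map(float, score_range)
    if not (lo < hi < 0.0):
        raise ConfigurationError(
            "score range endpoints must be negative with lower < upper")
    if not compounds or not targets:
        raise ConfigurationError("compounds and targets must be non-empty")
    rng = np.random.default_rng(seed)
    scores = rng.uniform(lo, hi, size=(len(compounds), len(targets)))
    return pd.DataFrame(scores, index=list(compounds), columns=list(targets))


# ---------------------------------------------------------------------------
# one-call study simulation
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> dict:
    """Generate one coherent synthetic study from a single root seed.

    Returns a dict with the PPI network, target sets, annotation catalog,
    dose-response data, flow events, alkane ladder and docking matrix, each
    driven by its own child seed stream.
    """
    s = config.seed
    universe = _gene_symbols(config.n_genes)
    targets = gen_target_sets(
        config.n_compounds, universe, core_size=50, per_compound=80,
        disease_frac=0.9, seed=child_seed(s, _STREAMS["targets"]))
    n_net = min(config.n_genes, 300)
    compounds = sorted(targets.compound_targets)
    return {
        "config": config,
        "ppi": gen_ppi_network(n_net, 5, seed=child_seed(s, _STREAMS["ppi"]),
                               planted_hubs=5),
        "target_sets": targets,
        "annotations": gen_annotations(
            universe, config.n_terms,
            planted=[("PLANTED0001", sorted(targets.core_genes))],
            seed=child_seed(s, _STREAMS["annotations"])),
        "dose_response": gen_dose_response(
            noise_sd=config.noise_sd, reps=config.replicate_count,
            seed=child_seed(s, _STREAMS["dose"]), cell_line="A-549"),
        "flow": gen_flow_events((0.7239, 0.1502, 0.093, 0.0329),
                                seed=child_seed(s, _STREAMS["flow"])),
        "ladder": gen_alkane_ladder(seed=child_seed(s, _STREAMS["ladder"])),
        "docking": gen_docking_matrix(
            compounds, ["ESR1", "CASP3", "PPARG", "PTGS2"],
            seed=child_seed(s, _STREAMS["docking"])),
    }
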