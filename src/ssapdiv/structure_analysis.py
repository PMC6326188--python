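"""Structural comparison of homologs: superposition, equivalent sites,
contact networks and rewiring, network proximity, and binned summaries.

Two residues are in contact when any pair of their atoms lies within 3.5 Å
under the dialect's atom filter: ``sidechain_3p5`` considers side-chain
atoms only (backbone N, Cα, C, O excluded; glycine contributes none),
``allatom_3p5`` considers every non-hydrogen atom. Per-site contact
neighborhoods of two homologs are compared through the equivalent-site
alignment; a site's rewired-contact fraction is one minus the Jaccard index
of its neighbor sets, f_r = (|G_r| + |L_r|) / (|G_r| + |L_r| + |C_r|) with
conserved (both homologs), gained (second only) and lost (first only)
contact sets.

Structural deviation between aligned homologs (sRMSD) is the arithmetic
mean of paired Cα distances — a mean of distances, not a root mean square,
despite the conventional name; it is implemented exactly as defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import entropy as _shannon_entropy

from .io_formats import AlignmentMap, PreferenceProfile, StructureModel, ValidationError

__all__ = [
    "SuperpositionResult", "ContactNetwork", "ContactComparison",
    "superpose", "srmsd", "build_contacts", "ensemble_contact_frequency",
    "compare_contacts", "sequence_divergence", "network_proximity_test",
    "divergence_binned_summary", "site_entropy",
]

logger = logging.getLogger("ssapdiv")

CONTACT_CUTOFF = 3.5
EQUIVALENCE_THRESHOLD = 3.5
_DIALECTS = ("sidechain_3p5", "allatom_3p5")


# ---------------------------------------------------------------------------
# Superposition and equivalent sites
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    """Rigid-body transform mapping structure B onto structure A, and the
    equivalent-site alignment it induces."""

    rotation: np.ndarray
    translation: np.ndarray
    paired_ca_distances: np.ndarray
    alignment: AlignmentMap

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with A ≈ B·Rᵀ + t."""
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    rot, _ = Rotation.align_vectors(A - ca, B - cb)
    R = rot.as_matrix()
    return R, ca - R @ cb


def superpose(a: StructureModel, b: StructureModel,
              seed_pairs: list[tuple[int, int]] | None = None,
              threshold: float = EQUIVALENCE_THRESHOLD,
              max_iter: int = 50) -> SuperpositionResult:
    """Iterative Kabsch superposition with mutual-nearest-neighbor re-pairing.

    Pairing starts from ``seed_pairs`` (e.g., a sequence alignment) or from
    residue order, and alternates between fitting the rigid transform on the
    current pairs and re-pairing Cα atoms that are mutual nearest neighbors
    within the equivalence threshold, until the paired set is stable. A
    pragmatic stand-in for a full structural aligner; externally produced
    alignment maps are accepted everywhere as first-class input.
    """
    ia, A = a.ca_sites()
    ib, B = b.ca_sites()
    if len(ia) < 3 or len(ib) < 3:
        raise ValidationError("superposition needs at least 3 Cα atoms per structure")
    if seed_pairs is not None:
        pos_a = {s: k for k, s in enumerate(ia)}
        pos_b = {s: k for k, s in enumerate(ib)}
        pairs = [(pos_a[sa], pos_b[sb]) for sa, sb in seed_pairs
                 if sa in pos_a and sb in pos_b]
    else:
        pairs = [(k, k) for k in range(min(len(ia), len(ib)))]
    if len(pairs) < 3:
        raise ValidationError("no significant superposition: fewer than 3 seed pairs")

    R = np.eye(3)
    t = np.zeros(3)
    for _ in range(max_iter):
        pa = np.asarray([p[0] for p in pairs])
        pb = np.asarray([p[1] for p in pairs])
        R, t = _kabsch(A[pa], B[pb])
        Bt = B @ R.T + t
        tree_a = cKDTree(A)
        tree_b = cKDTree(Bt)
        d_ab, j_ab = tree_b.query(A)      # nearest b for each a
        d_ba, j_ba = tree_a.query(Bt)     # nearest a for each b
        new_pairs = [
            (k, int(j_ab[k]))
            for k in range(len(A))
            if d_ab[k] <= threshold and j_ba[j_ab[k]] == k
        ]
        if len(new_pairs) < 3:
            raise ValidationError("no significant superposition: fewer than 3 "
                                  "equivalent Cα pairs survive")
        if new_pairs == pairs:
            break
        pairs = new_pairs

    pa = np.asarray([p[0] for p in pairs])
    pb = np.asarray([p[1] for p in pairs])
    R, t = _kabsch(A[pa], B[pb])
    dists = np.linalg.norm(A[pa] - (B[pb] @ R.T + t), axis=1)
    keep = dists <= threshold + 1e-9
    pairs_sites = [(int(ia[i]), int(ib[j]), float(d))
                   for (i, j), d, ok in zip(pairs, dists, keep) if ok]
    paired_a = {sa for sa, _, _ in pairs_sites}
    paired_b = {sb for _, sb, _ in pairs_sites}
    seq_a, seq_b = a.sequence, b.sequence
    mism = sum(1 for sa, sb, _ in pairs_sites if seq_a[sa] != seq_b[sb])
    alignment = AlignmentMap(
        pairs=pairs_sites,
        unpaired_a=[int(s) for s in ia if s not in paired_a],
        unpaired_b=[int(s) for s in ib if s not in paired_b],
        sequence_divergence=mism / len(pairs_sites) if pairs_sites else None,
        coverage_a=len(pairs_sites) / len(ia),
        coverage_b=len(pairs_sites) / len(ib),
        threshold=threshold,
    ).validate()
    return SuperpositionResult(R, t, np.asarray([d for _, _, d in pairs_sites]),
                               alignment)


def srmsd(alignment: AlignmentMap) -> float:
    """Mean Cα distance (Å) over equivalent-site pairs."""
    if not alignment.pairs:
        raise ValidationError("empty alignment: sRMSD undefined")
    return float(alignment.distances().mean())


def sequence_divergence(alignment: AlignmentMap, seq_a: str, seq_b: str) -> float:
    """Fraction of equivalent-site pairs whose amino acids differ."""
    if not alignment.pairs:
        raise ValidationError("empty alignment: divergence undefined")
    mism = sum(1 for sa, sb, _ in alignment.pairs if seq_a[sa] != seq_b[sb])
    return mism / alignment.n_pairs


# ---------------------------------------------------------------------------
# Contact networks
# ---------------------------------------------------------------------------


@dataclass
class ContactNetwork:
    """Undirected residue contact graph; ``edges`` maps sorted site pairs to
    the ensemble contact frequency E (1.0 for a single structure)."""

    nodes: set[int]
    edges: dict[tuple[int, int], float]
    dialect: str
    from_ensemble: bool = False

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, site: int) -> set[int]:
        out = set()
        for (i, j) in self.edges:
            if i == site:
                out.add(j)
            elif j == site:
                out.add(i)
        return out

    def neighbor_map(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {n: set() for n in self.nodes}
        for (i, j) in self.edges:
            out[i].add(j)
            out[j].add(i)
        return out

    def validate(self) -> "ContactNetwork":
        for (i, j), e in self.edges.items():
            if i == j:
                raise ValidationError(f"self-edge at site {i}")
            if (i, j) != tuple(sorted((i, j))):
                raise ValidationError(f"edge ({i}, {j}) not in sorted order")
            if not 0.0 <= e <= 1.0:
                raise ValidationError(f"edge ({i}, {j}): E={e} outside [0, 1]")
        return self


def build_contacts(s: StructureModel, dialect: str = "sidechain_3p5",
                   cutoff: float = CONTACT_CUTOFF,
                   exclude_sequential: bool = False) -> ContactNetwork:
    """Contact network of a structure under the named dialect.

    An edge joins residues i ≠ j when their minimal interatomic distance
    under the dialect's atom filter is ≤ ``cutoff``. Sequential |i−j| = 1
    neighbors are included by default; set ``exclude_sequential`` to drop
    them (a common contact-map convention).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}")
    sidechain = dialect == "sidechain_3p5"
    coords = []
    owner = []
    for i, res in enumerate(s.residues):
        xyz = res.atom_coords(sidechain_only=sidechain)
        coords.append(xyz)
        owner.extend([i] * len(xyz))
    nodes = set(range(len(s.residues)))
    if not owner:
        return ContactNetwork(nodes, {}, dialect)
    pts = np.concatenate([c for c in coords if len(c)])
    owner = np.asarray(owner)
    tree = cKDTree(pts)
    edges: dict[tuple[int, int], float] = {}
    for ai, aj in tree.query_pairs(cutoff):
        i, j = int(owner[ai]), int(owner[aj])
        if i == j:
            continue
        if exclude_sequential and abs(i - j) <= 1:
            continue
        edges[(min(i, j), max(i, j))] = 1.0
    return ContactNetwork(nodes, edges, dialect).validate()


def ensemble_contact_frequency(models: list[StructureModel],
                               dialect: str = "sidechain_3p5",
                               cutoff: float = CONTACT_CUTOFF,
                               exclude_sequential: bool = False) -> ContactNetwork:
    """Contact frequency E(i, j) = fraction of models containing edge (i, j);
    edges with E > 0 are retained."""
    if not models:
        raise ValidationError("ensemble needs at least one model")
    ref = [(r.number, r.insertion_code) for r in models[0].residues]
    for m in models[1:]:
        if [(r.number, r.insertion_code) for r in m.residues] != ref:
            raise ValidationError("inconsistent residue numbering across models")
    counts: dict[tuple[int, int], int] = {}
    for m in models:
        net = build_contacts(m, dialect, cutoff, exclude_sequential)
        for e in net.edges:
            counts[e] = counts.get(e, 0) + 1
    edges = {e: c / len(models) for e, c in counts.items()}
    return ContactNetwork(set(range(len(ref))), edges, dialect,
                          from_ensemble=len(models) > 1).validate()


# ---------------------------------------------------------------------------
# Contact rewiring between homologs
# ---------------------------------------------------------------------------


@dataclass
class SiteContacts:
    """Per-site contact comparison: conserved/gained/lost neighbor sets in
    the common (site_a-indexed) label space, f_r and the site class."""

    site_pair: tuple[int, int]
    conserved: frozenset
    gained: frozenset
    lost: frozenset
    f_r: float | None
    site_class: str  # "substituted" | "conserved_aa"


@dataclass
class ContactComparison:
    per_site: list[SiteContacts]
    totals: tuple[int, int, int]  # (G, L, C) summed over sites

    @property
    def pooled_rewired_fraction(self) -> float:
        g, l, c = self.totals
        if g + l + c == 0:
            raise ValidationError("no contacts to compare")
        return (g + l) / (g + l + c)


def compare_contacts(net_a: ContactNetwork, net_b: ContactNetwork,
                     alignment: AlignmentMap, seq_a: str, seq_b: str,
                     unaligned: str = "count") -> ContactComparison:
    """Classify each aligned site's contacts as conserved, gained or lost.

    Neighbor sets of the two homologs are mapped into a common label space
    through the alignment. A contact to an unaligned site has no image in
    the other homolog; with ``unaligned="count"`` (default) it is counted as
    lost/gained, with ``"ignore"`` it is dropped.
    """
    if not alignment.pairs:
        raise ValidationError("empty alignment: nothing to compare")
    if unaligned not in ("count", "ignore"):
        raise ValueError("unaligned must be 'count' or 'ignore'")
    a2b = alignment.a_to_b()
    b2a = alignment.b_to_a()
    nbr_a = net_a.neighbor_map()
    nbr_b = net_b.neighbor_map()
    per_site: list[SiteContacts] = []
    G = L = C = 0
    for sa, sb, _d in alignment.pairs:
        ha: set = set()
        for n in nbr_a.get(sa, ()):  # labels live in site_a space
            if n in a2b:
                ha.add(n)
            elif unaligned == "count":
                ha.add(("a", n))
        hb: set = set()
        for n in nbr_b.get(sb, ()):
            if n in b2a:
                hb.add(b2a[n])
            elif unaligned == "count":
                hb.add(("b", n))
        conserved = ha & hb
        lost = ha - hb
        gained = hb - ha
        denom = len(conserved) + len(lost) + len(gained)
        f_r = (len(gained) + len(lost)) / denom if denom else None
        per_site.append(SiteContacts(
            (sa, sb), frozenset(conserved), frozenset(gained), frozenset(lost),
            f_r, "substituted" if seq_a[sa] != seq_b[sb] else "conserved_aa"))
        G += len(gained)
        L += len(lost)
        C += len(conserved)
    return ContactComparison(per_site, (G, L, C))


# ---------------------------------------------------------------------------
# Network proximity test
# ---------------------------------------------------------------------------


def _to_graph(net: ContactNetwork, weighted: bool) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for (i, j), e in net.edges.items():
        g.add_edge(i, j, weight=(1.0 - e) if weighted else 1.0)
    return g


def network_proximity_test(net: ContactNetwork, query_sites, anchor_sites,
                           n_random: int = 1000, rng=None,
                           weighted: bool = False):
    """Are the query sites closer to the anchors than random site sets?

    The observed statistic is the mean, over query sites, of the shortest-path
    distance (Dijkstra; unweighted hops by default, 1−E edge weights
    optionally) to the nearest anchor. The null draws ``n_random`` site sets
    of equal size uniformly from non-anchor nodes; the empirical p-value is
    (#null ≤ observed + 1) / (n_random + 1). Returns
    (observed, null distribution, p).
    """
    query = sorted(set(query_sites))
    anchors = sorted(set(anchor_sites))
    if not query or not anchors:
        raise ValidationError("query and anchor sets must be non-empty")
    if len(query) + len(anchors) > len(net.nodes):
        raise ValidationError("query and anchor sets exceed the node count")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    g = _to_graph(net, weighted)
    dist = nx.multi_source_dijkstra_path_length(g, anchors, weight="weight")

    def stat(sites) -> float:
        vals = [dist[s] for s in sites if s in dist]
        if len(vals) < len(sites):
            logger.warning("%d of %d sites unreachable from anchors; excluded",
                           len(sites) - len(vals), len(sites))
        if not vals:
            raise ValidationError("no query site is reachable from the anchors")
        return float(np.mean(vals))

    observed = stat(query)
    candidates = np.asarray(sorted(set(net.nodes) - set(anchors)))
    null = np.empty(n_random)
    for k in range(n_random):
        null[k] = stat(gen.choice(candidates, size=len(query), replace=False))
    p = (np.count_nonzero(null <= observed) + 1) / (n_random + 1)
    return observed, null, float(p)


# ---------------------------------------------------------------------------
# Binned summaries and entropy
# ---------------------------------------------------------------------------


def divergence_binned_summary(records, bins=None, n_boot: int = 10000,
                              rng=None) -> pd.DataFrame:
    """Per-bin mean with 95% percentile-bootstrap confidence intervals.

    ``records`` is an iterable of (divergence, value) pairs; ``bins`` are
    edges over the divergence axis (default width 0.1 over [0, 1]). Empty
    bins are reported with n=0 and NaN statistics, not raised.
    """
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    bins = np.asarray(bins, dtype=float)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    recs = np.asarray(list(records), dtype=float).reshape(-1, 2)
    out = []
    for k in range(len(bins) - 1):
        lo, hi = bins[k], bins[k + 1]
        last = k == len(bins) - 2
        mask = (recs[:, 0] >= lo) & ((recs[:, 0] <= hi) if last else (recs[:, 0] < hi))
        vals = recs[mask, 1]
        if vals.size == 0:
            out.append((lo, hi, 0, math.nan, math.nan, math.nan))
            continue
        mean = float(vals.mean())
        if vals.size == 1:
            out.append((lo, hi, 1, mean, mean, mean))
            continue
        idx = gen.integers(0, vals.size, size=(n_boot, vals.size))
        boots = vals[idx].mean(axis=1)
        ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5])
        out.append((lo, hi, int(vals.size), mean, float(ci_lo), float(ci_hi)))
    return pd.DataFrame(out, columns=["bin_lo", "bin_hi", "n", "mean",
                                      "ci_lo", "ci_hi"])


def site_entropy(profile: PreferenceProfile) -> np.ndarray:
    """Per-site Shannon entropy (bits) of the preference rows; 0 for a point
    mass, log2(20) ≈ 4.32 for a uniform site."""
    profile.validate()
    return _shannon_entropy(profile.values, base=2, axis=1)
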