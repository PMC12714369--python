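"""Synthetic networks, expression, DEG tables and ortholog maps with
known ground truth.

The generators emulate the study design the package targets: a
hub-skewed TF->promoter network in which some TFs are themselves
targetable (dual nodes, so feed-forward loops can arise), a two-tissue
nitrogen deprivation/recovery TPM time course (time points 0, 0.5, 3,
24 h of deprivation and 24.5, 48 h after resupply; three replicates),
DEG tables consistent with the padj/log2FC thresholds, and ortholog
maps with a controlled conserved-edge fraction.

Expression is generated from a linear latent cascade: every gene has a
smooth intrinsic time course; a regulated gene's profile is the
variance-normalized signed sum of its regulators' profiles plus a small
intrinsic component, mapped affinely to a non-negative TPM scale with
i.i.d. replicate noise. Under this model an edge's planted sign is
recoverable from the Gini correlation whenever the regulator carries a
dominant share of the target's variance; signs drawn from node
potentials ("consistent" mode) make every feed-forward loop coherent
and hence fully recoverable, while i.i.d. signs ("iid" mode) also
produce incoherent loops whose direct and indirect contributions
partially cancel (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .expression import ExpressionMatrix
from .ffl import classify_ffl, enumerate_ffls
from .network import RegulatoryNetwork
from .orthology import OrthologMap, OrthologPair

DEFAULT_FAMILIES = ("AP2-EREBP", "bZIP", "MYB", "NAC", "WRKY", "C3H", "other")
DEFAULT_TISSUES = ("leaf", "root")
DEFAULT_TIME_POINTS = (0.0, 0.5, 3.0, 24.0, 24.5, 48.0)
DEFAULT_REPLICATES = 3

# latent-model constants: share of a regulated gene's profile coming from
# its (variance-normalized) regulator sum vs its own intrinsic course
REGULATION_WEIGHT = 1.0
INTRINSIC_WEIGHT = 0.3
CASCADE_ITERATIONS = 4


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic fixture set."""

    planted_edge_signs: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_ffls: list[tuple[tuple[str, str, str], str]] = field(default_factory=list)
    planted_conserved_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_clusters: dict[str, int] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_edge_signs": {f"{t}->{p}": s for (t, p), s in self.planted_edge_signs.items()},
            "planted_ffls": [
                {"tf1": t[0], "tf2": t[1], "target": t[2], "ffl_type": typ}
                for t, typ in self.planted_ffls
            ],
            "planted_conserved_edges": sorted(f"{t}->{p}" for t, p in self.planted_conserved_edges),
            "planted_clusters": self.planted_clusters,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "params": self.params,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _family_probabilities(n_families: int, skew: float) -> np.ndarray:
    w = skew ** np.arange(n_families)
    return w / w.sum()


def generate_network(
    n_tfs: int = 100,
    n_promoters: int = 70,
    n_dual_nodes: int = 15,
    mean_outdegree: float = 5.0,
    hub_fraction: float = 0.1,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    seed: int = 0,
    sign_mode: str = "iid",
    frac_negative: float = 0.4,
    family_skew: float = 0.6,
    n_planted_ffls: int = 0,
    name: str = "synthetic",
) -> tuple[RegulatoryNetwork, SyntheticTruth]:
    """Hub-skewed TF->promoter network with planted edge signs.

    ``n_dual_nodes`` of the TFs also appear as promoters (targetable),
    making feed-forward loops possible. A ``hub_fraction`` of TFs draw
    their outdegree from a Poisson with 5x the mean (heavy tail); the
    remainder get a low-variance draw keeping the overall mean at
    ``mean_outdegree``. Signs: "iid" draws each edge independently
    (negative with ``frac_negative``); "consistent" derives the sign
    from random node potentials, sign(u->v) = potential(u)*potential(v),
    which makes every FFL coherent while all four coherent types occur.

    ``n_planted_ffls`` additionally plants that many explicit loop
    triples (tf1 -> tf2 -> target plus the direct edge) on dual nodes
    and promoters that carry no other incoming edges, so the planted
    loops keep the low target indegree that makes their signs
    recoverable from co-expression.
    """
    if n_tfs < 1 or n_promoters < 1:
        raise DomainError("n_tfs and n_promoters must be >= 1")
    if not (0 <= n_dual_nodes <= n_tfs):
        raise DomainError("n_dual_nodes must lie in [0, n_tfs]")
    if not (0.0 <= hub_fraction <= 1.0):
        raise DomainError("hub_fraction must lie in [0, 1]")
    pool_size = n_promoters + n_dual_nodes
    if mean_outdegree > pool_size:
        raise DomainError(
            f"mean_outdegree {mean_outdegree} exceeds the promoter pool ({pool_size})"
        )
    if sign_mode not in ("iid", "consistent"):
        raise DomainError(f"unknown sign_mode {sign_mode!r}")

    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_tfs)))
    tf_ids = [f"TF{i + 1:0{width}d}" for i in range(n_tfs)]
    prom_ids = [f"P{i + 1:0{width}d}" for i in range(n_promoters)]
    dual_ids = list(rng.choice(tf_ids, size=n_dual_nodes, replace=False))
    target_pool = prom_ids + dual_ids

    fam_probs = _family_probabilities(len(families), family_skew)
    fam_of = {
        t: families[i]
        for t, i in zip(tf_ids, rng.choice(len(families), size=n_tfs, p=fam_probs))
    }

    n_hubs = int(round(hub_fraction * n_tfs))
    hub_set = set(rng.choice(tf_ids, size=n_hubs, replace=False)) if n_hubs else set()
    if n_tfs > n_hubs:
        lam_rest = max(
            0.2, mean_outdegree * (n_tfs - 5.0 * n_hubs) / (n_tfs - n_hubs)
        )
    else:
        lam_rest = mean_outdegree

    net = RegulatoryNetwork(name=name, species="speciesA")
    truth = SyntheticTruth(seed=seed)
    truth.params = {
        "n_tfs": n_tfs,
        "n_promoters": n_promoters,
        "n_dual_nodes": n_dual_nodes,
        "mean_outdegree": mean_outdegree,
        "hub_fraction": hub_fraction,
        "sign_mode": sign_mode,
        "frac_negative": frac_negative,
    }
    potential = {g: int(s) for g, s in zip(
        tf_ids + prom_ids, rng.choice([-1, 1], size=n_tfs + n_promoters)
    )}

    for tf in tf_ids:
        if tf in hub_set:
            k = rng.poisson(5.0 * mean_outdegree)
        else:
            # low-variance draw: floor + Bernoulli(fractional part)
            base = int(np.floor(lam_rest))
            k = base + int(rng.random() < (lam_rest - base))
        k = int(np.clip(k, 1, pool_size))
        candidates = [p for p in target_pool if p != tf]
        targets = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
        for prom in targets:
            net.add_edge(tf, str(prom))
            if sign_mode == "consistent":
                s = "+" if potential[tf] * potential[str(prom)] > 0 else "-"
            else:
                s = "-" if rng.random() < frac_negative else "+"
            truth.planted_edge_signs[(tf, str(prom))] = s

    if n_planted_ffls:
        inn = net.in_neighbors()

        def sign_for(u: str, v: str) -> str:
            if sign_mode == "consistent":
                return "+" if potential[u] * potential[v] > 0 else "-"
            return "-" if rng.random() < frac_negative else "+"

        clean_duals = [d for d in dual_ids if d not in inn]
        clean_proms = [p for p in prom_ids if p not in inn]
        rng.shuffle(clean_duals)
        rng.shuffle(clean_proms)
        planted = 0
        while planted < n_planted_ffls and clean_duals and clean_proms:
            tf2 = clean_duals.pop()
            target = clean_proms.pop()
            others = [t for t in tf_ids if t not in (tf2, target)]
            tf1 = others[rng.integers(len(others))]
            for u, v in ((tf1, tf2), (tf1, target), (tf2, target)):
                if net.add_edge(u, v):
                    truth.planted_edge_signs[(u, v)] = sign_for(u, v)
            planted += 1
        if planted < n_planted_ffls:
            raise DomainError(
                f"could only plant {planted} of {n_planted_ffls} FFLs; "
                "increase n_promoters/n_dual_nodes or lower mean_outdegree"
            )

    for tf in tf_ids:
        net.ensure_node(tf, "TF")
        net.nodes[tf].family = fam_of[tf]
    processes = ("Nitrogen transporter", "Nitrate assimilation",
                 "Carbon metabolism", "Amino acid metabolism", "Auxin signaling")
    for i, prom in enumerate(prom_ids):
        if prom in net.nodes:
            net.nodes[prom].process = processes[i % len(processes)]

    for inst in enumerate_ffls(net):
        signs = (
            truth.planted_edge_signs[(inst.tf1, inst.tf2)],
            truth.planted_edge_signs[(inst.tf2, inst.target)],
            truth.planted_edge_signs[(inst.tf1, inst.target)],
        )
        truth.planted_ffls.append((inst.triple, classify_ffl(signs)))

    net.validate()
    return net, truth


def _smooth_curve(rng: np.random.Generator, n_points: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n_points)
    a1, a2 = rng.uniform(0.5, 1.0), rng.uniform(0.2, 0.6)
    f1, f2 = rng.uniform(0.5, 1.5), rng.uniform(1.5, 2.5)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    trend = rng.normal(0.0, 1.0)
    return a1 * np.sin(2 * np.pi * f1 * u + p1) + a2 * np.sin(2 * np.pi * f2 * u + p2) + trend * u


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def generate_expression(
    net: RegulatoryNetwork,
    truth: SyntheticTruth,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS,
    n_replicates: int = DEFAULT_REPLICATES,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> ExpressionMatrix:
    """TPM-like time-course expression realizing the planted edge signs.

    Every gene receives a smooth intrinsic latent course per tissue; a
    regulated gene's latent profile is iteratively rebuilt as
    standardize(sum_e sign_e * x_regulator / sqrt(k) + 0.3 * intrinsic),
    which propagates regulation through TF->TF chains. Replicates add
    i.i.d. Gaussian noise of sd ``noise_sigma`` (latent units, profiles
    have unit variance) before an affine map onto a positive TPM scale;
    negative values are clipped at zero and the clipped fraction is
    recorded on the returned matrix (attribute ``clipped_fraction``).
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_t = len(time_points)
    n_cond = len(tissues) * n_t
    genes = sorted(net.nodes)

    intrinsic = {
        g: _standardize(
            np.concatenate([_smooth_curve(rng, n_t) for _ in tissues])
        )
        for g in genes
    }
    regulators: dict[str, list[tuple[str, float]]] = {}
    for (tf, prom), s in sorted(truth.planted_edge_signs.items()):
        regulators.setdefault(prom, []).append((tf, 1.0 if s == "+" else -1.0))
    # edges without planted signs (e.g. hand-built networks) act as activation
    for e in net.edges:
        if (e.tf_id, e.promoter_id) not in truth.planted_edge_signs:
            regulators.setdefault(e.promoter_id, []).append((e.tf_id, 1.0))

    latent = {g: intrinsic[g].copy() for g in genes}
    for _ in range(CASCADE_ITERATIONS):
        prev = latent
        latent = {}
        for g in genes:
            regs = regulators.get(g)
            if not regs:
                latent[g] = prev[g]
                continue
            combo = np.zeros(n_cond)
            for tf, s in regs:
                combo += s * prev[tf]
            combo = _standardize(combo / np.sqrt(len(regs)))
            latent[g] = _standardize(
                REGULATION_WEIGHT * combo + INTRINSIC_WEIGHT * intrinsic[g]
            )

    sample_ids, meta_rows = [], []
    for tissue in tissues:
        for t in time_points:
            for r in range(1, n_replicates + 1):
                sid = f"{tissue}_t{t:g}_r{r}"
                sample_ids.append(sid)
                phase = "baseline" if t == 0 else ("deprivation" if t <= 24 else "recovery")
                meta_rows.append(
                    {"sample_id": sid, "tissue": tissue, "phase": phase,
                     "time_h": t, "replicate": r}
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    n_samples = len(sample_ids)
    mat = np.empty((len(genes), n_samples))
    clipped = 0
    for gi, g in enumerate(genes):
        base = rng.uniform(5.0, 50.0)
        amp = base / 3.5
        row = np.empty(n_samples)
        si = 0
        for ti_tissue in range(len(tissues)):
            for ti in range(n_t):
                x = latent[g][ti_tissue * n_t + ti]
                for _ in range(n_replicates):
                    row[si] = base + amp * (x + rng.normal(0.0, noise_sigma))
                    si += 1
        neg = row < 0
        clipped += int(neg.sum())
        row[neg] = 0.0
        mat[gi] = row

    values = pd.DataFrame(mat, index=genes, columns=sample_ids)
    expr = ExpressionMatrix(values, meta)
    expr.clipped_fraction = clipped / mat.size  # type: ignore[attr-defined]
    truth.noise_sigma = noise_sigma
    return expr


def generate_deg_table(
    net: RegulatoryNetwork,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS[1:],
    frac_up: float = 0.15,
    frac_down: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """DEG records per (gene, tissue, time) at the requested up/down rates.

    Values are drawn consistent with the strict status thresholds:
    up means log2FC ~ U(1.1, 4) with padj ~ U(0, 0.049), down is the
    mirror image, and not_de genes get either a non-significant padj or
    a sub-threshold fold change.
    """
    if frac_up + frac_down > 1:
        raise DomainError("frac_up + frac_down must be <= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for tissue in tissues:
        for t in time_points:
            for g in sorted(net.nodes):
                u = rng.random()
                phase = "deprivation" if t <= 24 else "recovery"
                if u < frac_up:
                    log2fc = rng.uniform(1.1, 4.0)
                    padj = rng.uniform(0.0, 0.049)
                elif u < frac_up + frac_down:
                    log2fc = rng.uniform(-4.0, -1.1)
                    padj = rng.uniform(0.0, 0.049)
                else:
                    if rng.random() < 0.5:
                        log2fc = rng.uniform(-4.0, 4.0)
                        padj = rng.uniform(0.05, 1.0)
                    else:
                        log2fc = rng.uniform(-0.9, 0.9)
                        padj = rng.uniform(0.0, 1.0)
                rows.append(
                    {"gene_id": g, "tissue": tissue, "time_h": t, "phase": phase,
                     "log2fc": log2fc, "padj": padj}
                )
    return pd.DataFrame(rows)


def generate_ortholog_pair(
    net_a: RegulatoryNetwork,
    conservation_fraction: float = 0.3,
    one2many_rate: float = 0.1,
    noise_edge_rate: float = 0.3,
    seed: int = 0,
    species_b: str = "speciesB",
) -> tuple[RegulatoryNetwork, OrthologMap, SyntheticTruth]:
    """A partner network and ortholog map with a planted conserved fraction.

    Every node of ``net_a`` gets one species-B ortholog (two at
    ``one2many_rate``); a ``conservation_fraction`` of A edges is copied
    into B through the map, and ``noise_edge_rate`` * |E_A| extra
    B-only edges are added, rejecting any that would back-translate to
    an A edge (so the planted conserved set stays exact).
    """
    for v, nm in ((conservation_fraction, "conservation_fraction"),
                  (one2many_rate, "one2many_rate")):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"{nm} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs: list[OrthologPair] = []
    first_b: dict[str, str] = {}
    for i, g in enumerate(sorted(net_a.nodes)):
        b1 = f"Sb{i + 1:05d}a"
        first_b[g] = b1
        pairs.append(OrthologPair(g, b1, "one2one", True))
        if rng.random() < one2many_rate:
            pairs.append(OrthologPair(g, f"Sb{i + 1:05d}b", "one2many", rng.random() < 0.7))

    omap = OrthologMap(pairs, species_a=net_a.species or "speciesA", species_b=species_b)
    net_b = RegulatoryNetwork(name=f"{net_a.name}_partner", species=species_b)
    for p in pairs:
        role = net_a.nodes[p.gene_a].role
        net_b.ensure_node(p.gene_b, role)
        net_b.nodes[p.gene_b].role = role

    edges_a = [(e.tf_id, e.promoter_id) for e in net_a.edges]
    n_cons = int(round(conservation_fraction * len(edges_a)))
    idx = rng.choice(len(edges_a), size=n_cons, replace=False) if n_cons else []
    truth = SyntheticTruth(seed=seed, params={
        "conservation_fraction": conservation_fraction,
        "one2many_rate": one2many_rate,
        "noise_edge_rate": noise_edge_rate,
    })
    for i in idx:
        tf, prom = edges_a[i]
        net_b.add_edge(first_b[tf], first_b[prom])
        truth.planted_conserved_edges.add((tf, prom))

    a_edge_set = net_a.edge_pairs
    tf_pool = sorted(n.node_id for n in net_b.nodes.values() if n.is_tf)
    prom_pool = sorted(n.node_id for n in net_b.nodes.values() if n.is_promoter)
    n_noise = int(round(noise_edge_rate * len(edges_a)))
    attempts = 0
    added = 0
    while added < n_noise and attempts < 50 * max(1, n_noise):
        attempts += 1
        tb = tf_pool[rng.integers(len(tf_pool))]
        pb = prom_pool[rng.integers(len(prom_pool))]
        if tb == pb or net_b.has_edge(tb, pb):
            continue
        back = [
            (ta, pa)
            for ta in omap.orthologs_of_b(tb)
            for pa in omap.orthologs_of_b(pb)
        ]
        if any(bp in a_edge_set for bp in back):
            continue
        net_b.add_edge(tb, pb)
        added += 1
    net_b.validate()
    return net_b, omap, truth


@dataclass
class FixtureSet:
    network: RegulatoryNetwork
    truth: SyntheticTruth
    expression: ExpressionMatrix
    degs: pd.DataFrame
    partner_network: RegulatoryNetwork
    ortholog_map: OrthologMap
    ortholog_truth: SyntheticTruth


def generate_fixture_set(seed: int = 0, **network_kwargs) -> FixtureSet:
    """One coherent set of synthetic inputs for every pipeline stage."""
    net, truth = generate_network(seed=seed, **network_kwargs)
    expr = generate_expression(net, truth, seed=seed + 1)
    degs = generate_deg_table(net, seed=seed + 2)
    net_b, omap, otruth = generate_ortholog_pair(net, seed=seed + 3)
    return FixtureSet(net, truth, expr, degs, net_b, omap, otruth)
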