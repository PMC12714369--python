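"""TF-family over-representation by expected outdegree and chi-square.

For a family with ``m`` members among ``N`` TFs in a network carrying
``T`` edges, the expected outdegree is E = m/N * T. The observed family
outdegree O is compared to E with a two-cell goodness-of-fit statistic
(family vs all other TFs):

    chi2 = (O - E)^2 / E + ((T - O) - (T - E))^2 / (T - E)

evaluated against the chi-square distribution with one degree of
freedom. The two-cell construction keeps O and its complement on the
same footing and is the df = 1 test for a single category against the
rest of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError
from .network import RegulatoryNetwork, degree_table

UNASSIGNED_FAMILY = "unassigned"


@dataclass
class FamilyEnrichmentResult:
    family: str
    members: int
    observed_outdegree: int
    expected_outdegree: float
    chi_square: float
    p_value: float
    significant: bool
    p_bh: float = float("nan")


def expected_outdegree(members: int, total_tfs: int, total_edges: int) -> float:
    """Expected number of outgoing edges for a family of ``members`` TFs."""
    if total_tfs <= 0:
        raise DomainError("total_tfs must be positive")
    if not (0 <= members <= total_tfs):
        raise DomainError("members must lie in [0, total_tfs]")
    if total_edges < 0:
        raise DomainError("total_edges must be >= 0")
    return members * total_edges / total_tfs


def family_chi_square(
    observed: float, expected: float, total_edges: int
) -> tuple[float, float]:
    """Two-cell chi-square (family vs rest) with df = 1.

    Returns (chi_square, upper-tail p-value).
    """
    if not (0 < expected < total_edges):
        raise DomainError("expected must lie strictly between 0 and total_edges")
    if not (0 <= observed <= total_edges):
        raise DomainError("observed must lie in [0, total_edges]")
    rest_obs = total_edges - observed
    rest_exp = total_edges - expected
    chi2 = (observed - expected) ** 2 / expected + (rest_obs - rest_exp) ** 2 / rest_exp
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def family_enrichment_table(
    net: RegulatoryNetwork, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-family enrichment, sorted by ascending p-value.

    TFs without a family label are pooled into "unassigned". The
    significance flag uses the raw p-value against ``alpha``; a
    Benjamini-Hochberg adjusted column is reported alongside for
    reference but does not drive the flag.
    """
    total_edges = net.n_edges
    if total_edges == 0:
        return pd.DataFrame(
            columns=[
                "family", "members", "observed", "expected",
                "chi_square", "p_value", "p_bh", "significant",
            ]
        )
    deg = degree_table(net).set_index("node_id")
    tf_nodes = [net.nodes[t] for t in net.tf_ids]
    total_tfs = len(tf_nodes)
    fam_members: dict[str, int] = {}
    fam_obs: dict[str, int] = {}
    for node in tf_nodes:
        fam = node.family or UNASSIGNED_FAMILY
        fam_members[fam] = fam_members.get(fam, 0) + 1
        fam_obs[fam] = fam_obs.get(fam, 0) + int(deg.loc[node.node_id, "outdegree"])

    rows = []
    for fam in sorted(fam_members):
        m = fam_members[fam]
        obs = fam_obs[fam]
        exp = expected_outdegree(m, total_tfs, total_edges)
        if 0 < exp < total_edges:
            chi2, p = family_chi_square(obs, exp, total_edges)
        else:
            # family spans the whole network: no complement cell to test
            chi2, p = 0.0, 1.0
        rows.append(
            {
                "family": fam,
                "members": m,
                "observed": obs,
                "expected": exp,
                "chi_square": chi2,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["p_value"] < alpha
    df = df.sort_values(["p_value", "family"], kind="stable").reset_index(drop=True)
    return df
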