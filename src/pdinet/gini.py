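"""Gini correlation between TF and target expression; edge polarity calls.

The Gini correlation coefficient (GCC) is an asymmetric rank-weighted
correlation: the covariance of one variable's values with the other
variable's ranks, normalized by the same-variable version. For samples
(x_i, y_i), i = 1..n,

    GCC(x; y) = sum_i (2i - n - 1) x_{pi_y(i)}  /  sum_i (2i - n - 1) x_{pi_x(i)}

where pi_y orders samples by ascending y (ties broken by original
sample index) and pi_x by ascending x. GCC is invariant under strictly
increasing transforms of the ranking variable y and under positive
affine transforms of x, which makes it robust for non-normal expression
data.

Edges whose GCC exceeds +0.5 are called activating, below -0.5
repressing; everything else is undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, UndefinedValueError
from .expression import ExpressionMatrix
from .network import RegulatoryNetwork

DEFAULT_GCC_THRESHOLD = 0.5

POLARITY_ACTIVATING = "activating"
POLARITY_REPRESSING = "repressing"
POLARITY_UNDETERMINED = "undetermined"


def _stable_order(v: np.ndarray) -> np.ndarray:
    # ascending values, ties by ascending original index
    return np.argsort(v, kind="stable")


def gini_correlation(x, y) -> float:
    """GCC(x; y): x values weighted by the rank order of y.

    Requires equal lengths n >= 3 and non-constant x (the denominator
    is zero otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        raise DomainError("need at least 3 samples")
    w = 2 * np.arange(1, n + 1) - n - 1
    den = float(w @ x[_stable_order(x)])
    if den == 0.0:
        raise UndefinedValueError("x is constant; GCC undefined")
    num = float(w @ x[_stable_order(y)])
    return num / den


@dataclass
class SignedEdge:
    """A PDI edge with per-context Gini correlation and polarity."""

    tf_id: str
    promoter_id: str
    context: str
    gcc_tf_ranks: float = float("nan")  # GCC(target values; TF ranks)
    gcc_target_ranks: float = float("nan")  # GCC(TF values; target ranks)
    gcc: float = float("nan")
    polarity: str = POLARITY_UNDETERMINED
    reason: str = ""


@dataclass
class SignedNetwork:
    base: RegulatoryNetwork
    threshold: float = DEFAULT_GCC_THRESHOLD
    signed_edges: dict[str, list[SignedEdge]] = field(default_factory=dict)

    def edges_for(self, context: str) -> list[SignedEdge]:
        if context not in self.signed_edges:
            raise DomainError(f"context {context!r} not in signed network")
        return self.signed_edges[context]

    def polarity_lookup(self, context: str) -> dict[tuple[str, str], SignedEdge]:
        return {(e.tf_id, e.promoter_id): e for e in self.edges_for(context)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tf": e.tf_id,
                "promoter": e.promoter_id,
                "context": e.context,
                "gcc_tf_ranks": e.gcc_tf_ranks,
                "gcc_target_ranks": e.gcc_target_ranks,
                "gcc": e.gcc,
                "polarity": e.polarity,
                "reason": e.reason,
            }
            for ctx in sorted(self.signed_edges)
            for e in self.signed_edges[ctx]
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "tf", "promoter", "context", "gcc_tf_ranks",
                "gcc_target_ranks", "gcc", "polarity", "reason",
            ],
        )


def _polarity(gcc: float, threshold: float) -> str:
    if gcc > threshold:
        return POLARITY_ACTIVATING
    if gcc < -threshold:
        return POLARITY_REPRESSING
    return POLARITY_UNDETERMINED


def sign_edges(
    net: RegulatoryNetwork,
    expr: ExpressionMatrix,
    context: str,
    threshold: float = DEFAULT_GCC_THRESHOLD,
    snet: SignedNetwork | None = None,
) -> SignedNetwork:
    """Assign activating/repressing polarity to every edge for one tissue.

    Both GCC directions are computed over all in-context samples (every
    phase, time and replicate); the polarity-determining value is the
    direction with the larger absolute value, ties favoring the
    TF-ranks direction. Edges with a missing or constant gene get
    polarity "undetermined" with a reason code instead of an error.
    """
    in_ctx = expr.meta["tissue"] == context
    if not in_ctx.any():
        raise DomainError(f"no samples for context {context!r}")
    samples = list(expr.meta.index[in_ctx])
    values = expr.values[samples]
    present = set(values.index)

    edges: list[SignedEdge] = []
    for e in net.edges:
        se = SignedEdge(e.tf_id, e.promoter_id, context)
        if e.tf_id not in present or e.promoter_id not in present:
            se.reason = "missing_gene"
            edges.append(se)
            continue
        x_tf = values.loc[e.tf_id].to_numpy(dtype=float)
        x_tg = values.loc[e.promoter_id].to_numpy(dtype=float)
        try:
            # target values ordered by TF ranks / TF values ordered by target ranks
            gcc_tf_ranks = gini_correlation(x_tg, x_tf)
            gcc_target_ranks = gini_correlation(x_tf, x_tg)
        except UndefinedValueError:
            se.reason = "constant_profile"
            edges.append(se)
            continue
        se.gcc_tf_ranks = gcc_tf_ranks
        se.gcc_target_ranks = gcc_target_ranks
        se.gcc = (
            gcc_tf_ranks
            if abs(gcc_tf_ranks) >= abs(gcc_target_ranks)
            else gcc_target_ranks
        )
        se.polarity = _polarity(se.gcc, threshold)
        if se.polarity == POLARITY_UNDETERMINED:
            se.reason = "below_threshold"
        edges.append(se)

    if snet is None:
        snet = SignedNetwork(base=net, threshold=threshold)
    snet.signed_edges[context] = edges
    return snet


def signed_summary(snet: SignedNetwork) -> pd.DataFrame:
    """Counts of activating/repressing/undetermined edges per context,
    with a per-functional-module breakdown (by target-node process)."""
    rows = []
    for ctx in sorted(snet.signed_edges):
        for e in snet.signed_edges[ctx]:
            process = snet.base.nodes[e.promoter_id].process or "(none)"
            rows.append({"context": ctx, "process": process, "polarity": e.polarity})
    df = pd.DataFrame(rows, columns=["context", "process", "polarity"])
    if df.empty:
        return df
    summary = (
        df.groupby(["context", "process", "polarity"]).size().rename("n").reset_index()
    )
    return summary.sort_values(["context", "process", "polarity"]).reset_index(drop=True)


def polarity_counts(snet: SignedNetwork, context: str) -> dict[str, int]:
    counts = {POLARITY_ACTIVATING: 0, POLARITY_REPRESSING: 0, POLARITY_UNDETERMINED: 0}
    for e in snet.edges_for(context):
        counts[e.polarity] += 1
    return counts
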