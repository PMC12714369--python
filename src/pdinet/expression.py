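"""Expression matrices, DEG overlay, tissue specificity, temporal clustering.

The expression model targets a nitrogen deprivation/recovery time-course
design: TPM values for genes over samples annotated with tissue, phase
(baseline at 0 h, deprivation through 24 h, recovery after nitrate
resupply), time in hours and replicate number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import ConfigurationError, DomainError
from .network import RegulatoryNetwork

META_COLUMNS = ["sample_id", "tissue", "phase", "time_h", "replicate"]
PHASES = ("baseline", "deprivation", "recovery")

# DEG thresholds: strict inequalities, symmetric in log2FC
DEFAULT_PADJ = 0.05
DEFAULT_LOG2FC = 1.0


class ExpressionMatrix:
    """TPM values (genes x samples) with per-sample metadata.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns;
    ``meta`` is a DataFrame indexed by sample_id with columns tissue,
    phase, time_h, replicate (column order matches ``values``).
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame) -> None:
        self.values = values
        self.meta = meta
        self.validate()

    def validate(self) -> None:
        missing = [s for s in self.values.columns if s not in self.meta.index]
        extra = [s for s in self.meta.index if s not in self.values.columns]
        if missing or extra:
            raise ConfigurationError(
                f"sample mismatch between matrix and metadata; "
                f"matrix-only: {missing}, metadata-only: {extra}"
            )
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            loc = np.argwhere(np.isnan(arr))[0]
            raise ConfigurationError(
                f"missing value at gene {self.values.index[loc[0]]!r}, "
                f"sample {self.values.columns[loc[1]]!r}"
            )
        if (arr < 0).any():
            loc = np.argwhere(arr < 0)[0]
            raise ConfigurationError(
                f"negative TPM at gene {self.values.index[loc[0]]!r}, "
                f"sample {self.values.columns[loc[1]]!r}"
            )
        combos = self.meta[["tissue", "phase", "time_h", "replicate"]]
        if combos.duplicated().any():
            dup = combos[combos.duplicated()].iloc[0]
            raise ConfigurationError(f"duplicate sample condition: {dup.to_dict()}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def all_zero_genes(self) -> list[str]:
        mask = (self.values.to_numpy(dtype=float) == 0).all(axis=1)
        return list(self.values.index[mask])

    def subset_samples(self, mask: pd.Series) -> "ExpressionMatrix":
        samples = list(self.meta.index[mask])
        return ExpressionMatrix(self.values[samples], self.meta.loc[samples])


def read_expression(matrix_source, meta_source) -> ExpressionMatrix:
    """Read a TPM matrix TSV (gene_id column + sample columns) and a
    sample-metadata TSV (sample_id, tissue, phase, time_h, replicate)."""
    values = pd.read_csv(matrix_source, sep="\t", index_col=0)
    meta = pd.read_csv(meta_source, sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigurationError(f"metadata is missing columns: {missing}")
    meta = meta.set_index("sample_id")
    meta["time_h"] = meta["time_h"].astype(float)
    meta["replicate"] = meta["replicate"].astype(int)
    expr = ExpressionMatrix(values, meta.loc[list(values.columns)])
    n_zero = len(expr.all_zero_genes)
    if n_zero:
        import logging

        logging.getLogger(__name__).warning(
            "%d genes have all-zero expression", n_zero
        )
    return expr


def write_expression(expr: ExpressionMatrix, matrix_path, meta_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    expr.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------
# DEG overlay


def deg_status(
    log2fc: float,
    padj: float,
    padj_threshold: float = DEFAULT_PADJ,
    log2fc_threshold: float = DEFAULT_LOG2FC,
) -> str:
    """up / down / not_de under strict thresholds (padj < t, |log2FC| > f)."""
    if padj < padj_threshold and log2fc > log2fc_threshold:
        return "up"
    if padj < padj_threshold and log2fc < -log2fc_threshold:
        return "down"
    return "not_de"


def read_deg_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    required = {"gene_id", "tissue", "time_h", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"DEG table is missing columns: {sorted(missing)}")
    return df


def overlay_degs(
    net: RegulatoryNetwork,
    degs: pd.DataFrame,
    tissue: str,
    time_h: float,
    padj_threshold: float = DEFAULT_PADJ,
    log2fc_threshold: float = DEFAULT_LOG2FC,
) -> pd.DataFrame:
    """Label every network node up/down/not_de/no_data for one context.

    Returns a per-node table (node_id, status, log2fc, padj, process);
    a per-process summary is available via :func:`overlay_summary`.
    """
    sel = degs[(degs["tissue"] == tissue) & (degs["time_h"] == time_h)]
    by_gene = {str(r["gene_id"]): r for _, r in sel.iterrows()}
    rows = []
    for nid in sorted(net.nodes):
        rec = by_gene.get(nid)
        if rec is None:
            rows.append(
                {
                    "node_id": nid,
                    "status": "no_data",
                    "log2fc": np.nan,
                    "padj": np.nan,
                    "process": net.nodes[nid].process,
                }
            )
        else:
            rows.append(
                {
                    "node_id": nid,
                    "status": deg_status(
                        float(rec["log2fc"]), float(rec["padj"]),
                        padj_threshold, log2fc_threshold,
                    ),
                    "log2fc": float(rec["log2fc"]),
                    "padj": float(rec["padj"]),
                    "process": net.nodes[nid].process,
                }
            )
    return pd.DataFrame(rows, columns=["node_id", "status", "log2fc", "padj", "process"])


def overlay_summary(overlay: pd.DataFrame) -> pd.DataFrame:
    """Status counts per functional module (process attribute)."""
    grouped = (
        overlay.assign(process=overlay["process"].replace("", "(none)"))
        .groupby(["process", "status"])
        .size()
        .unstack(fill_value=0)
    )
    return grouped.sort_index()


# ---------------------------------------------------------------------
# Tissue specificity


def tissue_specificity_gini(
    expr: ExpressionMatrix, gene_id: str, groupby: str = "tissue"
) -> float:
    """Gini inequality index over per-group mean TPM.

    G = sum_i sum_j |m_i - m_j| / (2 g^2 mbar) for g group means m_i;
    0 for perfectly equal means, (g-1)/g when a single group carries all
    expression. Returns 0.0 by convention when all means are zero.
    """
    if gene_id not in expr.values.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    groups = expr.meta[groupby]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise DomainError("tissue specificity needs >= 2 groups")
    means = np.array(
        [expr.values.loc[gene_id, list(groups.index[groups == g])].mean() for g in levels],
        dtype=float,
    )
    mbar = means.mean()
    if mbar == 0:
        return 0.0
    g = len(means)
    diff_sum = np.abs(means[:, None] - means[None, :]).sum()
    return float(diff_sum / (2 * g * g * mbar))


# ---------------------------------------------------------------------
# Temporal clustering


@dataclass
class ClusteringResult:
    assignments: pd.DataFrame  # gene_id, cluster_id
    centroids: pd.DataFrame  # cluster_id x profile columns
    skipped_genes: list[str]  # constant-profile genes excluded
    k: int
    seed: int


def mean_profiles(expr: ExpressionMatrix, tissue: str | None = None) -> pd.DataFrame:
    """Per-gene mean-over-replicates profile over (phase, time) points,
    optionally restricted to one tissue. Columns ordered by time."""
    meta = expr.meta
    if tissue is not None:
        keep = meta["tissue"] == tissue
        if not keep.any():
            raise DomainError(f"no samples for tissue {tissue!r}")
        meta = meta[keep]
    values = expr.values[list(meta.index)]
    key = meta["tissue"].astype(str) + "|" + meta["time_h"].map("{:g}".format)
    order = (
        meta.assign(_key=key)
        .drop_duplicates("_key")
        .sort_values(["tissue", "time_h"])["_key"]
        .tolist()
    )
    prof = values.T.groupby(key.values).mean().T
    return prof[order]


def cluster_profiles(
    expr: ExpressionMatrix,
    k: int = 10,
    seed: int = 0,
    tissue: str | None = None,
) -> ClusteringResult:
    """k-means clustering of z-scored mean temporal profiles.

    Replicates are averaged per (tissue, time); each gene's profile is
    z-scored before Euclidean k-means with 10 restarts. Constant-profile
    genes cannot be z-scored and are excluded and reported.
    """
    if k < 2:
        raise DomainError("k must be >= 2")
    prof = mean_profiles(expr, tissue)
    arr = prof.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    usable = sd > 0
    skipped = list(prof.index[~usable])
    z = (arr[usable] - arr[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    if z.shape[0] < k:
        raise DomainError(
            f"only {z.shape[0]} genes with non-constant profiles for k={k}"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(z)
    assignments = pd.DataFrame(
        {"gene_id": prof.index[usable], "cluster_id": labels}
    ).reset_index(drop=True)
    centroids = pd.DataFrame(km.cluster_centers_, columns=prof.columns)
    centroids.index.name = "cluster_id"
    return ClusteringResult(assignments, centroids, skipped, k, seed)
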