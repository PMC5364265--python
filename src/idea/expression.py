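"""Differential expression and fold-change-ranked gene lists.

Turns a normalized, linear-scale expression matrix (features × samples)
plus a design table into per-condition differential-expression tables
(log2 fold change, t test, BH q-value) and direction-split ranked gene
lists.  No fold-change or significance cutoff is applied when building the
ranked lists: the entire measured transcriptome is ranked by the magnitude
of its response, which is what the downstream prefix-scan enrichment
consumes.

Fold changes are the ratio of treated to time-matched-control group means
on the linear intensity scale; the t test runs on log2 intensities (Welch
by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gene_sets import normalize_gene_id

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RankedGeneList",
    "read_expression_matrix",
    "read_design",
    "condition_label",
    "list_conditions",
    "compute_fold_changes",
    "collapse_probes",
    "split_ranked_lists",
    "write_rnk",
    "read_rnk",
    "ranked_lists_from_scores",
]

DESIGN_COLUMNS = ["sample_id", "time_h", "dose_nM", "role", "replicate"]


@dataclass
class ExpressionMatrix:
    """Normalized linear-scale intensities, features × samples.

    All intensities must be strictly positive (log-ratios must exist);
    feature and sample identifiers must be unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("intensities must be finite and strictly positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RankedGeneList:
    """One direction of one condition, ordered by decreasing |log2FC|.

    Rank 1 is the most strongly responding gene.  The "up" direction holds
    only positive log2 fold changes, "down" only negative; genes with a
    fold change of exactly zero belong to neither.  Ties in |log2FC| are
    broken lexicographically by gene id so that ranks are reproducible.
    """

    genes: list[str]
    log2fc: np.ndarray
    direction: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        if len(self.genes) != len(self.log2fc):
            raise ValueError("genes and log2fc lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        mag = np.abs(self.log2fc)
        if np.any(np.diff(mag) > 0):
            raise ValueError("|log2FC| must be non-increasing along the list")
        if self.direction == "up" and np.any(self.log2fc <= 0):
            raise ValueError("'up' list must contain only positive log2FC")
        if self.direction == "down" and np.any(self.log2fc >= 0):
            raise ValueError("'down' list must contain only negative log2FC")

    @property
    def N(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers / writers

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV matrix: first column feature id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the design table (sample_id, time_h, dose_nM, role, replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table missing column(s): {', '.join(missing)}")
    bad = set(df["role"]) - {"treated", "control"}
    if bad:
        raise ValueError(f"design role must be treated|control, got: {sorted(bad)}")
    return df


def condition_label(dose_nM: float, time_h: float) -> str:
    return f"{dose_nM:g}nM_{time_h:g}h"


def list_conditions(design: pd.DataFrame) -> list[str]:
    """Condition labels (dose × time) present among treated samples."""
    treated = design[design["role"] == "treated"]
    labels = {
        condition_label(d, t) for d, t in zip(treated["dose_nM"], treated["time_h"])
    }
    return sorted(labels)


# ---------------------------------------------------------------------------
# differential expression

def compute_fold_changes(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    condition: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-feature log2 fold change and t test for one condition.

    The treated group is the samples whose (dose, time) matches
    ``condition``; the control group is every ``control`` sample at the
    same time point (time-matched controls).  log2FC is the log2 ratio of
    linear-scale group means; the t test (Welch unless ``equal_var``) runs
    on log2 intensities; q-values are BH across all features.

    Features with zero variance in both groups and equal means get p = 1
    (flagged in the ``degenerate`` column) rather than NaN.

    Returns a DataFrame indexed by feature id with columns ``log2fc``,
    ``t_stat``, ``p_value``, ``q_value``, ``mean_treated``,
    ``mean_control`` (linear-scale means) and ``degenerate``.
    """
    from .core import bh_adjust

    labels = [condition_label(d, t) for d, t in zip(design["dose_nM"], design["time_h"])]
    design = design.assign(_cond=labels)
    treated = design[(design["_cond"] == condition) & (design["role"] == "treated")]
    if treated.empty:
        raise ValueError(f"condition {condition!r} has no treated samples")
    time_h = treated["time_h"].iloc[0]
    control = design[(design["time_h"] == time_h) & (design["role"] == "control")]
    if control.empty:
        raise ValueError(f"condition {condition!r} has no time-matched control samples")
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(
            f"condition {condition!r} needs >=2 treated and >=2 control replicates "
            f"(got {len(treated)} treated, {len(control)} control)"
        )

    tvals = expr.values[list(treated["sample_id"])].to_numpy()
    cvals = expr.values[list(control["sample_id"])].to_numpy()
    log_t = np.log2(tvals)
    log_c = np.log2(cvals)

    mean_t = tvals.mean(axis=1)
    mean_c = cvals.mean(axis=1)
    # difference of logs rather than log of ratio: exact sign flip when
    # treated/control roles are swapped
    log2fc = np.log2(mean_t) - np.log2(mean_c)

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance features trigger scipy precision warnings; they are
        # patched explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pval = stats.ttest_ind(log_t, log_c, axis=1, equal_var=equal_var)

    # degenerate features: zero variance in both groups -> scipy yields NaN
    var_t = log_t.var(axis=1)
    var_c = log_c.var(axis=1)
    zero_var = (var_t == 0) & (var_c == 0)
    equal_means = np.isclose(log_t.mean(axis=1), log_c.mean(axis=1))
    degenerate = zero_var.copy()
    flat = zero_var & equal_means
    sep = zero_var & ~equal_means
    with np.errstate(invalid="ignore"):
        tstat = np.where(flat, 0.0, tstat)
        pval = np.where(flat, 1.0, pval)
        tstat = np.where(
            sep, np.sign(log_t.mean(axis=1) - log_c.mean(axis=1)) * np.inf, tstat
        )
        pval = np.where(sep, 0.0, pval)

    qval = bh_adjust(pval)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_stat": tstat,
            "p_value": pval,
            "q_value": qval,
            "mean_treated": mean_t,
            "mean_control": mean_c,
            "degenerate": degenerate,
        },
        index=pd.Index(expr.feature_ids, name="feature_id"),
    )


def collapse_probes(
    table: pd.DataFrame, probe_to_gene: dict[str, str]
) -> pd.DataFrame:
    """Collapse a probe-level DE table to gene level via representative probes.

    For each gene the representative probe is the one with maximal |log2FC|
    (ties: smaller p, then lexicographically smaller probe id); all
    statistics for the gene are taken from that probe.  Unmapped probes are
    dropped with a logged count.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    mapping = {str(p): normalize_gene_id(g) for p, g in probe_to_gene.items()}
    mapped = table.index.astype(str).map(mapping)
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        logger.info("dropping %d unmapped probe(s)", n_unmapped)
    out = table.assign(gene=mapped).dropna(subset=["gene"])
    out = out.assign(_probe=out.index.astype(str), _absfc=out["log2fc"].abs())
    out = out.sort_values(
        ["_absfc", "p_value", "_probe"], ascending=[False, True, True], kind="mergesort"
    )
    out = out.drop_duplicates("gene", keep="first")
    out = out.set_index("gene").drop(columns=["_absfc"]).rename(
        columns={"_probe": "probe_id"}
    )
    return out.sort_index()


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV probe_id -> gene_symbol ('#' comments ignored)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["probe_id", "gene"],
        dtype=str,
    )
    return dict(zip(df["probe_id"], df["gene"]))


def split_ranked_lists(
    table: pd.DataFrame, metadata: dict | None = None
) -> tuple[RankedGeneList, RankedGeneList]:
    """Split a gene-level DE table into up/down ranked lists.

    Genes with positive log2FC go to the "up" list, negative to "down",
    exactly zero to neither; each list is sorted by decreasing |log2FC|
    with lexicographic gene-id tie-break.  No significance or fold-change
    threshold is applied.
    """
    metadata = dict(metadata or {})
    genes = table.index.astype(str)
    fc = table["log2fc"].to_numpy(dtype=float)

    def build(mask: np.ndarray, direction: str) -> RankedGeneList:
        sub = sorted(
            zip(genes[mask], fc[mask]), key=lambda gf: (-abs(gf[1]), gf[0])
        )
        return RankedGeneList(
            genes=[g for g, _ in sub],
            log2fc=np.array([f for _, f in sub], dtype=float),
            direction=direction,
            metadata=metadata,
        )

    return build(fc > 0, "up"), build(fc < 0, "down")


# ---------------------------------------------------------------------------
# RNK interoperability

def write_rnk(ranked: RankedGeneList, path: str | Path, header: list[str] | None = None) -> None:
    """Write a two-column RNK file (gene <TAB> signed log2FC)."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        for g, f in zip(ranked.genes, ranked.log2fc):
            fh.write(f"{g}\t{f:.10g}\n")


def read_rnk(path: str | Path) -> pd.DataFrame:
    """Read an RNK file into a gene/score DataFrame (comments ignored)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["gene", "score"],
        dtype={"gene": str},
    )
    df["gene"] = df["gene"].map(normalize_gene_id)
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].unique()
        raise ValueError(f"{path}: duplicate gene(s) in RNK: {dups[:5]}")
    return df


def ranked_lists_from_scores(
    df: pd.DataFrame, metadata: dict | None = None
) -> list[RankedGeneList]:
    """Build ranked lists from a gene/score table; empty directions omitted."""
    table = df.set_index("gene").rename(columns={"score": "log2fc"})
    up, down = split_ranked_lists(table, metadata)
    return [rl for rl in (up, down) if rl.N > 0]
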