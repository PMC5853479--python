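"""Two-cell-type expression filtering, classification and enrichment.

Operates on a genes x samples log2-normalised expression matrix
(log2(NREL)) with a cell-type label per sample.  Implements the
expressed-gene threshold (mean log2 >= 2 per type), the differential
filter (|linear fold change| >= 1.5 and P < 0.05, raw P, no multiple
testing correction), the transporter high-expression classification
(mean log2 >= 3.5) and a one-tailed hypergeometric over-representation
test as a stand-in for web-tool enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ExpressionMatrix",
    "VennSummary",
    "TransporterClassification",
    "DifferentialExpressionFilter",
    "expressed_genes",
    "venn_summary",
    "differential_expression",
    "classify_transporters",
    "enrichment",
    "read_expression_matrix",
    "write_expression_matrix",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with labels and annotations.

    ``data``: DataFrame indexed by gene id, one column per sample;
    ``sample_types``: Series mapping sample id -> cell-type label;
    ``annotations``: optional per-gene DataFrame with at least a
    ``category`` column and an integer ``transporter`` flag.
    """

    data: pd.DataFrame
    sample_types: pd.Series
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        missing = [s for s in self.data.columns if s not in self.sample_types.index]
        if missing:
            raise ValueError(f"samples without a cell-type label: {missing}")
        counts = self.sample_types.loc[list(self.data.columns)].value_counts()
        if (counts < 2).any():
            raise ValueError("every cell type needs >= 2 replicates")

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.sample_types.loc[list(self.data.columns)]))

    def samples_of(self, cell_type: str) -> list[str]:
        cols = [s for s in self.data.columns if self.sample_types[s] == cell_type]
        if not cols:
            raise KeyError(f"unknown cell type {cell_type!r}")
        return cols

    def type_means(self, cell_type: str) -> pd.Series:
        """Per-gene mean log2 expression over one cell type's replicates."""
        return self.data[self.samples_of(cell_type)].mean(axis=1)


def expressed_genes(matrix: ExpressionMatrix, cell_type: str,
                    threshold: float = 2.0) -> set:
    """Genes whose mean log2 over the type's replicates is >= threshold."""
    means = matrix.type_means(cell_type)
    return set(means.index[means >= threshold])


@dataclass
class VennSummary:
    a_only: int
    b_only: int
    common: int

    @property
    def union(self) -> int:
        return self.a_only + self.b_only + self.common

    @property
    def percent_common(self) -> int:
        """100 * |A ∩ B| / |A ∪ B|, rounded to the nearest integer."""
        if self.union == 0:
            return 0
        return int(round(100.0 * self.common / self.union))


def venn_summary(set_a, set_b) -> VennSummary:
    """Two-set overlap counts and percent-common-of-union."""
    a, b = set(set_a), set(set_b)
    common = len(a & b)
    return VennSummary(a_only=len(a) - common, b_only=len(b) - common, common=common)


class DifferentialExpressionFilter(BaseEstimator):
    """Two-group differential-expression filter on log2 values.

    Per gene: a pooled-variance two-sample t-test (the two-group special
    case of one-way ANOVA) on log2 replicate values, a signed linear fold
    change 2^(mean_a - mean_b) reported as -1/ratio when the ratio is
    below 1, and two pass flags:

    * ``passed_de`` — |fold change| >= ``fc_threshold`` (inclusive) and
      P < ``alpha`` (strict);
    * ``passed_p_only`` — P <= ``alpha`` with no fold-change restriction.

    Raw P-values are used by design (no multiple-testing correction);
    set ``correction="bh"`` to add Benjamini-Hochberg adjusted P-values
    as an extra column (the flags still use raw P).

    Zero within-group variance makes the t statistic undefined; such genes
    get the fallback P (0 when the group means differ, 1 when equal) and
    ``p_fallback = True``.
    """

    def __init__(self, fc_threshold: float = 1.5, alpha: float = 0.05,
                 correction: str | None = None):
        self.fc_threshold = fc_threshold
        self.alpha = alpha
        self.correction = correction

    def fit(self, X, y):
        """Fit from ``X`` (samples x genes) and cell-type labels ``y``."""
        X = pd.DataFrame(X)
        y = np.asarray(y)
        groups = list(pd.unique(y))
        if len(groups) != 2:
            raise ValueError(f"exactly two cell types required, got {groups}")
        ga, gb = groups
        a = X.loc[y == ga].to_numpy(dtype=float)
        b = X.loc[y == gb].to_numpy(dtype=float)
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("need >= 2 replicates per cell type")

        mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
        delta = mean_a - mean_b
        import warnings
        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            # near-zero-variance genes trigger scipy precision warnings; they
            # are routed through the fallback rule below
            warnings.simplefilter("ignore", RuntimeWarning)
            t = stats.ttest_ind(a, b, axis=0, equal_var=True)
        p = t.pvalue.copy()
        var_zero = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
        fallback = var_zero | ~np.isfinite(p)
        p[fallback & (delta != 0)] = 0.0
        p[fallback & (delta == 0)] = 1.0

        ratio = np.power(2.0, delta)
        signed_fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
        res = pd.DataFrame({
            f"mean_{ga}": mean_a,
            f"mean_{gb}": mean_b,
            "signed_fold_change": signed_fc,
            "p_value": p,
            "p_fallback": fallback,
        }, index=X.columns)
        if self.correction == "bh":
            res["p_adjusted"] = _benjamini_hochberg(p)
        # inclusive fold-change gate, with a guard so a gene sitting exactly
        # on the threshold is not dropped by float rounding of 2**delta
        res["passed_de"] = (np.abs(signed_fc) >= self.fc_threshold - 1e-9) & \
            (p < self.alpha)
        res["passed_p_only"] = p <= self.alpha
        self.groups_ = (ga, gb)
        self.results_ = res
        return self


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def differential_expression(matrix: ExpressionMatrix, fc_threshold: float = 1.5,
                            alpha: float = 0.05,
                            correction: str | None = None) -> pd.DataFrame:
    """Per-gene differential result between the matrix's two cell types.

    The fold-change sign is positive when the gene is higher in the first
    cell type (order of appearance in the sample labels).
    """
    filt = DifferentialExpressionFilter(
        fc_threshold=fc_threshold, alpha=alpha, correction=correction
    ).fit(matrix.data.T, matrix.sample_types.loc[list(matrix.data.columns)].to_numpy())
    return filt.results_


@dataclass
class TransporterClassification:
    """High-expression x differential classification of transporter genes.

    Among transporter genes in the P <= alpha differential set:
    group A — highly expressed (mean log2 >= threshold) in the second
    cell type only; group B — highly expressed in the first type only;
    group C — highly expressed in both.  A, B and C are disjoint by
    construction.
    """

    group_a: set
    group_b: set
    group_c: set
    table: pd.DataFrame
    high_threshold: float

    def group_of(self, gene) -> str | None:
        for name, g in (("A", self.group_a), ("B", self.group_b), ("C", self.group_c)):
            if gene in g:
                return name
        return None


def classify_transporters(matrix: ExpressionMatrix, transporter_flags: pd.Series,
                          de_results: pd.DataFrame, high_threshold: float = 3.5,
                          alpha: float = 0.05) -> TransporterClassification:
    """Classify differential transporter genes by where they are highly expressed.

    ``transporter_flags`` is a boolean/0-1 Series over gene ids; the
    differential set uses the P <= alpha rule without a fold-change gate.
    The first cell type in the matrix plays the "B" role (high there only),
    the second the "A" role, matching a BSC-first sample ordering.
    """
    type_a, type_b = matrix.cell_types[:2]
    tg = set(transporter_flags.index[transporter_flags.astype(bool)])
    mean_a = matrix.type_means(type_a)
    mean_b = matrix.type_means(type_b)
    diff = set(de_results.index[de_results["p_value"] <= alpha]) & tg
    high_a = set(mean_a.index[mean_a >= high_threshold]) & tg
    high_b = set(mean_b.index[mean_b >= high_threshold]) & tg
    group_c = diff & high_a & high_b
    group_b = (diff & high_a) - high_b
    group_a = (diff & high_b) - high_a
    rows = []
    for g in sorted(tg):
        rows.append({
            "gene_id": g,
            f"high_{type_a}": g in high_a,
            f"high_{type_b}": g in high_b,
            "differential": g in diff,
            "group": ("A" if g in group_a else "B" if g in group_b
                      else "C" if g in group_c else ""),
        })
    table = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()
    return TransporterClassification(
        group_a=group_a, group_b=group_b, group_c=group_c,
        table=table, high_threshold=high_threshold,
    )


def enrichment(de_genes, categories: pd.Series, background, alpha: float = 0.05,
               de_signs: pd.Series | None = None) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation per category.

    A stand-in for web-tool functional enrichment: for each category with
    members in ``background``, P = P(overlap >= observed) under the
    hypergeometric null of drawing |DE| genes from the background.
    ``categories`` maps gene id -> category label; ``de_signs`` (optional,
    sign of the fold change) adds a higher/lower direction split.

    Columns: n_category, n_de_in_category, n_de, n_background, p_value,
    enriched (P < alpha), n_higher, n_lower.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    de = set(de_genes)
    if not de <= background:
        raise ValueError("DE set must be a subset of the background")
    cats = categories.loc[categories.index.intersection(list(background))]
    rows = []
    m = len(background)
    n_de = len(de)
    for cat, members in cats.groupby(cats).groups.items():
        members = set(members)
        k = len(members & de)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_de)) if n_de else 1.0
        row = {
            "category": cat, "n_category": len(members), "n_de_in_category": k,
            "n_de": n_de, "n_background": m, "p_value": min(p, 1.0),
            "enriched": p < alpha,
        }
        if de_signs is not None:
            in_cat = [g for g in members & de]
            signs = de_signs.loc[in_cat]
            row["n_higher"] = int((signs > 0).sum())
            row["n_lower"] = int((signs < 0).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.set_index("category").sort_values("p_value")
    return out


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def write_expression_matrix(matrix: ExpressionMatrix, matrix_path,
                            annotation_path=None) -> None:
    """Write the tab-delimited matrix (genes x samples) and annotations.

    Sample cell types are encoded in the header as ``<type>_<replicate>``.
    """
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(matrix_path, sep="\t", index_label="gene_id")
    if annotation_path is not None and matrix.annotations is not None:
        matrix.annotations.to_csv(annotation_path, sep="\t", index_label="gene_id")


def read_expression_matrix(matrix_path, annotation_path=None) -> ExpressionMatrix:
    """Read the dialect written by :func:`write_expression_matrix`."""
    data = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    sample_types = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in data.columns}, name="cell_type"
    )
    ann = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col="gene_id")
    return ExpressionMatrix(data=data, sample_types=sample_types, annotations=ann)
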